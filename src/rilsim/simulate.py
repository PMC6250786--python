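"""Forward-in-time simulation of recombinant inbred line cross designs.

Two breeding designs are modelled for a selfing hermaphrodite / X0-male
species:

* **AI-RIL** (advanced-intercross RIL): a P0 inter-population cross, several
  rounds of sibling mating in small populations (default 7, with 3 mated
  hermaphrodites per round), then single-hermaphrodite selfing (default 10
  generations) to drive the nuclear genome to homozygosity.
* **F2 RIL**: the same P0 cross with minimal intercrossing (default 2 sibling
  mating rounds, 1 mated hermaphrodite) before the same selfing phase.

Meiosis uses an obligate single crossover per bivalent at a uniform position —
the expectation under the strong crossover interference of *Caenorhabditis* —
with a Poisson alternative for sensitivity analysis.  Males transmit their
single X intact to half of their sperm (X-bearing → hermaphrodite offspring)
and no X to the other half (→ X0 male offspring).  Mitochondria are strictly
maternal.

Selection is modelled as viability: each offspring survives with probability
equal to its fitness under a multiplicative Dobzhansky-Muller incompatibility
(DMI) model.  Each DMI term names two loci (either may be the mitochondrial
genome), the incompatible allele at each, a penalty ``s`` and a trigger rule
(recessive: homozygous or hemizygous at nuclear loci; dominant: any copy).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (
    HERMAPHRODITE,
    MALE,
    POPULATIONS,
    GenomeSpec,
    GenotypeTable,
    Haplotype,
    Individual,
    LineRecord,
    Marker,
    Segment,
    ValidationError,
    default_genome_spec,
    founder,
    genotype_at,
    merge_segments,
)

__all__ = [
    "CrossoverModel", "DMITerm", "DMIModel", "CrossDesign", "RunLog",
    "gamete", "cross", "self_fertilize", "viability", "run_design",
    "ExtinctionError",
]


class ExtinctionError(RuntimeError):
    """The DMI model is effectively lethal for the design: replicates cannot finish."""


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class CrossoverModel:
    """Crossover count model per bivalent.

    ``obligate_single`` places exactly one breakpoint, uniform over the
    chromosome; ``poisson`` draws the breakpoint count from Poisson(``rate``).
    """

    mode: str = "obligate_single"
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("obligate_single", "poisson"):
            raise ValidationError(f"unknown crossover mode {self.mode!r}")
        if self.mode == "poisson" and (self.rate is None or self.rate < 0):
            raise ValidationError("poisson mode needs a non-negative rate")


def _recombine(a: tuple[Segment, ...], b: tuple[Segment, ...], length: int,
               model: CrossoverModel, rng: np.random.Generator) -> tuple[Segment, ...]:
    """One recombinant chromatid from the parental pair (a, b)."""
    if model.mode == "obligate_single":
        cuts = [int(rng.integers(length))]
    else:
        n = int(rng.poisson(model.rate))
        cuts = sorted(int(rng.integers(length)) for _ in range(n))
    lead = int(rng.integers(2))
    if not cuts:
        return a if lead == 0 else b
    out: list[Segment] = []
    strands = (a, b)
    pos = 0
    for cut in [*cuts, length]:
        if cut > pos:
            strand = strands[lead]
            for s, e, anc in strand:
                if e <= pos or s >= cut:
                    continue
                out.append((max(s, pos), min(e, cut), anc))
            pos = cut
        lead ^= 1
    return merge_segments(out)


@dataclass(slots=True)
class Gamete:
    autosomes: list[Haplotype]      # one haplotype per autosome
    x: Haplotype | None             # None for nullo-X sperm


def gamete(parent: Individual, crossover_model: CrossoverModel,
           rng: np.random.Generator,
           genome_spec: GenomeSpec | None = None) -> Gamete:
    """One meiotic product.  No crossover occurs on a male's hemizygous X;
    he transmits it intact in half of his gametes and no X otherwise."""
    gs = genome_spec or default_genome_spec()
    autosomes = []
    for name, (h1, h2) in zip(gs.autosome_names, parent.autosomes):
        segs = _recombine(h1.segments, h2.segments, gs[name].length,
                          crossover_model, rng)
        autosomes.append(Haplotype(name, segs))
    if parent.sex == MALE:
        x = parent.x_haplotypes[0] if rng.random() < 0.5 else None
    else:
        x1, x2 = parent.x_haplotypes
        x = Haplotype("X", _recombine(x1.segments, x2.segments, gs["X"].length,
                                      crossover_model, rng))
    return Gamete(autosomes=autosomes, x=x)


# ---------------------------------------------------------------------------
# matings
# ---------------------------------------------------------------------------

def _zygote(egg: Gamete, sperm: Gamete, mitotype: str) -> Individual:
    if sperm.x is not None:
        return Individual(sex=HERMAPHRODITE,
                          autosomes=list(zip(egg.autosomes, sperm.autosomes)),
                          x_haplotypes=[egg.x, sperm.x], mitotype=mitotype)
    return Individual(sex=MALE,
                      autosomes=list(zip(egg.autosomes, sperm.autosomes)),
                      x_haplotypes=[egg.x], mitotype=mitotype)


def cross(male: Individual, herm: Individual, n_offspring: int,
          crossover_model: CrossoverModel, rng: np.random.Generator,
          genome_spec: GenomeSpec | None = None) -> list[Individual]:
    """Mate a male to a (pseudofemale) hermaphrodite.

    Offspring mitotype is maternal; X-bearing sperm yield XX hermaphrodites,
    nullo-X sperm yield X0 males.
    """
    if male.sex != MALE or herm.sex != HERMAPHRODITE:
        raise ValidationError("cross() requires (male, hermaphrodite) in that order")
    gs = genome_spec or default_genome_spec()
    return [_zygote(gamete(herm, crossover_model, rng, gs),
                    gamete(male, crossover_model, rng, gs), herm.mitotype)
            for _ in range(n_offspring)]


def self_fertilize(herm: Individual, n_offspring: int,
                   crossover_model: CrossoverModel, rng: np.random.Generator,
                   genome_spec: GenomeSpec | None = None) -> list[Individual]:
    """Self a hermaphrodite: ova and self-sperm drawn independently.

    All selfed offspring are hermaphrodites here (rare X-nondisjunction males
    are ignored); the mitotype is preserved.
    """
    if herm.sex != HERMAPHRODITE:
        raise ValidationError("self_fertilize() requires a hermaphrodite")
    gs = genome_spec or default_genome_spec()
    out = []
    for _ in range(n_offspring):
        egg = gamete(herm, crossover_model, rng, gs)
        sperm = gamete(herm, crossover_model, rng, gs)
        out.append(Individual(sex=HERMAPHRODITE,
                              autosomes=list(zip(egg.autosomes, sperm.autosomes)),
                              x_haplotypes=[egg.x, sperm.x],
                              mitotype=herm.mitotype))
    return out


# ---------------------------------------------------------------------------
# DMI fitness
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class DMITerm:
    """One two-locus incompatibility: penalty ``s`` applies when the individual
    matches ``allele_a`` at ``locus_a`` and ``allele_b`` at ``locus_b`` under
    the trigger rule.  A locus is ``(chromosome, position)``; use chromosome
    ``"MT"`` (position ignored) for the mitochondrial side, allowed on at most
    one side of a term."""

    chrom_a: str
    pos_a: int
    allele_a: str
    chrom_b: str
    pos_b: int
    allele_b: str
    s: float
    trigger: str = "recessive"  # recessive | dominant

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValidationError(f"penalty s={self.s} outside [0, 1]")
        if self.trigger not in ("recessive", "dominant"):
            raise ValidationError(f"unknown trigger {self.trigger!r}")
        if self.chrom_a == "MT" and self.chrom_b == "MT":
            raise ValidationError("MT allowed on at most one side of a DMI term")
        for allele in (self.allele_a, self.allele_b):
            if allele not in POPULATIONS:
                raise ValidationError(f"unknown allele {allele!r}")


@dataclass(frozen=True)
class DMIModel:
    """Multiplicative composition of DMI terms; fitness stays in [0, 1]."""

    terms: tuple[DMITerm, ...] = ()

    def __init__(self, terms: Sequence[DMITerm] = ()):
        object.__setattr__(self, "terms", tuple(terms))


def _locus_alleles(ind: Individual, chrom: str, pos: int,
                   gs: GenomeSpec) -> list[str]:
    if chrom == "MT":
        return [ind.mitotype]
    if chrom == "X":
        return [h.ancestry_at(pos) for h in ind.x_haplotypes]
    if chrom not in gs:
        raise ValidationError(f"DMI locus on unknown chromosome {chrom!r}")
    idx = gs.autosome_names.index(chrom)
    pair = ind.autosomes[idx]
    return [pair[0].ancestry_at(pos), pair[1].ancestry_at(pos)]


def _matches(ind: Individual, chrom: str, pos: int, allele: str, trigger: str,
             gs: GenomeSpec) -> bool:
    alleles = _locus_alleles(ind, chrom, pos, gs)
    if chrom == "MT" or trigger == "dominant":
        return allele in alleles
    # recessive: homozygous, or hemizygous on the male X
    return all(a == allele for a in alleles)


def viability(individual: Individual, dmi: DMIModel,
              genome_spec: GenomeSpec | None = None) -> float:
    """Fitness in [0, 1]: product of (1 - s) over triggered DMI terms."""
    gs = genome_spec or default_genome_spec()
    w = 1.0
    for t in dmi.terms:
        if (_matches(individual, t.chrom_a, t.pos_a, t.allele_a, t.trigger, gs)
                and _matches(individual, t.chrom_b, t.pos_b, t.allele_b, t.trigger, gs)):
            w *= 1.0 - t.s
    return w


# ---------------------------------------------------------------------------
# cross designs
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class CrossDesign:
    """Breeding schedule for one reciprocal direction (male_pop x herm_pop)."""

    male_pop: str
    herm_pop: str
    name: str = "AI-RIL"
    sib_mating_generations: int = 7
    selfing_generations: int = 10
    hermaphrodites_per_generation: int = 3
    brood_size: int = 10
    replicates: int = 20
    self_to_fixation: bool = False

    def __post_init__(self) -> None:
        if self.male_pop == self.herm_pop:
            raise ValidationError("male_pop and herm_pop must differ")
        for attr in ("sib_mating_generations", "selfing_generations",
                     "hermaphrodites_per_generation", "brood_size", "replicates"):
            if getattr(self, attr) < 1:
                raise ValidationError(f"{attr} must be positive")

    @classmethod
    def ai_ril(cls, male_pop: str, herm_pop: str, replicates: int = 20,
               **kwargs) -> "CrossDesign":
        return cls(male_pop, herm_pop, name="AI-RIL", sib_mating_generations=7,
                   hermaphrodites_per_generation=3, replicates=replicates, **kwargs)

    @classmethod
    def f2_ril(cls, male_pop: str, herm_pop: str, replicates: int = 20,
               **kwargs) -> "CrossDesign":
        return cls(male_pop, herm_pop, name="F2RIL", sib_mating_generations=2,
                   hermaphrodites_per_generation=1, replicates=replicates, **kwargs)


@dataclass
class RunLog:
    """Per-replicate bookkeeping: restarts and final selfing generation."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["replicate", "restarts",
                                                "selfing_generations",
                                                "extinctions"])


_MAX_RESTARTS = 100
_FIXATION_GRACE = 500  # extra selfing generations allowed under self_to_fixation


def _survivors(offspring: list[Individual], dmi: DMIModel, gs: GenomeSpec,
               rng: np.random.Generator) -> list[Individual]:
    if not dmi.terms:
        return offspring
    out = []
    for ind in offspring:
        w = viability(ind, dmi, gs)
        if w >= 1.0 or rng.random() < w:
            out.append(ind)
    return out


def _nuclear_homozygous(ind: Individual, panel: Sequence[Marker],
                        gs: GenomeSpec) -> bool:
    return all(genotype_at(ind, m, gs) != "AH"
               for m in panel if m.chromosome != "MT")


def _run_replicate(design: CrossDesign, dmi: DMIModel, panel: Sequence[Marker],
                   gs: GenomeSpec, xo: CrossoverModel,
                   rng: np.random.Generator) -> tuple[Individual, int] | None:
    """One replicate line; None signals extinction (caller restarts)."""
    male = founder(design.male_pop, MALE, gs)
    herm = founder(design.herm_pop, HERMAPHRODITE, gs)
    pool = _survivors(cross(male, herm, design.brood_size, xo, rng, gs), dmi, gs, rng)
    k = design.hermaphrodites_per_generation
    for _ in range(design.sib_mating_generations):
        herms = [i for i in pool if i.is_hermaphrodite]
        males = [i for i in pool if not i.is_hermaphrodite]
        if len(herms) < k or len(males) < k:
            return None
        chosen_h = [herms[j] for j in rng.permutation(len(herms))[:k]]
        chosen_m = [males[j] for j in rng.permutation(len(males))[:k]]
        brood: list[Individual] = []
        for m, h in zip(chosen_m, chosen_h):
            brood.extend(cross(m, h, design.brood_size, xo, rng, gs))
        pool = _survivors(brood, dmi, gs, rng)
    herms = [i for i in pool if i.is_hermaphrodite]
    if not herms:
        return None
    line = herms[int(rng.integers(len(herms)))]
    g = 0
    while True:
        if g >= design.selfing_generations:
            if not design.self_to_fixation or _nuclear_homozygous(line, panel, gs):
                return line, g
            if g >= design.selfing_generations + _FIXATION_GRACE:
                return None
        brood = _survivors(self_fertilize(line, design.brood_size, xo, rng, gs),
                           dmi, gs, rng)
        if not brood:
            return None
        line = brood[int(rng.integers(len(brood)))]
        g += 1


def run_design(design: CrossDesign, dmi: DMIModel | None = None,
               panel: Sequence[Marker] | None = None, seed: int = 0,
               crossover_model: CrossoverModel | None = None,
               genome_spec: GenomeSpec | None = None,
               ) -> tuple[GenotypeTable, RunLog]:
    """Simulate every replicate of a design and genotype the final lines.

    Replicate ``r`` uses the RNG substream ``(seed, r, restart)``, so replicates
    are independent, individually reproducible, and extinct attempts restart on
    a fresh substream (restarts are logged so conditioning bias is measurable).
    Identical (design, dmi, panel, seed) inputs give a bit-identical table.
    """
    dmi = dmi or DMIModel()
    gs = genome_spec or default_genome_spec()
    from .genome import default_marker_panel  # local to avoid import cycle noise
    panel = list(panel) if panel is not None else default_marker_panel(gs)
    xo = crossover_model or CrossoverModel()
    table = GenotypeTable(markers=panel)
    log = RunLog()
    direction = f"{design.male_pop}x{design.herm_pop}"
    for r in range(design.replicates):
        result = None
        for restart in itertools.count():
            if restart >= _MAX_RESTARTS:
                raise ExtinctionError(
                    f"replicate {r} of {design.name} {direction} went extinct "
                    f"{_MAX_RESTARTS} times; the DMI model appears lethal for "
                    "this design")
            rng = np.random.default_rng([seed, r, restart])
            result = _run_replicate(design, dmi, panel, gs, xo, rng)
            if result is not None:
                break
        line, final_g = result
        calls = tuple(genotype_at(line, m, gs) for m in panel)
        table.append(LineRecord(
            line_id=f"{design.name}_{direction}_r{r:03d}",
            design=design.name, male_pop=design.male_pop,
            herm_pop=design.herm_pop, mitotype=line.mitotype, calls=calls))
        log.rows.append({"replicate": r, "restarts": restart,
                         "selfing_generations": final_g, "extinctions": restart})
    return table, log
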