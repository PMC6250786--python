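"""Synthetic genotype-table fixtures.

Raw line-level genotype data for experiments of this kind are rarely
available in machine-readable form, so this module generates tables carrying the same
statistical structure — replicate counts, exact fixed-line allele fractions,
maternal mitotypes, co-segregating (complete-LD) marker blocks — for use in
tests and worked examples.  Exact-count fixtures hit requested fractions
exactly; the Bernoulli neutral fixture converges at 1/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    GenotypeTable,
    LineRecord,
    Marker,
    ValidationError,
    default_marker_panel,
)

__all__ = ["FixtureSpec", "make_table", "study_fixture_suite", "neutral_fixture"]


@dataclass
class FixtureSpec:
    """Recipe for an exact-count genotype table.

    ``focal_counts`` maps marker name -> number of lines fixed for the focal
    (default HK104) allele; unlisted nuclear markers default to 0.  Marker
    groups in ``coupled`` receive identical per-line assignments (complete
    co-segregation) and must therefore share a count.  ``het_lines`` lines are
    left heterozygous at every nuclear marker (unfixed lines); counts apply to
    the remaining homozygous lines.
    """

    n_lines: int
    design: str
    male_pop: str
    herm_pop: str
    focal_counts: Mapping[str, int] = field(default_factory=dict)
    coupled: Sequence[Sequence[str]] = ()
    het_lines: int = 0
    focal_pop: str = "HK104"
    markers: Sequence[Marker] | None = None  # default: bundled panel
    line_prefix: str | None = None
    seed: int = 0

    @property
    def mitotype(self) -> str:
        return self.herm_pop  # maternal inheritance


def _fixed_call(pop: str) -> str:
    return pop[0] * 2


def make_table(spec: FixtureSpec) -> GenotypeTable:
    """Build the table: line-to-allele assignment is randomized by seed but the
    per-marker counts are exact and deterministic per seed."""
    markers = list(spec.markers) if spec.markers is not None else default_marker_panel()
    nuclear = [m.name for m in markers if m.chromosome != "MT"]
    if spec.het_lines < 0 or spec.het_lines > spec.n_lines:
        raise ValidationError("het_lines outside [0, n_lines]")
    n_hom = spec.n_lines - spec.het_lines
    for name, count in spec.focal_counts.items():
        if name not in nuclear:
            raise ValidationError(f"count given for unknown/non-nuclear marker {name!r}")
        if not 0 <= count <= n_hom:
            raise ValidationError(f"{name}: count {count} outside [0, {n_hom}]")
    group_of: dict[str, int] = {}
    for gi, group in enumerate(spec.coupled):
        counts = {spec.focal_counts.get(name, 0) for name in group}
        if len(counts) > 1:
            raise ValidationError(
                f"coupled markers {tuple(group)} have differing counts {sorted(counts)}")
        for name in group:
            group_of[name] = gi
    rng = np.random.default_rng(spec.seed)
    other_pop = "AF16" if spec.focal_pop == "HK104" else "HK104"
    # het lines occupy the tail indices; homozygous assignment over the head
    assignment: dict[str, np.ndarray] = {}
    group_perm: dict[int, np.ndarray] = {}
    for name in nuclear:
        count = spec.focal_counts.get(name, 0)
        gi = group_of.get(name)
        if gi is not None:
            if gi not in group_perm:
                group_perm[gi] = rng.permutation(n_hom)
            perm = group_perm[gi]
        else:
            perm = rng.permutation(n_hom)
        focal = np.zeros(n_hom, dtype=bool)
        focal[perm[:count]] = True
        assignment[name] = focal
    prefix = spec.line_prefix or f"{spec.design}_{spec.male_pop}x{spec.herm_pop}"
    table = GenotypeTable(markers=markers)
    for i in range(spec.n_lines):
        calls = []
        for m in markers:
            if m.chromosome == "MT":
                calls.append(_fixed_call(spec.mitotype))
            elif i >= n_hom:
                calls.append("AH")
            else:
                focal = assignment[m.name][i]
                calls.append(_fixed_call(spec.focal_pop if focal else other_pop))
        table.append(LineRecord(line_id=f"{prefix}_r{i:03d}", design=spec.design,
                                male_pop=spec.male_pop, herm_pop=spec.herm_pop,
                                mitotype=spec.mitotype, calls=tuple(calls)))
    return table


def study_fixture_suite(seed: int = 0,
                        panel: Sequence[Marker] | None = None,
                        ) -> dict[str, GenotypeTable]:
    """Four tables with the structure of the two genotyping experiments.

    Experiment 1 (AI-RIL, reciprocal directions, 19 and 20 lines): the
    HK104-mitotype table fixes HK104 at cb-m124/cb-m127 in every line, couples
    the mid-chromosome-III marker cb-m205 to the X block (complete
    co-segregation), sets the third X marker near-absolute (17/19), and biases
    the remaining autosomes to 80% HK104-fixed lines (genome-wide HK104 bias in
    that direction is a qualitative feature being emulated; 80% is an
    assumption of this generator, not a measured value).  The AF16-mitotype
    table excludes HK104 from all three X markers and leaves autosomes
    unbiased.

    Experiment 2 (F2 RIL, 9 and 12 lines): genotyped only at the X-linked
    cb51757, with 4/9 and 1/12 lines HK104-fixed (fractions 0.44 and 0.08).
    """
    panel = list(panel) if panel is not None else default_marker_panel()
    by_name = {m.name: m for m in panel}
    # experiment 1 scored the nine AFLP markers plus the mitochondrial RFLP;
    # cb51757 was only scored in the F2 RIL experiment
    exp1_markers = [m for m in panel if m.name != "cb51757"]
    exp2_markers = [by_name["cb18178"], by_name["cb51757"]]
    autosomal = [m.name for m in panel
                 if m.chromosome not in ("X", "MT") and m.name != "cb-m205"]
    hk_counts = {"cb-m124": 19, "cb-m127": 19, "cb-m205": 19, "cb-m197": 17}
    hk_counts.update({name: round(0.8 * 19) for name in autosomal})
    suite = {
        "AI-RIL_AF16xHK104": make_table(FixtureSpec(
            n_lines=19, design="AI-RIL", male_pop="AF16", herm_pop="HK104",
            focal_counts=hk_counts,
            coupled=[["cb-m205", "cb-m124", "cb-m127"]],
            markers=exp1_markers, seed=seed)),
        "AI-RIL_HK104xAF16": make_table(FixtureSpec(
            n_lines=20, design="AI-RIL", male_pop="HK104", herm_pop="AF16",
            focal_counts={**{name: 10 for name in autosomal}, "cb-m205": 10,
                          "cb-m124": 0, "cb-m127": 0, "cb-m197": 0},
            markers=exp1_markers, seed=seed + 1)),
        "F2RIL_AF16xHK104": make_table(FixtureSpec(
            n_lines=9, design="F2RIL", male_pop="AF16", herm_pop="HK104",
            focal_counts={"cb51757": 4}, markers=exp2_markers, seed=seed + 2)),
        "F2RIL_HK104xAF16": make_table(FixtureSpec(
            n_lines=12, design="F2RIL", male_pop="HK104", herm_pop="AF16",
            focal_counts={"cb51757": 1}, markers=exp2_markers, seed=seed + 3)),
    }
    return suite


def neutral_fixture(n_lines: int, panel: Sequence[Marker] | None = None,
                    seed: int = 0, design: str = "AI-RIL",
                    male_pop: str = "AF16", herm_pop: str = "HK104",
                    ) -> GenotypeTable:
    """Null-distribution fixture: each line independently fixes either allele
    at each autosomal marker with probability 1/2 and the maternal allele at
    each X marker with probability 2/3 (markers independent across lines)."""
    if n_lines < 1:
        raise ValidationError("n_lines must be >= 1")
    panel = list(panel) if panel is not None else default_marker_panel()
    rng = np.random.default_rng(seed)
    paternal = male_pop
    table = GenotypeTable(markers=panel)
    for i in range(n_lines):
        calls = []
        for m in panel:
            if m.chromosome == "MT":
                calls.append(_fixed_call(herm_pop))
            elif m.chromosome == "X":
                pop = herm_pop if rng.random() < 2.0 / 3.0 else paternal
                calls.append(_fixed_call(pop))
            else:
                calls.append(_fixed_call(herm_pop if rng.random() < 0.5 else paternal))
        table.append(LineRecord(line_id=f"neutral_r{i:05d}", design=design,
                                male_pop=male_pop, herm_pop=herm_pop,
                                mitotype=herm_pop, calls=tuple(calls)))
    return table
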