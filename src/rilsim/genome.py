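"""Hybrid genome data model and genotype-table I/O.

The model tracks *ancestry*, not sequence: each chromosome copy (haplotype) is
an ordered list of intervals labelled with the founder population they descend
from. The two founder populations of interest are the *C. briggsae* wild
isolates AF16 and HK104, which are fully homozygous because they propagate by
selfing, so a single label per interval suffices.

Coordinates are 0-based, half-open ``[start, end)`` in base pairs throughout.

Sex determination is X0: hermaphrodites carry two X copies, males one.  The
mitochondrial genome is a single maternally inherited label (mitotype); there
is no heteroplasmy in this model, matching the empirical observation that
hybrid lines show none.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

POPULATIONS = ("AF16", "HK104")
#: single-letter call codes: A = AF16 allele, H = HK104 allele
CALL_CODES = ("AA", "HH", "AH", "NA")
MISSING_CALL = "NA"

CHROMOSOME_ORDER = ("I", "II", "III", "IV", "V", "X", "MT")

HERMAPHRODITE = "hermaphrodite"
MALE = "male"


class GenomeFormatError(ValueError):
    """A bundled or user-supplied table/panel/spec file is malformed."""


class ValidationError(ValueError):
    """A domain object violates its invariants."""


# ---------------------------------------------------------------------------
# chromosomes and genome spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ChromosomeSpec:
    name: str
    length: int
    kind: str  # autosome | sex_chromosome | mitochondrial

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"chromosome {self.name}: length must be positive")
        if self.kind not in ("autosome", "sex_chromosome", "mitochondrial"):
            raise ValidationError(f"chromosome {self.name}: unknown kind {self.kind!r}")
        if self.name == "MT" and self.kind != "mitochondrial":
            raise ValidationError("MT must have kind mitochondrial")


class GenomeSpec:
    """Five autosomes, one X and the mitochondrial genome.

    Behaves as a mapping from chromosome name to :class:`ChromosomeSpec`.
    """

    def __init__(self, chromosomes: Iterable[ChromosomeSpec]):
        self._by_name = {c.name: c for c in chromosomes}
        autosomes = [c for c in self._by_name.values() if c.kind == "autosome"]
        sex = [c for c in self._by_name.values() if c.kind == "sex_chromosome"]
        if len(autosomes) != 5:
            raise ValidationError(f"genome spec needs exactly 5 autosomes, got {len(autosomes)}")
        if len(sex) != 1 or sex[0].name != "X":
            raise ValidationError("genome spec needs exactly one sex chromosome named X")
        if "MT" not in self._by_name:
            raise ValidationError("genome spec needs a mitochondrial chromosome MT")
        self.autosome_names = tuple(sorted((c.name for c in autosomes),
                                           key=CHROMOSOME_ORDER.index))

    def __getitem__(self, name: str) -> ChromosomeSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def kind_of(self, name: str) -> str:
        return self._by_name[name].kind


def _read_bundled(filename: str) -> str:
    return resources.files("rilsim.data").joinpath(filename).read_text()


def _read_commented_csv(text: str, path: str) -> pd.DataFrame:
    try:
        return pd.read_csv(io.StringIO(text), comment="#", skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenomeFormatError(f"{path}: cannot parse CSV ({exc})") from exc


def load_genome_spec(path_or_text: str | None = None) -> GenomeSpec:
    """Load a genome spec CSV (``chromosome,length,kind``); default is bundled."""
    if path_or_text is None:
        text, label = _read_bundled("genome.csv"), "bundled genome.csv"
    else:
        with open(path_or_text) as fh:
            text, label = fh.read(), str(path_or_text)
    df = _read_commented_csv(text, label)
    for col in ("chromosome", "length", "kind"):
        if col not in df.columns:
            raise GenomeFormatError(f"{label}: missing column {col!r}")
    return GenomeSpec(
        ChromosomeSpec(str(r.chromosome), int(r.length), str(r.kind))
        for r in df.itertuples()
    )


def default_genome_spec() -> GenomeSpec:
    return load_genome_spec(None)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

#: a (start, end, ancestry) interval; plain tuples keep the simulator fast
Segment = tuple[int, int, str]


@dataclass(frozen=True, slots=True)
class AncestrySegment:
    start: int
    end: int
    ancestry: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"segment [{self.start}, {self.end}) is empty")


def merge_segments(segments: Sequence[Segment]) -> tuple[Segment, ...]:
    """Canonicalize: merge adjacent segments with equal ancestry, drop empties."""
    out: list[Segment] = []
    for s, e, anc in segments:
        if s >= e:
            continue
        if out and out[-1][2] == anc and out[-1][1] == s:
            out[-1] = (out[-1][0], e, anc)
        else:
            out.append((s, e, anc))
    return tuple(out)


@dataclass(frozen=True, slots=True)
class Haplotype:
    """One chromosome copy: ancestry segments exactly tiling [0, length)."""

    chromosome: str
    segments: tuple[Segment, ...]

    @classmethod
    def from_segments(cls, chromosome: str, segments: Sequence[Segment],
                      length: int) -> "Haplotype":
        merged = merge_segments(sorted(segments))
        hap = cls(chromosome, merged)
        hap.validate(length)
        return hap

    @classmethod
    def uniform(cls, chromosome: str, length: int, ancestry: str) -> "Haplotype":
        return cls(chromosome, ((0, length, ancestry),))

    def validate(self, length: int) -> None:
        segs = self.segments
        if not segs:
            raise ValidationError(f"{self.chromosome}: empty haplotype")
        if segs[0][0] != 0 or segs[-1][1] != length:
            raise ValidationError(f"{self.chromosome}: segments do not tile [0, {length})")
        for (s0, e0, a0), (s1, e1, a1) in zip(segs, segs[1:]):
            if e0 != s1:
                raise ValidationError(f"{self.chromosome}: gap/overlap at {e0}/{s1}")
            if a0 == a1:
                raise ValidationError(f"{self.chromosome}: unmerged adjacent segments at {s1}")

    def ancestry_at(self, position: int) -> str:
        for s, e, anc in self.segments:
            if s <= position < e:
                return anc
        raise IndexError(f"position {position} outside {self.chromosome} haplotype")

    @property
    def n_breakpoints(self) -> int:
        return len(self.segments) - 1


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class Individual:
    """A single worm: 5 autosome pairs, 1-2 X copies, one mitotype label."""

    sex: str
    autosomes: list[tuple[Haplotype, Haplotype]]
    x_haplotypes: list[Haplotype]
    mitotype: str

    def __post_init__(self) -> None:
        if self.sex not in (HERMAPHRODITE, MALE):
            raise ValidationError(f"unknown sex {self.sex!r}")
        want_x = 2 if self.sex == HERMAPHRODITE else 1
        if len(self.x_haplotypes) != want_x:
            raise ValidationError(
                f"{self.sex} must carry {want_x} X cop{'ies' if want_x == 2 else 'y'}, "
                f"got {len(self.x_haplotypes)}")
        if len(self.autosomes) != 5:
            raise ValidationError("individual must carry 5 autosome pairs")

    @property
    def is_hermaphrodite(self) -> bool:
        return self.sex == HERMAPHRODITE


def founder(population: str, sex: str, genome_spec: GenomeSpec | None = None) -> Individual:
    """A fully homozygous wild-isolate individual of the given population."""
    if population not in POPULATIONS:
        raise ValidationError(f"unknown population {population!r}; expected one of {POPULATIONS}")
    gs = genome_spec or default_genome_spec()
    autosomes = []
    for name in gs.autosome_names:
        hap = Haplotype.uniform(name, gs[name].length, population)
        autosomes.append((hap, hap))
    x = Haplotype.uniform("X", gs["X"].length, population)
    xs = [x, x] if sex == HERMAPHRODITE else [x]
    return Individual(sex=sex, autosomes=autosomes, x_haplotypes=xs, mitotype=population)


# ---------------------------------------------------------------------------
# markers and genotyping
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class Marker:
    name: str
    chromosome: str
    position: int
    assay: str  # AFLP | RFLP


def load_marker_panel(path_or_text: str | None = None,
                      genome_spec: GenomeSpec | None = None) -> list[Marker]:
    """Load a marker panel CSV (``name,chromosome,position,assay``).

    Defaults to the bundled 11-marker panel: nine AFLP indel markers on
    autosomes II-V and the X, the mitochondrial RFLP cb18178, and the X-linked
    RFLP cb51757 at 12.0 Mbp.
    """
    if path_or_text is None:
        text, label = _read_bundled("marker_panel.csv"), "bundled marker_panel.csv"
    else:
        with open(path_or_text) as fh:
            text, label = fh.read(), str(path_or_text)
    df = _read_commented_csv(text, label)
    for col in ("name", "chromosome", "position", "assay"):
        if col not in df.columns:
            raise GenomeFormatError(f"{label}: missing column {col!r}")
    gs = genome_spec or default_genome_spec()
    markers: list[Marker] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples()):
        name, chrom = str(row.name), str(row.chromosome)
        try:
            pos = int(row.position)
        except (TypeError, ValueError):
            raise GenomeFormatError(f"{label}: row {i + 1} ({name}): bad position {row.position!r}")
        if chrom not in gs:
            raise GenomeFormatError(f"{label}: row {i + 1} ({name}): unknown chromosome {chrom!r}")
        if not 0 <= pos < gs[chrom].length:
            raise GenomeFormatError(
                f"{label}: row {i + 1} ({name}): position {pos} outside {chrom} "
                f"[0, {gs[chrom].length})")
        if name in seen:
            raise GenomeFormatError(f"{label}: row {i + 1}: duplicate marker name {name!r}")
        seen.add(name)
        markers.append(Marker(name, chrom, pos, str(row.assay)))
    return markers


def default_marker_panel(genome_spec: GenomeSpec | None = None) -> list[Marker]:
    return load_marker_panel(None, genome_spec)


def _call_from_alleles(a: str, b: str) -> str:
    codes = sorted(pop[0] for pop in (a, b))  # 'A' < 'H'
    return "".join(codes) if codes[0] != codes[1] else codes[0] * 2


class HemizygousCallError(ValidationError):
    """A male was genotyped at an X marker without opting into doubled storage."""


def genotype_at(individual: Individual, marker: Marker,
                genome_spec: GenomeSpec | None = None, *,
                double_hemizygous: bool = False) -> str:
    """Read the ancestry call (AA/HH/AH) at a marker.

    MT markers report the mitotype as a homozygous-equivalent call.  A male
    genotyped at an X marker is hemizygous; his single allele is stored doubled
    only when ``double_hemizygous`` is set, otherwise this raises — final RIL
    are hermaphrodites, so default tables never contain hemizygous calls.
    """
    gs = genome_spec or default_genome_spec()
    if marker.chromosome not in gs:
        raise ValidationError(f"marker {marker.name}: unknown chromosome {marker.chromosome}")
    if not 0 <= marker.position < gs[marker.chromosome].length:
        raise IndexError(f"marker {marker.name}: position outside {marker.chromosome}")
    if marker.chromosome == "MT":
        return _call_from_alleles(individual.mitotype, individual.mitotype)
    if marker.chromosome == "X":
        alleles = [h.ancestry_at(marker.position) for h in individual.x_haplotypes]
        if len(alleles) == 1:
            if not double_hemizygous:
                raise HemizygousCallError(
                    f"male is hemizygous at {marker.name}; pass double_hemizygous=True "
                    "to store the single allele doubled")
            alleles = alleles * 2
        return _call_from_alleles(*alleles)
    idx = {name: i for i, name in enumerate(gs.autosome_names)}[marker.chromosome]
    pair = individual.autosomes[idx]
    return _call_from_alleles(pair[0].ancestry_at(marker.position),
                              pair[1].ancestry_at(marker.position))


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("line_id", "design", "male_pop", "herm_pop", "mitotype")


@dataclass(slots=True)
class LineRecord:
    line_id: str
    design: str           # e.g. AI-RIL | F2RIL
    male_pop: str
    herm_pop: str
    mitotype: str
    calls: tuple[str, ...]  # aligned with the table's marker list

    @property
    def cross_direction(self) -> tuple[str, str]:
        return (self.male_pop, self.herm_pop)


@dataclass
class GenotypeTable:
    """Lines x markers ancestry calls — the interchange object of the package."""

    markers: list[Marker]
    lines: list[LineRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate marker in table")
        for rec in self.lines:
            self._check_record(rec)

    def _check_record(self, rec: LineRecord) -> None:
        if len(rec.calls) != len(self.markers):
            raise ValidationError(
                f"line {rec.line_id}: {len(rec.calls)} calls for {len(self.markers)} markers")
        for m, call in zip(self.markers, rec.calls):
            if call not in CALL_CODES:
                raise ValidationError(f"line {rec.line_id}, marker {m.name}: bad call {call!r}")

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"marker {name!r} not in table")

    def calls_for(self, marker_name: str) -> list[str]:
        j = self.marker_names.index(marker_name)
        return [rec.calls[j] for rec in self.lines]

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def append(self, rec: LineRecord) -> None:
        self._check_record(rec)
        self.lines.append(rec)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.lines:
            row = {"line_id": rec.line_id, "design": rec.design,
                   "male_pop": rec.male_pop, "herm_pop": rec.herm_pop,
                   "mitotype": rec.mitotype}
            row.update(zip(self.marker_names, rec.calls))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + self.marker_names)


def concat_tables(tables: Sequence[GenotypeTable]) -> GenotypeTable:
    """Pool lines across tables sharing a marker set (e.g. reciprocal directions)."""
    if not tables:
        raise ValidationError("no tables to concatenate")
    first = tables[0]
    for t in tables[1:]:
        if t.marker_names != first.marker_names:
            raise ValidationError("tables have differing marker sets")
    return GenotypeTable(markers=list(first.markers),
                         lines=[replace(rec) for t in tables for rec in t.lines])


def write_genotype_table(table: GenotypeTable, path: str) -> None:
    """Write CSV (or TSV if the path ends in .tsv); byte-stable column order."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    table.to_frame().to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_genotype_table(path: str, genome_spec: GenomeSpec | None = None,
                        panel: Sequence[Marker] | None = None) -> GenotypeTable:
    """Read a genotype table CSV/TSV written by :func:`write_genotype_table`.

    Marker metadata (chromosome, position) is resolved against ``panel``
    (default: the bundled panel); a header marker absent from the panel is a
    format error naming the marker.
    """
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise GenomeFormatError(f"{path}: missing metadata column {col!r}")
    marker_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    by_name = {m.name: m for m in (panel if panel is not None
                                   else default_marker_panel(genome_spec))}
    markers = []
    for name in marker_cols:
        if name not in by_name:
            raise GenomeFormatError(f"{path}: marker {name!r} not in panel")
        markers.append(by_name[name])
    table = GenotypeTable(markers=markers)
    for i, row in df.iterrows():
        calls = tuple(str(row[c]) for c in marker_cols)
        for name, call in zip(marker_cols, calls):
            if call not in CALL_CODES:
                raise GenomeFormatError(
                    f"{path}: row {i + 2}, column {name!r}: bad call {call!r}")
        table.append(LineRecord(
            line_id=str(row["line_id"]), design=str(row["design"]),
            male_pop=str(row["male_pop"]), herm_pop=str(row["herm_pop"]),
            mitotype=str(row["mitotype"]), calls=calls))
    return table
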