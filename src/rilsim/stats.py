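"""Transmission-ratio-distortion (TRD) statistics for hybrid line panels.

TRD at a marker is the fraction of alleles, over all replicate lines of one
cross direction, descending from a focal founder population.  Each homozygous
line contributes two alleles, a heterozygous line one of each, missing calls
none — so for fully inbred lines the total is twice the line count.  Observed
fractions are compared with the neutral expectation by Pearson chi-square
(df = 1, no continuity correction) and Bonferroni-corrected across the test
family.

Null expectations: 0.5 for autosomal markers.  For X-linked markers the null
depends on cross direction, because the breeding males are X0: among the X
copies entering the line from the F1 generation, two of three descend from
the hermaphrodite (maternal) parent population — so 2/3 for the maternal X
allele and 1/3 for the paternal one.

Also here: the drift probability that all of n lines independently fix the
same allele, pairwise linkage disequilibrium (D, D', r^2) over line-level
fixed alleles (the mitotype acts as a one-allele-per-line locus), and the
reciprocal-cross asymmetry contrast measured maternal-relative so that a
mirror-image maternal bias in both directions registers as symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd
from scipy import stats as sps

from .genome import (
    CHROMOSOME_ORDER,
    MISSING_CALL,
    POPULATIONS,
    GenotypeTable,
    Marker,
    ValidationError,
)

__all__ = [
    "TRDResult", "LDResult", "trd_fraction", "null_expectation", "chisq_trd",
    "bonferroni", "apply_bonferroni", "drift_probability", "ld_pair",
    "reciprocal_asymmetry", "trd_report", "UndefinedResultError",
]


class UndefinedResultError(ValueError):
    """No informative lines: the requested statistic is undefined."""


X_MATERNAL_NULL = 2.0 / 3.0
X_PATERNAL_NULL = 1.0 / 3.0


@dataclass(slots=True)
class TRDResult:
    marker: str
    design: str
    cross_direction: tuple[str, str]  # (male_pop, herm_pop)
    n_lines: int
    focal_count: int
    total_count: int
    trd: float
    expected: float | None = None
    chisq: float | None = None
    p: float | None = None
    significant: bool | None = None
    low_expected_count: bool = False


def _focal_alleles(call: str, focal_code: str) -> tuple[int, int]:
    """(focal, total) allele contribution of one call."""
    if call == MISSING_CALL:
        return 0, 0
    return call.count(focal_code), 2


def trd_fraction(table: GenotypeTable, marker: str, focal_pop: str) -> TRDResult:
    """Allele-fraction TRD of ``focal_pop`` at ``marker`` (counts only; run
    :func:`chisq_trd` / :func:`apply_bonferroni` for inference)."""
    if focal_pop not in POPULATIONS:
        raise ValidationError(f"unknown focal population {focal_pop!r}")
    directions = {rec.cross_direction for rec in table.lines}
    designs = {rec.design for rec in table.lines}
    if len(directions) > 1 or len(designs) > 1:
        raise ValidationError("table mixes designs/directions; split before trd_fraction")
    focal_code = focal_pop[0]
    focal = total = 0
    for call in table.calls_for(marker):
        f, t = _focal_alleles(call, focal_code)
        focal += f
        total += t
    if total == 0:
        raise UndefinedResultError(f"no informative lines at {marker}")
    rec = table.lines[0]
    return TRDResult(marker=marker, design=rec.design,
                     cross_direction=rec.cross_direction, n_lines=table.n_lines,
                     focal_count=focal, total_count=total, trd=focal / total)


def null_expectation(marker_chromosome: str, cross_direction: tuple[str, str],
                     focal_pop: str) -> float:
    """Neutral expected allele fraction for a marker chromosome and direction.

    ``cross_direction`` is (male_pop, herm_pop); the hermaphrodite parent is
    maternal.  Mitochondrial markers have no TRD null (strict maternal
    inheritance) and raise.
    """
    male_pop, herm_pop = cross_direction
    if focal_pop not in (male_pop, herm_pop):
        raise ValidationError(f"focal {focal_pop!r} not a parent of direction "
                              f"{male_pop}x{herm_pop}")
    if marker_chromosome == "MT":
        raise ValidationError("mitotype has no neutral TRD expectation "
                              "(strictly maternal)")
    if marker_chromosome == "X":
        return X_MATERNAL_NULL if focal_pop == herm_pop else X_PATERNAL_NULL
    return 0.5


@dataclass(frozen=True, slots=True)
class ChisqResult:
    statistic: float
    p: float
    low_expected_count: bool  # an expected class count < 1: test unreliable


def chisq_trd(focal_count: int, total_count: int,
              expected_fraction: float) -> ChisqResult:
    """Pearson goodness-of-fit chi-square, df=1, over the two allele classes."""
    if total_count <= 0:
        raise ValidationError("total_count must be positive")
    if not 0.0 < expected_fraction < 1.0:
        raise ValidationError("expected_fraction must lie strictly in (0, 1)")
    e1 = expected_fraction * total_count
    e2 = total_count - e1
    stat = (focal_count - e1) ** 2 / e1 + ((total_count - focal_count) - e2) ** 2 / e2
    p = float(sps.chi2.sf(stat, df=1))
    return ChisqResult(statistic=float(stat), p=p,
                       low_expected_count=min(e1, e2) < 1.0)


def bonferroni(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return alpha / n_tests


def apply_bonferroni(results: Sequence[TRDResult], alpha: float,
                     n_tests: int) -> list[TRDResult]:
    """Set each result's ``significant`` flag at the Bonferroni threshold."""
    threshold = bonferroni(alpha, n_tests)
    out = []
    for r in results:
        if r.p is None:
            raise ValidationError(f"result for {r.marker} has no p-value")
        out.append(replace(r, significant=r.p < threshold))
    return out


def drift_probability(n_lines: int, per_line_prob: float = 0.5) -> float:
    """Probability that all ``n_lines`` lines independently fix the same
    specified allele by drift alone (each line fixes it with
    ``per_line_prob``; the empty product is 1)."""
    if n_lines < 0:
        raise ValidationError("n_lines must be >= 0")
    if not 0.0 <= per_line_prob <= 1.0:
        raise ValidationError("per_line_prob must lie in [0, 1]")
    return per_line_prob ** n_lines


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

MITOTYPE_LOCUS = "MT"


@dataclass(slots=True)
class LDResult:
    pair: tuple[str, str]
    n_informative: int
    n_excluded: int           # heterozygous or missing at either locus
    pA: float                 # focal-allele frequency at locus a
    pB: float
    D: float | None
    D_prime: float | None
    r2: float | None
    complete: bool            # r2 within 1e-9 of 1
    defined: bool             # False when a locus is monomorphic


_COMPLETE_TOL = 1e-9


def _line_allele(table: GenotypeTable, locus: str, rec_index: int,
                 focal_code: str) -> int | None:
    """Line-level fixed allele indicator (1 = focal) or None if uninformative."""
    rec = table.lines[rec_index]
    if locus == MITOTYPE_LOCUS:
        return 1 if rec.mitotype[0] == focal_code else 0
    j = table.marker_names.index(locus)
    call = rec.calls[j]
    if call == MISSING_CALL or call[0] != call[1]:
        return None
    return 1 if call[0] == focal_code else 0


def ld_pair(table: GenotypeTable, locus_a: str, locus_b: str,
            focal_pop: str = "HK104") -> LDResult:
    """Pairwise LD over line-level fixed alleles.

    Loci are marker names or ``"MT"`` (the mitotype, one allele per line).
    Lines heterozygous or missing at either locus are excluded and counted.
    A monomorphic locus leaves D/D'/r^2 undefined (``defined=False``).
    """
    focal_code = focal_pop[0]
    a_alleles, b_alleles = [], []
    excluded = 0
    for i in range(table.n_lines):
        a = _line_allele(table, locus_a, i, focal_code)
        b = _line_allele(table, locus_b, i, focal_code)
        if a is None or b is None:
            excluded += 1
            continue
        a_alleles.append(a)
        b_alleles.append(b)
    n = len(a_alleles)
    if n < 2:
        raise UndefinedResultError(
            f"fewer than 2 informative lines for ({locus_a}, {locus_b})")
    pA = sum(a_alleles) / n
    pB = sum(b_alleles) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDResult(pair=(locus_a, locus_b), n_informative=n,
                        n_excluded=excluded, pA=pA, pB=pB, D=None, D_prime=None,
                        r2=None, complete=False, defined=False)
    pAB = sum(1 for a, b in zip(a_alleles, b_alleles) if a == 1 and b == 1) / n
    D = pAB - pA * pB
    qA, qB = 1.0 - pA, 1.0 - pB
    if D >= 0:
        d_max = min(pA * qB, qA * pB)
    else:
        d_max = min(pA * pB, qA * qB)
    D_prime = D / d_max if d_max > 0 else 0.0
    r2 = D * D / (pA * qA * pB * qB)
    return LDResult(pair=(locus_a, locus_b), n_informative=n, n_excluded=excluded,
                    pA=pA, pB=pB, D=D, D_prime=D_prime, r2=r2,
                    complete=abs(r2 - 1.0) < _COMPLETE_TOL, defined=True)


# ---------------------------------------------------------------------------
# reciprocal asymmetry
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class AsymmetryResult:
    marker: str
    trd_dir1: float           # maternal-relative unless focal overrides
    trd_dir2: float
    delta_trd: float
    chisq: float
    p: float


def reciprocal_asymmetry(table_dir1: GenotypeTable, table_dir2: GenotypeTable,
                         marker: str, focal_pop: str | None = None,
                         ) -> AsymmetryResult:
    """Contrast TRD at a marker between the two reciprocal cross directions.

    By default each direction's TRD is measured for its own *maternal*
    (hermaphrodite-parent) population, so a bias toward the maternal side in
    both directions — the mirror-image mito-X pattern — gives delta = 0 and a
    null 2x2 homogeneity chi-square.  Pass ``focal_pop`` to compare raw
    fractions of one population's allele instead.
    """
    res = []
    for table in (table_dir1, table_dir2):
        focal = focal_pop or table.lines[0].herm_pop
        res.append(trd_fraction(table, marker, focal))
    contingency = [[r.focal_count, r.total_count - r.focal_count] for r in res]
    col_totals = [contingency[0][j] + contingency[1][j] for j in (0, 1)]
    if 0 in col_totals:
        # both directions fixed on the same side: perfectly homogeneous
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = sps.chi2_contingency(contingency, correction=False)
    return AsymmetryResult(marker=marker, trd_dir1=res[0].trd, trd_dir2=res[1].trd,
                           delta_trd=res[0].trd - res[1].trd,
                           chisq=float(chi2), p=float(p))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _concat_coordinate(marker: Marker, lengths: dict[str, int]) -> int:
    offset = 0
    for name in CHROMOSOME_ORDER:
        if name == marker.chromosome:
            return offset + marker.position
        offset += lengths.get(name, 0)
    raise ValidationError(f"marker {marker.name}: unknown chromosome")


def trd_report(tables: Sequence[GenotypeTable], panel: Sequence[Marker],
               alpha: float = 0.05, n_tests: int | None = None,
               focal_pop: str = "HK104") -> pd.DataFrame:
    """One row per (nuclear marker, table): TRD, null, chi-square, significance.

    ``n_tests`` defaults to (nuclear markers) x (tables supplied), mirroring a
    markers-times-directions Bonferroni family.  Markers are ordered by their
    coordinate after concatenating chromosomes I..X end to end.
    """
    lengths = {m.chromosome: 0 for m in panel}
    # chromosome lengths only order the report; marker positions suffice if a
    # genome spec is not supplied, using max position + 1 per chromosome
    for m in panel:
        lengths[m.chromosome] = max(lengths[m.chromosome], m.position + 1)
    nuclear = [m for m in panel if m.chromosome != "MT"]
    nuclear.sort(key=lambda m: _concat_coordinate(m, lengths))
    if n_tests is None:
        n_tests = max(1, len(nuclear) * len(tables))
    rows = []
    for table in tables:
        present = set(table.marker_names)
        for m in nuclear:
            if m.name not in present:
                continue
            res = trd_fraction(table, m.name, focal_pop)
            expected = null_expectation(m.chromosome, res.cross_direction, focal_pop)
            chi = chisq_trd(res.focal_count, res.total_count, expected)
            res.expected = expected
            res.chisq = chi.statistic
            res.p = chi.p
            res.low_expected_count = chi.low_expected_count
            rows.append(res)
    rows = apply_bonferroni(rows, alpha, n_tests) if rows else []
    df = pd.DataFrame(
        [{
            "marker": r.marker,
            "chrom": next(m.chromosome for m in nuclear if m.name == r.marker),
            "design": r.design,
            "direction": f"{r.cross_direction[0]}x{r.cross_direction[1]}",
            "n_lines": r.n_lines,
            "focal_count": r.focal_count,
            "total": r.total_count,
            "trd": r.trd,
            "expected": r.expected,
            "chisq": r.chisq,
            "p": r.p,
            "significant": r.significant,
            "low_expected_count": r.low_expected_count,
        } for r in rows],
        columns=["marker", "chrom", "design", "direction", "n_lines",
                 "focal_count", "total", "trd", "expected", "chisq", "p",
                 "significant", "low_expected_count"])
    return df


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as in human-readable fraction tables."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
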