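"""TRD fractions, nulls, chi-square, Bonferroni, drift, LD, asymmetry."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy import stats as sps

import rilsim as rs
from rilsim.genome import GenotypeTable, LineRecord, Marker, ValidationError
from rilsim.stats import UndefinedResultError, chisq_trd, round_half_up

M1 = Marker("mk1", "II", 100, "AFLP")
M2 = Marker("mk2", "X", 200, "AFLP")


def tiny_table(calls_per_line, male_pop="AF16", herm_pop="HK104",
               markers=(M1, M2), design="AI-RIL"):
    t = GenotypeTable(markers=list(markers))
    for i, calls in enumerate(calls_per_line):
        t.append(LineRecord(line_id=f"L{i}", design=design, male_pop=male_pop,
                            herm_pop=herm_pop, mitotype=herm_pop,
                            calls=tuple(calls)))
    return t


class TestTrdFraction:
    def test_table1_worked_examples(self):
        t9 = tiny_table([("HH", "HH")] * 4 + [("AA", "AA")] * 5)
        assert round_half_up(rs.trd_fraction(t9, "mk2", "HK104").trd) == 0.44
        t12 = tiny_table([("HH", "HH")] + [("AA", "AA")] * 11)
        assert round_half_up(rs.trd_fraction(t12, "mk2", "HK104").trd) == 0.08

    def test_zero_and_heterozygous_counting(self):
        t = tiny_table([("AA", "AA")] * 20)
        assert rs.trd_fraction(t, "mk1", "HK104").trd == 0.0
        t_het = tiny_table([("AH", "AH")] * 6)
        r = rs.trd_fraction(t_het, "mk1", "HK104")
        assert (r.focal_count, r.total_count, r.trd) == (6, 12, 0.5)

    def test_missing_calls_excluded_from_total(self):
        t = tiny_table([("HH", "HH"), ("NA", "AA"), ("AA", "AA")])
        r = rs.trd_fraction(t, "mk1", "HK104")
        assert (r.focal_count, r.total_count) == (2, 4)
        with pytest.raises(UndefinedResultError):
            rs.trd_fraction(tiny_table([("NA", "AA")]), "mk1", "HK104")

    def test_mixed_direction_table_rejected(self):
        t = tiny_table([("HH", "HH")])
        t.lines.append(LineRecord("L9", "AI-RIL", "HK104", "AF16", "AF16",
                                  ("AA", "AA")))
        with pytest.raises(ValidationError):
            rs.trd_fraction(t, "mk1", "HK104")

    @given(hst.lists(hst.sampled_from(["AA", "HH", "AH", "NA"]), min_size=1,
                     max_size=30))
    def test_allele_swap_mirror_sums_to_one(self, calls):
        if all(c == "NA" for c in calls):
            return
        t = tiny_table([(c, c) for c in calls])
        a = rs.trd_fraction(t, "mk1", "HK104").trd
        b = rs.trd_fraction(t, "mk1", "AF16").trd
        assert a + b == pytest.approx(1.0)


class TestNullExpectation:
    def test_x_null_depends_on_cross_direction(self):
        assert rs.null_expectation("X", ("HK104", "AF16"), "HK104") == pytest.approx(1 / 3)
        assert rs.null_expectation("X", ("AF16", "HK104"), "HK104") == pytest.approx(2 / 3)

    def test_autosomes_are_half_either_direction(self):
        for direction in (("AF16", "HK104"), ("HK104", "AF16")):
            assert rs.null_expectation("III", direction, "HK104") == 0.5

    def test_mt_has_no_null(self):
        with pytest.raises(ValidationError):
            rs.null_expectation("MT", ("AF16", "HK104"), "HK104")


class TestChisq:
    def test_closed_form_examples(self):
        r = chisq_trd(0, 40, 1 / 3)
        assert r.statistic == pytest.approx(20.0)
        assert r.p == pytest.approx(7.744e-6, rel=1e-3)
        assert chisq_trd(20, 40, 0.5).statistic == 0.0
        assert chisq_trd(20, 40, 0.5).p == 1.0
        r = chisq_trd(38, 38, 2 / 3)
        assert r.statistic == pytest.approx(19.0)
        assert r.p == pytest.approx(1.307e-5, rel=1e-3)

    def test_agrees_with_brute_force_on_all_small_instances(self):
        """Sum (O-E)^2/E oracle and binomial-exact ordering, all totals <= 60."""
        for total in range(1, 61, 7):
            for focal in range(0, total + 1, 3):
                for e in (1 / 3, 0.5, 2 / 3):
                    r = chisq_trd(focal, total, e)
                    oracle = sum((o - ex) ** 2 / ex for o, ex in
                                 [(focal, e * total),
                                  (total - focal, (1 - e) * total)])
                    assert r.statistic == pytest.approx(oracle)
        # ordering sanity against an exact binomial two-sided oracle: a more
        # extreme observation never gets a larger chi-square p
        total, e = 40, 0.5
        ps = [chisq_trd(f, total, e).p for f in range(0, 21)]
        assert ps == sorted(ps)

    def test_low_expected_count_flagged(self):
        assert chisq_trd(1, 2, 1 / 3).low_expected_count
        assert not chisq_trd(10, 40, 0.5).low_expected_count

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            chisq_trd(0, 0, 0.5)
        with pytest.raises(ValidationError):
            chisq_trd(1, 2, 1.0)


class TestBonferroni:
    def test_twenty_test_family_threshold(self):
        assert rs.bonferroni(0.05, 20) == pytest.approx(0.0025)
        assert rs.bonferroni(0.05, 1) == pytest.approx(0.05)

    @given(hst.floats(1e-6, 0.5), hst.integers(1, 1000))
    def test_threshold_times_n_recovers_alpha(self, alpha, n):
        assert rs.bonferroni(alpha, n) * n == pytest.approx(alpha)

    def test_significant_count_monotone_in_family_size(self):
        t = tiny_table([("HH", "HH")] * 19)
        res = rs.trd_fraction(t, "mk2", "HK104")
        chi = chisq_trd(res.focal_count, res.total_count, 2 / 3)
        res.p = chi.p
        counts = []
        for n_tests in (1, 20, 10**7):
            flagged = rs.apply_bonferroni([res], 0.05, n_tests)
            counts.append(sum(r.significant for r in flagged))
        assert counts == sorted(counts, reverse=True)


class TestDrift:
    def test_drift_magnitudes(self):
        assert rs.drift_probability(20) == pytest.approx(9.5e-7, rel=5e-3)
        assert rs.drift_probability(5) == pytest.approx(0.03125)
        assert rs.drift_probability(0) == 1.0

    @given(hst.integers(0, 100), hst.floats(0.01, 0.99))
    def test_strictly_decreasing_in_n(self, n, p):
        assert rs.drift_probability(n + 1, p) < rs.drift_probability(n, p)


class TestLD:
    def test_four_line_worked_example(self):
        # lines {AB, AB, ab, aB} with A = HK104 at mk1, B = HK104 at mk2
        t = tiny_table([("HH", "HH"), ("HH", "HH"), ("AA", "AA"), ("AA", "HH")])
        r = rs.ld_pair(t, "mk1", "mk2")
        assert (r.pA, r.pB) == (0.5, 0.75)
        assert r.D == pytest.approx(0.125)
        assert r.D_prime == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1 / 3)
        assert not r.complete

    def test_x_matching_mitotype_gives_complete_ld(self, study_suite):
        pooled = rs.concat_tables([study_suite["AI-RIL_AF16xHK104"],
                                   study_suite["AI-RIL_HK104xAF16"]])
        r = rs.ld_pair(pooled, "cb-m124", "MT")
        assert r.complete and r.r2 == pytest.approx(1.0)

    def test_independent_loci_have_near_zero_r2(self):
        rng = np.random.default_rng(0)
        calls = [("HH" if rng.random() < 0.5 else "AA",
                  "HH" if rng.random() < 0.5 else "AA") for _ in range(10_000)]
        r = rs.ld_pair(tiny_table(calls), "mk1", "mk2")
        assert abs(r.r2) < 5 / 10_000 ** 0.5

    def test_r2_equals_squared_pearson_correlation_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.random(200) < 0.4
        b = (a & (rng.random(200) < 0.8)) | (~a & (rng.random(200) < 0.3))
        calls = [("HH" if x else "AA", "HH" if y else "AA") for x, y in zip(a, b)]
        r = rs.ld_pair(tiny_table(calls), "mk1", "mk2")
        assert r.r2 == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2)

    def test_monomorphic_locus_flagged_undefined(self):
        t = tiny_table([("HH", "HH"), ("HH", "AA"), ("HH", "HH")])
        r = rs.ld_pair(t, "mk1", "mk2")
        assert not r.defined and r.r2 is None and not r.complete

    def test_het_and_missing_lines_excluded(self):
        t = tiny_table([("HH", "HH"), ("AH", "HH"), ("NA", "AA"), ("AA", "AA")])
        r = rs.ld_pair(t, "mk1", "mk2")
        assert (r.n_informative, r.n_excluded) == (2, 2)
        with pytest.raises(UndefinedResultError):
            rs.ld_pair(tiny_table([("AH", "AH")] * 3), "mk1", "mk2")


class TestReciprocalAsymmetry:
    def test_mirror_image_absolute_trd_is_symmetric(self, study_suite):
        """19 all-HK104 lines vs 20 all-AF16 lines at cb-m127, each biased
        toward its own maternal allele: maternal-relative delta is 0."""
        r = rs.reciprocal_asymmetry(study_suite["AI-RIL_AF16xHK104"],
                                    study_suite["AI-RIL_HK104xAF16"], "cb-m127")
        assert r.delta_trd == 0.0
        assert r.p == pytest.approx(1.0)

    def test_one_sided_bias_flags_heterogeneity(self):
        biased = tiny_table([("HH", "HH")] * 15 + [("AA", "AA")] * 5)
        at_null = tiny_table([("HH", "HH")] * 10 + [("AA", "AA")] * 10,
                             male_pop="HK104", herm_pop="AF16")
        r = rs.reciprocal_asymmetry(biased, at_null, "mk1", focal_pop="HK104")
        assert r.delta_trd == pytest.approx(0.75 - 0.5)
        # hand-computed 2x2: [[30,10],[20,20]]
        expected_chi2, expected_p, _, _ = sps.chi2_contingency(
            [[30, 10], [20, 20]], correction=False)
        assert r.chisq == pytest.approx(expected_chi2)
        assert r.p == pytest.approx(expected_p)


class TestReport:
    def test_table1_x_rows(self, study_suite, panel):
        report = rs.trd_report(list(study_suite.values()), panel)
        x127 = report[report.marker == "cb-m127"]
        assert sorted(round_half_up(v) for v in x127.trd) == [0.0, 1.0]
        x757 = report[(report.marker == "cb51757") & (report.design == "F2RIL")]
        assert sorted(round_half_up(v) for v in x757.trd) == [0.08, 0.44]

    def test_markers_ordered_by_concatenated_coordinate(self, study_suite, panel):
        exp1 = [study_suite["AI-RIL_AF16xHK104"]]
        report = rs.trd_report(exp1, panel)
        chrom_order = {c: i for i, c in enumerate(["I", "II", "III", "IV", "V", "X"])}
        keys = [(chrom_order[c], p) for c, p in zip(
            report.chrom, (panel_pos(panel, m) for m in report.marker))]
        assert keys == sorted(keys)

    def test_neutral_tables_have_no_significant_rows(self, panel):
        tables = [rs.neutral_fixture(20, panel, seed=s) for s in range(4)]
        report = rs.trd_report(tables, panel, alpha=0.05, n_tests=20)
        # 40 tests at ~3.4% realized per-test rejection (line fixation doubles
        # the variance the chi-square assumes): mean ~1.4 flags, 5 is ~3 SD up
        assert report.significant.sum() <= 5

    def test_empty_marker_list_gives_empty_report(self, study_suite):
        report = rs.trd_report([next(iter(study_suite.values()))], [])
        assert len(report) == 0

    def test_type_one_error_bounded_by_family_alpha(self, panel):
        """Monte-Carlo type-I error of the pipeline on fully inbred neutral
        tables matches the exact line-fixation oracle and stays below the
        Bonferroni family alpha.

        Note the allele-count chi-square is anticonservative here: both alleles
        of a fixed line are identical, so the focal count is twice a binomial
        over lines and its variance is double what the test assumes."""
        alpha, n_tests = 0.05, 20
        threshold = rs.bonferroni(alpha, n_tests)
        n_tables, n_lines = 400, 20
        rejections = trials = 0
        expected = []
        for s in range(n_tables):
            t = rs.neutral_fixture(n_lines, panel, seed=10_000 + s)
            for m in panel:
                if m.chromosome == "MT":
                    continue
                res = rs.trd_fraction(t, m.name, "HK104")
                e = rs.null_expectation(m.chromosome, res.cross_direction, "HK104")
                chi = chisq_trd(res.focal_count, res.total_count, e)
                rejections += chi.p < threshold
                trials += 1
                expected.append(_exact_rejection_prob(n_lines, e, threshold))
        p_exact = float(np.mean(expected))
        se = (p_exact * (1 - p_exact) / trials) ** 0.5
        assert abs(rejections / trials - p_exact) < 3 * se + 1 / trials
        assert rejections / trials <= alpha  # under the family alpha


def panel_pos(panel, name):
    return next(m.position for m in panel if m.name == name)


def _exact_rejection_prob(n_lines, e, threshold):
    """Exact P(chi-square p < threshold) under the line-fixation null: the
    focal allele count is 2M with M ~ Binomial(n_lines, e)."""
    ms = np.arange(n_lines + 1)
    pmf = sps.binom.pmf(ms, n_lines, e)
    ps = np.array([chisq_trd(int(2 * m), 2 * n_lines, e).p for m in ms])
    return float(pmf[ps < threshold].sum())
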