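import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import poolseqval as pv
from _oracles import ols_closed_form
from poolseqval.validate import DegenerateFitError


def rec(pool, indiv, coverage=100, complete=True, snp="s", pop="p"):
    return pv.ComparisonRecord(
        snp=snp, population=pop, pool_maf=pool, indiv_maf=indiv,
        coverage=coverage, complete=complete,
    )


def records_from(pairs, coverages=None):
    coverages = coverages or [100] * len(pairs)
    return [
        rec(x, y, c, snp=f"s{i}")
        for i, ((x, y), c) in enumerate(zip(pairs, coverages))
    ]


class TestIndividualMaf:
    def test_all_homozygous_major(self):
        assert pv.individual_maf(["AA"] * 20, "A") == 1

    def test_one_heterozygote(self):
        calls = ["AA"] * 19 + ["AT"]
        assert pv.individual_maf(calls, "A") == Fraction(39, 40)

    def test_missing_calls_use_pairwise_deletion(self):
        calls = ["AA"] * 18 + ["AT", None]
        assert pv.individual_maf(calls, "A") == Fraction(37, 38)

    def test_all_missing_is_domain_error(self):
        with pytest.raises(ValueError, match="missing"):
            pv.individual_maf([None, None], "A")


class TestPairRecords:
    def test_full_design_yields_27_records(self, study_run):
        _, table, _ = study_run
        exp = study_run[0]
        records = pv.pair_records(table, exp.genotypes)  # no dropout
        assert len(records) == 27
        assert all(r.complete for r in records)

    def test_dropout_flags_incomplete_records(self, study_run):
        exp, table, records = study_run
        n_incomplete = sum(not r.complete for r in records)
        assert len(records) == 27
        assert n_incomplete >= 1
        # every incomplete record really has a missing call behind it
        loci = {l: j for j, l in enumerate(exp.observed_genotypes.loci)}
        pools = exp.observed_genotypes.population_indices()
        for r in records:
            ix = pools[r.population]
            calls = exp.observed_genotypes.calls[ix, loci[r.snp]]
            assert (not r.complete) == any(c is None for c in calls)

    def test_empty_genotype_table_gives_empty_output(self, study_run):
        _, table, _ = study_run
        empty = pv.GenotypeMatrix([], [], [], np.empty((0, 0), object))
        assert pv.pair_records(table, empty) == []

    def test_mismatched_loci_are_reported_not_dropped_silently(
        self, study_run, caplog
    ):
        exp, table, _ = study_run
        gm = exp.genotypes.copy()
        gm.loci = ["other:1"] + gm.loci[1:]
        with caplog.at_level("WARNING", logger="poolseqval.validate"):
            records = pv.pair_records(table, gm)
        assert len(records) == 24  # one locus lost from each source
        assert "only in the genotype table" in caplog.text
        assert "only in the SNP table" in caplog.text


class TestRegression:
    def test_perfect_concordance(self):
        records = records_from([(0.1, 0.1), (0.5, 0.5), (0.9, 0.9)])
        slope, intercept, r2 = pv.regression_untransformed(records)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_normal_equations(self):
        pairs = [(0.1, 0.12), (0.5, 0.48), (0.8, 0.83), (1.0, 0.97)]
        slope, intercept, r2 = pv.regression_untransformed(
            records_from(pairs)
        )
        o_slope, o_intercept, o_r2 = ols_closed_form(*zip(*pairs))
        assert slope == pytest.approx(float(o_slope), abs=1e-12)
        assert intercept == pytest.approx(float(o_intercept), abs=1e-12)
        assert r2 == pytest.approx(float(o_r2), abs=1e-12)

    def test_constant_response_gives_zero_slope_and_r2(self):
        records = records_from([(0.1, 0.4), (0.5, 0.4), (0.9, 0.4)])
        slope, _, r2 = pv.regression_untransformed(records)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r2 == 0.0

    def test_zero_variance_predictor_is_degenerate(self):
        records = records_from([(0.5, 0.1), (0.5, 0.5), (0.5, 0.9)])
        with pytest.raises(DegenerateFitError):
            pv.regression_untransformed(records)

    def test_p_value_matches_slope_t_statistic(self):
        # 5-point dataset; p recomputed from t = slope/SE(slope), n-2 df
        pairs = [(0.05, 0.1), (0.2, 0.18), (0.45, 0.5), (0.7, 0.66),
                 (0.95, 0.9)]
        p = pv.regression_p_transformed(records_from(pairs))
        xt = [math.asin(math.sqrt(x)) for x, _ in pairs]
        yt = [math.asin(math.sqrt(y)) for _, y in pairs]
        slope, intercept, r2 = (float(v) for v in ols_closed_form(xt, yt))
        n = len(pairs)
        resid = [y - slope * x - intercept for x, y in zip(xt, yt)]
        s2 = sum(r * r for r in resid) / (n - 2)
        sxx = sum((x - sum(xt) / n) ** 2 for x in xt)
        t = slope / math.sqrt(s2 / sxx)
        p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_collinear_transformed_data_has_vanishing_p(self):
        pairs = [(f, f) for f in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert pv.regression_p_transformed(records_from(pairs)) < 1e-12

    def test_null_rejection_rate_is_nominal(self):
        # independent x and y: the slope p-value should reject at ~alpha
        rng = np.random.default_rng(2024)
        n_rep, n, alpha = 1000, 30, 0.05
        hits = 0
        for _ in range(n_rep):
            x = rng.uniform(0.05, 0.95, n)
            y = rng.uniform(0.05, 0.95, n)
            records = records_from(list(zip(x, y)))
            hits += pv.regression_p_transformed(records) < alpha
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(hits / n_rep - alpha) <= 3 * se


class TestPairedT:
    def test_identical_vectors(self):
        records = records_from([(0.1, 0.1), (0.5, 0.5), (0.9, 0.9)])
        assert pv.paired_t_transformed(records) == (0.0, 1.0)

    def test_constant_nonzero_difference_degenerates(self):
        # exactly constant arcsine difference: infinite t, p = 0
        t, p = pv.paired_t_transformed(records_from([(0.3, 0.2)] * 3))
        assert math.isinf(t) and t > 0
        assert p == 0.0
        # nearly constant difference (float jitter): p below any tolerance
        d = 0.01
        pairs = [
            (math.sin(math.asin(math.sqrt(f)) + d) ** 2, f)
            for f in (0.2, 0.5, 0.8)
        ]
        _, p_jitter = pv.paired_t_transformed(records_from(pairs))
        assert p_jitter < 1e-12

    def test_matches_formula_oracle(self):
        pairs = [(0.15, 0.1), (0.45, 0.52), (0.7, 0.69), (0.9, 0.84)]
        t, p = pv.paired_t_transformed(records_from(pairs))
        d = [
            math.asin(math.sqrt(x)) - math.asin(math.sqrt(y))
            for x, y in pairs
        ]
        n = len(d)
        mean = sum(d) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
        t_oracle = mean / (sd / math.sqrt(n))
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert p == pytest.approx(
            2 * stats.t.sf(abs(t_oracle), df=n - 1), abs=1e-12
        )


class TestMeanAbsDiff:
    def test_zero_differences(self):
        assert pv.mean_abs_diff(records_from([(0.3, 0.3)] * 4)) == (0, 0)

    def test_two_point_arithmetic(self):
        records = records_from([(0.52, 0.5), (0.54, 0.5)])
        mean, se = pv.mean_abs_diff(records)
        assert mean == pytest.approx(0.03)
        assert se == pytest.approx(0.01)

    def test_matches_transcription_oracle(self, study_run):
        _, _, records = study_run
        mean, se = pv.mean_abs_diff(records)
        diffs = [abs(r.pool_maf - r.indiv_maf) for r in records]
        m = sum(diffs) / len(diffs)
        s = math.sqrt(
            sum((d - m) ** 2 for d in diffs) / (len(diffs) - 1)
        )
        assert mean == pytest.approx(m, abs=1e-15)
        assert se == pytest.approx(s / math.sqrt(len(diffs)), abs=1e-15)


class TestCoverageEffect:
    def test_proportional_difference_gives_unit_correlation(self):
        pairs = [(0.5 + 0.001 * c, 0.5) for c in (10, 20, 40, 80)]
        records = records_from(pairs, coverages=[10, 20, 40, 80])
        r, _ = pv.coverage_effect(records)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_independent_coverage_gives_near_zero_correlation(self):
        rng = np.random.default_rng(7)
        n = 400
        records = records_from(
            [(0.5 + d, 0.5) for d in rng.uniform(0, 0.2, n)],
            coverages=list(rng.integers(55, 285, n)),
        )
        r, _ = pv.coverage_effect(records)
        assert abs(r) < 3 / math.sqrt(n)

    def test_matches_product_moment_formula(self):
        pairs = [(0.55, 0.5), (0.62, 0.6), (0.71, 0.7), (0.93, 0.9)]
        covs = [60, 120, 180, 240]
        r, p = pv.coverage_effect(records_from(pairs, coverages=covs))
        d = [abs(x - y) for x, y in pairs]
        n = len(d)
        mc, md = sum(covs) / n, sum(d) / n
        num = sum((c - mc) * (v - md) for c, v in zip(covs, d))
        den = math.sqrt(
            sum((c - mc) ** 2 for c in covs)
            * sum((v - md) ** 2 for v in d)
        )
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_flagged(self):
        records = records_from([(0.6, 0.5)] * 4, coverages=[100] * 4)
        with pytest.raises(DegenerateFitError):
            pv.coverage_effect(records)


class TestReports:
    def test_variant_counts_split_on_completeness(self):
        complete = records_from([(0.1, 0.1), (0.5, 0.52), (0.9, 0.88),
                                 (0.3, 0.33)], coverages=[60, 80, 100, 120])
        incomplete = [
            rec(0.7, 0.72, 140, complete=False, snp="x"),
            rec(0.2, 0.18, 160, complete=False, snp="y"),
        ]
        reports = pv.build_reports(complete + incomplete)
        assert reports["all"].n == 6
        assert reports["complete_only"].n == 4

    def test_variants_identical_when_all_complete(self):
        records = records_from(
            [(0.1, 0.1), (0.5, 0.52), (0.9, 0.88)],
            coverages=[60, 80, 100],
        )
        reports = pv.build_reports(records)
        d_all = {k: v for k, v in reports["all"].to_dict().items()
                 if k != "variant"}
        d_complete = {
            k: v for k, v in reports["complete_only"].to_dict().items()
            if k != "variant"
        }
        assert d_all == d_complete

    def test_all_incomplete_reports_gap_instead_of_crashing(self):
        records = [
            rec(0.5, 0.5, complete=False),
            rec(0.6, 0.6, complete=False),
        ]
        report = pv.build_report(records, "complete_only")
        assert report.n == 0
        assert report.slope is None
        assert "at least 3" in report.note

    def test_statistics_are_invariant_to_record_order(self, study_run):
        # mathematically order-free; numerically identical up to float
        # summation order
        _, _, records = study_run
        fwd = pv.build_report(records).to_dict()
        rev = pv.build_report(records[::-1]).to_dict()
        assert fwd.keys() == rev.keys()
        for key, value in fwd.items():
            if isinstance(value, float):
                assert rev[key] == pytest.approx(value, rel=1e-9, abs=1e-12)
            else:
                assert rev[key] == value


def test_arcsine_transform_bounds_and_midpoint():
    assert pv.arcsine_transform(0.0) == 0.0
    assert pv.arcsine_transform(1.0) == pytest.approx(math.pi / 2)
    assert pv.arcsine_transform(0.5) == pytest.approx(math.pi / 4)
    with pytest.raises(ValueError):
        pv.arcsine_transform(1.5)
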