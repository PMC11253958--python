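import math

import numpy as np
import pytest
from scipy.stats import norm, pearsonr

from iogfr.agreement_stats import (
    AgreementConfig,
    PairedGfr,
    agreement_report,
    baseline_subset,
    bland_altman,
    ccc,
    cluster_bootstrap_ci,
    coverage_probability,
    differences,
    mountain_curve,
    p_within,
    pairs_from_frame,
    random_intercept_regression,
    tdi,
)


def make_pairs(ref, test, patients=None, studies=None):
    n = len(ref)
    patients = patients or [f"P{i}" for i in range(n)]
    studies = studies or [1] * n
    return [
        PairedGfr(p, s, r, t)
        for p, s, r, t in zip(patients, studies, ref, test)
    ]


def identical_pairs(n=10, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(15, 55, n)
    return make_pairs(vals, vals)


class TestDifferences:
    def test_identical_methods_zero(self):
        assert np.allclose(differences(identical_pairs()), 0.0)

    def test_percent_scale(self):
        pairs = make_pairs([20.0], [22.0])
        assert differences(pairs, "percent_of_reference")[0] == pytest.approx(10.0)

    def test_absolute_scale(self):
        pairs = make_pairs([40.0], [38.0])
        assert differences(pairs, "absolute")[0] == pytest.approx(-2.0)

    def test_order_stable_by_patient_study(self):
        pairs = make_pairs([10, 20, 30], [11, 22, 33],
                           patients=["B", "A", "A"], studies=[1, 2, 1])
        d = differences(pairs, "absolute")
        assert d.tolist() == [3.0, 2.0, 1.0]  # A/1, A/2, B/1


class TestCcc:
    def test_perfect_agreement(self):
        assert ccc(identical_pairs()) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # population moments: 2*(2/3) / (2/3 + 2/3 + 1) = 4/7
        pairs = make_pairs([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert ccc(pairs) == pytest.approx(4.0 / 7.0, rel=1e-12)

    def test_bounded_by_pearson(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(15, 55, 40)
        test = 0.8 * ref + 5 + rng.normal(0, 3, 40)
        pairs = make_pairs(ref, test)
        r = pearsonr(ref, test).statistic
        assert abs(ccc(pairs)) <= abs(r) + 1e-12

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            ccc(make_pairs([1.0, 2.0], [1.0, 2.0]))


class TestTdi:
    def test_zero_differences(self):
        assert tdi(identical_pairs()) == pytest.approx(0.0)

    def test_closed_form_mean_zero(self):
        # mean 0, sample SD 5 -> z_0.95 * 5
        d = np.array([-5.0, 0.0, 5.0]) * (5.0 / np.std([-5.0, 0.0, 5.0], ddof=1))
        ref = np.full(3, 100.0)
        pairs = make_pairs(ref, ref * (1 + d / 100))
        expected = norm.ppf(0.95) * 5.0
        assert tdi(pairs) == pytest.approx(expected, rel=1e-9)

    def test_translation_monotone(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(20, 50, 30)
        test = ref * (1 + rng.normal(0, 0.05, 30))
        base = tdi(make_pairs(ref, test, studies=[1] * 30), scale="absolute")
        shifted = tdi(make_pairs(ref, test + 3.0), scale="absolute")
        assert shifted >= base

    def test_empirical_close_to_normal_on_gaussian(self):
        rng = np.random.default_rng(11)
        n = 10_000
        ref = np.full(n, 100.0)
        test = ref + rng.normal(1.0, 4.0, n)
        pairs = make_pairs(ref, test)
        t_norm = tdi(pairs, scale="absolute", method="normal")
        t_emp = tdi(pairs, scale="absolute", method="empirical")
        assert t_emp == pytest.approx(t_norm, rel=0.05)


class TestCoverageProbability:
    def test_zero_differences(self):
        assert coverage_probability(identical_pairs(), 5.0) == pytest.approx(100.0)

    def test_moment_matched_two_sigma(self):
        # differences with sample mean 0 and sample SD 2.5 at delta 5
        base = np.array([-1.0, 0.0, 1.0])
        d = base * (2.5 / np.std(base, ddof=1))
        ref = np.full(3, 30.0)
        pairs = make_pairs(ref, ref + d)
        expected = 100.0 * (norm.cdf(2) - norm.cdf(-2))  # 95.45
        assert coverage_probability(pairs, 5.0, "absolute") == pytest.approx(
            expected, rel=1e-9
        )

    def test_degenerate_sd(self):
        ref = np.array([20.0, 30.0, 40.0])
        pairs = make_pairs(ref, ref + 2.0)
        assert coverage_probability(pairs, 5.0, "absolute") == 100.0
        assert coverage_probability(pairs, 1.0, "absolute") == 0.0

    def test_monotone_in_delta(self):
        rng = np.random.default_rng(8)
        ref = rng.uniform(20, 50, 50)
        pairs = make_pairs(ref, ref * (1 + rng.normal(0.01, 0.05, 50)))
        cps = [coverage_probability(pairs, d, "absolute") for d in (1, 2, 5, 10, 50)]
        assert all(a <= b for a, b in zip(cps, cps[1:]))
        assert cps[-1] > 99.9

    def test_rejects_bad_delta(self):
        with pytest.raises(ValueError):
            coverage_probability(identical_pairs(), 0.0)


class TestPWithin:
    def test_identical(self):
        assert p_within(identical_pairs(), 10.0) == 100.0

    def test_counting_example(self):
        pairs = make_pairs([20.0, 30.0, 40.0], [21.0, 36.0, 40.0])
        # percent diffs 5, 20, 0 -> 2 of 3 within both 10% and 15%
        assert p_within(pairs, 10.0) == pytest.approx(200.0 / 3.0)
        assert p_within(pairs, 15.0) == pytest.approx(200.0 / 3.0)

    def test_p10_le_p15(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(20, 50, 100)
        pairs = make_pairs(ref, ref * (1 + rng.normal(0, 0.1, 100)))
        assert p_within(pairs, 10.0) <= p_within(pairs, 15.0)


class TestBlandAltman:
    def test_identical(self):
        ba = bland_altman(identical_pairs())
        assert ba.bias == 0.0
        assert ba.loa_lower == 0.0
        assert ba.loa_upper == 0.0

    def test_derived_limits(self):
        # percent diffs (-2, 0, 2): sample SD 2 -> limits +/- 3.92
        ref = np.full(3, 50.0)
        pairs = make_pairs(ref, ref * np.array([0.98, 1.0, 1.02]))
        ba = bland_altman(pairs, "percent_of_reference")
        assert ba.bias == pytest.approx(0.0, abs=1e-9)
        assert ba.loa_upper == pytest.approx(3.92, abs=1e-9)
        assert ba.loa_lower == pytest.approx(-3.92, abs=1e-9)

    def test_means_are_pair_means(self):
        pairs = make_pairs([20.0, 30.0, 40.0], [22.0, 28.0, 44.0])
        ba = bland_altman(pairs, "absolute")
        assert np.allclose(ba.means, [21.0, 29.0, 42.0])


class TestMountainCurve:
    def test_folded_percentiles(self):
        # diffs (-1, 0, 1, 2), n=4 -> 20/40/60/80 folded to 20/40/40/20
        ref = np.full(4, 50.0)
        pairs = make_pairs(ref, ref + np.array([-1.0, 0.0, 1.0, 2.0]))
        mc = mountain_curve(pairs, "absolute", orientation="test_minus_ref")
        assert np.allclose(mc.folded_percentile, [20, 40, 40, 20])
        assert np.allclose(mc.diffs, [-1, 0, 1, 2])

    def test_fold_cap_and_apex(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(20, 50, 51)
        pairs = make_pairs(ref, ref * (1 + rng.normal(0, 0.05, 51)))
        mc = mountain_curve(pairs)
        assert (mc.folded_percentile <= 50).all()
        apex = mc.diffs[np.argmax(mc.folded_percentile)]
        assert apex == pytest.approx(np.median(mc.diffs), abs=1e-9)

    def test_overestimation_shifts_apex_left(self):
        # default orientation is ref - test, so test > ref folds left of 0
        ref = np.linspace(20, 50, 20)
        pairs = make_pairs(ref, ref * 1.2)
        mc = mountain_curve(pairs)
        assert mc.diffs[np.argmax(mc.folded_percentile)] < 0


class TestRandomInterceptRegression:
    def test_identity_relation(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(15, 55, 30)
        patients = [f"P{i % 10}" for i in range(30)]
        studies = [i // 10 + 1 for i in range(30)]
        pairs = make_pairs(ref, ref, patients=patients, studies=studies)
        res = random_intercept_regression(pairs)
        assert res.slope == pytest.approx(1.0, abs=1e-6)
        assert res.intercept == pytest.approx(0.0, abs=1e-5)

    def test_cis_contain_point_estimates(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(15, 55, 60)
        test = 0.8 * ref + 6 + rng.normal(0, 3, 60)
        patients = [f"P{i % 20}" for i in range(60)]
        studies = [i // 20 + 1 for i in range(60)]
        res = random_intercept_regression(
            make_pairs(ref, test, patients=patients, studies=studies)
        )
        assert res.slope_ci[0] <= res.slope <= res.slope_ci[1]
        assert res.intercept_ci[0] <= res.intercept <= res.intercept_ci[1]

    def test_simulation_recovery(self):
        # spec-style oracle: slope 0.8, intercept 6, RI SD 2, resid SD 3,
        # 40 patients x 3 studies; truth inside the Wald CI in >= 90% of
        # replicates (scaled to 60 replicates for runtime)
        rng = np.random.default_rng(99)
        hits_slope = 0
        n_rep = 60
        for _ in range(n_rep):
            pairs = []
            for i in range(40):
                u = rng.normal(0, 2)
                for j in range(3):
                    ref = rng.uniform(15, 55)
                    test = 6 + 0.8 * ref + u + rng.normal(0, 3)
                    pairs.append(PairedGfr(f"P{i}", j + 1, ref, max(test, 0.1)))
            res = random_intercept_regression(pairs)
            if res.slope_ci[0] <= 0.8 <= res.slope_ci[1]:
                hits_slope += 1
        assert hits_slope / n_rep >= 0.90

    def test_requires_grouping(self):
        pairs = make_pairs([20.0, 30.0], [21.0, 29.0], patients=["A", "A"],
                           studies=[1, 2])
        with pytest.raises(ValueError):
            random_intercept_regression(pairs)


class TestClusterBootstrap:
    def test_identical_methods_degenerate_interval(self):
        pairs = identical_pairs(n=12)
        lo, hi = cluster_bootstrap_ci(
            lambda ps: float(differences(ps, "absolute").mean()),
            pairs, B=200, seed=1,
        )
        assert lo == 0.0 and hi == 0.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        ref = rng.uniform(20, 50, 40)
        pairs = make_pairs(ref, ref * (1 + rng.normal(0, 0.05, 40)),
                           patients=[f"P{i % 15}" for i in range(40)],
                           studies=[i // 15 + 1 for i in range(40)])
        a = cluster_bootstrap_ci(ccc, pairs, B=300, seed=42)
        b = cluster_bootstrap_ci(ccc, pairs, B=300, seed=42)
        assert a == b

    def test_rejects_small_B(self):
        with pytest.raises(ValueError):
            cluster_bootstrap_ci(ccc, identical_pairs(), B=50, seed=0)

    def test_nominal_coverage(self):
        # 40 patients x 2 studies of N(0,1) differences; 95% interval for the
        # mean difference should cover 0 ~95% of the time (120 replicates,
        # binomial 3-sigma band)
        rng = np.random.default_rng(123)
        covered = 0
        n_rep = 120
        for r in range(n_rep):
            pairs = []
            for i in range(40):
                for j in (1, 2):
                    ref = rng.uniform(20, 50)
                    pairs.append(PairedGfr(f"P{i}", j, ref, ref + rng.normal()))
            lo, hi = cluster_bootstrap_ci(
                lambda ps: float(differences(ps, "absolute").mean()),
                pairs, B=200, seed=r,
            )
            if lo <= 0.0 <= hi:
                covered += 1
        assert covered / n_rep == pytest.approx(0.95, abs=0.06)


class TestBaselineSubset:
    def test_counts_equal_patients(self):
        pairs = []
        for i in range(5):
            for j in range(1, i + 2):
                pairs.append(PairedGfr(f"P{i}", j, 30.0, 31.0))
        base = baseline_subset(pairs)
        assert len(base) == 5
        assert all(p.study_index == 1 for p in base)

    def test_single_study_patients_unchanged(self):
        pairs = [PairedGfr("A", 1, 30.0, 31.0), PairedGfr("B", 2, 25.0, 26.0)]
        base = baseline_subset(pairs)
        assert {p.patient_id for p in base} == {"A", "B"}

    def test_duplicate_baseline_rejected(self):
        pairs = [PairedGfr("A", 1, 30.0, 31.0), PairedGfr("A", 1, 32.0, 33.0)]
        with pytest.raises(ValueError, match="duplicate"):
            baseline_subset(pairs)


class TestAgreementReport:
    def test_identical_methods(self):
        pairs = identical_pairs(n=12)
        rep = agreement_report(pairs, AgreementConfig(bootstrap_B=200, seed=0))
        assert rep.ccc == pytest.approx(1.0)
        assert rep.tdi_p == pytest.approx(0.0)
        assert rep.cp_delta == pytest.approx(100.0)
        assert rep.p10 == 100.0
        assert rep.bias == 0.0

    def test_proportional_noise_closed_forms(self):
        # 5% proportional disagreement: TDI ~ 1.645*5, CP(delta=10%) ~ 95
        rng = np.random.default_rng(77)
        n = 4000
        ref = rng.uniform(20, 50, n)
        test = ref * (1 + rng.normal(0, 0.05, n))
        pairs = make_pairs(ref, test, patients=[f"P{i % 500}" for i in range(n)],
                           studies=[i // 500 + 1 for i in range(n)])
        cfg = AgreementConfig(cp_delta=10.0, cp_scale="percent_of_reference",
                              bootstrap_B=200, seed=5)
        rep = agreement_report(pairs, cfg)
        assert rep.tdi_p == pytest.approx(norm.ppf(0.95) * 5.0, rel=0.05)
        assert rep.cp_delta == pytest.approx(95.45, abs=1.0)
        assert rep.loa_lower <= rep.bias <= rep.loa_upper
        assert 0 <= rep.p10 <= rep.p15 <= 100

    def test_report_serializes(self):
        rep = agreement_report(identical_pairs(n=8),
                               AgreementConfig(bootstrap_B=200, seed=1))
        d = rep.to_dict()
        assert set(d["ci"]) == {"bias", "ccc", "tdi", "cp", "p10", "p15"}


class TestPairsFromFrame:
    def test_builds_pairs(self):
        import pandas as pd

        df = pd.DataFrame({
            "patient_id": ["A", "A", "B"],
            "study_index": [1, 2, 1],
            "m_ref": [30.0, 31.0, 25.0],
            "m_test": [32.0, 30.0, 26.0],
        })
        pairs = pairs_from_frame(df, "m_ref", "m_test")
        assert len(pairs) == 3
        assert pairs[0].ref_value == 30.0

    def test_missing_column_named(self):
        import pandas as pd

        df = pd.DataFrame({"patient_id": [], "study_index": []})
        with pytest.raises(KeyError, match="m_ref"):
            pairs_from_frame(df, "m_ref", "m_test")
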