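"""Two-sample MR estimators against algebraic and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genoverlap.meta import StudyEstimate, fixed_effect_meta
from genoverlap.mr import (
    MrInput,
    cochran_q,
    mr_egger,
    mr_ivw,
    run_mr_suite,
    wald_ratios,
    weighted_median,
    weighted_mode,
)
from genoverlap.simulate import random_snp_map, simulate_sumstats

from conftest import make_sumstats


def _input(bx, by, sy, sx=None):
    bx = np.asarray(bx, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    return MrInput(
        snp_ids=[f"rs{i}" for i in range(len(bx))],
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=np.asarray(by, dtype=float),
        se_outcome=np.asarray(sy, dtype=float),
    )


def _random_input(rng, j=8):
    bx = rng.uniform(0.05, 0.4, j) * rng.choice([-1, 1], j)
    by = rng.normal(0, 0.05, j)
    sy = rng.uniform(0.01, 0.1, j)
    return _input(bx, by, sy)


class TestWaldRatios:
    def test_direct_division(self):
        r, s = wald_ratios(_input([0.5], [0.1], [0.05]))
        assert r[0] == pytest.approx(0.2)
        assert s[0] == pytest.approx(0.1)

    def test_null_numerator(self):
        r, s = wald_ratios(_input([0.5], [0.0], [0.05]))
        assert r[0] == 0.0
        assert s[0] > 0

    def test_sign_flip_invariance(self):
        r1, s1 = wald_ratios(_input([0.5], [0.1], [0.05]))
        r2, s2 = wald_ratios(_input([-0.5], [-0.1], [0.05]))
        assert r1[0] == pytest.approx(r2[0])
        assert s1[0] == pytest.approx(s2[0])

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ValueError, match="rs1"):
            wald_ratios(_input([0.5, 0.0], [0.1, 0.1], [0.05, 0.05]))


class TestIvw:
    def test_single_instrument_equals_wald_ratio(self):
        inp = _input([0.4], [0.12], [0.03])
        res = mr_ivw(inp)
        r, s = wald_ratios(inp)
        assert res.estimate == pytest.approx(r[0])
        assert res.se == pytest.approx(s[0])

    def test_consensus_ratios_return_consensus(self, rng):
        bx = rng.uniform(0.1, 0.5, 6)
        res = mr_ivw(_input(bx, 0.3 * bx, rng.uniform(0.01, 0.05, 6)))
        assert res.estimate == pytest.approx(0.3, abs=1e-12)

    def test_equals_wls_through_origin(self, rng):
        sm_api = pytest.importorskip("statsmodels.api")
        inp = _random_input(rng)
        res = mr_ivw(inp)
        fit = sm_api.WLS(inp.beta_outcome, inp.beta_exposure, weights=1 / inp.se_outcome**2).fit()
        assert res.estimate == pytest.approx(float(fit.params[0]), abs=1e-12)

    def test_equals_ivw_meta_of_wald_ratios(self, rng):
        """Algebraic identity: IVW == fixed-effects meta of Wald ratios with
        weights bx^2/sy^2 — asserted to 1e-10 on random inputs."""
        for _ in range(20):
            inp = _random_input(rng)
            ratios, ses = wald_ratios(inp)
            pooled = fixed_effect_meta(
                [StudyEstimate(f"s{i}", r, s) for i, (r, s) in enumerate(zip(ratios, ses))]
            )
            res = mr_ivw(inp)
            assert abs(res.estimate - pooled.beta) < 1e-10
            assert abs(res.se - pooled.se) < 1e-10

    def test_parameter_recovery_j6(self):
        """J=6 instruments, no pleiotropy, large n: estimate close to truth
        in nearly all of 100 seeded replicates."""
        true_effect = 0.3
        hits = 0
        master = np.random.default_rng(606)
        for _ in range(100):
            rng = np.random.default_rng(master.integers(2**31))
            bx = rng.uniform(0.1, 0.3, 6)
            sy = np.full(6, 1 / np.sqrt(2 * 50000 * 0.25))
            by = true_effect * bx + sy * rng.standard_normal(6)
            res = mr_ivw(_input(bx, by, sy))
            hits += abs(res.estimate - true_effect) <= 3 * res.se
        assert hits >= 95


class TestEgger:
    def test_exact_interpolation_recovers_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.05 + 0.7 * bx
        slope, intercept = mr_egger(_input(bx, by, np.full(4, 0.02)))
        assert slope.estimate == pytest.approx(0.7, abs=1e-12)
        assert intercept.estimate == pytest.approx(0.05, abs=1e-12)

    def test_three_instrument_normal_equations_oracle(self):
        bx = np.array([0.12, 0.25, 0.4])
        by = np.array([0.02, 0.09, 0.11])
        sy = np.array([0.03, 0.05, 0.02])
        w = (1 / sy**2).astype(np.longdouble)
        X = np.column_stack([np.ones(3, dtype=np.longdouble), bx.astype(np.longdouble)])
        A = X.T @ (X * w[:, None])
        rhs = X.T @ (w * by.astype(np.longdouble))
        expected = np.linalg.solve(A.astype(float), rhs.astype(float))
        slope, intercept = mr_egger(_input(bx, by, sy))
        assert intercept.estimate == pytest.approx(float(expected[0]), abs=1e-10)
        assert slope.estimate == pytest.approx(float(expected[1]), abs=1e-10)

    def test_agrees_with_statsmodels_wls(self, rng):
        sm_api = pytest.importorskip("statsmodels.api")
        inp = _random_input(rng, j=10)
        flip = np.sign(inp.beta_exposure)
        X = np.column_stack([np.ones(10), inp.beta_exposure * flip])
        fit = sm_api.WLS(inp.beta_outcome * flip, X, weights=1 / inp.se_outcome**2).fit()
        slope, intercept = mr_egger(inp)
        assert slope.estimate == pytest.approx(float(fit.params[1]), abs=1e-10)
        assert intercept.estimate == pytest.approx(float(fit.params[0]), abs=1e-10)

    def test_too_few_instruments_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            mr_egger(_input([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))

    def test_intercept_coverage_under_balanced_pleiotropy(self):
        """95% CI for the intercept covers the zero truth at close to
        nominal rate over 200 seeded replicates."""
        j, sy0, tau, true_slope = 10, 0.04, 0.04, 0.1
        covered = 0
        master = np.random.default_rng(808)
        for _ in range(200):
            rng = np.random.default_rng(master.integers(2**31))
            bx = rng.uniform(0.1, 0.5, j)
            alpha = tau * rng.standard_normal(j)  # balanced pleiotropy, mean 0
            by = alpha + true_slope * bx + sy0 * rng.standard_normal(j)
            _, intercept = mr_egger(_input(bx, by, np.full(j, sy0)))
            covered += intercept.ci_lower <= 0.0 <= intercept.ci_upper
        assert 0.93 * 200 <= covered <= 0.97 * 200


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.9])
        res = weighted_median(_input(bx, by, np.ones(3) * 0.05), n_boot=200, seed=1)
        assert res.estimate == pytest.approx(0.2)

    def test_consensus_value_with_small_bootstrap_se(self, rng):
        bx = rng.uniform(0.2, 0.5, 5)
        res = weighted_median(_input(bx, 0.4 * bx, np.full(5, 0.01)), n_boot=200, seed=2)
        assert res.estimate == pytest.approx(0.4, abs=1e-10)
        assert 0 < res.se < 0.2

    def test_equal_weight_odd_j_equals_numpy_median(self, rng):
        bx = np.ones(7)
        by = rng.normal(0.2, 0.3, 7)
        res = weighted_median(_input(bx, by, np.full(7, 0.05)), n_boot=200, seed=3)
        assert res.estimate == pytest.approx(np.median(by))

    def test_robust_to_30pct_invalid_instruments(self):
        """3 of 10 instruments carry large pleiotropy; the weighted median
        stays within 3 SE of truth in >= 90% of 200 replicates."""
        truth = 0.2
        hits = 0
        master = np.random.default_rng(909)
        for _ in range(200):
            rng = np.random.default_rng(master.integers(2**31))
            bx = rng.uniform(0.1, 0.4, 10)
            sy = np.full(10, 0.02)
            by = truth * bx + sy * rng.standard_normal(10)
            by[:3] += rng.uniform(0.1, 0.3, 3)  # invalid: large directional pleiotropy
            res = weighted_median(_input(bx, by, sy), n_boot=200, seed=int(rng.integers(2**31)))
            hits += abs(res.estimate - truth) <= 3 * res.se
        assert hits >= 180

    def test_bootstrap_seeded_deterministic(self, rng):
        inp = _random_input(rng)
        a = weighted_median(inp, n_boot=200, seed=42)
        b = weighted_median(inp, n_boot=200, seed=42)
        assert a.se == b.se


class TestWeightedMode:
    def test_identical_ratios_return_common_value(self):
        bx = np.ones(4)
        res = weighted_mode(_input(bx, np.full(4, 0.3), np.full(4, 0.05)), n_boot=100, seed=1)
        assert res.estimate == pytest.approx(0.3)

    def test_single_instrument_returns_wald_ratio(self):
        res = weighted_mode(
            MrInput(["rs0", "rs1"], [0.5, 0.5], [0.01, 0.01], [0.1, 0.1], [0.05, 0.05]),
            n_boot=100,
            seed=2,
        )
        assert res.estimate == pytest.approx(0.2, abs=1e-6)

    def test_majority_cluster_wins_over_outliers(self, rng):
        bx = np.ones(10)
        by = np.concatenate([rng.normal(0.3, 0.01, 7), rng.normal(2.0, 0.01, 3)])
        res = weighted_mode(_input(bx, by, np.full(10, 0.05)), n_boot=100, seed=3)
        assert 0.25 < res.estimate < 0.35

    def test_mode_recovery_no_pleiotropy(self):
        truth = 0.3
        hits = 0
        master = np.random.default_rng(717)
        for _ in range(100):
            rng = np.random.default_rng(master.integers(2**31))
            bx = rng.uniform(0.1, 0.3, 6)
            sy = np.full(6, 1 / np.sqrt(2 * 50000 * 0.25))
            by = truth * bx + sy * rng.standard_normal(6)
            res = weighted_mode(_input(bx, by, sy), n_boot=200, seed=int(rng.integers(2**31)))
            hits += abs(res.estimate - truth) <= 3 * res.se
        assert hits >= 95


class TestCochranQ:
    def test_homogeneous_ratios_give_zero_q(self, rng):
        bx = rng.uniform(0.1, 0.5, 5)
        res = cochran_q(_input(bx, 0.25 * bx, rng.uniform(0.01, 0.05, 5)))
        assert res.estimate == pytest.approx(0.0, abs=1e-20)
        assert res.pval == pytest.approx(1.0)

    def test_two_study_closed_form(self, rng):
        for _ in range(10):
            inp = _random_input(rng, j=2)
            ratios, ses = wald_ratios(inp)
            expected = (ratios[0] - ratios[1]) ** 2 / (ses[0] ** 2 + ses[1] ** 2)
            assert cochran_q(inp).estimate == pytest.approx(expected, abs=1e-10)

    def test_chi_square_moment_under_homogeneity(self):
        """Mean Q over homogeneous replicates approximates J - 1."""
        j, reps = 6, 500
        qs = np.empty(reps)
        master = np.random.default_rng(202)
        for i in range(reps):
            rng = np.random.default_rng(master.integers(2**31))
            bx = rng.uniform(0.1, 0.5, j)
            sy = np.full(j, 0.03)
            by = 0.2 * bx + sy * rng.standard_normal(j)
            qs[i] = cochran_q(_input(bx, by, sy)).estimate
        assert abs(qs.mean() - (j - 1)) < 3 * np.sqrt(2 * (j - 1) / reps)


class TestOrientationInvariance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_estimators_invariant_to_pair_sign_flips(self, seed):
        rng = np.random.default_rng(seed)
        inp = _random_input(rng, j=6)
        flip = rng.choice([-1.0, 1.0], 6)
        flipped = MrInput(
            inp.snp_ids,
            inp.beta_exposure * flip,
            inp.se_exposure,
            inp.beta_outcome * flip,
            inp.se_outcome,
        )
        assert mr_ivw(inp).estimate == pytest.approx(mr_ivw(flipped).estimate, abs=1e-12)
        assert cochran_q(inp).estimate == pytest.approx(cochran_q(flipped).estimate, abs=1e-10)
        s1, i1 = mr_egger(inp)
        s2, i2 = mr_egger(flipped)
        assert s1.estimate == pytest.approx(s2.estimate, abs=1e-12)
        assert i1.estimate == pytest.approx(i2.estimate, abs=1e-12)
        m1 = weighted_median(inp, n_boot=100, seed=5)
        m2 = weighted_median(flipped, n_boot=100, seed=5)
        assert m1.estimate == pytest.approx(m2.estimate, abs=1e-12)


class TestRunMrSuite:
    def _tables(self, seed=0, j=6, effect=0.0, n_eff=50000):
        rng = np.random.default_rng(seed)
        sm = random_snp_map(j, block_size=1, seed=seed)
        bx = rng.uniform(0.1, 0.3, j)
        exposure = simulate_sumstats(sm, bx, n_eff, seed=seed + 1, trait="exposure")
        outcome = simulate_sumstats(sm, effect * bx, n_eff, seed=seed + 2, trait="outcome")
        return exposure, outcome, list(sm["snp_id"])

    def test_six_method_rows_in_fixed_order(self):
        exposure, outcome, ids = self._tables()
        table = run_mr_suite(exposure, outcome, ids, n_boot=200, seed=1)
        assert list(table["method"]) == [
            "ivw",
            "cochran_q",
            "egger_intercept",
            "egger_slope",
            "weighted_median",
            "weighted_mode",
        ]

    def test_deterministic_with_same_seed(self):
        exposure, outcome, ids = self._tables(seed=3)
        a = run_mr_suite(exposure, outcome, ids, n_boot=200, seed=9)
        b = run_mr_suite(exposure, outcome, ids, n_boot=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_allele_swapped_outcome_gives_identical_results(self):
        exposure, outcome, ids = self._tables(seed=4)
        swapped = outcome.df.copy()
        swapped.loc[0, ["effect_allele", "other_allele"]] = swapped.loc[
            0, ["other_allele", "effect_allele"]
        ].to_numpy()
        swapped.loc[0, "beta"] = -swapped.loc[0, "beta"]
        swapped.loc[0, "eaf"] = 1 - swapped.loc[0, "eaf"]
        from genoverlap.sumstats import SumStatTable

        a = run_mr_suite(exposure, outcome, ids, n_boot=200, seed=5)
        b = run_mr_suite(exposure, SumStatTable(swapped), ids, n_boot=200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_two_instruments_skip_egger_but_run_rest(self):
        exposure, outcome, ids = self._tables(j=2)
        table = run_mr_suite(exposure, outcome, ids, n_boot=200, seed=1)
        assert "egger_slope" not in set(table["method"])
        assert {"ivw", "cochran_q", "weighted_median", "weighted_mode"} <= set(table["method"])

    def test_null_effect_ivw_ci_covers_one(self):
        """True causal effect zero: the IVW odds-ratio CI covers 1 in about
        95% of replicates."""
        covered = 0
        for seed in range(200):
            exposure, outcome, ids = self._tables(seed=1000 + seed)
            inp_df = run_mr_suite(exposure, outcome, ids, n_boot=100, seed=seed)
            ivw = inp_df[inp_df["method"] == "ivw"].iloc[0]
            covered += ivw["or_ci_lower"] <= 1.0 <= ivw["or_ci_upper"]
        assert 0.90 * 200 <= covered <= 0.99 * 200
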