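"""Instrument selection and IVW / MR-Egger / weighted-median estimation."""

import numpy as np
import pytest

from coevoscan.mr import (
    MRInput,
    bonferroni_threshold,
    egger_correlated,
    ivw_correlated,
    run_all_methods,
    select_instruments,
    weighted_median,
    _weighted_median_point,
)
from coevoscan.simulate import sim_mr_dataset
from oracles import gls_oracle, weighted_median_oracle


def make_input(b_x, b_y, se_y=None, rho=None, se_x=None):
    j = len(b_x)
    return MRInput([f"rs{i}" for i in range(j)], np.asarray(b_x, float),
                   np.asarray(se_x if se_x is not None else np.full(j, 0.01), float),
                   np.asarray(b_y, float),
                   np.asarray(se_y if se_y is not None else np.full(j, 0.05), float),
                   np.asarray(rho if rho is not None else np.eye(j), float))


class TestSelectInstruments:
    def test_weak_instrument_dropped(self):
        # F = (b/se)^2 = 9.9 fails the strict > 10 rule
        kept = select_instruments(
            ["a", "b"], [np.sqrt(9.9) * 0.1, 0.5], [0.1, 0.1],
            [1e-6, 1e-6], np.eye(2))
        assert kept == [1]

    def test_greedy_pruning_keeps_strongest(self):
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        kept = select_instruments(["a", "b"], [0.5, 0.5], [0.01, 0.01],
                                  [1e-6, 1e-4], r2)
        assert kept == [0]

    def test_manual_five_snp_trace(self):
        # F filter drops snp2 (F=4); p filter drops snp4 (p=0.01);
        # pruning (by ascending p: 0,3,1) drops snp3 (r2=0.95 with snp0)
        b_x = [0.5, 0.4, 0.02, 0.5, 0.5]
        se_x = [0.01, 0.01, 0.01, 0.01, 0.01]
        p_x = [1e-8, 1e-5, 1e-6, 1e-7, 1e-2]
        r2 = np.eye(5)
        r2[0, 3] = r2[3, 0] = 0.95
        kept = select_instruments(list("abcde"), b_x, se_x, p_x, r2)
        assert kept == [0, 1]

    def test_nothing_survives(self):
        with pytest.raises(ValueError):
            select_instruments(["a"], [0.01], [0.1], [0.5], np.eye(1))


class TestIvw:
    def test_exact_proportionality(self):
        inp = make_input([0.2, 0.4, 0.3], [0.1, 0.2, 0.15])
        assert ivw_correlated(inp).beta == pytest.approx(0.5)

    def test_single_instrument_closed_form(self):
        inp = make_input([0.4], [0.12], se_y=[0.05])
        res = ivw_correlated(inp)
        assert res.beta == pytest.approx(0.12 / 0.4)
        assert res.se == pytest.approx(0.05 / 0.4)

    def test_identity_rho_equals_textbook_ivw(self, rng):
        b_x = rng.uniform(0.2, 0.6, 6)
        b_y = 0.3 * b_x + rng.normal(0, 0.02, 6)
        se_y = rng.uniform(0.02, 0.08, 6)
        inp = make_input(b_x, b_y, se_y=se_y)
        w = b_x**2 / se_y**2
        ratio = b_y / b_x
        textbook = np.sum(w * ratio) / np.sum(w)
        assert ivw_correlated(inp).beta == pytest.approx(textbook, abs=1e-12)

    def test_matches_gls_oracle_with_correlation(self, rng):
        for _ in range(30):
            j = int(rng.integers(3, 8))
            b_x = rng.uniform(-0.5, 0.5, j)
            b_y = rng.normal(0, 0.2, j)
            se_y = rng.uniform(0.02, 0.1, j)
            rho = np.full((j, j), 0.3)
            np.fill_diagonal(rho, 1.0)
            inp = make_input(b_x, b_y, se_y=se_y, rho=rho)
            res = ivw_correlated(inp)
            omega = np.outer(se_y, se_y) * rho
            coef, cov = gls_oracle(b_y, b_x[:, None], omega)
            assert res.beta == pytest.approx(float(coef[0]), abs=1e-10)
            assert res.se == pytest.approx(float(np.sqrt(cov[0, 0])), abs=1e-10)

    def test_random_effects_only_inflates_se(self):
        # heterogeneous ratios: Q/(J-1) > 1 inflates the SE, beta unchanged
        inp = make_input([0.3, 0.4, 0.5, 0.6], [0.3, 0.1, 0.5, 0.05])
        fe = ivw_correlated(inp)
        re = ivw_correlated(inp, random_effects=True)
        assert re.beta == pytest.approx(fe.beta)
        assert re.se > fe.se
        # perfectly proportional effects: Q = 0, the floor keeps se fixed
        clean = make_input([0.2, 0.4, 0.3], [0.1, 0.2, 0.15])
        assert ivw_correlated(clean, random_effects=True).se == pytest.approx(
            ivw_correlated(clean).se)

    def test_ci_and_p_are_consistent(self):
        res = ivw_correlated(make_input([0.3, 0.4, 0.5], [0.1, 0.12, 0.18]))
        lo, hi = res.ci95
        assert lo == pytest.approx(res.beta - 1.96 * res.se)
        assert hi == pytest.approx(res.beta + 1.96 * res.se)


class TestEgger:
    def test_exact_affine_relationship(self):
        b_x = np.array([0.2, 0.35, 0.5, 0.6])
        inp = make_input(b_x, 0.2 + 0.5 * b_x)
        res = egger_correlated(inp)
        assert res.egger_intercept == pytest.approx(0.2, abs=1e-10)
        assert res.beta == pytest.approx(0.5, abs=1e-10)

    def test_matches_gls_oracle(self, rng):
        for _ in range(30):
            j = int(rng.integers(4, 9))
            b_x = rng.uniform(0.1, 0.6, j)
            b_y = rng.normal(0.1 + 0.4 * b_x, 0.05)
            se_y = rng.uniform(0.02, 0.1, j)
            rho = np.full((j, j), 0.2)
            np.fill_diagonal(rho, 1.0)
            inp = make_input(b_x, b_y, se_y=se_y, rho=rho)
            res = egger_correlated(inp)
            omega = np.outer(se_y, se_y) * rho
            X = np.column_stack([np.ones(j), b_x])
            coef, cov = gls_oracle(b_y, X, omega)
            assert res.egger_intercept == pytest.approx(float(coef[0]), abs=1e-10)
            assert res.beta == pytest.approx(float(coef[1]), abs=1e-10)
            assert res.se == pytest.approx(float(np.sqrt(cov[1, 1])), abs=1e-10)

    def test_intercept_test_calibrated_under_no_pleiotropy(self):
        hits = 0
        for rep in range(50):
            inp, _ = sim_mr_dataset(n_instruments=10, causal_beta=0.3,
                                    pleiotropy_intercept=0.0, seed=rep)
            if egger_correlated(inp).pleiotropy_flag:
                hits += 1
        assert hits <= 8  # ~2.5 expected at the 5% two-sided level

    def test_planted_pleiotropy_detected_at_high_rate(self):
        hits = 0
        for rep in range(50):
            inp, _ = sim_mr_dataset(n_instruments=20, causal_beta=0.3,
                                    pleiotropy_intercept=0.3, seed=500 + rep)
            if egger_correlated(inp).pleiotropy_flag:
                hits += 1
        assert hits >= 40  # >= 80% power

    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            egger_correlated(make_input([0.3, 0.4], [0.1, 0.1]))


class TestWeightedMedian:
    def test_equal_weights_odd_ratios(self):
        assert _weighted_median_point(np.array([1.0, 2.0, 3.0]),
                                      np.ones(3)) == pytest.approx(2.0)

    def test_dominant_instrument_wins(self):
        ratios = np.array([1.0, 5.0, 9.0])
        weights = np.array([0.1, 10.0, 0.1])
        assert _weighted_median_point(ratios, weights) == pytest.approx(5.0)

    def test_matches_cumulative_weight_oracle(self, rng):
        for _ in range(100):
            j = int(rng.integers(3, 10))
            ratios = rng.normal(0, 1, j)
            weights = rng.uniform(0.1, 5.0, j)
            assert _weighted_median_point(ratios, weights) == pytest.approx(
                weighted_median_oracle(ratios, weights), abs=1e-12)

    def test_duplicate_instrument_half_weight_invariance(self, rng):
        ratios = rng.normal(0, 1, 5)
        weights = rng.uniform(0.5, 2.0, 5)
        dup_r = np.concatenate([ratios, [ratios[2]]])
        dup_w = weights.copy()
        dup_w[2] /= 2
        dup_w = np.concatenate([dup_w, [weights[2] / 2]])
        assert _weighted_median_point(dup_r, dup_w) == pytest.approx(
            _weighted_median_point(ratios, weights), abs=1e-12)

    def test_estimator_and_bootstrap_se(self):
        inp, truth = sim_mr_dataset(n_instruments=8, causal_beta=0.3, seed=3)
        res = weighted_median(inp, n_boot=300, seed=1)
        assert res.beta == pytest.approx(0.3, abs=0.15)
        assert res.se > 0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            weighted_median(make_input([0.0, 0.3, 0.4], [0.1, 0.1, 0.1]),
                            n_boot=10, seed=0)


class TestReportingRule:
    def test_pleiotropy_foregrounds_egger(self):
        inp, _ = sim_mr_dataset(n_instruments=20, causal_beta=0.3,
                                pleiotropy_intercept=0.5, se_y=0.02, seed=2)
        report = run_all_methods(inp, n_boot=100, seed=0)
        assert report["pleiotropy_detected"]
        assert report["primary"] == "Egger"

    def test_clean_data_keeps_ivw_primary(self):
        inp, _ = sim_mr_dataset(n_instruments=8, causal_beta=0.3, seed=6)
        report = run_all_methods(inp, n_boot=100, seed=0)
        assert report["primary"] == "IVW"


class TestBonferroni:
    def test_phewas_category_arithmetic(self):
        thr = bonferroni_threshold([90, 11, 603, 62, 11])
        assert float(f"{thr:.2e}") == 6.44e-5  # 3 significant digits
        assert sum([90, 11, 603, 62, 11]) == 777

    def test_simple_cases(self):
        assert bonferroni_threshold([20]) == pytest.approx(0.0025)
        assert bonferroni_threshold([1]) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold([])
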