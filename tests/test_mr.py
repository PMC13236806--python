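"""MR estimators: Wald, IVW, Cochran's Q, Egger, and Rucker model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from meqtlmr.instruments import InstrumentRecord, InstrumentSet
from meqtlmr.mr import (
    cochran_q,
    egger,
    harmonise,
    ivw_fixed,
    ivw_random,
    mr_all_cpgs,
    rucker_select,
    wald_ratio,
)
from meqtlmr.simulate import simulate_summary_pairs


def _pairs(gamma, Gamma, se_Gamma, se_gamma=None):
    gamma = np.asarray(gamma, dtype=float)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(gamma.size)],
            "gamma": gamma,
            "se_gamma": se_gamma if se_gamma is not None else np.full(gamma.size, 0.05),
            "Gamma": np.asarray(Gamma, dtype=float),
            "se_Gamma": np.asarray(se_Gamma, dtype=float),
        }
    )


class TestHarmonise:
    def test_negative_gamma_flipped_ratio_invariant(self):
        instr = pd.DataFrame(
            {"variant_id": ["v1"], "gamma": [-0.5], "se_gamma": [0.1]}
        )
        outcome = pd.DataFrame(
            {"variant_id": ["v1"], "Gamma": [0.2], "se_Gamma": [0.1]}
        )
        h = harmonise(instr, outcome).iloc[0]
        assert h["gamma"] == 0.5
        assert h["Gamma"] == -0.2
        assert h["Gamma"] / h["gamma"] == pytest.approx(-0.4)

    def test_missing_outcome_variant_dropped_with_warning(self):
        instr = pd.DataFrame(
            {"variant_id": ["v1", "v2"], "gamma": [0.5, 0.3], "se_gamma": [0.1, 0.1]}
        )
        outcome = pd.DataFrame(
            {"variant_id": ["v1"], "Gamma": [0.2], "se_Gamma": [0.1]}
        )
        with pytest.warns(UserWarning, match="v2"):
            h = harmonise(instr, outcome)
        assert list(h["variant_id"]) == ["v1"]

    def test_positive_gamma_identity(self):
        instr = pd.DataFrame(
            {"variant_id": ["v1"], "gamma": [0.5], "se_gamma": [0.1]}
        )
        outcome = pd.DataFrame(
            {"variant_id": ["v1"], "Gamma": [0.2], "se_Gamma": [0.1]}
        )
        h = harmonise(instr, outcome).iloc[0]
        assert (h["gamma"], h["Gamma"]) == (0.5, 0.2)

    def test_swapped_alleles_flip_outcome_sign(self):
        instr = pd.DataFrame(
            {"variant_id": ["v1"], "gamma": [0.5], "se_gamma": [0.1],
             "effect_allele": ["G"], "other_allele": ["A"]}
        )
        outcome = pd.DataFrame(
            {"variant_id": ["v1"], "Gamma": [0.2], "se_Gamma": [0.1],
             "effect_allele": ["A"], "other_allele": ["G"]}
        )
        h = harmonise(instr, outcome).iloc[0]
        assert h["Gamma"] == -0.2

    def test_no_pairable_instruments_rejected(self):
        instr = pd.DataFrame(
            {"variant_id": ["v9"], "gamma": [0.5], "se_gamma": [0.1]}
        )
        outcome = pd.DataFrame(
            {"variant_id": ["v1"], "Gamma": [0.2], "se_Gamma": [0.1]}
        )
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                harmonise(instr, outcome)


class TestWaldRatio:
    def test_closed_form(self):
        theta, se = wald_ratio(0.5, 0.1, 0.2, 0.1)
        assert theta == pytest.approx(0.4)
        assert se == pytest.approx(0.2)
        assert np.exp(theta) == pytest.approx(1.4918, abs=1e-4)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.5, 0.1, 0.0, 0.1)[0] == 0.0

    def test_zero_gamma_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 0.2, 0.1)

    def test_second_order_se_formula(self):
        # se^2 = seG^2/g^2 + G^2 seg^2 / g^4
        _, se2 = wald_ratio(0.5, 0.1, 0.2, 0.1, second_order=True)
        assert se2 == pytest.approx(np.sqrt(0.01 / 0.25 + 0.04 * 0.01 / 0.0625))

    def test_second_order_se_matches_monte_carlo(self):
        # with the denominator well separated from zero (gamma/se = 10) the
        # ratio's tails are tame and the delta SE tracks the empirical SD
        rng = np.random.default_rng(42)
        gamma, se_gamma, Gamma, se_Gamma = 0.5, 0.05, 0.2, 0.1
        _, se2 = wald_ratio(gamma, se_gamma, Gamma, se_Gamma, second_order=True)
        draws_G = rng.normal(Gamma, se_Gamma, 1_000_000)
        draws_g = rng.normal(gamma, se_gamma, 1_000_000)
        mc_sd = np.std(draws_G / draws_g)
        assert se2 == pytest.approx(mc_sd, rel=0.05)


def _wls_oracle(X, y, w):
    """Known-variance WLS: coef and covariance from the normal equations."""
    W = np.diag(w)
    cov = np.linalg.inv(X.T @ W @ X)
    coef = cov @ X.T @ W @ y
    return coef, np.sqrt(np.diag(cov))


class TestIvwFixed:
    def test_equal_ratio_degeneracy(self):
        pairs = _pairs([0.5, 1.0], [0.2, 0.4], [0.1, 0.2])
        theta, se = ivw_fixed(pairs)
        assert theta == pytest.approx(0.4, abs=1e-12)
        assert se == pytest.approx(1 / np.sqrt(50), abs=1e-12)
        q, p = cochran_q(pairs, theta)
        assert q == pytest.approx(0.0, abs=1e-24)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_single_pair_reduces_to_wald(self):
        pairs = _pairs([0.5], [0.2], [0.1])
        assert ivw_fixed(pairs) == wald_ratio(0.5, 0.05, 0.2, 0.1)

    def test_matches_zero_intercept_wls_oracle(self, rng):
        for _ in range(50):
            J = int(rng.integers(2, 9))
            pairs = _pairs(
                rng.uniform(0.1, 1.0, J),
                rng.normal(0, 0.3, J),
                rng.uniform(0.02, 0.3, J),
            )
            theta, se = ivw_fixed(pairs)
            X = pairs["gamma"].to_numpy()[:, None]
            w = 1 / pairs["se_Gamma"].to_numpy() ** 2
            coef, ses = _wls_oracle(X, pairs["Gamma"].to_numpy(), w)
            assert theta == pytest.approx(coef[0], abs=1e-10)
            assert se == pytest.approx(ses[0], abs=1e-10)


class TestCochranQ:
    def test_hand_computation(self):
        pairs = _pairs([1.0, 1.0], [0.2, 0.4], [0.1, 0.1])
        theta, _ = ivw_fixed(pairs)
        assert theta == pytest.approx(0.3, abs=1e-12)
        q, p = cochran_q(pairs, theta)
        assert q == pytest.approx(2.0, abs=1e-10)
        assert p == pytest.approx(0.15730, abs=1e-4)

    def test_null_distribution_mean(self, rng):
        qs = []
        for _ in range(500):
            pairs = simulate_summary_pairs(
                0.3, rng.uniform(0.2, 0.8, 5), se_gamma=1e-8, rng=rng
            )
            theta, _ = ivw_fixed(pairs)
            qs.append(cochran_q(pairs, theta)[0])
        # Q ~ chi-square(J-1) under valid instruments: mean 4 +/- MC error
        assert np.mean(qs) == pytest.approx(4.0, abs=4 * np.sqrt(8 / 500))


class TestIvwRandom:
    def test_floor_at_fixed_effects_se(self):
        pairs = _pairs([0.5, 1.0], [0.2, 0.4], [0.1, 0.2])  # Q = 0
        assert ivw_random(pairs) == ivw_fixed(pairs)

    def test_known_inflation(self):
        # construct Q = 8 with J = 3: se inflated by sqrt(8/2) = 2
        pairs = _pairs([1.0, 1.0, 1.0], [0.0, 0.2, 0.4], [0.1, 0.1, 0.1])
        theta_f, se_f = ivw_fixed(pairs)
        q, _ = cochran_q(pairs, theta_f)
        assert q == pytest.approx(8.0, abs=1e-10)
        theta_r, se_r = ivw_random(pairs)
        assert theta_r == theta_f
        assert se_r == pytest.approx(2.0 * se_f, abs=1e-12)

    def test_point_estimate_never_changes(self, rng):
        for _ in range(20):
            pairs = _pairs(
                rng.uniform(0.1, 1, 4), rng.normal(0, 0.5, 4), rng.uniform(0.05, 0.2, 4)
            )
            assert ivw_random(pairs)[0] == ivw_fixed(pairs)[0]


class TestEgger:
    def test_collinear_points_exact_line(self):
        pairs = _pairs([1.0, 2.0, 3.0], [0.3, 0.5, 0.7], [0.1, 0.1, 0.1])
        slope, se_s, intercept, se_i, p_i, q = egger(pairs)
        assert slope == pytest.approx(0.2, abs=1e-12)
        assert intercept == pytest.approx(0.1, abs=1e-12)
        assert q == pytest.approx(0.0, abs=1e-18)

    def test_matches_wls_with_intercept_oracle(self, rng):
        for _ in range(50):
            J = int(rng.integers(3, 9))
            pairs = _pairs(
                rng.uniform(0.1, 1.0, J),
                rng.normal(0, 0.3, J),
                rng.uniform(0.02, 0.3, J),
            )
            slope, se_s, intercept, se_i, _, _ = egger(pairs)
            X = np.column_stack([np.ones(J), pairs["gamma"]])
            w = 1 / pairs["se_Gamma"].to_numpy() ** 2
            coef, ses = _wls_oracle(X, pairs["Gamma"].to_numpy(), w)
            assert slope == pytest.approx(coef[1], abs=1e-10)
            assert intercept == pytest.approx(coef[0], abs=1e-10)
            assert se_s == pytest.approx(ses[1], abs=1e-10)
            assert se_i == pytest.approx(ses[0], abs=1e-10)

    def test_intercept_null_calibration(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            pairs = simulate_summary_pairs(
                0.2, rng.uniform(0.2, 0.8, 6), se_gamma=1e-8, rng=rng
            )
            _, _, _, _, p_i, _ = egger(pairs)
            rejections += p_i < 0.05
        rate = rejections / reps
        band = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < band + 0.01

    def test_constrained_intercept_equals_ivw(self, rng):
        # Egger with the intercept forced to zero is exactly IVW: verify via
        # the zero-intercept WLS oracle on Egger's weights
        pairs = _pairs(
            rng.uniform(0.1, 1.0, 5), rng.normal(0, 0.3, 5), rng.uniform(0.05, 0.2, 5)
        )
        X = pairs["gamma"].to_numpy()[:, None]
        w = 1 / pairs["se_Gamma"].to_numpy() ** 2
        coef, ses = _wls_oracle(X, pairs["Gamma"].to_numpy(), w)
        theta, se = ivw_fixed(pairs)
        assert theta == pytest.approx(coef[0], abs=1e-12)
        assert se == pytest.approx(ses[0], abs=1e-12)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            egger(_pairs([0.5, 1.0], [0.2, 0.4], [0.1, 0.1]))


class TestRuckerSelect:
    def test_equal_ratios_select_fixed_ivw(self):
        pairs = _pairs([0.5, 1.0], [0.2, 0.4], [0.1, 0.2])
        res = rucker_select(pairs, cpg="cg1")
        assert res.method == "ivw_fixed"
        assert res.cochran_Q_p == pytest.approx(1.0, abs=1e-12)

    def test_single_instrument_selects_wald(self):
        res = rucker_select(_pairs([0.5], [0.2], [0.1]), cpg="cg1")
        assert res.method == "wald"
        assert res.theta == pytest.approx(0.4)
        assert np.isnan(res.cochran_Q_p)

    def test_two_heterogeneous_instruments_fall_back_to_random(self):
        pairs = _pairs([1.0, 1.0], [0.0, 1.0], [0.1, 0.1])  # Q = 50, p << 0.05
        res = rucker_select(pairs)
        assert res.method == "ivw_random"
        assert np.isnan(res.rucker_p)  # transition test unavailable at J = 2
        assert res.se_theta > res.se_ivw_fixed

    def test_rucker_difference_triggers_egger(self):
        # strong directional pleiotropy: ratios drift with 1/gamma
        gammas = np.linspace(0.2, 1.0, 6)
        Gammas = 0.3 * gammas + 0.15  # slope 0.3, intercept 0.15
        pairs = _pairs(gammas, Gammas, np.full(6, 0.02))
        res = rucker_select(pairs)
        assert res.method == "egger"
        assert res.theta == pytest.approx(0.3, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.15, abs=1e-10)
        assert res.rucker_p < 0.05
        # all statistics retained despite Egger being selected
        assert np.isfinite(res.cochran_Q) and np.isfinite(res.se_ivw_random)

    def test_printed_rucker_transition_p(self):
        assert stats.chi2.sf(4.65, 1) == pytest.approx(0.031, abs=0.0005)

    def test_ci_is_exp_theta_pm_1p96_se(self):
        res = rucker_select(_pairs([0.5], [0.2], [0.1]))
        lo, hi = res.ci95
        assert lo == pytest.approx(np.exp(res.theta - 1.959964 * res.se_theta), rel=1e-6)
        assert hi == pytest.approx(np.exp(res.theta + 1.959964 * res.se_theta), rel=1e-6)


class TestInvariances:
    @given(
        st.floats(0.1, 5.0),
        st.integers(2, 8),
        st.integers(0, 2**31 - 1),
    )
    def test_scale_equivariance(self, c, J, seed):
        rng = np.random.default_rng(seed)
        pairs = _pairs(
            rng.uniform(0.1, 1.0, J), rng.normal(0, 0.3, J), rng.uniform(0.02, 0.3, J)
        )
        theta, _ = ivw_fixed(pairs)
        scaled_g = pairs.assign(gamma=pairs["gamma"] * c)
        assert ivw_fixed(scaled_g)[0] == pytest.approx(theta / c, rel=1e-9)
        scaled_G = pairs.assign(Gamma=pairs["Gamma"] * c, se_Gamma=pairs["se_Gamma"] * c)
        assert ivw_fixed(scaled_G)[0] == pytest.approx(theta * c, rel=1e-9)

    @given(st.integers(3, 8), st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, J, seed):
        rng = np.random.default_rng(seed)
        pairs = _pairs(
            rng.uniform(0.1, 1.0, J), rng.normal(0, 0.3, J), rng.uniform(0.02, 0.3, J)
        )
        perm = pairs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1, r2 = rucker_select(pairs), rucker_select(perm)
        assert r1.method == r2.method
        assert r1.theta == pytest.approx(r2.theta, rel=1e-12)
        assert r1.cochran_Q == pytest.approx(r2.cochran_Q, rel=1e-9)


def _iset(cpg, records, tissue="hepatocyte"):
    return InstrumentSet(cpg, tissue, records, 50.0)


class TestMrAllCpgs:
    def test_single_instrument_sets_yield_wald_without_q(self, rng):
        sets = [
            _iset(f"cg{i}", [InstrumentRecord(f"v{i}", 0.5, 0.05, 1e-8, 0.2)])
            for i in range(4)
        ]
        outcome = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(4)],
                "Gamma": rng.normal(0, 0.1, 4),
                "se_Gamma": 0.05,
            }
        )
        res = mr_all_cpgs(sets, outcome)
        assert len(res) == 4
        assert (res["method"] == "wald").all()
        assert res["cochran_Q"].isna().all()

    def test_unpairable_cpg_omitted_with_warning(self):
        sets = [
            _iset("cg_ok", [InstrumentRecord("v0", 0.5, 0.05, 1e-8, 0.2)]),
            _iset("cg_gone", [InstrumentRecord("v_missing", 0.5, 0.05, 1e-8, 0.2)]),
        ]
        outcome = pd.DataFrame(
            {"variant_id": ["v0"], "Gamma": [0.1], "se_Gamma": [0.05]}
        )
        with pytest.warns(UserWarning):
            res = mr_all_cpgs(sets, outcome)
        assert list(res["cpg"]) == ["cg_ok"]
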