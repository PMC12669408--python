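"""Twin mixed model: covariance builder, ML fit, BLUPs, risk-set refits."""

import numpy as np
import pandas as pd
import pytest

from twinjoint import (
    BLUPSet,
    LMMFit,
    LMMParams,
    SimulationConfig,
    compute_blups,
    fit_lmm,
    pair_marginal_cov,
    predict_marker,
    rrc_refit,
    simulate_dataset,
)


def manual_fit(params: LMMParams, pairs: dict) -> LMMFit:
    """Wrap raw parameters and BLUPs into an LMMFit without fitting."""
    blups = BLUPSet(
        b={k: np.atleast_1d(v) for k, v in pairs.get("b", {}).items()},
        u=dict(pairs.get("u", {})),
    )
    return LMMFit(params=params, blups=blups, loglik=0.0, converged=True,
                  slope=params.q == 2)


class TestPairMarginalCov:
    def test_intercept_only_identity(self):
        p = LMMParams(0.0, 0.0, np.array([[1.0]]), 0.0, 0.0)
        V = pair_marginal_cov([np.array([0.0]), np.array([1.0])], p)
        np.testing.assert_allclose(V, np.eye(2))

    def test_pair_effect_only_all_ones(self):
        p = LMMParams(0.0, 0.0, np.empty((0, 0)), 1.0, 0.0)
        V = pair_marginal_cov([np.array([0.0, 1.0]), np.array([2.0])], p)
        np.testing.assert_allclose(V, np.ones((3, 3)))

    def test_twin_swap_exchangeability(self, rng):
        p = LMMParams(0.0, 0.0, np.array([[0.3, 0.02], [0.02, 0.05]]), 0.2, 0.1)
        t1, t2 = rng.uniform(0, 5, 3), rng.uniform(0, 5, 2)
        V = pair_marginal_cov([t1, t2], p)
        W = pair_marginal_cov([t2, t1], p)
        perm = np.r_[np.arange(3, 5), np.arange(0, 3)]
        np.testing.assert_allclose(W, V[np.ix_(perm, perm)], atol=1e-12)

    def test_matches_monte_carlo_covariance(self, rng):
        p = LMMParams(0.0, 0.0, np.array([[0.4]]), 0.25, 0.09)
        t1, t2 = np.array([0.0, 2.0]), np.array([1.0])
        V = pair_marginal_cov([t1, t2], p)
        n = 1_000_000
        b = rng.normal(0, np.sqrt(0.4), (n, 2))
        u = rng.normal(0, np.sqrt(0.25), n)
        e = rng.normal(0, 0.3, (n, 3))
        y = np.column_stack([b[:, 0], b[:, 0], b[:, 1]]) + u[:, None] + e
        emp = np.cov(y.T)
        # SE of a covariance entry is O(var/sqrt(n))
        np.testing.assert_allclose(emp, V, atol=3 * 0.8 / np.sqrt(n) + 3e-3)

    def test_non_psd_sigma_b_rejected(self):
        with pytest.raises(ValueError):
            LMMParams(0.0, 0.0, np.array([[1.0, 2.0], [2.0, 1.0]]), 0.1, 0.1)


class TestFitLMM:
    def test_parameter_recovery(self):
        ds = simulate_dataset(
            SimulationConfig(n_pairs=2000, seed=17, grid_scheme="sparse",
                             grid_max_k=3, sigma_e=0.1)
        )
        fit = fit_lmm(ds)
        p = fit.params
        assert fit.converged
        assert p.beta0 == pytest.approx(1.0, abs=0.02)
        assert p.beta1 == pytest.approx(0.01, abs=0.004)
        assert p.Sigma_b[0, 0] == pytest.approx(0.01, rel=0.3)
        assert p.sigma_u2 == pytest.approx(0.01, rel=0.3)
        assert p.sigma_e2 == pytest.approx(0.01, rel=0.15)

    def test_zero_pair_variance_hits_boundary(self):
        ds = simulate_dataset(
            SimulationConfig(n_pairs=800, seed=23, sigma_u=0.0, grid_scheme="sparse",
                             grid_max_k=3, sigma_e=0.1)
        )
        fit = fit_lmm(ds)
        assert fit.params.sigma_u2 < 0.002

    def test_matches_statsmodels_mixedlm(self, small_sparse_dataset):
        import statsmodels.formula.api as smf

        long = small_sparse_dataset.longitudinal_frame()
        long["subject"] = long["pair_id"].astype(str) + "_" + long["twin_id"].astype(str)
        md = smf.mixedlm(
            "y ~ time",
            long,
            groups=long["pair_id"],
            re_formula="1",
            vc_formula={"subject": "0 + C(subject)"},
        )
        sm_fit = md.fit(reml=False, method="lbfgs")
        ours = fit_lmm(small_sparse_dataset)
        assert ours.loglik == pytest.approx(sm_fit.llf, abs=0.01)
        assert ours.params.beta0 == pytest.approx(sm_fit.params["Intercept"], abs=1e-3)
        assert ours.params.beta1 == pytest.approx(sm_fit.params["time"], abs=1e-3)

    def test_duplicating_pairs_doubles_loglik(self):
        ds = simulate_dataset(
            SimulationConfig(n_pairs=60, seed=2, grid_scheme="sparse", grid_max_k=3,
                             sigma_e=0.1)
        )
        long = ds.longitudinal_frame()
        copy = long.copy()
        copy["pair_id"] += 10_000
        doubled = pd.concat([long, copy], ignore_index=True)
        f1 = fit_lmm(long)
        f2 = fit_lmm(doubled)
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-4)
        assert f2.params.beta1 == pytest.approx(f1.params.beta1, abs=1e-4)
        assert f2.params.sigma_e2 == pytest.approx(f1.params.sigma_e2, rel=1e-3)

    def test_degenerate_design_rejected(self):
        long = pd.DataFrame(
            {"pair_id": [1, 1, 2, 2], "twin_id": [1, 2, 1, 2],
             "time": [1.0, 1.0, 1.0, 1.0], "y": [0.1, 0.2, 0.3, 0.4]}
        )
        with pytest.raises(ValueError, match="identifiable"):
            fit_lmm(long)
        fit = fit_lmm(long, fix_beta1=True)  # intercept-only fallback works
        assert fit.params.beta1 == 0.0


class TestBLUPs:
    def test_scalar_shrinkage(self):
        p = LMMParams(0.5, 0.1, np.array([[2.0]]), 0.0, 1.0)
        long = pd.DataFrame(
            {"pair_id": [1, 2], "twin_id": [1, 1], "time": [3.0, 1.0], "y": [2.0, 0.0]}
        )
        fit = manual_fit(p, {})
        blups = compute_blups(fit, long)
        resid = 2.0 - 0.5 - 0.1 * 3.0
        assert blups.b[(1, 1)][0] == pytest.approx(2.0 / 3.0 * resid)

    def test_on_line_data_gives_zero_blups(self):
        p = LMMParams(1.0, 0.01, np.array([[0.5]]), 0.2, 0.3)
        t = np.array([0.0, 2.0, 4.0])
        long = pd.DataFrame(
            {"pair_id": [1] * 6, "twin_id": [1, 1, 1, 2, 2, 2],
             "time": np.r_[t, t], "y": np.r_[1.0 + 0.01 * t, 1.0 + 0.01 * t]}
        )
        blups = compute_blups(manual_fit(p, {}), long)
        assert blups.u[1] == pytest.approx(0.0, abs=1e-12)
        assert blups.b[(1, 1)][0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_gls_oracle(self, rng):
        p = LMMParams(0.8, 0.05, np.array([[0.3, 0.01], [0.01, 0.02]]), 0.15, 0.1)
        t1, t2 = np.sort(rng.uniform(0, 6, 3)), np.sort(rng.uniform(0, 6, 2))
        y = rng.normal(1.0, 0.5, 5)
        long = pd.DataFrame(
            {"pair_id": [7] * 5, "twin_id": [1, 1, 1, 2, 2],
             "time": np.r_[t1, t2], "y": y}
        )
        blups = compute_blups(manual_fit(p, {}), long)
        # explicit GLS oracle: blup = D Z' V^{-1} (y - X beta)
        Z = np.zeros((5, 5))
        Z[:3, 0] = 1.0
        Z[:3, 1] = t1
        Z[3:, 2] = 1.0
        Z[3:, 3] = t2
        Z[:, 4] = 1.0
        D = np.zeros((5, 5))
        D[:2, :2] = p.Sigma_b
        D[2:4, 2:4] = p.Sigma_b
        D[4, 4] = p.sigma_u2
        V = Z @ D @ Z.T + 0.1 * np.eye(5)
        r = y - 0.8 - 0.05 * np.r_[t1, t2]
        oracle = D @ Z.T @ np.linalg.inv(V) @ r
        np.testing.assert_allclose(blups.b[(7, 1)], oracle[:2], atol=1e-9)
        np.testing.assert_allclose(blups.b[(7, 2)], oracle[2:4], atol=1e-9)
        assert blups.u[7] == pytest.approx(oracle[4], abs=1e-9)

    def test_blups_vanish_as_noise_dominates(self):
        long = pd.DataFrame(
            {"pair_id": [1, 1], "twin_id": [1, 2], "time": [0.0, 0.0], "y": [3.0, -1.0]}
        )
        p_big = LMMParams(0.0, 0.0, np.array([[0.5]]), 0.5, 1e8)
        blups = compute_blups(manual_fit(p_big, {}), long)
        assert abs(blups.b[(1, 1)][0]) < 1e-6
        assert abs(blups.u[1]) < 1e-6


class TestPredictMarker:
    def test_zero_blups_give_fixed_line(self):
        p = LMMParams(1.0, 0.01, np.array([[0.5]]), 0.2, 0.3)
        fit = manual_fit(p, {"b": {(1, 1): [0.0]}, "u": {1: 0.0}})
        t = np.array([0.0, 5.0])
        np.testing.assert_allclose(predict_marker(fit, 1, 1, t), 1.0 + 0.01 * t)

    def test_mode_difference_is_pair_effect(self):
        p = LMMParams(1.0, 0.01, np.array([[0.5]]), 0.2, 0.3)
        fit = manual_fit(p, {"b": {(1, 1): [0.2]}, "u": {1: -0.4}})
        t = np.array([0.0, 2.0, 9.0])
        with_u = predict_marker(fit, 1, 1, t, include_pair_effect=True)
        without = predict_marker(fit, 1, 1, t, include_pair_effect=False)
        np.testing.assert_allclose(with_u - without, -0.4)

    def test_unknown_subject_raises(self):
        p = LMMParams(1.0, 0.01, np.array([[0.5]]), 0.2, 0.3)
        fit = manual_fit(p, {"b": {(1, 1): [0.2]}, "u": {1: 0.0}})
        with pytest.raises(KeyError):
            predict_marker(fit, 9, 1, np.array([1.0]))

    def test_small_noise_fit_interpolates_observations(self):
        ds = simulate_dataset(
            SimulationConfig(n_pairs=150, seed=4, grid_scheme="sparse", grid_max_k=3)
        )  # sigma_e = 0: marker observed exactly
        fit = fit_lmm(ds)
        r = ds.records[0]
        pred = predict_marker(fit, r.pair_id, r.twin_id, r.obs_times)
        np.testing.assert_allclose(pred, r.obs_values, atol=5e-3)


class TestRRCRefit:
    def test_before_any_entry_raises(self, small_sparse_dataset):
        with pytest.raises(ValueError, match="empty risk set"):
            rrc_refit(small_sparse_dataset, -1.0)

    def test_full_risk_set_equals_truncated_fit(self):
        ds = simulate_dataset(
            SimulationConfig(n_pairs=120, seed=19, delay_prob=0.0,
                             grid_scheme="sparse", grid_max_k=3, sigma_e=0.1)
        )
        t0 = min(r.exit_age for r in ds.records) - 1e-9  # everyone still at risk
        refit = rrc_refit(ds, t0, min_pairs=2)
        long = ds.longitudinal_frame()
        truncated = long[long["time"] <= t0]
        direct = fit_lmm(truncated)
        assert refit.loglik == pytest.approx(direct.loglik, abs=1e-6)
        assert refit.params.beta0 == pytest.approx(direct.params.beta0, abs=1e-6)

    def test_thin_risk_set_returns_none(self, small_sparse_dataset):
        late = max(r.exit_age for r in small_sparse_dataset.records) - 1e-6
        assert rrc_refit(small_sparse_dataset, late, min_pairs=500) is None
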