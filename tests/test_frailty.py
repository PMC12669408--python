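"""Gamma-frailty likelihood: closed form, limits, invariances, ML fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, roots_genlaguerre

from twinjoint import (
    FrailtyParams,
    StartStopTable,
    WeibullParams,
    cluster_marginal_loglik,
    fit_frailty,
    frailty_loglik,
    simulate_dataset,
    subject_cumhaz,
    weibull_cumhaz,
)
from twinjoint.calibration import build_locf_startstop
from twinjoint.simulate import SimulationConfig


def params(alpha=0.0, lam=0.001, rho=2.0, theta=0.5):
    return FrailtyParams(alpha=alpha, theta=theta, weibull=WeibullParams(scale=lam, shape=rho))


def pair_frame(rows):
    return pd.DataFrame(rows, columns=["pair_id", "twin_id", "start", "stop", "status", "z"])


def random_pair(rng, max_intervals=3):
    """A random two-subject start-stop pair with events on some final rows."""
    rows = []
    for tid in (1, 2):
        entry = rng.uniform(0.0, 3.0)
        k = rng.integers(1, max_intervals + 1)
        cuts = np.sort(rng.uniform(entry, entry + 8.0, size=k + 1))
        cuts[0] = entry
        status = np.zeros(k, dtype=int)
        status[-1] = rng.integers(0, 2)
        for m in range(k):
            rows.append((1, tid, cuts[m], cuts[m + 1], status[m], rng.normal(1.0, 0.5)))
    return pair_frame(rows)


def laguerre_pair_loglik(rows, p, truncation_adjust=True, n_nodes=64):
    """Numerical-quadrature oracle: integrate the conditional likelihood over
    the updated gamma frailty with generalized Gauss-Laguerre nodes."""
    A = B = 0.0
    d = 0
    log_event = 0.0
    for _, g in rows.groupby("twin_id"):
        a_obs, a_entry = subject_cumhaz(g, p)
        A += a_obs
        B += a_entry
        ev = g[g["status"] == 1]
        d += len(ev)
        for _, r in ev.iterrows():
            log_event += (
                math.log(p.weibull.scale * p.weibull.shape)
                + (p.weibull.shape - 1.0) * math.log(r["stop"])
                + p.alpha * r["z"]
            )
    if not truncation_adjust:
        B = 0.0
    inv = 1.0 / p.theta
    # v = x / (inv + B) turns the updated-gamma weight into x^{inv-1} e^{-x}
    x, w = roots_genlaguerre(n_nodes, inv - 1.0)
    v = x / (inv + B)
    # E[v^d e^{-Av}] under Gamma(inv, inv + B): the substitution integrates
    # against x^{inv-1} e^{-x} / Gamma(inv), i.e. exactly the updated density
    integral = np.sum(w * v**d * np.exp(-A * v)) / math.gamma(inv)
    return log_event + math.log(integral)


class TestWeibullCumhaz:
    def test_values(self):
        wb = WeibullParams(scale=0.001, shape=2.0)
        assert weibull_cumhaz(10.0, wb) == pytest.approx(0.1)
        assert weibull_cumhaz(0.0, wb) == 0.0
        assert weibull_cumhaz(5.0, wb) == pytest.approx(0.025)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_cumhaz(-1.0, WeibullParams(scale=1.0, shape=1.0))


class TestSubjectCumhaz:
    def test_piecewise_example(self):
        rows = pair_frame([(1, 1, 0.0, 1.0, 0, 0.0), (1, 1, 1.0, 2.0, 1, math.log(2.0))])
        a_obs, a_entry = subject_cumhaz(rows, params(alpha=1.0, lam=1.0, rho=1.0, theta=0.5))
        assert a_obs == pytest.approx(3.0)
        assert a_entry == 0.0

    def test_alpha_zero_telescopes(self, rng):
        rows = random_pair(rng)
        one = rows[rows["twin_id"] == 1]
        p = params(alpha=0.0)
        a_obs, _ = subject_cumhaz(one, p)
        expected = weibull_cumhaz(one["stop"].iloc[-1], p.weibull) - weibull_cumhaz(
            one["start"].iloc[0], p.weibull
        )
        assert a_obs == pytest.approx(expected, rel=1e-12)

    def test_matches_riemann_oracle(self, rng):
        cuts = np.r_[0.5, np.sort(rng.uniform(0.6, 9.0, 4)), 10.0]
        z = rng.normal(0.0, 1.0, 5)
        rows = pair_frame(
            [(1, 1, cuts[i], cuts[i + 1], 0, z[i]) for i in range(5)]
        )
        p = params(alpha=0.7, lam=0.02, rho=1.6)
        a_obs, a_entry = subject_cumhaz(rows, p)
        s = np.linspace(cuts[0], cuts[-1], 1_000_000)
        zs = z[np.clip(np.searchsorted(cuts, s, side="right") - 1, 0, 4)]
        h = 0.02 * 1.6 * s**0.6 * np.exp(0.7 * zs)
        riemann = np.sum(h[:-1] * np.diff(s))
        assert a_obs == pytest.approx(riemann, rel=1e-4)
        assert a_entry == pytest.approx(0.02 * 0.5**1.6 * math.exp(0.7 * z[0]), rel=1e-12)

    def test_gap_rejected(self):
        rows = pair_frame([(1, 1, 0.0, 1.0, 0, 0.0), (1, 1, 1.5, 2.0, 0, 0.0)])
        with pytest.raises(ValueError):
            subject_cumhaz(rows, params())


class TestClusterLoglik:
    def test_no_event_closed_form(self):
        # A=1, B=0, theta=1: marginal survivor (1 + A)^{-1} = 1/2
        rows = pair_frame(
            [(1, 1, 0.0, 1.0, 0, 0.0), (1, 2, 0.0, 1.0, 0, 0.0)]
        )
        p = params(alpha=0.0, lam=0.5, rho=1.0, theta=1.0)
        assert cluster_marginal_loglik(rows, p) == pytest.approx(-math.log(2.0), abs=1e-12)

    def test_theta_zero_limit_is_independence_ph(self, rng):
        for _ in range(10):
            rows = random_pair(rng)
            p = params(alpha=0.5, theta=1e-10)
            got = cluster_marginal_loglik(rows, p)
            # independent Weibull PH loglik computed directly
            expected = 0.0
            for _, g in rows.groupby("twin_id"):
                a_obs, _ = subject_cumhaz(g, p)
                expected -= a_obs
                for _, r in g[g["status"] == 1].iterrows():
                    expected += (
                        math.log(p.weibull.scale * p.weibull.shape)
                        + (p.weibull.shape - 1.0) * math.log(r["stop"])
                        + p.alpha * r["z"]
                    )
            assert got == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("truncation_adjust", [True, False])
    def test_matches_gauss_laguerre_oracle(self, rng, truncation_adjust):
        for _ in range(25):
            rows = random_pair(rng)
            p = params(alpha=rng.normal(0.0, 0.5), theta=rng.uniform(0.2, 1.0))
            got = cluster_marginal_loglik(rows, p, truncation_adjust=truncation_adjust)
            oracle = laguerre_pair_loglik(rows, p, truncation_adjust=truncation_adjust)
            assert got == pytest.approx(oracle, abs=1e-8)

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            params(theta=-0.5)


class TestTableLoglik:
    def test_split_interval_invariance(self, small_dense_dataset):
        table = build_locf_startstop(small_dense_dataset)
        p = params(alpha=1.0)
        base = frailty_loglik(table, p)
        df = table.df.copy()
        # split the first row at its midpoint, same z
        row = df.iloc[0].copy()
        mid = 0.5 * (row["start"] + row["stop"])
        lower = row.copy()
        lower["stop"] = mid
        lower["status"] = 0
        upper = row.copy()
        upper["start"] = mid
        split = pd.concat(
            [pd.DataFrame([lower, upper]), df.iloc[1:]], ignore_index=True
        )
        assert frailty_loglik(StartStopTable(df=split), p) == pytest.approx(base, abs=1e-9)

    def test_naive_equals_adjusted_without_delay(self):
        ds = simulate_dataset(SimulationConfig(n_pairs=120, seed=6, delay_prob=0.0))
        table = build_locf_startstop(ds)
        p = params(alpha=1.0)
        assert frailty_loglik(table, p, truncation_adjust=True) == pytest.approx(
            frailty_loglik(table, p, truncation_adjust=False), abs=1e-10
        )

    def test_event_marker_direction(self, small_dense_dataset):
        # raising the marker on event rows raises the loglik when alpha > 0
        table = build_locf_startstop(small_dense_dataset)
        bumped = table.df.copy()
        bumped.loc[bumped["status"] == 1, "z"] += 0.05
        bumped = StartStopTable(df=bumped)
        for alpha, sign in ((1.0, 1.0), (-1.0, -1.0)):
            p = params(alpha=alpha)
            delta = frailty_loglik(bumped, p) - frailty_loglik(table, p)
            assert sign * delta > 0


class TestFitFrailty:
    def test_recovers_null_model(self):
        ds = simulate_dataset(
            SimulationConfig(n_pairs=2000, seed=31, alpha=0.0, theta=1e-12)
        )
        fit = fit_frailty(build_locf_startstop(ds))
        assert fit.converged
        assert abs(fit.estimates.alpha) < 3 * fit.se["alpha"]
        assert fit.estimates.theta < 3 * fit.se["theta"]

    def test_truncation_flag_immaterial_when_entries_zero(self):
        ds = simulate_dataset(SimulationConfig(n_pairs=150, seed=8, delay_prob=0.0))
        table = build_locf_startstop(ds)
        f_adj = fit_frailty(table, truncation_adjust=True, compute_se=False)
        f_nai = fit_frailty(table, truncation_adjust=False, compute_se=False)
        assert f_adj.loglik == pytest.approx(f_nai.loglik, abs=1e-5)
        assert f_adj.estimates.alpha == pytest.approx(f_nai.estimates.alpha, abs=1e-3)

    def test_exposure_from_zero_changes_naive_fit(self, small_dense_dataset):
        table = build_locf_startstop(small_dense_dataset)
        f1 = fit_frailty(table, truncation_adjust=False, compute_se=False)
        f2 = fit_frailty(
            table, truncation_adjust=False, compute_se=False, exposure_from_zero=True
        )
        assert f1.loglik != pytest.approx(f2.loglik, abs=1e-6)

    def test_zero_length_rows_dropped_with_warning(self):
        df = pair_frame(
            [(1, 1, 0.0, 0.0, 0, 1.0), (1, 1, 0.0, 2.0, 0, 1.0),
             (1, 2, 0.0, 2.0, 1, 1.0)]
        )
        with pytest.warns(UserWarning, match="zero-length"):
            table = StartStopTable(df=df)
        assert len(table.df) == 2
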