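"""Fit the LOCF gamma-frailty model, with and without the entry correction.

The marker is carried forward between observations as a piecewise-constant
time-varying covariate.  Under delayed entry the pair frailty must be
integrated against its *updated* gamma distribution — conditioning on both
twins surviving to their entry ages — otherwise the frailty variance and the
marker effect are estimated against the wrong mixing distribution.
"""

from twinjoint import (
    SimulationConfig,
    build_locf_startstop,
    fit_frailty,
    simulate_dataset,
)

config = SimulationConfig(n_pairs=2000, alpha=1.0, seed=11)
dataset = simulate_dataset(config)
table = build_locf_startstop(dataset)
print(f"{dataset.n_pairs} pairs, {table.n_events} events, "
      f"{len(table.df)} start-stop rows")

adjusted = fit_frailty(table, truncation_adjust=True)
naive = fit_frailty(table, truncation_adjust=False, compute_se=False)

e, se = adjusted.estimates, adjusted.se
print("\ntruncation-adjusted LOCF fit (truth in brackets):")
print(f"  alpha = {e.alpha:.3f} (se {se['alpha']:.3f})   [1.0]")
print(f"  theta = {e.theta:.3f} (se {se['theta']:.3f})   [0.5]")
print(f"  lambda= {e.weibull.scale:.5f}, rho = {e.weibull.shape:.3f}   [0.001, 2.0]")
print(f"naive fit (population frailty at entry): alpha = "
      f"{naive.estimates.alpha:.3f}, theta = {naive.estimates.theta:.3f}")
print("\nWith a dense error-free grid both fits recover the truth closely;")
print("the adjustment matters more as the marker effect grows.")
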