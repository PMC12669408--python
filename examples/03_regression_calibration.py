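"""Ordinary and risk-set regression calibration on a sparse, noisy grid.

With three or fewer noisy marker observations per subject, carrying values
forward attenuates the estimated marker effect.  Calibration replaces the
marker by mixed-model BLUP predictions on a dense age grid: ORC from one
model fitted to all data, RRC from refits on the risk set at each event age.
"""

from twinjoint import (
    SimulationConfig,
    build_calibrated_startstop,
    build_locf_startstop,
    build_rrc_schedule,
    fit_frailty,
    fit_lmm,
    make_dense_grid,
    simulate_dataset,
)

config = SimulationConfig(
    n_pairs=400, alpha=2.0, sigma_e=0.2, grid_scheme="sparse", grid_max_k=3, seed=3
)
dataset = simulate_dataset(config)
print(f"{dataset.n_pairs} pairs, {dataset.n_events} events, sigma_e = 0.2, alpha = 2")

locf = fit_frailty(build_locf_startstop(dataset), compute_se=False)

stage1 = fit_lmm(dataset)
grid = make_dense_grid(dataset, n_points=100)
orc_table = build_calibrated_startstop(dataset, stage1, grid, method="orc")
orc = fit_frailty(orc_table, compute_se=False)

schedule = build_rrc_schedule(dataset)
rrc_table = build_calibrated_startstop(dataset, schedule, grid, method="rrc")
rrc = fit_frailty(rrc_table, compute_se=False)

print(f"\nfirst-stage mixed model: beta0 = {stage1.params.beta0:.3f}, "
      f"beta1 = {stage1.params.beta1:.4f}, sigma_e2 = {stage1.params.sigma_e2:.4f}")
print(f"{len(schedule.times)} risk-set refits, {len(schedule.log)} reused for thin risk sets")
print("\nestimates of the marker effect alpha (truth 2.0):")
print(f"  LOCF: {locf.estimates.alpha:.3f}   <- attenuated by carry-forward + noise")
print(f"  ORC : {orc.estimates.alpha:.3f}")
print(f"  RRC : {rrc.estimates.alpha:.3f}")
print("\nCalibration recovers most of the attenuation because the BLUP")
print("predictions average the measurement error out of the covariate.")
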