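"""A small Monte-Carlo comparison of estimators on shared datasets.

Every replication simulates one cohort and fits all requested estimators on
the same data, then summarizes relative bias, spread and coverage.  Bundled
scenario YAMLs under twinjoint/scenarios reproduce the full study designs;
here a reduced scenario keeps the runtime to about a minute.
"""

from twinjoint import ScenarioSpec, SimulationConfig, run_scenario, summarize

spec = ScenarioSpec(
    sim=SimulationConfig(n_pairs=400, alpha=1.0),
    methods=("naive", "locf"),
    n_reps=25,
    base_seed=2026,
)
result = run_scenario(spec)

print(f"mean included pairs: {result.inc_g:.0f}, mean events: {result.events:.0f}")
print(f"fit failures: {result.failures or 'none'}\n")
print(result.table[["method", "param", "truth", "reBias", "MCSE", "SD", "CP"]]
      .round(3).to_string(index=False))
print("\nformatted in the two-estimator table layout:")
print(summarize(result, layout="table1").to_string(index=False))
print("\nreBias is (mean estimate - truth)/truth; MCSE its Monte-Carlo standard")
print("error; CP the coverage of Wald 95% intervals. At this reduced size the")
print("naive and adjusted fits differ little; the gap widens with larger alpha.")
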