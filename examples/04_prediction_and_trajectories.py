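"""Risk-prediction AUC comparison and smoking-cessation trajectories.

Fits three nested logistic risk models (smoking only; plus median-split
methylation; plus continuous methylation) and summarizes how methylation at a
smoking-responsive CpG recovers toward never-smoker levels with time since
quitting.
"""

import methmediate as mm

config = mm.SimulationConfig(
    n_population=8_000, n_pairs=300, n_probes=40,
    n_responsive_probes=6, n_discriminating_probes=10, seed=21,
)
matrix, sheet, _ = mm.simulate_population(config)
cc = mm.draw_nested_case_control(sheet, config.n_pairs, seed=22)
ccm = matrix.subset_samples(list(cc["sample_id"]))
probes = mm.mediator_probe_ids(config)

pred = mm.incremental_prediction(cc, ccm, probes)
print("in-sample AUC of nested lung-cancer risk models:")
print(f"  smoking status only:            {pred.auc_smoking_only:.3f}")
print(f"  + methylation (median split):   {pred.auc_plus_categorical:.3f}")
print(f"  + methylation (continuous):     {pred.auc_plus_continuous:.3f}")
print("methylation adds discrimination beyond smoking in expectation; on any "
      "single cohort the apparent-AUC increments can be small or even reversed.")

traj = mm.cessation_trajectories(matrix, sheet, probes[0])
print(f"\ncessation trajectory at {traj.probe} (beta scale):")
print(traj.bins.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(f"anchors: current smokers {traj.current_mean:.4f} < never {traj.never_mean:.4f}; "
      "former smokers climb back toward never-smoker levels within ~10 years.")

slope = mm.trajectory_slope(matrix, sheet, probes[0], scale="m")
print(f"M-value trend per year since quitting: {slope['slope']:.4f} "
      f"(95% CI {slope['ci_low']:.4f} to {slope['ci_high']:.4f}, n={slope['n']})")
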