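"""Case-control-weighted g-computation mediation analysis.

Decomposes the ever-smoking effect on lung-cancer log odds into a natural
direct effect and a natural indirect effect mediated by methylation at the
two designated smoking CpGs, singly and jointly, with pair-bootstrap
inference — the analysis that produces the TCE / NDE / NIE / proportion-
mediated blocks.
"""

import methmediate as mm

config = mm.SimulationConfig(seed=11)
truth = mm.true_effects_oracle(config)
p_never = config.smoking_prevalence[0]
prevalence = p_never * truth["p00"] + (1 - p_never) * truth["p11"]
print(f"population disease prevalence used for design weighting: {prevalence:.4f}")

matrix, sheet, _ = mm.simulate_population(config)
cc = mm.draw_nested_case_control(sheet, config.n_pairs, seed=12)
ccm = matrix.subset_samples(list(cc["sample_id"]))
mediators = mm.mediator_probe_ids(config)

results = {}
for label, probes in ((mediators[0], [mediators[0]]),
                      (mediators[1], [mediators[1]]),
                      ("joint", mediators)):
    results[label] = mm.bootstrap_mediation(
        cc, ccm, probes, prevalence=prevalence,
        n_bootstrap=200, n_mc=400, n_mc_bootstrap=50, seed=13,
    )

table = mm.report_mediation_block(results)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(f"\npopulation truth: TCE={truth['tce']:.3f}  NIE={truth['nie']:.3f}  "
      f"proportion mediated={truth['proportion_mediated']:.3f}")
print("each block partitions the total smoking effect (log-OR scale); the "
      "'Effect mediated' row is NIE/TCE, the share explained by methylation.")
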