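"""Locus-by-locus lung-cancer risk scan on a synthetic case-control set.

One unconditional logistic regression per probe (case status on beta values
standardized to 1 s.d., adjusted for chip, array position, estimated cell
proportions and age), with Bonferroni family-wise error control. Smoking-
responsive probes should surface at the top with OR per s.d. < 1
(hypomethylation in future cases).
"""

import methmediate as mm

config = mm.SimulationConfig(
    n_population=8_000, n_pairs=250, n_probes=80,
    n_responsive_probes=8, n_discriminating_probes=24, seed=3,
)
matrix, sheet, _ = mm.simulate_population(config)
cc = mm.draw_nested_case_control(sheet, config.n_pairs, seed=4)
cc = mm.assign_chips(cc, seed=5)
ccm = mm.apply_technical_layer(matrix.subset_samples(list(cc["sample_id"])), cc, config, seed=6)
ccm, report = mm.filter_missingness(ccm)
cc = cc[cc["sample_id"].isin(ccm.sample_ids)].reset_index(drop=True)
print(f"QC: removed {report.n_samples_removed} samples and "
      f"{report.n_probes_removed} probes (>5% / >20% missingness rules)")

profiles, purified, labels = mm.simulate_reference_panel(config, seed=7)
selected = [p for p in mm.select_discriminating_probes(purified, labels, fwer=0.01)
            if p in ccm.probe_ids]
props = mm.estimate_cell_proportions(
    ccm.subset_probes(selected), mm.ReferenceProfiles(profiles.profiles.loc[selected])
)
cc = mm.append_cell_proportions(cc, props)
print(f"deconvolution: {len(selected)} cell-discriminating probes at FWER<0.01")

scan = mm.ewas_scan(ccm, cc, adjust=("chip", "position", "cells", "age"))
top = scan.head(5)[["probe_id", "gene", "or_per_sd", "ci_low", "ci_high", "p_wald", "p_bonferroni"]]
print("top of the scan (OR per 1 s.d. of beta; <1 means hypomethylated in cases):")
print(top.to_string(index=False))
n_sig = int((scan["p_bonferroni"].dropna() < 0.05).sum())
print(f"{n_sig} probes reach Bonferroni-adjusted p < 0.05")
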