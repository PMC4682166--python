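stages:
- simulate
- preprocess
- deconvolve
- scan
- mediate
- report
out_dir: methmediate_run
simulation:
  n_population: 25000
  n_pairs: 1000
  n_probes: 200
  n_responsive_probes: 20
  n_mediators: 2
  n_discriminating_probes: 60
  smoking_prevalence:
  - 0.4
  - 0.3
  - 0.3
  relative_hypomethylation: 0.19
  reversal_halflife: 4.0
  cell_types:
  - CD4T
  - CD8T
  - NK
  - Bcell
  - Mono
  - Gran
  dirichlet_concentration:
  - 4.0
  - 2.5
  - 1.5
  - 2.0
  - 2.0
  - 12.0
  outcome_coeffs:
    intercept: -3.8
    direct_smoking_log_or: 1.1
    mediator_log_or_per_sd:
    - -0.25
    - -0.15
    age_log_or_per_sd: 0.3
    exposure_mediator_interaction:
    - 0.0
    - 0.0
    exposure_age_interaction: 0.0
  batch:
    samples_per_chip: 12
    chip_sd: 0.08
    position_sd: 0.04
  detection_missing_rate: 0.005
  noise_sd: 0.025
  age_range:
  - 45.0
  - 64.0
  max_years_since_quit: 30.0
  followup_years: 8.0
  seed: 0
analysis:
  prevalence: 0.01
  n_mc: 400
  n_bootstrap: 200
  probe_missing_threshold: 0.2
  sample_missing_threshold: 0.05
  fwer_cells: 0.01
  fwer_scan: 0.05
  min_stratum_n: 20
seed: 0
log_level: INFO
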