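# Methods

`methmediate` re-creates, on synthetic data with known ground truth, the
analysis chain of a prospective blood-methylation study of smoking and lung
cancer: quality-control filters, reference-based leukocyte deconvolution, a
locus-by-locus risk scan, smoking-stratified and matched-pair models,
risk-prediction comparison, cessation trajectories, and — the headline — a
case-control-weighted parametric g-computation mediation analysis that
partitions the smoking effect into natural direct and indirect components.
This note documents the generative model, the estimators, the numerical
choices, and what the validation studies do and do not demonstrate.

## The synthetic cohort generator

**Population.** Subjects carry age (uniform on 45–64 years, a typical
middle-aged screening window), smoking status (never/former/current with
default probabilities 0.40/0.30/0.30), time since quitting for former smokers
(uniform on 0.5–30 years), smoking duration and intensity, and leukocyte
proportions over six subtypes (CD4T, CD8T, NK, B cells, monocytes,
granulocytes) drawn from a Dirichlet whose concentration makes granulocytes
the dominant fraction, as in whole blood.

**Methylation.** Each probe has a per-cell-type mean beta value; a subject's
biological signal is the mixture of those means under their cell proportions.
Smoking-responsive probes (including the two designated mediator CpGs,
labelled with the canonical smoking loci cg05575921/*AHRR* and
cg03636183/*F2RL3*) are multiplied by `1 - r` in current smokers, with
relative hypomethylation `r = 0.19` by default — the replicated magnitude of
the smoking effect at the *AHRR* locus. In former smokers the shift decays
exponentially with time since quitting (`r * 2^(-t/h)`, half-life `h = 4`
years by default), so methylation approaches never-smoker levels roughly ten
years after cessation; the exponential form is a modelling choice, as the
motivating observations constrain only the qualitative reversal. Measurement
noise is specified as a beta-scale standard deviation and applied on the
logit scale via the delta method (`sd_logit = sd_beta / (m(1-m))`), which
keeps values strictly inside (0,1) while leaving the multiplicative
calibration of group means intact to first order. Batch structure (chip and
array-position shifts on the logit scale) and detection-style missingness are
applied by a separate technical layer; samples within a matched pair share a
chip with randomized within-pair order, mirroring the design practice of
processing pairs together while randomizing layout.

**Disease.** Lung cancer is generated prospectively from a logistic model on
ever-smoking, standardized mediator methylation, and standardized age; the
mediator coefficients are configured per 1 s.d. and converted internally
using calibration constants estimated once from a fixed-stream Monte Carlo of
the mediator law. Interaction coefficients default to zero (purely additive
pathways); the analysis stage still estimates them. Defaults give roughly 5%
cumulative incidence, a direct log-OR of 1.1 for ever-smoking, and a true
proportion mediated near one third — the same regime as the motivating
analysis. Cases receive an event time uniform over follow-up; nested
case-control sets are drawn by incidence-density sampling (controls are
disease-free at their case's event time; future cases may serve as earlier
controls; no subject is reused).

**Determinism.** Probe architecture, calibration constants and the truth
oracle use fixed internal streams, so the generative law — and therefore the
population truth — is a pure function of the configuration, while the
per-cohort seed moves only sampling noise. All cohort randomness flows from a
single seed through spawned substreams.

**Truth oracle.** Population natural effects for ever- vs never-smoking are
computed by large-sample Monte Carlo integration (2×10⁶ common-random-number
draws) of the generative mediator and outcome models: mediator values are
realized under each counterfactual exposure (with smoker detail drawn from
the ever-smoker conditional law), pushed through the true outcome model, and
averaged; effects are logit contrasts of the averaged probabilities, so
TCE = NDE + NIE holds identically. The oracle is cross-checked in the test
suite against deterministic Gauss-Legendre/Gauss-Hermite quadrature of the
same law. When the total effect is structurally zero the proportion mediated
is reported as undefined rather than a ratio of noise.

## Preprocessing

Samples with strictly more than 5% missing probes are excluded first, then
probes missing in strictly more than 20% of the retained samples — the order
fixes an ambiguity (sample exclusion is treated as its own final QC step) and
the strict inequalities implement "more than" literally. Filtering is
idempotent, and a sample exclusion that orphans its matched partner drops the
whole pair in the pipeline. M-values are `log2(beta/(1-beta))`; per-probe
standardization uses the n−1 denominator. Risk models run on standardized
beta; trajectory models may use M-values.

## Cell composition

Discriminating probes are selected on the purified panel by a per-probe
one-way F test across cell types with Bonferroni control (default FWER 0.01;
the boundary `fwer = 1` selects every probe, so the selection rule is
`p_bonferroni <= fwer`). Proportions are estimated per sample by nonnegative
least squares of observed betas on the reference profiles and then
renormalized to sum to one; the original constrained-projection estimator
leaves the sum free, and renormalization can be disabled. The scan drops the
largest-mean cell type from the adjustment set to avoid compositional
collinearity.

## Association models

The logistic fitter is a compact IRLS/Newton routine with step-halving,
convergence at a log-likelihood change below 1e-10 (max 100 iterations), and
Wald inference (`exp(b ± 1.96 se)`), chosen over a library fit because the
null-calibration studies run hundreds of thousands of per-probe fits; it is
validated against brute-force likelihood maximization and an independent
library implementation in the tests. Rank deficiency raises an error naming
the collinear columns; fits whose linear predictor exceeds 20 in absolute
value are flagged as separated, and the scan retries them with a ridge
penalty (λ = 0.5) rather than reporting a spurious zero p-value.
Conditional logistic regression for 1:1 pairs is logistic-through-origin on
within-pair covariate differences, which reproduces the discordant-pair ratio
exactly for a binary exposure. The scan standardizes each probe, fits the
shared adjustment block (chip and position as categorical fixed effects,
cell proportions, age), reports every probe with a status code, and applies
`p_adj = min(1, p × N)` with N equal to the probes actually fitted.
Stratified models add the standard exposure categories (cigarettes/day <15,
15–24, ≥25; duration <30, 30–39, ≥40 years; time since quitting <5, 5–14,
≥15 years) in the strata where they are defined.

## Mediation

The mediator model is linear in exposure (ever/never), age and their
interaction, fitted by weighted least squares with case weights π and control
weights 1 − π, so the regression targets the source population; π is a
required analysis input (the package default is 0.01, and validation studies
pass the true generative prevalence). With several mediators the weighted
residual correlation is estimated and draws are made jointly ("separate
pathways" for the means, correlated residuals), keeping the joint NIE
well-defined. The outcome model is unconditional logistic with a configurable
interaction set (default: exposure×mediator and exposure×age). G-computation
draws `n_mc` mediator vectors per subject under each counterfactual regime
(one shared noise stream across regimes), evaluates the outcome probability,
and averages over the π-weighted empirical covariate distribution; natural
effects are logit contrasts of the averaged probabilities, so TCE = NDE + NIE
is an identity of the procedure. Because the case-control sample
over-represents cases, the outcome intercept is corrected by
`-log[(n_case/n_ctrl)(1-π)/π]` before probabilities are computed; this makes
the estimator consistent at any prevalence rather than only in the
rare-outcome limit. A closed-form rare-outcome solution (normal mediator,
logistic outcome with exposure-mediator interaction) serves as an independent
oracle. Inference is a pair-resampling bootstrap (percentile CIs, resample
standard deviations, normal-approximation p-values); the uncertainty method
is the package's choice, as is evaluating the mediation on unmatched
density-sampled sets in the validation studies — matched controls are not a
random sample of non-cases and would distort the π-weighted standardization
population. Exposure is strictly binary ever/never; dose and duration
summaries are out of scope for the mediation estimand.

## Reporting

The AUC is the rank (Mann-Whitney) statistic with ties counted one half. The
prediction comparison fits three nested in-sample logistic models — smoking
status alone, plus above-median methylation indicators (ties assigned below),
plus continuous standardized methylation — reporting apparent AUCs; apparent
discrimination is optimistic and the nested ordering is monotone only in
expectation, which is how the tests assert it. Cessation trajectories
summarize former smokers in years-since-quit bins with normal-approximation
CIs against never/current anchors. The three-level mixed model of the
replication design is simplified to fixed-effects regression on M-values with
cluster-robust standard errors at the matched-set level — a documented
deviation. Rendered tables use fixed float formats and no timestamps, so
output bytes are reproducible.

## Validation studies and problem sizes

The acceptance suite uses: arithmetic identities on the shipped published
estimates (exact); g-computation vs the closed form at outcome prevalence
~10⁻³ with n_mc = 10,000 (agreement within three Monte Carlo s.e., estimated
from replicate runs); a recovery study of 200 default-configuration cohorts
(25,000-subject populations, 1,000 pairs analysed, 150 bootstrap resamples
each) checking that the mean estimated proportion mediated lies within ±0.03
of the oracle truth and that bootstrap 95% CIs cover it 90–99% of the time;
null calibration of the scan (200 replicates of 1,000 probes × 300 subjects)
and of the never-smoker stratum (100 replicates); exact estimator oracles;
and hand-enumerated filter fixtures. These sizes were chosen as the smallest
at which the checks are sharp.

## What passing tests do and do not show

The generator emulates the statistical structure of the motivating study —
effect sizes, reversal, leukocyte mixture, batch and missingness, partial
mediation — but not raw-intensity artefacts (no IDAT-level simulation, dye
bias, SNP-under-probe effects or sex chromosomes), genomic correlation
between probes, or exposure measurement error. Recovery of the true mediated
proportion under this law shows the estimators are correct and calibrated
under their assumptions (no unmeasured confounding, correctly specified
mediator and outcome models, known prevalence); it cannot certify those
assumptions in real cohorts, where residual smoking confounding remains the
central threat to a causal reading.

## Known limitations

* The mediator model assumes normal residuals; the generative law is
  logit-normal with a quit-time mixture in ever-smokers, so small biases in
  TCE/NIE (a few percent, largely cancelling in the ratio) are expected and
  visible in the recovery study.
* Apparent AUCs are not validated estimates of discrimination.
* The proportion mediated is unstable when the total effect is near zero;
  it is flagged rather than silently reported.
* Bonferroni control is the only multiplicity method; FDR-selected probe
  sets enter only as explicit mediator lists (optionally aggregated by mean).
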