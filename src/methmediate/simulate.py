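"""Synthetic nested case-control methylation cohorts with known ground truth.

The generator emulates a prospective blood-methylation study of smoking and
lung cancer:

* a population of subjects with age, smoking status (never/former/current),
  time since quitting, duration and intensity of smoking;
* an Illumina-450K-like (scaled down) beta-value matrix built from a
  leukocyte-mixture model: per-cell-type probe means mixed by subject-level
  Dirichlet proportions, a multiplicative smoking shift at designated
  smoking-responsive probes (current smokers sit at ``1 - r`` times the
  never-smoker mean, default r = 0.19), exponential reversal of that shift
  with time since quitting, and logit-scale measurement noise;
* disease generated prospectively from a logistic model in which part of the
  smoking effect flows through methylation at designated mediator probes,
  then a nested case-control set drawn by incidence-density sampling;
* a purified-cell reference panel, chip/position batch effects and
  detection-p missingness for the technical layer.

The probe architecture and the calibration constants of the outcome model are
drawn from fixed internal streams, so the generative law - and hence the
population truth returned by :func:`true_effects_oracle` - is a pure function
of the :class:`~methmediate.config.SimulationConfig`, while ``config.seed``
controls only the sampling noise of an individual cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ConfigurationError, SimulationConfig
from .containers import MethylationMatrix, ReferenceProfiles, validate_sample_sheet

# Internal streams; independent of config.seed by design (see module docstring).
_ARCHITECTURE_SEED = 715
_CALIBRATION_SEED = 20151215
_ORACLE_SEED = 904823

_BETA_EPS = 1e-6

#: Well-known smoking CpGs used to label the first two designated mediators.
_NAMED_MEDIATORS = [
    ("cg05575921", "AHRR", 5, 373378, "N_Shore", 0.85),
    ("cg03636183", "F2RL3", 19, 17000585, "N_Shore", 0.80),
]


class MatchingError(RuntimeError):
    """Raised when eligible controls cannot be found for some cases."""

    def __init__(self, unmatched: Sequence[str]):
        self.unmatched = list(unmatched)
        super().__init__(
            f"no eligible control for {len(self.unmatched)} case(s): "
            f"{self.unmatched[:10]}"
        )


@dataclass
class CohortTruth:
    """Ground truth accompanying a simulated population.

    Holds the per-subject cell proportions, the per-probe multiplicative
    smoking effect (current vs never), the realized outcome-model
    coefficients including the internal standardization constants, and the
    population natural-effect decomposition from the truth oracle.
    """

    cell_proportions: pd.DataFrame
    probe_smoking_factor: pd.Series
    outcome_coefficients: dict
    mediator_probes: list[str]
    natural_effects: dict
    seed: int

    def __post_init__(self) -> None:
        props = self.cell_proportions.to_numpy()
        if np.any(props < -1e-12) or np.any(np.abs(props.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("cell proportions must be nonnegative and sum to 1")
        for key in ("tce", "nde", "nie"):
            if not np.isfinite(self.natural_effects[key]):
                raise ValueError(f"non-finite truth quantity {key}")


# ---------------------------------------------------------------------------
# Probe architecture and calibration (pure functions of the config)
# ---------------------------------------------------------------------------

def _architecture(config: SimulationConfig):
    return _architecture_cached(config.with_(seed=0))


@lru_cache(maxsize=32)
def _architecture_cached(config: SimulationConfig):
    """Per-probe structure: ids, annotations, per-cell-type base means.

    Layout: mediator probes first, then the remaining responsive probes, then
    cell-discriminating probes, then inert probes. Responsive and inert
    probes share their mean across cell types; discriminating probes get
    independent per-type means so that the purified panel carries signal.
    """
    rng = np.random.default_rng(_ARCHITECTURE_SEED)
    P, K = config.n_probes, len(config.cell_types)
    n_resp, n_med, n_disc = (
        config.n_responsive_probes,
        config.n_mediators,
        config.n_discriminating_probes,
    )
    probe_ids: list[str] = []
    genes: list[str] = []
    chroms: list[int] = []
    positions: list[int] = []
    regions: list[str] = []
    base = np.empty(P)
    for j in range(P):
        if j < min(n_med, len(_NAMED_MEDIATORS)):
            pid, gene, chrom, pos, region, level = _NAMED_MEDIATORS[j]
            base[j] = level
        else:
            pid = f"cg{10000000 + j:08d}"
            gene, region = "", ""
            chrom = int(rng.integers(1, 23))
            pos = int(rng.integers(10_000, 100_000_000))
            if j < n_resp:
                base[j] = rng.uniform(0.55, 0.92)
            else:
                base[j] = rng.uniform(0.10, 0.90)
        probe_ids.append(pid)
        genes.append(gene)
        chroms.append(chrom)
        positions.append(pos)
        regions.append(region)
    means = np.tile(base, (K, 1))  # K x P
    disc_lo, disc_hi = n_resp, n_resp + n_disc
    if n_disc:
        means[:, disc_lo:disc_hi] = rng.uniform(0.15, 0.85, size=(K, n_disc))
    annotations = pd.DataFrame(
        {"gene": genes, "chromosome": chroms, "position": positions, "region": regions},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return {
        "probe_ids": probe_ids,
        "annotations": annotations,
        "means": means,
        "mediator_idx": np.arange(n_med),
        "responsive_idx": np.arange(n_resp),
        "discriminating_idx": np.arange(disc_lo, disc_hi),
    }


def _smoking_factor(config: SimulationConfig, status: np.ndarray, ysq: np.ndarray) -> np.ndarray:
    """Multiplicative shift of responsive-probe means: 1-r for current smokers,
    exponential return toward 1 with time since quitting for former smokers."""
    r = config.relative_hypomethylation
    factor = np.ones(status.shape[0])
    factor[status == 2] = 1.0 - r
    former = status == 1
    factor[former] = 1.0 - r * np.exp2(-ysq[former] / config.reversal_halflife)
    return factor


def _draw_smoking(config: SimulationConfig, rng: np.random.Generator, n: int):
    status = rng.choice(3, size=n, p=np.asarray(config.smoking_prevalence))
    ysq = np.full(n, np.nan)
    former = status == 1
    ysq[former] = rng.uniform(0.5, config.max_years_since_quit, former.sum())
    return status, ysq


def _mediator_betas(
    config: SimulationConfig,
    status: np.ndarray,
    ysq: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mediator-probe betas for given smoking covariates (n x n_mediators)."""
    arch = _architecture(config)
    base = arch["means"][0, arch["mediator_idx"]]  # shared across cell types
    factor = _smoking_factor(config, status, ysq)
    mean = np.clip(np.outer(factor, base), 1e-4, 1 - 1e-4)
    sd_logit = config.noise_sd / (mean * (1.0 - mean))
    betas = expit(logit(mean) + rng.standard_normal(mean.shape) * sd_logit)
    return np.clip(betas, _BETA_EPS, 1 - _BETA_EPS)


def _calibration(config: SimulationConfig, n: int = 200_000):
    return _calibration_cached(config.with_(seed=0), n)


@lru_cache(maxsize=32)
def _calibration_cached(config: SimulationConfig, n: int = 200_000):
    """Marginal mean/s.d. of each mediator probe under the generative law.

    Fixed-stream Monte Carlo; these constants convert the configured
    per-1-s.d. outcome coefficients to the raw beta scale.
    """
    if config.n_mediators == 0:
        return np.empty(0), np.empty(0)
    rng = np.random.default_rng(_CALIBRATION_SEED)
    status, ysq = _draw_smoking(config, rng, n)
    betas = _mediator_betas(config, status, ysq, rng)
    return betas.mean(axis=0), betas.std(axis=0, ddof=1)


def _age_moments(config: SimulationConfig) -> tuple[float, float]:
    lo, hi = config.age_range
    return (lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0)


def _outcome_linear_predictor(
    config: SimulationConfig,
    ever: np.ndarray,
    ages: np.ndarray,
    mediator_betas: np.ndarray,
) -> np.ndarray:
    oc = config.outcome_coeffs
    age_mean, age_sd = _age_moments(config)
    z_age = (ages - age_mean) / age_sd
    lp = oc.intercept + oc.direct_smoking_log_or * ever + oc.age_log_or_per_sd * z_age
    lp = lp + oc.exposure_age_interaction * ever * z_age
    if config.n_mediators:
        mu, sd = _calibration(config)
        z = (mediator_betas - mu) / sd
        lp = lp + z @ np.asarray(oc.mediator_log_or_per_sd)
        lp = lp + ever * (z @ np.asarray(oc.exposure_mediator_interaction))
    return lp


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

def simulate_population(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, pd.DataFrame, CohortTruth]:
    """Simulate the full prospective cohort before case-control sampling.

    Returns the biological (pre-technical-layer) beta matrix, the population
    sample sheet (``case`` is the prospective disease indicator, with an
    ``event_time`` column for cases), and the :class:`CohortTruth`.
    Deterministic given ``config.seed``.
    """
    arch = _architecture(config)
    n, P = config.n_population, config.n_probes
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_cov, rng_cells, rng_meth, rng_out, rng_chip = map(np.random.default_rng, streams)

    ages = rng_cov.uniform(*config.age_range, n)
    status, ysq = _draw_smoking(config, rng_cov, n)
    ever = (status > 0).astype(float)
    start_age = rng_cov.uniform(16.0, 22.0, n)
    smoke_years = np.full(n, np.nan)
    smoke_years[status == 2] = ages[status == 2] - start_age[status == 2]
    smoke_years[status == 1] = np.clip(
        ages[status == 1] - start_age[status == 1] - ysq[status == 1], 1.0, None
    )
    cigs = np.full(n, np.nan)
    n_ever = int(ever.sum())
    cigs[ever > 0] = np.clip(rng_cov.normal(15.0, 6.0, n_ever), 1.0, 60.0)

    conc = np.asarray(config.dirichlet_concentration)
    gam = rng_cells.standard_gamma(conc, size=(n, conc.size))
    cells = gam / gam.sum(axis=1, keepdims=True)

    # Mixture mean on the beta scale, smoking shift, logit-scale noise.
    mix = cells @ arch["means"]  # n x P
    factor = _smoking_factor(config, status, ysq)
    mix[:, arch["responsive_idx"]] *= factor[:, None]
    mix = np.clip(mix, 1e-4, 1 - 1e-4)
    sd_logit = config.noise_sd / (mix * (1.0 - mix))
    betas = expit(logit(mix) + rng_meth.standard_normal((n, P)) * sd_logit)
    betas = np.clip(betas, _BETA_EPS, 1 - _BETA_EPS)

    med_betas = betas[:, arch["mediator_idx"]]
    lp = _outcome_linear_predictor(config, ever, ages, med_betas)
    disease = rng_out.random(n) < expit(lp)
    event_time = np.full(n, np.inf)
    event_time[disease] = rng_out.uniform(0.0, config.followup_years, int(disease.sum()))

    spc = config.batch.samples_per_chip
    order = rng_chip.permutation(n)
    chip = np.empty(n, dtype=object)
    position = np.empty(n, dtype=int)
    chip[order] = [f"chip{c // spc + 1:04d}" for c in range(n)]
    position[order] = [c % spc + 1 for c in range(n)]

    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    smoking_labels = np.array(["never", "former", "current"])[status]
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "pair_id": pd.array([pd.NA] * n, dtype="string"),
            "case": disease.astype(int),
            "event_time": event_time,
            "age": ages,
            "sex": "F",
            "smoking_status": smoking_labels,
            "years_since_quit": ysq,
            "smoke_years": smoke_years,
            "cigs_per_day": cigs,
            "chip": chip,
            "position": position,
        }
    )
    matrix = MethylationMatrix(
        pd.DataFrame(betas.T, index=arch["annotations"].index, columns=sample_ids),
        arch["annotations"],
    )
    probe_factor = pd.Series(1.0, index=arch["annotations"].index)
    probe_factor.iloc[arch["responsive_idx"]] = 1.0 - config.relative_hypomethylation
    mu, sd = _calibration(config)
    truth = CohortTruth(
        cell_proportions=pd.DataFrame(cells, index=sample_ids, columns=list(config.cell_types)),
        probe_smoking_factor=probe_factor,
        outcome_coefficients={
            "intercept": config.outcome_coeffs.intercept,
            "direct_smoking_log_or": config.outcome_coeffs.direct_smoking_log_or,
            "mediator_log_or_per_sd": list(config.outcome_coeffs.mediator_log_or_per_sd),
            "age_log_or_per_sd": config.outcome_coeffs.age_log_or_per_sd,
            "exposure_mediator_interaction": list(
                config.outcome_coeffs.exposure_mediator_interaction
            ),
            "exposure_age_interaction": config.outcome_coeffs.exposure_age_interaction,
            "mediator_mean": list(mu),
            "mediator_sd": list(sd),
        },
        mediator_probes=[arch["probe_ids"][j] for j in arch["mediator_idx"]],
        natural_effects=true_effects_oracle(config),
        seed=config.seed,
    )
    return matrix, sheet, truth


def mediator_probe_ids(config: SimulationConfig) -> list[str]:
    arch = _architecture(config)
    return [arch["probe_ids"][j] for j in arch["mediator_idx"]]


def responsive_probe_ids(config: SimulationConfig) -> list[str]:
    arch = _architecture(config)
    return [arch["probe_ids"][j] for j in arch["responsive_idx"]]


def discriminating_probe_ids(config: SimulationConfig) -> list[str]:
    arch = _architecture(config)
    return [arch["probe_ids"][j] for j in arch["discriminating_idx"]]


# ---------------------------------------------------------------------------
# Nested case-control sampling
# ---------------------------------------------------------------------------

def draw_nested_case_control(
    population: pd.DataFrame,
    n_pairs: int,
    matching_vars: Sequence[str] = (),
    seed: int = 0,
    calipers: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Incidence-density sample 1:1 case-control pairs from the population.

    Each control is disease-free at its case's event time (future cases may
    serve as controls before their own event), matches the case exactly on
    categorical ``matching_vars`` and within a caliper on continuous ones
    (default caliper 2.0 for ``age``, must be supplied otherwise), and no
    subject appears in more than one pair. Raises :class:`MatchingError`
    listing the unmatched cases when the risk set is exhausted.
    """
    calipers = dict(calipers or {})
    calipers.setdefault("age", 2.0)
    for var in matching_vars:
        if var not in population.columns:
            raise KeyError(f"matching variable {var!r} not in sample sheet")
    cases_available = population.index[population["case"] == 1]
    if len(cases_available) < n_pairs:
        raise MatchingError(
            [f"requested {n_pairs} pairs but only {len(cases_available)} cases exist"]
        )
    rng = np.random.default_rng(seed)
    chosen_cases = rng.choice(cases_available, size=n_pairs, replace=False)

    disease = population["case"].to_numpy()
    event_time = (
        population["event_time"].to_numpy()
        if "event_time" in population
        else np.where(disease == 1, 0.0, np.inf)
    )
    used = np.zeros(len(population), dtype=bool)
    pos = {idx: i for i, idx in enumerate(population.index)}
    used[[pos[c] for c in chosen_cases]] = True

    match_cols = {v: population[v].to_numpy() for v in matching_vars}
    rows: list[tuple] = []  # (pair, case_idx, control_idx)
    unmatched: list[str] = []
    for k, case_idx in enumerate(chosen_cases):
        i = pos[case_idx]
        eligible = ~used
        eligible &= event_time > event_time[i]  # at risk at the case's event time
        for var, col in match_cols.items():
            if var in calipers:
                eligible &= np.abs(col - col[i]) <= calipers[var]
            else:
                eligible &= col == col[i]
        candidates = np.flatnonzero(eligible)
        if candidates.size == 0:
            unmatched.append(str(population["sample_id"].iloc[i]))
            continue
        j = int(rng.choice(candidates))
        used[j] = True
        rows.append((k, i, j))
    if unmatched:
        raise MatchingError(unmatched)

    records = []
    for k, i, j in rows:
        pair = f"P{k + 1:05d}"
        case_row = population.iloc[i].copy()
        ctrl_row = population.iloc[j].copy()
        case_row["case"], ctrl_row["case"] = 1, 0
        case_row["pair_id"] = ctrl_row["pair_id"] = pair
        records.append(case_row)
        records.append(ctrl_row)
    sheet = pd.DataFrame(records).reset_index(drop=True)
    return validate_sample_sheet(sheet)


def assign_chips(
    sheet: pd.DataFrame,
    samples_per_chip: int = 12,
    seed: int = 0,
    keep_pairs_together: bool = True,
) -> pd.DataFrame:
    """(Re)assign chips/positions; matched pairs share a chip by default,
    mirroring the design practice of processing case-control pairs together."""
    sheet = sheet.copy()
    rng = np.random.default_rng(seed)
    if keep_pairs_together and "pair_id" in sheet.columns and sheet["pair_id"].notna().all():
        pair_order = rng.permutation(sheet["pair_id"].unique())
        ordered = []
        for p in pair_order:
            members = sheet.index[sheet["pair_id"] == p].to_numpy()
            ordered.extend(rng.permutation(members).tolist())  # randomize within pair
    else:
        ordered = list(rng.permutation(sheet.index.to_numpy()))
    chips = np.empty(len(sheet), dtype=object)
    positions = np.empty(len(sheet), dtype=int)
    for slot, idx in enumerate(ordered):
        loc = sheet.index.get_loc(idx)
        chips[loc] = f"chip{slot // samples_per_chip + 1:04d}"
        positions[loc] = slot % samples_per_chip + 1
    sheet["chip"] = chips
    sheet["position"] = positions
    return sheet


# ---------------------------------------------------------------------------
# Reference panel and technical layer
# ---------------------------------------------------------------------------

def simulate_reference_panel(
    config: SimulationConfig,
    seed: int = 0,
    n_replicates: int = 6,
    purified_noise_sd: float = 0.01,
) -> tuple[ReferenceProfiles, MethylationMatrix, pd.Series]:
    """Purified-leukocyte panel: true per-type probe means plus replicate
    samples (e.g. six healthy donors per type) drawn around them."""
    if len(config.cell_types) < 2:
        raise ConfigurationError("reference panel needs at least two cell types")
    arch = _architecture(config)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    means = arch["means"]  # K x P
    K, P = means.shape
    cols, labels, data = [], [], []
    for k, ct in enumerate(config.cell_types):
        mean = np.clip(means[k], 1e-4, 1 - 1e-4)
        sd_logit = purified_noise_sd / (mean * (1 - mean))
        for r in range(n_replicates):
            betas = expit(logit(mean) + rng.standard_normal(P) * sd_logit)
            data.append(np.clip(betas, _BETA_EPS, 1 - _BETA_EPS))
            cols.append(f"{ct}_rep{r + 1}")
            labels.append(ct)
    purified = MethylationMatrix(
        pd.DataFrame(np.column_stack(data), index=arch["annotations"].index, columns=cols),
        arch["annotations"],
    )
    profiles = ReferenceProfiles(
        pd.DataFrame(means.T, index=arch["annotations"].index, columns=list(config.cell_types))
    )
    return profiles, purified, pd.Series(labels, index=cols, name="cell_type")


def apply_technical_layer(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    config: SimulationConfig,
    seed: int = 0,
    contaminated_samples: Sequence[str] = (),
    contaminated_rate: float = 0.5,
) -> MethylationMatrix:
    """Add chip/position shifts (logit scale) and detection-p missingness.

    Requires ``chip`` and ``position`` columns in the sheet. Samples listed in
    ``contaminated_samples`` receive an elevated missingness rate (for
    exercising the QC filters).
    """
    if not (0.0 <= config.detection_missing_rate <= 1.0) or not (0.0 <= contaminated_rate <= 1.0):
        raise ConfigurationError("missingness rates must lie in [0,1]")
    for col in ("chip", "position"):
        if col not in sheet.columns:
            raise ConfigurationError(f"sample sheet lacks {col!r}; assign chips first")
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    missing_samples = [s for s in matrix.sample_ids if s not in sheet.index]
    if missing_samples:
        raise ConfigurationError(f"samples without chip assignment: {missing_samples[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    values = matrix.values.copy()

    chips = sheet.loc[matrix.sample_ids, "chip"]
    positions = sheet.loc[matrix.sample_ids, "position"]
    chip_levels = pd.unique(chips)
    pos_levels = pd.unique(positions)
    chip_shift = pd.Series(rng.normal(0.0, config.batch.chip_sd, len(chip_levels)), index=chip_levels)
    pos_shift = pd.Series(
        rng.normal(0.0, config.batch.position_sd, len(pos_levels)), index=pos_levels
    )
    shift = chip_shift[chips].to_numpy() + pos_shift[positions].to_numpy()
    if np.any(shift != 0.0):  # skip the logit round trip in the exact-identity case
        arr = values.to_numpy()
        shifted = expit(logit(arr) + shift[None, :])
        values = pd.DataFrame(
            np.clip(shifted, _BETA_EPS, 1 - _BETA_EPS), index=values.index, columns=values.columns
        )

    rate = np.full(matrix.n_samples, config.detection_missing_rate)
    contaminated = set(contaminated_samples)
    for j, s in enumerate(matrix.sample_ids):
        if s in contaminated:
            rate[j] = contaminated_rate
    if np.any(rate > 0):
        drop = rng.random(values.shape) < rate[None, :]
        values = values.mask(drop)
    return MethylationMatrix(values, matrix.annotations)


# ---------------------------------------------------------------------------
# Population truth oracle
# ---------------------------------------------------------------------------

def true_effects_oracle(config: SimulationConfig, n_draws: int = 2_000_000) -> dict:
    """Population-truth natural effects of ever- vs never-smoking; the truth
    is a pure function of the configuration, so the per-cohort seed is
    irrelevant and results are cached per configuration."""
    return dict(_oracle_cached(config.with_(seed=0), n_draws))


@lru_cache(maxsize=32)
def _oracle_cached(config: SimulationConfig, n_draws: int = 2_000_000) -> dict:
    """Population-truth natural effects of ever- vs never-smoking.

    Large-sample Monte Carlo integration of the generative mediator and
    outcome models with common random numbers across counterfactual regimes:
    for each draw of covariates and smoker detail (current/former and time
    since quitting, from the ever-smoker conditional law), mediator values
    are realized under never and under ever exposure, pushed through the true
    outcome model under each exposure, and averaged. Effects are logit
    contrasts of the averaged probabilities; ``tce = nde + nie`` holds by
    construction. Deterministic (fixed internal stream) and cached per config.
    """
    rng = np.random.default_rng(_ORACLE_SEED)
    ages = rng.uniform(*config.age_range, n_draws)
    p_never, p_former, p_current = config.smoking_prevalence
    p_cur_given_ever = p_current / (p_former + p_current) if (p_former + p_current) > 0 else 0.0
    status_ever = np.where(rng.random(n_draws) < p_cur_given_ever, 2, 1)
    ysq = np.full(n_draws, np.nan)
    former = status_ever == 1
    ysq[former] = rng.uniform(0.5, config.max_years_since_quit, former.sum())

    J = config.n_mediators
    if J:
        arch = _architecture(config)
        base = arch["means"][0, arch["mediator_idx"]]
        eps = rng.standard_normal((n_draws, J))

        def mediator(regime_factor: np.ndarray) -> np.ndarray:
            mean = np.clip(np.outer(regime_factor, base), 1e-4, 1 - 1e-4)
            sd_logit = config.noise_sd / (mean * (1 - mean))
            return np.clip(expit(logit(mean) + eps * sd_logit), _BETA_EPS, 1 - _BETA_EPS)

        m_never = mediator(np.ones(n_draws))
        m_ever = mediator(_smoking_factor(config, status_ever, ysq))
    else:
        m_never = m_ever = np.empty((n_draws, 0))

    def p_bar(a: float, m: np.ndarray) -> float:
        lp = _outcome_linear_predictor(config, np.full(n_draws, a), ages, m)
        return float(expit(lp).mean())

    p11, p10, p00 = p_bar(1.0, m_ever), p_bar(1.0, m_never), p_bar(0.0, m_never)
    if not (0.0 < min(p11, p10, p00) and max(p11, p10, p00) < 1.0):
        raise ValueError("degenerate counterfactual probability in truth oracle")
    nde = float(logit(p10) - logit(p00))
    nie = float(logit(p11) - logit(p10))
    tce = nde + nie
    out = {
        "tce": tce,
        "nde": nde,
        "nie": nie,
        "p11": p11,
        "p10": p10,
        "p00": p00,
        "n_draws": n_draws,
        "proportion_defined": True,
    }
    mc_se = np.sqrt((1 - p11) / (p11 * n_draws)) + np.sqrt((1 - p00) / (p00 * n_draws))
    if abs(tce) < 5 * mc_se:
        out["proportion_mediated"] = float("nan")
        out["proportion_defined"] = False
    else:
        out["proportion_mediated"] = nie / tce
    return out
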