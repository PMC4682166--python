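"""Core in-memory containers shared across the pipeline.

The central object is :class:`MethylationMatrix`, a probes x samples table of
Illumina-style beta values (fraction methylated, in the open interval (0, 1))
with missingness represented as NaN and carried alongside per-probe
annotations (gene, chromosome, position, CpG-island region).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["gene", "chromosome", "position", "region"]

#: Column dictionary of the sample sheet (see io.read_sample_sheet).
SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "pair_id",
    "case",
    "age",
    "sex",
    "smoking_status",
    "years_since_quit",
    "smoke_years",
    "cigs_per_day",
    "chip",
    "position",
]

SMOKING_LEVELS = ("never", "former", "current")


class ValidationError(ValueError):
    """Input data violates a documented contract."""


class DegenerateProbeError(ValueError):
    """A probe has too few observations or zero spread to be standardized."""


class MethylationMatrix:
    """Probes x samples beta-value matrix with missingness mask and annotations.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns. NaN encodes
        a missing (non-detected) measurement; every observed value must lie
        strictly inside (0, 1).
    annotations
        Optional DataFrame indexed by probe id with columns
        ``gene, chromosome, position, region``. Missing annotations are
        filled with empty strings / -1.
    """

    def __init__(self, values: pd.DataFrame, annotations: pd.DataFrame | None = None):
        if not values.index.is_unique:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
        if not values.columns.is_unique:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = values.to_numpy(dtype=float)
        bad = np.isfinite(arr) & ((arr <= 0.0) | (arr >= 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of (0,1) at probe {values.index[i]!r}, "
                f"sample {values.columns[j]!r}: {arr[i, j]!r}"
            )
        self.values = values.astype(float)
        self.values.index.name = "probe_id"
        self.values.columns.name = None
        if annotations is None:
            annotations = pd.DataFrame(index=values.index)
        annotations = annotations.reindex(values.index)
        for col, default in zip(ANNOTATION_COLUMNS, ["", -1, -1, ""]):
            if col not in annotations:
                annotations[col] = default
        self.annotations = annotations[ANNOTATION_COLUMNS].copy()
        self.annotations["gene"] = self.annotations["gene"].fillna("")
        self.annotations["region"] = self.annotations["region"].fillna("")

    # -- basic interface ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask, True where the entry is missing."""
        return self.values.isna()

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes: Sequence[str]) -> "MethylationMatrix":
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return MethylationMatrix(self.values.loc[list(probes)], self.annotations.loc[list(probes)])

    def subset_samples(self, samples: Sequence[str]) -> "MethylationMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return MethylationMatrix(self.values[list(samples)], self.annotations)

    def probe_values(self, probe: str) -> pd.Series:
        """Beta values of one probe across samples (NaN = missing)."""
        return self.values.loc[probe]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MethylationMatrix({self.n_probes} probes x {self.n_samples} samples)"


@dataclass
class ReferenceProfiles:
    """Mean methylation of purified leukocyte subtypes at a probe subset.

    ``profiles`` is probes x cell-types; used as the design of the
    constrained projection in reference-based deconvolution.
    """

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValidationError("reference panel needs at least two cell types")
        if self.profiles.shape[0] == 0:
            raise ValidationError("reference panel probe set is empty")
        arr = self.profiles.to_numpy()
        if not np.all((arr > 0) & (arr < 1)):
            raise ValidationError("reference profile means must lie in (0,1)")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.profiles.index


@dataclass
class FilterReport:
    """Outcome of the missingness QC filters (samples first, then probes)."""

    sample_threshold: float
    probe_threshold: float
    removed_samples: list[str]
    removed_probes: list[str]
    n_samples_before: int
    n_probes_before: int

    @property
    def n_samples_removed(self) -> int:
        return len(self.removed_samples)

    @property
    def n_probes_removed(self) -> int:
        return len(self.removed_probes)

    def to_dict(self) -> dict:
        return {
            "sample_threshold": self.sample_threshold,
            "probe_threshold": self.probe_threshold,
            "removed_samples": list(self.removed_samples),
            "removed_probes": list(self.removed_probes),
            "n_samples_before": self.n_samples_before,
            "n_probes_before": self.n_probes_before,
            "n_samples_removed": self.n_samples_removed,
            "n_probes_removed": self.n_probes_removed,
        }


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    names: list[str]
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    flag: str = "ok"  # ok | separation | no_convergence

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def p_wald(self) -> np.ndarray:
        from scipy import stats

        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2.0)
        i = self.names.index(name)
        return (
            float(self.params[i] - z * self.se[i]),
            float(self.params[i] + z * self.se[i]),
        )


@dataclass
class MediatorModel:
    """Design-weighted linear models for the mediator(s).

    One column of ``coefficients`` per mediator probe, rows
    ``intercept, exposure, age, exposure:age``. ``sigma`` holds residual
    standard deviations; ``residual_corr`` the weighted residual correlation
    across mediators (identity for a single mediator).
    """

    coefficients: pd.DataFrame
    sigma: pd.Series
    residual_corr: pd.DataFrame
    prevalence: float | None
    n_obs: int

    @property
    def mediators(self) -> list[str]:
        return list(self.coefficients.columns)

    def residual_cov(self) -> np.ndarray:
        s = self.sigma.to_numpy()
        return self.residual_corr.to_numpy() * np.outer(s, s)


@dataclass
class OutcomeModel:
    """Logistic disease model with configurable interaction set."""

    fit: LogisticFit
    mediators: list[str]
    interactions: tuple[str, ...]
    n_cases: int
    n_controls: int


@dataclass
class MediationResult:
    """Natural-effect decomposition of the smoking effect on the log-OR scale.

    ``tce = nde + nie`` holds by construction (shared p(1,0) term);
    ``proportion_mediated = nie / tce`` on the log scale.
    """

    tce: float
    nde: float
    nie: float
    proportion_mediated: float
    mediators: list[str]
    prevalence: float | None
    n_mc: int
    seed: int | None
    proportion_unstable: bool = False
    n_bootstrap: int = 0
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mediators": list(self.mediators),
            "tce": self.tce,
            "nde": self.nde,
            "nie": self.nie,
            "proportion_mediated": self.proportion_mediated,
            "proportion_unstable": self.proportion_unstable,
            "prevalence": self.prevalence,
            "n_mc": self.n_mc,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "se": dict(self.se),
            "ci": {k: list(v) for k, v in self.ci.items()},
            "p": dict(self.p),
        }


@dataclass
class PredictionComparison:
    """In-sample AUCs of three nested lung-cancer risk models."""

    auc_smoking_only: float
    auc_plus_categorical: float
    auc_plus_continuous: float
    n: int
    probes: list[str]


@dataclass
class TrajectorySummary:
    """Mean methylation by years-since-quitting bin with group anchors."""

    probe: str
    scale: str
    bins: pd.DataFrame  # columns: bin_low, bin_high, n, mean, ci_low, ci_high
    never_mean: float
    current_mean: float


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-sample covariate sheet against the column dictionary.

    Raises :class:`ValidationError` listing the offending rows for
    inconsistent smoking fields or broken pair structure.
    """
    required = ["sample_id", "case", "age", "smoking_status"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing required columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    bad_status = ~sheet["smoking_status"].isin(SMOKING_LEVELS)
    if bad_status.any():
        rows = sheet.loc[bad_status, "sample_id"].tolist()
        raise ValidationError(
            f"smoking_status must be one of {SMOKING_LEVELS}; offending samples: {rows[:5]}"
        )
    if "years_since_quit" in sheet.columns:
        ysq = sheet["years_since_quit"]
        former = sheet["smoking_status"] == "former"
        bad = (former & ysq.isna()) | (~former & ysq.notna())
        if bad.any():
            rows = sheet.loc[bad, "sample_id"].tolist()
            raise ValidationError(
                "years_since_quit must be set for former smokers and empty "
                f"otherwise; offending samples: {rows[:5]}"
            )
    if "pair_id" in sheet.columns and sheet["pair_id"].notna().any():
        counts = sheet["pair_id"].value_counts()
        lonely = counts[counts != 2].index.tolist()
        if lonely:
            raise ValidationError(f"pair ids without exactly two members: {lonely[:5]}")
        paired = sheet[sheet["pair_id"].notna()]
        per_pair = paired.groupby("pair_id")["case"].sum()
        bad_pairs = per_pair[per_pair != 1].index.tolist()
        if bad_pairs:
            raise ValidationError(
                f"each pair must contain one case and one control; offending pairs: {bad_pairs[:5]}"
            )
    return sheet
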