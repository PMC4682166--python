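"""Risk-prediction comparison, cessation trajectories and table/plot output.

The prediction comparison mirrors the incremental-AUC analysis: a logistic
model of case status on smoking status alone, then adding mediator
methylation as median-split indicators, then as continuous standardized
values, with apparent (in-sample) AUC for each nested model. Cessation
trajectories summarize mean methylation by years-since-quitting bins against
never- and current-smoker anchors. Mixed-effects trajectory models from the
replication design are simplified here to fixed-effects regression on
M-values with cluster-robust (matched-set) standard errors.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import RESULT_COLUMNS, fit_logistic
from .containers import (
    MediationResult,
    MethylationMatrix,
    PredictionComparison,
    TrajectorySummary,
    ValidationError,
)
from .preprocess import beta_to_m, standardize_probe


class MissingArtifactError(FileNotFoundError):
    """An upstream result required for rendering is absent."""


def auc_rank(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC with ties counted one half.

    Equals the probability that a random case scores above a random control,
    plus half the probability of a tie.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and aligned")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def incremental_prediction(
    sheet: pd.DataFrame,
    matrix: MethylationMatrix,
    probes: Sequence[str],
) -> PredictionComparison:
    """Apparent AUCs of three nested risk models on the same subjects.

    Model 1: smoking status (never/former/current indicators); model 2 adds
    each probe as an above-median indicator (ties go to the below-or-equal
    stratum, i.e. indicator = beta > median over the analysed subjects);
    model 3 adds the probes as continuous standardized betas instead.
    """
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    med = matrix.values.loc[list(probes)].T.loc[sheet.index]
    keep = med.notna().all(axis=1)
    sheet, med = sheet[keep.to_numpy()], med[keep]
    y = sheet["case"].to_numpy(dtype=float)
    base = [np.ones(len(sheet))]
    names = ["intercept"]
    for level in ("former", "current"):  # skip absent levels (all-zero columns)
        col = (sheet["smoking_status"] == level).to_numpy(dtype=float)
        if col.any():
            base.append(col)
            names.append(level)

    def auc_of(cols, colnames):
        fit = fit_logistic(np.column_stack(cols), y, names=colnames)
        return auc_rank(np.column_stack(cols) @ fit.params, y)

    auc1 = auc_of(base, names)
    split_cols, split_names = list(base), list(names)
    cont_cols, cont_names = list(base), list(names)
    for p in probes:
        v = med[p].to_numpy(dtype=float)
        split_cols.append((v > np.median(v)).astype(float))
        split_names.append(f"{p}_above_median")
        cont_cols.append(np.asarray(standardize_probe(v)))
        cont_names.append(f"{p}_sd")
    auc2 = auc_of(split_cols, split_names)
    auc3 = auc_of(cont_cols, cont_names)
    return PredictionComparison(
        auc_smoking_only=auc1,
        auc_plus_categorical=auc2,
        auc_plus_continuous=auc3,
        n=len(sheet),
        probes=list(probes),
    )


def cessation_trajectories(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    probe: str,
    bins: Sequence[float] = (0.0, 2.0, 5.0, 10.0, 20.0, 31.0),
    scale: str = "beta",
) -> TrajectorySummary:
    """Mean methylation by years-since-quitting bin in former smokers.

    Returns per-bin means with normal-approximation 95% CIs plus never- and
    current-smoker anchor means; ``scale`` may be ``beta`` or ``m``.
    """
    if scale not in ("beta", "m"):
        raise ValidationError("scale must be 'beta' or 'm'")
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    v = matrix.probe_values(probe).loc[sheet.index]
    if scale == "m":
        v = beta_to_m(v)
    former = sheet["smoking_status"] == "former"
    ysq = sheet.loc[former, "years_since_quit"]
    vals = v[former.to_numpy()]
    edges = np.asarray(bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing")
    observed_max = float(ysq.max()) if len(ysq) else 0.0
    if len(ysq) and (ysq.min() < edges[0] or observed_max >= edges[-1]):
        raise ValidationError("bins must cover the observed years-since-quit range")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (ysq >= lo) & (ysq < hi)
        x = vals[in_bin.to_numpy()].dropna()
        if len(x) == 0:
            rows.append(
                {"bin_low": lo, "bin_high": hi, "n": 0, "mean": np.nan, "ci_low": np.nan, "ci_high": np.nan}
            )
            continue
        m = float(x.mean())
        half = 1.96 * float(x.std(ddof=1)) / np.sqrt(len(x)) if len(x) > 1 else np.nan
        rows.append(
            {"bin_low": lo, "bin_high": hi, "n": int(len(x)), "mean": m, "ci_low": m - half, "ci_high": m + half}
        )
    never = v[(sheet["smoking_status"] == "never").to_numpy()].dropna()
    current = v[(sheet["smoking_status"] == "current").to_numpy()].dropna()
    return TrajectorySummary(
        probe=probe,
        scale=scale,
        bins=pd.DataFrame(rows),
        never_mean=float(never.mean()) if len(never) else float("nan"),
        current_mean=float(current.mean()) if len(current) else float("nan"),
    )


def trajectory_slope(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    probe: str,
    scale: str = "m",
) -> dict:
    """Linear trend of methylation on years since quitting in former smokers,
    with cluster-robust standard errors at the matched-set level when pair
    identifiers exist (fixed-effects simplification of a nested mixed model)."""
    import statsmodels.api as sm

    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    v = matrix.probe_values(probe).loc[sheet.index]
    if scale == "m":
        v = beta_to_m(v)
    former = (sheet["smoking_status"] == "former").to_numpy()
    obs = former & v.notna().to_numpy()
    sub = sheet[obs]
    X = sm.add_constant(np.column_stack([sub["years_since_quit"], sub["age"]]))
    model = sm.OLS(v[obs].to_numpy(dtype=float), X)
    if "pair_id" in sub.columns and sub["pair_id"].notna().all():
        res = model.fit(cov_type="cluster", cov_kwds={"groups": sub["pair_id"]})
    else:
        res = model.fit(cov_type="HC1")
    ci = res.conf_int()[1]
    return {
        "slope": float(res.params[1]),
        "se": float(res.bse[1]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p": float(res.pvalues[1]),
        "n": int(obs.sum()),
    }


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def write_scan_table(scan: pd.DataFrame, path: str) -> None:
    scan[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_stratified_table(stratified: Mapping[str, dict], path: str) -> None:
    rows = []
    for stratum, rec in stratified.items():
        rows.append({"stratum": stratum, **rec})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_mediation_table(block_table: pd.DataFrame, path: str) -> None:
    block_table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_mediation_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def render_tables(
    out_dir: str,
    scan: pd.DataFrame | None = None,
    stratified: Mapping[str, dict] | None = None,
    mediation: pd.DataFrame | None = None,
    trajectory: TrajectorySummary | None = None,
    prediction: PredictionComparison | None = None,
    plots: bool = True,
) -> list[str]:
    """Write publication-shaped TSVs (and optional SVG plots) to ``out_dir``.

    Output bytes are deterministic for fixed inputs: fixed float formats and
    no timestamps. Returns the list of files written. An empty scan yields a
    header-only TSV; a requested artifact that is None is simply skipped,
    while rendering nothing at all raises :class:`MissingArtifactError`.
    """
    if all(x is None for x in (scan, stratified, mediation, trajectory, prediction)):
        raise MissingArtifactError("no upstream results supplied to render")
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def record(name: str) -> str:
        path = os.path.join(out_dir, name)
        written.append(path)
        return path

    if scan is not None:
        write_scan_table(scan, record("scan_results.tsv"))
        if plots and len(scan):
            _scan_plot(scan, record("scan_pvalues.svg"))
    if stratified is not None:
        write_stratified_table(stratified, record("stratified_results.tsv"))
    if mediation is not None:
        write_mediation_table(mediation, record("mediation_results.tsv"))
    if prediction is not None:
        pd.DataFrame(
            [
                {
                    "model": "smoking_only",
                    "auc": prediction.auc_smoking_only,
                    "n": prediction.n,
                },
                {
                    "model": "plus_median_split",
                    "auc": prediction.auc_plus_categorical,
                    "n": prediction.n,
                },
                {
                    "model": "plus_continuous",
                    "auc": prediction.auc_plus_continuous,
                    "n": prediction.n,
                },
            ]
        ).to_csv(record("prediction_auc.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    if trajectory is not None:
        traj = trajectory.bins.copy()
        traj.insert(0, "probe", trajectory.probe)
        traj["never_mean"] = trajectory.never_mean
        traj["current_mean"] = trajectory.current_mean
        traj.to_csv(record("trajectory.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
        if plots:
            _trajectory_plot(trajectory, record("trajectory.svg"))
    return written


def _scan_plot(scan: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "methmediate"  # reproducible SVG ids
    fig, ax = plt.subplots(figsize=(6, 3.5))
    p = scan["p_wald"].to_numpy()
    ax.scatter(np.arange(len(p)), -np.log10(p), s=6, color="#33557a")
    n = int(scan["p_wald"].notna().sum())
    if n:
        ax.axhline(-np.log10(0.05 / n), linestyle="--", color="#aa3333", linewidth=1)
    ax.set_xlabel("probe rank")
    ax.set_ylabel("-log10 p")
    ax.set_title("locus-by-locus risk scan")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def _trajectory_plot(trajectory: TrajectorySummary, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "methmediate"  # reproducible SVG ids
    fig, ax = plt.subplots(figsize=(6, 3.5))
    b = trajectory.bins
    centers = (b["bin_low"] + b["bin_high"]) / 2.0
    ax.errorbar(
        centers,
        b["mean"],
        yerr=np.abs(b[["ci_low", "ci_high"]].sub(b["mean"], axis=0)).T.to_numpy(),
        fmt="o-",
        capsize=3,
        label="former smokers",
    )
    ax.axhline(trajectory.never_mean, color="green", linestyle="--", label="never")
    ax.axhline(trajectory.current_mean, color="red", linestyle=":", label="current")
    ax.set_xlabel("years since quitting")
    ax.set_ylabel(f"methylation ({trajectory.scale})")
    ax.set_title(trajectory.probe)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
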