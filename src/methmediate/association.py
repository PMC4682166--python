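"""Locus-by-locus risk analysis: logistic fits, matched-pair conditional
logistic, epigenome-wide scan, smoking stratification and Bonferroni control.

The unconditional logistic fitter is a compact iteratively reweighted least
squares (IRLS/Newton) routine on numpy arrays: the scan fits one model per
probe and a null-calibration study runs hundreds of thousands of such fits,
so per-fit overhead matters. Convergence is declared when the log-likelihood
changes by less than 1e-10 (at most 100 iterations); inference is Wald, with
ORs and symmetric-on-log confidence intervals ``exp(b +/- 1.96 se)``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DegenerateProbeError, LogisticFit, MethylationMatrix, ValidationError
from .preprocess import standardize_probe

RESULT_COLUMNS = [
    "probe_id",
    "gene",
    "chromosome",
    "position",
    "region",
    "or_per_sd",
    "ci_low",
    "ci_high",
    "p_wald",
    "p_bonferroni",
    "n_cases",
    "n_controls",
    "status",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"collinear design columns: {self.columns}")


class ConcordantPairsError(RuntimeError):
    """All matched pairs are concordant; the conditional likelihood is flat."""


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] == 0:
        return
    rmat = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(rmat))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[i] for i in range(len(diag)) if diag[i] <= tol]
    if bad or np.linalg.matrix_rank(X) < X.shape[1]:
        if not bad:  # rank deficiency not visible on the QR diagonal ordering
            bad = list(names)
        raise RankDeficiencyError(bad)


def _loglik(lp: np.ndarray, y: np.ndarray) -> float:
    # y*lp - log(1 + exp(lp)), numerically stable
    return float(np.sum(y * lp - np.logaddexp(0.0, lp)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    l2: float = 0.0,
    penalize_intercept: bool = False,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` must include the intercept column if one is wanted. Separation and
    non-convergence are flagged on the returned fit rather than silently
    accepted; rank deficiency raises :class:`RankDeficiencyError` naming the
    collinear columns. A ridge penalty ``l2`` (excluding the first column
    unless ``penalize_intercept``) supports the penalized fallback used for
    separated probes in the scan.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be 2-D with one row per outcome")
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("outcome must be binary 0/1")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if l2 == 0.0:
        _check_rank(X, names)
    pen = np.full(X.shape[1], l2)
    if not penalize_intercept and X.shape[1] and np.all(X[:, 0] == 1.0):
        pen[0] = 0.0

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        lp = X @ beta
        p = np.clip(1.0 / (1.0 + np.exp(-lp)), 1e-12, 1 - 1e-12)
        w = p * (1.0 - p)
        xtwx = X.T @ (X * w[:, None]) + np.diag(pen)
        score = X.T @ (y - p) - pen * beta
        try:
            delta = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(xtwx, score, rcond=None)[0]
        # step-halving keeps the likelihood monotone on hard problems
        step = 1.0
        ll_new = -np.inf
        for _ in range(12):
            cand = beta + step * delta
            ll_new = _loglik(X @ cand, y) - 0.5 * float(pen @ cand**2)
            if ll_new >= ll_old - 1e-12 or not np.isfinite(ll_old):
                break
            step /= 2.0
        beta = beta + step * delta
        if abs(ll_new - ll_old) < tol:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new

    lp = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-lp)), 1e-12, 1 - 1e-12)
    w = p * (1.0 - p)
    xtwx = X.T @ (X * w[:, None]) + np.diag(pen)
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(xtwx)
    flag = "ok"
    if not converged:
        flag = "no_convergence"
    elif l2 == 0.0 and np.max(np.abs(lp)) > 20.0:
        flag = "separation"
    return LogisticFit(
        names=names,
        params=beta,
        cov=cov,
        loglik=_loglik(lp, y),
        n_iter=n_iter,
        converged=converged,
        flag=flag,
    )


def fit_conditional_logistic_pairs(
    pairs: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str] = (),
) -> dict:
    """Conditional logistic regression for 1:1 matched pairs.

    Implemented as logistic regression through the origin on within-pair
    (case minus control) covariate differences; fully concordant pairs carry
    no information and are dropped. For a single binary exposure the estimate
    equals the discordant-pair (McNemar) ratio ``log(n10/n01)`` exactly.
    """
    if "pair_id" not in pairs.columns or pairs["pair_id"].isna().any():
        raise ValidationError("pair_id required for conditional logistic regression")
    cols = [exposure, *covariates]
    wide_case = pairs[pairs["case"] == 1].set_index("pair_id")[cols]
    wide_ctrl = pairs[pairs["case"] == 0].set_index("pair_id")[cols]
    common = wide_case.index.intersection(wide_ctrl.index)
    diffs = (wide_case.loc[common] - wide_ctrl.loc[common]).to_numpy(dtype=float)
    keep = np.isfinite(diffs).all(axis=1)
    diffs = diffs[keep]
    informative = np.any(diffs != 0.0, axis=1)
    diffs = diffs[informative]
    if diffs.shape[0] == 0 or np.all(diffs[:, 0] == 0.0):
        raise ConcordantPairsError("no discordant information in the matched pairs")
    fit = fit_logistic(diffs, np.ones(diffs.shape[0]), names=cols)
    return {
        "log_or": fit.coef(exposure),
        "se": fit.se_of(exposure),
        "p": float(fit.p_wald[cols.index(exposure)]),
        "n_informative_pairs": int(diffs.shape[0]),
        "fit": fit,
    }


def bonferroni_adjust(p_values, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``p_adj = min(1, p * N)``."""
    p = np.asarray(p_values, dtype=float)
    finite = p[~np.isnan(p)]
    if np.any((finite <= 0) | (finite > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    n = n_tests if n_tests is not None else p.size
    return np.minimum(1.0, p * n)


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def build_adjustment_design(
    sheet: pd.DataFrame,
    adjust: Sequence[str] = ("chip", "position", "cells", "age"),
) -> pd.DataFrame:
    """Adjustment covariate block shared by every probe in the scan.

    ``chip``/``position`` enter as categorical fixed effects (reference level
    = first observed); ``cells`` expands to the estimated cell-proportion
    columns with the largest-mean type dropped to avoid compositional
    collinearity; any other entry is taken as a numeric sheet column.
    """
    blocks: list[pd.DataFrame] = []
    for term in adjust:
        if term in ("chip", "position"):
            cat = pd.Categorical(sheet[term])
            dummies = pd.get_dummies(cat, prefix=term, drop_first=True, dtype=float)
            dummies.index = sheet.index
            blocks.append(dummies)
        elif term == "cells":
            cell_cols = [c for c in sheet.columns if c.startswith("cell_")]
            if not cell_cols:
                raise ValidationError("no cell_* columns in sheet; run deconvolution first")
            drop = sheet[cell_cols].mean().idxmax()
            blocks.append(sheet[[c for c in cell_cols if c != drop]].astype(float))
        else:
            if term not in sheet.columns:
                raise ValidationError(f"adjustment column {term!r} not in sample sheet")
            blocks.append(sheet[[term]].astype(float))
    if not blocks:
        return pd.DataFrame(index=sheet.index)
    return pd.concat(blocks, axis=1)


def _probe_fit(z, y, Z, names):
    """One scan fit with penalized fallback on separation/non-convergence."""
    X = np.column_stack([np.ones(len(y)), z, Z])
    fit = fit_logistic(X, y, names=names)
    status = fit.flag
    if status in ("separation", "no_convergence"):
        fit = fit_logistic(X, y, names=names, l2=0.5)
        status = "penalized"
    return fit, status


def ewas_scan(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    adjust: Sequence[str] = ("chip", "position", "cells", "age"),
    probes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-probe unconditional logistic scan of case status on standardized beta.

    Every probe is standardized to 1 s.d. over its non-missing samples and
    fitted with the shared adjustment block; results are sorted by Wald
    p-value and Bonferroni-adjusted with N = number of probes that produced a
    p-value. Probes that fail are reported with a status code, never dropped.
    """
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    samples = [s for s in matrix.sample_ids if s in sheet.index]
    if len(samples) < matrix.n_samples:
        raise ValidationError("matrix contains samples absent from the sheet")
    sub = sheet.loc[list(matrix.sample_ids)]
    y_all = sub["case"].to_numpy(dtype=float)
    Z_all = build_adjustment_design(sub, adjust).to_numpy(dtype=float)
    z_names = list(build_adjustment_design(sub, adjust).columns)
    names = ["intercept", "beta_sd", *z_names]

    probe_list = list(probes) if probes is not None else list(matrix.probe_ids)
    values = matrix.values.loc[probe_list].to_numpy()
    ann = matrix.annotations.loc[probe_list]

    rows = []
    for i, probe in enumerate(probe_list):
        v = values[i]
        obs = ~np.isnan(v)
        y = y_all[obs]
        rec = {
            "probe_id": probe,
            "gene": ann["gene"].iloc[i],
            "chromosome": ann["chromosome"].iloc[i],
            "position": ann["position"].iloc[i],
            "region": ann["region"].iloc[i],
            "or_per_sd": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_wald": np.nan,
            "n_cases": int(y.sum()),
            "n_controls": int((1 - y).sum()),
            "status": "ok",
        }
        try:
            if obs.sum() < 2 or y.sum() in (0, len(y)):
                raise DegenerateProbeError("insufficient outcome variation")
            z = standardize_probe(v[obs])
            fit, status = _probe_fit(z, y, Z_all[obs], names)
            b, se = fit.coef("beta_sd"), fit.se_of("beta_sd")
            rec.update(
                or_per_sd=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
                p_wald=float(fit.p_wald[1]),
                status=status,
            )
        except DegenerateProbeError:
            rec["status"] = "degenerate"
        except (np.linalg.LinAlgError, ValidationError):
            rec["status"] = "failed"
        rows.append(rec)

    table = pd.DataFrame(rows)
    n_tests = int(table["p_wald"].notna().sum())
    table["p_bonferroni"] = np.nan
    fitted = table["p_wald"].notna()
    table.loc[fitted, "p_bonferroni"] = bonferroni_adjust(
        table.loc[fitted, "p_wald"].to_numpy(), n_tests
    )
    table = table.sort_values("p_wald", na_position="last", kind="mergesort")
    return table[RESULT_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Smoking stratification
# ---------------------------------------------------------------------------

def cigarettes_category(x: float) -> str:
    """Cigarettes/day: ``<15``, ``15-24``, ``>=25`` (15 falls in ``15-24``)."""
    if x < 15:
        return "<15"
    if x < 25:
        return "15-24"
    return ">=25"


def duration_category(years: float) -> str:
    """Smoking duration: ``<30``, ``30-39``, ``>=40`` years."""
    if years < 30:
        return "<30"
    if years < 40:
        return "30-39"
    return ">=40"


def time_since_quit_category(years: float) -> str:
    """Time since quitting: ``<5``, ``5-14``, ``>=15`` years."""
    if years < 5:
        return "<5"
    if years < 15:
        return "5-14"
    return ">=15"


_STRATUM_EXTRAS: Mapping[str, tuple[tuple[str, object], ...]] = {
    "never": (),
    "former": (
        ("years_since_quit", time_since_quit_category),
        ("smoke_years", duration_category),
    ),
    "current": (
        ("smoke_years", duration_category),
        ("cigs_per_day", cigarettes_category),
    ),
}


def stratified_by_smoking(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    probe: str,
    min_stratum_n: int = 20,
    extra_adjust: Mapping[str, tuple] | None = None,
) -> dict:
    """Probe-level risk model fitted separately in never/former/current strata.

    Strata receive the stratum-appropriate additional adjustments as
    categorical terms with the standard cut-points (time since quitting in
    former smokers; duration in former and current; intensity in current).
    Strata below ``min_stratum_n`` or without outcome variation are skipped
    with an explanatory entry rather than an error.
    """
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    sheet = sheet.loc[list(matrix.sample_ids)]
    v_all = matrix.probe_values(probe)
    extras = dict(_STRATUM_EXTRAS if extra_adjust is None else extra_adjust)
    out: dict[str, dict] = {}
    for stratum in ("never", "former", "current"):
        rows = sheet["smoking_status"] == stratum
        v = v_all[rows.to_numpy()]
        sub = sheet[rows]
        obs = v.notna().to_numpy()
        sub, v = sub[obs], v[obs]
        if len(sub) == 0:
            out[stratum] = {"status": "skipped", "reason": "empty stratum", "n": 0}
            continue
        if len(sub) < min_stratum_n:
            out[stratum] = {"status": "skipped", "reason": "stratum below minimum size", "n": len(sub)}
            continue
        y = sub["case"].to_numpy(dtype=float)
        if y.sum() in (0, len(y)):
            out[stratum] = {"status": "skipped", "reason": "no outcome variation", "n": len(sub)}
            continue
        try:
            z = standardize_probe(v.to_numpy())
        except DegenerateProbeError:
            out[stratum] = {"status": "skipped", "reason": "degenerate probe", "n": len(sub)}
            continue
        blocks = []
        names = ["intercept", "beta_sd"]
        for col, categorize in extras.get(stratum, ()):
            cats = sub[col].map(categorize)
            dummies = pd.get_dummies(cats, prefix=col, drop_first=True, dtype=float)
            blocks.append(dummies.to_numpy())
            names.extend(dummies.columns)
        Z = np.column_stack(blocks) if blocks else np.empty((len(sub), 0))
        fit, status = _probe_fit(z, y, Z, names)
        b, se = fit.coef("beta_sd"), fit.se_of("beta_sd")
        out[stratum] = {
            "status": status,
            "n": len(sub),
            "n_cases": int(y.sum()),
            "n_controls": int(len(y) - y.sum()),
            "or_per_sd": float(np.exp(b)),
            "ci_low": float(np.exp(b - 1.96 * se)),
            "ci_high": float(np.exp(b + 1.96 * se)),
            "p_wald": float(fit.p_wald[1]),
        }
    return out
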