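"""Case-control-weighted parametric g-computation mediation analysis.

Decomposes the total causal effect (TCE) of ever- vs never-smoking on
lung-cancer log odds into a natural direct effect (NDE) and a natural
indirect effect (NIE) mediated by blood methylation at one or more CpG
probes, with the proportion mediated NIE/TCE on the log scale.

Design: a linear mediator model (methylation ~ smoking + age + smoking:age)
fitted by weighted least squares with case weights equal to the disease
prevalence pi and control weights 1 - pi, and a logistic outcome model
(case ~ smoking + methylation + age + configured interactions) fitted on the
case-control sample. G-computation then standardizes over the pi-weighted
empirical covariate distribution: for each counterfactual regime (a', a'')
mediator values are drawn from the mediator model at exposure a'' (jointly,
with the weighted residual correlation, when there are several mediators),
pushed through the outcome model at exposure a', and averaged. Natural
effects are logit contrasts of the averaged probabilities, so TCE = NDE + NIE
holds by construction via the shared p(1,0) term.

Because the case-control sample over-represents cases, the outcome-model
intercept is corrected by ``-log[(n_case/n_ctrl) * (1-pi)/pi]`` before
probabilities are computed; with that correction the estimator is consistent
at any prevalence rather than only in the rare-outcome limit. A closed-form
rare-outcome oracle (normal mediator, logistic outcome with
exposure-mediator interaction) is provided for cross-checking.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .association import fit_logistic
from .config import ConfigurationError
from .containers import (
    MediationResult,
    MediatorModel,
    MethylationMatrix,
    OutcomeModel,
    ValidationError,
)

MEDIATOR_DESIGN = ["intercept", "exposure", "age", "exposure:age"]
DEFAULT_INTERACTIONS = ("exposure:mediator", "exposure:age")


class DegenerateProbabilityError(RuntimeError):
    """A counterfactual probability collapsed to 0 or 1."""


class BootstrapFailureError(RuntimeError):
    """Too many bootstrap resamples failed to fit."""


def ever_exposure(sheet: pd.DataFrame) -> np.ndarray:
    """Binary ever(1)/never(0) smoking exposure."""
    return (sheet["smoking_status"] != "never").to_numpy(dtype=float)


def mediator_frame(
    matrix: MethylationMatrix,
    mediator_probes: Sequence[str],
    aggregate: str | None = None,
) -> pd.DataFrame:
    """Samples x mediators beta values; ``aggregate='mean'`` collapses the
    probe list to its per-sample mean (e.g. a gene-level FDR probe set)."""
    frame = matrix.values.loc[list(mediator_probes)].T
    if aggregate is None:
        return frame
    if aggregate != "mean":
        raise ConfigurationError(f"unknown aggregation {aggregate!r}")
    name = f"mean({','.join(mediator_probes)})"
    return frame.mean(axis=1).to_frame(name)


def _analysis_frame(sheet: pd.DataFrame, mediators: pd.DataFrame):
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    mediators = mediators.loc[sheet.index]
    keep = mediators.notna().all(axis=1).to_numpy()
    return sheet[keep], mediators[keep]


def _design_weights(case: np.ndarray, prevalence: float | None) -> np.ndarray:
    if prevalence is None:
        w = np.ones(case.shape[0])
    else:
        if not (0.0 < prevalence < 1.0):
            raise ConfigurationError("prevalence must lie strictly in (0,1)")
        w = np.where(case == 1, prevalence, 1.0 - prevalence)
    return w / w.sum()


def _fit_mediator_arrays(ever, age, Y, w):
    """Weighted normal equations for the mediator regressions (arrays only)."""
    X = np.column_stack([np.ones(len(ever)), ever, age, ever * age])
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ Y)  # 4 x J
    resid = Y - X @ coef
    n, p = X.shape
    wss = (w[:, None] * resid**2).sum(axis=0)  # sum w = 1
    sigma2 = wss * n / (n - p)
    cov = (w[:, None] * resid).T @ resid * n / (n - p)
    denom = np.sqrt(np.outer(sigma2, sigma2))
    corr = cov / denom
    np.fill_diagonal(corr, 1.0)
    return coef, np.sqrt(sigma2), corr


def fit_mediator_models(
    sheet: pd.DataFrame,
    matrix: MethylationMatrix,
    mediator_probes: Sequence[str],
    prevalence: float,
    aggregate: str | None = None,
) -> MediatorModel:
    """Design-weighted linear regressions of each mediator on exposure and age.

    Cases are weighted by the disease prevalence and controls by one minus
    the prevalence, so the fitted regression targets the source population
    rather than the case-enriched sample. The joint residual correlation
    across mediators is estimated with the same weights.
    """
    med = mediator_frame(matrix, mediator_probes, aggregate)
    sheet, med = _analysis_frame(sheet, med)
    ever = ever_exposure(sheet)
    age = sheet["age"].to_numpy(dtype=float)
    case = sheet["case"].to_numpy()
    w = _design_weights(case, prevalence)
    Y = med.to_numpy(dtype=float)
    if np.any(np.nanstd(Y, axis=0) == 0.0):
        flat = [c for c in med.columns if med[c].std() == 0.0]
        raise ValidationError(f"constant mediator(s): {flat}")
    coef, sigma, corr = _fit_mediator_arrays(ever, age, Y, w)
    n = len(sheet)
    return MediatorModel(
        coefficients=pd.DataFrame(coef, index=MEDIATOR_DESIGN, columns=med.columns),
        sigma=pd.Series(sigma, index=med.columns),
        residual_corr=pd.DataFrame(corr, index=med.columns, columns=med.columns),
        prevalence=prevalence,
        n_obs=n,
    )


def _outcome_design(
    ever: np.ndarray,
    age: np.ndarray,
    M: np.ndarray,
    mediators: Sequence[str],
    interactions: Sequence[str],
):
    cols = [np.ones(len(ever)), ever]
    names = ["intercept", "exposure"]
    for j, m in enumerate(mediators):
        cols.append(M[:, j])
        names.append(m)
    cols.append(age)
    names.append("age")
    for term in interactions:
        if term == "exposure:mediator":
            for j, m in enumerate(mediators):
                cols.append(ever * M[:, j])
                names.append(f"exposure:{m}")
        elif term == "exposure:age":
            cols.append(ever * age)
            names.append("exposure:age")
        else:
            raise ConfigurationError(f"unknown interaction term {term!r}")
    return np.column_stack(cols), names


def fit_outcome_model(
    sheet: pd.DataFrame,
    matrix: MethylationMatrix,
    mediator_probes: Sequence[str],
    interactions: Sequence[str] = DEFAULT_INTERACTIONS,
    aggregate: str | None = None,
) -> OutcomeModel:
    """Logistic model of case status on exposure, mediator(s), age and the
    configured interaction set (default: exposure x mediator, exposure x age)."""
    med = mediator_frame(matrix, mediator_probes, aggregate)
    sheet, med = _analysis_frame(sheet, med)
    ever = ever_exposure(sheet)
    age = sheet["age"].to_numpy(dtype=float)
    y = sheet["case"].to_numpy(dtype=float)
    X, names = _outcome_design(ever, age, med.to_numpy(dtype=float), med.columns, interactions)
    fit = fit_logistic(X, y, names=names)
    return OutcomeModel(
        fit=fit,
        mediators=list(med.columns),
        interactions=tuple(interactions),
        n_cases=int(y.sum()),
        n_controls=int(len(y) - y.sum()),
    )


def _terms_from_fit(fit, mediators: Sequence[str]) -> dict:
    names = fit.names
    get = fit.coef
    theta_m = np.array([get(m) for m in mediators])
    theta_int = np.array(
        [get(f"exposure:{m}") if f"exposure:{m}" in names else 0.0 for m in mediators]
    )
    return {
        "intercept": get("intercept"),
        "exposure": get("exposure"),
        "mediator": theta_m,
        "age": get("age") if "age" in names else 0.0,
        "exposure:mediator": theta_int,
        "exposure:age": get("exposure:age") if "exposure:age" in names else 0.0,
    }


def _outcome_terms(outcome: OutcomeModel):
    return _terms_from_fit(outcome.fit, outcome.mediators)


def _gcompute_arrays(gam, chol, th, age, w, intercept, a, a_star, n_mc, rng):
    """Core g-computation on plain arrays; returns (nde, nie, p11, p10, p00)."""
    n = age.shape[0]
    J = gam.shape[1]
    eps = rng.standard_normal((n_mc, n, J)) @ chol.T

    def mediator_mean(a2: float) -> np.ndarray:
        X = np.column_stack([np.ones(n), np.full(n, a2), age, a2 * age])
        return X @ gam  # n x J

    def p_bar(a1: float, a2: float) -> float:
        M = mediator_mean(a2)[None, :, :] + eps  # n_mc x n x J
        lp = (
            intercept
            + th["exposure"] * a1
            + th["age"] * age[None, :]
            + th["exposure:age"] * a1 * age[None, :]
            + M @ th["mediator"]
            + a1 * (M @ th["exposure:mediator"])
        )
        return float(w @ expit(lp).mean(axis=0))

    p11, p10, p00 = p_bar(a, a), p_bar(a, a_star), p_bar(a_star, a_star)
    for name, p in (("p(a,a)", p11), ("p(a,a*)", p10), ("p(a*,a*)", p00)):
        if not (0.0 < p < 1.0):
            raise DegenerateProbabilityError(f"{name} = {p}")
    nde = float(logit(p10) - logit(p00))
    nie = float(logit(p11) - logit(p10))
    return nde, nie, p11, p10, p00


def _corrected_intercept(intercept: float, case: np.ndarray, prevalence: float | None) -> float:
    if prevalence is None:
        return intercept
    n_case = int((case == 1).sum())
    n_ctrl = int((case == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValidationError("need both cases and controls for the design correction")
    return intercept - np.log((n_case / n_ctrl) * (1.0 - prevalence) / prevalence)


def gcompute_mediation(
    mediator_model: MediatorModel,
    outcome_model: OutcomeModel,
    sheet: pd.DataFrame,
    prevalence: float | None = None,
    a: float = 1.0,
    a_star: float = 0.0,
    n_mc: int = 400,
    seed: int | None = 0,
) -> MediationResult:
    """Monte Carlo g-computation of NDE, NIE and TCE (point estimates).

    For each counterfactual regime (a', a'') in {(a,a), (a,a*), (a*,a*)},
    ``n_mc`` mediator vectors per subject are drawn from the mediator model
    at exposure a'' (sharing one noise stream across regimes), the outcome
    probability is evaluated at exposure a', and probabilities are averaged
    over draws and the pi-weighted empirical covariate distribution. With
    ``prevalence=None`` the sheet is treated as the standardization
    population itself: uniform weights and no intercept correction.
    """
    if n_mc < 1:
        raise ConfigurationError("n_mc must be >= 1")
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    age = sheet["age"].to_numpy(dtype=float)
    case = sheet["case"].to_numpy()
    n = len(sheet)
    w = _design_weights(case, prevalence)

    gam = mediator_model.coefficients.to_numpy()  # 4 x J
    J = gam.shape[1]
    chol = np.linalg.cholesky(mediator_model.residual_cov() + 1e-15 * np.eye(J))
    th = _outcome_terms(outcome_model)
    intercept = _corrected_intercept(th["intercept"], case, prevalence)
    nde, nie, *_ = _gcompute_arrays(
        gam, chol, th, age, w, intercept, a, a_star, n_mc, np.random.default_rng(seed)
    )
    tce = nde + nie
    mc_tol = 2.0 / np.sqrt(max(n_mc * n, 1))
    unstable = bool(abs(tce) < mc_tol)
    proportion = float("nan") if unstable else nie / tce
    return MediationResult(
        tce=tce,
        nde=nde,
        nie=nie,
        proportion_mediated=proportion,
        mediators=list(outcome_model.mediators),
        prevalence=prevalence,
        n_mc=n_mc,
        seed=seed,
        proportion_unstable=unstable,
    )


def closed_form_nde_nie(
    gamma: Mapping[str, float],
    theta: Mapping[str, float],
    sigma: float,
    covariate_value: float = 0.0,
    a: float = 1.0,
    a_star: float = 0.0,
) -> dict:
    """Rare-outcome closed forms for a single normal mediator.

    ``gamma``: mediator model {g0, g1, g2, optionally g3 (exposure x covariate)};
    ``theta``: outcome model {t1 exposure, t2 mediator, t3 exposure x mediator}.
    Evaluated at covariate value ``c``:

    NDE = [t1 + t3 (g0 + g1 a* + g2 c + t2 s^2)](a - a*) + 1/2 t3^2 s^2 (a^2 - a*^2)
    NIE = (t2 g1 + t3 g1 a)(a - a*)
    """
    c = covariate_value
    g0, g2 = gamma.get("g0", 0.0), gamma.get("g2", 0.0)
    g1 = gamma.get("g1", 0.0) + gamma.get("g3", 0.0) * c
    t1, t2, t3 = theta.get("t1", 0.0), theta.get("t2", 0.0), theta.get("t3", 0.0)
    s2 = sigma**2
    nde = (t1 + t3 * (g0 + g1 * a_star + g2 * c + t2 * s2)) * (a - a_star)
    nde += 0.5 * t3**2 * s2 * (a**2 - a_star**2)
    nie = (t2 * g1 + t3 * g1 * a) * (a - a_star)
    return {"nde": float(nde), "nie": float(nie)}


def bootstrap_mediation(
    sheet: pd.DataFrame,
    matrix: MethylationMatrix,
    mediator_probes: Sequence[str],
    prevalence: float,
    interactions: Sequence[str] = DEFAULT_INTERACTIONS,
    aggregate: str | None = None,
    n_bootstrap: int = 200,
    n_mc: int = 400,
    n_mc_bootstrap: int | None = None,
    seed: int = 0,
    max_failure_fraction: float = 0.10,
) -> MediationResult:
    """Full mediation analysis with resampling inference.

    The resampling unit is the matched pair when pair identifiers exist and
    the subject otherwise; both models are refitted and g-computation rerun
    on every resample. Standard errors are resample standard deviations, CIs
    percentile (2.5/97.5), and p-values normal approximations on the log-OR
    scale. Aborts when more than ``max_failure_fraction`` of resamples fail.
    """
    if n_bootstrap < 2:
        raise ConfigurationError("n_bootstrap must be >= 2")
    if n_mc_bootstrap is None:
        n_mc_bootstrap = n_mc
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    med = mediator_frame(matrix, mediator_probes, aggregate)
    sheet, med = _analysis_frame(sheet, med)
    mediator_names = list(med.columns)
    ever_all = ever_exposure(sheet)
    age_all = sheet["age"].to_numpy(dtype=float)
    case_all = sheet["case"].to_numpy()
    Y_all = med.to_numpy(dtype=float)
    n = len(sheet)

    def estimate(idx: np.ndarray, mc: int, rng: np.random.Generator) -> dict:
        ever, age, case, Y = ever_all[idx], age_all[idx], case_all[idx], Y_all[idx]
        if np.any(Y.std(axis=0) == 0.0):
            raise ValidationError("constant mediator in resample")
        w = _design_weights(case, prevalence)
        gam, sigma, corr = _fit_mediator_arrays(ever, age, Y, w)
        X, names = _outcome_design(ever, age, Y, mediator_names, interactions)
        fit = fit_logistic(X, case.astype(float), names=names)
        th = _terms_from_fit(fit, mediator_names)
        chol = np.linalg.cholesky(corr * np.outer(sigma, sigma) + 1e-15 * np.eye(len(sigma)))
        intercept = _corrected_intercept(th["intercept"], case, prevalence)
        nde, nie, *_ = _gcompute_arrays(
            gam, chol, th, age, w, intercept, 1.0, 0.0, mc, rng
        )
        tce = nde + nie
        unstable = bool(abs(tce) < 2.0 / np.sqrt(max(mc * len(idx), 1)))
        return {
            "tce": tce,
            "nde": nde,
            "nie": nie,
            "proportion_mediated": float("nan") if unstable else nie / tce,
            "unstable": unstable,
        }

    ss = np.random.SeedSequence(seed)
    all_idx = np.arange(n)
    point_vals = estimate(all_idx, n_mc, np.random.default_rng(ss.spawn(1)[0]))

    by_pair = "pair_id" in sheet.columns and sheet["pair_id"].notna().all()
    if by_pair:
        codes, _ = pd.factorize(sheet["pair_id"])
        order = np.argsort(codes, kind="stable")
        groups = np.split(all_idx[order], np.unique(codes[order], return_index=True)[1][1:])
        n_pairs = len(groups)

    draws: list[dict] = []
    failures = 0
    child_seeds = ss.spawn(n_bootstrap)
    for b in range(n_bootstrap):
        rng = np.random.default_rng(child_seeds[b])
        if by_pair:
            chosen = rng.integers(0, n_pairs, size=n_pairs)
            idx = np.concatenate([groups[g] for g in chosen])
        else:
            idx = rng.integers(0, n, size=n)
        try:
            draws.append(estimate(idx, n_mc_bootstrap, rng))
        except (np.linalg.LinAlgError, RuntimeError, ValidationError, ValueError):
            failures += 1
    if failures > max_failure_fraction * n_bootstrap:
        raise BootstrapFailureError(
            f"{failures}/{n_bootstrap} bootstrap resamples failed to fit"
        )

    stat = {
        key: np.array([d[key] for d in draws])
        for key in ("tce", "nde", "nie", "proportion_mediated")
    }
    se, ci, pvals = {}, {}, {}
    for key, arr in stat.items():
        ok = np.isfinite(arr)
        vals = arr[ok]
        se[key] = float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")
        ci[key] = (
            (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
            if vals.size >= 2
            else (float("nan"), float("nan"))
        )
        if se[key] and np.isfinite(se[key]) and se[key] > 0:
            pvals[key] = float(2.0 * stats.norm.sf(abs(point_vals[key]) / se[key]))
        else:
            pvals[key] = float("nan")
    return MediationResult(
        tce=point_vals["tce"],
        nde=point_vals["nde"],
        nie=point_vals["nie"],
        proportion_mediated=point_vals["proportion_mediated"],
        mediators=mediator_names,
        prevalence=prevalence,
        n_mc=n_mc,
        seed=seed,
        proportion_unstable=point_vals["unstable"],
        n_bootstrap=n_bootstrap,
        se=se,
        ci=ci,
        p=pvals,
    )


# ---------------------------------------------------------------------------
# Published-table plumbing
# ---------------------------------------------------------------------------

def report_mediation_block(results: Mapping[str, MediationResult]) -> pd.DataFrame:
    """Arrange results for mediator sets into the standard published layout:
    one block per mediator set, rows TCE / NDE / NIE / Effect mediated."""
    rows = []
    for block, res in results.items():
        for label, key, value in (
            ("TCE", "tce", res.tce),
            ("NDE", "nde", res.nde),
            ("NIE", "nie", res.nie),
            ("Effect mediated", "proportion_mediated", res.proportion_mediated),
        ):
            ci = res.ci.get(key, (float("nan"), float("nan")))
            rows.append(
                {
                    "block": block,
                    "quantity": label,
                    "log_or": value,
                    "se": res.se.get(key, float("nan")),
                    "p": res.p.get(key, float("nan")),
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                }
            )
    return pd.DataFrame(rows)


def load_published_estimates() -> pd.DataFrame:
    """Published mediation estimates from the motivating prospective study of
    smoking, blood methylation and lung cancer (log-OR scale)."""
    with resources.files("methmediate.data").joinpath(
        "published_mediation_estimates.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def published_arithmetic() -> dict:
    """Consistency arithmetic on the published estimates: proportion mediated
    as NIE/TCE per block, and NDE + NIE as the reconstructed TCE."""
    table = load_published_estimates().set_index(["block", "quantity"])["log_or"]
    out: dict[str, dict] = {}
    for block in table.index.get_level_values("block").unique():
        tce = table[(block, "TCE")]
        nde = table[(block, "NDE")]
        nie = table[(block, "NIE")]
        out[block] = {
            "tce": float(tce),
            "nde": float(nde),
            "nie": float(nie),
            "published_proportion": float(table[(block, "Effect mediated")]),
            "nie_over_tce": float(nie / tce),
            "nde_plus_nie": float(nde + nie),
        }
    return out
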