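"""Reference-based leukocyte deconvolution (constrained-projection estimator).

Blood methylation is modelled as a convex mixture of purified cell-type
profiles. Discriminating probes are selected by a per-probe one-way F test
across cell types on the purified panel with Bonferroni family-wise error
control; per-sample proportions are then obtained by nonnegative least
squares of the observed betas on the reference profiles, renormalized to sum
to one (the original constrained-projection estimator leaves the sum free;
the compositional renormalization can be disabled).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .containers import MethylationMatrix, ReferenceProfiles, ValidationError


def select_discriminating_probes(
    purified: MethylationMatrix,
    type_labels: pd.Series | Sequence[str],
    fwer: float = 0.01,
) -> pd.Index:
    """Probes differentially methylated across cell types on the purified panel.

    Computes a one-way F statistic per probe and keeps probes whose
    Bonferroni-adjusted p-value is at or below ``fwer`` (the boundary
    ``fwer=1.0`` therefore selects every probe). Requires at least two
    replicates per cell type. Deterministic.
    """
    labels = pd.Series(type_labels, index=purified.sample_ids)
    groups = labels.groupby(labels).groups
    if len(groups) < 2:
        raise ValidationError("need at least two cell types")
    sizes = {g: len(ix) for g, ix in groups.items()}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValidationError(f"cell types with fewer than two replicates: {small}")

    X = purified.values.to_numpy()  # probes x samples, no missing expected on a panel
    if np.isnan(X).any():
        raise ValidationError("purified panel must be fully observed")
    n = X.shape[1]
    k = len(groups)
    grand = X.mean(axis=1)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for g, ix in groups.items():
        cols = [purified.sample_ids.get_loc(s) for s in ix]
        sub = X[:, cols]
        gm = sub.mean(axis=1)
        ss_between += len(cols) * (gm - grand) ** 2
        ss_within += ((sub - gm[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    p = np.where(np.isnan(p), 1.0, p)  # zero within- and between-group spread
    p_adj = np.minimum(1.0, p * X.shape[0])
    return purified.probe_ids[p_adj <= fwer]


def estimate_cell_proportions(
    matrix: MethylationMatrix,
    reference: ReferenceProfiles,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Per-sample cell-type proportions by nonnegative least squares.

    For every sample, observed betas at the reference probes are projected
    onto the reference profiles under a nonnegativity constraint
    (active-set NNLS), then renormalized to sum to one. Returns a DataFrame
    (samples x cell types) with an additional ``residual_norm`` column.
    """
    probes = [p for p in reference.probe_ids if p in matrix.probe_ids]
    K = len(reference.cell_types)
    if len(probes) < K:
        raise ValidationError(
            f"only {len(probes)} reference probes present in matrix; need >= {K}"
        )
    A_full = reference.profiles.loc[probes].to_numpy()  # probes x K
    if np.linalg.matrix_rank(A_full) < K:
        raise ValidationError("reference profiles are rank deficient")
    B = matrix.values.loc[probes].to_numpy()  # probes x samples
    out = np.empty((matrix.n_samples, K))
    resid = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        obs = ~np.isnan(B[:, j])
        if obs.sum() < K:
            raise ValidationError(
                f"sample {matrix.sample_ids[j]!r} has fewer usable reference probes than cell types"
            )
        coef, rnorm = nnls(A_full[obs], B[obs, j])
        total = coef.sum()
        if renormalize:
            if total <= 0:
                raise ValidationError(
                    f"all-zero mixture solution for sample {matrix.sample_ids[j]!r}"
                )
            coef = coef / total
        out[j] = coef
        resid[j] = rnorm
    result = pd.DataFrame(out, index=matrix.sample_ids, columns=reference.cell_types)
    result["residual_norm"] = resid
    return result


def append_cell_proportions(sheet: pd.DataFrame, proportions: pd.DataFrame) -> pd.DataFrame:
    """Merge estimated proportions into the sample sheet as ``cell_<type>`` columns."""
    props = proportions.drop(columns=["residual_norm"], errors="ignore")
    props = props.rename(columns={c: f"cell_{c}" for c in props.columns})
    merged = sheet.merge(props, left_on="sample_id", right_index=True, how="left")
    return merged
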