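"""QC filters and scale transforms for beta-value matrices.

Filtering follows the discovery-cohort rules: samples with *more than* 5% of
probes non-detected are excluded first, then probes missing in *more than*
20% of the retained samples. Both inequalities are strict and the
samples-then-probes order is fixed (sample exclusion is treated as a separate
final QC step). Risk analyses run on per-probe standardized beta values;
trajectory models may use M-values, ``M = log2(beta / (1 - beta))``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DegenerateProbeError, FilterReport, MethylationMatrix, ValidationError


class EmptyMatrixError(RuntimeError):
    """All probes or all samples were removed by filtering."""


def filter_missingness(
    matrix: MethylationMatrix,
    probe_threshold: float = 0.20,
    sample_threshold: float = 0.05,
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply the missingness QC filters (samples first, then probes).

    A sample is removed when its missing fraction exceeds ``sample_threshold``
    strictly; then a probe is removed when its missing fraction among the
    retained samples exceeds ``probe_threshold`` strictly. Idempotent.
    """
    for name, t in (("probe_threshold", probe_threshold), ("sample_threshold", sample_threshold)):
        if not (0.0 <= t <= 1.0):
            raise ValidationError(f"{name} must lie in [0,1], got {t}")
    mask = matrix.mask
    sample_frac = mask.mean(axis=0)
    bad_samples = sample_frac.index[sample_frac > sample_threshold].tolist()
    kept_samples = [s for s in matrix.sample_ids if s not in set(bad_samples)]
    if not kept_samples:
        raise EmptyMatrixError("all samples removed by missingness filter")
    probe_frac = mask[kept_samples].mean(axis=1)
    bad_probes = probe_frac.index[probe_frac > probe_threshold].tolist()
    kept_probes = [p for p in matrix.probe_ids if p not in set(bad_probes)]
    if not kept_probes:
        raise EmptyMatrixError("all probes removed by missingness filter")
    filtered = MethylationMatrix(
        matrix.values.loc[kept_probes, kept_samples], matrix.annotations.loc[kept_probes]
    )
    report = FilterReport(
        sample_threshold=sample_threshold,
        probe_threshold=probe_threshold,
        removed_samples=bad_samples,
        removed_probes=bad_probes,
        n_samples_before=matrix.n_samples,
        n_probes_before=matrix.n_probes,
    )
    return filtered, report


def beta_to_m(beta):
    """M-value transform, ``M = log2(beta / (1 - beta))``; NaN propagates."""
    arr = np.asarray(beta, dtype=float)
    observed = ~np.isnan(arr)
    if np.any((arr[observed] <= 0.0) | (arr[observed] >= 1.0)):
        raise ValidationError("beta values must lie strictly in (0,1)")
    out = np.full_like(arr, np.nan)
    out[observed] = np.log2(arr[observed] / (1.0 - arr[observed]))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index, name=beta.name)
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Exact inverse of :func:`beta_to_m`: ``beta = 2^M / (1 + 2^M)``."""
    arr = np.asarray(m, dtype=float)
    # exp2 overflows harmlessly to inf for very large M; use the stable form
    out = 1.0 / (1.0 + np.exp2(-arr))
    out = np.where(np.isnan(arr), np.nan, out)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index, name=m.name)
    return out if out.ndim else float(out)


def standardize_probe(values) -> np.ndarray:
    """Center and scale one probe to mean 0, s.d. 1 (denominator n-1).

    Missing values are preserved. Raises :class:`DegenerateProbeError` when
    fewer than two observations remain or the spread is zero.
    """
    arr = np.asarray(values, dtype=float)
    observed = ~np.isnan(arr)
    if observed.sum() < 2:
        raise DegenerateProbeError("need at least two non-missing values")
    sd = arr[observed].std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateProbeError("zero spread; probe cannot be standardized")
    out = (arr - arr[observed].mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
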