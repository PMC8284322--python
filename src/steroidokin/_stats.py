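"""Shared count-statistics helpers: NB dispersion estimation and log-scale SEs.

Both the differential caller and the stability caller model counts as
negative binomial with variance ``mu + d * mu^2`` and test log2 fold changes
with delta-method standard errors.  The gene-wise method-of-moments
dispersion is shrunk 50/50 toward a parametric ``a/mu + b`` mean-dispersion
trend fitted across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)


def mom_dispersion(normalized: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-gene method-of-moments NB dispersion.

    ``groups`` labels the columns of ``normalized``; replicate variance is
    computed within each group (>= 2 members) and pooled over groups by
    degrees of freedom, then inverted through ``var = mu + d mu^2``.
    """
    num = np.zeros(normalized.shape[0])
    den = np.zeros(normalized.shape[0])
    dof = 0
    for _, cols in groups.groupby(groups):
        if len(cols) < 2:
            continue
        block = normalized[cols.index].to_numpy()
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        w = len(cols) - 1
        num += w * (v - m)
        den += w * m**2
        dof += w
    if dof == 0:
        return pd.Series(0.0, index=normalized.index)
    d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return pd.Series(np.clip(d, 0.0, None), index=normalized.index)


def trend_dispersion(disp: pd.Series, mean_counts: pd.Series) -> pd.Series:
    """Fit the parametric trend ``d(mu) = a/mu + b`` by least squares.

    Genes with near-zero mean are excluded from the fit; ``a`` and ``b`` are
    clipped at zero so the trend is a valid dispersion everywhere.
    """
    mu = mean_counts.to_numpy(dtype=float)
    d = disp.to_numpy(dtype=float)
    ok = mu > 1e-8
    if ok.sum() < 2:
        return pd.Series(np.full_like(d, d[ok].mean() if ok.any() else 0.0),
                         index=disp.index)
    X = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, d[ok], rcond=None)
    a, b = np.clip(coef, 0.0, None)
    fitted = np.where(ok, a / np.maximum(mu, 1e-8) + b, d)
    return pd.Series(fitted, index=disp.index)


def shrunk_dispersion(normalized: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """50/50 blend of gene-wise MoM dispersion and the fitted trend."""
    gene_d = mom_dispersion(normalized, groups)
    trend = trend_dispersion(gene_d, normalized.mean(axis=1))
    return 0.5 * gene_d + 0.5 * trend


def log2_mean_se(mu: np.ndarray, dispersion: np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Delta-method SE of ``log2(mean of n NB counts)`` with mean ``mu``.

    ``Var(log2 mean) ~= (1/mu + d) / (n ln2^2)``.
    """
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-8)
    return np.sqrt((1.0 / mu + np.asarray(dispersion)) / np.asarray(n)) / LN2


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
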