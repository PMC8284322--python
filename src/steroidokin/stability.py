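"""Stimulation-coupled RNA stability analysis from precursor/mature counts.

Exon-intron split analysis (EISA) compares the stimulation-induced change in
exonic (mature) signal with the change in intronic (precursor) signal: a
purely transcriptional response moves both equally, while a decay change
moves the mature pool away from the precursor pool.  The per-gene statistic
is ``z = (delta_exon - delta_intron) / SE`` with delta-method SEs, two-sided
normal p-values and BH correction across testable genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, log2_mean_se, shrunk_dispersion
from .containers import ConfigError, DataError, TimeCourseMatrix

LOG_OFFSET = 0.5
#: minimum mean normalized intron count for a gene to be testable
MIN_INTRON_MEAN = 10.0


def pre_mature_correlation(pre_fc: pd.Series | np.ndarray, mat_fc: pd.Series | np.ndarray) -> float:
    """Pearson correlation between precursor and mature fold-change series.

    Returns NaN for a constant series (correlation undefined).
    """
    pre = np.asarray(pre_fc, dtype=float)
    mat = np.asarray(mat_fc, dtype=float)
    if pre.shape != mat.shape:
        raise DataError("precursor and mature series differ in length")
    if pre.size < 3:
        raise ConfigError("need at least 3 time points")
    if np.ptp(pre) == 0 or np.ptp(mat) == 0:
        return float("nan")
    return float(stats.pearsonr(pre, mat)[0])


def cross_correlation_lag(
    pre_fc: pd.Series | np.ndarray,
    mat_fc: pd.Series | np.ndarray,
    max_lag_steps: int,
) -> tuple[int, float]:
    """Best grid-step delay of the mature series behind the precursor.

    Evaluates the Pearson correlation of ``pre[0:n-lag]`` with
    ``mat[lag:n]`` for every lag in ``[0, max_lag_steps]`` and returns the
    lag maximizing it (smallest lag on ties).  Constant series return
    ``(0, nan)``.
    """
    pre = np.asarray(pre_fc, dtype=float)
    mat = np.asarray(mat_fc, dtype=float)
    if pre.shape != mat.shape:
        raise DataError("precursor and mature series differ in length")
    n = pre.size
    if max_lag_steps >= n:
        raise ConfigError("max_lag_steps must be smaller than the series length")
    best_lag, best_r = 0, -np.inf
    for lag in range(max_lag_steps + 1):
        a, b = pre[: n - lag], mat[lag:]
        if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        r = float(stats.pearsonr(a, b)[0])
        if r > best_r + 1e-12:
            best_lag, best_r = lag, r
    if not np.isfinite(best_r):
        return 0, float("nan")
    return best_lag, best_r


def _delta_and_se(matrix: TimeCourseMatrix) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Pooled stim-vs-baseline log2fc, its SE, and mean normalized counts."""
    meta = matrix.sample_meta
    base = meta.index[meta["time"] == 0]
    stim = meta.index[meta["time"] > 0]
    if len(base) < 2 or len(stim) < 2:
        raise DataError("need >= 2 replicates in both baseline and stimulated sets")
    norm = matrix.normalized()
    disp = shrunk_dispersion(norm, meta["time"])
    mu_b = norm[base].mean(axis=1)
    mu_s = norm[stim].mean(axis=1)
    delta = np.log2((mu_s + LOG_OFFSET) / (mu_b + LOG_OFFSET))
    se = np.sqrt(
        log2_mean_se(mu_b, disp, len(base)) ** 2
        + log2_mean_se(mu_s, disp, len(stim)) ** 2
    )
    return delta, pd.Series(se, index=norm.index), norm.mean(axis=1)


def eisa_call(
    pre: TimeCourseMatrix,
    mat: TimeCourseMatrix,
    fdr: float = 0.05,
    min_intron_mean: float = MIN_INTRON_MEAN,
    intronless: set[str] | None = None,
) -> pd.DataFrame:
    """EISA stability calls from paired precursor/mature count matrices.

    All post-stimulation samples are pooled against the t = 0 baseline.
    Genes that are intronless or whose mean normalized precursor count is
    below ``min_intron_mean`` are ``untestable``.  Among testable genes,
    ``destabilized`` requires ``z < 0`` and ``q <= fdr`` (mature change
    lagging the precursor change), ``stabilized`` the opposite sign.

    Returns a frame with ``delta_exon, delta_intron, z_stat, p, q, class``.
    """
    intronless = intronless or set()
    d_ex, se_ex, _ = _delta_and_se(mat)
    d_in, se_in, mean_in = _delta_and_se(pre)
    genes = d_ex.index.intersection(d_in.index)
    d_ex, se_ex = d_ex[genes], se_ex[genes]
    d_in, se_in, mean_in = d_in[genes], se_in[genes], mean_in[genes]

    testable = (mean_in >= min_intron_mean) & ~genes.isin(sorted(intronless))
    z = (d_ex - d_in) / np.sqrt(se_ex**2 + se_in**2)
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=genes)
    p[~testable] = np.nan
    q = pd.Series(bh_qvalues(p.to_numpy()), index=genes)

    cls = pd.Series("unchanged", index=genes, dtype=object)
    cls[(q <= fdr) & (z < 0)] = "destabilized"
    cls[(q <= fdr) & (z > 0)] = "stabilized"
    cls[~testable] = "untestable"
    out = pd.DataFrame(
        {
            "delta_exon": d_ex,
            "delta_intron": d_in,
            "z_stat": z.where(testable),
            "p": p,
            "q": q,
            "class": cls,
        }
    )
    out.index.name = "gene_id"
    if testable.sum() == 0:
        import warnings

        warnings.warn("no testable genes for EISA", stacklevel=2)
    return out


def overlap_odds_ratio(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[float, float, np.ndarray]:
    """Odds ratio and Fisher exact p for the overlap of two gene sets.

    The 2x2 table counts universe members by membership in each set; the
    odds ratio uses a Haldane 0.5 correction when any cell is zero, the
    two-sided Fisher test uses the raw table.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise DataError("sets must be subsets of the universe")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    table = np.array([[n11, n10], [n01, n00]], dtype=float)
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    return float(odds), float(p), table.astype(int)
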