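"""Synthesis / processing / decay rate estimation from a short 4sU pulse.

A pulse of length ``tau`` labels a fraction of each RNA pool that depends
only on the first-order rates.  For the precursor pool
``f_P = 1 - exp(-gamma tau)`` inverts in closed form to the processing rate;
for the mature pool ``f_M(gamma, beta, tau)`` is monotone in the decay rate
``beta`` and is inverted numerically.  Synthesis follows from decay and
steady-state abundance (``alpha = beta * M``).  All rates are per hour.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import ConfigError, DataError, TimeCourseMatrix

#: clipping bound for observed labeled fractions
FRACTION_EPS = 1e-4
#: minimum mean total count for a gene to be estimated
MIN_TOTAL_MEAN = 10.0
#: bisection bracket for the decay rate (1/h)
BETA_BRACKET = (1e-4, 1e3)
#: |beta - gamma| below this uses the equal-rate limit of f_M
EQUAL_RATE_TOL = 1e-6


def precursor_labeled_fraction(gamma: float, tau: float) -> float:
    """``f_P = 1 - exp(-gamma tau)``."""
    return 1.0 - np.exp(-gamma * tau)


def mature_labeled_fraction(gamma: float, beta: float, tau: float) -> float:
    """Labeled fraction of the mature pool at steady state.

    ``f_M = 1 - (beta e^{-gamma tau} - gamma e^{-beta tau}) / (beta - gamma)``
    with the analytic ``beta == gamma`` limit
    ``1 - (1 + beta tau) e^{-beta tau}``.
    """
    if abs(beta - gamma) < EQUAL_RATE_TOL:
        return 1.0 - (1.0 + beta * tau) * np.exp(-beta * tau)
    return 1.0 - (beta * np.exp(-gamma * tau) - gamma * np.exp(-beta * tau)) / (beta - gamma)


def half_life(beta):
    """Half-life ``ln 2 / beta`` in hours; elementwise for arrays."""
    beta_arr = np.asarray(beta, dtype=float)
    if np.any(beta_arr <= 0):
        raise ConfigError("decay rate must be > 0")
    out = np.log(2.0) / beta_arr
    return out if out.shape else float(out)


def _mean_normalized(x: TimeCourseMatrix | pd.DataFrame) -> pd.Series:
    if isinstance(x, TimeCourseMatrix):
        return x.normalized().mean(axis=1)
    return pd.DataFrame(x).mean(axis=1)


def _mean_raw(x: TimeCourseMatrix | pd.DataFrame) -> pd.Series:
    if isinstance(x, TimeCourseMatrix):
        return x.counts.mean(axis=1)
    return pd.DataFrame(x).mean(axis=1)


def labeled_scale_from_references(
    labeled: TimeCourseMatrix | pd.DataFrame,
    total: TimeCourseMatrix | pd.DataFrame,
    reference_fractions: pd.Series,
) -> float:
    """Relative labeled-vs-total library scale from reference genes.

    For a reference gene with known labeled fraction ``f`` the raw ratio
    ``labeled / total`` equals ``c * f`` where ``c`` is the unknown relative
    depth of the labeled library; the median of ``ratio / f`` over the
    references estimates ``c`` (median-of-ratios, robust to outliers).
    """
    lab = _mean_normalized(labeled)
    tot = _mean_normalized(total)
    refs = reference_fractions.index.intersection(lab.index)
    if len(refs) == 0:
        raise DataError("no reference genes present in the matrices")
    ratio = (lab[refs] / tot[refs].replace(0.0, np.nan)).to_numpy()
    f_true = reference_fractions[refs].to_numpy(dtype=float)
    ok = np.isfinite(ratio) & (f_true > 0)
    if not ok.any():
        raise DataError("reference genes have no usable counts")
    return float(np.median(ratio[ok] / f_true[ok]))


def estimate_decay_onecomp(
    labeled: TimeCourseMatrix | pd.DataFrame,
    total: TimeCourseMatrix | pd.DataFrame,
    tau: float,
    scale: float = 1.0,
    eps: float = FRACTION_EPS,
    min_total_mean: float = MIN_TOTAL_MEAN,
) -> pd.DataFrame:
    """One-compartment decay estimate ``beta = -ln(1 - f) / tau``.

    ``f`` is the labeled/total ratio divided by ``scale`` (the relative
    depth of the labeled library, e.g. from
    :func:`labeled_scale_from_references`), clipped to ``[eps, 1 - eps]``.
    Genes with mean total count below ``min_total_mean`` are flagged
    ``low_coverage`` with undefined rates.
    """
    if tau <= 0:
        raise ConfigError("pulse length tau must be > 0")
    lab = _mean_normalized(labeled)
    tot = _mean_normalized(total)
    common = lab.index[lab.index.isin(tot.index)]  # preserve input order
    lab, tot = lab[common], tot[common]
    raw_total = _mean_raw(total)[common]

    f_raw = (lab / tot.replace(0.0, np.nan)) / scale
    f = f_raw.clip(eps, 1.0 - eps)
    beta = -np.log(1.0 - f) / tau
    flags = pd.Series("", index=common, dtype=object)
    clipped = f_raw.notna() & ((f_raw < eps) | (f_raw > 1.0 - eps))
    flags[clipped] = "clipped"
    low = (raw_total < min_total_mean) | f_raw.isna()
    beta[low] = np.nan
    flags[low] = "low_coverage"
    out = pd.DataFrame(
        {
            "beta_hat": beta,
            "half_life": np.log(2.0) / beta,
            "n_effective": raw_total,
            "flag": flags,
        }
    )
    out.index.name = "gene_id"
    return out


def estimate_rates_twocomp(
    labeled_pre: TimeCourseMatrix | pd.DataFrame,
    labeled_mat: TimeCourseMatrix | pd.DataFrame,
    total_pre: TimeCourseMatrix | pd.DataFrame,
    total_mat: TimeCourseMatrix | pd.DataFrame,
    tau: float,
    scale: float = 1.0,
    eps: float = FRACTION_EPS,
    min_total_mean: float = MIN_TOTAL_MEAN,
    ftol: float = 1e-8,
) -> pd.DataFrame:
    """Two-compartment rate estimation from labeled/total precursor+mature.

    Processing: ``gamma = -ln(1 - f_P)/tau`` from the precursor labeled
    fraction.  Decay: ``beta`` solves ``f_M(gamma, beta, tau) = f_M_obs`` by
    bisection on ``[1e-4, 1e3]`` per hour (``f_M`` is monotone in beta).
    Synthesis: ``alpha = beta * M`` with ``M`` the normalized mean total
    mature abundance.  Genes whose observed ``f_M`` falls outside the
    bracket's range are flagged ``bracket``.

    Returns a frame with ``alpha_hat, gamma_hat, beta_hat, half_life,
    n_effective, flag``.
    """
    if tau <= 0:
        raise ConfigError("pulse length tau must be > 0")
    for name, x in (("labeled_pre", labeled_pre), ("labeled_mat", labeled_mat),
                    ("total_pre", total_pre), ("total_mat", total_mat)):
        if x is None:
            raise DataError(f"missing layer {name}")
    lp, lm = _mean_normalized(labeled_pre), _mean_normalized(labeled_mat)
    tp, tm = _mean_normalized(total_pre), _mean_normalized(total_mat)
    keep = lm.index.isin(lp.index) & lm.index.isin(tp.index) & lm.index.isin(tm.index)
    common = lm.index[keep]  # preserve input order
    lp, lm, tp, tm = lp[common], lm[common], tp[common], tm[common]
    raw_total = _mean_raw(total_mat)[common]

    f_p = ((lp / tp.replace(0.0, np.nan)) / scale).clip(eps, 1.0 - eps)
    f_m_obs = ((lm / tm.replace(0.0, np.nan)) / scale).clip(eps, 1.0 - eps)
    gamma = -np.log(1.0 - f_p) / tau

    lo, hi = BETA_BRACKET
    beta = np.full(len(common), np.nan)
    flags = np.full(len(common), "", dtype=object)
    for i, gid in enumerate(common):
        g, fm = gamma.iloc[i], f_m_obs.iloc[i]
        if not np.isfinite(g) or not np.isfinite(fm) or raw_total.iloc[i] < min_total_mean:
            flags[i] = "low_coverage"
            continue

        def resid(b, g=g, fm=fm):
            return mature_labeled_fraction(g, b, tau) - fm

        r_lo, r_hi = resid(lo), resid(hi)
        if r_lo > 0 or r_hi < 0:
            # observed fraction unreachable within the bracket
            beta[i] = lo if r_lo > 0 else hi
            flags[i] = "bracket"
            continue
        beta[i] = brentq(resid, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
        if abs(resid(beta[i])) > ftol:
            flags[i] = "bracket"

    beta_s = pd.Series(beta, index=common)
    out = pd.DataFrame(
        {
            "alpha_hat": beta_s * tm,
            "gamma_hat": gamma,
            "beta_hat": beta_s,
            "half_life": np.log(2.0) / beta_s,
            "n_effective": raw_total,
            "flag": flags,
        }
    )
    out.index.name = "gene_id"
    return out
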