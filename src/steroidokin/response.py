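"""Temporal response profiling: differential calling, clustering, kinetics.

Works on a mature-layer :class:`~steroidokin.containers.TimeCourseMatrix`
with an unstimulated baseline at t = 0.  Differential genes are called per
time point with a negative-binomial Wald test (BH across all gene x time
tests), temporal log2 fold-change profiles are clustered with k-means, and
each profile's time-to-peak and peakiness are read off a cubic smoothing
spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline, make_smoothing_spline
from sklearn.cluster import KMeans

from ._stats import bh_qvalues, log2_mean_se, shrunk_dispersion
from .containers import ConfigError, DataError, TimeCourseMatrix

DEFAULT_PSEUDOCOUNT = 0.5
#: dense-grid step (h) for peak interpolation
DENSE_STEP = 0.05
#: |log2fc| of the cluster mean peak separating strong from weak responses
STRONG_PEAK_LOG2 = 2.0


def _split_baseline(matrix: TimeCourseMatrix):
    meta = matrix.sample_meta
    base = meta.index[meta["time"] == 0]
    if len(base) == 0:
        raise DataError("no baseline (t = 0) samples present")
    times = sorted(t for t in meta["time"].unique() if t > 0)
    return base, times


def log2fc_profiles(
    matrix: TimeCourseMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-gene log2 fold change vs the t = 0 baseline at every time point.

    ``log2((mean_stim + p) / (mean_base + p))`` on size-factor-normalized
    counts; the t = 0 column is identically zero.
    """
    base, times = _split_baseline(matrix)
    norm = matrix.normalized()
    mu_b = norm[base].mean(axis=1)
    out = {0.0: pd.Series(0.0, index=matrix.gene_ids)}
    meta = matrix.sample_meta
    for t in times:
        cols = meta.index[meta["time"] == t]
        mu_s = norm[cols].mean(axis=1)
        out[t] = np.log2((mu_s + pseudocount) / (mu_b + pseudocount))
    prof = pd.DataFrame(out)
    prof.index.name = "gene_id"
    return prof


def call_differential(
    matrix: TimeCourseMatrix,
    fdr_threshold: float = 0.001,
    fc_threshold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB Wald test per gene per time vs baseline, BH across all tests.

    A gene is significant if any time point passes both the FDR threshold
    and the fold-change threshold.  With a single replicate per condition
    the test falls back to Poisson (dispersion 0) and genes are flagged.
    Returns ``(gene_table, test_table)``.
    """
    base, times = _split_baseline(matrix)
    meta = matrix.sample_meta
    norm = matrix.normalized()
    single_rep = len(base) < 2 or any(
        (meta["time"] == t).sum() < 2 for t in times
    )
    if single_rep:
        disp = pd.Series(0.0, index=matrix.gene_ids)
    else:
        disp = shrunk_dispersion(norm, meta["time"])

    all_zero = matrix.counts.sum(axis=1) == 0
    mu_b = norm[base].mean(axis=1)
    n_b = len(base)
    rows = []
    for t in times:
        cols = meta.index[meta["time"] == t]
        mu_s = norm[cols].mean(axis=1)
        lfc = np.log2((mu_s + pseudocount) / (mu_b + pseudocount))
        se = np.sqrt(
            log2_mean_se(mu_b, disp, n_b) ** 2
            + log2_mean_se(mu_s, disp, len(cols)) ** 2
        )
        z = lfc / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p[all_zero.to_numpy()] = np.nan
        rows.append(pd.DataFrame({
            "gene_id": matrix.gene_ids, "time": t,
            "log2fc": lfc.to_numpy(), "z": np.asarray(z), "p": p,
        }))
    tests = pd.concat(rows, ignore_index=True)
    tests["q"] = bh_qvalues(tests["p"].to_numpy())
    tests["hit"] = (tests["q"] <= fdr_threshold) & (
        tests["log2fc"].abs() >= np.log2(fc_threshold)
    )

    gene = tests.groupby("gene_id", sort=False).agg(
        significant=("hit", "any"),
        best_q=("q", "min"),
        max_abs_log2fc=("log2fc", lambda s: s.abs().max()),
    ).reindex(matrix.gene_ids)
    gene["flag"] = ""
    gene.loc[all_zero, ["significant"]] = False
    gene.loc[all_zero, "flag"] = "all_zero"
    if single_rep:
        gene["flag"] = (gene["flag"] + ";single_replicate").str.strip(";")
    return gene, tests


@dataclass
class ClusterResult:
    """K-means clustering of temporal profiles with kinetic naming."""

    labels: pd.Series          # gene -> cluster name (e.g. "as1")
    centers: pd.DataFrame      # cluster name x time mean profile
    degenerate: bool = False


def time_to_peak(
    profile: pd.Series, dense_step: float = DENSE_STEP, lam: float = 1.0
) -> tuple[float, float]:
    """Time of maximal |log2fc| and peakiness of one temporal profile.

    The profile (indexed by time in hours, >= 4 points) is fit with a
    cubic smoothing spline (roughness penalty ``lam``; 0 interpolates
    exactly) and evaluated on a dense grid; time-to-peak is the argmax of
    the smoothed |log2fc| and peakiness is peak height divided by the full
    width at half maximum (h) of the |log2fc| curve.  Smoothing rather than
    interpolation lets the peak sit between sampling times and keeps the
    estimate stable under count noise; an exact interpolant pins every
    maximum to a sampling knot.  A flat profile returns ``(nan, nan)``.
    """
    t = np.asarray(profile.index, dtype=float)
    y = profile.to_numpy(dtype=float)
    if t.size < 4:
        raise ConfigError("need at least 4 time points for peak estimation")
    order = np.argsort(t)
    if t.size >= 5:
        spline = make_smoothing_spline(t[order], y[order], lam=lam if lam > 0 else 1e-12)
    else:  # smoothing spline needs >= 5 points; interpolate exactly at 4
        spline = CubicSpline(t[order], y[order], bc_type="natural")
    dense = np.arange(t.min(), t.max() + dense_step / 2, dense_step)
    a = np.abs(spline(dense))
    peak = a.max()
    if peak < 1e-9:
        return float("nan"), float("nan")
    ttp = float(dense[int(np.argmax(a))])
    fwhm = float(np.count_nonzero(a >= peak / 2) * dense_step)
    return ttp, float(peak / fwhm)


def peak_table(
    profiles: pd.DataFrame, dense_step: float = DENSE_STEP, lam: float = 1.0
) -> pd.DataFrame:
    """:func:`time_to_peak` applied to every row of a profile matrix."""
    vals = [time_to_peak(profiles.loc[g], dense_step, lam=lam) for g in profiles.index]
    out = pd.DataFrame(vals, index=profiles.index, columns=["time_to_peak", "peakiness"])
    out.index.name = "gene_id"
    return out


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 12,
    seed: int = 0,
    n_init: int = 50,
    zscore: bool = False,
) -> ClusterResult:
    """K-means on temporal log2fc profiles with kinetic cluster names.

    Cluster names encode direction (``a``/``r`` from the sign of the mean
    profile's peak), strength (``s``/``w`` by |peak| >= 2 log2 units) and an
    index assigned by ascending mean time-to-peak within each
    direction/strength group — e.g. ``as1`` peaks before ``as2``.  Profiles
    are optionally row z-scored before clustering (default off, preserving
    magnitude separation).
    """
    if profiles.shape[0] < k:
        raise ConfigError(f"need at least k={k} profiles, got {profiles.shape[0]}")
    X = profiles.to_numpy(dtype=float)
    if zscore:
        sd = X.std(axis=1, keepdims=True)
        X = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    degenerate = np.unique(X, axis=0).shape[0] < k
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)

    times = np.asarray(profiles.columns, dtype=float)
    info = []
    for c in range(k):
        members = profiles.index[raw == c]
        if len(members) == 0:
            continue
        mean_prof = profiles.loc[members].mean(axis=0)
        ipk = int(np.argmax(np.abs(mean_prof.to_numpy())))
        peak_val = float(mean_prof.iloc[ipk])
        try:
            ttp, _ = time_to_peak(mean_prof)
        except ConfigError:
            ttp = float(times[ipk])
        if np.isnan(ttp):
            ttp = float(times[ipk])
        direction = "a" if peak_val >= 0 else "r"
        strength = "s" if abs(peak_val) >= STRONG_PEAK_LOG2 else "w"
        info.append((c, direction, strength, ttp, mean_prof))
    names = {}
    frame = pd.DataFrame(
        [(c, d, s, t) for c, d, s, t, _ in info],
        columns=["cluster", "direction", "strength", "ttp"],
    )
    for (d, s), grp in frame.groupby(["direction", "strength"]):
        for i, (_, row) in enumerate(grp.sort_values("ttp").iterrows(), start=1):
            names[int(row["cluster"])] = f"{d}{s}{i}"
    labels = pd.Series([names[c] for c in raw], index=profiles.index, name="cluster")
    centers = pd.DataFrame(
        {names[c]: mean for c, _, _, _, mean in info}
    ).T.sort_index()
    centers.columns = profiles.columns
    return ClusterResult(labels=labels, centers=centers, degenerate=degenerate)


def decay_vs_peak(
    rates: pd.DataFrame | pd.Series,
    peaks: pd.DataFrame | pd.Series,
    clusters: pd.Series | None = None,
    min_genes: int = 10,
) -> dict:
    """Spearman correlation between decay rate and time-to-peak.

    ``rates`` provides per-gene ``beta_hat`` (frame or series), ``peaks``
    per-gene ``time_to_peak``.  Returns the correlation, p-value, n and, if
    cluster labels are given, a per-cluster median table.  Fewer than
    ``min_genes`` shared genes flags the result instead of computing it.
    """
    beta = rates["beta_hat"] if isinstance(rates, pd.DataFrame) else rates
    ttp = peaks["time_to_peak"] if isinstance(peaks, pd.DataFrame) else peaks
    joined = pd.concat({"beta": beta, "ttp": ttp}, axis=1).dropna()
    result = {"n": int(len(joined)), "flag": ""}
    if len(joined) < min_genes:
        result.update(rho=float("nan"), p=float("nan"), flag="too_few_genes")
        return result
    rho, p = stats.spearmanr(joined["beta"], joined["ttp"])
    result.update(rho=float(rho), p=float(p))
    if clusters is not None:
        medians = joined.join(clusters.rename("cluster"), how="inner").groupby(
            "cluster"
        ).median().rename(columns={"beta": "median_beta", "ttp": "median_time_to_peak"})
        result["cluster_medians"] = medians
    return result
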