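"""Plate-based siRNA screen analysis for hormone-output readouts.

Each well's hormone reading is divided by its viability reading and then by
the geometric mean of the mock-control wells on the same plate and
condition, cancelling plate-level multiplicative batch effects exactly.
Per-siRNA effects are mean log2 normalized readings with one-sample t-tests;
genes are classified by two-siRNA concordance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataError

REQUIRED_COLUMNS = (
    "plate", "well", "sirna", "target_gene", "condition", "aldosterone", "viability",
)
MOCK = "mock"


def _check_table(plate_table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in plate_table.columns]
    if missing:
        raise DataError(f"plate table lacks columns: {missing}")
    if (plate_table["aldosterone"] <= 0).any() or (plate_table["viability"] <= 0).any():
        raise DataError("aldosterone and viability readings must be positive")


def normalize_wells(plate_table: pd.DataFrame) -> pd.DataFrame:
    """Viability- and mock-normalized aldosterone per well.

    ``normalized = (aldosterone / viability) / geomean of mock wells'
    (aldosterone / viability)`` within the same plate and condition.  Plates
    lacking a mock well for a condition are dropped with a warning.  The
    mock wells of every plate/condition have geometric mean exactly 1 after
    normalization.
    """
    _check_table(plate_table)
    df = plate_table.copy()
    df["ratio"] = df["aldosterone"] / df["viability"]
    out = []
    for (plate, cond), grp in df.groupby(["plate", "condition"], sort=False):
        mocks = grp.loc[grp["sirna"] == MOCK, "ratio"]
        if mocks.empty:
            warnings.warn(
                f"plate {plate} condition {cond} has no mock wells; excluded",
                stacklevel=2,
            )
            continue
        gm = float(np.exp(np.mean(np.log(mocks))))
        g = grp.copy()
        g["normalized"] = g["ratio"] / gm
        out.append(g)
    if not out:
        raise DataError("no plate/condition group had mock wells")
    return pd.concat(out, ignore_index=True).drop(columns="ratio")


def summarize_effects(
    normalized: pd.DataFrame, alpha: float = 0.05, plate_center: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-siRNA effects and per-gene concordance classes.

    Effects are mean log2 normalized readings per siRNA and condition, with
    the SE across wells and a two-sided one-sample t-test against 0.  A gene
    is a ``repressor`` when >= 2 of its siRNAs significantly increase the
    reading (knockdown raises output), an ``activator`` when >= 2
    significantly decrease it, ``discordant`` when significant effects go
    both ways, ``single-sirna`` when only one siRNA was screened, otherwise
    ``none``.

    ``plate_center`` (default off) additionally subtracts a leave-own-
    gene-out trimmed mean of the siRNA wells' log2 values per plate and
    condition.  Mock normalization fixes the scale but leaves a residual
    location error shared by every well of a plate (the mock wells' own
    sampling noise); with many siRNAs per plate and few real hits the plate
    location estimate removes that residual and decorrelates the per-siRNA
    tests.  With few siRNAs per plate (as in a small candidate screen) the
    location estimate is itself contaminated by real hits, so a generous
    mock-well block is the safer design and centering stays off.
    """
    if "normalized" not in normalized.columns:
        raise DataError("run normalize_wells first (no 'normalized' column)")
    df = normalized[normalized["sirna"] != MOCK].copy()
    df["log2_norm"] = np.log2(df["normalized"])
    if plate_center:
        # leave-own-gene-out 30% trimmed mean: robust to the few wells with
        # real effects, and a gene's own wells must not shift the location
        # estimate used to center that gene
        def _center(grp: pd.DataFrame) -> pd.Series:
            locs = {}
            for gene in grp["target_gene"].unique():
                others = grp.loc[grp["target_gene"] != gene, "log2_norm"]
                if len(others) >= 5:
                    locs[gene] = float(stats.trim_mean(others, 0.3))
                elif len(others) > 0:
                    locs[gene] = float(others.median())
                else:
                    locs[gene] = 0.0
            return grp["log2_norm"] - grp["target_gene"].map(locs)

        df["log2_norm"] = (
            df.groupby(["plate", "condition"], group_keys=False, sort=False)
            .apply(_center, include_groups=False)
            .reindex(df.index)
        )

    rows = []
    for (sirna, gene, cond), grp in df.groupby(
        ["sirna", "target_gene", "condition"], sort=False
    ):
        vals = grp["log2_norm"].to_numpy()
        n = vals.size
        effect = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        if n >= 2:
            p = float(stats.ttest_1samp(vals, 0.0).pvalue)
        else:
            p = float("nan")
        flag = "" if grp["plate"].nunique() > 1 or n < 2 else "single_plate"
        rows.append((sirna, gene, cond, effect, se, p, n, flag))
    sirna_table = pd.DataFrame(
        rows,
        columns=["sirna", "target_gene", "condition", "effect", "se",
                 "p_value", "n_replicates", "flag"],
    )

    gene_rows = []
    for (gene, cond), grp in sirna_table.groupby(["target_gene", "condition"], sort=False):
        sig = grp["p_value"] <= alpha
        n_pos = int((sig & (grp["effect"] > 0)).sum())
        n_neg = int((sig & (grp["effect"] < 0)).sum())
        if len(grp) < 2:
            cls = "single-sirna"
        elif n_pos >= 1 and n_neg >= 1:
            cls = "discordant"
        elif n_pos >= 2:
            cls = "repressor"
        elif n_neg >= 2:
            cls = "activator"
        else:
            cls = "none"
        gene_rows.append((gene, cond, len(grp), n_pos, n_neg, cls))
    gene_table = pd.DataFrame(
        gene_rows,
        columns=["target_gene", "condition", "n_sirnas",
                 "n_sig_up", "n_sig_down", "gene_class"],
    )
    return sirna_table, gene_table
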