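"""Shared containers and error types.

The central container is :class:`TimeCourseMatrix`, a genes x samples integer
count matrix with per-sample metadata (time in hours, replicate, condition,
and a layer tag distinguishing precursor / mature / labeled / total pools).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_LAYERS = ("precursor", "mature", "labeled", "total")


class SteroidokinError(Exception):
    """Base class for package errors."""


class ConfigError(SteroidokinError):
    """Invalid configuration or parameters."""


class DataError(SteroidokinError):
    """Malformed or inconsistent input data."""


class NumericalError(SteroidokinError):
    """A numerical routine failed to produce a finite result."""


@dataclass
class TimeCourseMatrix:
    """Gene x sample count matrix with sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer counts, index = gene ids, columns = sample ids.
    sample_meta
        One row per sample (index = sample ids) with columns
        ``time`` (hours), ``replicate``, ``condition`` and ``layer``
        (one of ``precursor``, ``mature``, ``labeled``, ``total``).
    lib_sizes
        Positive per-sample library sizes; defaults to column sums.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.sample_meta.index):
            missing = set(self.counts.columns) ^ set(self.sample_meta.index)
            raise DataError(
                "sample metadata does not match count columns; unmatched: "
                + ", ".join(sorted(map(str, missing)))
            )
        for col in ("time", "replicate", "layer"):
            if col not in self.sample_meta.columns:
                raise DataError(f"sample metadata lacks required column {col!r}")
        bad_layers = set(self.sample_meta["layer"]) - set(VALID_LAYERS)
        if bad_layers:
            raise DataError(f"unknown layer tags: {sorted(bad_layers)}")
        vals = self.counts.to_numpy()
        if vals.size:
            if np.any(vals < 0):
                bad = np.argwhere(vals < 0)
                cells = [
                    f"({self.counts.index[i]}, {self.counts.columns[j]})"
                    for i, j in bad[:5]
                ]
                raise DataError("negative counts at " + ", ".join(cells))
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(vals != np.round(vals))
                cells = [
                    f"({self.counts.index[i]}, {self.counts.columns[j]})"
                    for i, j in bad[:5]
                ]
                raise DataError("non-integer counts at " + ", ".join(cells))
        if self.counts.index.has_duplicates:
            raise DataError("duplicate gene ids in count matrix")
        if self.lib_sizes is None:
            sizes = self.counts.sum(axis=0).astype(float)
            sizes[sizes <= 0] = 1.0
            self.lib_sizes = sizes
        else:
            self.lib_sizes = pd.Series(self.lib_sizes, index=self.counts.columns, dtype=float)
            if np.any(self.lib_sizes.to_numpy() <= 0):
                raise DataError("library sizes must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def size_factors(self) -> pd.Series:
        """Relative size factors: lib sizes divided by their geometric mean.

        Using relative (not absolute) factors makes every downstream log
        fold-change invariant to a global rescaling of all library sizes.
        """
        ls = self.lib_sizes.to_numpy()
        gm = np.exp(np.mean(np.log(ls)))
        return pd.Series(ls / gm, index=self.counts.columns)

    def normalized(self) -> pd.DataFrame:
        """Counts divided by relative size factors."""
        return self.counts / self.size_factors()

    def subset_samples(self, mask: pd.Series | np.ndarray) -> "TimeCourseMatrix":
        cols = self.sample_meta.index[np.asarray(mask, dtype=bool)]
        return TimeCourseMatrix(
            counts=self.counts[cols],
            sample_meta=self.sample_meta.loc[cols],
            lib_sizes=self.lib_sizes[cols],
        )

    def layer(self, name: str) -> "TimeCourseMatrix":
        if name not in VALID_LAYERS:
            raise ConfigError(f"unknown layer {name!r}")
        return self.subset_samples((self.sample_meta["layer"] == name).to_numpy())


@dataclass
class SimTruth:
    """Ground truth attached to a simulated experiment."""

    kinetics: pd.DataFrame = field(default_factory=pd.DataFrame)
    archetypes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    planted_motifs: list[tuple[str, list[str]]] = field(default_factory=list)
    screen_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    reference_genes: list[str] = field(default_factory=list)
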