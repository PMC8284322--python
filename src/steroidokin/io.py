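"""Readers and writers for the package's plain-text interchange formats.

Counts travel as TSV (genes x samples) with a sidecar sample-metadata TSV;
MTX triplets are supported read-only.  UTR sequences use FASTA (written in
the DNA alphabet by default, stored internally as RNA).  All TSV output can
carry a commented header recording the seed and configuration hash.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.io import mmread

from .containers import DataError, TimeCourseMatrix

METADATA_COLUMNS = ("time", "replicate", "condition", "layer")


def write_tsv(df: pd.DataFrame, path: str | Path, seed: int | None = None,
              config_hash: str | None = None, index: bool = True) -> None:
    """Write a TSV with an optional commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        parts = []
        if seed is not None:
            parts.append(f"seed={seed}")
        if config_hash is not None:
            parts.append(f"config_hash={config_hash}")
        if parts:
            fh.write("# steroidokin " + " ".join(parts) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_counts(
    path: str | Path,
    metadata_path: str | Path,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> TimeCourseMatrix:
    """Load a count matrix (TSV genes x samples, or MTX triplet) + metadata.

    For ``.mtx`` input, ``genes_path`` and ``samples_path`` name one-id-per-
    line row and column files.  The sample metadata TSV must index every
    count column and provide ``time, replicate, condition, layer``.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or samples_path is None:
            raise DataError("MTX input needs genes_path and samples_path")
        mat = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense")
                         else mmread(path))
        genes = [line.strip() for line in open(genes_path) if line.strip()]
        samples = [line.strip() for line in open(samples_path) if line.strip()]
        if mat.shape != (len(genes), len(samples)):
            raise DataError(
                f"MTX shape {mat.shape} does not match {len(genes)} genes x "
                f"{len(samples)} samples"
            )
        counts = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"sample metadata lacks columns: {missing}")
    unmatched = set(counts.columns) ^ set(meta.index)
    if unmatched:
        raise DataError(
            "metadata/sample mismatch; unmatched samples: "
            + ", ".join(sorted(map(str, unmatched)))
        )
    meta = meta.loc[counts.columns]
    lib = meta["lib_size"] if "lib_size" in meta.columns else None
    return TimeCourseMatrix(counts, meta, lib)


def write_counts(
    matrix: TimeCourseMatrix,
    path: str | Path,
    metadata_path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write a :class:`TimeCourseMatrix` as count TSV + metadata TSV."""
    write_tsv(matrix.counts, path, seed=seed, config_hash=config_hash)
    meta = matrix.sample_meta.copy()
    meta["lib_size"] = matrix.lib_sizes
    write_tsv(meta, metadata_path, seed=seed, config_hash=config_hash)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` with the RNA alphabet.

    Sequences are upper-cased and T is normalized to U; duplicate ids raise.
    An empty file yields an empty list with a warning.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper().replace("T", "U")))
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return records


def write_fasta(
    records: list[tuple[str, str]], path: str | Path, dna_alphabet: bool = True
) -> None:
    """Write ``(id, sequence)`` records as FASTA; U->T by default."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = []
    for gid, seq in records:
        s = seq.upper().replace("U", "T") if dna_alphabet else seq.upper()
        out.append(SeqRecord(Seq(s), id=gid, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a minimal gene annotation table (gene_id, exonic/intronic length).

    Lengths are in bases; interval inputs, when used, follow the BED
    convention (0-based half-open).
    """
    tab = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "exonic_len", "intronic_len"}
    missing = required - set(tab.columns)
    if missing:
        raise DataError(f"annotation lacks columns: {sorted(missing)}")
    if tab["gene_id"].duplicated().any():
        raise DataError("duplicate gene ids in annotation")
    if (tab[["exonic_len", "intronic_len"]] < 0).to_numpy().any():
        raise DataError("negative lengths in annotation")
    return tab.set_index("gene_id")
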