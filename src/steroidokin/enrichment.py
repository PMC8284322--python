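"""Sequence-set enrichment: ranked k-mer statistics, RBP motif matching,
and preranked gene-set enrichment.

The ranked k-mer test asks whether sequences containing a k-mer sit at the
extremes of a gene ranking (e.g. by decay rate): a Mann-Whitney rank
association per k-mer, BH-corrected over all k-mers observed.  K-mers can
then be matched against RBP position-weight matrices by best-window
log-odds.  Preranked GSEA uses the classic weighted Kolmogorov-Smirnov
running sum with gene-label permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues
from .containers import ConfigError, DataError

RNA_ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _kmer_presence(records: list[tuple[str, str]], k: int) -> dict[str, np.ndarray]:
    """Map each observed k-mer to the indices of sequences containing it."""
    hits: dict[str, set[int]] = {}
    for idx, (_, seq) in enumerate(records):
        seq = _normalize_seq(seq)
        seen = {seq[i: i + k] for i in range(len(seq) - k + 1)}
        for kmer in seen:
            if set(kmer) - set(RNA_ALPHABET):
                continue
            hits.setdefault(kmer, set()).add(idx)
    return {km: np.fromiter(ix, dtype=int) for km, ix in hits.items()}


def ranked_kmer_enrichment(
    utrs: list[tuple[str, str]],
    ranking: pd.Series,
    k: int = 7,
    top_n: int | None = 500,
) -> pd.DataFrame:
    """Rank-association of k-mer presence with a per-gene score.

    For every k-mer observed in at least one sequence, a Mann-Whitney test
    compares the ranking scores of sequences containing vs lacking it
    (normal approximation with tie and continuity corrections).  Direction
    is ``unstable-assoc`` when carriers rank high (higher score = faster
    decay).  Returns the ``top_n`` k-mers by p-value (all if ``None``) with
    BH q-values computed across every tested k-mer.
    """
    if len(ranking) == 0:
        raise DataError("empty ranking")
    seq_ids = [gid for gid, _ in utrs]
    if len(set(seq_ids)) != len(seq_ids):
        raise DataError("duplicate sequence ids")
    missing = [g for g in ranking.index if g not in set(seq_ids)]
    if missing:
        raise DataError(f"ranked genes without sequences: {missing[:5]}")
    records = [(gid, seq) for gid, seq in utrs if gid in set(ranking.index)]
    scores = ranking.loc[[gid for gid, _ in records]].to_numpy(dtype=float)
    n = len(records)
    ranks = stats.rankdata(scores)

    presence = _kmer_presence(records, k)
    kmers = sorted(presence)
    n1 = np.array([presence[km].size for km in kmers], dtype=float)
    ranksum = np.array([ranks[presence[km]].sum() for km in kmers])
    n2 = n - n1
    u = ranksum - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    # tie correction on the shared ranking
    _, counts = np.unique(scores, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / max(n**3 - n, 1)
    var_u = n1 * n2 * (n + 1) / 12.0 * tie_term
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mean_u - np.sign(u - mean_u) * 0.5) / np.sqrt(var_u)
    z = np.where(var_u > 0, z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "kmer": kmers,
            "score": z,
            "p_value": p,
            "q_value": bh_qvalues(p),
            "n_with": n1.astype(int),
            "direction": np.where(z >= 0, "unstable-assoc", "stable-assoc"),
        }
    ).sort_values(["p_value", "kmer"], kind="mergesort", ignore_index=True)
    return out.head(top_n) if top_n is not None else out


def set_kmer_enrichment(
    target_utrs: list[tuple[str, str]],
    background_utrs: list[tuple[str, str]],
    k: int = 5,
) -> pd.DataFrame:
    """Fisher-exact k-mer presence enrichment of a target set vs background.

    ``log2_enrichment`` compares presence odds with a Haldane 0.5
    correction, so swapping target and background exactly negates it.
    """
    if not target_utrs or not background_utrs:
        raise DataError("both sequence sets must be non-empty")
    t_ids = {gid for gid, _ in target_utrs}
    b_ids = {gid for gid, _ in background_utrs}
    if t_ids & b_ids:
        raise DataError(f"gene ids shared between sets: {sorted(t_ids & b_ids)[:5]}")
    pres_t = _kmer_presence(target_utrs, k)
    pres_b = _kmer_presence(background_utrs, k)
    n_t, n_b = len(target_utrs), len(background_utrs)
    rows = []
    for km in sorted(set(pres_t) | set(pres_b)):
        a = pres_t.get(km, np.empty(0)).size
        b = pres_b.get(km, np.empty(0)).size
        _, p = stats.fisher_exact([[a, n_t - a], [b, n_b - b]])
        log2_enr = float(
            np.log2(((a + 0.5) / (n_t - a + 0.5)) / ((b + 0.5) / (n_b - b + 0.5)))
        )
        rows.append((km, log2_enr, p, a, b))
    out = pd.DataFrame(
        rows, columns=["kmer", "log2_enrichment", "p_value", "n_target", "n_background"]
    )
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "kmer"], kind="mergesort", ignore_index=True)


# ---------------------------------------------------------------------------
# RBP motif matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifRecord:
    """An RBP recognition motif as a position-probability matrix."""

    rbp_name: str
    pwm: np.ndarray  # positions x 4 (ACGU), rows sum to 1
    consensus: str

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise DataError(f"{self.rbp_name}: PWM must be positions x 4")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
            raise DataError(f"{self.rbp_name}: PWM rows must sum to 1")
        object.__setattr__(self, "pwm", pwm)


#: toy MEME-minimal motif database: an ARE-binding motif, a U-rich motif and
#: a GC-rich control (synthetic stand-ins, not measured RBP specificities)
TOY_MOTIF_DB = """\
MEME version 4

ALPHABET= ACGU

MOTIF ARE_RBP AUUUA
letter-probability matrix: alength= 4 w= 5
0.910 0.030 0.030 0.030
0.030 0.030 0.030 0.910
0.030 0.030 0.030 0.910
0.030 0.030 0.030 0.910
0.910 0.030 0.030 0.030

MOTIF URICH_RBP UUUUU
letter-probability matrix: alength= 4 w= 5
0.030 0.030 0.030 0.910
0.030 0.030 0.030 0.910
0.030 0.030 0.030 0.910
0.030 0.030 0.030 0.910
0.030 0.030 0.030 0.910

MOTIF GC_CTRL GCGCG
letter-probability matrix: alength= 4 w= 5
0.030 0.030 0.910 0.030
0.030 0.910 0.030 0.030
0.030 0.030 0.910 0.030
0.030 0.910 0.030 0.030
0.030 0.030 0.910 0.030
"""


def parse_meme_minimal(text: str) -> list[MotifRecord]:
    """Parse MEME-minimal-format PWMs (ACGU alphabet)."""
    records = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1]
            consensus = parts[2] if len(parts) > 2 else ""
            i += 1
            while i < len(lines) and "letter-probability" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise DataError(f"motif {name}: missing probability matrix")
            width = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for j in range(width):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            i += width
            records.append(MotifRecord(name, np.array(rows), consensus))
        i += 1
    return records


def toy_motif_db() -> list[MotifRecord]:
    return parse_meme_minimal(TOY_MOTIF_DB)


def _log_odds(pwm: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    return np.log2(np.maximum(pwm, floor) / 0.25)


def match_kmers_to_motifs(
    kmers: list[str],
    motif_db: list[MotifRecord],
    score_threshold: float = 0.8,
) -> pd.DataFrame:
    """Assign k-mers to RBP motifs by best-window PWM log-odds.

    The k-mer is slid against the PWM in whichever direction fits (k-mer
    window over a shorter PWM, or PWM window over a shorter k-mer) and the
    best sum of log2(p/0.25) terms is kept.  A k-mer is assigned when its
    score reaches ``score_threshold`` times the maximal achievable score of
    that alignment geometry, so a threshold of 1 keeps only exact-consensus
    matches.
    """
    rows = []
    for motif in motif_db:
        lo = _log_odds(motif.pwm)
        width = lo.shape[0]
        per_pos_max = lo.max(axis=1)
        for kmer in kmers:
            km = _normalize_seq(kmer)
            if set(km) - set(RNA_ALPHABET):
                raise DataError(f"k-mer {kmer!r} not over {RNA_ALPHABET}")
            idx = np.array([_BASE_INDEX[b] for b in km])
            klen = idx.size
            if klen >= width:
                offsets = range(klen - width + 1)
                best = max(
                    lo[np.arange(width), idx[o: o + width]].sum() for o in offsets
                )
                best_possible = per_pos_max.sum()
            else:
                offsets = range(width - klen + 1)
                best = max(
                    lo[np.arange(o, o + klen), idx].sum() for o in offsets
                )
                best_possible = max(
                    per_pos_max[o: o + klen].sum() for o in offsets
                )
            if best_possible > 0 and best >= score_threshold * best_possible - 1e-12:
                rows.append((kmer, motif.rbp_name, float(best), float(best_possible)))
    return pd.DataFrame(rows, columns=["kmer", "rbp", "score", "max_score"])


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _running_es(stat_sorted: np.ndarray, in_set: np.ndarray) -> float:
    weights = np.abs(stat_sorted)
    hit_w = np.where(in_set, weights, 0.0)
    total_hit = hit_w.sum()
    n_miss = in_set.size - int(in_set.sum())
    if total_hit == 0 or n_miss == 0:
        return 0.0
    p_hit = np.cumsum(hit_w) / total_hit
    p_miss = np.cumsum(~in_set) / n_miss
    running = p_hit - p_miss
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranked_genes: pd.Series,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Classic weighted-KS preranked gene-set enrichment.

    ``ranked_genes`` maps gene id -> ranking statistic; genes are sorted by
    decreasing statistic and the running sum is weighted by |stat|.  The
    p-value comes from gene-label permutations (random same-size sets), the
    normalized ES from dividing by the mean |permuted ES|.  Deterministic
    for a given seed.
    """
    if n_perm < 100:
        raise ConfigError("need at least 100 permutations")
    order = ranked_genes.sort_values(ascending=False)
    genes = order.index.to_numpy()
    stat = order.to_numpy(dtype=float)
    members = np.isin(genes, sorted(gene_set))
    n_hit = int(members.sum())
    if n_hit == 0:
        return {"es": float("nan"), "nes": float("nan"), "p": float("nan"),
                "n_hits": 0, "flag": "empty_intersection"}
    es = _running_es(stat, members)
    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    n = genes.size
    for i in range(n_perm):
        idx = rng.choice(n, size=n_hit, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        perm_es[i] = _running_es(stat, mask)
    p = (1.0 + np.count_nonzero(np.abs(perm_es) >= abs(es))) / (n_perm + 1.0)
    scale = np.abs(perm_es).mean()
    nes = es / scale if scale > 0 else float("nan")
    return {"es": es, "nes": float(nes), "p": float(p), "n_hits": n_hit, "flag": ""}
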