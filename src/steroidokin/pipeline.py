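"""End-to-end pipeline: simulate -> kinetics -> response -> stability ->
enrichment -> screen, with a run manifest for reproducibility.

Every stage writes plain TSV outputs carrying the seed and a configuration
hash in a commented header; rerunning with the same configuration is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import ConfigError
from .enrichment import gsea_preranked, match_kmers_to_motifs, ranked_kmer_enrichment, toy_motif_db
from .io import write_counts, write_fasta, write_tsv
from .kinetics import estimate_rates_twocomp, labeled_scale_from_references
from .response import call_differential, cluster_profiles, decay_vs_peak, log2fc_profiles, peak_table
from .screen import normalize_wells, summarize_effects
from .simulate import CourseConfig, simulate_course, simulate_screen, simulate_utrs
from .stability import eisa_call, overlap_odds_ratio


@dataclass
class PipelineConfig:
    """Parameters of a full simulated-analysis run."""

    seed: int = 0
    n_genes: int = 500
    n_replicates: int = 2
    dispersion: float = 0.05
    tau: float = 1.0 / 3.0
    k_clusters: int = 12
    diff_fdr: float = 0.001
    fc_threshold: float = 2.0
    eisa_fdr: float = 0.05
    min_intron_mean: float = 10.0
    kmer_k: int = 7
    utr_length: int = 200
    planted_motif: str = "UAUUUAU"
    planted_fraction: float = 0.8
    screen_alpha: float = 0.05
    screen_effect: float = 1.5
    gsea_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:  # wrong types/values
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    tables: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage on simulated data and write all outputs to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed, chash = config.seed, config.config_hash()
    tables: dict = {}

    # --- simulate -----------------------------------------------------
    sim_cfg = CourseConfig(
        n_genes=config.n_genes,
        n_replicates=config.n_replicates,
        dispersion=config.dispersion,
        pulse_tau=config.tau,
    )
    sim = simulate_course(sim_cfg, seed)
    for name, matrix in {**sim.course, **sim.pulse}.items():
        write_counts(matrix, outdir / f"counts_{name}.tsv",
                     outdir / f"samples_{name}.tsv", seed=seed, config_hash=chash)
    write_tsv(sim.truth.kinetics, outdir / "truth_kinetics.tsv",
              seed=seed, config_hash=chash)

    # --- kinetics -----------------------------------------------------
    ref_fracs = sim.truth.kinetics.loc[sim.truth.reference_genes, "f_m"]
    scale = labeled_scale_from_references(
        sim.pulse["labeled_mature"], sim.pulse["total_mature"], ref_fracs
    )
    rates = estimate_rates_twocomp(
        sim.pulse["labeled_precursor"], sim.pulse["labeled_mature"],
        sim.pulse["total_precursor"], sim.pulse["total_mature"],
        tau=config.tau, scale=scale,
    )
    write_tsv(rates, outdir / "kinetic_rates.tsv", seed=seed, config_hash=chash)
    tables["rates"] = rates

    # --- response -----------------------------------------------------
    mature = sim.course["mature"]
    gene_table, tests = call_differential(
        mature, fdr_threshold=config.diff_fdr, fc_threshold=config.fc_threshold
    )
    profiles = log2fc_profiles(mature)
    sig = gene_table.index[gene_table["significant"]]
    k = min(config.k_clusters, max(2, len(sig)))
    if len(sig) >= 2:
        clusters = cluster_profiles(profiles.loc[sig], k=k, seed=seed)
        labels = clusters.labels
        write_tsv(clusters.centers, outdir / "cluster_centers.tsv",
                  seed=seed, config_hash=chash)
    else:
        labels = pd.Series(dtype=object)
    peaks = peak_table(profiles.loc[sig]) if len(sig) else pd.DataFrame()
    write_tsv(gene_table, outdir / "differential_genes.tsv", seed=seed, config_hash=chash)
    write_tsv(profiles, outdir / "log2fc_profiles.tsv", seed=seed, config_hash=chash)
    if len(peaks):
        corr = decay_vs_peak(rates, peaks, clusters=labels)
        write_tsv(
            pd.DataFrame([{k2: v for k2, v in corr.items() if k2 != "cluster_medians"}]),
            outdir / "decay_vs_peak.tsv", seed=seed, config_hash=chash, index=False,
        )
        tables["decay_vs_peak"] = corr
    tables.update(gene_table=gene_table, profiles=profiles, peaks=peaks, labels=labels)

    # --- stability ----------------------------------------------------
    calls = eisa_call(
        sim.course["precursor"], mature,
        fdr=config.eisa_fdr, min_intron_mean=config.min_intron_mean,
    )
    write_tsv(calls, outdir / "stability_calls.tsv", seed=seed, config_hash=chash)
    tables["stability"] = calls
    if len(labels):
        universe = set(calls.index[calls["class"] != "untestable"]) & set(labels.index)
        destab = set(calls.index[calls["class"] == "destabilized"]) & universe
        rows = []
        for cl in sorted(labels.unique()):
            members = set(labels.index[labels == cl]) & universe
            if universe and members:
                odds, p, _ = overlap_odds_ratio(destab, members, universe)
                rows.append((cl, odds, p))
        if rows:
            write_tsv(pd.DataFrame(rows, columns=["cluster", "odds_ratio", "p"]),
                      outdir / "destabilized_cluster_overlap.tsv",
                      seed=seed, config_hash=chash, index=False)

    # --- enrichment ---------------------------------------------------
    beta_true = sim.truth.kinetics["beta0"]
    course_genes = beta_true[~beta_true.index.str.startswith("REF")]
    utrs, planted = simulate_utrs(
        course_genes, config.planted_motif, config.planted_fraction,
        length=config.utr_length, seed=seed,
    )
    write_fasta(utrs, outdir / "utrs.fasta")
    ranking = rates["beta_hat"].reindex(course_genes.index).dropna()
    kmers = ranked_kmer_enrichment(
        [(g, s) for g, s in utrs if g in set(ranking.index)], ranking, k=config.kmer_k
    )
    write_tsv(kmers, outdir / "kmer_enrichment.tsv", seed=seed,
              config_hash=chash, index=False)
    matches = match_kmers_to_motifs(list(kmers["kmer"].head(50)), toy_motif_db())
    write_tsv(matches, outdir / "kmer_motif_matches.tsv", seed=seed,
              config_hash=chash, index=False)
    tables.update(kmers=kmers, planted=planted, motif_matches=matches)
    if len(labels):
        biggest = labels.value_counts().index[0]
        gsea = gsea_preranked(
            profiles.abs().max(axis=1),
            set(labels.index[labels == biggest]),
            n_perm=config.gsea_permutations, seed=seed,
        )
        write_tsv(pd.DataFrame([gsea]), outdir / "gsea.tsv", seed=seed,
                  config_hash=chash, index=False)
        tables["gsea"] = gsea

    # --- screen -------------------------------------------------------
    sirnas = [f"si{g}_{i}" for g in "ABCDEFGH" for i in (1, 2)]
    genes = [s.split("_")[0][2:] for s in sirnas]
    effects = pd.Series(1.0, index=sirnas)
    effects[["siA_1", "siA_2"]] = config.screen_effect
    plate = simulate_screen(effects, pd.Series(genes, index=sirnas), seed=seed)
    norm = normalize_wells(plate)
    sirna_table, gene_table_s = summarize_effects(norm, alpha=config.screen_alpha)
    write_tsv(plate, outdir / "screen_plates.tsv", seed=seed, config_hash=chash, index=False)
    write_tsv(sirna_table, outdir / "screen_sirna_effects.tsv", seed=seed,
              config_hash=chash, index=False)
    write_tsv(gene_table_s, outdir / "screen_gene_classes.tsv", seed=seed,
              config_hash=chash, index=False)
    tables.update(screen_sirna=sirna_table, screen_genes=gene_table_s)

    manifest = {
        "package": "steroidokin",
        "version": __version__,
        "seed": seed,
        "config_hash": chash,
        "config": asdict(config),
        "outputs": sorted(
            [p.name for p in outdir.iterdir() if p.is_file()] + ["manifest.json"]
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(outdir=outdir, manifest=manifest, tables=tables)
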