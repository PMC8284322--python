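# steroidokin

Tools for dissecting the kinetics of stimulus-induced gene expression in
steroidogenic cells — the setting where a hormone such as angiotensin II
(AngII) triggers a transcriptional program whose *timing* is shaped by RNA
decay. The package answers, on count-level RNA-seq data, the questions that
arise in such studies:

- How fast is each transcript synthesized, processed, and degraded?
  (`kinetics`: rate estimation from a short 4sU metabolic-labeling pulse)
- Which genes respond, with what temporal shape, and when do they peak?
  (`response`: NB differential calling, k-means temporal clustering,
  time-to-peak / peakiness)
- Which transcripts are stabilized or destabilized *during* the response?
  (`stability`: exon–intron split analysis, EISA)
- Which 3′-UTR elements and RNA-binding-protein (RBP) motifs track with
  instability? (`enrichment`: ranked/set k-mer tests, PWM matching,
  preranked GSEA)
- Which RBP knockdowns raise or lower hormone output in a plate-based
  siRNA screen? (`screen`: mock/viability normalization, two-siRNA
  concordance)

Because real stimulation courses are large and deposit-bound, the package
ships a first-class simulator (`simulate`) that generates every input with
known ground truth, so each analysis stage is validated end to end.

## The model

Each gene follows the two-compartment first-order system

    dP/dt = α(t) − γ·P        (precursor, intronic signal)
    dM/dt = γ·P − β(t)·M      (mature, exonic signal)

with synthesis rate α (transcripts/h), processing rate γ (1/h), and decay
rate β (1/h); half-life t½ = ln2/β. Stimulus-driven transcription follows a
double-sigmoid impulse α(t) = α₀·s(t) rising to `fold_peak` around `t_on`
and resolving to `fold_late` around `t_off`. A 4sU pulse of length τ labels

    f_P = 1 − e^(−γτ)
    f_M = 1 − (β·e^(−γτ) − γ·e^(−βτ)) / (β − γ)

of the precursor and mature pools at steady state; `kinetics` inverts these
(closed form for γ, monotone bisection for β) to recover rates per gene.
EISA compares the stimulated change in exonic vs intronic signal,
z = (Δexon − Δintron)/SE: a transcript whose mature pool lags its precursor
pool is being destabilized.

## Worked example

```python
import steroidokin as sk
from scipy.stats import spearmanr

# simulate a 12-time-point duplicate stimulation course plus a 20-min
# 4sU pulse for 300 genes with known kinetics
sim = sk.simulate_course(sk.CourseConfig(n_genes=300), seed=7)

# recover rates from the pulse (labeled-library depth from reference genes)
scale = sk.labeled_scale_from_references(
    sim.pulse["labeled_mature"], sim.pulse["total_mature"],
    sim.truth.kinetics.loc[sim.truth.reference_genes, "f_m"])
rates = sk.estimate_rates_twocomp(
    sim.pulse["labeled_precursor"], sim.pulse["labeled_mature"],
    sim.pulse["total_precursor"], sim.pulse["total_mature"],
    tau=1/3, scale=scale)

ok = rates["beta_hat"].notna() & (rates["flag"] == "")
truth = sim.truth.kinetics
print(f"estimated rates for {int(ok.sum())} genes")
rho = spearmanr(rates.loc[ok, 'beta_hat'], truth.loc[ok[ok].index, 'beta0']).statistic
print(f"Spearman rho(beta_hat, beta_true) = {rho:.3f}")

gene_table, _ = sk.call_differential(sim.course["mature"])
print(f"{int(gene_table['significant'].sum())} of {len(gene_table)} genes significant")
```

prints

```
estimated rates for 319 genes
Spearman rho(beta_hat, beta_true) = 0.964
108 of 320 genes significant
```

— the estimator ranks simulated decay rates almost perfectly (ρ = 0.96)
and the differential caller flags the ~1/3 of simulated genes that were
built to respond. The first rows of the rate table look like

```
         alpha_hat  gamma_hat  beta_hat  half_life  n_effective          flag
G00000     132.752     13.273     2.855      0.243         46.5
G00001      50.913      1.034     2.909      0.238         17.5
G00002         NaN      3.361       NaN        NaN          7.0  low_coverage
```

with rates per hour, half-lives in hours, and genes below the coverage
floor flagged rather than reported.

## Command line

Every stage is also a subcommand of the `steroidokin` console script:

```
steroidokin run --seed 1 --outdir out/          # full simulated pipeline
steroidokin simulate --seed 1 --outdir sim/     # data + ground truth only
steroidokin kinetics --labeled ... --total ... --tau 0.333 --out rates.tsv
steroidokin respond --counts ... --meta ... --k 12 --fdr 0.001 --outdir out/
steroidokin stability --pre-counts ... --mat-counts ... --out calls.tsv
steroidokin enrich rank|set|gsea ...
steroidokin screen --plates plates.tsv --outdir out/
```

All outputs are TSV with a commented header carrying the seed and a
configuration hash; `run` writes a `manifest.json` and is bit-identical
when rerun with the same configuration. Exit codes: 0 ok, 2 configuration
error, 3 data error, 4 numerical failure.

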