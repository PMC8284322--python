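# Methods

This note records the models, estimators, parameter choices, and numerical
conventions behind `steroidokin`, and what the simulation-based validation
does and does not establish about real data.

## Two-compartment RNA kinetics

Every gene is modeled as a precursor pool P (intronic signal) feeding a
mature pool M (exonic signal):

    dP/dt = α(t) − γ P,     dM/dt = γ P − β(t) M

α is the synthesis rate in transcripts/h, γ the processing rate (1/h), β
the first-order decay rate (1/h), half-life ln2/β. All rates are reported
per hour throughout. The simulator integrates this system with LSODA
(rtol 1e-9, atol 1e-12) from the unstimulated steady state P(0) = α(0)/γ,
M(0) = α(0)/β₀. A stimulation-coupled decay change multiplies β by
`beta_stim_fold` from `beta_switch_time` onward; the integration is split
at the switch so the solver never steps across the discontinuity.

### Transcription impulse

Stimulus-driven transcription uses the product-of-two-sigmoids impulse

    s(t) = (1/fp) · [1 + (fp−1) σ(k(t−t_on))] · [fl + (fp−fl) σ(−k(t−t_off))]

(σ the logistic function, fp = `fold_peak`, fl = `fold_late`, k = `slope`).
One practical constraint follows from the shared slope: only the rise side
affects the t = 0 state, so archetypes keep `slope·t_on ≳ 4` to make t = 0
a genuine unstimulated steady state. Default archetypes emulate a
steroidogenic stimulation course: a strongly induced immediate-early class
(~20-fold, fast decay), mid and late activated classes (~6- and ~4-fold,
progressively slower decay and later onset), a destabilized class (6-fold
induction coupled with a 2× decay increase from 1 h), a repressed class,
and a flat background making up half the transcriptome. The default
sampling grid is {0, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24} h in
duplicate: dense early coverage (responses begin within 15 min) and
resolution by 24 h.

### Count noise

Counts are negative binomial with variance μ + d·μ², gene-shared
dispersion d = 0.05 by default (d = 0 degenerates to Poisson), sampled as
a gamma–Poisson mixture. Course samples (different wells/time points) draw
independent biological factors. The pulse experiment is different: the
labeled and total libraries of one replicate are split from the *same*
RNA sample, so the gamma-distributed biological factor is drawn once per
gene per replicate and shared across all four pulse matrices, leaving only
Poisson noise library-specific. This matters quantitatively — with fully
independent noise on all four matrices the labeled/total ratio carries
twice the biological variance and the decay estimator's median relative
error has a floor near 0.26 at dispersion 0.05, regardless of depth.

### Labeled-library depth

The labeled library is sequenced to its own depth (default 0.3× the total
library's yield), so the labeled/total count ratio equals c·f with an
unknown scale c. Twenty stable "reference" genes with known labeled
fractions (spike-in-like) are simulated alongside; the estimator recovers
c as the median of (observed ratio / known fraction) over the references.

## Rate estimation from a 4sU pulse

A pulse of length τ labels fractions

    f_P = 1 − e^(−γτ),
    f_M = 1 − (β e^(−γτ) − γ e^(−βτ)) / (β − γ)

of the two pools at steady state, with the analytic limit
f_M = 1 − (1+βτ)e^(−βτ) used when |β−γ| < 1e-6. The two-compartment
estimator inverts f_P in closed form for γ, then solves f_M(γ̂, β) = f̂_M
for β by Brent's method on [1e-4, 1e3] /h (f_M is monotone in β; residual
tolerance 1e-8, genes whose observed fraction is unreachable inside the
bracket are flagged `bracket`). α̂ = β̂ × normalized mature abundance.
Observed fractions are clipped to [1e-4, 1−1e-4] (flagged when clipping
binds — this caps recoverable γ near 28/h for a 20-min pulse); genes with
mean total counts below 10 are flagged `low_coverage` and not estimated.

## Differential calling and temporal clustering

Counts are normalized by relative size factors (library sizes divided by
their geometric mean), making every downstream log fold-change invariant
to a global library-size rescaling. Per gene and time point the caller
computes log2((μ_t + 0.5)/(μ_0 + 0.5)) and a Wald z with the delta-method
variance Var(log2 mean) ≈ (1/μ + d)/(n ln²2), where d is a per-gene
method-of-moments dispersion shrunk 50/50 toward a fitted a/μ + b trend.
BH correction runs across all gene × time tests; a gene is significant if
any time point passes both FDR ≤ 0.001 and |fold change| ≥ 2. With a
single replicate the test degrades to Poisson and flags every gene.

K-means (scikit-learn, fixed seed, n_init = 50) clusters the significant
genes' fold-change trajectories; z-scoring before clustering is optional
and off by default so magnitude separates strong from weak responders.
Cluster names encode direction (a/r from the sign of the mean profile's
peak), strength (s/w at |peak| ≥ 2 log2 units), and an index by ascending
time-to-peak within each direction/strength group, so `as1` is the
earliest strong activated class.

### Time-to-peak and peakiness

Profiles are fit with a natural cubic *smoothing* spline (roughness
penalty λ = 1.0; exact interpolation at exactly 4 points, where smoothing
splines are undefined) and evaluated on a 0.05-h grid; time-to-peak is the
argmax of |log2fc| and peakiness is peak height divided by the full width
at half maximum. Smoothing rather than interpolation is deliberate: any
shape-preserving interpolant places every maximum exactly at a sampling
knot, quantizing time-to-peak to the grid and destroying rank resolution
under count noise, while the smoothing spline moves continuously with the
data and is stable against replicate noise. Peak/FWHM is an explicit,
reproducible peakiness definition chosen for this package; flat profiles
(peak < 1e-9) return NaN.

## EISA stability calls

All post-stimulation samples are pooled against the t = 0 baseline
(per-time contrasts are a caller option upstream). Per gene,
Δexon and Δintron are offset log2 fold changes of normalized means and

    z = (Δexon − Δintron) / sqrt(SE²_exon + SE²_intron)

with the same delta-method, trend-shrunk SEs as the differential caller;
two-sided normal p, BH across testable genes. `destabilized` requires
z < 0 and q ≤ 0.05, `stabilized` the opposite sign; genes that are
intronless or fall below a mean normalized intron count of 10 are
`untestable`. The statistic is a replicate-variance z rather than a
moderated linear-model fit: simpler, fully specified, and calibrated by
simulation at 2–3 replicates.

A caveat the pooled contrast inherits: it is calibrated for responses that
are approximately step-like inside the pooled window. Under a sharp
transient impulse the mature pool lags the precursor pool *within* the
window, which biases Δexon − Δintron slightly negative for purely
transcriptional genes. The calibration and power study therefore uses
step-induction transcription with stimulated samples at 8–24 h, after the
mature pools have re-equilibrated; on strongly impulse-shaped data the
per-time-point mode is the safer choice.

## Sequence enrichment

*Ranked k-mer test.* For every k-mer present in at least one 3′-UTR, a
Mann–Whitney test (normal approximation with tie and continuity
corrections) compares the decay-rate ranks of sequences containing vs
lacking it; BH across all observed k-mers; carriers ranking high are
`unstable-assoc`. This is a rank-association statistic with the same
inferential target as published rank-based word-enrichment tools, not a
reimplementation of any of them.

*Set test.* Fisher exact on presence/absence between a target and a
background set, with Haldane-corrected log2 enrichment so swapping the
sets exactly negates it. Overlapping gene ids between sets are an error.

*Motif matching.* K-mers score against RBP position-probability matrices
by best-window log2(p/0.25) log-odds (probabilities floored at 1e-3),
sliding whichever of k-mer/PWM is longer along the other; assignment
requires `score_threshold` (default 0.8) of the window's maximal
achievable score, so a threshold of 1 keeps exact-consensus matches only.
The bundled motif file is a synthetic three-motif toy database (ARE-like,
U-rich, GC control) in MEME-minimal text format — stand-ins for testing
and demonstration, not measured RBP specificities.

*Preranked GSEA.* Classic weighted Kolmogorov–Smirnov running sum with
weight |stat|; p-values from random same-size gene sets (gene-label
permutation, +1-corrected), NES = ES / mean |permuted ES|; deterministic
for a given seed.

## Screen analysis

Per well, aldosterone/viability ratios are divided by the geometric mean
of the same plate and condition's mock-control wells, cancelling
multiplicative plate batch effects exactly. Per-siRNA effects are mean
log2 normalized readings with a two-sided one-sample t-test at α = 0.05;
a gene is `repressor` (resp. `activator`) when ≥ 2 siRNAs are
significantly positive (negative), `discordant` when significant effects
disagree, `single-sirna` when only one was screened.

Mock normalization leaves a residual location error shared by every well
of a plate (the mock wells' own sampling noise), which correlates the two
siRNAs' tests and inflates the joint false-classification rate. Two design
choices keep this inside a 1.5× envelope of the nominal joint rate: the
simulator defaults to a generous 16-well mock block per plate and
condition (shrinking the shared error), and `summarize_effects` offers an
optional leave-own-gene-out trimmed-mean plate centering. Centering stays
*off* by default: in a small candidate screen (16 siRNAs) one true hit
contaminates ~19% of a plate's wells, enough to bias any robust location
estimate and manufacture false calls in the opposite direction; with
hundreds of siRNAs per plate the centering becomes the better tool.
The screen simulator draws plate batch factors (lognormal, sd 0.3), per-
well viability (lognormal, sd 0.1) that multiplies the aldosterone output
and cancels on normalization, a small viability measurement error
(sd 0.05), and lognormal reading noise (sd 0.2); basal output is 10× lower
than stimulated, and siRNA replicates spread round-robin across plates.

## Validation studies and their scope

`scripts/acceptance.py` (same code path as `tests/test_acceptance.py`)
measures, on freshly simulated data: decay-rate recovery (500 genes, β
log-uniform [0.05, 4] /h, γ [0.5, 10] /h, 20-min pulse, dispersion 0.05,
2 replicates → Spearman ρ ≈ 0.97, median relative error ≈ 0.16);
the inverse decay/time-to-peak law under one shared impulse (ρ ≈ −0.91);
EISA calibration and power (1000 genes, 200 with 2× decay increase, 3
replicates → empirical FDR ≈ 0.03 at nominal 0.05, sensitivity ≈ 0.76);
planted 7-mer recovery (top-10 rank in 20/20 runs); screen effect recovery
and null classification (≈ 0.001 misclassification over 1400 null
gene-screens); null-calibration KS checks; and the closed-form oracles
(steady state and labeled fractions to ≤ 1e-6, exact one-compartment
inversion). Study sizes were chosen so the full script completes in well
under a minute on one CPU.

What passing these studies shows: the estimators invert the generative
model they target, at realistic noise, with calibrated error rates. What
it does not show: robustness to features the simulator omits — isoform
mixtures and alternative 3′ ends, positionally biased coverage, labeling-
efficiency variation across transcripts, plate spatial gradients,
transfection-efficiency differences between siRNAs, or decay that is not
first-order. Conclusions about real data inherit those assumptions.

## Numerical conventions

- Size factors are relative (geometric-mean-centered), never absolute.
- 0.5 offsets before log2 of normalized means; fraction clipping 1e-4.
- β = γ degeneracy switches to the analytic limit at |β−γ| < 1e-6.
- Ties in the cross-correlation lag scan resolve to the smallest lag;
  ties in ranked k-mer p-values sort lexicographically for determinism.
- Sequences are RNA (ACGU) in memory; FASTA is written in the DNA
  alphabet by default and normalized back to RNA on read.
- All randomness flows through `numpy.random.default_rng` seeds; every
  pipeline output carries the seed and a configuration hash in a
  commented header, and reruns are bit-identical.
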