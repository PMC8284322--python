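"""Ground-truth simulator for stimulus-response RNA kinetics experiments.

Generates the four kinds of data the analysis modules consume, each with a
known ground truth:

* a stimulation time course (precursor + mature count matrices) driven by an
  impulse-shaped transcription rate through a two-compartment ODE,
* a short metabolic-labeling pulse at unstimulated steady state (labeled +
  total counts for both pools),
* random 3'-UTR sequences with a k-mer planted in high-decay genes,
* multi-plate siRNA screen tables with batch and viability effects.

The transcription impulse is the product-of-two-sigmoids form commonly used
for stimulus-response expression trajectories: a rise to ``fold_peak`` around
``t_on`` followed by relaxation to ``fold_late`` around ``t_off``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .containers import ConfigError, DataError, NumericalError, SimTruth, TimeCourseMatrix

RNA_ALPHABET = "ACGU"

# |beta - gamma| below this uses the equal-rate analytic limit
EQUAL_RATE_TOL = 1e-6


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpulseParams:
    """Parameters of the double-sigmoid transcription impulse.

    ``baseline_rate`` is in transcripts/h; ``fold_peak`` and ``fold_late``
    are unitless multipliers of baseline; ``t_on``/``t_off`` are the onset
    and resolution times in hours; ``slope`` (1/h) sets sigmoid steepness.
    """

    baseline_rate: float = 1.0
    fold_peak: float = 1.0
    fold_late: float = 1.0
    t_on: float = 0.5
    t_off: float = 4.0
    slope: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be > 0")
        if self.fold_peak <= 0 or self.fold_late <= 0:
            raise ConfigError("fold_peak and fold_late must be > 0")
        if self.t_on < 0 or self.t_off <= self.t_on:
            raise ConfigError("need t_off > t_on >= 0")
        if self.slope <= 0:
            raise ConfigError("slope must be > 0")


@dataclass(frozen=True)
class GeneKinetics:
    """Per-gene first-order kinetic parameters.

    ``alpha`` is the unstimulated synthesis rate (transcripts/h), ``gamma``
    the precursor processing rate (1/h), ``beta0`` the unstimulated decay
    rate (1/h).  ``beta_stim_fold`` multiplies beta from
    ``beta_switch_time`` onward (1 = constant decay).
    """

    gene_id: str
    alpha: float
    gamma: float
    beta0: float
    beta_stim_fold: float = 1.0
    beta_switch_time: float = 0.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.gamma, self.beta0) <= 0:
            raise ConfigError(f"{self.gene_id}: alpha, gamma, beta0 must be > 0")
        if self.beta_stim_fold <= 0:
            raise ConfigError(f"{self.gene_id}: beta_stim_fold must be > 0")


# ---------------------------------------------------------------------------
# deterministic kinetics
# ---------------------------------------------------------------------------

def impulse_rate(params: ImpulseParams, t):
    """Transcription rate alpha(t) of the double-sigmoid impulse.

    ``s(t) = (1/fp) * [1 + (fp-1) sig(k(t-t_on))] * [fl + (fp-fl) sig(-k(t-t_off))]``
    with ``sig`` the logistic function; returns ``baseline_rate * s(t)``.
    Accepts scalar or array ``t >= 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigError("time must be >= 0")
    fp, fl, k = params.fold_peak, params.fold_late, params.slope

    def sig(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))

    rise = 1.0 + (fp - 1.0) * sig(k * (t - params.t_on))
    fall = fl + (fp - fl) * sig(-k * (t - params.t_off))
    out = params.baseline_rate * rise * fall / fp
    return out if out.shape else float(out)


def decay_rate_at(kin: GeneKinetics, t):
    """beta(t): beta0 before the switch time, beta0*fold afterwards."""
    t = np.asarray(t, dtype=float)
    beta = np.where(
        (t >= kin.beta_switch_time) & (kin.beta_stim_fold != 1.0),
        kin.beta0 * kin.beta_stim_fold,
        kin.beta0,
    )
    return beta if beta.shape else float(beta)


def solve_two_compartment(
    kin: GeneKinetics,
    impulse: ImpulseParams,
    grid: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dP/dt = alpha(t) - gamma P, dM/dt = gamma P - beta(t) M.

    The initial condition is the unstimulated steady state
    ``P(0) = alpha(0)/gamma``, ``M(0) = alpha(0)/beta0``.  A decay switch at
    ``beta_switch_time`` is handled by integrating piecewise so the solver
    never steps across the discontinuity.  Returns ``(P, M)`` on ``grid``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ConfigError("grid must be strictly increasing and start at 0")

    a0 = impulse_rate(impulse, 0.0)
    y0 = np.array([a0 / kin.gamma, a0 / kin.beta0])

    switch = kin.beta_switch_time if kin.beta_stim_fold != 1.0 else np.inf
    segments: list[tuple[float, float, float]] = []  # (t0, t1, beta)
    t_end = grid[-1]
    if switch <= 0:
        segments.append((0.0, t_end, kin.beta0 * kin.beta_stim_fold))
    elif switch >= t_end:
        segments.append((0.0, t_end, kin.beta0))
    else:
        segments.append((0.0, switch, kin.beta0))
        segments.append((switch, t_end, kin.beta0 * kin.beta_stim_fold))

    out = np.empty((grid.size, 2))
    out[0] = y0
    y = y0
    for t0, t1, beta in segments:
        mask = (grid > t0) & (grid <= t1)
        t_eval = grid[mask]

        def rhs(t, state, beta=beta):
            p, m = state
            a = impulse_rate(impulse, t)
            return [a - kin.gamma * p, kin.gamma * p - beta * m]

        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", t_eval=t_eval if t_eval.size else None,
            rtol=rtol, atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise NumericalError(f"ODE integration failed for gene {kin.gene_id}")
        if t_eval.size:
            out[mask] = sol.y.T
        y = sol.y[:, -1]

    P = np.clip(out[:, 0], 0.0, None)
    M = np.clip(out[:, 1], 0.0, None)
    return P, M


def labeled_fractions(kin: GeneKinetics, tau: float) -> tuple[float, float]:
    """Labeled fractions of the precursor and mature pools after a pulse.

    At steady state with constant rates, a pulse of length ``tau`` labels

    ``f_P = 1 - exp(-gamma tau)``
    ``f_M = 1 - (beta e^{-gamma tau} - gamma e^{-beta tau}) / (beta - gamma)``

    with the ``beta == gamma`` limit ``f_M = 1 - (1 + beta tau) e^{-beta tau}``.
    """
    if tau <= 0:
        raise ConfigError("pulse length tau must be > 0")
    g, b = kin.gamma, kin.beta0
    f_p = 1.0 - np.exp(-g * tau)
    if abs(b - g) < EQUAL_RATE_TOL:
        f_m = 1.0 - (1.0 + b * tau) * np.exp(-b * tau)
    else:
        f_m = 1.0 - (b * np.exp(-g * tau) - g * np.exp(-b * tau)) / (b - g)
    return float(np.clip(f_p, 0.0, 1.0)), float(np.clip(f_m, 0.0, 1.0))


# ---------------------------------------------------------------------------
# count noise
# ---------------------------------------------------------------------------

def sample_counts(
    expected: np.ndarray,
    lib_sizes: np.ndarray | float,
    dispersion: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw negative-binomial counts around ``lib_size * expected``.

    Variance is ``mu + dispersion * mu^2``; ``dispersion = 0`` degenerates to
    Poisson.  ``expected`` is genes x samples; ``lib_sizes`` broadcasts over
    columns.  Reproducible for a given seed / generator.
    """
    if dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise DataError("expected abundances must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mu = expected * np.asarray(lib_sizes, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    # NB as gamma-Poisson mixture keeps the parametrization explicit
    lam = rng.gamma(shape=r, scale=mu[pos] / r)
    counts[pos] = rng.poisson(lam)
    return counts


# ---------------------------------------------------------------------------
# full course simulation
# ---------------------------------------------------------------------------

#: default sampling times (h) for the stimulation course: dense early
#: coverage (changes start within 15 min) and return toward baseline by 24 h
DEFAULT_TIME_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0)


@dataclass(frozen=True)
class Archetype:
    """A response class: one impulse shape plus per-gene rate ranges.

    Rates are drawn log-uniformly from ``(lo, hi)`` ranges. ``fraction`` is
    the share of simulated genes assigned to this archetype.
    """

    name: str
    fraction: float
    impulse: ImpulseParams
    alpha_range: tuple[float, float] = (20.0, 500.0)
    gamma_range: tuple[float, float] = (0.5, 10.0)
    beta_range: tuple[float, float] = (0.05, 4.0)
    beta_stim_fold: float = 1.0
    beta_switch_time: float = 0.0


def default_archetypes() -> list[Archetype]:
    """Archetypes emulating a steroidogenic stimulation response.

    Immediate-early genes combine strong induction with fast decay; late
    genes are induced slowly and are stable; a destabilized class couples
    induction with a 2x decay increase; the rest of the transcriptome is
    flat.  Magnitudes follow the ~20-fold early and ~4-fold late induction
    scale typical of such courses.
    """
    # onsets are sharp (slope * t_on >> 1) so the t = 0 state is genuinely
    # the unstimulated steady state
    return [
        Archetype(
            "immediate_early", 0.10,
            ImpulseParams(fold_peak=20.0, fold_late=1.0, t_on=0.5, t_off=1.5, slope=12.0),
            beta_range=(1.0, 4.0),
        ),
        Archetype(
            "activated_mid", 0.10,
            ImpulseParams(fold_peak=6.0, fold_late=1.0, t_on=1.0, t_off=4.0, slope=4.0),
            beta_range=(0.3, 1.0),
        ),
        Archetype(
            "activated_late", 0.10,
            ImpulseParams(fold_peak=4.0, fold_late=1.0, t_on=2.0, t_off=8.0, slope=2.0),
            beta_range=(0.05, 0.3),
        ),
        Archetype(
            "destabilized", 0.10,
            ImpulseParams(fold_peak=6.0, fold_late=1.0, t_on=1.0, t_off=4.0, slope=4.0),
            beta_range=(0.2, 1.0), beta_stim_fold=2.0, beta_switch_time=1.0,
        ),
        Archetype(
            "repressed", 0.10,
            ImpulseParams(fold_peak=0.25, fold_late=1.0, t_on=1.0, t_off=6.0, slope=4.0),
            beta_range=(0.2, 2.0),
        ),
        Archetype(
            "flat", 0.50,
            ImpulseParams(fold_peak=1.0, fold_late=1.0, t_on=0.5, t_off=4.0, slope=2.0),
            beta_range=(0.05, 2.0),
        ),
    ]


@dataclass
class CourseConfig:
    """Configuration for :func:`simulate_course`."""

    n_genes: int = 500
    archetypes: list[Archetype] = field(default_factory=default_archetypes)
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    n_replicates: int = 2
    dispersion: float = 0.05
    depth: float = 1.0
    pulse_tau: float = 1.0 / 3.0
    pulse_replicates: int = 2
    pulse_labeled_depth: float = 0.3
    n_reference: int = 20


@dataclass
class SimulatedExperiment:
    """Everything :func:`simulate_course` produces."""

    course: dict[str, TimeCourseMatrix]
    pulse: dict[str, TimeCourseMatrix]
    expected: dict[str, pd.DataFrame]
    truth: SimTruth


def _draw_gene_kinetics(
    config: CourseConfig, rng: np.random.Generator
) -> tuple[list[GeneKinetics], list[ImpulseParams], pd.Series]:
    if not config.archetypes:
        raise ConfigError("at least one archetype is required")
    fracs = np.array([a.fraction for a in config.archetypes], dtype=float)
    if np.any(fracs < 0) or fracs.sum() <= 0:
        raise ConfigError("archetype fractions must be non-negative and sum > 0")
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * config.n_genes).astype(int)
    counts[-1] += config.n_genes - counts.sum()

    kinetics: list[GeneKinetics] = []
    impulses: list[ImpulseParams] = []
    labels: list[str] = []
    gi = 0
    for arch, n in zip(config.archetypes, counts):
        for _ in range(n):
            gid = f"G{gi:05d}"
            gi += 1
            alpha = float(np.exp(rng.uniform(*np.log(arch.alpha_range))))
            gamma = float(np.exp(rng.uniform(*np.log(arch.gamma_range))))
            beta0 = float(np.exp(rng.uniform(*np.log(arch.beta_range))))
            kinetics.append(
                GeneKinetics(gid, alpha, gamma, beta0,
                             arch.beta_stim_fold, arch.beta_switch_time)
            )
            impulses.append(replace(arch.impulse, baseline_rate=alpha))
            labels.append(arch.name)
    for r in range(config.n_reference):
        gid = f"REF{r:03d}"
        alpha = float(np.exp(rng.uniform(np.log(50), np.log(300))))
        gamma = float(np.exp(rng.uniform(np.log(1.0), np.log(4.0))))
        beta0 = float(np.exp(rng.uniform(np.log(0.1), np.log(0.5))))
        kinetics.append(GeneKinetics(gid, alpha, gamma, beta0))
        impulses.append(ImpulseParams(baseline_rate=alpha))
        labels.append("reference")
    ids = [k.gene_id for k in kinetics]
    return kinetics, impulses, pd.Series(labels, index=ids, name="archetype")


def simulate_course(config: CourseConfig, seed: int) -> SimulatedExperiment:
    """Simulate a stimulation course plus an unstimulated pulse experiment.

    Returns count matrices for the course (precursor and mature layers over
    the time grid x replicates) and for the pulse (labeled and total counts
    for both pools at steady state), together with noise-free expected
    abundances and the full ground truth.
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(config.time_grid, dtype=float)
    kinetics, impulses, labels = _draw_gene_kinetics(config, rng)
    ids = list(labels.index)
    n = len(ids)

    exp_p = np.empty((n, grid.size))
    exp_m = np.empty((n, grid.size))
    for i, (kin, imp) in enumerate(zip(kinetics, impulses)):
        exp_p[i], exp_m[i] = solve_two_compartment(kin, imp, grid)

    def course_matrix(expected: np.ndarray, layer: str) -> TimeCourseMatrix:
        cols, times, reps = [], [], []
        blocks = []
        for r in range(config.n_replicates):
            blocks.append(
                sample_counts(expected, config.depth, config.dispersion, rng)
            )
            for t in grid:
                cols.append(f"{layer}_t{t:g}_r{r + 1}")
                times.append(t)
                reps.append(r + 1)
        counts = pd.DataFrame(
            np.hstack(blocks), index=ids, columns=cols
        )
        meta = pd.DataFrame(
            {
                "time": times,
                "replicate": reps,
                "condition": ["stimulated" if t > 0 else "unstimulated" for t in times],
                "layer": layer,
            },
            index=cols,
        )
        return TimeCourseMatrix(counts, meta, pd.Series(1.0, index=cols))

    course = {
        "precursor": course_matrix(exp_p, "precursor"),
        "mature": course_matrix(exp_m, "mature"),
    }

    # pulse experiment at unstimulated steady state
    p_ss = np.array([k.alpha / k.gamma for k in kinetics])
    m_ss = np.array([k.alpha / k.beta0 for k in kinetics])
    fr = np.array([labeled_fractions(k, config.pulse_tau) for k in kinetics])
    fr = fr.reshape(-1, 2)
    f_p, f_m = fr[:, 0], fr[:, 1]

    # the labeled library is sequenced to its own depth: rescale so its
    # expected yield is pulse_labeled_depth x the total library's yield
    labeled_yield = (f_p * p_ss + f_m * m_ss).sum()
    total_yield = (p_ss + m_ss).sum()
    if labeled_yield > 0:
        labeled_depth = config.pulse_labeled_depth * total_yield / labeled_yield
    else:
        labeled_depth = config.pulse_labeled_depth
    pulse_spec = {
        "labeled_precursor": (f_p * p_ss, labeled_depth, "labeled"),
        "labeled_mature": (f_m * m_ss, labeled_depth, "labeled"),
        "total_precursor": (p_ss, 1.0, "total"),
        "total_mature": (m_ss, 1.0, "total"),
    }
    # the labeled and total libraries of one replicate are split from the
    # same RNA sample, so biological (overdispersion) noise is shared across
    # the four matrices within a replicate and only Poisson noise is
    # library-specific
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        bio = rng.gamma(shape=r, scale=1.0 / r, size=(len(ids), config.pulse_replicates))
    else:
        bio = np.ones((len(ids), config.pulse_replicates))
    pulse: dict[str, TimeCourseMatrix] = {}
    for name, (abund, depth_factor, layer) in pulse_spec.items():
        expected = abund[:, None] * bio
        counts = sample_counts(
            expected, config.depth * depth_factor, 0.0, rng
        )
        cols = [f"{name}_r{r + 1}" for r in range(config.pulse_replicates)]
        meta = pd.DataFrame(
            {
                "time": 0.0,
                "replicate": np.arange(1, config.pulse_replicates + 1),
                "condition": "unstimulated",
                "layer": layer,
            },
            index=cols,
        )
        pulse[name] = TimeCourseMatrix(
            pd.DataFrame(counts, index=ids, columns=cols), meta,
            pd.Series(1.0, index=cols),
        )

    truth = SimTruth(
        kinetics=pd.DataFrame(
            {
                "alpha": [k.alpha for k in kinetics],
                "gamma": [k.gamma for k in kinetics],
                "beta0": [k.beta0 for k in kinetics],
                "beta_stim_fold": [k.beta_stim_fold for k in kinetics],
                "beta_switch_time": [k.beta_switch_time for k in kinetics],
                "f_p": f_p,
                "f_m": f_m,
            },
            index=pd.Index(ids, name="gene_id"),
        ),
        archetypes=labels,
        reference_genes=[g for g in ids if g.startswith("REF")],
    )
    expected = {
        "precursor": pd.DataFrame(exp_p, index=ids, columns=grid),
        "mature": pd.DataFrame(exp_m, index=ids, columns=grid),
    }
    return SimulatedExperiment(course=course, pulse=pulse, expected=expected, truth=truth)


# ---------------------------------------------------------------------------
# 3'-UTR sequences
# ---------------------------------------------------------------------------

def simulate_utrs(
    gene_decay_ranks: pd.Series,
    motif: str,
    planted_fraction: float,
    length: int = 200,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Random 3'-UTRs with ``motif`` planted in top-decay-quartile genes.

    ``gene_decay_ranks`` maps gene id -> decay score (higher = less stable).
    The motif (RNA alphabet) replaces a random window in ``planted_fraction``
    of the top-quartile genes.  Returns ``(records, planted_gene_ids)`` where
    records are ``(gene_id, sequence)`` pairs in input order.
    """
    if not 0 <= planted_fraction <= 1:
        raise ConfigError("planted_fraction must be in [0, 1]")
    motif = motif.upper().replace("T", "U")
    if len(motif) > length:
        raise ConfigError("motif longer than sequence length")
    if set(motif) - set(RNA_ALPHABET):
        raise ConfigError(f"motif must be over {RNA_ALPHABET}")
    if gene_decay_ranks.index.has_duplicates:
        raise DataError("duplicate gene ids in decay ranking")

    rng = np.random.default_rng(seed)
    ids = list(gene_decay_ranks.index)
    n = len(ids)
    n_top = max(1, n // 4)
    top = set(gene_decay_ranks.sort_values(ascending=False).index[:n_top])
    n_plant = int(round(planted_fraction * len(top)))
    planted = set(rng.permutation(sorted(top))[:n_plant]) if n_plant else set()

    records = []
    for gid in ids:
        seq = "".join(rng.choice(list(RNA_ALPHABET), size=length))
        if gid in planted:
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        records.append((gid, seq))
    return records, sorted(planted)


# ---------------------------------------------------------------------------
# siRNA screen plates
# ---------------------------------------------------------------------------

def simulate_screen(
    effects: pd.Series,
    sirna_to_gene: pd.Series,
    n_plates: int = 4,
    replicates_per_sirna: int = 6,
    batch_sd: float = 0.3,
    noise_sd: float = 0.2,
    viability_sd: float = 0.1,
    viability_read_sd: float = 0.05,
    mocks_per_plate: int = 16,
    conditions: tuple[str, ...] = ("basal", "stimulated"),
    basal_level: float = 100.0,
    stim_fold: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate plate-based aldosterone/viability screen readings.

    Each well's aldosterone reading is
    ``plate_batch * viability * level(condition) * effect * lognormal(noise)``;
    the viability reading is the same per-well viability with small
    measurement noise.  Mock wells (effect 1) appear on every plate for every
    condition.  Replicates of each siRNA are spread across plates round-robin.
    """
    if mocks_per_plate < 1:
        raise ConfigError("every plate needs at least one mock well")
    if replicates_per_sirna < 1 or n_plates < 1:
        raise ConfigError("need at least one plate and one replicate")
    rng = np.random.default_rng(seed)
    batch = np.exp(rng.normal(0.0, batch_sd, size=n_plates))
    rows = []
    well_counter = dict.fromkeys(range(n_plates), 0)

    def add_well(plate: int, sirna: str, gene: str, cond: str, effect: float) -> None:
        level = basal_level * (stim_fold if cond == "stimulated" else 1.0)
        viability = float(np.exp(rng.normal(0.0, viability_sd)))
        aldo = (
            batch[plate] * viability * level * effect
            * float(np.exp(rng.normal(0.0, noise_sd)))
        )
        viab_reading = viability * float(np.exp(rng.normal(0.0, viability_read_sd)))
        well_counter[plate] += 1
        rows.append(
            {
                "plate": f"P{plate + 1}",
                "well": f"W{well_counter[plate]:03d}",
                "sirna": sirna,
                "target_gene": gene,
                "condition": cond,
                "aldosterone": aldo,
                "viability": viab_reading,
            }
        )

    for plate in range(n_plates):
        for cond in conditions:
            for _ in range(mocks_per_plate):
                add_well(plate, "mock", "mock", cond, 1.0)
    for i, (sirna, effect) in enumerate(effects.items()):
        gene = str(sirna_to_gene[sirna])
        for cond in conditions:
            for r in range(replicates_per_sirna):
                plate = (i + r) % n_plates
                add_well(plate, str(sirna), gene, cond, float(effect))
    return pd.DataFrame(rows)
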