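"""Monte-Carlo simulation of single trials and psychometric functions.

A simulated trial follows the observer model's two-step protocol:

1. *Early commitment.*  A reduced set of measurement samples (20% of the
   full count) is binned on the 0.5° direction grid; the peak bin center
   theta_MAX yields the binary commitment chi (integrate vs. segregate).
2. *Conditional estimation.*  A fresh full set of samples (5000 by
   default) is binned, the histogram is multiplied by the prior weight
   function selected by (model variant, chi), and the maximum-a-posteriori
   direction theta_i is read out as the peak bin center.  The trial's
   categorical report is coherent when |theta_i| < theta_S/2 and
   transparent otherwise (boundary -> transparent).

Histogram counts of n i.i.d. measurement samples are multinomial over the
grid's bin masses, so whole batches of trials are drawn directly as
multinomial histograms (exact CDF-based bin masses).  This is
distributionally identical to binning individual draws and orders of
magnitude faster.

Histogram-argmax ties are broken deterministically: the bin with the
smallest |center| wins, and of the two mirrored candidates the positive
one.  RNG substreams are derived per (seed, condition, level), so results
are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .direction_model import (
    DirectionGrid,
    ModelVariant,
    ParameterError,
    PriorParams,
    SensoryParams,
    StimulusConfig,
    likelihood_bin_masses,
    prior_weights_for,
    wrap_degrees,
)

__all__ = [
    "MeasurementSamples",
    "SimulationSettings",
    "TrialOutcome",
    "TrialBatch",
    "SimPsychometric",
    "sample_measurements",
    "simulate_trial",
    "simulate_trial_batch",
    "simulate_psychometric",
    "default_levels",
]

COHERENT = "coherent"
TRANSPARENT = "transparent"


@dataclass(frozen=True)
class MeasurementSamples:
    """Sampled sensory measurements theta_m (degrees, wrapped)."""

    angles: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.size == 0:
            raise ParameterError("at least one measurement sample is required")
        if np.any(a < -180.0) or np.any(a >= 180.0):
            raise ParameterError("angles must be wrapped to [-180, 180)")
        object.__setattr__(self, "angles", a)

    @property
    def n(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class SimulationSettings:
    """Monte-Carlo settings: full-stage sample count, fraction used by the
    early chi stage, and the RNG seed."""

    n_full: int = 5000
    early_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_full < 100:
            raise ParameterError(f"n_full must be >= 100, got {self.n_full}")
        if not (0.0 < self.early_fraction <= 1.0):
            raise ParameterError(
                f"early_fraction must lie in (0, 1], got {self.early_fraction}"
            )

    @property
    def n_early(self) -> int:
        return int(round(self.early_fraction * self.n_full))


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated trial: early commitment, early peak, MAP direction
    and the categorical percept."""

    chi: int
    theta_max: float
    theta_map: float
    percept: str


@dataclass(frozen=True)
class TrialBatch:
    """Vectorized outcomes of many trials under one condition."""

    chi: np.ndarray        # int, 1 or 2
    theta_max: np.ndarray  # degrees
    theta_map: np.ndarray  # degrees
    coherent: np.ndarray   # bool

    @property
    def n_trials(self) -> int:
        return self.chi.size

    @property
    def p_coherent(self) -> float:
        return float(self.coherent.mean())

    def outcome(self, i: int) -> TrialOutcome:
        return TrialOutcome(
            chi=int(self.chi[i]),
            theta_max=float(self.theta_max[i]),
            theta_map=float(self.theta_map[i]),
            percept=COHERENT if self.coherent[i] else TRANSPARENT,
        )


@dataclass(frozen=True)
class SimPsychometric:
    """Simulated psychometric function: coherent-report fraction per
    LI-proportion level (levels as fractions in [0, 1])."""

    levels: np.ndarray
    n_per_level: int
    p_coherent: np.ndarray
    seed: int

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        pc = np.asarray(self.p_coherent, dtype=float)
        if lv.shape != pc.shape:
            raise ValueError("levels and p_coherent must have equal length")
        if np.any((pc < 0) | (pc > 1)):
            raise ValueError("p_coherent entries must lie in [0, 1]")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "p_coherent", pc)


def default_levels(n_levels: int = 11) -> np.ndarray:
    """Equally spaced LI proportions spanning 0 to 1 inclusive."""
    return np.linspace(0.0, 1.0, n_levels)


# ---------------------------------------------------------------------------
# sampling


def sample_measurements(
    stim: StimulusConfig,
    sens: SensoryParams,
    n: int,
    rng: np.random.Generator,
) -> MeasurementSamples:
    """Draw n i.i.d. sensory measurements from the mixture likelihood.

    Each draw picks a mixture term (probabilities A_S/2, A_S/2, A_L for
    the -theta_S, +theta_S and pattern terms), adds Gaussian noise of the
    term's width and wraps to [-180, 180).
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    centers = np.array(
        [-stim.theta_S + stim.theta_L, stim.theta_S + stim.theta_L, stim.theta_L]
    )
    sigmas = np.array([sens.sigma_S, sens.sigma_S, sens.sigma_L])
    probs = np.array([stim.A_S / 2.0, stim.A_S / 2.0, stim.A_L])
    which = rng.choice(3, size=n, p=probs)
    angles = centers[which] + sigmas[which] * rng.standard_normal(n)
    return MeasurementSamples(wrap_degrees(angles))


# ---------------------------------------------------------------------------
# argmax with the documented tie rule


def _tie_break_order(grid: DirectionGrid) -> np.ndarray:
    """Bin indices sorted by argmax priority: smallest |center| first,
    positive member of a mirrored pair before the negative one."""
    c = grid.centers
    return np.lexsort((c < 0, np.abs(c)))


def _argmax_bins(values: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Row-wise argmax over bins with the deterministic tie rule.

    ``values`` has shape (n_trials, n_bins); returns original bin indices.
    """
    permuted = values[:, order]
    return order[np.argmax(permuted, axis=1)]


# ---------------------------------------------------------------------------
# batched trial simulation


def simulate_trial_batch(
    stim: StimulusConfig,
    sens: SensoryParams,
    priors: PriorParams | None,
    variant: ModelVariant,
    settings: SimulationSettings,
    n_trials: int,
    rng: np.random.Generator,
    grid: DirectionGrid | None = None,
) -> TrialBatch:
    """Simulate ``n_trials`` independent trials of one stimulus condition.

    Stage-1 and stage-2 histograms are drawn as independent multinomial
    counts over the grid's exact bin masses (fresh samples per stage).
    """
    if n_trials < 1:
        raise ParameterError(f"n_trials must be >= 1, got {n_trials}")
    priors = variant.validate_priors(priors)
    grid = grid or DirectionGrid()
    masses = likelihood_bin_masses(grid, stim, sens)
    order = _tie_break_order(grid)
    centers = grid.centers
    half = stim.theta_S / 2.0

    counts_early = rng.multinomial(settings.n_early, masses, size=n_trials)
    theta_max = centers[_argmax_bins(counts_early, order)]
    chi = np.where(np.abs(theta_max) < half, 1, 2)

    counts_full = rng.multinomial(settings.n_full, masses, size=n_trials)
    theta_map = centers[_argmax_bins(counts_full, order)].copy()
    for chi_value in (1, 2):
        weights = prior_weights_for(grid, variant, chi_value, priors)
        if weights is None:
            continue
        sel = chi == chi_value
        if not np.any(sel):
            continue
        weighted = counts_full[sel] * weights
        theta_map[sel] = centers[_argmax_bins(weighted, order)]

    coherent = np.abs(theta_map) < half
    return TrialBatch(chi=chi, theta_max=theta_max, theta_map=theta_map, coherent=coherent)


def simulate_trial(
    stim: StimulusConfig,
    sens: SensoryParams,
    priors: PriorParams | None,
    variant: ModelVariant,
    settings: SimulationSettings,
    rng: np.random.Generator,
    grid: DirectionGrid | None = None,
) -> TrialOutcome:
    """Simulate a single trial (see :func:`simulate_trial_batch`)."""
    batch = simulate_trial_batch(stim, sens, priors, variant, settings, 1, rng, grid)
    return batch.outcome(0)


def _level_rng(seed: int, level_index: int) -> np.random.Generator:
    """Per-level substream; independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(level_index)]))


def simulate_psychometric(
    levels,
    n_per_level: int,
    sens: SensoryParams,
    priors: PriorParams | None,
    variant: ModelVariant,
    settings: SimulationSettings,
    theta_S: float = 60.0,
    grid: DirectionGrid | None = None,
) -> SimPsychometric:
    """Simulate a full psychometric function.

    For each LI-proportion level in ``levels`` (fractions in [0, 1]) runs
    ``n_per_level`` independent trials with A_L set to the level and
    returns the coherent-report fraction per level.  Deterministic for a
    fixed ``settings.seed``.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ParameterError("levels must be non-empty")
    if np.any((levels < 0) | (levels > 1)):
        raise ParameterError("levels must lie in [0, 1]")
    grid = grid or DirectionGrid()
    p_coherent = np.empty(levels.size)
    for k, level in enumerate(levels):
        stim = StimulusConfig(theta_S=theta_S, A_L=float(level))
        batch = simulate_trial_batch(
            stim, sens, priors, variant, settings, n_per_level,
            _level_rng(settings.seed, k), grid,
        )
        p_coherent[k] = batch.p_coherent
    return SimPsychometric(
        levels=levels, n_per_level=n_per_level, p_coherent=p_coherent, seed=settings.seed
    )
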