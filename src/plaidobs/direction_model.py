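"""Probabilistic core of the causal-inference observer model.

Direction space is circular, measured in degrees, with the pattern
(vector-average) direction at 0° and the two component directions at
±theta_S (±60° in the default design).  All densities live on a discrete
grid of 0.5°-wide bins covering [-180, 180).

The observer's likelihood over perceived direction is a three-component
wrapped-Gaussian mixture: two component terms at ±theta_S with width
sigma_S and weight A_S/2 each, and one pattern term at 0° with width
sigma_L and weight A_L, where A_S = 1 - A_L and A_L is the proportion of
line-intersection (LI) apertures in the stimulus.

Two conditional priors, both centered on the pattern direction, act as
multiplicative weight functions on the binned measurement histogram:

* the *integrating* prior, a wrapped Gaussian of width sigma_P peaking at
  0°, which enhances the pattern direction, and
* the *segregating* prior, 1 minus a peak-normalized wrapped Gaussian of
  width sigma_C, which inhibits the pattern direction (its maximum sits
  diametrically opposite, near ±180°).

Which prior applies on a trial is selected by an early binary commitment
chi (1 = integrate, 2 = segregate) combined with the model variant:
M1 never applies a prior, M2 applies the integrating prior on chi = 1
trials, M3 applies the segregating prior on chi = 2 trials, and M4 (a
control) applies whichever prior chi selects.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import norm

__all__ = [
    "DirectionGrid",
    "StimulusConfig",
    "SensoryParams",
    "PriorParams",
    "ModelVariant",
    "DensityOnGrid",
    "ParameterError",
    "ConfigurationError",
    "likelihood_pdf",
    "likelihood_bin_masses",
    "integrate_prior",
    "segregate_prior",
    "prior_weights_for",
    "conditional_posterior",
    "chi_decision",
    "wrap_degrees",
]

#: wraps summed when evaluating wrapped Gaussians; +-2 full turns is ample
#: for widths up to a few hundred degrees.
N_WRAPS = 2

NORMALIZATION_TOL = 1e-9


class ParameterError(ValueError):
    """A numeric model parameter is out of its valid domain."""


class ConfigurationError(ValueError):
    """Model variant and supplied prior parameters are inconsistent."""


def wrap_degrees(angle):
    """Wrap angles (degrees) onto the half-open interval [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class DirectionGrid:
    """Uniform discretization of circular direction space.

    Bins are half-open intervals [c - w/2, c + w/2) around each center c;
    centers run from -180 to 180 - bin_width.  ``bin_width`` must divide
    360 exactly.
    """

    bin_width: float = 0.5

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ParameterError(f"bin_width must be positive, got {self.bin_width}")
        n = 360.0 / self.bin_width
        if abs(n - round(n)) > 1e-12:
            raise ParameterError(
                f"bin_width must divide 360 exactly, got {self.bin_width}"
            )

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.bin_width))

    @property
    def centers(self) -> np.ndarray:
        return -180.0 + self.bin_width * np.arange(self.n_bins)

    @property
    def edges(self) -> np.ndarray:
        """n_bins + 1 bin edges, starting at -180 - bin_width/2 so that
        each center sits mid-bin."""
        return -180.0 - self.bin_width / 2.0 + self.bin_width * np.arange(self.n_bins + 1)

    def bin_index(self, angle) -> np.ndarray:
        """Index of the bin containing each (wrapped) angle."""
        a = wrap_degrees(angle)
        idx = np.floor((a + 180.0 + self.bin_width / 2.0) / self.bin_width).astype(int)
        return idx % self.n_bins


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus geometry: component direction magnitude theta_S, pattern
    direction theta_L (0 in the default design) and LI-aperture proportion
    A_L.  The component weight A_S = 1 - A_L is derived."""

    theta_S: float = 60.0
    theta_L: float = 0.0
    A_L: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.A_L <= 1.0):
            raise ParameterError(f"A_L must lie in [0, 1], got {self.A_L}")
        if self.theta_S <= 0:
            raise ParameterError(f"theta_S must be positive, got {self.theta_S}")

    @property
    def A_S(self) -> float:
        return 1.0 - self.A_L

    @property
    def source_directions(self) -> tuple[float, float, float]:
        """True direction set: (-theta_S, +theta_S, pattern)."""
        return (-self.theta_S, self.theta_S, self.theta_L)


@dataclass(frozen=True)
class SensoryParams:
    """Sensory likelihood widths (degrees): sigma_S for each component
    term, sigma_L for the pattern term."""

    sigma_S: float
    sigma_L: float

    def __post_init__(self):
        for name in ("sigma_S", "sigma_L"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class PriorParams:
    """Conditional prior widths (degrees); either may be absent."""

    sigma_P: float | None = None
    sigma_C: float | None = None

    def __post_init__(self):
        for name in ("sigma_P", "sigma_C"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be positive and finite, got {v}")


class ModelVariant(str, Enum):
    """Observer-model variants differing only in conditional-prior use."""

    M1 = "M1"  # no prior
    M2 = "M2"  # integrating prior on chi = 1 trials
    M3 = "M3"  # segregating prior on chi = 2 trials
    M4 = "M4"  # both priors, selected by chi (control)

    @property
    def n_parameters(self) -> int:
        """Free parameters fitted for this variant (sensory + prior widths)."""
        return {"M1": 2, "M2": 3, "M3": 3, "M4": 4}[self.value]

    @property
    def needs_sigma_P(self) -> bool:
        return self in (ModelVariant.M2, ModelVariant.M4)

    @property
    def needs_sigma_C(self) -> bool:
        return self in (ModelVariant.M3, ModelVariant.M4)

    def validate_priors(self, priors: PriorParams | None) -> PriorParams:
        priors = priors or PriorParams()
        if self.needs_sigma_P and priors.sigma_P is None:
            raise ConfigurationError(f"{self.value} requires sigma_P")
        if self.needs_sigma_C and priors.sigma_C is None:
            raise ConfigurationError(f"{self.value} requires sigma_C")
        return priors


@dataclass
class DensityOnGrid:
    """Discrete carrier for densities/weight functions on a DirectionGrid.

    ``values`` are per-degree densities when ``normalized`` is True
    (sum * bin_width == 1); otherwise they are arbitrary nonnegative
    weights (priors use the convention max == 1).
    """

    grid: DirectionGrid
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("values must have one entry per grid bin")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")
        if self.normalized:
            total = self.values.sum() * self.grid.bin_width
            if abs(total - 1.0) > NORMALIZATION_TOL:
                raise ValueError(f"normalized density sums to {total}, not 1")

    @property
    def total_mass(self) -> float:
        return float(self.values.sum() * self.grid.bin_width)

    def bin_masses(self) -> np.ndarray:
        return self.values * self.grid.bin_width

    def normalize(self) -> "DensityOnGrid":
        total = self.values.sum() * self.grid.bin_width
        if total <= 0:
            raise ValueError("cannot normalize a zero density")
        return DensityOnGrid(self.grid, self.values / total, normalized=True)


# ---------------------------------------------------------------------------
# wrapped-Gaussian building blocks


def _wrapped_gaussian_pdf(theta: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Wrapped normal density on the circle (degrees), summed over
    +-N_WRAPS full turns."""
    theta = np.asarray(theta, dtype=float)
    out = np.zeros_like(theta)
    for k in range(-N_WRAPS, N_WRAPS + 1):
        out += norm.pdf(theta + 360.0 * k, loc=mu, scale=sigma)
    return out


def _wrapped_gaussian_bin_masses(grid: DirectionGrid, mu: float, sigma: float) -> np.ndarray:
    """Exact bin masses of the wrapped normal via CDF differences."""
    edges = grid.edges
    masses = np.zeros(grid.n_bins)
    for k in range(-N_WRAPS, N_WRAPS + 1):
        cdf = norm.cdf(edges + 360.0 * k, loc=mu, scale=sigma)
        masses += np.diff(cdf)
    return masses


#: memo for prior weight vectors — the same few widths are evaluated
#: thousands of times during a fit; entries are treated as read-only
_UNIT_PEAK_CACHE: dict = {}
_UNIT_PEAK_CACHE_MAX = 512


def _unit_peak_wrapped_gaussian(grid: DirectionGrid, sigma: float) -> np.ndarray:
    """Wrapped Gaussian centered at 0 scaled so its peak value is 1."""
    key = (grid.bin_width, round(float(sigma), 12))
    cached = _UNIT_PEAK_CACHE.get(key)
    if cached is None:
        raw = _wrapped_gaussian_pdf(grid.centers, 0.0, sigma)
        peak = _wrapped_gaussian_pdf(np.array([0.0]), 0.0, sigma)[0]
        cached = raw / peak
        cached.setflags(write=False)
        if len(_UNIT_PEAK_CACHE) >= _UNIT_PEAK_CACHE_MAX:
            _UNIT_PEAK_CACHE.pop(next(iter(_UNIT_PEAK_CACHE)))
        _UNIT_PEAK_CACHE[key] = cached
    return cached


# ---------------------------------------------------------------------------
# likelihood


def _mixture_components(stim: StimulusConfig, sens: SensoryParams):
    """(weight, center, sigma) triples of the measurement mixture."""
    return (
        (stim.A_S / 2.0, -stim.theta_S + stim.theta_L, sens.sigma_S),
        (stim.A_S / 2.0, stim.theta_S + stim.theta_L, sens.sigma_S),
        (stim.A_L, stim.theta_L, sens.sigma_L),
    )


def likelihood_pdf(
    grid: DirectionGrid, stim: StimulusConfig, sens: SensoryParams
) -> DensityOnGrid:
    """Measurement distribution P(theta_m | theta): the normalized
    three-term wrapped-Gaussian mixture evaluated at bin centers."""
    values = np.zeros(grid.n_bins)
    for w, mu, sigma in _mixture_components(stim, sens):
        if w > 0:
            values += w * _wrapped_gaussian_pdf(grid.centers, mu, sigma)
    return DensityOnGrid(grid, values).normalize()


def likelihood_bin_masses(
    grid: DirectionGrid, stim: StimulusConfig, sens: SensoryParams
) -> np.ndarray:
    """Exact per-bin probability masses of the measurement mixture.

    These are the multinomial cell probabilities of a histogram of i.i.d.
    measurement samples; used by the trial simulator.
    """
    masses = np.zeros(grid.n_bins)
    for w, mu, sigma in _mixture_components(stim, sens):
        if w > 0:
            masses += w * _wrapped_gaussian_bin_masses(grid, mu, sigma)
    total = masses.sum()
    # CDF differences over +-N_WRAPS turns already capture all but ~1e-16
    # of the mass; renormalize so the multinomial draw is exact.
    return masses / total


# ---------------------------------------------------------------------------
# conditional priors


def integrate_prior(grid: DirectionGrid, sigma_P: float) -> DensityOnGrid:
    """Integrating (pattern-enhancing) prior weight function.

    A wrapped Gaussian centered on the pattern direction (0°), returned
    unnormalized with peak value 1.
    """
    if not (np.isfinite(sigma_P) and sigma_P > 0):
        raise ParameterError(f"sigma_P must be positive and finite, got {sigma_P}")
    return DensityOnGrid(grid, _unit_peak_wrapped_gaussian(grid, sigma_P))


def segregate_prior(grid: DirectionGrid, sigma_C: float) -> DensityOnGrid:
    """Segregating (pattern-inhibiting) prior weight function.

    1 minus the peak-normalized wrapped Gaussian of width sigma_C:
    zero at the pattern direction, approaching 1 diametrically opposite.
    """
    if not (np.isfinite(sigma_C) and sigma_C > 0):
        raise ParameterError(f"sigma_C must be positive and finite, got {sigma_C}")
    values = 1.0 - _unit_peak_wrapped_gaussian(grid, sigma_C)
    # guard tiny negative round-off at the center bin
    return DensityOnGrid(grid, np.clip(values, 0.0, 1.0))


def prior_weights_for(
    grid: DirectionGrid,
    variant: ModelVariant,
    chi: int,
    priors: PriorParams | None,
) -> np.ndarray | None:
    """Multiplicative prior weights selected by (variant, chi).

    Returns ``None`` when the selected prior is flat (no reweighting).
    """
    if chi not in (1, 2):
        raise ParameterError(f"chi must be 1 or 2, got {chi}")
    priors = variant.validate_priors(priors)
    if variant in (ModelVariant.M2, ModelVariant.M4) and chi == 1:
        return integrate_prior(grid, priors.sigma_P).values
    if variant in (ModelVariant.M3, ModelVariant.M4) and chi == 2:
        return segregate_prior(grid, priors.sigma_C).values
    return None


def conditional_posterior(
    hist: DensityOnGrid,
    variant: ModelVariant,
    chi: int,
    priors: PriorParams | None = None,
) -> DensityOnGrid:
    """Conditional posterior over direction given the early commitment chi.

    Multiplies the (normalized) measurement histogram bin-wise by the
    prior weight selected by (variant, chi) and renormalizes to unit mass.
    M1 trials and unselected-prior trials pass through unchanged.
    """
    if not hist.normalized:
        raise ValueError("conditional_posterior expects a normalized histogram")
    weights = prior_weights_for(hist.grid, variant, chi, priors)
    if weights is None:
        return hist
    return DensityOnGrid(hist.grid, hist.values * weights).normalize()


# ---------------------------------------------------------------------------
# early categorical decision


def chi_decision(theta_max: float, theta_S: float) -> int:
    """Early binary commitment from the reduced-sample direction peak.

    chi = 1 (integrate) when the peak lies closer to the pattern direction
    than to either component direction, i.e. |theta_max| < theta_S / 2;
    otherwise chi = 2 (segregate).  The boundary |theta_max| = theta_S / 2
    maps to 2 (fixed tie rule).
    """
    return 1 if abs(wrap_degrees(theta_max)) < theta_S / 2.0 else 2
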