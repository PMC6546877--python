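"""Psychometric-function fitting, bias and perceptual-stability statistics.

The response curve P(coherent | LI level) is modelled as a two-parameter
cumulative Gaussian Phi((level - pse) / spread), fitted to per-level
binomial counts by maximum likelihood.  ``pse`` is the point of
subjective equality (the LI percentage at which the predicted coherent
probability is exactly 0.5) and ``spread`` the transition width in % LI.
No lapse or guess rates are fitted: with 30 trials per level they are not
identifiable and the two-parameter family matches the PSE/slope summary
statistics used downstream.

Derived statistics:

* **bias** — a subject's PSE minus a reference PSE (the pooled
  low-density population fit), in % LI; positive values mean more LI
  apertures are needed for coherence, i.e. a transparent-direction bias.
* **PSI** (perceptual stability index) — the fraction of stimulus levels
  at which the fitted curve is confidently (probability beyond 0.75 /
  below 0.25) on the side of the dominant percept.
* bootstrap uncertainty — per-level binomial resampling (400 resamples by
  default) with refitting; degenerate resamples are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychometricData",
    "PsychometricFit",
    "BiasEstimate",
    "PSIResult",
    "BootstrapResult",
    "DegenerateFitError",
    "fit_psychometric",
    "bootstrap_fit",
    "estimate_bias",
    "compute_psi",
]

#: lower bound on the fitted transition width (% LI); keeps the likelihood
#: bounded on perfectly separable (step) data.
MIN_SPREAD = 1e-2
MAX_SPREAD = 1e4
_P_CLIP = 1e-12


class DegenerateFitError(ValueError):
    """Raised when all responses fall in one category.

    ``sign`` is +1 when every response was coherent (curve pinned at 1)
    and -1 when every response was transparent.
    """

    def __init__(self, sign: int):
        self.sign = sign
        side = "coherent" if sign > 0 else "transparent"
        super().__init__(f"all responses are {side}; psychometric fit is degenerate")


@dataclass(frozen=True)
class PsychometricData:
    """Per-level binomial response counts.

    ``levels`` are LI percentages (0-100, strictly increasing);
    ``n_trials`` and ``n_coherent`` give the per-level counts.
    """

    levels: np.ndarray
    n_trials: np.ndarray
    n_coherent: np.ndarray

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        nt = np.asarray(self.n_trials, dtype=int)
        nc = np.asarray(self.n_coherent, dtype=int)
        if not (lv.shape == nt.shape == nc.shape) or lv.ndim != 1:
            raise ValueError("levels, n_trials, n_coherent must be equal-length 1-d")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(nt < 0) or np.any(nc < 0) or np.any(nc > nt):
            raise ValueError("need 0 <= n_coherent <= n_trials at every level")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "n_trials", nt)
        object.__setattr__(self, "n_coherent", nc)

    @property
    def p_coherent(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_trials > 0, self.n_coherent / self.n_trials, np.nan)

    @classmethod
    def from_sim(cls, sim) -> "PsychometricData":
        """Build from a simulated psychometric (levels as fractions)."""
        n = np.full(sim.levels.size, sim.n_per_level, dtype=int)
        k = np.rint(sim.p_coherent * sim.n_per_level).astype(int)
        return cls(levels=100.0 * sim.levels, n_trials=n, n_coherent=k)


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted cumulative-Gaussian curve.

    ``slope`` is the curve's steepness at the PSE, d P / d level
    = phi(0) / spread per % LI.
    """

    pse: float
    spread: float
    loglik: float
    family: str = "cumulative_gaussian"

    def predict(self, levels) -> np.ndarray:
        return norm.cdf((np.asarray(levels, dtype=float) - self.pse) / self.spread)

    @property
    def slope(self) -> float:
        return float(norm.pdf(0.0) / self.spread)


@dataclass(frozen=True)
class BiasEstimate:
    """Signed PSE difference (subject minus reference) in % LI.

    Positive: the subject needs more LI for coherence than the reference
    (transparent-direction bias); negative: coherent-direction bias.
    """

    value: float


@dataclass(frozen=True)
class PSIResult:
    """Perceptual stability index in [0, 1] with its dominant percept."""

    psi: float
    dominant: str
    threshold: float = 0.75


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap replicates of the psychometric fit."""

    pse: np.ndarray
    spread: np.ndarray
    n_failed: int
    seed: int

    @property
    def n_resamples(self) -> int:
        return self.pse.size + self.n_failed

    def pse_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = 100.0 * (1.0 - level) / 2.0
        return tuple(np.percentile(self.pse, [lo, 100.0 - lo]))


# ---------------------------------------------------------------------------
# fitting


def _nll(params: np.ndarray, levels, n, k) -> float:
    pse, log_spread = params
    p = norm.cdf((levels - pse) / np.exp(log_spread))
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_psychometric(data: PsychometricData) -> PsychometricFit:
    """Binomial maximum-likelihood fit of the cumulative-Gaussian curve.

    Raises :class:`DegenerateFitError` when every response falls in one
    category (the MLE then runs away to an unbounded PSE).
    """
    used = data.n_trials > 0
    if used.sum() < 3:
        raise ValueError("need at least 3 levels with trials to fit")
    levels = data.levels[used]
    n = data.n_trials[used]
    k = data.n_coherent[used]
    if k.sum() == 0:
        raise DegenerateFitError(-1)
    if k.sum() == n.sum():
        raise DegenerateFitError(+1)

    # moment-style start: interpolate the 0.5 crossing, spread from the
    # 0.25-0.75 transition extent
    p_hat = k / n
    pse0 = float(np.interp(0.5, np.clip(np.sort(p_hat), 0, 1), levels[np.argsort(p_hat)]))
    span = levels[-1] - levels[0]
    starts = [(pse0, s) for s in (span / 20.0, span / 5.0, span)]

    best = None
    log_bounds = (np.log(MIN_SPREAD), np.log(MAX_SPREAD))
    for pse_start, spread_start in starts:
        res = minimize(
            _nll,
            x0=np.array([pse_start, np.log(spread_start)]),
            args=(levels, n, k),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        x = res.x.copy()
        x[1] = np.clip(x[1], *log_bounds)
        value = _nll(x, levels, n, k)
        if best is None or value < best[0]:
            best = (value, x)
    value, (pse, log_spread) = best
    return PsychometricFit(pse=float(pse), spread=float(np.exp(log_spread)), loglik=-value)


def bootstrap_fit(
    data: PsychometricData, n_resamples: int = 400, seed: int = 0
) -> BootstrapResult:
    """Nonparametric per-level binomial bootstrap of the fit.

    Each resample redraws n_coherent ~ Binomial(n_trials, p_hat) at every
    level and refits; degenerate resamples are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    p_hat = np.where(data.n_trials > 0, data.n_coherent / np.maximum(data.n_trials, 1), 0.0)
    pses, spreads, failed = [], [], 0
    for _ in range(n_resamples):
        k = rng.binomial(data.n_trials, p_hat)
        try:
            fit = fit_psychometric(
                PsychometricData(data.levels, data.n_trials, k)
            )
        except DegenerateFitError:
            failed += 1
            continue
        pses.append(fit.pse)
        spreads.append(fit.spread)
    return BootstrapResult(
        pse=np.asarray(pses), spread=np.asarray(spreads), n_failed=failed, seed=seed
    )


def estimate_bias(fit: PsychometricFit, reference: PsychometricFit) -> BiasEstimate:
    """Bias = subject PSE minus reference PSE (% LI, positive =
    transparent-direction)."""
    return BiasEstimate(value=float(fit.pse - reference.pse))


def compute_psi(
    fit: PsychometricFit,
    levels,
    threshold: float = 0.75,
    bias: BiasEstimate | None = None,
) -> PSIResult:
    """Perceptual stability index of a fitted curve over stimulus levels.

    A level is confidently coherent when the fitted probability exceeds
    ``threshold`` and confidently transparent when it is below
    ``1 - threshold``.  The dominant percept is the side with more
    confident levels (ties resolved by the bias sign when given, else
    coherent); PSI is the dominant side's confident count over the total
    number of levels.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be non-empty")
    p = fit.predict(levels)
    n_coh = int(np.sum(p > threshold))
    n_tra = int(np.sum(p < 1.0 - threshold))
    if n_coh > n_tra:
        dominant = "coherent"
    elif n_tra > n_coh:
        dominant = "transparent"
    elif bias is not None and bias.value > 0:
        dominant = "transparent"
    else:
        dominant = "coherent"
    count = n_coh if dominant == "coherent" else n_tra
    return PSIResult(psi=count / levels.size, dominant=dominant, threshold=threshold)
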