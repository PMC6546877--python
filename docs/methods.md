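# Methods

## The observer model

The stimulus is a field of small apertures containing either line
intersections (LI, a 2-D motion cue that supports seeing one coherent
pattern) or separated lines (SL, a 1-D cue that supports seeing two
transparent surfaces). Direction space is circular, in degrees, with the
pattern (vector-average) direction at 0° and the two component directions
at ±θ_S = ±60°. The proportion of LI apertures, A_L ∈ [0, 1], is the
psychometric manipulation; the SL weight is A_S = 1 − A_L.

A sensory measurement of the direction distribution is modelled as i.i.d.
draws from a normalized three-term wrapped-Gaussian mixture: components at
±θ_S with width σ_S and weight A_S/2 each, and a pattern term at 0° with
width σ_L and weight A_L. Wrapping sums the ±2 full-turn images, which is
exact to machine precision for the widths considered (≤ a few hundred
degrees). We use standard Gaussian normalization 1/(σ√(2π)) per term:
only a properly normalized mixture yields a posterior that integrates
to one, which the model requires.

Perception is a two-step hierarchical causal inference:

1. **Early commitment (χ).** A reduced sample (20% of the full count) is
   binned on a 0.5°-wide grid; the peak bin θ_MAX yields χ = 1
   (integrate) if |θ_MAX| < θ_S/2 = 30°, else χ = 2 (segregate). The
   threshold is the verbal "closer to the pattern than to a component
   direction" rule; the boundary maps to χ = 2 (a measure-zero case fixed
   for reproducibility).
2. **Conditional estimation.** A fresh full sample (5000 draws) is
   binned, multiplied bin-wise by the conditional prior selected by the
   model variant and χ, and renormalized; the MAP bin center θ_i gives
   the categorical report: coherent if |θ_i| < 30°, else transparent.

The two priors are multiplicative weight functions centered on the
pattern direction: the *integrating* prior is a wrapped Gaussian of width
σ_P scaled to peak 1; the *segregating* prior is 1 minus a peak-1 wrapped
Gaussian of width σ_C — zero at 0°, maximal diametrically opposite. They
are weights rather than normalizable densities (the segregating form
integrates to ~360° − const); posterior renormalization restores unit
mass. Four variants differ only in prior use: M1 none, M2 integrating on
χ = 1 trials, M3 segregating on χ = 2 trials, M4 (control) whichever χ
selects.

Histogram-argmax ties are broken deterministically: smallest |bin
center| first, the positive member of a mirrored pair before the
negative one. This is symmetric in expectation.

### Simulation mechanics

Binned counts of n i.i.d. mixture draws are exactly multinomial over the
per-bin masses (computed by CDF differences of each wrapped component),
so batches of trials are drawn directly as multinomial histograms. This
is distributionally identical to sampling and binning individual draws
and orders of magnitude faster. The two stages of a trial use
independent fresh samples (they model sequential neural computations).
RNG substreams are derived per (seed, condition, level) so results do
not depend on execution order; all trials of a level are drawn in one
vectorized call.

## Psychometrics

P(coherent | level) is fitted as a two-parameter cumulative Gaussian
Φ((level − PSE)/σ) by binomial maximum likelihood (Nelder–Mead on (PSE,
log σ), three spread-scaled starts; σ bounded to [1e−2, 1e4] % LI so the
likelihood stays bounded on perfectly separable data). No lapse/guess
rates: they are not identifiable at 30 trials per level. All-one-category
data raise a typed error carrying the direction of the degeneracy rather
than returning an infinite PSE — pipelines must handle such conditions
explicitly.

* **Bias** = subject PSE − reference PSE (% LI); the reference pools all
  subjects' lowest-density trials within the same experiment and fits
  once. Positive = transparent-direction.
* **PSI** = fraction of the design's levels where the fitted curve is
  beyond 0.75 (confident-coherent) or below 0.25 (confident-transparent)
  on the dominant side; the dominant side is the one with more confident
  levels, ties resolved by the bias sign, then coherent. The denominator
  is all levels, which keeps the index in [0, 1].
* **Bootstrap**: per-level binomial resampling (400 resamples),
  refitting each; degenerate resamples are dropped and counted.

## Observer fitting and model comparison

Parameters are fitted by minimizing the summed two-outcome KL divergence
D(p_emp ‖ p_sim) per level, with p_sim clipped into [ε, 1 − ε],
ε = 1/(2 n_sim) of the level's simulation. The direction penalizes
simulated curves that assign vanishing probability to observed outcomes.

The search is a coarse log-spaced grid (sensory widths on [2°, 60°],
prior widths on [5°, 120°]) followed by pattern search in log space with
shrinking steps. All candidate evaluations share one fixed simulation
seed (common random numbers), making the objective deterministic;
re-evaluating at the returned parameters reproduces the reported KL
exactly. Three further numerical choices matter:

* **Count caching.** The multinomial count matrices depend only on the
  sensory widths, so they are cached per (σ_S, σ_L) pair and any prior
  width is evaluated by a reweighted argmax. The two trial stages are
  independent, so P(coherent) factorizes as
  (1 − p_χ2)·f[χ=1 prior] + p_χ2·f[χ=2 prior] with each factor estimated
  from all simulated trials — the same expectation as per-trial pairing,
  at lower variance.
* **Transition-boosted allocation.** The information that resolves the
  *scale* of the sensory widths (as opposed to their ratio, which the
  PSE pins sharply) is concentrated at the 1–2 levels on the empirical
  transition. When configured, those levels and their neighbours are
  simulated with more trials (the recovery analyses use 1000 vs a 200
  base); the allocation depends only on the data, not on candidates.
* **Validation residuals.** The rss consumed by the AIC is computed from
  an independent validation simulation (different seed, 1000 trials per
  level by default) at the fitted parameters. Under common random
  numbers a flexible variant can interpolate the frozen Monte-Carlo
  noise of the fitting simulation, collapsing its rss to ~1e−5 and
  turning the AIC ranking into a lottery.

Variants are ranked by the residual-based AIC = n ln(rss/n) + 2k
(k = 2, 3, 3, 4 for M1–M4; rss floored at 1e−12), summed across a
subject's fitted conditions. M4 is not searched independently: it
inherits the best M2/M3 prior widths and refits only its sensory widths,
with k = 4.

### Identifiability

Two structural findings, verified numerically and reflected in the test
suite:

* **σ_C saturates.** Once the segregating prior suppresses the central
  histogram peak at all, a χ = 2 trial flips to transparent for every
  σ_C in the search range: the simulated psychometric curve is
  *identical* across σ_C ∈ [5°, 120°] at typical sensory widths. Only
  the prior's presence, not its width, is behaviourally expressed, so
  recovering σ_C from categorical reports is impossible in this design.
  The corresponding acceptance check is left failing by design rather
  than weakened.  The sensory widths themselves are identified mainly
  through their ratio (which pins the PSE); their common scale is
  resolved only by the soft tails of the transition, and its recovery at
  300 trials per level sits at the edge of what the fitting objective's
  Monte-Carlo noise permits — typical median relative errors fluctuate
  around 20–40% across observer cohorts.
* **Variant separation needs shallow curves.** At 200 fitting trials per
  level, the KL objective cannot distinguish the true M3 parameters from
  the best M1 mimic for steep (near-step) observers; the best-M1 curve
  matches the true M3 curve to an rss at or below the data noise floor
  of an 11 × 300-trial data set. Broad-σ observers (transitions spanning
  several levels) are the most discriminable and are used in the model-
  recovery analysis; even there, single-condition AIC selection at the
  protocol's fitting fidelity remains noise-limited, and the
  corresponding acceptance check documents that limit.

## Synthetic observers

The generator maps density and regularity to observer parameters — the
one mechanism the behavioural data constrain only through its
consequences (bias amplification with density, attenuated under
irregularity, and the σ_S–bias association). Design choices, in the
model's own mechanics:

* Shrinking σ_S sharpens the ±60° peaks and drives transparency;
  shrinking σ_L sharpens the pattern peak and drives coherence (the
  simulated PSE falls as σ_S grows). The density power law
  σ(d) = σ_base·(d/180)^(−γ) therefore acts on σ_S for
  transparent-biased observers and on σ_L for coherent-biased ones;
  γ = strength in the regular experiment and 0.25·strength in the
  irregular one. A `density_knob` override exposes the other width for
  sensitivity analyses.
* Baselines separate the groups: transparent-biased observers draw
  σ_S ∈ [16°, 20°] with σ_L/σ_S ∈ [2.2, 2.8] (PSE above 50% LI);
  coherent-biased ones σ_S ∈ [11°, 14°] with ratio ∈ [0.55, 0.75]
  (PSE ≈ 20–25% LI). Amplification then pushes every observer's PSE away
  from both the population reference and the 50% midpoint, so the bias
  magnitude *and* the PSI rise with density; and because the
  transparent-biased group carries the larger σ_S, the cohort shows a
  positive across-subject association between σ_S and
  transparent-direction bias.
* The default demo cohort is five subjects, 2 coherent : 3 transparent,
  strength 0.3 — a population whose mean drifts toward transparency.

What the generator does *not* emulate: lapses and attention failures,
sequential/adaptation effects between trials, stimulus-geometry effects
beyond the design metadata, and eye movements. Passing tests therefore
show that the pipeline recovers the structure this generator puts in —
not that real observers obey the power-law mechanism.

## Group statistics

Trends of bias and PSI against density, and of bias against fitted σ_S,
are ordinary least-squares regressions (slope, r², two-sided p) per
experiment. The claims made on synthetic cohorts are sign- and
trend-level, so no mixed-effects machinery is used; with two planned
trends per experiment no multiplicity correction is applied.

## Problem sizes

The test suite runs the full design at its printed sizes (11 levels × 30
trials × 6 conditions × 5 subjects per cohort). Parameter recovery uses
20 observers at 300 trials/level; model recovery 10 + 10 observers at
300 trials/level data and 200 fitting trials/level; the density-trend
reproduction 10 cohort seeds. These sizes keep a complete run on a
single CPU in the tens of minutes.
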