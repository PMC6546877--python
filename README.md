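# plaidobs

Bayesian causal-inference observer models and a psychophysics analysis
pipeline for bistable plaid motion.

A plaid — two superimposed drifting line gratings — can be perceived
either as one **coherent** pattern moving in the vector-average direction
or as two **transparent** surfaces sliding in the component directions
(±60° about vertical here). Decomposing the plaid into local apertures
containing line intersections (LI, a 2-D cue supporting coherence) or
separated lines (SL, a 1-D cue supporting transparency) makes the percept
parametrically controllable through the LI proportion, and lets one ask
how aperture density and spatial regularity stabilize one interpretation
over the other.

`plaidobs` is written for computational-neuroscience and visual-
psychophysics researchers who want to simulate, fit and compare the
hierarchical causal-inference observers for this task:

* **Observer core** — the measurement likelihood is a wrapped-Gaussian
  mixture over circular direction space,

  P(θ_m | θ) = (A_S/2)·N(θ; −θ_S, σ_S²) + (A_S/2)·N(θ; +θ_S, σ_S²)
  + A_L·N(θ; 0, σ_L²),  A_S = 1 − A_L,

  binned at 0.5°. An early commitment χ from a reduced sample (χ = 1 iff
  |θ_MAX| < θ_S/2) selects a conditional prior: none (M1), a pattern-
  enhancing Gaussian of width σ_P on integrate trials (M2), a pattern-
  inhibiting `1 − Gaussian(σ_C)` on segregate trials (M3), or both (M4).
  The MAP direction of the prior-weighted histogram of 5000 fresh draws
  gives the trial's categorical report.
* **Psychometrics** — binomial ML fits of cumulative-Gaussian curves
  (PSE, spread), bias relative to a pooled low-density reference, the
  75%-confidence perceptual stability index (PSI), and a 400-resample
  bootstrap.
* **Model fitting** — Kullback–Leibler minimization of simulated against
  empirical psychometric functions under common random numbers, and
  residual-based AIC comparison of M1–M4.
* **Synthetic cohorts** — ground-truth observers whose biases amplify
  with aperture density (attenuated under irregular placement), so every
  pipeline stage is testable without any human data.
* **Pipeline + CLI** — trial-table CSV in, JSON results out;
  `plaidobs synth | fit-psycho | fit-model | trends | run`.

## Worked example

Simulate a prior-free observer (σ_S = 15°, σ_L = 10°) over the standard
design — 11 LI proportions from 0 to 100%, 30 trials each — then fit and
summarize:

```python
import numpy as np
from plaidobs import (ModelVariant, SensoryParams, SimulationSettings,
                      PsychometricData, fit_psychometric, compute_psi,
                      simulate_psychometric, default_levels)

sim = simulate_psychometric(default_levels(), 30, SensoryParams(15.0, 10.0),
                            None, ModelVariant.M1, SimulationSettings(seed=1))
data = PsychometricData.from_sim(sim)
fit = fit_psychometric(data)
print("p_coherent:", np.round(sim.p_coherent, 3).tolist())
print(f"PSE = {fit.pse:.2f} % LI, spread = {fit.spread:.2f} % LI")
print("P(coherent) at PSE =", round(float(fit.predict(fit.pse)), 3))
psi = compute_psi(fit, data.levels)
print(f"PSI = {psi.psi:.3f} (dominant: {psi.dominant})")
```

prints

```
p_coherent: [0.0, 0.0, 0.0, 0.9, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
PSE = 28.46 % LI, spread = 1.20 % LI
P(coherent) at PSE = 0.5
PSI = 0.727 (dominant: coherent)
```

The observer needs ~28% LI apertures before coherence dominates (the
point of subjective equality), the transition is sharp (spread ≈ 1% LI,
a consequence of the near-deterministic 5000-sample MAP readout), and
8 of the 11 stimulus levels lie confidently (P > 0.75) on the dominant —
coherent — side, giving PSI = 8/11 ≈ 0.727.

A full synthetic-cohort analysis (5 subjects × 2 experiments × 3
densities, biases, PSI, density trends) runs end to end with:

```bash
plaidobs run --seed 5 --out-dir results_demo
```

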