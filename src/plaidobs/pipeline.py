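"""End-to-end orchestration: trial-table I/O, per-condition analysis,
group-level trend statistics and result serialization.

The pipeline mirrors the study's analysis chain on a trial table
(subject, experiment, density, level %, trial, response):

1. per (subject, experiment, density): binomial counts per level,
   psychometric fit, optional bootstrap;
2. bias per condition relative to the pooled low-density reference of the
   same experiment (all subjects' lowest-density trials fitted once);
3. perceptual stability index (PSI) per condition;
4. optional observer-model fits (M1-M4) with AIC comparison per subject;
5. group trends: OLS regression of bias and PSI on density per
   experiment, and the correlation between fitted sigma_S and bias.

Group statistics are ordinary least-squares trends (slope, r-squared,
two-sided p); the claims made on synthetic cohorts are sign- and
trend-level, so no mixed-effects machinery is used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .direction_model import ConfigurationError, ModelVariant, PriorParams
from .model_fitting import SearchConfig, compare_models
from .psychometrics import (
    DegenerateFitError,
    PsychometricData,
    bootstrap_fit,
    compute_psi,
    estimate_bias,
    fit_psychometric,
)
from .synthetic_data import (
    TRIAL_TABLE_COLUMNS,
    ExperimentDesign,
    generate_experiment,
    make_cohort,
)
from .trial_simulator import COHERENT, SimulationSettings

__all__ = [
    "GroupTrend",
    "RunConfig",
    "PipelineError",
    "read_trials",
    "write_trials",
    "condition_data",
    "reference_fits",
    "density_trend",
    "sigma_bias_correlation",
    "run_end_to_end",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending keys."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


@dataclass(frozen=True)
class GroupTrend:
    """OLS trend of a statistic against a predictor (density or sigma_S)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    condition: str
    n: int


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results"
    trials_csv: str | None = None     # read instead of synthesizing when set
    seed: int = 0
    n_subjects: int = 5
    cohort_strength: float = 0.3
    irregular_attenuation: float = 0.25
    bias_mix: dict = field(default_factory=lambda: {"coherent": 0.4, "transparent": 0.6})
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    n_bootstrap: int = 400
    fit_variants: tuple[str, ...] = ()   # e.g. ("M1","M2","M3","M4"); empty = skip
    cohort_variant: str = "M1"           # generating variant of synthetic observers
    sigma_P: float | None = None         # ground-truth prior widths for synthesis
    sigma_C: float | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)

    def __post_init__(self):
        # surface unknown variant tags and variant/prior mismatches at
        # configuration time, naming the missing field
        for tag in self.fit_variants:
            ModelVariant(tag)
        gen = ModelVariant(self.cohort_variant)
        if gen.needs_sigma_P and self.sigma_P is None:
            raise ConfigurationError(
                f"cohort_variant {gen.value} requires sigma_P in the run config"
            )
        if gen.needs_sigma_C and self.sigma_C is None:
            raise ConfigurationError(
                f"cohort_variant {gen.value} requires sigma_C in the run config"
            )

    @property
    def cohort_priors(self) -> PriorParams:
        return PriorParams(sigma_P=self.sigma_P, sigma_C=self.sigma_C)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = ExperimentDesign(**raw.pop("design", {}))
        search = SearchConfig(**raw.pop("search", {}))
        simulation = SimulationSettings(**raw.pop("simulation", {}))
        return cls(design=design, search=search, simulation=simulation, **raw)


# ---------------------------------------------------------------------------
# trial-table I/O


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=TRIAL_TABLE_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise PipelineError("read_trials", f"missing columns {sorted(missing)}")
    return df[TRIAL_TABLE_COLUMNS]


def condition_data(trials: pd.DataFrame) -> dict:
    """Per-(subject, experiment, density) binomial counts.

    Returns a dict keyed by (subject, experiment, density) holding
    :class:`PsychometricData` with levels in % LI.
    """
    out = {}
    grouped = trials.groupby(["subject", "experiment", "density"], sort=True)
    for key, block in grouped:
        per_level = block.groupby("level_pct")["response"].agg(
            n_trials="count", n_coherent=lambda r: int((r == COHERENT).sum())
        )
        out[key] = PsychometricData(
            levels=per_level.index.to_numpy(dtype=float),
            n_trials=per_level["n_trials"].to_numpy(),
            n_coherent=per_level["n_coherent"].to_numpy(),
        )
    return out


def reference_fits(trials: pd.DataFrame) -> dict:
    """Pooled low-density reference psychometric fit per experiment.

    All subjects' trials at the lowest density of each experiment are
    pooled and fitted once; the resulting PSE anchors the bias estimates
    of every condition in that experiment.
    """
    refs = {}
    for exp, block in trials.groupby("experiment"):
        low = block[block["density"] == block["density"].min()]
        per_level = low.groupby("level_pct")["response"].agg(
            n_trials="count", n_coherent=lambda r: int((r == COHERENT).sum())
        )
        data = PsychometricData(
            levels=per_level.index.to_numpy(dtype=float),
            n_trials=per_level["n_trials"].to_numpy(),
            n_coherent=per_level["n_coherent"].to_numpy(),
        )
        refs[exp] = fit_psychometric(data)
    return refs


# ---------------------------------------------------------------------------
# group statistics


def density_trend(values, densities, condition: str = "") -> GroupTrend:
    """OLS regression of a per-(subject, density) statistic on density."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(densities, dtype=float)
    if y.size != x.size:
        raise PipelineError("density_trend", "values and densities differ in length")
    if y.size < 3:
        raise PipelineError("density_trend", f"need >= 3 points, got {y.size}")
    if np.ptp(x) == 0:
        raise PipelineError("density_trend", "constant predictor (single density)")
    if np.ptp(y) == 0:
        # flat statistic: no trend by definition (OLS r-squared is 0/0 here)
        return GroupTrend(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0,
            condition=condition, n=int(y.size),
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return GroupTrend(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        condition=condition,
        n=int(y.size),
    )


def sigma_bias_correlation(fits: dict, biases: dict) -> dict:
    """Association between fitted sigma_S and bias, per experiment.

    ``fits`` maps (subject, experiment, density) to a FitResult (or any
    object with ``params['sigma_S']``); ``biases`` maps the same keys to
    BiasEstimate.  Points are collapsed across densities within each
    experiment and regressed by OLS.
    """
    mismatch = set(fits) ^ set(biases)
    if mismatch:
        raise PipelineError(
            "sigma_bias_correlation", f"unmatched condition keys: {sorted(mismatch)[:6]}"
        )
    out = {}
    experiments = sorted({k[1] for k in fits})
    for exp in experiments:
        keys = sorted(k for k in fits if k[1] == exp)
        x = np.array([fits[k].params["sigma_S"] for k in keys])
        y = np.array([biases[k].value for k in keys])
        if np.ptp(x) == 0:
            raise PipelineError("sigma_bias_correlation", f"constant sigma_S in {exp}")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        out[exp] = GroupTrend(
            slope=float(model.params[1]),
            intercept=float(model.params[0]),
            r_squared=float(model.rsquared),
            p_value=float(model.pvalues[1]),
            condition=f"sigma_S-bias:{exp}",
            n=int(x.size),
        )
    return out


# ---------------------------------------------------------------------------
# orchestration


def _stable_key_hash(key) -> int:
    """Deterministic across processes (unlike built-in str hashing)."""
    import zlib

    return zlib.crc32("|".join(map(str, key)).encode())


def _fit_conditions(data_by_key: dict, refs: dict):
    """Psychometric fit, bias and PSI per condition; degenerate conditions
    are reported, not silently dropped."""
    fits, biases, psis, failures = {}, {}, {}, {}
    for key, data in data_by_key.items():
        exp = key[1]
        try:
            fit = fit_psychometric(data)
        except DegenerateFitError as err:
            failures[key] = err.sign
            continue
        bias = estimate_bias(fit, refs[exp])
        fits[key] = fit
        biases[key] = bias
        psis[key] = compute_psi(fit, data.levels, bias=bias)
    return fits, biases, psis, failures


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full pipeline and write JSON results.

    Stages: synthesize (or read) trials -> per-condition psychometric
    fits + bootstrap -> bias and PSI -> optional observer-model fits and
    AIC comparison -> group trends.  Identical configs produce identical
    outputs; all seeds are recorded in the result bundle.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- data ---
    ground_truth = None
    if config.trials_csv:
        trials = read_trials(config.trials_csv)
    else:
        cohort = make_cohort(
            config.n_subjects,
            bias_mix=config.bias_mix,
            seeds=[config.seed * 1000 + i for i in range(config.n_subjects)],
            strength=config.cohort_strength,
            variant=ModelVariant(config.cohort_variant),
            priors=config.cohort_priors,
            irregular_attenuation=config.irregular_attenuation,
            design=config.design,
        )
        trials = pd.concat(
            [generate_experiment(s, config.design, config.simulation) for s in cohort],
            ignore_index=True,
        )
        ground_truth = [s.to_record() for s in cohort]
        write_trials(trials, out_dir / "trials.csv")
        (out_dir / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=2, sort_keys=True)
        )

    # --- psychometrics ---
    try:
        refs = reference_fits(trials)
    except DegenerateFitError as err:
        raise PipelineError("reference_fits", str(err)) from err
    data_by_key = condition_data(trials)
    fits, biases, psis, failures = _fit_conditions(data_by_key, refs)

    boots = {}
    if config.n_bootstrap:
        for key, data in data_by_key.items():
            if key not in fits:
                continue
            boot_seed = int(
                np.random.SeedSequence(
                    [config.seed, _stable_key_hash(key)]
                ).generate_state(1)[0]
                % 2**31
            )
            boots[key] = bootstrap_fit(data, n_resamples=config.n_bootstrap, seed=boot_seed)

    # --- model fits ---
    comparisons = {}
    if config.fit_variants:
        variants = [ModelVariant(v) for v in config.fit_variants]
        subjects = sorted({k[0] for k in data_by_key})
        for subj in subjects:
            conds = [data_by_key[k] for k in sorted(data_by_key) if k[0] == subj and k in fits]
            comparisons[subj] = compare_models(
                conds, variants=variants, search_cfg=config.search,
                settings=config.simulation,
            )

    # --- group trends ---
    trends = {}
    for exp in sorted({k[1] for k in fits}):
        keys = sorted(k for k in fits if k[1] == exp)
        dens = [k[2] for k in keys]
        trends[f"bias:{exp}"] = density_trend(
            [biases[k].value for k in keys], dens, condition=f"bias:{exp}"
        )
        trends[f"psi:{exp}"] = density_trend(
            [psis[k].psi for k in keys], dens, condition=f"psi:{exp}"
        )

    bundle = {
        "seed": config.seed,
        "n_conditions": len(data_by_key),
        "reference_pse": {exp: refs[exp].pse for exp in refs},
        "conditions": {
            "|".join(map(str, key)): {
                "pse": fits[key].pse,
                "spread": fits[key].spread,
                "bias": biases[key].value,
                "psi": psis[key].psi,
                "psi_dominant": psis[key].dominant,
                **(
                    {
                        "pse_boot_sd": float(np.std(boots[key].pse)),
                        "boot_failures": boots[key].n_failed,
                    }
                    if key in boots
                    else {}
                ),
            }
            for key in sorted(fits)
        },
        "degenerate_conditions": {
            "|".join(map(str, k)): sign for k, sign in sorted(failures.items())
        },
        "model_comparison": {
            subj: {
                "best": mc.best.value,
                "aic": {v.value: mc.aic[v] for v in mc.aic},
                "delta_aic": {v.value: mc.delta_aic[v] for v in mc.delta_aic},
            }
            for subj, mc in comparisons.items()
        },
        "trends": {name: asdict(t) for name, t in trends.items()},
    }
    (out_dir / "results.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle
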