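"""Tests for the Monte-Carlo trial simulator: sampling fidelity,
categorical endpoint behaviour, prior effects and determinism."""

import numpy as np
import pytest

from plaidobs.direction_model import (
    ModelVariant,
    ParameterError,
    PriorParams,
    SensoryParams,
    StimulusConfig,
    likelihood_bin_masses,
)
from plaidobs.trial_simulator import (
    SimulationSettings,
    default_levels,
    sample_measurements,
    simulate_psychometric,
    simulate_trial,
    simulate_trial_batch,
    _tie_break_order,
)

M = ModelVariant


def circular_mean_deg(angles):
    rad = np.deg2rad(angles)
    return np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))


class TestSampleMeasurements:
    def test_pure_pattern_samples_center_on_zero(self, rng):
        s = sample_measurements(
            StimulusConfig(A_L=1.0), SensoryParams(5.0, 1.0), 100_000, rng
        )
        assert abs(circular_mean_deg(s.angles)) < 0.1

    def test_pure_component_samples_split_evenly_by_sign(self):
        # mirror symmetry: P(angle > 0) = 1/2 exactly; binomial oracle bound
        rng = np.random.default_rng(7)
        n = 100_000
        s = sample_measurements(StimulusConfig(A_L=0.0), SensoryParams(10.0, 10.0), n, rng)
        frac_pos = np.mean(s.angles > 0)
        assert abs(frac_pos - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_fixed_seed_reproduces_sample_sequence(self):
        a = sample_measurements(
            StimulusConfig(A_L=0.3), SensoryParams(12.0, 9.0), 1000,
            np.random.default_rng(42),
        )
        b = sample_measurements(
            StimulusConfig(A_L=0.3), SensoryParams(12.0, 9.0), 1000,
            np.random.default_rng(42),
        )
        assert np.array_equal(a.angles, b.angles)

    def test_sample_histogram_matches_bin_masses(self, grid, stim, sens, rng):
        # links the two sampling routes: binned i.i.d. draws follow the
        # same cell probabilities the batch simulator draws from directly
        n = 200_000
        s = sample_measurements(stim, sens, n, rng)
        counts = np.bincount(grid.bin_index(s.angles), minlength=grid.n_bins)
        masses = likelihood_bin_masses(grid, stim, sens)
        # coarse chunks to keep the comparison well-conditioned
        emp = counts.reshape(72, 10).sum(axis=1) / n
        exp = masses.reshape(72, 10).sum(axis=1)
        assert np.max(np.abs(emp - exp)) < 5 * np.sqrt(exp.max() / n) + 1e-4

    def test_requires_at_least_one_sample(self, stim, sens, rng):
        with pytest.raises(ParameterError):
            sample_measurements(stim, sens, 0, rng)


class TestSimulationSettings:
    def test_early_stage_uses_stated_fraction(self):
        assert SimulationSettings().n_early == 1000  # 20% of 5000

    @pytest.mark.parametrize("kwargs", [
        dict(n_full=50), dict(early_fraction=0.0), dict(early_fraction=1.5),
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimulationSettings(**kwargs)


class TestTieBreakOrder:
    def test_prefers_small_magnitude_then_positive(self, grid):
        order = _tie_break_order(grid)
        centers = grid.centers[order]
        assert centers[0] == 0.0
        assert centers[1] == 0.5 and centers[2] == -0.5
        mags = np.abs(centers)
        assert np.all(np.diff(mags) >= 0)


class TestSimulateTrial:
    def test_pure_pattern_stimulus_is_seen_coherent(self):
        batch = simulate_trial_batch(
            StimulusConfig(A_L=1.0), SensoryParams(5.0, 5.0), None, M.M1,
            SimulationSettings(), 1000, np.random.default_rng(0),
        )
        assert batch.p_coherent >= 0.99

    def test_pure_component_stimulus_is_seen_transparent(self):
        batch = simulate_trial_batch(
            StimulusConfig(A_L=0.0), SensoryParams(5.0, 5.0), None, M.M1,
            SimulationSettings(), 1000, np.random.default_rng(0),
        )
        assert batch.p_coherent <= 0.01

    def test_outcome_fields_are_consistent(self):
        out = simulate_trial(
            StimulusConfig(A_L=0.5), SensoryParams(10.0, 8.0), None, M.M1,
            SimulationSettings(), np.random.default_rng(3),
        )
        assert out.chi in (1, 2)
        assert (out.percept == "coherent") == (abs(out.theta_map) < 30.0)

    def test_segregating_prior_reduces_coherent_frequency(self):
        # paired common-random-number comparison at ambiguous stimulus
        kwargs = dict(
            stim=StimulusConfig(A_L=1.0 / 3.0),
            sens=SensoryParams(12.0, 12.0),
            settings=SimulationSettings(),
            n_trials=2000,
        )
        m1 = simulate_trial_batch(
            variant=M.M1, priors=None, rng=np.random.default_rng(11), **kwargs
        )
        m3 = simulate_trial_batch(
            variant=M.M3, priors=PriorParams(sigma_C=30.0),
            rng=np.random.default_rng(11), **kwargs
        )
        assert m3.p_coherent < m1.p_coherent

    def test_variant_prior_mismatch_raises(self):
        from plaidobs.direction_model import ConfigurationError

        with pytest.raises(ConfigurationError):
            simulate_trial_batch(
                StimulusConfig(A_L=0.5), SensoryParams(10, 10), None, M.M3,
                SimulationSettings(), 10, np.random.default_rng(0),
            )


class TestSimulatePsychometric:
    def test_default_design_levels_are_equally_spaced(self):
        levels = default_levels()
        assert levels.size == 11
        assert levels[0] == 0.0 and levels[-1] == 1.0
        assert np.allclose(np.diff(levels), 0.1)

    def test_endpoint_ordering_and_range(self):
        sp = simulate_psychometric(
            default_levels(), 300, SensoryParams(15.0, 10.0), None, M.M1,
            SimulationSettings(seed=21),
        )
        assert np.all((sp.p_coherent >= 0) & (sp.p_coherent <= 1))
        assert sp.p_coherent[0] <= sp.p_coherent[-1]

    def test_same_seed_reproduces_curve(self):
        args = (default_levels(), 200, SensoryParams(14.0, 9.0), None, M.M1)
        a = simulate_psychometric(*args, SimulationSettings(seed=5))
        b = simulate_psychometric(*args, SimulationSettings(seed=5))
        assert np.array_equal(a.p_coherent, b.p_coherent)

    def test_flat_prior_variants_match_no_prior_fractions(self):
        # M2 with a very wide prior and M3 with a vanishing prior behave
        # as the prior-free observer at common seeds (3 binomial SE)
        n = 400
        args = (default_levels(), n, SensoryParams(15.0, 10.0))
        settings = SimulationSettings(seed=8)
        base = simulate_psychometric(*args, None, M.M1, settings).p_coherent
        wide = simulate_psychometric(
            *args, PriorParams(sigma_P=1e4), M.M2, settings
        ).p_coherent
        narrow = simulate_psychometric(
            *args, PriorParams(sigma_C=0.01), M.M3, settings
        ).p_coherent
        se = 3 * np.sqrt(np.maximum(base * (1 - base), 0.25 / n) / n)
        assert np.all(np.abs(wide - base) <= se)
        assert np.all(np.abs(narrow - base) <= se)

    def test_expected_curve_is_monotone_in_aperture_proportion(self):
        sp = simulate_psychometric(
            default_levels(), 2000, SensoryParams(18.0, 12.0), None, M.M1,
            SimulationSettings(seed=13),
        )
        violations = np.sum(np.diff(sp.p_coherent) < -1e-12)
        assert violations < 2

    def test_wider_component_likelihood_lowers_pse(self):
        # sigma_S up -> component peaks flatten -> coherence easier.
        # direction checked on a 3 x 3 sweep of (sigma_S, sigma_L)
        def crossing(p, levels):
            return float(np.interp(0.5, p, levels))

        levels = default_levels()
        settings = SimulationSettings(seed=17)
        for sigma_L in (8.0, 12.0, 16.0):
            pses = []
            for sigma_S in (10.0, 18.0, 30.0):
                sp = simulate_psychometric(
                    levels, 300, SensoryParams(sigma_S, sigma_L), None, M.M1, settings
                )
                pses.append(crossing(sp.p_coherent, levels))
            assert pses[0] > pses[-1]

    def test_levels_validation(self):
        with pytest.raises(ParameterError):
            simulate_psychometric(
                [], 10, SensoryParams(10, 10), None, M.M1, SimulationSettings()
            )
        with pytest.raises(ParameterError):
            simulate_psychometric(
                [1.2], 10, SensoryParams(10, 10), None, M.M1, SimulationSettings()
            )
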