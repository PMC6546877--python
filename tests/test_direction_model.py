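"""Unit and property tests for the probabilistic core: likelihood
mixture, conditional priors, posteriors and the early chi decision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaidobs.direction_model import (
    ConfigurationError,
    DensityOnGrid,
    DirectionGrid,
    ModelVariant,
    ParameterError,
    PriorParams,
    SensoryParams,
    StimulusConfig,
    chi_decision,
    conditional_posterior,
    integrate_prior,
    likelihood_bin_masses,
    likelihood_pdf,
    segregate_prior,
    wrap_degrees,
)

M = ModelVariant


class TestDirectionGrid:
    def test_default_grid_covers_circle_at_half_degree(self, grid):
        assert grid.n_bins == 720
        assert grid.centers[0] == -180.0
        assert grid.centers[-1] == 179.5
        spacing = np.diff(grid.centers)
        assert np.allclose(spacing, grid.bin_width)
        # wrap-around: the last and first centers are one bin apart mod 360
        assert ((grid.centers[0] - grid.centers[-1]) % 360.0) == grid.bin_width

    @pytest.mark.parametrize("bad", [0.0, -1.0, 0.7])
    def test_bin_width_must_divide_360(self, bad):
        with pytest.raises(ParameterError):
            DirectionGrid(bin_width=bad)

    def test_bin_index_assigns_half_open_bins(self, grid):
        # bins are [c - w/2, c + w/2): the left edge belongs, the right not
        idx0 = grid.bin_index(0.0)
        assert grid.centers[idx0] == 0.0
        assert grid.centers[grid.bin_index(0.24)] == 0.0
        assert grid.centers[grid.bin_index(0.25)] == 0.5
        assert grid.centers[grid.bin_index(-0.26)] == -0.5
        assert grid.centers[grid.bin_index(179.9)] == -180.0  # wraps

    @given(st.floats(-1e4, 1e4))
    @settings(max_examples=100, derandomize=True)
    def test_wrap_degrees_lands_in_halfopen_interval(self, angle):
        w = float(wrap_degrees(angle))
        assert -180.0 <= w < 180.0
        assert abs((w - angle) % 360.0) < 1e-6 or abs((w - angle) % 360.0 - 360.0) < 1e-6


class TestStimulusConfig:
    def test_component_weight_is_complement_of_pattern_weight(self):
        assert StimulusConfig(A_L=0.4).A_S == pytest.approx(0.6)
        assert StimulusConfig(A_L=1.0).A_S == 0.0

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_mixture_weight_bounds(self, bad):
        with pytest.raises(ParameterError):
            StimulusConfig(A_L=bad)

    @pytest.mark.parametrize("cls,kwargs", [
        (SensoryParams, dict(sigma_S=-1.0, sigma_L=5.0)),
        (SensoryParams, dict(sigma_S=5.0, sigma_L=np.inf)),
        (PriorParams, dict(sigma_P=0.0)),
        (PriorParams, dict(sigma_C=-3.0)),
    ])
    def test_nonpositive_widths_rejected(self, cls, kwargs):
        with pytest.raises(ParameterError):
            cls(**kwargs)


class TestLikelihood:
    def test_mixture_weights_follow_aperture_proportion(self, grid, sens):
        # A_L = 0.4 -> weights (0.3, 0.3, 0.4) for (-60, +60, pattern):
        # integrate the mass in a window around each mixture center
        pdf = likelihood_pdf(grid, StimulusConfig(A_L=0.4), SensoryParams(5.0, 5.0))
        mass = pdf.bin_masses()
        c = grid.centers
        for center, expected in [(-60.0, 0.3), (60.0, 0.3), (0.0, 0.4)]:
            window = np.abs(wrap_degrees(c - center)) < 25.0
            assert mass[window].sum() == pytest.approx(expected, abs=1e-6)

    def test_pure_pattern_stimulus_is_unimodal_and_centered(self, grid):
        pdf = likelihood_pdf(grid, StimulusConfig(A_L=1.0), SensoryParams(10.0, 10.0))
        assert grid.centers[np.argmax(pdf.values)] == 0.0
        flipped = pdf.values[::-1]
        # mirror symmetry about 0 (centers are asymmetric by one bin: roll)
        assert np.allclose(pdf.values[1:], np.roll(flipped, 1)[1:], atol=1e-12)

    def test_pure_component_stimulus_has_equal_peaks_at_components(self, grid):
        pdf = likelihood_pdf(grid, StimulusConfig(A_L=0.0), SensoryParams(10.0, 10.0))
        v = pdf.values
        i_pos = np.argmax(v)
        assert abs(grid.centers[i_pos]) == pytest.approx(60.0)
        i_neg = grid.bin_index(-grid.centers[i_pos])
        assert v[i_pos] == pytest.approx(v[i_neg], rel=1e-12)

    @given(
        st.floats(2.0, 80.0), st.floats(2.0, 80.0), st.floats(0.0, 1.0)
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_likelihood_normalizes_to_unit_mass(self, sigma_S, sigma_L, A_L):
        grid = DirectionGrid()
        pdf = likelihood_pdf(grid, StimulusConfig(A_L=A_L), SensoryParams(sigma_S, sigma_L))
        assert pdf.total_mass == pytest.approx(1.0, abs=1e-9)
        masses = likelihood_bin_masses(grid, StimulusConfig(A_L=A_L), SensoryParams(sigma_S, sigma_L))
        assert masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bin_masses_match_pdf_at_moderate_widths(self, grid, stim, sens):
        # CDF-based masses and midpoint pdf agree closely at 0.5 deg bins
        pdf = likelihood_pdf(grid, stim, sens)
        masses = likelihood_bin_masses(grid, stim, sens)
        assert np.max(np.abs(masses - pdf.bin_masses())) < 1e-6


class TestPriors:
    def test_integrating_prior_peaks_on_pattern_direction(self, grid):
        for sigma_P in (5.0, 40.0, 300.0):
            w = integrate_prior(grid, sigma_P).values
            assert grid.centers[np.argmax(w)] == 0.0
            assert w.max() == pytest.approx(1.0)

    def test_integrating_prior_flattens_in_wide_limit(self, grid):
        w = integrate_prior(grid, 1e4).values
        assert w.max() / w.min() < 1.01

    def test_integrating_prior_is_even(self, grid):
        w = integrate_prior(grid, 25.0).values
        pos = w[grid.bin_index(np.arange(0.5, 180.0, 0.5))]
        neg = w[grid.bin_index(-np.arange(0.5, 180.0, 0.5))]
        assert np.allclose(pos, neg, rtol=1e-12)

    def test_segregating_prior_inhibits_pattern_direction(self, grid):
        w = segregate_prior(grid, 30.0).values
        assert grid.centers[np.argmin(w)] == 0.0
        assert np.all((w >= 0.0) & (w <= 1.0))

    def test_segregating_prior_vanishes_in_narrow_limit(self, grid):
        w = segregate_prior(grid, 0.01).values
        keep = grid.centers != 0.0
        assert np.all(w[keep] > 0.999)
        assert w[grid.bin_index(0.0)] == pytest.approx(0.0, abs=1e-12)

    def test_segregating_prior_maximal_diametrically_opposite(self, grid):
        # exhaustive scan: no bin beats the bin at -180 (the +180 alias)
        w = segregate_prior(grid, 45.0).values
        assert w[grid.bin_index(-180.0)] >= w.max() - 1e-15

    @pytest.mark.parametrize("func", [integrate_prior, segregate_prior])
    def test_prior_width_must_be_positive(self, grid, func):
        with pytest.raises(ParameterError):
            func(grid, 0.0)


class TestConditionalPosterior:
    @pytest.fixture()
    def hist(self, grid, stim, sens):
        return likelihood_pdf(grid, stim, sens)

    def test_no_prior_variant_passes_histogram_through(self, hist):
        for chi in (1, 2):
            post = conditional_posterior(hist, M.M1, chi)
            assert np.array_equal(post.values, hist.values)

    def test_posterior_mass_is_unity_for_all_variants_and_chi(self, hist):
        priors = PriorParams(sigma_P=30.0, sigma_C=30.0)
        for variant in M:
            for chi in (1, 2):
                post = conditional_posterior(hist, variant, chi, priors)
                assert post.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_segregating_posterior_suppresses_pattern_bin(self, grid, hist):
        # independent bin-wise oracle: multiply and renormalize by hand
        w = 1.0 - np.exp(-(grid.centers**2) / (2 * 30.0**2))
        expected = hist.values * w
        expected /= expected.sum() * grid.bin_width
        post = conditional_posterior(hist, M.M3, 2, PriorParams(sigma_C=30.0))
        i0 = grid.bin_index(0.0)
        assert post.values[i0] < hist.values[i0]
        assert np.allclose(post.values, expected, atol=1e-6)

    def test_unselected_prior_leaves_histogram_unchanged(self, hist):
        post = conditional_posterior(hist, M.M2, 2, PriorParams(sigma_P=30.0))
        assert np.array_equal(post.values, hist.values)
        post = conditional_posterior(hist, M.M3, 1, PriorParams(sigma_C=30.0))
        assert np.array_equal(post.values, hist.values)

    @pytest.mark.parametrize("variant,priors", [
        (M.M2, PriorParams()),
        (M.M3, PriorParams(sigma_P=30.0)),
        (M.M4, PriorParams(sigma_C=30.0)),
    ])
    def test_variant_prior_mismatch_is_a_configuration_error(self, hist, variant, priors):
        with pytest.raises(ConfigurationError):
            conditional_posterior(hist, variant, 1 if variant is M.M2 else 2, priors)

    def test_effectively_flat_priors_reduce_to_no_prior_variant(self, grid, hist):
        base = conditional_posterior(hist, M.M1, 1)
        wide = conditional_posterior(hist, M.M2, 1, PriorParams(sigma_P=1e4))
        narrow = conditional_posterior(hist, M.M3, 2, PriorParams(sigma_C=0.01))
        assert np.max(np.abs(wide.values - base.values)) < 1e-3
        # the segregating weight is identically 0 at the 0-bin for every
        # width (it is peak-normalized), so flatness in the narrow limit
        # holds everywhere except that single bin
        keep = grid.centers != 0.0
        assert np.max(np.abs(narrow.values - base.values)[keep]) < 1e-3


class TestChiDecision:
    @pytest.mark.parametrize("theta_max,expected", [
        (0.0, 1),       # on the pattern direction
        (-60.0, 2),     # exactly on a component direction
        (30.0, 2),      # boundary theta_S/2: documented tie rule
        (-30.0, 2),
        (29.5, 1),
        (179.5, 2),
    ])
    def test_examples(self, theta_max, expected):
        assert chi_decision(theta_max, 60.0) == expected

    def test_matches_nearest_source_direction_oracle_on_all_grid_points(self, grid):
        # brute force: chi = 1 iff the circular distance to the pattern
        # direction is smaller than to the nearest component direction
        sources = np.array([0.0, 60.0, -60.0])
        for theta in grid.centers:
            dists = np.abs(wrap_degrees(theta - sources))
            if dists[0] == dists[1:].min():
                assert chi_decision(theta, 60.0) == 2  # tie rule
            else:
                expected = 1 if dists[0] < dists[1:].min() else 2
                assert chi_decision(theta, 60.0) == expected


class TestDensityOnGrid:
    def test_normalized_flag_enforces_unit_mass(self, grid):
        values = np.ones(grid.n_bins)
        with pytest.raises(ValueError):
            DensityOnGrid(grid, values, normalized=True)
        ok = DensityOnGrid(grid, values / 360.0, normalized=True)
        assert ok.total_mass == pytest.approx(1.0)

    def test_negative_values_rejected(self, grid):
        values = np.ones(grid.n_bins)
        values[3] = -1e-9
        with pytest.raises(ValueError):
            DensityOnGrid(grid, values)
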