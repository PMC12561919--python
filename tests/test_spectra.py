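"""State-conditioned spectra, NNMF band discovery, spectral
parameterization, alpha-peak selection and critical-node selection."""

import numpy as np
import pytest

from alphastates.io import ParcelTimeSeries
from alphastates.spectra import (
    SpectralFit,
    fit_spectral_model,
    nnmf_bands,
    select_alpha_peak,
    select_critical_nodes,
    state_multitaper,
)


def _white_ts(n_parcels=1, seconds=100, fs=250.0, seed=0):
    rng = np.random.default_rng(seed)
    return ParcelTimeSeries(
        rng.standard_normal((n_parcels, int(seconds * fs))), fs
    )


class TestMultitaper:
    def test_grid_spacing_is_half_hz(self):
        ts = _white_ts()
        spec = state_multitaper(ts, np.zeros(ts.n_samples, int), n_states=1)
        assert np.allclose(np.diff(spec.freqs), 0.5)

    def test_white_noise_spectrum_is_flat(self):
        ts = _white_ts(seconds=200, seed=1)
        spec = state_multitaper(ts, np.zeros(ts.n_samples, int), n_states=1)
        band = (spec.freqs >= 5) & (spec.freqs <= 40)
        p = spec.psd[0, 0][band]
        assert p.max() / p.mean() < 1.2 and p.min() / p.mean() > 0.8

    def test_duplicated_parcel_has_unit_coherence(self):
        base = _white_ts(seconds=60, seed=2).data[0]
        ts = ParcelTimeSeries(np.stack([base, base]), 250.0)
        spec = state_multitaper(ts, np.zeros(ts.n_samples, int), n_states=1)
        assert np.nanmin(spec.coherence[0, 0, 1]) > 0.999

    def test_independent_parcels_have_low_coherence(self):
        ts = _white_ts(n_parcels=2, seconds=100, seed=3)
        spec = state_multitaper(ts, np.zeros(ts.n_samples, int), n_states=1)
        assert np.nanmean(spec.coherence[0, 0, 1]) < 0.2

    def test_state_with_no_window_is_missing(self):
        ts = _white_ts(seconds=20, seed=4)
        path = np.zeros(ts.n_samples, int)  # state 1 never on
        with pytest.warns(UserWarning, match="state 1"):
            spec = state_multitaper(ts, path, n_states=2)
        assert np.all(np.isnan(spec.psd[1]))
        assert np.all(np.isfinite(spec.psd[0]))

    def test_psd_nonnegative_and_coherence_bounded(self):
        ts = _white_ts(n_parcels=3, seconds=60, seed=5)
        path = (np.arange(ts.n_samples) // 2500) % 2
        spec = state_multitaper(ts, path, n_states=2)
        assert np.nanmin(spec.psd) >= 0
        assert np.nanmin(spec.coherence) >= 0
        assert np.nanmax(spec.coherence) <= 1


class TestNNMF:
    def test_rank_one_input_reconstructs(self):
        rng = np.random.default_rng(0)
        spectrum = rng.uniform(0.1, 1.0, 50)
        weights = rng.uniform(0.5, 2.0, 30)
        V = np.outer(weights, spectrum)
        W, H, err = nnmf_bands(V, n_modes=1, seed=0)
        assert err / np.linalg.norm(V) < 1e-3

    def test_alpha_mode_identified_in_mixture(self):
        rng = np.random.default_rng(1)
        f = np.arange(1, 45.5, 0.5)
        alpha = np.exp(-0.5 * ((f - 10) / 1.5) ** 2)
        broad = np.full_like(f, 0.4)
        V = []
        for _ in range(40):
            V.append(rng.uniform(0.2, 1.5) * alpha
                     + rng.uniform(0.2, 1.5) * broad
                     + rng.uniform(0, 0.01, f.size))
        W, H, _ = nnmf_bands(np.array(V), n_modes=2, seed=0)
        peak_freqs = f[H.argmax(axis=1)]
        assert any(7 <= pf <= 14 for pf in peak_freqs)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(0, 1, (20, 30))
        out1 = nnmf_bands(V, seed=3)
        out2 = nnmf_bands(V, seed=3)
        assert np.allclose(out1[1], out2[1])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            nnmf_bands(np.zeros((5, 10)))


class TestSpectralFit:
    def test_pure_power_law(self):
        f = np.arange(1, 45.5, 0.5)
        fit = fit_spectral_model(10**0.5 * f**-1.2, f)
        assert abs(fit.exponent - 1.2) <= 0.05
        assert fit.peaks == []

    def test_power_law_plus_alpha_bump(self):
        f = np.arange(1, 45.5, 0.5)
        logp = 0.5 - 1.2 * np.log10(f) + 0.8 * np.exp(
            -0.5 * ((f - 10) / (2 / 2.355)) ** 2
        )
        fit = fit_spectral_model(10**logp, f)
        assert len(fit.peaks) == 1
        cf, height, fwhm = fit.peaks[0]
        assert abs(cf - 10) <= 0.3
        assert abs(height - 0.8) <= 0.1
        assert abs(fwhm - 2.0) <= 0.5

    def test_bump_below_min_height_ignored(self):
        f = np.arange(1, 45.5, 0.5)
        logp = 0.5 - 1.2 * np.log10(f) + 0.2 * np.exp(
            -0.5 * ((f - 10) / (2 / 2.355)) ** 2
        )
        assert fit_spectral_model(10**logp, f).peaks == []

    @pytest.mark.parametrize("seed", range(20))
    def test_recovery_under_noise_seed_sweep(self, seed):
        rng = np.random.default_rng(seed)
        f = np.arange(1, 45.5, 0.5)
        exponent = rng.uniform(0.8, 1.5)
        cf_true = rng.uniform(8.5, 12.0)
        logp = (
            rng.uniform(-0.5, 0.5)
            - exponent * np.log10(f)
            + rng.uniform(0.5, 1.0)
            * np.exp(-0.5 * ((f - cf_true) / 1.0) ** 2)
            + rng.normal(0, 0.02, f.size)
        )
        fit = fit_spectral_model(10**logp, f)
        in_band = [p for p in fit.peaks if 7 <= p[0] <= 14]
        assert abs(fit.exponent - exponent) <= 0.05
        assert in_band and abs(in_band[0][0] - cf_true) <= 0.3

    def test_nonfinite_psd_rejected(self):
        f = np.arange(1, 45.5, 0.5)
        p = f**-1.0
        p[3] = np.nan
        with pytest.raises(ValueError):
            fit_spectral_model(p, f)


def _fit_with_peaks(*cfs):
    return SpectralFit(0.0, 1.0, [(cf, 0.5, 2.0) for cf in cfs], 0.99)


class TestAlphaSelection:
    def test_lower_of_two_in_band_peaks(self):
        fits = [[_fit_with_peaks(9.5, 12.0)]]
        out = select_alpha_peak(fits)
        assert out.center_freq[0, 0] == 9.5
        assert out.source[0, 0] == "fitted"

    def test_single_peak(self):
        assert select_alpha_peak([[_fit_with_peaks(10.0)]]).center_freq[0, 0] == 10.0

    def test_group_fallback_flagged(self):
        fits = [
            [_fit_with_peaks(10.0)],
            [_fit_with_peaks(10.8)],
            [_fit_with_peaks(20.0)],  # no in-band peak
        ]
        out = select_alpha_peak(fits)
        assert out.center_freq[2, 0] == pytest.approx(10.4)
        assert out.source[2, 0] == "group-fallback"

    def test_no_subject_in_band_is_error(self):
        with pytest.raises(ValueError, match="fallback"):
            select_alpha_peak([[_fit_with_peaks(20.0)]])


class TestCriticalNodes:
    def test_single_dominant_edge(self):
        C = np.full((4, 4), 0.1)
        C[0, 1] = C[1, 0] = 0.9
        np.fill_diagonal(C, 0)
        assert set(select_critical_nodes(C, edge_fraction=1 / 6)) == {0, 1}

    def test_star_hub_included(self):
        C = np.full((5, 5), 0.05)
        for j in (0, 1, 3, 4):
            C[2, j] = C[j, 2] = 0.8
        np.fill_diagonal(C, 0)
        nodes = select_critical_nodes(C, edge_fraction=3 / 10)
        assert 2 in nodes

    @pytest.mark.parametrize("seed", range(5))
    def test_node_count_bounded_by_twice_edges(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        C = rng.uniform(0, 1, (n, n))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 0)
        n_edges = 4
        frac = n_edges / (n * (n - 1) / 2)
        nodes = select_critical_nodes(C, edge_fraction=frac)
        assert 1 <= len(nodes) <= 2 * n_edges

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        C = rng.uniform(0, 1, (6, 6))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 0)
        perm = rng.permutation(6)
        nodes = select_critical_nodes(C, edge_fraction=0.2)
        nodes_p = select_critical_nodes(C[np.ix_(perm, perm)], edge_fraction=0.2)
        assert set(perm[nodes_p]) == set(nodes)

    def test_zero_edge_fraction_takes_strongest(self):
        C = np.full((10, 10), 0.1)
        C[3, 7] = C[7, 3] = 0.9
        np.fill_diagonal(C, 0)
        with pytest.warns(UserWarning, match="strongest"):
            nodes = select_critical_nodes(C, edge_fraction=1e-6)
        assert set(nodes) == {3, 7}

    def test_asymmetric_matrix_rejected(self):
        C = np.zeros((3, 3))
        C[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            select_critical_nodes(C)
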