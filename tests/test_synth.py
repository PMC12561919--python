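"""Generator ground-truth properties: Markov paths, schedules, spectra
of the rendered oscillations, and probit-consistent responses."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import welch
from scipy.stats import norm

from alphastates.synth import (
    SimConfig,
    draw_subject_effects,
    simulate_parcel_timeseries,
    simulate_responses,
    simulate_state_sequence,
    simulate_trials,
)


class TestStateSequence:
    def test_absorbing_chain_is_constant(self):
        path = simulate_state_sequence(np.eye(2), [1, 0], 500, seed=0)
        assert np.all(path == 0)

    def test_single_state(self):
        assert np.all(simulate_state_sequence(np.ones((1, 1)), [1.0], 100) == 0)

    def test_empirical_transition_frequencies(self):
        tm = np.array([[0.9, 0.1], [0.2, 0.8]])
        path = simulate_state_sequence(tm, [0.5, 0.5], 200_000, seed=3)
        # oracle: count observed transitions
        counts = np.zeros((2, 2))
        np.add.at(counts, (path[:-1], path[1:]), 1)
        emp = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(emp - tm).max() < 0.01

    def test_reproducible_given_seed(self):
        tm = np.array([[0.7, 0.3], [0.3, 0.7]])
        a = simulate_state_sequence(tm, [0.5, 0.5], 1000, seed=5)
        b = simulate_state_sequence(tm, [0.5, 0.5], 1000, seed=5)
        assert np.array_equal(a, b)

    def test_nonstochastic_matrix_rejected_naming_row(self):
        bad = np.array([[0.5, 0.4], [0.3, 0.7]])
        with pytest.raises(ValueError, match="row 0"):
            simulate_state_sequence(bad, [0.5, 0.5], 10)


class TestParcelTimeseries:
    def test_zero_amplitude_gives_no_alpha_peak(self):
        from alphastates.spectra import fit_spectral_model

        cfg = SimConfig(
            n_parcels=2, n_states=1, n_subjects=1,
            state_amp_map=np.zeros((2, 1)), seed=0,
        )
        path = np.zeros(int(90 * cfg.fs), dtype=int)
        ts = simulate_parcel_timeseries(path, cfg, 0)
        f, p = welch(ts.data[0], cfg.fs, nperseg=512)
        sel = (f >= 1) & (f <= 45)
        fit = fit_spectral_model(p[sel], f[sel])
        assert not any(7 <= pk[0] <= 14 for pk in fit.peaks)

    def test_peak_located_by_periodogram(self):
        cfg = SimConfig(
            n_parcels=1, n_states=1, n_subjects=1,
            state_peak_freq=[10.0], state_amp_map=np.array([[3.0]]),
            noise_sd=0.5, seed=0,
        )
        path = np.zeros(int(60 * cfg.fs), dtype=int)
        ts = simulate_parcel_timeseries(path, cfg, 1)
        f, p = welch(ts.data[0], cfg.fs, nperseg=1024)
        band = (f >= 2) & (f <= 40)
        assert abs(f[band][np.argmax(p[band])] - 10.0) <= 0.5

    def test_state_masked_spectra_separate_peaks(self):
        cfg = SimConfig(
            n_parcels=1, n_states=2, n_subjects=1,
            state_peak_freq=[9.8, 11.0],
            state_amp_map=np.array([[2.0, 2.0]]), noise_sd=0.5, seed=0,
        )
        n = int(200 * cfg.fs)
        tm = np.array([[0.995, 0.005], [0.005, 0.995]])
        path = simulate_state_sequence(tm, [0.5, 0.5], n, seed=2)
        ts = simulate_parcel_timeseries(path, cfg, 3)
        # masked periodogram oracle over each state's own samples
        for k, target in [(0, 9.8), (1, 11.0)]:
            f, p = welch(ts.data[0][path == k], cfg.fs, nperseg=512)
            band = (f >= 5) & (f <= 16)
            assert abs(f[band][np.argmax(p[band])] - target) <= 0.5

    def test_zero_mean_per_parcel(self):
        cfg = SimConfig(n_parcels=3, n_states=1, n_subjects=1, seed=0)
        ts = simulate_parcel_timeseries(np.zeros(1000, int), cfg, 0)
        assert np.abs(ts.data.mean(axis=1)).max() < 1e-10

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_states=1, state_peak_freq=[130.0])


class TestTrials:
    def test_half_present_exactly_per_block(self):
        cfg = SimConfig(n_subjects=1, seed=0)
        trials = simulate_trials(cfg, 0)
        for _, block in trials.groupby("block"):
            assert block["S"].sum() == 40
            assert len(block) == 80

    def test_two_trial_block(self):
        cfg = SimConfig(
            n_subjects=1, n_blocks=2, n_main_trials_per_block=2, seed=0
        )
        trials = simulate_trials(cfg, 0)
        for _, block in trials.groupby("block"):
            assert sorted(block["S"]) == [0, 1]

    def test_seed_changes_order_not_counts(self):
        cfg = SimConfig(n_subjects=1, n_blocks=2, n_main_trials_per_block=20)
        a = simulate_trials(cfg, 0)
        b = simulate_trials(cfg, 1)
        assert a["S"].sum() == b["S"].sum()
        assert not np.array_equal(a["S"], b["S"])

    def test_onsets_strictly_increasing_with_spacing(self):
        cfg = SimConfig(n_subjects=2, n_blocks=2, n_main_trials_per_block=10)
        trials = simulate_trials(cfg, 0)
        for _, sub in trials.groupby("subject"):
            gaps = np.diff(sub["onset_sample"])
            assert np.all(gaps >= cfg.trial_spacing_s * cfg.fs)

    def test_too_short_recording_rejected(self):
        cfg = SimConfig(n_subjects=1)
        with pytest.raises(ValueError, match="need"):
            simulate_trials(cfg, 0, n_samples=100)


class TestResponses:
    @staticmethod
    def _trials(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "subject": "s00",
                "condition": "conservative",
                "S": rng.integers(0, 2, n),
            }
        )

    def test_null_betas_give_half_rate(self):
        trials = self._trials(10_000)
        Y = simulate_responses(
            trials, np.zeros(len(trials)), np.zeros(len(trials)),
            np.zeros(8), seed=0,
        )
        se = 0.5 / np.sqrt(len(trials))
        assert abs(Y.mean() - 0.5) < 3 * se

    def test_pure_sensitivity_beta(self):
        # b1=2: hit rate Phi(2), FA 0.5, d' = 2 by the closed form
        from alphastates.sdt import sdt_measures

        trials = self._trials(40_000, seed=1)
        beta = np.array([0, 2.0, 0, 0, 0, 0, 0, 0])
        Y = simulate_responses(
            trials, np.zeros(len(trials)), np.zeros(len(trials)), beta, seed=1
        )
        S = trials["S"].to_numpy()
        m = sdt_measures(
            int(Y[S == 1].sum()), int((1 - Y[S == 1]).sum()),
            int(Y[S == 0].sum()), int((1 - Y[S == 0]).sum()),
        )
        assert abs(m.hit_rate - norm.cdf(2)) < 0.01
        assert abs(m.fa_rate - 0.5) < 0.01
        assert abs(m.d_prime - 2.0) < 0.1

    def test_negative_power_slope_lowers_dprime_across_terciles(self):
        from alphastates.sdt import sdt_measures

        rng = np.random.default_rng(2)
        n = 60_000
        trials = self._trials(n, seed=2)
        P = rng.standard_normal(n)
        beta = np.array([0, 1.5, 0, 0, 0, -0.3, 0, 0])
        Y = simulate_responses(trials, P, np.zeros(n), beta, seed=2)
        S = trials["S"].to_numpy()
        edges = np.quantile(P, [1 / 3, 2 / 3])
        dps = []
        for lo, hi in [(-np.inf, edges[0]), (edges[0], edges[1]),
                       (edges[1], np.inf)]:
            m = (P >= lo) & (P < hi)
            dps.append(
                sdt_measures(
                    int(Y[m & (S == 1)].sum()),
                    int((1 - Y)[m & (S == 1)].sum()),
                    int(Y[m & (S == 0)].sum()),
                    int((1 - Y)[m & (S == 0)].sum()),
                ).d_prime
            )
        assert dps[0] > dps[1] > dps[2]

    def test_probit_round_trip_on_eta_grid(self):
        # empirical response frequency matches Phi(eta) at n=1e5
        rng = np.random.default_rng(3)
        for eta in (-1.5, -0.5, 0.0, 0.8, 2.0):
            n = 100_000
            trials = pd.DataFrame(
                {"subject": "s00", "condition": "c", "S": np.zeros(n, int)}
            )
            Y = simulate_responses(
                trials, np.zeros(n), np.zeros(n),
                np.array([eta, 0, 0, 0, 0, 0, 0, 0]), seed=int(rng.integers(1e6)),
            )
            p = norm.cdf(eta)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(Y.mean() - p) < 3 * se

    def test_wrong_beta_length_rejected(self):
        trials = self._trials(10)
        with pytest.raises(ValueError, match="8"):
            simulate_responses(
                trials, np.zeros(10), np.zeros(10), np.zeros(5), seed=0
            )

    def test_random_effects_applied_per_cell(self):
        cfg = SimConfig(n_subjects=4, subject_re_sd=(0.5, 0.5), seed=0)
        eff = draw_subject_effects(cfg, 0)
        assert set(eff.columns) == {"subject", "condition", "u0", "u1"}
        assert len(eff) == 4 * 2
        assert eff[["u0", "u1"]].std().min() > 0
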