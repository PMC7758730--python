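import warnings

import numpy as np
import pytest
from scipy import special

from conftest import pixel_periodogram_band_power
from wfstate.synthio import (
    SimConfig,
    build_truth,
    calibrate_amp_slope,
    generate_session,
    generate_trials,
    save_session,
    synthesize_movie,
)


def quiet_cfg(**kw):
    kw.setdefault("n_trials", 30)
    kw.setdefault("grid_size", 8)
    kw.setdefault("response_window_s", (1.5, 2.0))
    return SimConfig(**kw)


def gen(cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_session(cfg)


class TestConfigValidation:
    def test_rejects_inverted_range(self):
        with pytest.raises(ValueError, match="min"):
            SimConfig(quiescent_range_s=(2.0, 0.5)).validate()

    def test_rejects_all_excluded_quiescence(self):
        with pytest.raises(ValueError, match="0.7"):
            SimConfig(quiescent_range_s=(0.3, 0.6)).validate()

    def test_warns_on_partial_exclusion(self):
        with pytest.warns(UserWarning, match="excluded"):
            SimConfig(quiescent_range_s=(0.5, 2.0)).validate()

    def test_rejects_effect_without_outcome_coupling(self):
        with pytest.raises(ValueError, match="outcome_logit_slope"):
            SimConfig(outcome_logit_slope=0.0, band_power_effect_db=-1.5).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = quiet_cfg(seed=5, band_power_effect_db=-2.0)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg


class TestTrials:
    def test_quiescent_durations_inside_configured_range(self):
        cfg = quiet_cfg(n_trials=300, quiescent_range_s=(0.5, 2.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trials, _ = generate_trials(cfg)
        dur = trials.quiescent_end_s - trials.quiescent_start_s
        assert dur.min() >= 0.5 and dur.max() <= 2.0

    def test_event_ordering_invariants(self):
        trials, _ = generate_trials(quiet_cfg(n_trials=150, seed=2,
                                              quiescent_range_s=(0.8, 2.0)))
        assert (trials.iti_start_s < trials.quiescent_start_s).all()
        assert (trials.quiescent_start_s < trials.quiescent_end_s).all()
        assert (trials.quiescent_end_s <= trials.stim_onset_s).all()
        assert (trials.stim_onset_s < trials.gocue_s).all()
        responded = np.isfinite(trials.response_s)
        assert (trials.response_s[responded] > trials.gocue_s[responded]).all()
        assert (trials.response_s[responded]
                <= trials.response_window_end_s[responded]).all()

    def test_outcomes_consistent_with_contrasts(self):
        trials, _ = generate_trials(quiet_cfg(n_trials=200, seed=3,
                                              quiescent_range_s=(0.8, 2.0)))
        zero = (trials.contrast_left == 0) & (trials.contrast_right == 0)
        nogo = trials.outcome.isin(["CorrectReject", "FalseAlarm"])
        assert (zero == nogo).all()
        assert (trials.rewarded == trials.outcome.isin(
            ["CorrectChoice", "CorrectReject"])).all()

    def test_state_autocorrelation_matches_config(self):
        cfg = quiet_cfg(n_trials=4000, state_ar_coeff=0.8, seed=4,
                        quiescent_range_s=(0.8, 2.0))
        _, s = generate_trials(cfg)
        rho = np.corrcoef(s[:-1], s[1:])[0, 1]
        assert rho == pytest.approx(0.8, abs=0.05)

    def test_outcome_slope_sign_recovered_across_seeds(self):
        """Logistic fit of Miss on the true state recovers the slope sign."""
        import statsmodels.api as sm

        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = quiet_cfg(n_trials=200, seed=seed, quiescent_range_s=(0.8, 2.0))
            trials, s = generate_trials(cfg)
            stim = (trials.contrast_left > 0) | (trials.contrast_right > 0)
            keep = stim & trials.outcome.isin(
                ["Miss", "CorrectChoice", "IncorrectChoice"])
            y = (trials.outcome[keep] == "Miss").astype(float)
            X = sm.add_constant(s[keep.to_numpy()])
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            if fit.params[1] > 0:
                hits += 1
        assert hits >= int(0.95 * n_seeds)


class TestCalibration:
    def test_zero_effect_gives_zero_slope(self):
        assert calibrate_amp_slope(0.0, 1.5, 0.3) == 0.0

    def test_calibrated_slope_satisfies_the_moment_equation(self):
        """Independent quadrature check of the calibration target."""
        alpha = calibrate_amp_slope(-1.5, 1.5, 0.3)
        # dense-grid integration, independent of the Gauss-Hermite path
        s = np.linspace(-8, 8, 200_001)
        phi = np.exp(-0.5 * s**2)
        phi /= phi.sum()
        from wfstate.synthio import _solve_base_logit

        p_miss = special.expit(_solve_base_logit(1.5, 0.3) + 1.5 * s)
        g = 10 ** (alpha * s / 10)
        e_miss = np.sum(phi * p_miss * g) / np.sum(phi * p_miss)
        e_choice = np.sum(phi * (1 - p_miss) * g) / np.sum(phi * (1 - p_miss))
        assert 10 * np.log10(e_choice / e_miss) == pytest.approx(-1.5, abs=1e-6)


class TestMovie:
    def test_seed_determinism_is_bitwise(self):
        a = gen(quiet_cfg(seed=11))
        b = gen(quiet_cfg(seed=11))
        np.testing.assert_array_equal(a[0].calcium_frames, b[0].calcium_frames)
        np.testing.assert_array_equal(a[0].hemo_frames, b[0].hemo_frames)
        assert a[1].equals(b[1])
        np.testing.assert_array_equal(a[2].spike_times_s, b[2].spike_times_s)
        np.testing.assert_array_equal(a[3].diameter, b[3].diameter)

    def test_channel_clocks_interleave_by_half_frame(self):
        movie = gen(quiet_cfg(seed=12))[0]
        dt = np.abs(movie.timestamps_cal - movie.timestamps_hemo)
        np.testing.assert_allclose(dt, 1 / (2 * movie.fs), atol=1e-12)
        assert np.all(np.diff(movie.timestamps_cal) > 0)

    def test_no_artifact_config_leaves_heartbeat_band_at_noise_floor(self):
        cfg = quiet_cfg(seed=13, hemo_gain_map_scale=0.0)
        movie = gen(cfg)[0]
        sl = slice(0, movie.calcium_frames.shape[1])
        p_hb = pixel_periodogram_band_power(movie.calcium_frames, movie.fs, sl, (9, 13))
        # white-noise floor: sigma^2 * n * band fraction
        n = movie.calcium_frames.shape[1]
        nyq = movie.fs / 2
        floor = cfg.noise_sd**2 * n * 4.0 / nyq
        assert np.median(p_hb) < 3 * floor

    def test_noise_free_single_mode_movie_is_rank_one(self):
        cfg = quiet_cfg(seed=14, noise_sd=0.0, slow_amp=0.0, stim_amp=0.0,
                        hemo_gain_map_scale=0.0, hemo_artifact_amp=0.0)
        trials, s = generate_trials(cfg)
        truth = build_truth(cfg, trials, s)
        movie = synthesize_movie(truth, trials, cfg)
        sv = np.linalg.svd(movie.calcium_frames, compute_uv=False)
        assert sv[1] < 1e-10 * sv[0]

    def test_doubling_amplitude_quadruples_band_power(self):
        """Amplitude-power square law: 2x amplitude = +6.02 dB, via the
        pixel-space periodogram oracle."""
        base = dict(seed=15, noise_sd=0.0, slow_amp=0.0, stim_amp=0.0,
                    hemo_artifact_amp=0.0, hemo_gain_map_scale=0.0)
        m1 = None
        powers = {}
        for amp in (1.0, 2.0):
            cfg = quiet_cfg(amp_3_6=amp, **base)
            trials, s = generate_trials(cfg)
            truth = build_truth(cfg, trials, s)
            movie = synthesize_movie(truth, trials, cfg)
            sl = slice(0, movie.calcium_frames.shape[1])
            powers[amp] = pixel_periodogram_band_power(
                movie.calcium_frames, movie.fs, sl, (3, 6))
        ratio = powers[2.0] / powers[1.0]
        np.testing.assert_allclose(10 * np.log10(ratio), 6.0206, atol=1e-6)

    def test_null_config_power_unrelated_to_outcome(self):
        """With zero effect and zero outcome coupling, Choice and Miss
        quiescent-power distributions are statistically indistinguishable."""
        from scipy.stats import mannwhitneyu

        pvals = []
        for seed in range(10):
            cfg = quiet_cfg(n_trials=60, seed=seed, outcome_logit_slope=0.0,
                            band_power_effect_db=0.0, state_amp_db_slope=4.0,
                            quiescent_range_s=(0.8, 2.0))
            movie, trials, _, _, _ = gen(cfg)
            powers = []
            for _, tr in trials.iterrows():
                i0 = int(tr.quiescent_start_s * movie.fs)
                i1 = int(tr.quiescent_end_s * movie.fs)
                p = pixel_periodogram_band_power(
                    movie.calcium_frames[20:21], movie.fs, slice(i0, i1), (3, 6))[0]
                powers.append(p)
            powers = np.asarray(powers)
            is_miss = (trials.outcome == "Miss").to_numpy()
            is_choice = trials.outcome.isin(
                ["CorrectChoice", "IncorrectChoice"]).to_numpy()
            if is_miss.sum() >= 3 and is_choice.sum() >= 3:
                pvals.append(mannwhitneyu(powers[is_choice], powers[is_miss]).pvalue)
        pvals = np.asarray(pvals)
        assert np.mean(pvals < 0.05) <= 0.3
        assert 0.15 < pvals.mean() < 0.9


class TestSpikes:
    def test_tuned_units_fire_only_post_stimulus(self):
        movie, trials, spikes, _, _ = gen(quiet_cfg(seed=16))
        tuned = spikes.cluster_ids >= spikes.meta["n_mua_clusters"]
        t_tuned = spikes.spike_times_s[tuned]
        onsets = trials.stim_onset_s.to_numpy()
        # every tuned spike lies in some trial's 50-150 ms response window
        ok = np.zeros(t_tuned.size, dtype=bool)
        for t0 in onsets:
            ok |= (t_tuned >= t0 + 0.05) & (t_tuned <= t0 + 0.15)
        assert ok.all()

    def test_spike_times_sorted_and_clusters_declared(self):
        _, _, spikes, _, _ = gen(quiet_cfg(seed=17))
        assert np.all(np.diff(spikes.spike_times_s) >= 0)
        assert spikes.cluster_ids.max() < spikes.cluster_depths_um.size

    def test_zero_coupling_gives_no_fluorescence_coherence(self):
        from wfstate.ephys import bin_and_smooth_mua, coherence_spectrum

        cfg = quiet_cfg(n_trials=60, seed=18, spike_coupling_gain=0.0)
        movie, trials, spikes, _, truth = gen(cfg)
        mua_ids = spikes.cluster_ids < spikes.meta["n_mua_clusters"]
        mua = bin_and_smooth_mua(spikes.spike_times_s[mua_ids], 0,
                                 movie.timestamps_cal[-1], fs_out=movie.fs,
                                 smoothing_sd_s=0.0)
        g = cfg.grid_size
        pix = truth.coupling_pixel[0] * g + truth.coupling_pixel[1]
        f = movie.calcium_frames[pix][: mua.rate.size]
        coh = coherence_spectrum(mua.rate, f, movie.fs, segment_s=2.0)
        lowf = coh.freqs_hz <= 6
        # independence: mean coherence near the 1/n_segments bias floor
        assert coh.coherence[lowf].mean() < 3.0 / coh.n_segments + 0.05

    def test_high_coupling_gives_lowpass_coherence_profile(self):
        from wfstate.ephys import bin_and_smooth_mua, coherence_spectrum

        cfg = quiet_cfg(n_trials=120, seed=19, spike_coupling_gain=1.0,
                        mua_base_rate_hz=600.0, noise_sd=0.01, slow_amp=1.5,
                        hemo_gain_map_scale=0.0, hemo_artifact_amp=0.0)
        movie, trials, spikes, _, truth = gen(cfg)
        mua_ids = spikes.cluster_ids < spikes.meta["n_mua_clusters"]
        mua = bin_and_smooth_mua(spikes.spike_times_s[mua_ids], 0,
                                 movie.timestamps_cal[-1], fs_out=movie.fs,
                                 smoothing_sd_s=0.0)
        g = cfg.grid_size
        pix = truth.coupling_pixel[0] * g + truth.coupling_pixel[1]
        f = movie.calcium_frames[pix][: mua.rate.size]
        coh = coherence_spectrum(mua.rate, f, movie.fs, segment_s=4.0)
        low = (coh.freqs_hz >= 0.5) & (coh.freqs_hz <= 6)
        high = coh.freqs_hz >= 10
        assert coh.coherence[low].mean() > 0.8
        assert coh.coherence[high].mean() < coh.coherence[low].mean() - 0.3


class TestPupil:
    def test_pupil_tracks_state_with_configured_sign(self):
        cfg = quiet_cfg(n_trials=200, seed=20, pupil_state_corr=-0.5,
                        quiescent_range_s=(0.8, 2.0))
        movie, trials, _, pupil, truth = gen(cfg)
        r = np.corrcoef(pupil.diameter, truth.latent_state)[0, 1]
        assert -0.75 < r < -0.25
        dt = np.diff(pupil.timestamps_s).mean()
        np.testing.assert_allclose(
            pupil.derivative[1:-1],
            (pupil.diameter[2:] - pupil.diameter[:-2]) / (2 * dt), rtol=1e-6)


def test_save_session_writes_expected_files(tmp_path):
    cfg = quiet_cfg(seed=21, n_trials=10)
    movie, trials, spikes, pupil, _ = gen(cfg)
    save_session(tmp_path, movie, trials, spikes, pupil, config=cfg)
    for name in ("movie.h5", "spikes.h5", "trials.csv", "pupil.csv", "config.yaml"):
        assert (tmp_path / name).exists()
    import h5py

    with h5py.File(tmp_path / "movie.h5") as f:
        assert f["calcium"].shape == movie.calcium_frames.shape
    with h5py.File(tmp_path / "spikes.h5") as f:
        assert f["spikes/times"].shape == spikes.spike_times_s.shape
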