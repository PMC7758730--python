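"""Synthetic widefield decision-making sessions with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without real recordings:

- dual-channel (calcium-dependent / calcium-independent) movies at 35 Hz per
  channel with alternate-frame illumination (the two clocks interleave, offset
  by half a frame period);
- a trial structure with a pre-trial baseline, an enforced quiescent period of
  0.5-2.0 s (uniform), a go cue 0.3-0.8 s after stimulus onset and a
  1.5-5 s response window;
- a latent synchronization state (lag-1 autoregressive across trials, held
  constant within each trial) that modulates 3-6 Hz fluorescence power and the
  outcome probabilities (Miss / False Alarm log-odds);
- a narrowband heartbeat-frequency (default 11 Hz) hemodynamic artifact,
  injected into the calcium channel through a per-pixel gain map and present
  gain-free in the hemodynamic channel;
- multiunit spiking whose rate follows the fluorescence at one pixel low-pass
  filtered below 8 Hz, plus contrast-tuned transient units 50-150 ms after
  stimulus onset for decoder tests; and
- a pupil trace correlated with the latent state.

The 3-6 Hz component is narrowband-filtered Gaussian noise (irregular and
rhythmic, like cortical low-frequency activity) rather than a pure sinusoid.
The per-trial amplitude slope on the latent state is calibrated numerically so
that the generative Choice-Miss power ratio equals ``band_power_effect_db``
exactly under the configured outcome model.

All randomness descends from one root seed through named child streams
(state / trials / movie / spikes / pupil), so identical seeds give
bit-identical sessions and each part can be regenerated independently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, signal, special

__all__ = [
    "SimConfig",
    "SimTruth",
    "WidefieldMovie",
    "SpikeData",
    "PupilTrace",
    "generate_session",
    "generate_trials",
    "synthesize_movie",
    "generate_spike_data",
    "generate_pupil",
    "calibrate_amp_slope",
    "OUTCOMES",
]

OUTCOMES = ("CorrectChoice", "IncorrectChoice", "Miss", "CorrectReject", "FalseAlarm")

# named child streams off the root seed
_STREAMS = {"state": 0, "trials": 1, "movie": 2, "spikes": 3, "pupil": 4}


@dataclass
class SimConfig:
    """Parameters of a synthetic session.  All times in seconds."""

    grid_size: int = 16
    fs_channel: float = 35.0
    n_trials: int = 100
    iti_pre_range_s: tuple[float, float] = (0.5, 3.0)     # baseline before quiescence
    quiescent_range_s: tuple[float, float] = (0.5, 2.0)
    gocue_delay_range_s: tuple[float, float] = (0.3, 0.8)
    response_window_s: tuple[float, float] = (1.5, 5.0)
    feedback_s: float = 0.5
    contrast_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0)
    p_bilateral: float = 0.15        # fraction of trials with contrast on both sides

    # latent synchronization state and its couplings
    state_ar_coeff: float = 0.8
    band_power_effect_db: float = -1.5   # target Choice - Miss 3-6 Hz difference
    outcome_logit_slope: float = 1.5     # effect of state on Miss log-odds
    miss_base_rate: float = 0.30
    false_alarm_base_rate: float = 0.35
    state_amp_db_slope: float | None = None   # dB per state unit; None = calibrated

    # movie composition (a.u.)
    amp_3_6: float = 1.0
    slow_amp: float = 0.4
    stim_amp: float = 1.0
    noise_sd: float = 0.05
    hemo_gain_map_scale: float = 1.0
    hemo_artifact_amp: float = 0.5
    heartbeat_hz: float = 11.0

    # spiking / LFP
    spike_coupling_gain: float = 1.0
    mua_base_rate_hz: float = 60.0
    n_mua_clusters: int = 16
    n_tuned_units: int = 8
    tuned_base_rate_hz: float = 2.0
    tuned_rate_gain_hz: float = 60.0
    lfp_fs: float = 100.0
    lfp_noise_sd: float = 0.2

    # pupil and reaction times
    pupil_state_corr: float = -0.5
    rt_base_s: float = 0.4
    rt_state_slope: float = 0.15
    rt_noise_sd: float = 0.08

    session_id: str = "sim00"
    subject_id: str = "m00"
    genotype_id: str = "g0"
    seed: int = 0

    def validate(self) -> None:
        for name in ("iti_pre_range_s", "quiescent_range_s",
                     "gocue_delay_range_s", "response_window_s"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if self.fs_channel <= 12.0:
            raise ValueError("fs_channel must exceed 12 Hz (2 x 6 Hz band edge)")
        if not all(0.0 <= c <= 1.0 for c in self.contrast_levels):
            raise ValueError("contrast levels must be fractions in [0, 1]")
        if self.quiescent_range_s[1] < 0.7:
            raise ValueError(
                "quiescent_range_s max < 0.7 s: every trial would be excluded "
                "by the downstream minimum-duration rule"
            )
        if self.quiescent_range_s[0] < 0.7:
            warnings.warn(
                "quiescent minimum < 0.7 s: some trials will be excluded downstream",
                stacklevel=2,
            )
        if self.outcome_logit_slope == 0 and self.band_power_effect_db != 0 \
                and self.state_amp_db_slope is None:
            raise ValueError(
                "band_power_effect_db != 0 requires outcome_logit_slope != 0 "
                "(or an explicit state_amp_db_slope)"
            )

    def rng(self, stream: str) -> np.random.Generator:
        """Named child stream of the root seed."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class SimTruth:
    """Generative ground truth for parameter-recovery tests."""

    latent_state: np.ndarray        # per calcium frame
    state_per_trial: np.ndarray
    hemo_gain_map: np.ndarray       # (rows, cols)
    true_effect_db: float
    true_outcome_slope: float
    amp_db_slope: float             # calibrated dB-per-state-unit amplitude slope
    spatial_modes: dict             # name -> (rows, cols) map
    coupling_pixel: tuple[int, int]
    stim_center_right: tuple[int, int]
    stim_center_left: tuple[int, int]


@dataclass
class WidefieldMovie:
    """Dual-channel pixel x time movie with interleaved clocks."""

    calcium_frames: np.ndarray      # (pixels, t)
    hemo_frames: np.ndarray         # (pixels, t)
    timestamps_cal: np.ndarray
    timestamps_hemo: np.ndarray
    fs: float
    pixel_shape: tuple[int, int]


@dataclass
class SpikeData:
    spike_times_s: np.ndarray       # sorted ascending
    cluster_ids: np.ndarray
    cluster_depths_um: np.ndarray   # one depth per declared cluster
    lfp: np.ndarray                 # (channels, t)
    lfp_fs: float
    lfp_timestamps_s: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class PupilTrace:
    timestamps_s: np.ndarray
    diameter: np.ndarray
    derivative: np.ndarray


# ---------------------------------------------------------------------------
# calibration of the state -> amplitude coupling


def _gauss_hermite(n: int = 101):
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / w.sum()


def _solve_base_logit(slope: float, target_rate: float) -> float:
    """Intercept b0 with marginal rate E_s[sigmoid(b0 + slope*s)] = target."""
    x, w = _gauss_hermite()

    def marginal(b0):
        return float(np.sum(w * special.expit(b0 + slope * x))) - target_rate

    return optimize.brentq(marginal, -20.0, 20.0)


def calibrate_amp_slope(effect_db: float, outcome_slope: float,
                        base_rate: float) -> float:
    """Amplitude slope alpha (dB per state unit) hitting the target effect.

    Per-trial 3-6 Hz power scales as ``10**(alpha*s/10)`` with the latent
    state ``s ~ N(0, 1)``; Miss probability is ``sigmoid(b0 + beta*s)``.  The
    pipeline's effect estimate is the dB ratio of condition-mean powers, so we
    solve (by bisection over Gauss-Hermite quadrature)::

        10*log10( E[10**(alpha*s/10) | Choice] / E[10**(alpha*s/10) | Miss] )
            = effect_db
    """
    if effect_db == 0:
        return 0.0
    b0 = _solve_base_logit(outcome_slope, base_rate)
    x, w = _gauss_hermite()
    p_miss = special.expit(b0 + outcome_slope * x)

    def f(alpha):
        g = 10.0 ** (alpha * x / 10.0)
        e_miss = np.sum(w * p_miss * g) / np.sum(w * p_miss)
        e_choice = np.sum(w * (1 - p_miss) * g) / np.sum(w * (1 - p_miss))
        return 10.0 * np.log10(e_choice / e_miss) - effect_db

    return optimize.brentq(f, -60.0, 60.0)


# ---------------------------------------------------------------------------
# trials


def generate_trials(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Trial event table plus the per-trial latent state.

    The latent state is a stationary lag-1 autoregressive sequence across
    trials (unit marginal variance).  Outcomes are drawn from logistic models
    on the state: Miss on stimulus-present trials, False Alarm on zero-
    contrast trials (with opposite state sign: desynchronization promotes
    responding).
    """
    config.validate()
    rng_state = config.rng("state")
    rng = config.rng("trials")
    n = config.n_trials

    # latent state, AR(1), stationary N(0,1)
    phi = config.state_ar_coeff
    innov = rng_state.standard_normal(n)
    s = np.empty(n)
    s[0] = innov[0]
    for j in range(1, n):
        s[j] = phi * s[j - 1] + np.sqrt(1.0 - phi**2) * innov[j]

    beta = config.outcome_logit_slope
    b0_miss = _solve_base_logit(beta, config.miss_base_rate)
    b0_fa = _solve_base_logit(beta, config.false_alarm_base_rate)

    levels = np.asarray(config.contrast_levels, dtype=float)
    nonzero = levels[levels > 0]
    resp_window = rng.uniform(*config.response_window_s)

    rows = []
    cursor = 1.0
    for j in range(n):
        iti_pre = rng.uniform(*config.iti_pre_range_s)
        quiescent = rng.uniform(*config.quiescent_range_s)
        gocue_delay = rng.uniform(*config.gocue_delay_range_s)

        iti_start = cursor
        q_start = iti_start + iti_pre
        stim_onset = q_start + quiescent
        gocue = stim_onset + gocue_delay

        # stimulus contrasts
        c_left = c_right = 0.0
        if rng.uniform() < config.p_bilateral and nonzero.size:
            c_left = float(rng.choice(nonzero))
            c_right = float(rng.choice(nonzero))
        else:
            c = float(rng.choice(levels))
            if rng.uniform() < 0.5:
                c_left = c
            else:
                c_right = c

        stim_present = (c_left > 0) or (c_right > 0)
        response_s = np.nan
        direction = 0
        reward_side = 0
        if stim_present:
            if c_right > c_left:
                correct_side = 1
            elif c_left > c_right:
                correct_side = -1
            else:
                correct_side = int(rng.choice([-1, 1]))  # equal contrasts: random reward
                reward_side = correct_side
            p_miss = special.expit(b0_miss + beta * s[j])
            if rng.uniform() < p_miss:
                outcome = "Miss"
            else:
                c_max = max(c_left, c_right)
                p_correct = 0.55 + 0.44 * np.sqrt(c_max)
                chose_correct = rng.uniform() < p_correct
                direction = correct_side if chose_correct else -correct_side
                outcome = "CorrectChoice" if direction == correct_side else "IncorrectChoice"
                rt = (config.rt_base_s + config.rt_state_slope * s[j]
                      + 0.3 * (1.0 - c_max) + config.rt_noise_sd * rng.standard_normal())
                rt = float(np.clip(rt, 0.05, resp_window - 1e-3))
                response_s = gocue + rt
        else:
            p_fa = special.expit(b0_fa - beta * s[j])
            if rng.uniform() < p_fa:
                outcome = "FalseAlarm"
                direction = int(rng.choice([-1, 1]))
                rt = (config.rt_base_s + config.rt_state_slope * s[j]
                      + config.rt_noise_sd * rng.standard_normal())
                rt = float(np.clip(rt, 0.05, resp_window - 1e-3))
                response_s = gocue + rt
            else:
                outcome = "CorrectReject"

        trial_end = response_s if np.isfinite(response_s) else gocue + resp_window
        rewarded = outcome in ("CorrectChoice", "CorrectReject")
        rows.append(dict(
            trial=j,
            iti_start_s=iti_start,
            quiescent_start_s=q_start,
            quiescent_end_s=stim_onset,
            stim_onset_s=stim_onset,
            gocue_s=gocue,
            response_s=response_s,
            response_window_end_s=gocue + resp_window,
            response_direction=direction,
            contrast_left=c_left,
            contrast_right=c_right,
            reward_side=reward_side,
            outcome=outcome,
            rewarded=rewarded,
            reaction_time_s=(response_s - gocue if np.isfinite(response_s)
                             else np.nan),
            session_id=config.session_id,
            subject_id=config.subject_id,
            genotype_id=config.genotype_id,
        ))
        cursor = trial_end + config.feedback_s

    return pd.DataFrame(rows), s


# ---------------------------------------------------------------------------
# movie


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Smooth Gaussian random field, unit SD."""
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return f / f.std()


def _gaussian_bump(shape, center, sigma) -> np.ndarray:
    r, c = np.mgrid[0:shape[0], 0:shape[1]]
    return np.exp(-(((r - center[0]) ** 2) + ((c - center[1]) ** 2)) / (2 * sigma**2))


def _bandlimited_noise(rng, n, fs, band, order=4) -> np.ndarray:
    x = rng.standard_normal(n)
    nyq = fs / 2.0
    lo = band[0] / nyq
    hi = min(band[1] / nyq, 0.99)
    if band[0] <= 0:
        sos = signal.butter(order, hi, btype="lowpass", output="sos")
    else:
        sos = signal.butter(order, [lo, hi], btype="bandpass", output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / y.std()


def _gcamp_kernel(fs: float, rise_s: float = 0.05, decay_s: float = 0.4) -> np.ndarray:
    """Sharp-rising / slow-decaying fluorescence impulse response."""
    t = np.arange(0, 6 * decay_s, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def build_truth(config: SimConfig, trials: pd.DataFrame,
                state_per_trial: np.ndarray) -> SimTruth:
    """Assemble ground truth (per-frame state, gain map, spatial modes)."""
    g = config.grid_size
    rng = config.rng("movie")
    shape = (g, g)

    # per-frame latent state on the calcium clock: each trial's value held
    # over its span, carried forward through inter-trial gaps
    duration = float(trials["response_window_end_s"].iloc[-1]) + 1.0
    n_frames = int(np.floor(duration * config.fs_channel))
    ts_cal = np.arange(n_frames) / config.fs_channel
    starts = trials["iti_start_s"].to_numpy()
    idx = np.searchsorted(starts, ts_cal, side="right") - 1
    latent = state_per_trial[np.clip(idx, 0, len(state_per_trial) - 1)]
    latent = np.where(idx < 0, state_per_trial[0], latent)

    state_mode = 0.7 + 0.3 * _gaussian_bump(shape, (g // 2, g // 2), g / 2.5)
    slow_mode = 0.6 + 0.4 * _gaussian_bump(shape, (g // 4, g // 4), g / 3.0)
    stim_center_right = (g // 4, g // 4)       # left-hemisphere visual cortex
    stim_center_left = (g // 4, 3 * g // 4)
    bump_r = _gaussian_bump(shape, stim_center_right, g / 8.0)
    bump_l = _gaussian_bump(shape, stim_center_left, g / 8.0)

    gain_map = config.hemo_gain_map_scale * np.clip(
        1.0 + 0.4 * _smooth_field(rng, shape, sigma=g / 8.0), 0.2, None
    )
    if config.hemo_gain_map_scale == 0:
        gain_map = np.zeros(shape)

    if config.state_amp_db_slope is not None:
        alpha = config.state_amp_db_slope
    elif config.outcome_logit_slope == 0:
        alpha = 0.0
    else:
        alpha = calibrate_amp_slope(
            config.band_power_effect_db,
            config.outcome_logit_slope,
            config.miss_base_rate,
        )

    return SimTruth(
        latent_state=latent,
        state_per_trial=state_per_trial,
        hemo_gain_map=gain_map,
        true_effect_db=config.band_power_effect_db,
        true_outcome_slope=config.outcome_logit_slope,
        amp_db_slope=alpha,
        spatial_modes={
            "state": state_mode,
            "slow": slow_mode,
            "stim_right": bump_r,
            "stim_left": bump_l,
        },
        coupling_pixel=(g // 4, g // 4),
        stim_center_right=stim_center_right,
        stim_center_left=stim_center_left,
    )


def synthesize_movie(truth: SimTruth, trials: pd.DataFrame,
                     config: SimConfig) -> WidefieldMovie:
    """Render both channels from the ground truth.

    calcium = state-modulated 3-6 Hz mode + slow background + stimulus
    transients (GCaMP-like kernel) + gain_map * heartbeat artifact + white
    noise; hemo = gain-free artifact copy + independent white noise.
    """
    fs = config.fs_channel
    rng = config.rng("movie")
    # burn the draws used by build_truth so movie noise is independent yet
    # reproducible: regenerate truth's stream consumption deterministically
    _ = _smooth_field(rng, (config.grid_size, config.grid_size),
                      sigma=config.grid_size / 8.0)

    n_frames = truth.latent_state.shape[0]
    ts_cal = np.arange(n_frames) / fs
    ts_hemo = ts_cal + 1.0 / (2.0 * fs)

    # temporal signals on the calcium clock
    osc = _bandlimited_noise(rng, n_frames, fs, (3.0, 6.0))
    amp = config.amp_3_6 * 10.0 ** (truth.amp_db_slope * truth.latent_state / 20.0)
    # broadband slow background up to the oscillation band edge, so the
    # fluorescence (and hence MUA coherence) has power at all <= 6 Hz
    slow = _bandlimited_noise(rng, n_frames, fs, (0.0, 3.0))

    kernel = _gcamp_kernel(fs)
    impulses_r = np.zeros(n_frames)
    impulses_l = np.zeros(n_frames)
    for _, tr in trials.iterrows():
        i = int(np.round(tr.stim_onset_s * fs))
        if 0 <= i < n_frames:
            impulses_r[i] += tr.contrast_right
            impulses_l[i] += tr.contrast_left
    resp_r = np.convolve(impulses_r, kernel)[:n_frames]
    resp_l = np.convolve(impulses_l, kernel)[:n_frames]

    # heartbeat-band artifact on the interleaved 2*fs clock, then split
    band = (config.heartbeat_hz - 1.0, config.heartbeat_hz + 1.0)
    fine = _bandlimited_noise(rng, 2 * n_frames, 2 * fs, band)
    h_cal = config.hemo_artifact_amp * fine[0::2]
    h_hemo = config.hemo_artifact_amp * fine[1::2]

    modes = truth.spatial_modes
    p = config.grid_size**2
    cal = (
        modes["state"].reshape(p, 1) * (amp * osc)[None, :]
        + config.slow_amp * modes["slow"].reshape(p, 1) * slow[None, :]
        + config.stim_amp * modes["stim_right"].reshape(p, 1) * resp_r[None, :]
        + config.stim_amp * modes["stim_left"].reshape(p, 1) * resp_l[None, :]
        + truth.hemo_gain_map.reshape(p, 1) * h_cal[None, :]
    )
    hemo = np.broadcast_to(h_hemo, (p, n_frames)).copy()
    if config.noise_sd > 0:
        cal = cal + config.noise_sd * rng.standard_normal((p, n_frames))
        hemo = hemo + config.noise_sd * rng.standard_normal((p, n_frames))

    return WidefieldMovie(
        calcium_frames=cal,
        hemo_frames=hemo,
        timestamps_cal=ts_cal,
        timestamps_hemo=ts_hemo,
        fs=fs,
        pixel_shape=(config.grid_size, config.grid_size),
    )


# ---------------------------------------------------------------------------
# spikes / LFP / pupil


def generate_spike_data(truth: SimTruth, movie: WidefieldMovie,
                        trials: pd.DataFrame, config: SimConfig) -> SpikeData:
    """Spikes from an inhomogeneous Poisson process coupled to fluorescence.

    The MUA rate follows the calcium trace at ``truth.coupling_pixel``
    low-pass filtered below 8 Hz.  Rates driven negative by the coupling are
    clipped to zero (the clipped fraction is recorded in ``meta``).  A set of
    contrast-tuned units fires transiently 50-150 ms after stimulus onset for
    decoder tests.  The LFP is the rate trace resampled plus noise.
    """
    if config.spike_coupling_gain < 0:
        raise ValueError("spike_coupling_gain must be >= 0")
    rng = config.rng("spikes")
    fs = movie.fs
    g = config.grid_size
    pix = truth.coupling_pixel[0] * g + truth.coupling_pixel[1]
    f = movie.calcium_frames[pix]
    nyq = fs / 2.0
    sos = signal.butter(4, 8.0 / nyq, btype="lowpass", output="sos")
    f_lp = signal.sosfiltfilt(sos, f - f.mean())
    scale = f_lp.std() or 1.0

    rate = config.mua_base_rate_hz * (
        1.0 + config.spike_coupling_gain * f_lp / scale
    )
    clipped = float(np.mean(rate < 0))
    if clipped > 0:
        logging.getLogger(__name__).info(
            "spike coupling drove the rate negative in %.1f%% of frames; clipped",
            100 * clipped,
        )
    rate = np.maximum(rate, 0.0)

    counts = rng.poisson(rate / fs)
    times = []
    clusters = []
    ts = movie.timestamps_cal
    dt = 1.0 / fs
    nz = np.nonzero(counts)[0]
    for i in nz:
        times.append(ts[i] + dt * rng.uniform(size=counts[i]))
        clusters.append(rng.integers(0, config.n_mua_clusters, size=counts[i]))
    # contrast-tuned transient units (state-independent stimulus coding)
    for _, tr in trials.iterrows():
        c = tr.contrast_right  # decode contralateral (right-field) stimulus
        t0 = tr.stim_onset_s + 0.05
        t1 = tr.stim_onset_s + 0.15
        for u in range(config.n_tuned_units):
            lam = (config.tuned_base_rate_hz
                   + config.tuned_rate_gain_hz * c) * (t1 - t0)
            n_sp = rng.poisson(lam)
            if n_sp:
                times.append(t0 + (t1 - t0) * rng.uniform(size=n_sp))
                clusters.append(np.full(n_sp, config.n_mua_clusters + u))

    times = np.concatenate(times) if times else np.empty(0)
    clusters = np.concatenate(clusters) if clusters else np.empty(0, dtype=int)
    order = np.argsort(times, kind="stable")
    times = times[order]
    clusters = clusters[order].astype(int)

    n_clusters = config.n_mua_clusters + config.n_tuned_units
    depths = rng.uniform(100.0, 900.0, size=n_clusters)

    lfp_ts = np.arange(0, ts[-1], 1.0 / config.lfp_fs)
    lfp = np.interp(lfp_ts, ts, rate / config.mua_base_rate_hz - 1.0)
    lfp = lfp + config.lfp_noise_sd * rng.standard_normal(lfp.shape)

    return SpikeData(
        spike_times_s=times,
        cluster_ids=clusters,
        cluster_depths_um=depths,
        lfp=lfp[None, :],
        lfp_fs=config.lfp_fs,
        lfp_timestamps_s=lfp_ts,
        meta={"clipped_rate_fraction": clipped,
              "n_mua_clusters": config.n_mua_clusters,
              "n_tuned_units": config.n_tuned_units},
    )


def generate_pupil(truth: SimTruth, config: SimConfig) -> PupilTrace:
    """Pupil diameter = rho * state + sqrt(1-rho^2) * slow independent noise."""
    rng = config.rng("pupil")
    rho = config.pupil_state_corr
    n = truth.latent_state.shape[0]
    noise = _bandlimited_noise(rng, n, config.fs_channel, (0.0, 0.5))
    z = rho * truth.latent_state + np.sqrt(max(0.0, 1 - rho**2)) * noise
    ts = np.arange(n) / config.fs_channel
    diameter = 3.0 + 0.5 * z
    deriv = np.gradient(diameter, ts)
    return PupilTrace(timestamps_s=ts, diameter=diameter, derivative=deriv)


def generate_session(config: SimConfig):
    """Full synthetic session.

    Returns ``(movie, trials, spikes, pupil, truth)``.  Identical seeds give
    bit-identical outputs.
    """
    trials, s = generate_trials(config)
    truth = build_truth(config, trials, s)
    movie = synthesize_movie(truth, trials, config)
    spikes = generate_spike_data(truth, movie, trials, config)
    pupil = generate_pupil(truth, config)
    return movie, trials, spikes, pupil, truth


# ---------------------------------------------------------------------------
# persistence


def save_session(out_dir, movie: WidefieldMovie, trials: pd.DataFrame,
                 spikes: SpikeData, pupil: PupilTrace,
                 config: SimConfig | None = None) -> None:
    """Write the session to disk (HDF5 for movie/spikes, CSV for tables)."""
    import os

    import h5py

    os.makedirs(out_dir, exist_ok=True)
    with h5py.File(os.path.join(out_dir, "movie.h5"), "w") as f:
        f.create_dataset("calcium", data=movie.calcium_frames)
        f.create_dataset("hemo", data=movie.hemo_frames)
        f.create_dataset("timestamps_cal", data=movie.timestamps_cal)
        f.create_dataset("timestamps_hemo", data=movie.timestamps_hemo)
        f.attrs["fs"] = movie.fs
        f.attrs["pixel_shape"] = movie.pixel_shape
    with h5py.File(os.path.join(out_dir, "spikes.h5"), "w") as f:
        sp = f.create_group("spikes")
        sp.create_dataset("times", data=spikes.spike_times_s)
        sp.create_dataset("clusters", data=spikes.cluster_ids)
        sp.create_dataset("depths", data=spikes.cluster_depths_um)
        f.create_dataset("lfp", data=spikes.lfp)
        f.create_dataset("lfp_timestamps", data=spikes.lfp_timestamps_s)
        f.attrs["lfp_fs"] = spikes.lfp_fs
    trials.to_csv(os.path.join(out_dir, "trials.csv"), index=False)
    pd.DataFrame({
        "timestamps_s": pupil.timestamps_s,
        "diameter": pupil.diameter,
        "derivative": pupil.derivative,
    }).to_csv(os.path.join(out_dir, "pupil.csv"), index=False)
    if config is not None:
        config.to_yaml(os.path.join(out_dir, "config.yaml"))
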