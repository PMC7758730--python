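"""Spike/LFP state measures and the imaging-electrophysiology bridge.

Multiunit activity (MUA) is binned at the imaging rate (35 Hz) and smoothed
with a Gaussian window so its 3-6 Hz band power can be analyzed exactly like
the fluorescence.  The module also provides: light-artifact removal from the
LFP by running-median template subtraction, the per-trial Fano factor of
summed population spike counts, Welch magnitude-squared coherence,
cross-frequency power correlation, and a ridge-regularized spatiotemporal
filter predicting MUA from the compressed movie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from wfstate.svdstore import SVDStore

__all__ = [
    "MuaTrace",
    "FanoResult",
    "CoherenceSpectrum",
    "bin_and_smooth_mua",
    "remove_light_artifact",
    "fano_factor",
    "coherence_spectrum",
    "crossfreq_power_correlation",
    "fit_spike_prediction_filter",
]


@dataclass
class MuaTrace:
    rate: np.ndarray           # spikes/s, Gaussian-smoothed
    timestamps_s: np.ndarray
    smoothing_sd_s: float
    bin_counts: np.ndarray     # pre-smoothing counts (conserve total spikes)


@dataclass
class FanoResult:
    """Per-trial Fano factor F = var(X)/mean(X) of population spike counts."""

    fano: np.ndarray           # NaN where mean count is zero (flagged)
    mean_count: np.ndarray
    var_count: np.ndarray
    windows: list
    undefined: np.ndarray      # True where F is undefined


@dataclass
class CoherenceSpectrum:
    freqs_hz: np.ndarray
    coherence: np.ndarray      # in [0, 1]
    n_segments: int
    signal_pair: tuple[str, str] = ("x", "y")


def bin_and_smooth_mua(
    spike_times_s: np.ndarray,
    t_start: float,
    t_end: float,
    fs_out: float = 35.0,
    smoothing_sd_s: float = 0.025,
) -> MuaTrace:
    """Histogram spikes at 1/fs_out bins, convert to rate, Gaussian-smooth.

    The smoothing kernel is normalized so the mean rate is preserved; the
    pre-smoothing bin counts conserve the total spike count within
    ``[t_start, t_end)`` exactly.
    """
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    edges = np.arange(t_start, t_end + 0.5 / fs_out, 1.0 / fs_out)
    if len(edges) < 2:
        raise ValueError("empty binning range")
    counts, _ = np.histogram(spike_times_s, bins=edges)
    if counts.sum() == 0:
        warnings.warn("no spikes in the binning range", stacklevel=2)
    rate = counts * fs_out
    if smoothing_sd_s > 0:
        from scipy.ndimage import gaussian_filter1d

        # circular boundary keeps the normalized kernel mass inside the
        # trace, so the mean rate is preserved exactly
        rate = gaussian_filter1d(rate.astype(float), smoothing_sd_s * fs_out,
                                 mode="wrap")
    centers = edges[:-1] + 0.5 / fs_out
    return MuaTrace(rate=rate, timestamps_s=centers,
                    smoothing_sd_s=smoothing_sd_s, bin_counts=counts)


def remove_light_artifact(
    lfp: np.ndarray,
    fs: float,
    light_onsets_s: np.ndarray,
    segment_s: float | None = None,
    n_median: int = 500,
) -> np.ndarray:
    """Subtract the illumination-pulse artifact template from an LFP trace.

    Per onset the trace segment is aligned and its baseline (the sample
    before onset) subtracted; a running median over ``n_median`` pulses forms
    the artifact template, which is subtracted at each onset.  Pulses of one
    illumination color only should be passed per call.  Onsets closer than
    the segment length are handled by truncating the subtraction, with a
    warning.
    """
    lfp = np.asarray(lfp, dtype=float)
    onsets = np.asarray(light_onsets_s, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one light onset")
    if segment_s is None:
        gaps = np.diff(np.sort(onsets))
        segment_s = float(np.median(gaps)) if gaps.size else 0.02
    seg_len = max(1, int(round(segment_s * fs)))
    idx = np.round(onsets * fs).astype(int)
    idx = idx[(idx >= 1) & (idx + seg_len <= lfp.size)]
    if idx.size == 0:
        raise ValueError("no onset with a full segment inside the trace")
    gaps_samp = np.diff(idx)
    if np.any(gaps_samp < seg_len):
        warnings.warn("onsets closer than the segment length; subtraction truncated",
                      stacklevel=2)

    segs = np.stack([lfp[i:i + seg_len] - lfp[i - 1] for i in idx])
    templates = (
        pd.DataFrame(segs)
        .rolling(n_median, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    cleaned = lfp.copy()
    for j, i in enumerate(idx):
        stop = i + seg_len
        if j + 1 < len(idx):
            stop = min(stop, idx[j + 1])  # truncate at the next onset
        cleaned[i:stop] -= templates[j, : stop - i]
    return cleaned


def fano_factor(
    spike_times_s: np.ndarray,
    windows: list[tuple[float, float]],
    sub_bin_s: float = 1.0 / 35.0,
) -> FanoResult:
    """Per-trial Fano factor of summed population activity.

    Within each window, population spike counts are taken over sub-bins of
    duration ``sub_bin_s`` tiling the window, and ``F = var(X)/mean(X)`` with
    the sample variance (n-1 denominator).  Windows with zero mean count are
    flagged undefined (NaN).
    """
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    fano = np.empty(len(windows))
    means = np.empty(len(windows))
    vars_ = np.empty(len(windows))
    undef = np.zeros(len(windows), dtype=bool)
    for i, (t0, t1) in enumerate(windows):
        n_bins = int(np.floor((t1 - t0) / sub_bin_s))
        if n_bins < 2:
            fano[i] = np.nan
            means[i] = vars_[i] = np.nan
            undef[i] = True
            continue
        edges = t0 + sub_bin_s * np.arange(n_bins + 1)
        counts, _ = np.histogram(spike_times_s, bins=edges)
        m = counts.mean()
        v = counts.var(ddof=1)
        means[i], vars_[i] = m, v
        if m == 0:
            fano[i] = np.nan
            undef[i] = True
        else:
            fano[i] = v / m
    return FanoResult(fano=fano, mean_count=means, var_count=vars_,
                      windows=list(windows), undefined=undef)


def coherence_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    segment_s: float = 2.0,
    labels: tuple[str, str] = ("x", "y"),
) -> CoherenceSpectrum:
    """Welch magnitude-squared coherence (Hann taper, 50% overlap)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length (resample upstream)")
    nperseg = int(round(segment_s * fs))
    n_segments = max(0, (x.size - nperseg // 2) // (nperseg // 2))
    if n_segments < 2:
        raise ValueError("fewer than 2 segments: coherence is identically 1")
    freqs, coh = signal.coherence(x, y, fs=fs, nperseg=nperseg,
                                  noverlap=nperseg // 2, window="hann")
    coh = np.clip(coh, 0.0, 1.0)
    return CoherenceSpectrum(freqs_hz=freqs, coherence=coh,
                             n_segments=int(n_segments), signal_pair=labels)


def crossfreq_power_correlation(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    max_freq_hz: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation of instantaneous band powers across frequency pairs.

    The traces are cut into non-overlapping windows; per window the one-sided
    periodogram power of each signal at each frequency bin is computed, and
    the Pearson correlation of ``power_x(f1)`` with ``power_y(f2)`` across
    windows fills the matrix.  Zero-variance bands yield NaN cells.

    Returns ``(freqs_hz, corr_matrix)`` with ``corr[i, j]`` the correlation
    between x-power at ``freqs[i]`` and y-power at ``freqs[j]``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = int(round(window_s * fs))
    n_win = x.size // n
    if n_win < 20:
        raise ValueError("need at least 20 windows")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    px = np.empty((n_win, freqs.size))
    py = np.empty((n_win, freqs.size))
    for w in range(n_win):
        seg_x = x[w * n:(w + 1) * n]
        seg_y = y[w * n:(w + 1) * n]
        px[w] = np.abs(np.fft.rfft(seg_x - seg_x.mean())) ** 2
        py[w] = np.abs(np.fft.rfft(seg_y - seg_y.mean())) ** 2
    if max_freq_hz is not None:
        keep = freqs <= max_freq_hz
        freqs, px, py = freqs[keep], px[:, keep], py[:, keep]

    px_c = px - px.mean(axis=0)
    py_c = py - py.mean(axis=0)
    sx = px_c.std(axis=0)
    sy = py_c.std(axis=0)
    corr = (px_c.T @ py_c) / n_win
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = corr / np.outer(sx, sy)
    corr[~np.isfinite(corr)] = np.nan
    return freqs, corr


def fit_spike_prediction_filter(
    store: SVDStore,
    mua: MuaTrace,
    lags_s: tuple[float, float] = (-0.5, 0.5),
    alphas: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
    max_components: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Linear spatiotemporal filter predicting MUA from the compressed movie.

    Ridge regression from lagged temporal components ``V(t - lag)`` to the
    MUA rate; the penalty is chosen on a log-spaced grid by cross-validation
    over contiguous folds.  The fitted weight matrix (k x n_lags) is split by
    a rank-1 SVD into a spatial component (mapped to pixel space through
    ``U``) and a temporal kernel.

    Returns ``(weight_map, lag_axis_s, temporal_kernel, cv_r)`` where
    ``weight_map`` is the (rows, cols) spatial pattern and ``cv_r`` the
    cross-validated prediction correlation.
    """
    from sklearn.linear_model import Ridge
    from sklearn.model_selection import KFold

    # MUA resampled onto the store's frame clock
    rate = np.interp(store.timestamps, mua.timestamps_s, mua.rate)
    fs = store.fs
    lag_lo = int(np.round(lags_s[0] * fs))
    lag_hi = int(np.round(lags_s[1] * fs))
    lags = np.arange(lag_lo, lag_hi + 1)
    lag_axis = lags / fs

    # top components carry the signal; capping k bounds the design matrix
    # (k * n_lags features x n_frames samples) for long sessions
    V = store.V if max_components is None else store.V[:max_components]
    U = store.U if max_components is None else store.U[:, :max_components]
    k, t = V.shape
    # frames where every lagged index stays inside the recording
    valid = np.arange(max(0, lags.max()), t + min(0, lags.min()))
    # design: X[t, (i, l)] = V[i, t - lag_l]
    X = np.empty((valid.size, k * lags.size))
    for li, lag in enumerate(lags):
        X[:, li * k:(li + 1) * k] = V[:, valid - lag].T
    yv = rate[valid]
    X = X - X.mean(axis=0)
    yv = yv - yv.mean()

    if alphas is None:
        alphas = np.logspace(0, 6, 7) * k

    kf = KFold(n_splits=n_folds, shuffle=False)
    best = (None, -np.inf)
    for a in alphas:
        rs = []
        for tr_idx, te_idx in kf.split(X):
            model = Ridge(alpha=a, fit_intercept=False).fit(X[tr_idx], yv[tr_idx])
            pred = model.predict(X[te_idx])
            if pred.std() == 0 or yv[te_idx].std() == 0:
                rs.append(0.0)
            else:
                rs.append(np.corrcoef(pred, yv[te_idx])[0, 1])
        r = float(np.mean(rs))
        if r > best[1]:
            best = (a, r)
    alpha, cv_r = best

    w = Ridge(alpha=alpha, fit_intercept=False).fit(X, yv).coef_
    W = w.reshape(lags.size, k).T        # k x n_lags
    uu, ss, vv = np.linalg.svd(W, full_matrices=False)
    spatial = uu[:, 0] * ss[0]
    kernel = vv[0]
    if kernel[np.argmax(np.abs(kernel))] < 0:   # sign convention: peak positive
        kernel = -kernel
        spatial = -spatial
    weight_map = (U @ spatial).reshape(store.pixel_shape)
    return weight_map, lag_axis, kernel, float(cv_r)
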