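"""Band-power maps and condition-difference maps in the SVD domain.

With ``f_n(t) = U[n] @ V``, the Fourier transform of every pixel trace is
``fhat_n(w) = sum_i U[n, i] Vhat_i(w)``: transforming the ``k`` temporal
components once is enough to obtain the spectrum of every pixel.  The band
power of all pixels is then assembled through the k x k cross-spectral matrix
``C = sum_{w in band} Vhat(w) Vhat(w)^H``::

    P[n] = sum_{w in band} |fhat_n(w)|^2 = U[n] @ C @ U[n]

which costs ``O(k^2 * bins + pixels * k^2)`` instead of a per-pixel FFT.

Spectra are one-sided power (not density): ``|Vhat_i(w)|^2`` sums over bins to
``sum_t V_i(t)^2`` (Parseval), so band sums are directly comparable across
windows of equal length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wfstate.svdstore import SVDStore, frame_slice

__all__ = [
    "ComponentSpectra",
    "PowerMap",
    "DiffMap",
    "component_spectra",
    "compute_power_map",
    "roi_band_power",
    "diff_map_db",
    "stim_triggered_map",
]


@dataclass
class ComponentSpectra:
    """One-sided spectra of the temporal components over one window."""

    vhat: np.ndarray          # (k, n_freqs) complex
    freqs_hz: np.ndarray      # (n_freqs,)
    window: tuple[int, int]   # frame range [start, stop)
    taper_tag: str = "rect"


@dataclass
class PowerMap:
    """Per-pixel band power P(x, y) in a.u.^2, optionally trial-averaged."""

    power: np.ndarray         # (rows, cols)
    band_hz: tuple[float, float]
    n_trials_averaged: int = 1

    def __post_init__(self):
        if np.any(self.power < -1e-12):
            raise ValueError("power map must be nonnegative")


@dataclass
class DiffMap:
    """Condition power ratio per pixel, in dB: 10*log10(P_a / P_b)."""

    diff_db: np.ndarray       # (rows, cols); NaN where masked
    mask: np.ndarray          # True = below-threshold / invalid pixel
    conditions: tuple[str, str]
    band_hz: tuple[float, float] | None = None


def _resolve_window(store: SVDStore, window) -> slice:
    """A window is either a frame slice or a (start_s, end_s) pair."""
    if isinstance(window, slice):
        return window
    start_s, end_s = window
    return frame_slice(store.timestamps, start_s, end_s)


def component_spectra(
    store: SVDStore,
    window,
    taper: str = "rect",
    detrend: bool = False,
) -> ComponentSpectra:
    """One-sided DFT of every temporal component over a window.

    ``vhat`` is scaled so that ``sum_w |vhat_i(w)|^2 == sum_t V_i(t)^2``
    exactly for the rectangular taper (the Hann taper is amplitude-compensated
    by its RMS, so white-noise power is approximately preserved).
    """
    sl = _resolve_window(store, window)
    seg = store.V[:, sl]
    n = seg.shape[1]
    if n < 2:
        raise ValueError("window must contain at least 2 samples")
    if detrend:
        seg = seg - seg.mean(axis=1, keepdims=True)
    if taper == "rect":
        pass
    elif taper == "hann":
        w = np.hanning(n)
        seg = seg * (w / np.sqrt(np.mean(w**2)))
    else:
        raise ValueError(f"unknown taper {taper!r}")

    F = np.fft.rfft(seg, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / store.fs)
    # one-sided fold weights: interior bins carry both +/- frequencies
    weights = np.full(freqs.shape, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    vhat = F * np.sqrt(weights / n)
    return ComponentSpectra(
        vhat=vhat,
        freqs_hz=freqs,
        window=(sl.start if sl.start is not None else 0,
                sl.stop if sl.stop is not None else store.n_frames),
        taper_tag=taper,
    )


def _band_bins(freqs: np.ndarray, band_hz: tuple[float, float]) -> np.ndarray:
    # inclusive edges, with a tolerance of 1e-6 bin spacings so edge bins are
    # not dropped by floating-point error in the frame-rate estimate
    low, high = band_hz
    tol = 1e-6 * (freqs[1] - freqs[0]) if freqs.size > 1 else 0.0
    return (freqs >= low - tol) & (freqs <= high + tol)


def compute_power_map(
    store: SVDStore,
    window,
    band_hz: tuple[float, float] = (3.0, 6.0),
    taper: str = "rect",
) -> PowerMap:
    """Per-pixel power summed over band bins (``low <= f <= high`` inclusive).

    Assembled via the k x k band cross-spectral matrix, never via per-pixel
    FFTs (peak memory bounded by ``pixels*k + k*t``).
    """
    spec = component_spectra(store, window, taper=taper)
    nyq = store.fs / 2.0
    if not (0 < band_hz[0] <= band_hz[1] <= nyq):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq:.3f}]")
    sel = _band_bins(spec.freqs_hz, band_hz)
    if not np.any(sel):
        df = spec.freqs_hz[1] - spec.freqs_hz[0]
        min_len = int(np.ceil(store.fs / (band_hz[1] - band_hz[0]))) + 1
        raise ValueError(
            f"no frequency bins inside band {band_hz}: bin spacing {df:.3f} Hz; "
            f"use a window of at least ~{min_len} samples"
        )
    vb = spec.vhat[:, sel]
    C = np.real(vb @ vb.conj().T)          # k x k band cross-spectral matrix
    power = np.einsum("pk,kl,pl->p", store.U, C, store.U, optimize=True)
    power = np.maximum(power, 0.0).reshape(store.pixel_shape)
    return PowerMap(power=power, band_hz=tuple(band_hz))


def average_power_maps(maps: list[PowerMap]) -> PowerMap:
    """Condition mean of per-trial power maps (e.g. P_choice, P_miss)."""
    if not maps:
        raise ValueError("no maps to average")
    band = maps[0].band_hz
    if any(m.band_hz != band for m in maps):
        raise ValueError("maps have mismatched bands")
    power = np.mean([m.power for m in maps], axis=0)
    return PowerMap(power=power, band_hz=band,
                    n_trials_averaged=sum(m.n_trials_averaged for m in maps))


def roi_band_power(
    store: SVDStore,
    roi: tuple[int, int],
    windows: list,
    band_hz: tuple[float, float] = (3.0, 6.0),
    taper: str = "rect",
) -> np.ndarray:
    """Band power of one ROI pixel per window.

    Equals ``compute_power_map`` evaluated at that pixel; computed from the
    pixel's component weights directly so the cost per window is O(k * n).
    """
    n = store.pixel_index(*roi)
    u = store.U[n]
    out = np.empty(len(windows))
    for j, window in enumerate(windows):
        spec = component_spectra(store, window, taper=taper)
        sel = _band_bins(spec.freqs_hz, band_hz)
        if not np.any(sel):
            raise ValueError(f"window {window} too short for band {band_hz}")
        fhat = u @ spec.vhat[:, sel]
        out[j] = float(np.sum(np.abs(fhat) ** 2))
    return out


def diff_map_db(
    map_a: PowerMap,
    map_b: PowerMap,
    mask_percentile: float = 20.0,
    reference: PowerMap | None = None,
    conditions: tuple[str, str] = ("a", "b"),
) -> DiffMap:
    """Condition difference map ``10*log10(P_a / P_b)`` with low-power mask.

    Pixels whose time-averaged power (the ``reference`` map, by default the
    mean of the two condition maps) falls below ``mask_percentile`` of all
    pixels are masked -- this blanks pixels outside the brain.  Zero
    denominators are masked and never yield infinities.
    """
    if map_a.power.shape != map_b.power.shape:
        raise ValueError("maps have mismatched grids")
    if map_a.band_hz != map_b.band_hz:
        raise ValueError("maps have mismatched bands")
    ref = reference.power if reference is not None else 0.5 * (map_a.power + map_b.power)
    thresh = np.percentile(ref, mask_percentile)
    mask = ref < thresh
    bad = (map_b.power <= 0) | (map_a.power <= 0)
    mask = mask | bad
    diff = np.full(map_a.power.shape, np.nan)
    ok = ~bad
    diff[ok] = 10.0 * np.log10(map_a.power[ok] / map_b.power[ok])
    diff[mask] = np.nan
    return DiffMap(diff_db=diff, mask=mask, conditions=conditions,
                   band_hz=map_a.band_hz)


def stim_triggered_map(
    store: SVDStore,
    trials,
    selector=None,
    response_window_ms: tuple[float, float] = (70.0, 80.0),
) -> np.ndarray:
    """Average stimulus-triggered response map.

    Per selected trial: mean frame in the post-stimulus response window minus
    the frame immediately preceding that window (each baseline-subtracted at
    stimulus onset, which cancels in the difference).  ``trials`` is a
    DataFrame with a ``stim_onset_s`` column; ``selector`` is an optional
    boolean mask or callable on the DataFrame (e.g. high contralateral
    contrast).
    """
    import pandas as pd  # local import; trials is a DataFrame

    if callable(selector):
        keep = np.asarray(selector(trials), dtype=bool)
    elif selector is not None:
        keep = np.asarray(selector, dtype=bool)
    else:
        keep = np.ones(len(trials), dtype=bool)
    onsets = np.asarray(trials.loc[keep, "stim_onset_s"], dtype=float)
    if onsets.size == 0:
        raise ValueError("no trials match selector")

    ts = store.timestamps
    lo_s, hi_s = response_window_ms[0] / 1000.0, response_window_ms[1] / 1000.0
    acc_v = np.zeros(store.k)
    n_used = 0
    for t0 in onsets:
        # "the frame at t = lo-hi ms": first frame at or after the window
        # start (at ~35 Hz the frame period spans the 10 ms window), averaged
        # with any further frames inside the window
        i0 = int(np.searchsorted(ts, t0 + lo_s, side="left"))
        i1 = max(i0 + 1, int(np.searchsorted(ts, t0 + hi_s, side="left")))
        if i0 < 1 or i1 > store.n_frames:
            continue
        v_resp = store.V[:, i0:i1].mean(axis=1)
        v_prev = store.V[:, i0 - 1]
        acc_v += v_resp - v_prev
        n_used += 1
    if n_used == 0:
        raise ValueError("no selected trial has frames inside the response window")
    resp = store.U @ (acc_v / n_used)
    return resp.reshape(store.pixel_shape)
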