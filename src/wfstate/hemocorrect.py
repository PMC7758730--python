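"""Regression-based hemodynamic correction in the compressed domain.

Blood volume/oxygenation changes contaminate the calcium-dependent channel,
most strongly in the heartbeat band (9-13 Hz).  The correction subtracts a
per-pixel multiple of the calcium-independent channel from the calcium
channel.  The multiple is estimated by least squares between the two channels
after linear detrending, 0.01 Hz high-pass and 9-13 Hz band-pass filtering;
it is then applied to the *raw* (unfiltered) hemodynamic signal.

Both estimation and subtraction run in the SVD domain: temporal filters act on
the component time courses ``V`` (filtering is linear, so it commutes with the
spatial mixing by ``U``), and the per-pixel regression is assembled from k x k
component cross-products -- the full pixel x time movie is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from wfstate.svdstore import SVDStore

__all__ = ["HemoGainMap", "estimate_hemo_gains", "apply_hemo_correction"]


@dataclass
class HemoGainMap:
    """Per-pixel regression multiple of the calcium-independent signal."""

    gain: np.ndarray                 # (rows, cols), dimensionless
    band_used: tuple[float, float] = (9.0, 13.0)
    highpass_hz: float = 0.01
    diagnostics: np.ndarray | None = None   # residual heartbeat-band power fraction
    degenerate: np.ndarray | None = None    # pixels with zero-variance hemo band


def _filter_v(V: np.ndarray, fs: float, band: tuple[float, float], highpass_hz: float) -> np.ndarray:
    """Detrend + zero-phase 0.01 Hz high-pass + zero-phase band-pass, row-wise."""
    Vf = signal.detrend(V, axis=1, type="linear")
    nyq = fs / 2.0
    if highpass_hz > 0:
        sos_hp = signal.butter(4, highpass_hz / nyq, btype="highpass", output="sos")
        Vf = signal.sosfiltfilt(sos_hp, Vf, axis=1)
    sos_bp = signal.butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos_bp, Vf, axis=1)


def _align_hemo_v(hemo: SVDStore, target_ts: np.ndarray) -> np.ndarray:
    """Resample the hemo channel's V onto the calcium clock.

    With alternate-frame illumination the two channels share one frame rate
    and differ by a constant half-frame delay.  A Fourier fractional-delay
    shift is then exact for band-limited signals; linear interpolation would
    attenuate the heartbeat band by ``cos(pi * f / fs)`` (about 0.55 at 11 Hz
    and 35 Hz frames) and inflate the regression gains by its inverse.  When
    the clocks are not a constant offset apart, fall back to linear
    interpolation.
    """
    ts = hemo.timestamps
    if ts.shape == target_ts.shape:
        delta = ts - target_ts
        if np.allclose(delta, delta[0], atol=1e-9):
            n = hemo.V.shape[1]
            freqs = np.fft.rfftfreq(n, d=np.median(np.diff(target_ts)))
            phase = np.exp(-2j * np.pi * freqs * delta[0])
            return np.fft.irfft(np.fft.rfft(hemo.V, axis=1) * phase, n=n, axis=1)
    out = np.empty((hemo.k, target_ts.shape[0]))
    for i in range(hemo.k):
        out[i] = np.interp(target_ts, ts, hemo.V[i])
    return out


def estimate_hemo_gains(
    cal: SVDStore,
    hemo: SVDStore,
    band_hz: tuple[float, float] = (9.0, 13.0),
    highpass_hz: float = 0.01,
) -> HemoGainMap:
    """Per-pixel least-squares gain of filtered calcium on filtered hemo.

    For pixel ``n`` with filtered traces ``c_n = U_cal[n] @ Vf_cal`` and
    ``h_n = U_hemo[n] @ Vf_hemo``::

        gain_n = <c_n, h_n> / <h_n, h_n>

    assembled from the cross-product matrices ``Vf_cal @ Vf_hemo.T`` and
    ``Vf_hemo @ Vf_hemo.T`` (no intercept: both signals are detrended and
    high-passed, so their means are ~0).  Pixels with (near) zero-variance
    hemo band signal get gain 0 and a degeneracy flag.
    """
    if cal.pixel_shape != hemo.pixel_shape:
        raise ValueError("channels have mismatched pixel grids")
    fs = cal.fs
    if band_hz[1] >= fs / 2.0:
        raise ValueError(
            f"heartbeat band {band_hz} exceeds Nyquist {fs / 2.0:.2f} Hz"
        )

    Vh_aligned = _align_hemo_v(hemo, cal.timestamps)
    Vf_cal = _filter_v(cal.V, fs, band_hz, highpass_hz)
    Vf_hemo = _filter_v(Vh_aligned, fs, band_hz, highpass_hz)

    C_ch = Vf_cal @ Vf_hemo.T            # k_cal x k_hemo
    C_hh = Vf_hemo @ Vf_hemo.T           # k_hemo x k_hemo
    C_cc = Vf_cal @ Vf_cal.T

    num = np.einsum("pk,kl,pl->p", cal.U, C_ch, hemo.U, optimize=True)
    den = np.einsum("pk,kl,pl->p", hemo.U, C_hh, hemo.U, optimize=True)
    cal_pow = np.einsum("pk,kl,pl->p", cal.U, C_cc, cal.U, optimize=True)

    scale = float(np.max(den)) if den.size else 0.0
    degenerate = den <= max(scale, 1.0) * 1e-12
    gain = np.zeros_like(den)
    ok = ~degenerate
    gain[ok] = num[ok] / den[ok]

    # residual heartbeat-band power fraction after subtraction = 1 - r^2
    diag = np.ones_like(gain)
    good = ok & (cal_pow > 0)
    diag[good] = 1.0 - (num[good] ** 2) / (den[good] * cal_pow[good])
    diag = np.clip(diag, 0.0, 1.0)

    shape = cal.pixel_shape
    return HemoGainMap(
        gain=gain.reshape(shape),
        band_used=tuple(band_hz),
        highpass_hz=highpass_hz,
        diagnostics=diag.reshape(shape),
        degenerate=degenerate.reshape(shape),
    )


def apply_hemo_correction(
    cal: SVDStore,
    hemo: SVDStore,
    gains: HemoGainMap | None,
    rank: int | None = None,
) -> SVDStore:
    """Subtract ``gains * hemo`` from the calcium channel, in the SVD domain.

    The hemo channel is first linearly interpolated onto the calcium
    timestamps.  The corrected movie ``U_c V_c - diag(g) U_h V_h'`` is
    refactored through a QR + small-SVD step so the result is again a valid
    store (orthonormal ``U``, singular-value-scaled ``V``) with rank at most
    ``k_cal + k_hemo``.

    ``gains=None`` is the pass-through mode for sessions recorded without a
    hemodynamic channel: the calcium store is returned re-tagged
    ``"uncorrected"``.
    """
    if gains is None:
        out = SVDStore(
            U=cal.U.copy(), V=cal.V.copy(),
            singular_values=cal.singular_values.copy(),
            timestamps=cal.timestamps.copy(),
            pixel_shape=cal.pixel_shape, channel_tag="uncorrected",
        )
        return out
    if cal.pixel_shape != hemo.pixel_shape:
        raise ValueError("channels have mismatched pixel grids")
    if gains.gain.shape != cal.pixel_shape:
        raise ValueError("gain map does not match pixel grid")

    g = gains.gain.reshape(-1)
    Vh = _align_hemo_v(hemo, cal.timestamps)

    U_stack = np.hstack([cal.U, g[:, None] * hemo.U])       # p x (k_c + k_h)
    V_stack = np.vstack([cal.V, -Vh])                       # (k_c + k_h) x t

    Q, R = np.linalg.qr(U_stack)
    M = R @ V_stack
    Um, s, Vt = np.linalg.svd(M, full_matrices=False)
    k_out = min(rank or len(s), len(s))
    U_new = Q @ Um[:, :k_out]
    V_new = s[:k_out, None] * Vt[:k_out]

    # fix the sign convention (largest-|U| entry positive per component)
    idx = np.argmax(np.abs(U_new), axis=0)
    signs = np.sign(U_new[idx, np.arange(k_out)])
    signs[signs == 0] = 1.0
    U_new *= signs
    V_new *= signs[:, None]

    return SVDStore(
        U=U_new,
        V=V_new,
        singular_values=s[:k_out].copy(),
        timestamps=cal.timestamps.copy(),
        pixel_shape=cal.pixel_shape,
        channel_tag="corrected",
    )
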