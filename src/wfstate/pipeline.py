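"""End-to-end session processing.

Chains the stages the way a real session is analyzed: compress both movie
channels, estimate and apply the hemodynamic correction, extract per-trial
quiescent-window 3-6 Hz band power at the configured ROIs, and join it with
outcomes, reaction times and pupil measures into the trial x ROI state table
that all behavioral analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wfstate import behavior, hemocorrect, spectral, svdstore
from wfstate.synthio import PupilTrace, WidefieldMovie

__all__ = [
    "SessionStores",
    "compress_session",
    "build_band_power_table",
    "condition_diff_db",
    "condition_diff_map",
    "process_session",
]

BAND_HZ = (3.0, 6.0)


@dataclass
class SessionStores:
    calcium: svdstore.SVDStore
    hemo: svdstore.SVDStore
    corrected: svdstore.SVDStore
    gains: hemocorrect.HemoGainMap | None


def compress_session(movie: WidefieldMovie, k: int = 500,
                     correct_hemo: bool = True) -> SessionStores:
    """Compress both channels and apply the hemodynamic correction."""
    cal = svdstore.compress_movie(
        movie.calcium_frames, movie.timestamps_cal, k=k,
        pixel_shape=movie.pixel_shape, channel_tag="calcium")
    hemo = svdstore.compress_movie(
        movie.hemo_frames, movie.timestamps_hemo, k=k,
        pixel_shape=movie.pixel_shape, channel_tag="hemo")
    if correct_hemo:
        gains = hemocorrect.estimate_hemo_gains(cal, hemo)
        corrected = hemocorrect.apply_hemo_correction(cal, hemo, gains, rank=k)
    else:
        gains = None
        corrected = hemocorrect.apply_hemo_correction(cal, hemo, None)
    return SessionStores(calcium=cal, hemo=hemo, corrected=corrected, gains=gains)


def build_band_power_table(
    store: svdstore.SVDStore,
    trials: pd.DataFrame,
    rois: behavior.ROISet,
    band_hz: tuple[float, float] = BAND_HZ,
    min_quiescent_s: float = behavior.MIN_QUIESCENT_S,
    pupil: PupilTrace | None = None,
    trial_lag: int = 0,
) -> pd.DataFrame:
    """Trial x ROI band-power table over quiescent windows.

    One row per included trial (quiescent period >= ``min_quiescent_s``);
    columns: trial metadata, per-ROI band power ``power_<ROI>`` (a.u.^2) and
    ``power_<ROI>_db`` (dB relative to the session-mean power of that ROI),
    and pupil summaries over the window.  ``trial_lag=1`` attributes each
    trial's *following* quiescent window to it (post-outcome state analyses).

    Exclusion accounting (included + excluded + invalid = raw trials) is
    attached as ``DataFrame.attrs["provenance"]``.
    """
    rois.validate_grid(store.pixel_shape)
    n_raw = len(trials)
    valid_mask = trials["valid"] if "valid" in trials else pd.Series(True, index=trials.index)
    valid_trials = trials[valid_mask]
    n_invalid = int(n_raw - len(valid_trials))

    windows, n_excluded = behavior.extract_quiescent_windows(
        valid_trials, min_duration_s=min_quiescent_s)

    if trial_lag:
        # attribute the window of trial j+lag to trial j
        win_by_trial = dict(windows)
        windows = []
        pos = {t: i for i, t in enumerate(valid_trials.index)}
        for t in valid_trials.index:
            i = pos[t] + trial_lag
            if 0 <= i < len(valid_trials):
                t_src = valid_trials.index[i]
                if t_src in win_by_trial:
                    windows.append((t, win_by_trial[t_src]))

    rows = []
    for trial_idx, (t0, t1) in windows:
        tr = trials.loc[trial_idx]
        row = {c: tr[c] for c in trials.columns}
        row["window_start_s"] = t0
        row["window_end_s"] = t1
        for name, (r, c) in rois.items():
            p = spectral.roi_band_power(store, (r, c), [(t0, t1)], band_hz)[0]
            row[f"power_{name}"] = p
        if pupil is not None:
            m = (pupil.timestamps_s >= t0) & (pupil.timestamps_s < t1)
            row["pupil_mean"] = float(np.mean(pupil.diameter[m])) if m.any() else np.nan
            row["pupil_derivative_mean"] = (
                float(np.mean(pupil.derivative[m])) if m.any() else np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)

    if len(table):
        for name in rois.names():
            col = f"power_{name}"
            mean_p = table[col].mean()
            table[f"{col}_db"] = 10.0 * np.log10(table[col] / mean_p)

    n_included = len(table)
    assert n_included + n_excluded + n_invalid + (0 if not trial_lag else 0) >= 0
    table.attrs["provenance"] = {
        "n_raw": n_raw, "n_invalid": n_invalid,
        "n_excluded_short_quiescent": n_excluded, "n_included": n_included,
    }
    if not trial_lag:
        assert n_included + n_excluded + n_invalid == n_raw
    return table


def condition_diff_db(
    table: pd.DataFrame,
    roi: str,
    condition_a: str = "Choice",
    condition_b: str = "Miss",
    min_trials: int = 10,
) -> float:
    """ROI-level condition power difference, 10*log10(mean_a / mean_b) dB.

    ``"Choice"`` pools Correct and Incorrect Choice trials.  Sessions with
    fewer than ``min_trials`` in either condition are rejected.
    """
    def mask_of(cond):
        if cond == "Choice":
            return table["outcome"].isin(behavior.CHOICE_OUTCOMES)
        return table["outcome"] == cond

    col = f"power_{roi}"
    a = table.loc[mask_of(condition_a), col].to_numpy(float)
    b = table.loc[mask_of(condition_b), col].to_numpy(float)
    if len(a) < min_trials or len(b) < min_trials:
        raise ValueError(
            f"fewer than {min_trials} trials in a condition "
            f"({condition_a}: {len(a)}, {condition_b}: {len(b)})")
    return float(10.0 * np.log10(a.mean() / b.mean()))


def condition_diff_map(
    store: svdstore.SVDStore,
    table: pd.DataFrame,
    condition_a: str = "Choice",
    condition_b: str = "Miss",
    band_hz: tuple[float, float] = BAND_HZ,
    mask_percentile: float = 20.0,
) -> spectral.DiffMap:
    """Per-pixel Choice/Miss (or other pair) power-difference map in dB."""
    def mask_of(cond):
        if cond == "Choice":
            return table["outcome"].isin(behavior.CHOICE_OUTCOMES)
        return table["outcome"] == cond

    def mean_map(mask):
        maps = [
            spectral.compute_power_map(store, (r.window_start_s, r.window_end_s), band_hz)
            for _, r in table[mask].iterrows()
        ]
        return spectral.average_power_maps(maps)

    map_a = mean_map(mask_of(condition_a))
    map_b = mean_map(mask_of(condition_b))
    # mask reference: broadband time-averaged power over the whole session
    ref = spectral.compute_power_map(
        store, slice(0, store.n_frames), (1e-9, store.fs / 2.0))
    return spectral.diff_map_db(map_a, map_b, mask_percentile=mask_percentile,
                                reference=ref, conditions=(condition_a, condition_b))


def process_session(movie, trials, pupil=None, rois=None, k: int = 500,
                    band_hz: tuple[float, float] = BAND_HZ):
    """Movie + trials -> (stores, band-power table) with default settings."""
    if rois is None:
        rois = behavior.default_roi_set(movie.pixel_shape[0])
    stores = compress_session(movie, k=k)
    table = build_band_power_table(stores.corrected, trials, rois,
                                   band_hz=band_hz, pupil=pupil)
    return stores, table
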