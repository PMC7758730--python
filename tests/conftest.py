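import warnings

import numpy as np
import pandas as pd
import pytest

from wfstate import behavior, pipeline
from wfstate.synthio import SimConfig, generate_session


def pixel_periodogram_band_power(frames, fs, frame_sl, band_hz):
    """Dense pixel-space oracle: one-sided periodogram band power per pixel.

    Written directly against the raw movie; never touches the SVD path.
    """
    seg = np.asarray(frames, dtype=float)[:, frame_sl]
    n = seg.shape[1]
    F = np.fft.rfft(seg, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    w = np.full(freqs.shape, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    P = (np.abs(F) ** 2) * w / n
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return P[:, sel].sum(axis=1)


@pytest.fixture(scope="session")
def small_session():
    """One fixed synthetic session shared across tests (60 trials, 12x12)."""
    cfg = SimConfig(n_trials=60, grid_size=12, response_window_s=(1.5, 2.0), seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        movie, trials, spikes, pupil, truth = generate_session(cfg)
    return dict(config=cfg, movie=movie, trials=trials, spikes=spikes,
                pupil=pupil, truth=truth)


@pytest.fixture(scope="session")
def small_stores(small_session):
    return pipeline.compress_session(small_session["movie"], k=140)


@pytest.fixture(scope="session")
def small_table(small_session, small_stores):
    rois = behavior.default_roi_set(small_session["config"].grid_size)
    return pipeline.build_band_power_table(
        small_stores.corrected, small_session["trials"], rois,
        pupil=small_session["pupil"])


def make_state_table(rng, n_sessions=10, n_trials=200, cond_effect_db=0.0,
                     rois=("VIS", "SS"), session_sd=0.8, subject_sd=0.5,
                     genotype_sd=0.3, noise_sd=1.0, n_subjects=5, n_genotypes=2):
    """Fabricated multi-session band-power table for mixed-model tests.

    Power (in dB) = grand mean + genotype/subject/session offsets + condition
    effect (Miss = 0, Choice = cond_effect_db) + trial noise.
    """
    rows = []
    genotypes = [f"g{i}" for i in range(n_genotypes)]
    subj_geno = {f"m{i:02d}": genotypes[i % n_genotypes] for i in range(n_subjects)}
    subjects = list(subj_geno)
    g_off = {g: genotype_sd * rng.standard_normal() for g in genotypes}
    s_off = {s: subject_sd * rng.standard_normal() for s in subjects}
    for si in range(n_sessions):
        subject = subjects[si % n_subjects]
        genotype = subj_geno[subject]
        sess = f"s{si:02d}"
        sess_off = session_sd * rng.standard_normal()
        for t in range(n_trials):
            is_choice = rng.uniform() < 0.7
            outcome = "CorrectChoice" if is_choice else "Miss"
            base = g_off[genotype] + s_off[subject] + sess_off
            row = dict(outcome=outcome, contrast_left=0.0, contrast_right=0.5,
                       session_id=sess, subject_id=subject, genotype_id=genotype)
            for j, roi in enumerate(rois):
                mu = base + 0.4 * j + (cond_effect_db if is_choice else 0.0)
                row[f"power_{roi}_db"] = mu + noise_sd * rng.standard_normal()
                row[f"power_{roi}"] = 10 ** (row[f"power_{roi}_db"] / 10.0)
            rows.append(row)
    return pd.DataFrame(rows)
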