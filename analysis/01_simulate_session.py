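"""Generate the reference synthetic session used by the later analysis steps.

A 200-trial dual-channel widefield session (16x16 grid, 35 Hz per channel)
with the default generative conditions: quiescent periods 0.5-2.0 s, go cue
0.3-0.8 s post-stimulus, contrasts {0, 25, 50, 100}%, a latent
synchronization state driving both 3-6 Hz power (Choice-Miss target -1.5 dB)
and outcome probabilities, an 11 Hz hemodynamic artifact with per-pixel
gains, and state-coupled spiking.

Writes results/session/ (movie.h5, spikes.h5, trials.csv, pupil.csv,
config.yaml) plus the ground-truth gain map for later comparison.
"""

import os
import warnings

import h5py
import numpy as np

from wfstate.synthio import SimConfig, generate_session, save_session

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "session")


def main():
    cfg = SimConfig(grid_size=16, n_trials=200, seed=2024,
                    response_window_s=(1.5, 2.5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        movie, trials, spikes, pupil, truth = generate_session(cfg)
    save_session(OUT, movie, trials, spikes, pupil, config=cfg)
    with h5py.File(os.path.join(OUT, "truth.h5"), "w") as f:
        f.create_dataset("hemo_gain_map", data=truth.hemo_gain_map)
        f.create_dataset("latent_state_per_trial", data=truth.state_per_trial)
        f.attrs["true_effect_db"] = truth.true_effect_db
        f.attrs["amp_db_slope"] = truth.amp_db_slope

    dur = movie.timestamps_cal[-1]
    q = trials.quiescent_end_s - trials.quiescent_start_s
    print(f"session: {cfg.n_trials} trials, {dur / 60:.1f} min, "
          f"{movie.calcium_frames.shape[0]} pixels x {movie.calcium_frames.shape[1]} frames/channel")
    print(f"quiescent durations: {q.min():.2f}-{q.max():.2f} s "
          f"({(q < 0.7).sum()} trials below the 0.7 s inclusion threshold)")
    print("outcomes:", trials.outcome.value_counts().to_dict())
    print(f"{spikes.spike_times_s.size} spikes in "
          f"{spikes.cluster_depths_um.size} clusters")
    print(f"wrote {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
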