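"""Trial-equalized stimulus decoding under the three condition splits.

Builds the 50-150 ms post-stimulus population spike-count matrix from the
reference session and compares cross-validated decoding of contralateral
stimulus presence between Choice and Miss trials, low and high 3-6 Hz power,
and low and high Fano factor -- equalizing per-contrast trial counts before
each comparison.

Writes results/decoding_summary.csv.
"""

import os

import h5py
import numpy as np
import pandas as pd

from wfstate import decode, ephys

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 7


def main():
    with h5py.File(os.path.join(ROOT, "session", "spikes.h5")) as f:
        spike_times = f["spikes/times"][()]
        clusters = f["spikes/clusters"][()]
    table = pd.read_csv(os.path.join(ROOT, "band_power_table.csv"))
    trials = pd.read_csv(os.path.join(ROOT, "session", "trials.csv"))

    sub = trials.loc[table.trial].reset_index(drop=True)
    matrix = decode.build_spike_count_matrix(spike_times, clusters, sub)

    n_mua = 16
    mua_times = spike_times[clusters < n_mua]
    windows = list(zip(table.window_start_s, table.window_end_s))
    fano = ephys.fano_factor(mua_times, windows).fano

    rows = []

    def compare(name, in_a, in_b, label_a, label_b):
        try:
            m_a, m_b, _ = decode.equalize_trial_counts(matrix, in_a, in_b, seed=SEED)
            acc_a = decode.decode_stimulus(m_a, seed=SEED)["accuracy"]
            acc_b = decode.decode_stimulus(m_b, seed=SEED)["accuracy"]
        except ValueError as e:
            print(f"{name}: skipped ({e})")
            return
        print(f"{name}: {label_a} {acc_a:.2f} vs {label_b} {acc_b:.2f} "
              f"(n = {len(m_a)} + {len(m_b)})")
        rows.append(dict(split=name, acc_a=acc_a, acc_b=acc_b,
                         label_a=label_a, label_b=label_b,
                         n_a=len(m_a), n_b=len(m_b)))

    outcome = table.outcome.to_numpy()
    is_choice = np.isin(outcome, ["CorrectChoice", "IncorrectChoice"])
    is_miss = outcome == "Miss"
    compare("choice_vs_miss", is_choice, is_miss, "Choice", "Miss")

    low_p, high_p, _ = decode.median_state_split(table.power_VIS.to_numpy())
    compare("power_split", low_p, high_p, "low power", "high power")

    low_f, high_f, _ = decode.median_state_split(fano)
    compare("fano_split", low_f, high_f, "low Fano", "high Fano")

    pd.DataFrame(rows).to_csv(os.path.join(ROOT, "decoding_summary.csv"),
                              index=False)


if __name__ == "__main__":
    main()
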