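"""Bridge the imaging signal to electrophysiology on the reference session.

Bins the multiunit activity at the imaging rate, computes fluorescence-MUA
coherence and cross-frequency power correlation, the per-trial Fano factor in
the quiescent windows, and fits the spatiotemporal filter predicting MUA from
the compressed movie.

Writes results/ephys_bridge.h5.
"""

import os

import h5py
import numpy as np
import pandas as pd
from scipy import stats

from wfstate import ephys, svdstore

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    corrected = svdstore.load_store(os.path.join(ROOT, "stores.h5"), "corrected")
    with h5py.File(os.path.join(ROOT, "session", "spikes.h5")) as f:
        spike_times = f["spikes/times"][()]
        clusters = f["spikes/clusters"][()]
    table = pd.read_csv(os.path.join(ROOT, "band_power_table.csv"))

    n_mua = 16   # generator convention: clusters [0, 16) are the MUA pool
    mua_times = spike_times[clusters < n_mua]
    t_end = corrected.timestamps[-1]
    mua = ephys.bin_and_smooth_mua(mua_times, 0.0, t_end, fs_out=corrected.fs)

    # coherence with the fluorescence at the VIS ROI pixel
    g = corrected.pixel_shape[0]
    from wfstate.svdstore import extract_pixel_trace

    _, f_vis = extract_pixel_trace(corrected, g // 4, g // 4)
    n = min(f_vis.size, mua.rate.size)
    coh = ephys.coherence_spectrum(mua.rate[:n], f_vis[:n], corrected.fs,
                                   segment_s=4.0, labels=("MUA", "fluorescence"))
    low = (coh.freqs_hz >= 1) & (coh.freqs_hz <= 6)
    high = coh.freqs_hz >= 10
    print(f"MUA-fluorescence coherence: {coh.coherence[low].mean():.2f} at 1-6 Hz, "
          f"{coh.coherence[high].mean():.2f} above 10 Hz")

    freqs_cf, cf = ephys.crossfreq_power_correlation(
        mua.rate[:n], f_vis[:n], corrected.fs, window_s=2.0, max_freq_hz=15)

    windows = list(zip(table.window_start_s, table.window_end_s))
    fano = ephys.fano_factor(mua_times, windows)
    ok = np.isfinite(fano.fano)
    rho = stats.spearmanr(table.power_VIS.to_numpy()[ok], fano.fano[ok])[0]
    print(f"Fano factor vs 3-6 Hz power: Spearman rho = {rho:+.2f} "
          f"({ok.sum()} trials)")

    wmap, lag_axis, kernel, cv_r = ephys.fit_spike_prediction_filter(
        corrected, mua, lags_s=(-0.2, 0.4), max_components=64)
    peak = np.unravel_index(np.argmax(np.abs(wmap)), wmap.shape)
    print(f"spike-prediction filter: cv r = {cv_r:.2f}, spatial peak at {peak}, "
          f"kernel peak lag {lag_axis[np.argmax(kernel)] * 1000:.0f} ms")

    out = os.path.join(ROOT, "ephys_bridge.h5")
    with h5py.File(out, "w") as f:
        f.create_dataset("coherence/freqs", data=coh.freqs_hz)
        f.create_dataset("coherence/msc", data=coh.coherence)
        f.create_dataset("crossfreq/freqs", data=freqs_cf)
        f.create_dataset("crossfreq/corr", data=cf)
        f.create_dataset("fano/per_trial", data=fano.fano)
        f.create_dataset("filter/weight_map", data=wmap)
        f.create_dataset("filter/lag_s", data=lag_axis)
        f.create_dataset("filter/kernel", data=kernel)
        f.attrs["cv_r"] = cv_r
        f.attrs["fano_power_spearman"] = rho
    print(f"wrote {os.path.abspath(out)}")


if __name__ == "__main__":
    main()
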