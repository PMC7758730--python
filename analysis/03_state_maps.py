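"""Trial-state analysis: band-power table, Choice-Miss maps, percentile curves.

From the corrected store of 02: per-trial quiescent-window 3-6 Hz power at
the five ROIs, the Choice-Miss power-difference map in dB (with the
20th-percentile low-power mask), and the percent-outcome-vs-power-percentile
curves for VIS.

Writes results/band_power_table.csv, results/diff_map_choice_miss.npz and
results/percentile_rates_VIS.csv.
"""

import os

import numpy as np
import pandas as pd

from wfstate import behavior, pipeline, svdstore

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    corrected = svdstore.load_store(os.path.join(ROOT, "stores.h5"), "corrected")
    trials = pd.read_csv(os.path.join(ROOT, "session", "trials.csv"))
    pupil_df = pd.read_csv(os.path.join(ROOT, "session", "pupil.csv"))

    from wfstate.synthio import PupilTrace

    pupil = PupilTrace(timestamps_s=pupil_df.timestamps_s.to_numpy(),
                       diameter=pupil_df.diameter.to_numpy(),
                       derivative=pupil_df.derivative.to_numpy())

    rois = behavior.default_roi_set(corrected.pixel_shape[0])
    table = pipeline.build_band_power_table(corrected, trials, rois, pupil=pupil)
    table.to_csv(os.path.join(ROOT, "band_power_table.csv"), index=False)
    prov = table.attrs["provenance"]
    print(f"trials: {prov['n_raw']} raw, {prov['n_excluded_short_quiescent']} "
          f"excluded (<0.7 s quiescence), {prov['n_included']} analyzed")

    for roi in rois.names():
        d = pipeline.condition_diff_db(table, roi)
        print(f"  Choice-Miss 3-6 Hz difference at {roi}: {d:+.2f} dB")

    dm = pipeline.condition_diff_map(corrected, table)
    np.savez(os.path.join(ROOT, "diff_map_choice_miss.npz"),
             diff_db=dm.diff_db, mask=dm.mask)
    ok = dm.diff_db[~dm.mask]
    print(f"diff map: {np.nanmean(ok):+.2f} dB mean over unmasked pixels "
          f"({int(dm.mask.sum())} pixels masked)")

    rates = behavior.percentile_rates(table, "VIS")
    out = pd.concat([rates.counts, rates.rates], axis=1)
    out.insert(0, "percentile_bin", [1, 2, 3, 4, 5])
    out.to_csv(os.path.join(ROOT, "percentile_rates_VIS.csv"), index=False)
    print("percent Miss by VIS power percentile:",
          np.round(rates.rates.pct_miss.to_numpy(), 1))


if __name__ == "__main__":
    main()
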