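"""Trial-equalized decoding of stimulus presence from population spikes.

A per-trial population activity vector is built from the spike counts of all
units in a 100 ms window (default 50-150 ms after stimulus onset).  Before
comparing decoder performance between two conditions (Choice vs Miss, low vs
high 3-6 Hz power, low vs high Fano factor), trial counts are equalized
within every contrast level by random subsampling, so both decoders see the
same amount and composition of training data.  Decoding is L2-penalized
logistic regression with 5-fold stratified cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeCountMatrix",
    "build_spike_count_matrix",
    "equalize_trial_counts",
    "decode_stimulus",
    "median_state_split",
]


@dataclass
class SpikeCountMatrix:
    """Trials x units spike counts in the decoding window, with labels."""

    counts: np.ndarray               # (n_trials, n_units) nonnegative ints
    labels: np.ndarray               # bool, stimulus present (contralateral)
    contrasts: np.ndarray            # contralateral contrast per trial
    window_ms: tuple[float, float] = (50.0, 150.0)
    trial_index: np.ndarray | None = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")
        if self.counts.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per trial required")
        if self.trial_index is None:
            self.trial_index = np.arange(self.counts.shape[0])

    def subset(self, mask: np.ndarray) -> "SpikeCountMatrix":
        mask = np.asarray(mask)
        return SpikeCountMatrix(
            counts=self.counts[mask],
            labels=self.labels[mask],
            contrasts=self.contrasts[mask],
            window_ms=self.window_ms,
            trial_index=self.trial_index[mask],
            tags=dict(self.tags),
        )

    def __len__(self) -> int:
        return self.counts.shape[0]


def build_spike_count_matrix(
    spike_times_s: np.ndarray,
    cluster_ids: np.ndarray,
    trials: pd.DataFrame,
    window_ms: tuple[float, float] = (50.0, 150.0),
    contrast_column: str = "contrast_right",
) -> SpikeCountMatrix:
    """Count spikes per unit in the post-stimulus decoding window per trial.

    The label is presence of a contralateral stimulus
    (``contrast_column > 0``).
    """
    units = np.unique(cluster_ids)
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    counts = np.zeros((len(trials), units.size), dtype=int)
    for i, (_, tr) in enumerate(trials.iterrows()):
        t0, t1 = tr.stim_onset_s + lo, tr.stim_onset_s + hi
        in_win = (spike_times_s >= t0) & (spike_times_s < t1)
        if np.any(in_win):
            ids, n = np.unique(cluster_ids[in_win], return_counts=True)
            counts[i, np.searchsorted(units, ids)] = n
    contrasts = trials[contrast_column].to_numpy(float)
    return SpikeCountMatrix(
        counts=counts,
        labels=contrasts > 0,
        contrasts=contrasts,
        window_ms=tuple(window_ms),
        trial_index=trials.index.to_numpy(),
    )


def equalize_trial_counts(
    matrix: SpikeCountMatrix,
    in_a: np.ndarray,
    in_b: np.ndarray,
    seed: int = 0,
) -> tuple[SpikeCountMatrix, SpikeCountMatrix, dict]:
    """Equalize per-contrast trial counts between two conditions.

    Within each contrast level present in both conditions, the larger
    condition is randomly subsampled (seeded) to the smaller's count; trial
    order is preserved.  Contrast levels with zero trials in either condition
    are dropped (recorded in the returned log).  Raises when no contrast
    level has trials in both conditions.
    """
    rng = np.random.default_rng(seed)
    in_a = np.asarray(in_a, dtype=bool)
    in_b = np.asarray(in_b, dtype=bool)
    keep_a = np.zeros(len(matrix), dtype=bool)
    keep_b = np.zeros(len(matrix), dtype=bool)
    log = {"dropped_contrasts": [], "per_contrast_n": {}}

    for c in np.unique(matrix.contrasts):
        ia = np.flatnonzero(in_a & (matrix.contrasts == c))
        ib = np.flatnonzero(in_b & (matrix.contrasts == c))
        if ia.size == 0 or ib.size == 0:
            if ia.size or ib.size:
                log["dropped_contrasts"].append(float(c))
            continue
        n = min(ia.size, ib.size)
        if ia.size > n:
            ia = np.sort(rng.choice(ia, size=n, replace=False))
        if ib.size > n:
            ib = np.sort(rng.choice(ib, size=n, replace=False))
        keep_a[ia] = True
        keep_b[ib] = True
        log["per_contrast_n"][float(c)] = n

    if not keep_a.any():
        raise ValueError("no contrast level has trials in both conditions")
    out_a, out_b = matrix.subset(keep_a), matrix.subset(keep_b)
    # post-hoc assertion: equalization preserves per-contrast balance exactly
    for c in log["per_contrast_n"]:
        assert (out_a.contrasts == c).sum() == (out_b.contrasts == c).sum()
    return out_a, out_b, log


def decode_stimulus(
    matrix: SpikeCountMatrix,
    seed: int = 0,
    n_folds: int = 5,
    Cs: np.ndarray | None = None,
) -> dict:
    """Cross-validated accuracy of L2 logistic regression on spike counts.

    Stratified 5-fold CV; the L2 penalty is chosen by inner cross-validation
    over a fixed log-spaced grid.  Returns ``{"accuracy", "log_loss", "n",
    "n_units"}``.
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.metrics import log_loss
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(matrix.labels, dtype=int)
    if len(matrix) < 10:
        raise ValueError("need at least 10 trials")
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    X = matrix.counts.astype(float)
    if Cs is None:
        Cs = np.logspace(-3, 2, 6)

    import warnings

    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs, losses = [], []
    for tr_idx, te_idx in outer.split(X, y):
        inner_folds = min(3, np.bincount(y[tr_idx]).min())
        with warnings.catch_warnings():
            # scikit-learn 1.9 emits transition FutureWarnings for the
            # penalty/l1_ratios API; the fit is plain L2 either way
            warnings.simplefilter("ignore", FutureWarning)
            model = LogisticRegressionCV(
                Cs=Cs, cv=max(2, inner_folds), penalty="l2", max_iter=2000,
                scoring="accuracy", random_state=seed,
            ).fit(X[tr_idx], y[tr_idx])
        accs.append(model.score(X[te_idx], y[te_idx]))
        proba = model.predict_proba(X[te_idx])
        losses.append(log_loss(y[te_idx], proba, labels=[0, 1]))
    return {
        "accuracy": float(np.mean(accs)),
        "log_loss": float(np.mean(losses)),
        "n": int(len(y)),
        "n_units": int(X.shape[1]),
    }


def median_state_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Split trials strictly below / strictly above the median of a measure.

    Ties at the median are excluded (keeps "below and above the median"
    literal).  Returns boolean masks ``(low, high)`` plus a count log.
    Raises when all values are identical (degenerate split).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("need at least 2 trials with a finite measure")
    med = np.median(values[finite])
    low = finite & (values < med)
    high = finite & (values > med)
    if not low.any() and not high.any():
        raise ValueError("all values identical: median split is empty")
    log = {"median": float(med), "n_low": int(low.sum()),
           "n_high": int(high.sum()),
           "n_excluded_ties": int(finite.sum() - low.sum() - high.sum())}
    return low, high, log
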