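"""Trial classification and state-behavior statistics.

Trials fall into five outcomes: Correct Choice and Incorrect Choice (a wheel
response within the response window), Miss (no response when one was
required), and -- on zero-contrast No-Go trials -- Correct Reject (response
withheld) and False Alarm (wheel turned).  Cortical state is measured in the
enforced pre-stimulus quiescent window; trials with quiescent periods shorter
than 0.7 s are excluded.

The module joins per-trial band power at named ROI pixels to outcomes and
provides the analyses built on that table: percentile rate curves, reaction
time residual correlations, the pupil ANCOVA (parallel-lines intercept
difference) and the mixed-model fitting contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROISet",
    "PercentileRates",
    "AncovaResult",
    "classify_trials",
    "extract_quiescent_windows",
    "percentile_rates",
    "rt_power_correlation",
    "pupil_ancova",
    "fit_state_mixed_model",
    "fit_percentile_glmm",
    "default_roi_set",
]

MIN_QUIESCENT_S = 0.7
PERCENTILE_POINTS = (20.0, 40.0, 60.0, 80.0)
CHOICE_OUTCOMES = ("CorrectChoice", "IncorrectChoice")


@dataclass
class ROISet:
    """Named ROI pixel coordinates, e.g. {"VIS": (4, 4), "SS": (10, 6)}."""

    rois: dict[str, tuple[int, int]]

    def __post_init__(self):
        if len(set(self.rois)) != len(self.rois):
            raise ValueError("ROI names must be unique")

    def validate_grid(self, pixel_shape: tuple[int, int]) -> None:
        for name, (r, c) in self.rois.items():
            if not (0 <= r < pixel_shape[0] and 0 <= c < pixel_shape[1]):
                raise ValueError(f"ROI {name} at ({r},{c}) outside grid {pixel_shape}")

    def items(self):
        return self.rois.items()

    def names(self):
        return list(self.rois)


def default_roi_set(grid_size: int) -> ROISet:
    """Stereotypic ROI placement scaled to a square grid."""
    g = grid_size
    return ROISet({
        "VIS": (g // 4, g // 4),
        "SS": (g // 2, 3 * g // 4),
        "AUD": (3 * g // 4, g // 8),
        "RSP": (g // 2, g // 2),
        "MO": (7 * g // 8, g // 2),
    })


# ---------------------------------------------------------------------------
# trial classification and quiescent windows


def classify_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Assign outcomes from raw trial events.

    Requires columns ``contrast_left``, ``contrast_right``,
    ``response_direction`` (-1 left / +1 right / 0 none), ``response_s``
    (NaN when no response), ``gocue_s`` and ``response_window_end_s``.
    Optional ``reward_side`` breaks equal-contrast ties (those trials are
    rewarded at random by the task).

    Adds ``outcome``, ``rewarded``, ``reaction_time_s`` (go cue to response)
    and ``valid`` (False for contradictory events: a response recorded outside
    the response window).
    """
    df = events.copy()
    n = len(df)
    outcome = np.empty(n, dtype=object)
    valid = np.ones(n, dtype=bool)

    cl = df["contrast_left"].to_numpy(float)
    cr = df["contrast_right"].to_numpy(float)
    resp = df["response_s"].to_numpy(float)
    direction = df["response_direction"].to_numpy(int)
    gocue = df["gocue_s"].to_numpy(float)
    win_end = df["response_window_end_s"].to_numpy(float)
    reward_side = (df["reward_side"].to_numpy(int)
                   if "reward_side" in df else np.zeros(n, dtype=int))

    responded = np.isfinite(resp)
    out_of_window = responded & ((resp <= gocue) | (resp > win_end))
    if np.any(out_of_window):
        valid[out_of_window] = False
        warnings.warn(
            f"{int(out_of_window.sum())} trial(s) with a response outside the "
            "response window were flagged invalid and excluded",
            stacklevel=2,
        )

    stim_present = (cl > 0) | (cr > 0)
    correct_side = np.where(cr > cl, 1, np.where(cl > cr, -1, reward_side))

    for i in range(n):
        if not valid[i]:
            outcome[i] = "Invalid"
        elif stim_present[i]:
            if not responded[i]:
                outcome[i] = "Miss"
            elif direction[i] == correct_side[i] and correct_side[i] != 0:
                outcome[i] = "CorrectChoice"
            else:
                outcome[i] = "IncorrectChoice"
        else:
            outcome[i] = "FalseAlarm" if responded[i] else "CorrectReject"

    df["outcome"] = outcome
    df["valid"] = valid
    df["rewarded"] = np.isin(outcome, ("CorrectChoice", "CorrectReject"))
    df["reaction_time_s"] = np.where(responded, resp - gocue, np.nan)
    return df


def extract_quiescent_windows(
    trials: pd.DataFrame,
    min_duration_s: float = MIN_QUIESCENT_S,
) -> tuple[list[tuple[int, tuple[float, float]]], int]:
    """Valid pre-stimulus state windows ``[quiescent_start, quiescent_end)``.

    Trials with quiescent duration strictly less than ``min_duration_s`` are
    excluded (a 0.7 s window is included).  Returns ``(windows, n_excluded)``
    where each window is ``(trial_index, (start_s, end_s))``.
    """
    windows = []
    n_excluded = 0
    for i, tr in trials.iterrows():
        dur = tr.quiescent_end_s - tr.quiescent_start_s
        if dur < min_duration_s:
            n_excluded += 1
            continue
        windows.append((i, (float(tr.quiescent_start_s), float(tr.quiescent_end_s))))
    return windows, n_excluded


# ---------------------------------------------------------------------------
# percentile rate curves


@dataclass
class PercentileRates:
    """Per-percentile-bin trial counts and outcome rates for one ROI."""

    bin_edges: np.ndarray            # power values at the 20/40/60/80% points
    counts: pd.DataFrame             # one row per bin
    rates: pd.DataFrame              # one row per bin, percentages
    roi: str = ""

    def check_complementarity(self) -> None:
        c, r = self.counts, self.rates
        for i in range(len(c)):
            if c.N_contrast[i] > 0:
                assert abs(r.pct_choice[i] + r.pct_miss[i] - 100.0) < 1e-9
            if c.N_nonequalContrast[i] > 0:
                assert abs(r.pct_correct[i] + r.pct_incorrect[i] - 100.0) < 1e-9
            if c.N_zero[i] > 0:
                assert abs(r.pct_reject[i] + r.pct_falsealarm[i] - 100.0) < 1e-9


def _percentile_bin(power: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin membership: [0,20), [20,40), [40,60), [60,80), [80,100]."""
    return np.searchsorted(edges, power, side="right")


def percentile_rates(table: pd.DataFrame, roi: str,
                     power_column: str | None = None,
                     edges_mode: str = "percentile") -> PercentileRates:
    """Outcome rates per power-percentile bin for one ROI.

    Power values at the 20/40/60/80% points of the session's per-trial ROI
    power define five bins; each trial is classified into a bin, and within
    each bin the rates are::

        %Choice  = N_choice / N_contrast * 100     (stimulus-present trials)
        %Miss    = N_miss / N_contrast * 100
        %Correct = N_correct / N_nonequalContrast * 100
        %Incorrect likewise (equal-contrast trials excluded: rewarded randomly)
        %CorrectReject = N_reject / N_zero * 100   (zero-contrast trials)
        %FalseAlarm likewise

    ``edges_mode="percentile"`` (default) uses distribution percentiles with
    linear interpolation between order statistics; ``"fraction_of_max"`` uses
    fixed fractions of the maximum power instead.
    """
    col = power_column or f"power_{roi}"
    power = table[col].to_numpy(float)
    finite = np.isfinite(power)
    if finite.sum() < 5:
        raise ValueError("need at least 5 trials with finite power")
    power = power[finite]
    sub = table.loc[finite].reset_index(drop=True)

    if edges_mode == "percentile":
        edges = np.percentile(power, PERCENTILE_POINTS)
    elif edges_mode == "fraction_of_max":
        edges = power.max() * np.asarray(PERCENTILE_POINTS) / 100.0
    else:
        raise ValueError(f"unknown edges_mode {edges_mode!r}")
    if np.all(edges == edges[0]) and power.min() == power.max():
        warnings.warn("all powers identical: single-bin degenerate case", stacklevel=2)

    bins = _percentile_bin(power, edges)
    outcome = sub["outcome"].to_numpy(object)
    cl = sub["contrast_left"].to_numpy(float)
    cr = sub["contrast_right"].to_numpy(float)
    stim = (cl > 0) | (cr > 0)
    equal_contrast = stim & (cl == cr)
    is_choice = np.isin(outcome, CHOICE_OUTCOMES)

    rows_c, rows_r = [], []
    for b in range(5):
        m = bins == b
        n_contrast = int(np.sum(m & stim))
        n_choice = int(np.sum(m & stim & is_choice))
        n_miss = int(np.sum(m & (outcome == "Miss")))
        n_noneq = int(np.sum(m & is_choice & ~equal_contrast))
        n_correct = int(np.sum(m & (outcome == "CorrectChoice") & ~equal_contrast))
        n_incorrect = int(np.sum(m & (outcome == "IncorrectChoice") & ~equal_contrast))
        n_zero = int(np.sum(m & ~stim))
        n_reject = int(np.sum(m & (outcome == "CorrectReject")))
        n_fa = int(np.sum(m & (outcome == "FalseAlarm")))
        rows_c.append(dict(
            N_trials=int(m.sum()), N_contrast=n_contrast, N_choice=n_choice,
            N_miss=n_miss, N_nonequalContrast=n_noneq, N_correct=n_correct,
            N_incorrect=n_incorrect, N_zero=n_zero, N_reject=n_reject,
            N_falsealarm=n_fa,
        ))

        def pct(num, den):
            return 100.0 * num / den if den > 0 else np.nan

        rows_r.append(dict(
            pct_choice=pct(n_choice, n_contrast),
            pct_miss=pct(n_miss, n_contrast),
            pct_correct=pct(n_correct, n_noneq),
            pct_incorrect=pct(n_incorrect, n_noneq),
            pct_reject=pct(n_reject, n_zero),
            pct_falsealarm=pct(n_fa, n_zero),
        ))

    result = PercentileRates(
        bin_edges=np.asarray(edges),
        counts=pd.DataFrame(rows_c),
        rates=pd.DataFrame(rows_r),
        roi=roi,
    )
    result.check_complementarity()
    return result


# ---------------------------------------------------------------------------
# reaction times and pupil


def rt_power_correlation(table: pd.DataFrame, roi: str) -> tuple[float, float, int]:
    """Pearson correlation of contrast-residualized reaction time with power.

    Reaction time (go cue to response) varies with stimulus strength, so the
    mean RT per contrast pair is subtracted first; the residuals are
    correlated with the trial's ROI band power over Choice trials.  Raises
    when the residuals have zero variance (undefined correlation).
    """
    col = f"power_{roi}"
    sub = table[np.isin(table["outcome"], CHOICE_OUTCOMES)
                & np.isfinite(table["reaction_time_s"])
                & np.isfinite(table[col])].copy()
    if len(sub) < 3:
        raise ValueError("need at least 3 Choice trials with reaction times")
    key = list(zip(sub["contrast_left"], sub["contrast_right"]))
    sub["__contrast_key"] = key
    resid = sub["reaction_time_s"] - sub.groupby("__contrast_key")[
        "reaction_time_s"].transform("mean")
    if resid.std() == 0 or sub[col].std() == 0:
        raise ValueError("zero-variance residuals: correlation undefined")
    r, p = stats.pearsonr(resid, sub[col])
    return float(r), float(p), int(len(sub))


@dataclass
class AncovaResult:
    """Parallel-lines ANCOVA of power on a pupil covariate by condition."""

    slope: float                     # common slope (power per covariate unit)
    intercepts: dict[str, float]
    intercept_difference: float      # condition b - condition a
    se: float                        # standard error of the difference
    p_value: float
    n_per_condition: dict[str, int]


def pupil_ancova(table: pd.DataFrame, roi: str,
                 covariate: str = "diameter",
                 conditions: tuple[str, str] = ("Choice", "Miss")) -> AncovaResult:
    """Fit power ~ covariate + condition (one shared slope, two intercepts).

    The intercept difference (second minus first condition) captures the main
    effect of behavioral condition on power after accounting for the common
    pupil effect; its two-sided t-test p-value is returned.  ``covariate`` is
    ``"diameter"`` (column ``pupil_mean``) or ``"derivative"``
    (``pupil_derivative_mean``).
    """
    import statsmodels.api as sm

    col_map = {"diameter": "pupil_mean", "derivative": "pupil_derivative_mean"}
    cov_col = col_map[covariate]
    pow_col = f"power_{roi}"

    def cond_of(o):
        if o in CHOICE_OUTCOMES:
            return "Choice"
        return o

    cond = table["outcome"].map(cond_of)
    keep = cond.isin(conditions) & np.isfinite(table[cov_col]) & np.isfinite(table[pow_col])
    sub = table[keep]
    cond = cond[keep]
    counts = {c: int((cond == c).sum()) for c in conditions}
    if min(counts.values()) < 3:
        raise ValueError(f"need >= 3 trials per condition, got {counts}")

    is_b = (cond == conditions[1]).to_numpy(float)
    X = np.column_stack([
        np.ones(len(sub)),
        sub[cov_col].to_numpy(float),
        is_b,
    ])
    fit = sm.OLS(sub[pow_col].to_numpy(float), X).fit()
    slope = float(fit.params[1])
    delta = float(fit.params[2])
    return AncovaResult(
        slope=slope,
        intercepts={conditions[0]: float(fit.params[0]),
                    conditions[1]: float(fit.params[0] + delta)},
        intercept_difference=delta,
        se=float(fit.bse[2]),
        p_value=float(fit.pvalues[2]),
        n_per_condition=counts,
    )


# ---------------------------------------------------------------------------
# mixed models


def _to_long(table: pd.DataFrame, rois: list[str]) -> pd.DataFrame:
    long = table.melt(
        id_vars=[c for c in table.columns if not c.startswith("power_")],
        value_vars=[f"power_{r}" for r in rois],
        var_name="area", value_name="power",
    )
    long["area"] = long["area"].str.removeprefix("power_")
    return long


def fit_state_mixed_model(
    table: pd.DataFrame,
    condition_pair: tuple[str, str] = ("Choice", "Miss"),
    with_interaction: bool = False,
    rois: list[str] | None = None,
    power_in_db: bool = True,
) -> pd.DataFrame:
    """Nested mixed model of band power on trial condition and cortical area.

    Fixed effects: condition and area (plus their interaction on request).
    Random effects: area-dependent offsets nested by genotype, subject within
    genotype, and session within subject -- expressed as independent variance
    components (one variance per nesting level x area combination).  Fitted by
    maximum likelihood with :mod:`statsmodels` ``MixedLM``.

    With a single session the random effects are unidentifiable and the model
    collapses to ordinary least squares of ``power ~ cond + area``.

    Returns a DataFrame of fixed-effect estimates, SEs and p-values (rows for
    the condition effect and, when requested, condition x area terms).
    Non-convergence raises with diagnostics.
    """
    import statsmodels.formula.api as smf

    if rois is None:
        rois = sorted(c.removeprefix("power_") for c in table.columns
                      if c.startswith("power_") and not c.endswith("_db"))
    cols = [f"power_{r}" + ("_db" if power_in_db else "") for r in rois]
    work = table.copy()
    for r, c in zip(rois, cols):
        work[f"power_{r}"] = work[c]

    def cond_of(o):
        return "Choice" if o in CHOICE_OUTCOMES else o

    work["cond"] = work["outcome"].map(cond_of)
    work = work[work["cond"].isin(condition_pair)]
    long = _to_long(work, rois).dropna(subset=["power"])
    long["cond"] = pd.Categorical(long["cond"], categories=list(condition_pair))

    fixed = "power ~ C(cond) * C(area)" if with_interaction else "power ~ C(cond) + C(area)"
    n_sessions = long["session_id"].nunique()

    if n_sessions < 2:
        import statsmodels.api as sm

        fit = smf.ols(fixed, data=long).fit()
        out = _collect_fixed(fit.params, fit.bse, fit.pvalues)
        out["model"] = "ols_single_session"
        return out

    # single top-level group; each nesting level enters as an independent
    # variance component with area-dependent offsets (the model's covariance
    # is diagonal per level x area cell rather than unstructured per level)
    long["grp"] = "all"
    vc = {"session_area": "0 + C(session_id):C(area)"}
    if long["genotype_id"].nunique() > 1:
        vc["genotype_area"] = "0 + C(genotype_id):C(area)"
    if long["subject_id"].nunique() > 1:
        vc["subject_area"] = "0 + C(subject_id):C(area)"

    md = smf.mixedlm(fixed, data=long, groups="grp",
                     re_formula="0", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = md.fit(reml=False, method=["lbfgs", "powell"], maxiter=400)
    if not fit.converged:
        raise RuntimeError(
            f"mixed model did not converge (n={len(long)}, sessions={n_sessions}); "
            f"gradient norm issues -- inspect the data or simplify the model"
        )
    out = _collect_fixed(fit.fe_params, fit.bse_fe, fit.pvalues[:len(fit.fe_params)])
    out["model"] = "mixedlm_vc"
    return out


def _collect_fixed(params, bse, pvalues) -> pd.DataFrame:
    rows = []
    for name in params.index:
        if "cond" in name or name == "Intercept" or "area" in name:
            rows.append(dict(term=name, estimate=float(params[name]),
                             se=float(bse[name]), p_value=float(pvalues[name])))
    return pd.DataFrame(rows)


def condition_effect(fit_result: pd.DataFrame) -> tuple[float, float, float]:
    """(estimate, se, p) of the condition main effect from the fit table."""
    rows = fit_result[fit_result["term"].str.contains("cond")
                      & ~fit_result["term"].str.contains(":")]
    if len(rows) != 1:
        raise ValueError(f"expected one condition main-effect row, got {len(rows)}")
    r = rows.iloc[0]
    return float(r.estimate), float(r.se), float(r.p_value)


def fit_percentile_glmm(
    table: pd.DataFrame,
    roi: str,
    response: str = "Miss",
) -> dict:
    """Logistic mixed model: response ~ 1 + powerPercentile + (1 | session).

    The power percentile (1-5) of each trial within its session is the fixed
    covariate; sessions get random intercepts.  ``response`` selects the
    binary outcome and its trial subset: ``Miss`` (vs Choice, stimulus-present
    trials), ``FalseAlarm`` (vs Correct Reject, zero-contrast trials) or
    ``Incorrect`` (vs Correct, non-equal-contrast Choice trials).

    Returns ``{"slope", "ci_low", "ci_high", "p_value", "n", "separation"}``.
    Complete separation is reported explicitly; the slope then comes from the
    variational fit, flagged.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    col = f"power_{roi}"
    work = table[np.isfinite(table[col])].copy()

    if response == "Miss":
        stim = (work["contrast_left"] > 0) | (work["contrast_right"] > 0)
        work = work[stim & work["outcome"].isin(CHOICE_OUTCOMES + ("Miss",))]
        y = (work["outcome"] == "Miss").astype(int)
    elif response == "FalseAlarm":
        zero = (work["contrast_left"] == 0) & (work["contrast_right"] == 0)
        work = work[zero]
        y = (work["outcome"] == "FalseAlarm").astype(int)
    elif response == "Incorrect":
        keep = work["outcome"].isin(CHOICE_OUTCOMES) \
            & ~((work["contrast_left"] == work["contrast_right"]))
        work = work[keep]
        y = (work["outcome"] == "IncorrectChoice").astype(int)
    else:
        raise ValueError(f"unknown response {response!r}")

    if work["session_id"].nunique() < 2:
        raise ValueError("need >= 2 sessions for the random-intercept model")
    if y.nunique() < 2:
        raise ValueError("all responses identical: complete separation")

    # session-wise power percentile bin, 1..5
    def bin_session(g):
        edges = np.percentile(g, PERCENTILE_POINTS)
        return pd.Series(np.searchsorted(edges, g, side="right") + 1, index=g.index)

    work = work.assign(y=y)
    work["powerPercentile"] = work.groupby("session_id")[col].transform(bin_session)

    # separation check: does any percentile value have only one response?
    tab = pd.crosstab(work["powerPercentile"], work["y"])
    separated = bool((tab == 0).any(axis=None)) and (
        (tab.loc[:, 0] == 0).all() or (tab.loc[:, 1] == 0).all()
    )

    exog = np.column_stack([np.ones(len(work)),
                            work["powerPercentile"].to_numpy(float)])
    sessions = pd.Categorical(work["session_id"])
    exog_vc = pd.get_dummies(sessions).to_numpy(float)
    ident = np.zeros(exog_vc.shape[1], dtype=int)

    model = BinomialBayesMixedGLM(work["y"].to_numpy(float), exog, exog_vc, ident)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit_vb()
    slope = float(fit.fe_mean[1])
    sd = float(fit.fe_sd[1])
    z = slope / sd if sd > 0 else np.inf
    p = 2 * stats.norm.sf(abs(z))
    return {
        "slope": slope,
        "ci_low": slope - 1.96 * sd,
        "ci_high": slope + 1.96 * sd,
        "p_value": float(p),
        "n": int(len(work)),
        "separation": separated,
    }
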