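import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import make_state_table
from wfstate.behavior import (
    classify_trials,
    default_roi_set,
    extract_quiescent_windows,
    fit_percentile_glmm,
    fit_state_mixed_model,
    condition_effect,
    percentile_rates,
    pupil_ancova,
    rt_power_correlation,
)


def events_frame(rows):
    defaults = dict(contrast_left=0.0, contrast_right=0.0, response_direction=0,
                    response_s=np.nan, gocue_s=1.0, response_window_end_s=3.0,
                    reward_side=0, quiescent_start_s=0.0, quiescent_end_s=0.9)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestClassifyTrials:
    def test_correct_choice_from_in_window_turn(self):
        df = classify_trials(events_frame([
            dict(contrast_right=0.5, response_direction=1, response_s=1.5)]))
        assert df.outcome[0] == "CorrectChoice" and df.rewarded[0]
        assert df.reaction_time_s[0] == pytest.approx(0.5)

    def test_wrong_direction_is_incorrect_choice(self):
        df = classify_trials(events_frame([
            dict(contrast_right=0.5, response_direction=-1, response_s=1.5)]))
        assert df.outcome[0] == "IncorrectChoice" and not df.rewarded[0]

    def test_zero_contrast_no_movement_is_correct_reject(self):
        df = classify_trials(events_frame([dict()]))
        assert df.outcome[0] == "CorrectReject" and df.rewarded[0]

    def test_zero_contrast_turn_is_false_alarm(self):
        df = classify_trials(events_frame([
            dict(response_direction=1, response_s=2.0)]))
        assert df.outcome[0] == "FalseAlarm"

    def test_stimulus_with_no_response_is_miss(self):
        df = classify_trials(events_frame([dict(contrast_left=1.0)]))
        assert df.outcome[0] == "Miss"

    def test_response_outside_window_flagged_invalid(self):
        with pytest.warns(UserWarning, match="invalid"):
            df = classify_trials(events_frame([
                dict(contrast_left=0.5, response_direction=-1, response_s=5.0)]))
        assert not df.valid[0]
        assert df.outcome[0] == "Invalid"

    def test_equal_contrast_reward_side_breaks_tie(self):
        df = classify_trials(events_frame([
            dict(contrast_left=0.5, contrast_right=0.5, reward_side=-1,
                 response_direction=-1, response_s=1.5),
            dict(contrast_left=0.5, contrast_right=0.5, reward_side=-1,
                 response_direction=1, response_s=1.5)]))
        assert list(df.outcome) == ["CorrectChoice", "IncorrectChoice"]

    def test_matches_generator_outcomes_end_to_end(self):
        from wfstate.synthio import SimConfig, generate_trials

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trials, _ = generate_trials(SimConfig(n_trials=300, seed=5))
        reclassified = classify_trials(trials.drop(columns=["outcome", "rewarded"]))
        assert (reclassified.outcome == trials.outcome).all()
        assert (reclassified.rewarded == trials.rewarded).all()


class TestQuiescentWindows:
    def test_short_quiescence_excluded_boundary_included(self):
        trials = events_frame([
            dict(quiescent_start_s=0.0, quiescent_end_s=0.6),    # 0.6 s: out
            dict(quiescent_start_s=0.0, quiescent_end_s=0.7),    # exactly 0.7: in
            dict(quiescent_start_s=0.0, quiescent_end_s=1.5)])
        windows, n_excluded = extract_quiescent_windows(trials)
        assert n_excluded == 1
        assert [w[0] for w in windows] == [1, 2]
        assert windows[0][1] == (0.0, 0.7)

    def test_empty_table_gives_empty_list(self):
        windows, n_excluded = extract_quiescent_windows(events_frame([]))
        assert windows == [] and n_excluded == 0


def worked_example_table():
    """250-trial table whose lowest-power 50 trials have the documented
    composition: 40 stimulus trials (36 Choice of which 1 equal-contrast,
    4 Miss; among non-equal Choice: 28 Correct, 7 Incorrect) and 10
    zero-contrast trials (6 Correct Reject, 4 False Alarm)."""
    rows = []

    def add(n, outcome, cl, cr):
        for _ in range(n):
            rows.append(dict(outcome=outcome, contrast_left=cl, contrast_right=cr))

    add(28, "CorrectChoice", 0.0, 0.5)
    add(7, "IncorrectChoice", 0.0, 0.5)
    add(1, "CorrectChoice", 0.5, 0.5)        # equal contrast, excluded from C/I
    add(4, "Miss", 0.0, 1.0)
    add(6, "CorrectReject", 0.0, 0.0)
    add(4, "FalseAlarm", 0.0, 0.0)
    assert len(rows) == 50
    # 200 filler trials with higher power, arbitrary outcomes
    for i in range(200):
        rows.append(dict(outcome="CorrectChoice", contrast_left=0.0, contrast_right=1.0))
    df = pd.DataFrame(rows)
    df["power_VIS"] = np.arange(1.0, 251.0)   # first 50 = lowest power
    return df


class TestPercentileRates:
    def test_reproduces_documented_worked_example(self):
        res = percentile_rates(worked_example_table(), "VIS")
        c0 = res.counts.iloc[0]
        assert (c0.N_trials, c0.N_contrast, c0.N_choice, c0.N_miss) == (50, 40, 36, 4)
        assert (c0.N_nonequalContrast, c0.N_correct, c0.N_incorrect) == (35, 28, 7)
        assert (c0.N_zero, c0.N_reject, c0.N_falsealarm) == (10, 6, 4)
        r0 = res.rates.iloc[0]
        assert r0.pct_choice == 90.0 and r0.pct_miss == 10.0
        assert r0.pct_correct == 80.0 and r0.pct_incorrect == 20.0
        assert r0.pct_reject == 60.0 and r0.pct_falsealarm == 40.0

    def test_distinct_powers_give_equal_bins(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "power_VIS": np.arange(1.0, 101.0),
            "outcome": rng.choice(["CorrectChoice", "Miss"], 100),
            "contrast_left": 0.0,
            "contrast_right": 0.5,
        })
        res = percentile_rates(df, "VIS")
        assert list(res.counts.N_trials) == [20, 20, 20, 20, 20]

    def test_all_choice_gives_zero_miss_everywhere(self):
        df = pd.DataFrame({
            "power_VIS": np.linspace(1, 2, 40),
            "outcome": "CorrectChoice",
            "contrast_left": 0.0,
            "contrast_right": 1.0,
        })
        res = percentile_rates(df, "VIS")
        assert (res.rates.pct_miss.dropna() == 0).all()

    def test_identical_powers_warn_single_bin(self):
        df = pd.DataFrame({
            "power_VIS": np.ones(20),
            "outcome": "CorrectChoice",
            "contrast_left": 0.0,
            "contrast_right": 1.0,
        })
        with pytest.warns(UserWarning, match="single-bin"):
            res = percentile_rates(df, "VIS")
        assert res.counts.N_trials.sum() == 20

    def test_too_few_trials_raises(self):
        df = worked_example_table().head(3)
        with pytest.raises(ValueError):
            percentile_rates(df, "VIS")


class TestRtPowerCorrelation:
    @staticmethod
    def synthetic_table(rng, n=120, slope=0.05, noise=0.02):
        power = rng.uniform(0, 10, n)
        contrast = rng.choice([0.25, 0.5, 1.0], n)
        rt = 0.3 + slope * power + 0.2 * (1 - contrast) + noise * rng.standard_normal(n)
        return pd.DataFrame({
            "power_VIS": power, "reaction_time_s": rt,
            "outcome": "CorrectChoice",
            "contrast_left": 0.0, "contrast_right": contrast,
        })

    def test_positive_slope_recovered_across_seeds(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            r, p, n = rt_power_correlation(self.synthetic_table(rng), "VIS")
            hits += r > 0
        assert hits >= 29

    def test_shuffled_power_gives_null_correlation(self):
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            df = self.synthetic_table(rng)
            df["power_VIS"] = rng.permutation(df["power_VIS"].to_numpy())
            rs.append(rt_power_correlation(df, "VIS")[0])
        assert abs(np.mean(rs)) < 2 / np.sqrt(120)

    def test_zero_variance_residuals_signal_undefined(self):
        df = pd.DataFrame({
            "power_VIS": [1.0, 2.0, 3.0, 4.0],
            "reaction_time_s": [0.5, 0.5, 0.7, 0.7],
            "outcome": "CorrectChoice",
            "contrast_left": 0.0, "contrast_right": [0.5, 0.5, 1.0, 1.0],
        })
        with pytest.raises(ValueError, match="undefined"):
            rt_power_correlation(df, "VIS")


class TestPupilAncova:
    @staticmethod
    def synthetic_table(rng, n=200, beta=0.8, delta=1.5, noise=1.0):
        pupil = rng.uniform(1, 5, n)
        is_miss = rng.uniform(size=n) < 0.4
        power = beta * pupil + delta * is_miss + noise * rng.standard_normal(n)
        return pd.DataFrame({
            "power_VIS": power, "pupil_mean": pupil,
            "pupil_derivative_mean": rng.standard_normal(n),
            "outcome": np.where(is_miss, "Miss", "CorrectChoice"),
        })

    def test_recovers_intercept_difference(self):
        """Generative delta is recovered: 2-SE coverage per seed and an
        unbiased mean across seeds."""
        ests, covered = [], 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            res = pupil_ancova(self.synthetic_table(rng, delta=1.5), "VIS")
            ests.append(res.intercept_difference)
            covered += abs(res.intercept_difference - 1.5) < 2 * res.se
        assert covered >= int(0.9 * 30)
        assert np.mean(ests) == pytest.approx(1.5, abs=0.15)

    def test_null_gives_small_effect_and_calibrated_p(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            res = pupil_ancova(self.synthetic_table(rng, delta=0.0), "VIS")
            ps.append(res.p_value)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.15

    def test_slope_shared_between_conditions(self):
        rng = np.random.default_rng(1)
        res = pupil_ancova(self.synthetic_table(rng), "VIS")
        # parallel lines by construction: intercept difference is the only
        # condition-dependent parameter
        assert set(res.intercepts) == {"Choice", "Miss"}
        assert res.intercepts["Miss"] - res.intercepts["Choice"] == pytest.approx(
            res.intercept_difference)

    def test_single_condition_raises(self):
        rng = np.random.default_rng(2)
        df = self.synthetic_table(rng)
        df["outcome"] = "Miss"
        with pytest.raises(ValueError):
            pupil_ancova(df, "VIS")


class TestStateMixedModel:
    def test_single_session_collapses_to_ols(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        table = make_state_table(rng, n_sessions=1, n_trials=150)
        res = fit_state_mixed_model(table)
        est, se, p = condition_effect(res)
        long = table.melt(
            id_vars=["outcome", "session_id"],
            value_vars=["power_VIS_db", "power_SS_db"],
            var_name="area", value_name="power")
        long["cond"] = np.where(long.outcome == "Miss", "Miss", "Choice")
        long["cond"] = pd.Categorical(long["cond"], categories=["Choice", "Miss"])
        ols = smf.ols("power ~ C(cond) + C(area)", data=long).fit()
        assert est == pytest.approx(ols.params["C(cond)[T.Miss]"], abs=1e-6)

    def test_recovers_injected_condition_effect(self):
        ests = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            table = make_state_table(rng, n_sessions=10, n_trials=200,
                                     cond_effect_db=-1.5)
            res = fit_state_mixed_model(table, condition_pair=("Miss", "Choice"))
            est, se, p = condition_effect(res)
            ests.append(est)
            assert p < 0.05
        assert np.mean(ests) == pytest.approx(-1.5, abs=0.3)

    def test_null_effect_not_significant_in_most_seeds(self):
        sig = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            table = make_state_table(rng, n_sessions=8, n_trials=60,
                                     cond_effect_db=0.0)
            res = fit_state_mixed_model(table)
            _, _, p = condition_effect(res)
            sig += p < 0.05
        assert sig <= 4  # ~5% nominal; binomial slack at 20 seeds


class TestPercentileGlmm:
    @staticmethod
    def simulate(rng, slope=0.4, n_sessions=10, n_trials=200):
        from scipy.special import expit

        rows = []
        for s in range(n_sessions):
            sess_off = 0.5 * rng.standard_normal()
            power = rng.uniform(0, 10, n_trials)
            edges = np.percentile(power, [20, 40, 60, 80])
            pct = np.searchsorted(edges, power, side="right") + 1
            p_miss = expit(-1.5 + sess_off + slope * pct)
            is_miss = rng.uniform(size=n_trials) < p_miss
            for i in range(n_trials):
                rows.append(dict(
                    outcome="Miss" if is_miss[i] else "CorrectChoice",
                    contrast_left=0.0, contrast_right=0.5,
                    power_VIS=power[i], session_id=f"s{s}"))
        return pd.DataFrame(rows)

    def test_positive_slope_recovered_with_ci_excluding_zero(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            res = fit_percentile_glmm(self.simulate(rng, slope=0.4), "VIS")
            hits += (res["slope"] > 0) and (res["ci_low"] > 0)
        assert hits >= 9

    def test_null_slope_centered_on_zero(self):
        slopes = [fit_percentile_glmm(
            self.simulate(np.random.default_rng(50 + s), slope=0.0), "VIS")["slope"]
            for s in range(10)]
        assert abs(np.mean(slopes)) < 0.05

    def test_identical_responses_raise(self):
        rng = np.random.default_rng(4)
        df = self.simulate(rng, slope=0.0)
        df["outcome"] = "CorrectChoice"
        with pytest.raises(ValueError, match="separation|identical"):
            fit_percentile_glmm(df, "VIS")


def test_default_roi_set_inside_grid():
    rois = default_roi_set(16)
    rois.validate_grid((16, 16))
    assert set(rois.names()) == {"VIS", "SS", "AUD", "RSP", "MO"}
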