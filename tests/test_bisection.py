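"""Psychometric model, discrimination summaries, fitting and exclusion rule."""

import math

import numpy as np
import pytest

from titrate import (
    DurationSummary,
    PsychometricFit,
    TEST_DURATIONS_S,
    TrialEvents,
    classify_fit,
    fit_pseudologistic,
    pseudologistic_p_long,
    simulate_bisection_subject,
    summarize_discrimination,
    summarize_test,
)
from titrate.synthetic import BisectionDesign, BisectionGenParams


def anchor_trial(duration, chosen, idx, latency=0.4):
    return TrialEvents(
        subject_id="S1", session_index=1, trial_index=idx,
        trial_type="bisection_free", cue_duration_s=duration,
        press_times_s=[] if chosen == "none" else [duration + latency],
        chosen_lever=chosen,
        response_latency_s=None if chosen == "none" else latency,
    )


class TestPseudologistic:
    def test_half_point_at_t50(self):
        for t50 in (3.0, 4.0, 5.5):
            assert pseudologistic_p_long(t50, t50, 0.2) == pytest.approx(0.5, abs=1e-15)

    def test_step_limit_for_small_gamma(self):
        assert pseudologistic_p_long(1.01 * 4.0, 4.0, 1e-6) > 1 - 1e-12
        assert pseudologistic_p_long(0.99 * 4.0, 4.0, 1e-6) < 1e-12

    def test_matches_arbitrary_precision_evaluation(self):
        # frozen from a 30-digit symbolic evaluation of the closed form
        assert pseudologistic_p_long(2.0, 4.0, 0.2) == pytest.approx(
            1.15168763508858762736539101254e-4, rel=1e-12)
        assert pseudologistic_p_long(5.0, 4.0, 0.2) == pytest.approx(
            0.859820435146273544331858179806, rel=1e-12)

    def test_strictly_increasing_in_duration(self):
        grid = np.linspace(1.0, 12.0, 500)
        p = pseudologistic_p_long(grid, 4.0, 0.25)
        assert np.all(np.diff(p) > 0)

    def test_gamma_flattens_the_curve_at_t50(self):
        eps = 1e-5
        slopes = [
            (pseudologistic_p_long(4 + eps, 4.0, g) - pseudologistic_p_long(4 - eps, 4.0, g))
            / (2 * eps)
            for g in (0.1, 0.2, 0.4)
        ]
        assert slopes[0] > slopes[1] > slopes[2] > 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pseudologistic_p_long(0.0, 4.0, 0.2)
        with pytest.raises(ValueError):
            pseudologistic_p_long(2.0, 4.0, -0.1)


class TestDiscriminationSummary:
    def test_percent_correct_direct_ratio(self):
        trials = [anchor_trial(2.0, "short", i) for i in range(1, 73)]
        trials += [anchor_trial(2.0, "long", i) for i in range(73, 81)]
        summ = summarize_discrimination(trials)
        assert summ.percent_correct == pytest.approx(90.0)
        assert summ.n_trials == 80 and summ.n_correct == 72

    def test_all_unanswered_gives_zero_and_absent_latencies(self):
        trials = [anchor_trial(8.0, "none", i) for i in range(1, 11)]
        summ = summarize_discrimination(trials)
        assert summ.percent_correct == 0.0
        assert summ.mean_latency_correct_ms is None
        assert summ.mean_latency_incorrect_ms is None

    def test_latencies_split_by_outcome_in_ms(self):
        trials = [anchor_trial(2.0, "short", 1, latency=0.2),
                  anchor_trial(8.0, "long", 2, latency=0.4),
                  anchor_trial(2.0, "long", 3, latency=1.0)]
        summ = summarize_discrimination(trials)
        assert summ.mean_latency_correct_ms == pytest.approx(300.0)
        assert summ.mean_latency_incorrect_ms == pytest.approx(1000.0)

    def test_non_anchor_duration_rejected(self):
        with pytest.raises(ValueError):
            summarize_discrimination([anchor_trial(4.0, "short", 1)])

    def test_near_step_subject_is_nearly_perfect(self):
        params = BisectionGenParams(
            gamma=1e-6,
            design=__import__("titrate").BisectionDesign({2.0: 500, 8.0: 500}),
        )
        trials = simulate_bisection_subject(params, seed=5)
        summ = summarize_discrimination(trials)
        assert summ.percent_correct >= 99.0


class TestSummarizeTest:
    def test_pooled_condition_counts(self):
        # two pooled test sessions: 120 per anchor, 24 per intermediate
        trials = simulate_bisection_subject(BisectionGenParams(), seed=1)
        summaries = summarize_test(trials)
        assert [s.stimulus_duration_s for s in summaries] == list(TEST_DURATIONS_S)
        assert [s.n_trials for s in summaries] == [120, 24, 24, 24, 24, 24, 120]

    def test_single_session_counts(self):
        # one test session of two 90-trial blocks: 60 per anchor, 12 per intermediate
        params = BisectionGenParams(design=BisectionDesign.single_session())
        summaries = summarize_test(simulate_bisection_subject(params, seed=1))
        assert [s.n_trials for s in summaries] == [60, 12, 12, 12, 12, 12, 60]

    def test_all_long_responses(self):
        trials = simulate_bisection_subject(
            BisectionGenParams(T50_s=4.0, gamma=1e-6), seed=2)
        # force every choice long by relabelling
        for t in trials:
            if t.chosen_lever != "none":
                t.chosen_lever = "long"
        for s in summarize_test(trials):
            assert s.p_long == 1.0

    def test_omission_rate_recovered(self):
        trials = simulate_bisection_subject(
            BisectionGenParams(omit_prob=0.4), seed=3)
        summaries = summarize_test(trials)
        total = sum(s.n_trials for s in summaries)
        responded = sum(s.n_responded for s in summaries)
        se = math.sqrt(0.4 * 0.6 / total)
        assert responded / total == pytest.approx(0.6, abs=3 * se)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_test([])


def summaries_from_probabilities(t50, gamma, n_per=(120, 12, 12, 12, 12, 12, 120)):
    """Noiseless per-duration summaries whose p_long equal the model exactly.

    Uses fractional long counts so the proportions are exact, bypassing
    binomial sampling.
    """
    return [
        DurationSummary(d, n, n, n_long=pseudologistic_p_long(d, t50, gamma) * n)
        for d, n in zip(TEST_DURATIONS_S, n_per)
    ]


class TestFit:
    def test_noiseless_self_consistency(self):
        # exact proportions generated from (4, 0.2): recovery to high precision
        fit = fit_pseudologistic(summaries_from_probabilities(4.0, 0.2))
        assert fit.T50_s == pytest.approx(4.0, abs=1e-6)
        assert fit.gamma == pytest.approx(0.2, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.usable

    def test_fit_optimum_confirmed_by_grid_search(self):
        trials = simulate_bisection_subject(BisectionGenParams(), seed=17)
        summaries = summarize_test(trials)
        fit = fit_pseudologistic(summaries)
        t = np.array([s.stimulus_duration_s for s in summaries])
        p = np.array([s.p_long for s in summaries])

        def sse(t50, g):
            return np.sum((pseudologistic_p_long(t, t50, g) - p) ** 2)

        best_grid = min(
            sse(t50, g)
            for t50 in np.linspace(2.1, 7.9, 60)
            for g in np.linspace(0.01, 1.0, 60)
        )
        assert sse(fit.T50_s, fit.gamma) <= best_grid + 1e-12

    def test_reversed_levers_flagged_unusable(self):
        # monotone-decreasing proportions cannot be fit by an increasing curve
        summaries = [
            DurationSummary(d, 100, 100, n_long=int(100 * p))
            for d, p in zip(TEST_DURATIONS_S, (0.98, 0.9, 0.75, 0.5, 0.25, 0.1, 0.02))
        ]
        fit = fit_pseudologistic(summaries)
        assert fit.r_squared <= 0.5
        assert not fit.usable

    def test_zero_response_durations_excluded_not_imputed(self):
        summaries = summaries_from_probabilities(4.0, 0.2)
        summaries[3] = DurationSummary(4.0, 12, 0, 0)
        fit = fit_pseudologistic(summaries)
        assert fit.converged

    def test_too_few_durations_rejected(self):
        with pytest.raises(ValueError):
            fit_pseudologistic(summaries_from_probabilities(4.0, 0.2)[:3])

    def test_recovery_error_shrinks_with_trials(self):
        errs = []
        for factor, seed in ((1, 101), (10, 102), (100, 103)):
            design = __import__("titrate").BisectionDesign(
                {d: 12 * factor for d in TEST_DURATIONS_S})
            t50s = []
            for subj in range(8):
                trials = simulate_bisection_subject(
                    BisectionGenParams(design=design), seed=seed * 100 + subj)
                t50s.append(fit_pseudologistic(summarize_test(trials)).T50_s)
            errs.append(abs(np.mean(t50s) - 4.0) + np.std(t50s))
        assert errs[2] < errs[0]


class TestClassifyFit:
    @pytest.mark.parametrize(
        "r2,converged,expected",
        [(0.95, True, True), (0.50, True, False), (0.51, True, True),
         (0.95, False, False)],
    )
    def test_exclusion_rule_inclusive_at_bound(self, r2, converged, expected):
        fit = PsychometricFit(T50_s=4.0, gamma=0.2, r_squared=r2,
                              converged=converged, usable=False)
        assert classify_fit(fit) is expected
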