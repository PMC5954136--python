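"""Seeded generative models of bisection and peak-interval behavior.

Every analysis stage in this package is validated by parameter recovery on
data from these generators, which emulate the two operant task designs:

* **Bisection**: 2 vs 8-s anchors plus intermediate probe durations
  {2.5, 3.2, 4, 5, 6.3} s; each responded trial is a Bernoulli "long"
  choice with probability given by the pseudologistic psychometric
  function, and trials are omitted (no response) with a fixed probability.

* **Peak interval**: FI 30-s trials (tone up to 60 s, first press after
  30 s reinforced) randomly intermixed with 90-s unreinforced probe
  trials.  On each probe trial the subject samples a remembered criterion
  m ~ lognormal with mean FI and coefficient of variation ``memory_cv``,
  and responds in three states — low, high, low — with the high state
  spanning [start, stop] where start = b_start * m * j1 and
  stop = b_stop * m * j2, the j's independent lognormal threshold jitters.
  The multiplicative structure gives scalar timing: start-time variability
  grows in proportion to the interval, so its coefficient of variation is
  independent of FI.  Presses are homogeneous Poisson within each state.

* **Stress** is modelled as trial-level parameter perturbation (response
  omission, psychometric flattening, rate scaling) plus ITI foot-shock
  events logged on the following trial; analyses ignore the shock events
  except for session labelling.

A single root seed drives per-subject child seeds derived deterministically
from the subject index, so any simulated cohort is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bisection import TEST_DURATIONS_S, pseudologistic_p_long
from .events_io import TrialEvents

__all__ = [
    "BisectionDesign",
    "BisectionGenParams",
    "PeakGenParams",
    "StressConfig",
    "simulate_bisection_subject",
    "simulate_peak_session",
    "simulate_cohort",
    "scalar_property_check",
]


def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Draw lognormal variates with the given arithmetic mean and CV."""
    if cv == 0:
        return mean if size is None else np.full(size, float(mean))
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def subject_rng(root_seed: int, subject_index: int) -> np.random.Generator:
    """Deterministic per-subject generator spawned from one root seed."""
    return np.random.default_rng(np.random.SeedSequence(root_seed).spawn(subject_index + 1)[-1])


@dataclass(frozen=True)
class BisectionDesign:
    """Trial counts per stimulus duration of a bisection test condition.

    The default pools the two test sessions of a condition cycle (each two
    90-trial blocks): 120 trials per anchor and 24 per intermediate
    duration, the counts an individual bisection curve is estimated from.
    """

    n_per_duration: dict[float, int] = field(
        default_factory=lambda: {2.0: 120, 2.5: 24, 3.2: 24, 4.0: 24, 5.0: 24, 6.3: 24, 8.0: 120}
    )

    @staticmethod
    def single_session() -> "BisectionDesign":
        """One test session of two 90-trial blocks: 60 per anchor, 12 per intermediate."""
        return BisectionDesign(
            {2.0: 60, 2.5: 12, 3.2: 12, 4.0: 12, 5.0: 12, 6.3: 12, 8.0: 60}
        )

    @property
    def n_trials(self) -> int:
        return sum(self.n_per_duration.values())


@dataclass(frozen=True)
class BisectionGenParams:
    """Generative parameters of a simulated bisection subject."""

    T50_s: float = 4.0
    gamma: float = 0.2
    omit_prob: float = 0.0
    sigma_at: str = "t"
    latency_mean_s: float = 0.5
    latency_cv: float = 0.3
    design: BisectionDesign = field(default_factory=BisectionDesign)

    def __post_init__(self) -> None:
        if not (0.0 <= self.omit_prob <= 1.0):
            raise ValueError("omit_prob must be a probability")
        if self.T50_s <= 0 or self.gamma <= 0:
            raise ValueError("T50_s and gamma must be positive")


@dataclass(frozen=True)
class PeakGenParams:
    """Generative parameters of a simulated peak-interval subject.

    ``start_threshold`` and ``stop_threshold`` multiply the per-trial memory
    sample m (mean ``fi_s``, CV ``memory_cv``); independent lognormal jitter
    of CV ``threshold_jitter_cv`` perturbs each threshold per trial.  State
    rates are presses per second.
    """

    fi_s: float = 30.0
    fi_cue_max_s: float = 60.0
    probe_window_s: float = 90.0
    memory_cv: float = 0.2
    start_threshold: float = 0.7
    stop_threshold: float = 1.5
    threshold_jitter_cv: float = 0.3
    r1: float = 0.1
    r2: float = 1.5
    r3: float = 0.1
    omit_prob: float = 0.05
    n_fi: int = 37
    n_probe: int = 18
    iti_range_s: tuple[float, float] = (10.0, 30.0)

    def __post_init__(self) -> None:
        if self.start_threshold >= self.stop_threshold:
            raise ValueError("start_threshold must be < stop_threshold")
        if min(self.r1, self.r2, self.r3) < 0:
            raise ValueError("state rates must be nonnegative")
        if not (0.0 <= self.omit_prob <= 1.0):
            raise ValueError("omit_prob must be a probability")


@dataclass(frozen=True)
class StressConfig:
    """Foot-shock session: parameter perturbation plus logged shock events."""

    n_shocks: int = 10
    shock_amp_label: str = "0.25mA_0.5s"
    omit_prob_multiplier: float = 8.0
    gamma_multiplier: float = 1.5
    rate_multiplier: float = 0.8
    min_gap_before_cue_s: float = 10.0

    def __post_init__(self) -> None:
        if min(self.omit_prob_multiplier, self.gamma_multiplier, self.rate_multiplier) < 0:
            raise ValueError("multipliers must be nonnegative")


def simulate_bisection_subject(
    params: BisectionGenParams,
    seed: int | np.random.Generator,
    *,
    subject_id: str = "S1",
    session_index: int = 1,
    stress: StressConfig | None = None,
) -> list[TrialEvents]:
    """Simulate one subject's bisection-test trials in randomized order.

    Per-duration trial counts match the design exactly.  Omitted trials
    have ``chosen_lever="none"`` and no presses; responded trials carry a
    single choice press at cue offset + latency.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamma = params.gamma
    omit_prob = params.omit_prob
    if stress is not None:
        gamma = gamma * stress.gamma_multiplier
        omit_prob = min(1.0, omit_prob * stress.omit_prob_multiplier)
    durations = [
        d for d, k in sorted(params.design.n_per_duration.items()) for _ in range(k)
    ]
    order = rng.permutation(len(durations))
    trials = []
    for idx, j in enumerate(order, start=1):
        d = durations[j]
        trial_type = "bisection_free" if d in (TEST_DURATIONS_S[0], TEST_DURATIONS_S[-1]) else "bisection_test"
        omitted = rng.random() < omit_prob
        if omitted:
            trials.append(
                TrialEvents(
                    subject_id=subject_id,
                    session_index=session_index,
                    trial_index=idx,
                    trial_type=trial_type,
                    cue_duration_s=d,
                    chosen_lever="none",
                )
            )
            continue
        p = pseudologistic_p_long(d, params.T50_s, gamma, sigma_at=params.sigma_at)
        chosen = "long" if rng.random() < p else "short"
        press_t = d + float(_lognormal_mean_cv(rng, params.latency_mean_s, params.latency_cv))
        latency = press_t - d  # store the float the event log will reproduce
        correct_anchor = (d == TEST_DURATIONS_S[0] and chosen == "short") or (
            d == TEST_DURATIONS_S[-1] and chosen == "long"
        )
        trials.append(
            TrialEvents(
                subject_id=subject_id,
                session_index=session_index,
                trial_index=idx,
                trial_type=trial_type,
                cue_duration_s=d,
                press_times_s=[press_t],
                chosen_lever=chosen,
                response_latency_s=latency,
                reinforced=trial_type == "bisection_free" and correct_anchor,
            )
        )
    if stress is not None:
        _attach_shocks(trials, stress, rng)
    return trials


def _draw_start_stop(params: PeakGenParams, rng: np.random.Generator) -> tuple[float, float]:
    """Per-trial high-state boundaries; redraws the rare jitter pairs that
    would invert start/stop so the marginals stay lognormal."""
    m = float(_lognormal_mean_cv(rng, params.fi_s, params.memory_cv))
    for _ in range(1000):
        j1 = float(_lognormal_mean_cv(rng, 1.0, params.threshold_jitter_cv))
        j2 = float(_lognormal_mean_cv(rng, 1.0, params.threshold_jitter_cv))
        start = params.start_threshold * m * j1
        stop = params.stop_threshold * m * j2
        if start < stop:
            return start, stop
    raise RuntimeError("could not draw start < stop; check thresholds")


def _poisson_press_times(
    rng: np.random.Generator, rate: float, t0: float, t1: float
) -> list[float]:
    if rate <= 0 or t1 <= t0:
        return []
    n = rng.poisson(rate * (t1 - t0))
    return sorted(rng.uniform(t0, t1, size=n).tolist())


def simulate_peak_session(
    params: PeakGenParams,
    stress: StressConfig | None = None,
    seed: int | np.random.Generator = 0,
    *,
    subject_id: str = "S1",
    session_index: int = 1,
) -> list[TrialEvents]:
    """Simulate one peak-interval session of intermixed FI and probe trials.

    FI trials terminate (reinforced) at the first press after ``fi_s``, or
    unreinforced at ``fi_cue_max_s`` if no such press occurs; probe trials
    run the full window unreinforced.  With a stress config, omission and
    rates are perturbed and shock events are interleaved in ITIs with at
    least ``min_gap_before_cue_s`` before the next cue onset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    omit_prob = params.omit_prob
    rate_mult = 1.0
    if stress is not None:
        omit_prob = min(1.0, omit_prob * stress.omit_prob_multiplier)
        rate_mult = stress.rate_multiplier
    types = ["fi"] * params.n_fi + ["probe"] * params.n_probe
    rng.shuffle(types)
    trials = []
    for idx, trial_type in enumerate(types, start=1):
        window = params.probe_window_s if trial_type == "probe" else params.fi_cue_max_s
        omitted = rng.random() < omit_prob
        if omitted:
            presses: list[float] = []
        else:
            start, stop = _draw_start_stop(params, rng)
            start = min(start, window)
            stop = min(stop, window)
            presses = (
                _poisson_press_times(rng, params.r1 * rate_mult, 0.0, start)
                + _poisson_press_times(rng, params.r2 * rate_mult, start, stop)
                + _poisson_press_times(rng, params.r3 * rate_mult, stop, window)
            )
        reinforced = False
        if trial_type == "fi":
            after = [t for t in presses if t > params.fi_s]
            if after:
                reinforced = True
                presses = [t for t in presses if t <= after[0]]
        trials.append(
            TrialEvents(
                subject_id=subject_id,
                session_index=session_index,
                trial_index=idx,
                trial_type=trial_type,
                cue_duration_s=params.probe_window_s if trial_type == "probe" else params.fi_cue_max_s,
                press_times_s=presses,
                response_latency_s=presses[0] if presses else None,
                reinforced=reinforced,
            )
        )
    if stress is not None:
        _attach_shocks(trials, stress, rng)
    return trials


def _attach_shocks(trials: list[TrialEvents], stress: StressConfig, rng: np.random.Generator) -> None:
    """Log ITI foot-shocks on pseudo-randomly chosen trials.

    Shock times are negative (seconds before the trial's cue onset) and at
    least ``min_gap_before_cue_s`` before the cue.
    """
    if not trials:
        return
    eligible = np.arange(1, len(trials))  # never before the very first trial
    k = min(stress.n_shocks, len(eligible))
    chosen = rng.choice(eligible, size=k, replace=False)
    for i in sorted(chosen.tolist()):
        gap = stress.min_gap_before_cue_s + rng.uniform(0.0, 10.0)
        trials[i].shock_times_s.append(-float(gap))


def simulate_cohort(
    n_subjects: int,
    root_seed: int,
    *,
    task: str = "peak",
    bisection_params: BisectionGenParams | None = None,
    peak_params: PeakGenParams | None = None,
    stress: StressConfig | None = None,
    sessions: tuple[int, ...] = (1,),
) -> tuple[list[TrialEvents], pd.DataFrame]:
    """Simulate a cohort and return (trials, truth table of generating params)."""
    if task not in ("peak", "bisection"):
        raise ValueError("task must be 'peak' or 'bisection'")
    all_trials: list[TrialEvents] = []
    truth_rows = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        rng = subject_rng(root_seed, i)
        for sess in sessions:
            if task == "peak":
                p = peak_params or PeakGenParams()
                all_trials.extend(
                    simulate_peak_session(p, stress, rng, subject_id=sid, session_index=sess)
                )
            else:
                p = bisection_params or BisectionGenParams()
                all_trials.extend(
                    simulate_bisection_subject(
                        p, rng, subject_id=sid, session_index=sess, stress=stress
                    )
                )
        row = {"subject_id": sid, "root_seed": root_seed, "subject_index": i}
        row.update({k: v for k, v in vars(p).items() if np.isscalar(v) or isinstance(v, str)})
        truth_rows.append(row)
    return all_trials, pd.DataFrame(truth_rows)


def scalar_property_check(
    params: PeakGenParams,
    fi_values: list[float],
    n: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Coefficient of variation of generative start times per FI value.

    Under the multiplicative (scalar) generator the CV is the same at every
    FI; the table reports per-FI mean, SD, CV and the Monte-Carlo standard
    error of the CV so invariance can be checked at simulation precision.
    """
    if n < 100:
        raise ValueError("need n >= 100 trials per FI")
    rows = []
    rng = np.random.default_rng(seed)
    for fi in fi_values:
        p = replace(params, fi_s=fi)
        starts = np.array([_draw_start_stop(p, rng)[0] for _ in range(n)])
        mean, sd = float(starts.mean()), float(starts.std(ddof=1))
        cv = sd / mean if mean > 0 else 0.0
        # asymptotic SE of a lognormal-ish CV estimate
        se_cv = cv * math.sqrt((0.5 + cv * cv) / n)
        rows.append({"fi_s": fi, "n": n, "mean_start_s": mean, "sd_start_s": sd,
                     "cv": cv, "se_cv": se_cv})
    return pd.DataFrame(rows)
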