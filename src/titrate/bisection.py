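"""Temporal-bisection performance summaries and pseudologistic psychometric fits.

In the bisection task an animal is trained to press one lever after a short
anchor duration (2 s) and another after a long anchor (8 s); test sessions add
intermediate probe durations.  The proportion of "long" classifications as a
function of stimulus duration is an ogival psychometric function, modelled
here by the pseudologistic form

    p(long | t) = 1 / (1 + exp(-pi * (t - T50) / (sqrt(3) * sigma(t))))

where ``T50`` is the point of subjective equality (PSE, the duration judged
equally often short and long) and, under the scalar-timing default,
``sigma(t) = gamma * t`` so that ``gamma`` is proportional to the Weber
fraction: larger gamma means a shallower curve and poorer temporal
sensitivity.  Constant and Poisson variance components are taken as
negligible and fixed at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .events_io import TrialEvents

__all__ = [
    "ANCHOR_SHORT_S",
    "ANCHOR_LONG_S",
    "TEST_DURATIONS_S",
    "DurationSummary",
    "PsychometricFit",
    "DiscriminationSessionSummary",
    "pseudologistic_p_long",
    "summarize_discrimination",
    "summarize_test",
    "fit_pseudologistic",
    "classify_fit",
]

ANCHOR_SHORT_S = 2.0
ANCHOR_LONG_S = 8.0
#: the seven-duration bisection test set: anchors plus five intermediates
TEST_DURATIONS_S = (2.0, 2.5, 3.2, 4.0, 5.0, 6.3, 8.0)

R_SQUARED_EXCLUSION = 0.5  # fits with r^2 <= this are excluded from analysis


@dataclass(frozen=True)
class DurationSummary:
    """Choice behavior at one stimulus duration, pooled over trials."""

    stimulus_duration_s: float
    n_trials: int
    n_responded: int
    n_long: int

    @property
    def p_respond(self) -> float:
        return self.n_responded / self.n_trials

    @property
    def p_long(self) -> float | None:
        """Proportion "long" among responded trials; None if none responded."""
        if self.n_responded == 0:
            return None
        return self.n_long / self.n_responded


@dataclass
class PsychometricFit:
    """Fitted pseudologistic parameters with fit quality."""

    T50_s: float
    gamma: float
    r_squared: float
    converged: bool
    usable: bool
    sigma_at: str = "t"
    per_duration: list[DurationSummary] = field(default_factory=list)

    def predict(self, t) -> np.ndarray | float:
        return pseudologistic_p_long(t, self.T50_s, self.gamma, sigma_at=self.sigma_at)


@dataclass(frozen=True)
class DiscriminationSessionSummary:
    """Accuracy and latency summary of one session of free-choice trials."""

    session_index: int
    n_trials: int
    n_correct: int
    percent_correct: float
    mean_latency_correct_ms: float | None
    mean_latency_incorrect_ms: float | None


def pseudologistic_p_long(
    t, T50_s: float, gamma: float, *, sigma_at: str = "t"
) -> np.ndarray | float:
    """Probability of a "long" classification at duration ``t`` seconds.

    ``sigma_at="t"`` (default) evaluates the timing noise at the probe
    duration, sigma = gamma * t (scalar variability); ``sigma_at="t50"``
    uses sigma = gamma * T50, which reduces to an ordinary logistic in t.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("stimulus duration t must be positive")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if sigma_at == "t":
        sigma = gamma * t_arr
    elif sigma_at == "t50":
        sigma = gamma * T50_s
    else:
        raise ValueError("sigma_at must be 't' or 't50'")
    z = math.pi * (t_arr - T50_s) / (math.sqrt(3.0) * sigma)
    p = special.expit(z)  # overflow-safe logistic
    return float(p) if np.isscalar(t) or t_arr.ndim == 0 else p


def _correct_lever(cue_duration_s: float) -> str:
    if cue_duration_s == ANCHOR_SHORT_S:
        return "short"
    if cue_duration_s == ANCHOR_LONG_S:
        return "long"
    raise ValueError(
        f"non-anchor duration {cue_duration_s} s in free-choice trials "
        f"(anchors are {ANCHOR_SHORT_S} and {ANCHOR_LONG_S} s)"
    )


def summarize_discrimination(trials: list[TrialEvents]) -> DiscriminationSessionSummary:
    """Percent correct and response latencies over one session's free-choice trials.

    A trial is correct when the chosen lever matches the lever assigned to
    its anchor duration; unanswered trials count as not correct.  Latency
    means (ms) are computed over responded trials per outcome and are absent
    when no trial falls in the outcome.
    """
    if not trials:
        raise ValueError("no trials given")
    n_correct = 0
    lat_correct: list[float] = []
    lat_incorrect: list[float] = []
    for t in trials:
        if not t.is_bisection:
            raise ValueError(f"trial {t.trial_index} is not a bisection trial")
        target = _correct_lever(t.cue_duration_s)
        if t.chosen_lever == target:
            n_correct += 1
            if t.response_latency_s is not None:
                lat_correct.append(t.response_latency_s)
        elif t.chosen_lever not in (None, "none"):
            if t.response_latency_s is not None:
                lat_incorrect.append(t.response_latency_s)
    return DiscriminationSessionSummary(
        session_index=trials[0].session_index,
        n_trials=len(trials),
        n_correct=n_correct,
        percent_correct=100.0 * n_correct / len(trials),
        mean_latency_correct_ms=1e3 * float(np.mean(lat_correct)) if lat_correct else None,
        mean_latency_incorrect_ms=1e3 * float(np.mean(lat_incorrect)) if lat_incorrect else None,
    )


def summarize_test(
    trials: list[TrialEvents],
    durations: tuple[float, ...] = TEST_DURATIONS_S,
) -> list[DurationSummary]:
    """Per-duration response and choice proportions over bisection-test trials.

    Trials from several sessions are pooled before proportions are computed,
    so averaging across sessions weighs every trial equally.
    """
    if not trials:
        raise ValueError("no trials given")
    allowed = set(durations)
    by_dur: dict[float, list[TrialEvents]] = {}
    for t in trials:
        if t.cue_duration_s not in allowed:
            raise ValueError(
                f"duration {t.cue_duration_s} s not in the test set {sorted(allowed)}"
            )
        by_dur.setdefault(t.cue_duration_s, []).append(t)
    out = []
    for d in sorted(by_dur):
        group = by_dur[d]
        responded = [t for t in group if t.chosen_lever not in (None, "none")]
        out.append(
            DurationSummary(
                stimulus_duration_s=d,
                n_trials=len(group),
                n_responded=len(responded),
                n_long=sum(t.chosen_lever == "long" for t in responded),
            )
        )
    return out


def classify_fit(fit: PsychometricFit, threshold: float = R_SQUARED_EXCLUSION) -> bool:
    """Inclusion rule: usable iff converged and r^2 strictly above threshold.

    The exclusion is inclusive at the bound (r^2 <= threshold is excluded).
    """
    return bool(fit.converged and fit.r_squared > threshold)


def fit_pseudologistic(
    summaries: list[DurationSummary],
    *,
    objective: str = "ls",
    sigma_at: str = "t",
    weighted: bool = False,
    threshold: float = R_SQUARED_EXCLUSION,
) -> PsychometricFit:
    """Fit the pseudologistic psychometric function to per-duration proportions.

    Parameters
    ----------
    summaries:
        Per-duration choice summaries; durations with zero responded trials
        are excluded from the fit (not imputed).
    objective:
        ``"ls"`` (default) minimizes unweighted squared error on the
        per-duration p(long) proportions; ``"ml"`` maximizes the binomial
        likelihood of the per-duration long counts.
    sigma_at:
        Noise model of :func:`pseudologistic_p_long`.
    weighted:
        With ``objective="ls"``, weight each duration's residual by its
        responded-trial count (anchors carry ~10x the trials of
        intermediates in the standard design).
    threshold:
        r^2 exclusion bound applied via :func:`classify_fit`.

    r^2 is always reported as 1 - SSE/SST over the per-duration proportions,
    matching how fit quality is screened for exclusion.
    """
    used = [s for s in summaries if s.n_responded > 0]
    if len({s.stimulus_duration_s for s in used}) < 4:
        raise ValueError("need p_long at >= 4 distinct durations to fit")
    t = np.array([s.stimulus_duration_s for s in used])
    p = np.array([s.p_long for s in used])
    n = np.array([s.n_responded for s in used], dtype=float)

    lo, hi = float(t.min()), float(t.max())
    t50_0 = math.sqrt(lo * hi)  # geometric mean of the duration range
    x0 = np.array([t50_0, 0.3])
    bounds = ([lo * (1 + 1e-9), 1e-3], [hi * (1 - 1e-9), 2.0])

    if objective == "ls":
        w = np.sqrt(n) if weighted else np.ones_like(n)

        def resid(theta):
            return w * (pseudologistic_p_long(t, theta[0], theta[1], sigma_at=sigma_at) - p)

        sol = optimize.least_squares(resid, x0, bounds=bounds, xtol=1e-12, ftol=1e-12)
        t50_hat, gamma_hat = sol.x
        converged = bool(sol.success)
    elif objective == "ml":
        k = np.array([s.n_long for s in used], dtype=float)

        def nll(theta):
            q = pseudologistic_p_long(t, theta[0], theta[1], sigma_at=sigma_at)
            q = np.clip(q, 1e-12, 1 - 1e-12)
            return -np.sum(k * np.log(q) + (n - k) * np.log(1 - q))

        sol = optimize.minimize(
            nll, x0, bounds=list(zip(*bounds)), method="L-BFGS-B"
        )
        t50_hat, gamma_hat = sol.x
        converged = bool(sol.success)
    else:
        raise ValueError("objective must be 'ls' or 'ml'")

    pred = pseudologistic_p_long(t, t50_hat, gamma_hat, sigma_at=sigma_at)
    sse = float(np.sum((p - pred) ** 2))
    sst = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -math.inf)
    fit = PsychometricFit(
        T50_s=float(t50_hat),
        gamma=float(gamma_hat),
        r_squared=r2,
        converged=converged,
        usable=False,
        sigma_at=sigma_at,
        per_duration=list(summaries),
    )
    fit.usable = classify_fit(fit, threshold)
    return fit
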