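"""Single-trial low-high-low change-point decomposition of probe trials.

On an individual probe trial a well-trained animal responds in three states:
a low rate early in the trial, an abrupt transition to a high rate around the
expected reinforcement time, and a return to a low rate afterwards.  This
module fits that three-state piecewise-constant rate model to 1-s binned
trials by exhaustive search over all legal change-point pairs, subject to
minimum state durations (high state >= 4 s, each low state >= 1 s).  The
left edges of the first and last high-state bins are the start and stop
times; spread = stop - start.  A trial qualifies for analysis only when the
high-state rate strictly exceeds both low-state rates (r2 > r1 and r2 > r3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .events_io import BinnedTrial

#: absolute score tolerance below which two segmentations count as tied
TIE_TOL = 1e-9

__all__ = [
    "ThreeStateConstraints",
    "SingleTrialResult",
    "SubjectBlockSummary",
    "BracketedCorrelations",
    "three_state_fit",
    "qualifies",
    "summarize_block",
    "bracketed_correlations",
]


@dataclass(frozen=True)
class ThreeStateConstraints:
    """Minimum state durations and the analysis window, all in seconds."""

    bin_width_s: float = 1.0
    min_high_s: float = 4.0
    min_low_s: float = 1.0
    window_s: float = 90.0

    def __post_init__(self) -> None:
        if self.min_high_s < self.bin_width_s or self.min_low_s < self.bin_width_s:
            raise ValueError("minimum state durations must be >= one bin width")

    @property
    def min_high_bins(self) -> int:
        return int(round(self.min_high_s / self.bin_width_s))

    @property
    def min_low_bins(self) -> int:
        return int(round(self.min_low_s / self.bin_width_s))


@dataclass(frozen=True)
class SingleTrialResult:
    """Three-state decomposition of one probe trial.

    ``start_s``/``stop_s`` are the left edges of the first/last high-state
    bins, so ``spread_s = stop_s - start_s`` spans ``(high bins - 1)`` bin
    widths.  ``r1, r2, r3`` are mean press rates (per second) in the three
    states and ``objective_value`` is the residual sum of squares of the
    piecewise-constant rate model at the optimum.
    """

    start_s: float
    stop_s: float
    r1: float
    r2: float
    r3: float
    objective_value: float
    qualifies: bool

    @property
    def spread_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class SubjectBlockSummary:
    """Medians, IQRs, rates and ratios over one subject's block of trials.

    Summary fields are computed over qualifying trials only and are None
    when a block has no qualifying trial; ``proportion_qualifying`` is
    taken over all trials of the block.  The initiation ratio r1/r2 and
    suppression ratio r3/r2 equal 1 under no response differentiation and
    0 under perfect differentiation.
    """

    n_trials: int
    n_qualifying: int
    median_start_s: float | None = None
    median_stop_s: float | None = None
    median_spread_s: float | None = None
    iqr_start_s: float | None = None
    iqr_stop_s: float | None = None
    iqr_spread_s: float | None = None
    mean_r1: float | None = None
    mean_r2: float | None = None
    mean_r3: float | None = None
    initiation_ratio: float | None = None
    suppression_ratio: float | None = None

    @property
    def proportion_qualifying(self) -> float:
        return self.n_qualifying / self.n_trials if self.n_trials else 0.0


@dataclass(frozen=True)
class BracketedCorrelations:
    """Pearson correlations over trials whose high state brackets the FI."""

    start_stop_r: float | None
    start_spread_r: float | None
    n_bracketed: int


def qualifies(result: SingleTrialResult) -> bool:
    """Inclusion filter: high-state rate strictly exceeds both low rates."""
    return result.r2 > result.r1 and result.r2 > result.r3


def three_state_fit(
    trial: BinnedTrial,
    constraints: ThreeStateConstraints = ThreeStateConstraints(),
    *,
    objective: str = "sse",
) -> SingleTrialResult:
    """Best low-high-low segmentation of a 1-s binned trial.

    Searches every change-point pair (s, e) — the high state occupying bins
    s..e inclusive — subject to the minimum state durations, and scores each
    candidate with the configured objective:

    - ``"sse"`` (default): residual sum of squares of the piecewise-constant
      rate model (each state's rate is its segment mean), minimized;
    - ``"index"``: the classic duration-weighted rate-difference index
      t1*(r - r1) + t2*(r2 - r) + t3*(r - r3), with r the whole-trial mean
      rate and t_k the state durations, maximized.

    Ties are broken toward the earliest start, then the earliest stop.
    """
    w = constraints.bin_width_s
    if abs(trial.bin_width_s - w) > 1e-12:
        raise ValueError("trial bin width does not match constraints")
    n = trial.n_bins
    k_low = constraints.min_low_bins
    k_high = constraints.min_high_bins
    if n < 2 * k_low + k_high:
        raise ValueError("window too short for the minimum state durations")

    x = trial.counts.astype(float) / w  # per-bin rates
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    total = csum[n]
    total2 = csum2[n]
    mean_all = total / n

    if objective not in ("sse", "index"):
        raise ValueError("objective must be 'sse' or 'index'")
    maximize = objective == "index"

    # Scores within TIE_TOL of the global optimum count as tied and resolve
    # to the earliest (start, stop) pair.  Mathematically tied segmentations
    # are common with integer counts and their float scores can differ by
    # rounding depending on summation order; genuine score differences in
    # count data are many orders of magnitude larger than the tolerance.
    starts = range(k_low, n - k_low - k_high + 1)
    per_s_scores: list[np.ndarray] = []
    for s in starts:
        e = np.arange(s + k_high - 1, n - k_low)
        n1 = float(s)
        n2 = (e - s + 1).astype(float)
        n3 = (n - 1 - e).astype(float)
        sum1 = csum[s]
        sum2 = csum[e + 1] - csum[s]
        sum3 = total - csum[e + 1]
        if maximize:
            score = -(
                n1 * w * (mean_all - sum1 / n1)
                + n2 * w * (sum2 / n2 - mean_all)
                + n3 * w * (mean_all - sum3 / n3)
            )
        else:
            # SSE = sum x^2 - sum_k (segment sum)^2 / segment length
            score = total2 - (sum1 * sum1 / n1 + sum2 * sum2 / n2 + sum3 * sum3 / n3)
        per_s_scores.append(score)
    m = min(float(sc.min()) for sc in per_s_scores)
    best: tuple[int, int] | None = None
    best_score = math.inf
    for s, score in zip(starts, per_s_scores):
        hit = np.nonzero(score <= m + TIE_TOL)[0]
        if hit.size:
            j = int(hit[0])
            best = (s, s + k_high - 1 + j)
            best_score = float(score[j])
            break
    assert best is not None
    s, e = best
    r1 = csum[s] / s
    r2 = (csum[e + 1] - csum[s]) / (e - s + 1)
    r3 = (total - csum[e + 1]) / (n - 1 - e)
    obj = -best_score if maximize else best_score
    result = SingleTrialResult(
        start_s=s * w,
        stop_s=e * w,
        r1=float(r1),
        r2=float(r2),
        r3=float(r3),
        objective_value=float(obj),
        qualifies=False,
    )
    return SingleTrialResult(
        start_s=result.start_s,
        stop_s=result.stop_s,
        r1=result.r1,
        r2=result.r2,
        r3=result.r3,
        objective_value=result.objective_value,
        qualifies=qualifies(result),
    )


def _iqr(values: np.ndarray) -> float:
    q75, q25 = np.percentile(values, [75, 25])  # linear interpolation
    return float(q75 - q25)


def summarize_block(
    results: list[SingleTrialResult],
    *,
    ratio_aggregation: str = "per_trial",
) -> SubjectBlockSummary:
    """Medians, IQRs and rate ratios over one subject's block of trials.

    Pass all of the block's results; the qualification filter is applied
    internally.  ``ratio_aggregation="per_trial"`` (default) averages each
    trial's r1/r2 and r3/r2; ``"block"`` takes the ratio of block-mean
    rates instead.
    """
    qual = [r for r in results if r.qualifies]
    summary = SubjectBlockSummary(n_trials=len(results), n_qualifying=len(qual))
    if not qual:
        return summary
    start = np.array([r.start_s for r in qual])
    stop = np.array([r.stop_s for r in qual])
    spread = np.array([r.spread_s for r in qual])
    r1 = np.array([r.r1 for r in qual])
    r2 = np.array([r.r2 for r in qual])
    r3 = np.array([r.r3 for r in qual])
    summary.median_start_s = float(np.median(start))
    summary.median_stop_s = float(np.median(stop))
    summary.median_spread_s = float(np.median(spread))
    summary.iqr_start_s = _iqr(start)
    summary.iqr_stop_s = _iqr(stop)
    summary.iqr_spread_s = _iqr(spread)
    summary.mean_r1 = float(r1.mean())
    summary.mean_r2 = float(r2.mean())
    summary.mean_r3 = float(r3.mean())
    if ratio_aggregation == "per_trial":
        # qualifying trials have r2 > r1 >= 0, hence r2 > 0
        summary.initiation_ratio = float(np.mean(r1 / r2))
        summary.suppression_ratio = float(np.mean(r3 / r2))
    elif ratio_aggregation == "block":
        summary.initiation_ratio = float(r1.mean() / r2.mean())
        summary.suppression_ratio = float(r3.mean() / r2.mean())
    else:
        raise ValueError("ratio_aggregation must be 'per_trial' or 'block'")
    return summary


def bracketed_correlations(
    results: list[SingleTrialResult],
    fi_s: float = 30.0,
    *,
    min_trials: int = 3,
) -> BracketedCorrelations:
    """Start-stop and start-spread Pearson correlations over bracketed trials.

    Only qualifying trials whose high state strictly brackets the fixed
    interval (start < fi < stop) enter the correlations.  A correlation is
    None when fewer than ``min_trials`` trials bracket or when either
    variable has zero variance.
    """
    sub = [r for r in results if r.qualifies and r.start_s < fi_s < r.stop_s]
    n = len(sub)
    if n < min_trials:
        return BracketedCorrelations(None, None, n)
    start = np.array([r.start_s for r in sub])
    stop = np.array([r.stop_s for r in sub])
    spread = np.array([r.spread_s for r in sub])

    def _r(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return None
        return float(stats.pearsonr(a, b).statistic)

    return BracketedCorrelations(_r(start, stop), _r(start, spread), n)
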