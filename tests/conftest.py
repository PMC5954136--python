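"""Shared fixtures and independent oracles for the titrate test suite."""

from __future__ import annotations

import numpy as np
import pytest

from titrate import BisectionGenParams, PeakGenParams, simulate_peak_session


def naive_three_state(
    counts,
    bin_width_s: float = 1.0,
    min_high_bins: int = 4,
    min_low_bins: int = 1,
    tie_tol: float = 1e-9,
):
    """Brute-force low-high-low segmentation by exhaustive double loop.

    Deliberately naive: every candidate recomputes its segment means and
    squared deviations from scratch.  Returns (start_bin, stop_bin, sse)
    for the earliest (start, stop) within ``tie_tol`` of the optimum.
    """
    x = np.asarray(counts, dtype=float) / bin_width_s
    n = len(x)
    scores: dict[tuple[int, int], float] = {}
    for s in range(min_low_bins, n - min_low_bins - min_high_bins + 1):
        for e in range(s + min_high_bins - 1, n - min_low_bins):
            sse = 0.0
            for seg in (x[:s], x[s : e + 1], x[e + 1 :]):
                sse += float(np.sum((seg - seg.mean()) ** 2))
            scores[(s, e)] = sse
    m = min(scores.values())
    for (s, e) in sorted(scores):
        if scores[(s, e)] <= m + tie_tol:
            return s, e, scores[(s, e)]
    raise AssertionError("unreachable")


def step_trial_counts(n_bins: int, lo_hi_lo: tuple[int, int], value: int) -> np.ndarray:
    """Counts that are ``value`` on bins [s, e] inclusive and zero elsewhere."""
    s, e = lo_hi_lo
    counts = np.zeros(n_bins, dtype=int)
    counts[s : e + 1] = value
    return counts


@pytest.fixture
def peak_params():
    return PeakGenParams()


@pytest.fixture
def bisection_params():
    return BisectionGenParams()


@pytest.fixture
def probe_trials(peak_params):
    """One seeded peak session's probe trials."""
    trials = simulate_peak_session(peak_params, seed=7)
    return [t for t in trials if t.trial_type == "probe"]
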