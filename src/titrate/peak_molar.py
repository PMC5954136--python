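"""Molar (trial-averaged) peak-interval analysis.

Probe-trial lever pressing averaged over a two-session block rises toward the
trained fixed interval (FI 30 s) and falls afterwards.  The block-averaged
rate curve is summarized by a temporal discrimination index (max rate / mean
rate) and, for the final training block, by a Gaussian + linear-ramp fit

    R(t) = a * exp(-0.5 * ((t - t0) / b)^2) + c * (t - t0) + d

whose Gaussian center ``t0`` is the peak time, ``2 b`` the width, and
``width / peak time`` the coefficient of variation.  Only probe trials enter
molar curves; FI trials are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .events_io import BinnedTrial, TrialEvents, bin_trial

__all__ = [
    "MolarCurve",
    "PeakFitResult",
    "average_block",
    "discrimination_index",
    "gaussian_ramp",
    "fit_gaussian_ramp",
    "response_proportion",
]

MOLAR_BIN_WIDTH_S = 2.0
PROBE_WINDOW_S = 90.0


@dataclass(frozen=True)
class MolarCurve:
    """Mean response rate per bin across a block's probe trials."""

    bin_width_s: float
    bin_centers_s: np.ndarray
    rate_per_s: np.ndarray
    n_trials: int
    block_id: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers_s", np.asarray(self.bin_centers_s, float))
        object.__setattr__(self, "rate_per_s", np.asarray(self.rate_per_s, float))
        if (self.rate_per_s < 0).any():
            raise ValueError("negative rate in molar curve")
        if len(self.bin_centers_s) != len(self.rate_per_s):
            raise ValueError("bin_centers_s and rate_per_s length mismatch")


@dataclass
class PeakFitResult:
    """Gaussian + ramp parameters of a molar curve.

    ``peak_time_s`` is the Gaussian center t0 (not the argmax of the
    composite curve), ``width_s = 2 b`` and ``cv = width_s / peak_time_s``.
    ``c`` and ``d`` are ramp slope and offset nuisance parameters.
    """

    a: float
    peak_time_s: float
    b: float
    c: float
    d: float
    r_squared: float
    converged: bool

    @property
    def width_s(self) -> float:
        return 2.0 * self.b

    @property
    def cv(self) -> float:
        return self.width_s / self.peak_time_s

    @property
    def peak_rate_per_s(self) -> float:
        """Fitted rate at the Gaussian center, R(t0) = a + d."""
        return gaussian_ramp(self.peak_time_s, self.a, self.peak_time_s, self.b, self.c, self.d)

    @property
    def argmax_time_s(self) -> float:
        """Alternative peak-time readout: argmax of the composite R(t) on [0, 90]."""
        grid = np.linspace(0.0, PROBE_WINDOW_S, 9001)
        vals = gaussian_ramp(grid, self.a, self.peak_time_s, self.b, self.c, self.d)
        return float(grid[np.argmax(vals)])


def average_block(
    trials: list[TrialEvents],
    *,
    bin_width_s: float = MOLAR_BIN_WIDTH_S,
    window_s: float = PROBE_WINDOW_S,
    block_id: tuple[int, int] | None = None,
) -> MolarCurve:
    """Average probe-trial press rates per bin across a two-session block."""
    if not trials:
        raise ValueError("empty block")
    if any(t.trial_type != "probe" for t in trials):
        raise ValueError("molar curves are computed over probe trials only")
    counts = np.stack(
        [bin_trial(t, bin_width_s, window_s).counts for t in trials]
    )
    rate = counts.mean(axis=0) / bin_width_s
    n_bins = counts.shape[1]
    centers = (np.arange(n_bins) + 0.5) * bin_width_s
    if block_id is None:
        sessions = sorted({t.session_index for t in trials})
        block_id = (sessions[0], sessions[-1])
    return MolarCurve(
        bin_width_s=bin_width_s,
        bin_centers_s=centers,
        rate_per_s=rate,
        n_trials=len(trials),
        block_id=block_id,
    )


def discrimination_index(curve: MolarCurve) -> float:
    """Temporal discrimination index: maximum rate divided by mean rate.

    Equals 1 for a flat curve and grows as responding concentrates around
    the criterion time; undefined (raises) for an all-zero curve.
    """
    r = curve.rate_per_s
    mean = r.mean()
    if mean == 0:
        raise ValueError("discrimination index undefined for an all-zero curve")
    return float(r.max() / mean)


def gaussian_ramp(t, a: float, t0: float, b: float, c: float, d: float):
    """Evaluate R(t) = a*exp(-0.5*((t-t0)/b)^2) + c*(t-t0) + d."""
    if b <= 0:
        raise ValueError("Gaussian width parameter b must be positive")
    t_arr = np.asarray(t, dtype=float)
    out = a * np.exp(-0.5 * ((t_arr - t0) / b) ** 2) + c * (t_arr - t0) + d
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def fit_gaussian_ramp(curve: MolarCurve) -> PeakFitResult:
    """Least-squares Gaussian + ramp fit of a molar curve.

    Initialization: t0 at the curve argmax, b = 10 s, d at the minimum rate,
    c = 0, a at max - min.  Bounds keep t0 inside the probe window and
    b in (0.5, 90) s.  A flat (degenerate) curve is reported with
    ``converged=False``.
    """
    t = curve.bin_centers_s
    y = curve.rate_per_s
    ymax, ymin = float(y.max()), float(y.min())
    if ymax == ymin:
        return PeakFitResult(
            a=0.0, peak_time_s=float(t[np.argmax(y)]), b=1.0, c=0.0, d=ymin,
            r_squared=-math.inf, converged=False,
        )
    t_lo, t_hi = 0.0, float(curve.bin_width_s * len(t))
    p0 = [ymax - ymin, float(t[np.argmax(y)]), 10.0, 0.0, ymin]
    lower = [0.0, t_lo, 0.5, -np.inf, -np.inf]
    upper = [np.inf, t_hi, t_hi, np.inf, np.inf]
    try:
        popt, _ = optimize.curve_fit(
            gaussian_ramp, t, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    a, t0, b, c, d = (float(v) for v in popt)
    pred = gaussian_ramp(t, a, t0, b, c, d)
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else -math.inf
    return PeakFitResult(a=a, peak_time_s=t0, b=b, c=c, d=d, r_squared=r2, converged=converged)


def response_proportion(trials: list[TrialEvents]) -> float:
    """Fraction of probe trials with at least one lever press."""
    if not trials:
        raise ValueError("no trials given")
    if any(t.trial_type != "probe" for t in trials):
        raise ValueError("response proportion is defined over probe trials only")
    return sum(t.n_presses > 0 for t in trials) / len(trials)
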