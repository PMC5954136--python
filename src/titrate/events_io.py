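"""Canonical data model and long-format event-log I/O for operant timing sessions.

Every analysis stage in this package consumes :class:`TrialEvents` objects.
Time is measured in seconds relative to the cue (tone) onset of each trial;
inter-trial events such as foot-shocks carry negative times on the trial that
follows them.  On disk a session is a long-format CSV with one row per event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_TYPES",
    "EVENT_TYPES",
    "CSV_COLUMNS",
    "EventRecord",
    "TrialEvents",
    "BinnedTrial",
    "Diagnostics",
    "SchemaError",
    "ValidationError",
    "read_events",
    "write_events",
    "bin_trial",
    "validate_session",
    "write_binned_matrix",
    "group_by_subject_session",
    "group_blocks",
]

TRIAL_TYPES = ("bisection_forced", "bisection_free", "bisection_test", "fi", "probe")
EVENT_TYPES = (
    "cue_on",
    "cue_off",
    "press_short_lever",
    "press_long_lever",
    "press",
    "reinforcer",
    "shock",
)
CSV_COLUMNS = (
    "subject_id",
    "session_index",
    "trial_index",
    "trial_type",
    "cue_duration_s",
    "event_type",
    "t_s",
)

_BISECTION_TYPES = frozenset({"bisection_forced", "bisection_free", "bisection_test"})
_PRESS_EVENTS = frozenset({"press_short_lever", "press_long_lever", "press"})


class SchemaError(ValueError):
    """Raised when an event file does not conform to the long-format schema."""


class ValidationError(ValueError):
    """Raised when event data violate the trial-level invariants."""


@dataclass(frozen=True)
class EventRecord:
    """One time-stamped event of one trial.

    ``t_s`` is relative to cue onset; negative values denote inter-trial
    events (e.g. ITI foot-shocks) logged on the following trial.
    """

    subject_id: str
    session_index: int
    trial_index: int
    trial_type: str
    cue_duration_s: float
    event_type: str
    t_s: float

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(f"unknown trial_type {self.trial_type!r}")
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event_type {self.event_type!r}")
        if self.cue_duration_s < 0:
            raise ValidationError("cue_duration_s must be nonnegative")


@dataclass
class TrialEvents:
    """One trial's cue metadata and behavioral events.

    ``press_times_s`` are relative to cue onset and sorted.  For bisection
    trials ``chosen_lever`` is ``"short"``, ``"long"`` or ``"none"`` and
    ``response_latency_s`` is measured from cue offset (lever presentation)
    to the first press; for FI/probe trials ``chosen_lever`` is ``None`` and
    latency is measured from cue onset.
    """

    subject_id: str
    session_index: int
    trial_index: int
    trial_type: str
    cue_duration_s: float
    press_times_s: list[float] = field(default_factory=list)
    chosen_lever: str | None = None
    response_latency_s: float | None = None
    reinforced: bool = False
    shock_times_s: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(f"unknown trial_type {self.trial_type!r}")
        if any(t2 < t1 for t1, t2 in zip(self.press_times_s, self.press_times_s[1:])):
            raise ValidationError(
                f"press times not sorted in trial {self.trial_index} "
                f"of subject {self.subject_id}"
            )
        if self.is_bisection and self.chosen_lever is None:
            self.chosen_lever = "none" if not self.press_times_s else self.chosen_lever

    @property
    def is_bisection(self) -> bool:
        return self.trial_type in _BISECTION_TYPES

    @property
    def n_presses(self) -> int:
        return len(self.press_times_s)

    def to_records(self) -> list[EventRecord]:
        """Expand the trial back into time-ordered event records."""
        head = dict(
            subject_id=self.subject_id,
            session_index=self.session_index,
            trial_index=self.trial_index,
            trial_type=self.trial_type,
            cue_duration_s=self.cue_duration_s,
        )
        if self.is_bisection:
            press_ev = "press_long_lever" if self.chosen_lever == "long" else "press_short_lever"
        else:
            press_ev = "press"
        # (t, tie-break priority, event_type); cue_on first and cue_off last
        # among same-time events, reinforcer immediately after its press
        timed: list[tuple[float, int, str]] = [(t, 0, "shock") for t in self.shock_times_s]
        timed.append((0.0, 1, "cue_on"))
        timed.extend((t, 2, press_ev) for t in self.press_times_s)
        if self.reinforced and self.press_times_s:
            reinf_t = self.press_times_s[0] if self.is_bisection else self.press_times_s[-1]
            timed.append((reinf_t, 3, "reinforcer"))
        timed.append((self._cue_off_time(), 4, "cue_off"))
        timed.sort(key=lambda e: (e[0], e[1]))
        return [EventRecord(event_type=ev, t_s=t, **head) for t, _, ev in timed]

    def _cue_off_time(self) -> float:
        if self.trial_type == "fi" and self.reinforced and self.press_times_s:
            # tone terminates at the reinforced press
            return self.press_times_s[-1]
        if self.is_bisection:
            return self.cue_duration_s
        return self.cue_duration_s


@dataclass(frozen=True)
class BinnedTrial:
    """Press counts of one trial in half-open, fixed-width time bins.

    Bins are ``[k*w, (k+1)*w)`` from cue onset; ``counts / bin_width_s`` is
    the response rate in presses per second.
    """

    bin_width_s: float
    window_s: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        n = math.ceil(self.window_s / self.bin_width_s)
        if len(self.counts) != n:
            raise ValidationError(f"expected {n} bins, got {len(self.counts)}")
        if (self.counts < 0).any():
            raise ValidationError("negative bin count")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def rates_per_s(self) -> np.ndarray:
        return self.counts / self.bin_width_s

    @property
    def bin_left_edges_s(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_s


@dataclass
class Diagnostics:
    """Findings collected while reading or validating a session."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.errors and not self.warnings

    def __len__(self) -> int:
        return len(self.errors) + len(self.warnings)


def _fmt(x: float) -> str:
    """Exact round-trip float formatting (shortest repr)."""
    return repr(float(x))


def write_events(trials: Iterable[TrialEvents], path: str | Path) -> None:
    """Serialize trials to a long-format event CSV (one row per event)."""
    path = Path(path)
    lines = [",".join(CSV_COLUMNS)]
    for trial in trials:
        for r in trial.to_records():
            lines.append(
                f"{r.subject_id},{r.session_index},{r.trial_index},{r.trial_type},"
                f"{_fmt(r.cue_duration_s)},{r.event_type},{_fmt(r.t_s)}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _trial_from_records(recs: list[EventRecord], diag: Diagnostics) -> TrialEvents | None:
    r0 = recs[0]
    key = f"subject {r0.subject_id} session {r0.session_index} trial {r0.trial_index}"
    non_shock = [r for r in recs if r.event_type != "shock"]
    ts = [r.t_s for r in non_shock]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValidationError(f"non-monotone t_s within {key}")
    cue_on = [r for r in recs if r.event_type == "cue_on"]
    if not cue_on or cue_on[0].t_s != 0.0:
        diag.errors.append(f"{key}: missing cue_on at t=0")
        return None
    presses = [r for r in recs if r.event_type in _PRESS_EVENTS]
    press_times = [r.t_s for r in presses]
    shock_times = [r.t_s for r in recs if r.event_type == "shock"]
    reinforced = any(r.event_type == "reinforcer" for r in recs)
    is_bisection = r0.trial_type in _BISECTION_TYPES
    chosen = None
    latency = None
    if is_bisection:
        if presses:
            chosen = "long" if presses[0].event_type == "press_long_lever" else "short"
            latency = press_times[0] - r0.cue_duration_s
        else:
            chosen = "none"
    elif press_times:
        latency = press_times[0]
    return TrialEvents(
        subject_id=r0.subject_id,
        session_index=r0.session_index,
        trial_index=r0.trial_index,
        trial_type=r0.trial_type,
        cue_duration_s=r0.cue_duration_s,
        press_times_s=press_times,
        chosen_lever=chosen,
        response_latency_s=latency,
        reinforced=reinforced,
        shock_times_s=shock_times,
    )


def read_events(
    path: str | Path,
    dialect: dict | None = None,
    *,
    errors: str = "raise",
) -> list[TrialEvents] | tuple[list[TrialEvents], Diagnostics]:
    """Read a long-format event CSV into trials grouped by subject and session.

    Parameters
    ----------
    path:
        CSV file with header ``subject_id, session_index, trial_index,
        trial_type, cue_duration_s, event_type, t_s``.
    dialect:
        Optional keyword overrides passed to :func:`pandas.read_csv`
        (e.g. ``{"sep": ";"}``).
    errors:
        ``"raise"`` (default) raises on the first malformed row;
        ``"collect"`` skips malformed rows, records them in a
        :class:`Diagnostics` report and returns ``(trials, diagnostics)``.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **(dialect or {}))
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    diag = Diagnostics()
    records: list[EventRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                EventRecord(
                    subject_id=str(row.subject_id),
                    session_index=int(row.session_index),
                    trial_index=int(row.trial_index),
                    trial_type=str(row.trial_type),
                    cue_duration_s=float(row.cue_duration_s),
                    event_type=str(row.event_type),
                    t_s=float(row.t_s),
                )
            )
        except (ValueError, ValidationError) as exc:
            if errors == "raise":
                raise SchemaError(f"row {i + 2}: {exc}") from exc
            diag.errors.append(f"row {i + 2}: {exc}")
    trials: list[TrialEvents] = []
    for _, group in _iter_trial_groups(records):
        try:
            trial = _trial_from_records(group, diag)
        except ValidationError:
            raise
        if trial is not None:
            trials.append(trial)
    trials.sort(key=lambda t: (t.subject_id, t.session_index, t.trial_index))
    if errors == "collect":
        return trials, diag
    return trials


def _iter_trial_groups(
    records: Sequence[EventRecord],
) -> Iterator[tuple[tuple, list[EventRecord]]]:
    groups: dict[tuple, list[EventRecord]] = {}
    for r in records:
        groups.setdefault((r.subject_id, r.session_index, r.trial_index), []).append(r)
    yield from sorted(groups.items())


def group_by_subject_session(
    trials: Iterable[TrialEvents],
) -> dict[tuple[str, int], list[TrialEvents]]:
    """Group trials into ``{(subject_id, session_index): [trials...]}``."""
    out: dict[tuple[str, int], list[TrialEvents]] = {}
    for t in trials:
        out.setdefault((t.subject_id, t.session_index), []).append(t)
    for v in out.values():
        v.sort(key=lambda t: t.trial_index)
    return out


def bin_trial(trial: TrialEvents, bin_width_s: float, window_s: float) -> BinnedTrial:
    """Count presses into half-open ``[k*w, (k+1)*w)`` bins from cue onset.

    Presses at ``t < 0`` or ``t >= window_s`` are excluded.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    if window_s < bin_width_s:
        raise ValueError("window_s must be >= bin_width_s")
    n = math.ceil(window_s / bin_width_s)
    t = np.asarray(trial.press_times_s, dtype=float)
    t = t[(t >= 0) & (t < window_s)]
    idx = np.floor(t / bin_width_s).astype(np.int64)
    idx = np.clip(idx, 0, n - 1)  # guards float-edge spill on the last bin
    counts = np.bincount(idx, minlength=n)
    return BinnedTrial(bin_width_s=bin_width_s, window_s=window_s, counts=counts)


def validate_session(
    trials: Iterable[TrialEvents],
    *,
    probe_window_s: float = 90.0,
    fi_cue_max_s: float = 60.0,
) -> Diagnostics:
    """Check a session's trials against the task design.

    Flags probe trials whose cue duration differs from the probe window,
    FI trials with implausible cue duration, duplicate trial indices, and
    probe trials marked reinforced.
    """
    diag = Diagnostics()
    seen: set[tuple[str, int, int]] = set()
    for t in trials:
        key = (t.subject_id, t.session_index, t.trial_index)
        name = f"subject {t.subject_id} session {t.session_index} trial {t.trial_index}"
        if key in seen:
            diag.errors.append(f"{name}: duplicate trial_index")
        seen.add(key)
        if t.trial_type == "probe":
            if t.cue_duration_s != probe_window_s:
                diag.warnings.append(
                    f"{name}: probe trial with cue_duration_s={t.cue_duration_s}, "
                    f"expected {probe_window_s}"
                )
            if t.reinforced:
                diag.errors.append(f"{name}: probe trial marked reinforced")
        elif t.trial_type == "fi" and t.cue_duration_s > fi_cue_max_s:
            diag.warnings.append(
                f"{name}: fi trial cue_duration_s={t.cue_duration_s} exceeds "
                f"{fi_cue_max_s}"
            )
        if t.is_bisection:
            responded = bool(t.press_times_s)
            if (t.chosen_lever == "none") == responded:
                diag.errors.append(f"{name}: chosen_lever inconsistent with presses")
    return diag


def write_binned_matrix(
    trials: Sequence[TrialEvents],
    path: str | Path,
    bin_width_s: float,
    window_s: float,
) -> pd.DataFrame:
    """Write one row per trial, one column per bin, with identifier columns."""
    rows = []
    for t in trials:
        binned = bin_trial(t, bin_width_s, window_s)
        row: dict = {
            "subject_id": t.subject_id,
            "session_index": t.session_index,
            "trial_index": t.trial_index,
            "trial_type": t.trial_type,
        }
        row.update({f"bin_{k}": int(c) for k, c in enumerate(binned.counts)})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def group_blocks(
    trials: Iterable[TrialEvents],
    *,
    block_size: int = 2,
    sessions: tuple[int, int] | None = None,
) -> dict[tuple[str, tuple[int, int]], list[TrialEvents]]:
    """Group each subject's trials into consecutive ``block_size``-session blocks.

    ``sessions=(lo, hi)`` restricts to that inclusive session range first
    (e.g. training sessions 6-19).  A trailing partial block is kept when
    the session count is not a multiple of ``block_size``.  Returns
    ``{(subject_id, (first_session, last_session)): [trials...]}``.
    """
    per_subject: dict[str, dict[int, list[TrialEvents]]] = {}
    for t in trials:
        if sessions is not None and not (sessions[0] <= t.session_index <= sessions[1]):
            continue
        per_subject.setdefault(t.subject_id, {}).setdefault(t.session_index, []).append(t)
    out: dict[tuple[str, tuple[int, int]], list[TrialEvents]] = {}
    for sid, by_sess in sorted(per_subject.items()):
        ordered = sorted(by_sess)
        for i in range(0, len(ordered), block_size):
            block_sessions = ordered[i : i + block_size]
            key = (sid, (block_sessions[0], block_sessions[-1]))
            out[key] = [t for s in block_sessions for t in by_sess[s]]
    return out


def read_vendor_log(path: str | Path):  # pragma: no cover - documented stub
    """Converter stub for proprietary operant-chamber native formats.

    Vendor event logs are not parsed by this package; export sessions to the
    long-format CSV schema (see :data:`CSV_COLUMNS`) and use
    :func:`read_events` instead.
    """
    raise NotImplementedError(
        "vendor-native formats are out of scope; convert to the long-format "
        "CSV schema and use read_events()"
    )
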