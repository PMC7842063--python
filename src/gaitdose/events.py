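"""Gait-event extraction from instrumented-shoe pressure traces.

The instrumented shoe carries three force-sensitive resistors (FSRs) per
insole — greater toe, lateral heel, medial heel.  Foot-contact intervals are
detected per channel by thresholding, then fused into heel-strike / toe-off
events: a heel-strike is the earliest onset among the two heel channels of a
footfall, a toe-off the latest offset among all three channels.  Consecutive
heel-strikes of one leg delimit a gait cycle, split into stance
(heel-strike → toe-off) and swing (toe-off → next heel-strike).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

LEGS = ("left", "right")
CHANNELS = ("toe", "lateral_heel", "medial_heel")
HEEL_CHANNELS = ("lateral_heel", "medial_heel")

HEEL_STRIKE = "heel_strike"
TOE_OFF = "toe_off"


class InvalidConfigError(ValueError):
    """A configuration value violates its documented constraints."""


class SchemaError(ValueError):
    """Tabular input does not match the documented schema."""


@dataclass(frozen=True)
class ContactInterval:
    """A maximal interval of foot–ground contact on one FSR channel."""

    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(f"offset must exceed onset ({self.onset}, {self.offset})")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class GaitEvent:
    leg: str
    event_type: str  # heel_strike | toe_off
    time: float

    def __post_init__(self) -> None:
        if self.leg not in LEGS:
            raise ValueError(f"unknown leg {self.leg!r}")
        if self.event_type not in (HEEL_STRIKE, TOE_OFF):
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.time < 0:
            raise ValueError("event times must be non-negative")


@dataclass(frozen=True)
class GaitCycle:
    """One heel-strike → toe-off → heel-strike triple of a single leg.

    ``stance_time + swing_time == cycle_time`` holds exactly by construction.
    """

    leg: str
    heel_strike: float
    toe_off: float
    next_heel_strike: float

    def __post_init__(self) -> None:
        if not (self.heel_strike < self.toe_off < self.next_heel_strike):
            raise ValueError(
                "cycle events must be ordered heel_strike < toe_off < next_heel_strike"
            )

    @property
    def stance_time(self) -> float:
        return self.toe_off - self.heel_strike

    @property
    def swing_time(self) -> float:
        return self.next_heel_strike - self.toe_off

    @property
    def cycle_time(self) -> float:
        return self.next_heel_strike - self.heel_strike


@dataclass
class FsrTrace:
    """Uniformly sampled pressure trace of one FSR channel."""

    leg: str
    channel: str
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class WalkTrial:
    """One overground pass: both-leg events plus trial metadata."""

    subject_id: str
    session: str  # pre | post
    montage: str
    events: list[GaitEvent]
    distance_m: float
    height_m: float
    affected_side: str
    duration_s: float | None = None  # measured walk time over distance_m

    def events_for(self, leg: str) -> list[GaitEvent]:
        return [e for e in self.events if e.leg == leg]

    @property
    def duration(self) -> float:
        """Measured walk duration, falling back to the event-stream span."""
        if self.duration_s is not None:
            return self.duration_s
        if not self.events:
            return 0.0
        return max(e.time for e in self.events) - min(e.time for e in self.events)


@dataclass
class ValidationIssue:
    leg: str
    kind: str  # non_monotone_time | missing_toe_off | missing_heel_strike | duplicate_time
    time: float
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def detect_contact_intervals(
    trace: FsrTrace,
    threshold_fraction: float = 0.2,
    debounce_window: float = 0.05,
) -> list[ContactInterval]:
    """Threshold a pressure trace into maximal contact intervals.

    The threshold sits at ``threshold_fraction`` of the channel's dynamic
    range above its minimum.  Sub-threshold gaps shorter than
    ``debounce_window`` are bridged, and supra-threshold runs shorter than
    ``debounce_window`` are discarded, to suppress sensor chatter.
    """
    if not 0 < threshold_fraction < 1:
        raise InvalidConfigError("threshold_fraction must lie in (0, 1)")
    if debounce_window < 0:
        raise InvalidConfigError("debounce_window must be non-negative")

    x = trace.samples
    if x.size == 0:
        return []
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:  # flat trace: no dynamic range, no contact
        return []
    threshold = lo + threshold_fraction * (hi - lo)
    above = x > threshold
    if not above.any():
        return []

    starts = np.flatnonzero(above & np.r_[True, ~above[:-1]])
    ends = np.flatnonzero(above & np.r_[~above[1:], True])

    fs = trace.sampling_rate
    runs = [(s / fs, (e + 1) / fs) for s, e in zip(starts, ends)]

    # bridge short gaps, then drop short runs
    merged: list[tuple[float, float]] = []
    for on, off in runs:
        if merged and on - merged[-1][1] < debounce_window:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    kept = [(on, off) for on, off in merged if off - on >= debounce_window]
    return [ContactInterval(on, off) for on, off in kept]


def _merge_footfalls(intervals: Sequence[tuple[str, ContactInterval]]) -> list[list[tuple[str, ContactInterval]]]:
    """Group channel intervals into disjoint footfall windows by time overlap."""
    ordered = sorted(intervals, key=lambda ci: ci[1].onset)
    groups: list[list[tuple[str, ContactInterval]]] = []
    window_end = -np.inf
    for item in ordered:
        if item[1].onset > window_end:
            groups.append([item])
        else:
            groups[-1].append(item)
        window_end = max(window_end, item[1].offset)
    return groups


def derive_gait_events(
    contacts_by_channel: Mapping[str, Sequence[ContactInterval]],
    leg: str,
) -> list[GaitEvent]:
    """Fuse per-channel contact intervals into heel-strike / toe-off events.

    Per footfall, heel-strike is the earliest onset among the heel channels
    and toe-off the latest offset among all three channels.  Footfalls
    lacking either heel or toe contact are excluded with a logged warning —
    a partial footfall cannot yield both events reliably.
    """
    missing = set(CHANNELS) - set(contacts_by_channel)
    if missing:
        raise SchemaError(f"missing channels: {sorted(missing)}")

    tagged = [
        (channel, interval)
        for channel in CHANNELS
        for interval in contacts_by_channel[channel]
    ]
    events: list[GaitEvent] = []
    for group in _merge_footfalls(tagged):
        heel_onsets = [iv.onset for ch, iv in group if ch in HEEL_CHANNELS]
        has_toe = any(ch == "toe" for ch, _ in group)
        if not heel_onsets or not has_toe:
            t0 = min(iv.onset for _, iv in group)
            logger.warning(
                "footfall at %.3f s on %s leg lacks %s contact; excluded",
                t0, leg, "heel" if not heel_onsets else "toe",
            )
            continue
        hs = min(heel_onsets)
        to = max(iv.offset for _, iv in group)
        events.append(GaitEvent(leg, HEEL_STRIKE, hs))
        events.append(GaitEvent(leg, TOE_OFF, to))
    return sorted(events, key=lambda e: e.time)


def segment_gait_cycles(events: Iterable[GaitEvent]) -> list[GaitCycle]:
    """Segment one leg's alternating event stream into complete gait cycles.

    A cycle needs a heel-strike, the following toe-off, and the next
    heel-strike; the trailing incomplete cycle is discarded.
    """
    evs = sorted(events, key=lambda e: e.time)
    legs = {e.leg for e in evs}
    if len(legs) > 1:
        raise ValueError(f"events from multiple legs: {sorted(legs)}")
    hs_times = [e.time for e in evs if e.event_type == HEEL_STRIKE]
    to_times = [e.time for e in evs if e.event_type == TOE_OFF]
    if len(hs_times) < 2:
        logger.warning("fewer than 2 heel-strikes: no complete gait cycle")
        return []
    leg = evs[0].leg
    cycles: list[GaitCycle] = []
    to_arr = np.asarray(to_times)
    for hs, nxt in zip(hs_times[:-1], hs_times[1:]):
        inside = to_arr[(to_arr > hs) & (to_arr < nxt)]
        if inside.size != 1:
            logger.warning(
                "cycle %.3f–%.3f s on %s leg has %d toe-offs; skipped",
                hs, nxt, leg, inside.size,
            )
            continue
        cycles.append(GaitCycle(leg, hs, float(inside[0]), nxt))
    return cycles


def validate_event_stream(events: Iterable[GaitEvent]) -> ValidationReport:
    """Report ordering, alternation and duplicate-timestamp problems.

    Report-only: the input is never mutated.
    """
    report = ValidationReport()
    evs = list(events)
    for leg in LEGS:
        leg_events = [e for e in evs if e.leg == leg]
        times = [e.time for e in leg_events]
        for a, b in zip(times[:-1], times[1:]):
            if b < a:
                report.issues.append(ValidationIssue(
                    leg, "non_monotone_time", b,
                    f"{leg} leg events not sorted at t={b:.3f}"))
        seen: set[float] = set()
        for e in leg_events:
            if e.time in seen:
                report.issues.append(ValidationIssue(
                    leg, "duplicate_time", e.time,
                    f"duplicate {leg} event at t={e.time:.3f}"))
            seen.add(e.time)
        ordered = sorted(leg_events, key=lambda e: e.time)
        for prev, cur in zip(ordered[:-1], ordered[1:]):
            if prev.event_type == cur.event_type:
                kind = ("missing_toe_off" if cur.event_type == HEEL_STRIKE
                        else "missing_heel_strike")
                report.issues.append(ValidationIssue(
                    leg, kind, cur.time,
                    f"consecutive {cur.event_type} on {leg} leg at t={cur.time:.3f}"))
    return report
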