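"""Spatiotemporal gait indices from segmented gait cycles.

Seventeen per-trial parameters are computed, per side (affected /
unaffected) where a side-specific definition exists:

* temporal — stride time, step time, %stance, %swing, %single-support time
  (each per side) and cadence (steps/min);
* spatial — normalized step length and walk ratio (per side) and the gait
  stability ratio (GSR);
* symmetry — the symmetry index (SI) on the left/right %stance values.

Definitions::

    step length      = step time * walking speed
    normalized SL    = step length / body height
    GSR              = cadence (steps/s) / walking speed     [steps/m]
    walk ratio       = step length / cadence (steps/min)
    SI               = (X_L - X_R) * 100 / (0.5 * (X_L + X_R))
    %SST (leg L)     = contralateral swing time * 100 / leg-L cycle time

Walking speed itself is measured (distance / duration) and feeds the
spatial indices; it is reported alongside but is not one of the 17
parameters carried into the change-score analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

from .events import (
    HEEL_STRIKE,
    LEGS,
    GaitCycle,
    GaitEvent,
    WalkTrial,
    segment_gait_cycles,
    validate_event_stream,
)

logger = logging.getLogger(__name__)


class InvalidInputError(ValueError):
    """An input violates a documented precondition."""


#: The 17 gait parameters compared across montages and modelled against
#: lobular electric fields (walking speed is an input, not a member).
GAIT_PARAMETERS: tuple[str, ...] = (
    "normalized_step_length_affected",
    "normalized_step_length_unaffected",
    "walk_ratio_affected",
    "walk_ratio_unaffected",
    "gait_stability_ratio",
    "symmetry_index",
    "stride_time_affected",
    "stride_time_unaffected",
    "step_time_affected",
    "step_time_unaffected",
    "pct_stance_affected",
    "pct_stance_unaffected",
    "pct_swing_affected",
    "pct_swing_unaffected",
    "pct_single_support_affected",
    "pct_single_support_unaffected",
    "cadence",
)


@dataclass(frozen=True)
class TrialContext:
    """Per-trial measurement context."""

    walkway_distance: float  # m
    walk_duration: float     # s
    height: float            # m
    affected_side: str       # left | right

    def __post_init__(self) -> None:
        if self.walkway_distance <= 0 or self.walk_duration <= 0 or self.height <= 0:
            raise InvalidInputError("distance, duration and height must be positive")
        if self.affected_side not in LEGS:
            raise InvalidInputError(f"affected_side must be one of {LEGS}")


@dataclass
class GaitIndexSet:
    """All per-trial gait parameters (NaN where not computable)."""

    walking_speed: float = math.nan
    normalized_step_length_affected: float = math.nan
    normalized_step_length_unaffected: float = math.nan
    walk_ratio_affected: float = math.nan
    walk_ratio_unaffected: float = math.nan
    gait_stability_ratio: float = math.nan
    symmetry_index: float = math.nan
    symmetry_index_affected: float = math.nan  # affected-minus-unaffected variant
    stride_time_affected: float = math.nan
    stride_time_unaffected: float = math.nan
    step_time_affected: float = math.nan
    step_time_unaffected: float = math.nan
    pct_stance_affected: float = math.nan
    pct_stance_unaffected: float = math.nan
    pct_swing_affected: float = math.nan
    pct_swing_unaffected: float = math.nan
    pct_single_support_affected: float = math.nan
    pct_single_support_unaffected: float = math.nan
    cadence: float = math.nan
    errors: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "errors"}

    def parameters(self) -> dict[str, float]:
        """The canonical 17-parameter vector."""
        return {name: getattr(self, name) for name in GAIT_PARAMETERS}


def compute_walking_speed(distance: float, duration: float) -> float:
    """Overground walking speed from a timed pass over a known distance."""
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    if distance <= 0:
        raise InvalidInputError("distance must be positive")
    return distance / duration


def compute_cadence(events: list[GaitEvent]) -> float:
    """Steady-state cadence in steps/min from both legs' heel-strikes.

    The first heel-strike starts the walk; every later heel-strike is a
    step.  Cadence is the step count over the first-to-last heel-strike
    span, which is insensitive to where the recording window is cut.
    """
    hs = sorted(e.time for e in events if e.event_type == HEEL_STRIKE)
    if len(hs) < 2 or hs[-1] <= hs[0]:
        return math.nan
    return (len(hs) - 1) * 60.0 / (hs[-1] - hs[0])


def _step_times_by_leg(events: list[GaitEvent]) -> dict[str, list[float]]:
    """Step time of leg L: contralateral heel-strike → next leg-L heel-strike."""
    hs = sorted(
        ((e.time, e.leg) for e in events if e.event_type == HEEL_STRIKE),
        key=lambda p: p[0],
    )
    out: dict[str, list[float]] = {leg: [] for leg in LEGS}
    for (t0, leg0), (t1, leg1) in zip(hs[:-1], hs[1:]):
        if leg1 != leg0:
            out[leg1].append(t1 - t0)
    return out


def _mean(values: list[float]) -> float:
    return sum(values) / len(values) if values else math.nan


def compute_temporal_indices(
    cycles_affected: list[GaitCycle],
    cycles_unaffected: list[GaitCycle],
    events: list[GaitEvent],
) -> dict[str, float]:
    """Per-trial means of the temporal indices.

    Stride time and the stance/swing percentages are averaged over each
    leg's retained cycles; %SST of a leg is the mean contralateral swing
    time as a percentage of that leg's mean cycle time; step times are
    read off the merged heel-strike sequence; cadence comes from
    :func:`compute_cadence`.
    """
    if not cycles_affected or not cycles_unaffected:
        raise InvalidInputError("need at least one complete cycle per leg")

    def leg_stats(cycles: list[GaitCycle]) -> dict[str, float]:
        return {
            "stride": _mean([c.cycle_time for c in cycles]),
            "pct_stance": _mean([c.stance_time / c.cycle_time * 100.0 for c in cycles]),
            "pct_swing": _mean([c.swing_time / c.cycle_time * 100.0 for c in cycles]),
            "swing": _mean([c.swing_time for c in cycles]),
        }

    aff, unaff = leg_stats(cycles_affected), leg_stats(cycles_unaffected)
    step_by_leg = _step_times_by_leg(events)
    leg_aff = cycles_affected[0].leg
    leg_unaff = cycles_unaffected[0].leg
    return {
        "stride_time_affected": aff["stride"],
        "stride_time_unaffected": unaff["stride"],
        "pct_stance_affected": aff["pct_stance"],
        "pct_stance_unaffected": unaff["pct_stance"],
        "pct_swing_affected": aff["pct_swing"],
        "pct_swing_unaffected": unaff["pct_swing"],
        "pct_single_support_affected": unaff["swing"] * 100.0 / aff["stride"],
        "pct_single_support_unaffected": aff["swing"] * 100.0 / unaff["stride"],
        "step_time_affected": _mean(step_by_leg[leg_aff]),
        "step_time_unaffected": _mean(step_by_leg[leg_unaff]),
        "cadence": compute_cadence(events),
    }


def compute_spatial_indices(
    step_time_affected: float,
    step_time_unaffected: float,
    walking_speed: float,
    cadence: float,
    height: float,
) -> dict[str, float]:
    """Step length, normalized step length, GSR and walk ratio.

    The cadence argument is in steps/min; the GSR converts it to steps/s
    internally, so GSR carries units of steps per metre.
    """
    if walking_speed <= 0 or height <= 0:
        raise InvalidInputError("walking speed and height must be positive")
    if cadence <= 0:
        raise InvalidInputError("cadence must be positive")
    out: dict[str, float] = {
        "gait_stability_ratio": (cadence / 60.0) / walking_speed,
    }
    for side, step_time in (("affected", step_time_affected),
                            ("unaffected", step_time_unaffected)):
        step_length = step_time * walking_speed
        out[f"step_length_{side}"] = step_length
        out[f"normalized_step_length_{side}"] = step_length / height
        out[f"walk_ratio_{side}"] = step_length / cadence
    return out


def compute_symmetry_index(stance_pct_left: float, stance_pct_right: float) -> float:
    """Signed left-minus-right asymmetry as a percentage of the bilateral mean.

    Zero means perfectly symmetric use of the two legs; the sign says which
    leg spends the larger fraction of its cycle in stance.
    """
    if stance_pct_left <= 0 or stance_pct_right <= 0:
        raise InvalidInputError("stance percentages must be positive")
    mean = 0.5 * (stance_pct_left + stance_pct_right)
    return (stance_pct_left - stance_pct_right) * 100.0 / mean


def compute_index_set(
    trial: WalkTrial,
    context: TrialContext,
    trim_cycles: int = 1,
) -> GaitIndexSet:
    """Full per-trial gait parameter set from a validated event stream.

    ``trim_cycles`` complete cycles are dropped from each end of each leg's
    pass (default 1) to reduce acceleration/deceleration bias near the
    walkway ends; set 0 to keep everything.  Fields of a leg with no
    complete cycle are reported NaN with an error code rather than raising.
    """
    report = validate_event_stream(trial.events)
    if not report.ok:
        raise InvalidInputError(
            f"event stream failed validation ({len(report.issues)} issues); "
            "first: " + report.issues[0].message
        )

    result = GaitIndexSet()
    errors: list[str] = []
    result.walking_speed = compute_walking_speed(
        context.walkway_distance, context.walk_duration)

    leg_aff = context.affected_side
    leg_unaff = "right" if leg_aff == "left" else "left"

    def cycles_for(leg: str) -> list[GaitCycle]:
        cyc = segment_gait_cycles(trial.events_for(leg))
        if trim_cycles > 0 and len(cyc) > 2 * trim_cycles:
            cyc = cyc[trim_cycles:-trim_cycles]
        return cyc

    cyc_aff, cyc_unaff = cycles_for(leg_aff), cycles_for(leg_unaff)
    if not cyc_aff:
        errors.append("no_complete_cycle_affected")
    if not cyc_unaff:
        errors.append("no_complete_cycle_unaffected")
    if errors:
        result.cadence = compute_cadence(trial.events)
        result.errors = tuple(errors)
        return result

    temporal = compute_temporal_indices(cyc_aff, cyc_unaff, trial.events)
    for key, value in temporal.items():
        setattr(result, key, value)

    spatial = compute_spatial_indices(
        temporal["step_time_affected"],
        temporal["step_time_unaffected"],
        result.walking_speed,
        temporal["cadence"],
        context.height,
    )
    for key, value in spatial.items():
        if hasattr(result, key):
            setattr(result, key, value)

    stance_by_leg = {
        leg_aff: temporal["pct_stance_affected"],
        leg_unaff: temporal["pct_stance_unaffected"],
    }
    result.symmetry_index = compute_symmetry_index(
        stance_by_leg["left"], stance_by_leg["right"])
    # affected-minus-unaffected variant: positive = affected leg spends the
    # larger cycle fraction in stance
    result.symmetry_index_affected = compute_symmetry_index(
        temporal["pct_stance_affected"], temporal["pct_stance_unaffected"])

    result.errors = tuple(errors)
    return result
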