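"""Synthetic hemiplegic-gait cohorts with planted ground truth.

Real instrumented-shoe recordings and subject-specific electric-field
models are not publicly deposited, so every downstream stage is exercised
on synthetic data with known ground truth:

* two-leg gait event trains — phase-shifted periodic heel-strike/toe-off
  sequences with side-asymmetric stance fractions and optional per-event
  timing jitter (hemiplegic gait spends a larger cycle fraction in stance
  on the paretic side);
* rectangular-pulse FSR pressure traces consistent with those events;
* per-subject mean lobular electric-field vectors for the two cerebellar
  tDCS montages (dentate-targeting vs. leg-representation-targeting),
  qualitatively matching published field ranges;
* a plantable linear electric-field → gait-change map used to test
  recovery by the PLS regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (
    HEEL_STRIKE,
    LEGS,
    TOE_OFF,
    FsrTrace,
    GaitEvent,
    InvalidConfigError,
    SchemaError,
    WalkTrial,
)
from .indices import GAIT_PARAMETERS

logger = logging.getLogger(__name__)

MONTAGES = ("dentate", "leg")

# Cerebellar lobule parcellation (SUIT-style), re-keyed relative to the
# lesioned hemisphere: hemispheric lobules as contra-/ipsi-lesional plus the
# unpaired vermis subdivisions, and the two dentate nuclei.
_HEMI_LOBULES = ("I_IV", "V", "VI", "CrusI", "CrusII", "VIIb", "VIIIa", "VIIIb", "IX", "X")
_VERMIS_LOBULES = ("VI", "CrusI", "CrusII", "VIIb", "VIIIa", "VIIIb", "IX", "X")

DEFAULT_LOBULE_LABELS: tuple[str, ...] = (
    tuple(f"Contra_{name}" for name in _HEMI_LOBULES)
    + tuple(f"Ipsi_{name}" for name in _HEMI_LOBULES)
    + tuple(f"Vermis_{name}" for name in _VERMIS_LOBULES)
    + ("Contra_Dentate", "Ipsi_Dentate")
)

_LEG_AREA_LOBULES = ("VIIb", "VIIIa", "VIIIb", "IX")  # lower-limb representations


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    height: float  # m
    affected_side: str  # left | right

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise InvalidConfigError("height must be positive")
        if self.affected_side not in LEGS:
            raise InvalidConfigError(f"affected_side must be one of {LEGS}")


@dataclass(frozen=True)
class GaitGenConfig:
    """Parameters of the periodic two-leg gait event generator."""

    cycle_time: float = 1.0                  # s per leg
    stance_fraction_affected: float = 0.6    # fraction of cycle
    stance_fraction_unaffected: float = 0.6
    walking_speed: float = 1.0               # m/s
    walkway_distance: float = 10.0           # m
    timing_jitter_sd: float = 0.0            # s, per event, truncated at 3 SD
    phase_offset: float = 0.5                # fraction of cycle between legs
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.stance_fraction_affected, self.stance_fraction_unaffected):
            if not 0.0 < frac < 1.0:
                raise InvalidConfigError("stance fractions must lie in (0, 1)")
        if self.cycle_time <= 0 or self.walking_speed <= 0 or self.walkway_distance <= 0:
            raise InvalidConfigError("cycle_time, speed and distance must be positive")
        if self.timing_jitter_sd < 0:
            raise InvalidConfigError("timing_jitter_sd must be non-negative")


@dataclass(frozen=True)
class MontageProfile:
    """Mean lobular field strengths of one stimulation montage."""

    montage_id: str
    lobule_labels: tuple[str, ...]
    mean_field: tuple[float, ...]         # V/m per lobule
    between_subject_sd: tuple[float, ...]  # V/m per lobule

    def __post_init__(self) -> None:
        n = len(self.lobule_labels)
        if len(set(self.lobule_labels)) != n:
            raise InvalidConfigError("lobule labels must be unique")
        if len(self.mean_field) != n or len(self.between_subject_sd) != n:
            raise InvalidConfigError("field vectors must match label count")
        if any(v < 0 for v in self.mean_field):
            raise InvalidConfigError("mean fields must be non-negative")


@dataclass(frozen=True)
class PlantedAssociation:
    """A known linear map from centered E-fields to gait-parameter changes."""

    coefficient_matrix: pd.DataFrame  # lobules x parameters, %change per V/m
    noise_sd: float | np.ndarray = 0.0
    seed: int = 0
    active_lobules: tuple[str, ...] = field(default=())


def default_montage_profiles(
    lobule_labels: tuple[str, ...] = DEFAULT_LOBULE_LABELS,
    between_subject_sd: float = 0.05,
) -> dict[str, MontageProfile]:
    """Built-in field profiles for the dentate and leg montages.

    Qualitative defaults: the dentate montage reaches the dentate nuclei at
    0.25 V/m and the cerebellar lobules at 0.12 V/m; the leg montage
    reaches the lower-limb representations (lobules VIIb–IX) and the
    dentate nuclei at 0.10 V/m and the remaining lobules at 0.05 V/m.
    Published results state only the corresponding inequalities (> 0.2,
    > 0.1, > 0.08 V/m), so these constants are user-overridable.
    """
    dentate_mean, leg_mean = [], []
    for label in lobule_labels:
        if label.endswith("Dentate"):
            dentate_mean.append(0.25)
            leg_mean.append(0.10)
        else:
            dentate_mean.append(0.12)
            is_leg_area = any(label.endswith(suffix) for suffix in _LEG_AREA_LOBULES)
            leg_mean.append(0.10 if is_leg_area else 0.05)
    sds = tuple(between_subject_sd for _ in lobule_labels)
    return {
        "dentate": MontageProfile("dentate", tuple(lobule_labels),
                                  tuple(dentate_mean), sds),
        "leg": MontageProfile("leg", tuple(lobule_labels),
                              tuple(leg_mean), sds),
    }


def generate_cohort(
    n_subjects: int,
    height_range: tuple[float, float] = (1.55, 1.85),
    affected_side_ratio: float = 0.4,
    seed: int = 0,
) -> list[SubjectProfile]:
    """Draw a cohort with heights in ``height_range`` and a fixed
    left-affected fraction (deterministic rounding of ``ratio * n``)."""
    if n_subjects < 1:
        raise InvalidConfigError("n_subjects must be >= 1")
    lo, hi = height_range
    if lo <= 0 or hi < lo:
        raise InvalidConfigError("height_range must be positive and ordered")
    if not 0.0 <= affected_side_ratio <= 1.0:
        raise InvalidConfigError("affected_side_ratio must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    heights = rng.uniform(lo, hi, size=n_subjects)
    n_left = int(math.floor(affected_side_ratio * n_subjects + 0.5))
    sides = np.array(["left"] * n_left + ["right"] * (n_subjects - n_left))
    rng.shuffle(sides)
    return [
        SubjectProfile(f"S{i + 1:02d}", float(h), str(s))
        for i, (h, s) in enumerate(zip(heights, sides))
    ]


def generate_gait_events(
    profile: SubjectProfile,
    config: GaitGenConfig,
    session: str = "pre",
    montage: str = "none",
) -> WalkTrial:
    """Periodic two-leg gait event train for one overground pass.

    The affected leg starts at t = 0 and the unaffected leg is offset by
    ``phase_offset`` of a cycle; per-leg toe-off follows each heel-strike
    by ``stance_fraction * cycle_time``.  Independent truncated-Gaussian
    jitter (cut at 3 SD) perturbs every event; jitter large enough to
    break event ordering raises an error rather than emitting an invalid
    stream.
    """
    duration = config.walkway_distance / config.walking_speed
    n_cycles = int(math.ceil(duration / config.cycle_time))
    rng = np.random.default_rng(config.seed)

    leg_aff = profile.affected_side
    leg_unaff = "right" if leg_aff == "left" else "left"
    # start at 3 SD so truncated jitter cannot push an event before t = 0
    t_start = 3.0 * config.timing_jitter_sd
    plan = (
        (leg_aff, t_start, config.stance_fraction_affected),
        (leg_unaff, t_start + config.phase_offset * config.cycle_time,
         config.stance_fraction_unaffected),
    )

    def jitter(n: int) -> np.ndarray:
        if config.timing_jitter_sd == 0:
            return np.zeros(n)
        sd = config.timing_jitter_sd
        return np.clip(rng.normal(0.0, sd, size=n), -3 * sd, 3 * sd)

    events: list[GaitEvent] = []
    for leg, offset, stance_frac in plan:
        hs = offset + np.arange(n_cycles + 1) * config.cycle_time + jitter(n_cycles + 1)
        to = (offset + np.arange(n_cycles) * config.cycle_time
              + stance_frac * config.cycle_time + jitter(n_cycles))
        merged = np.empty(2 * n_cycles + 1)
        merged[0::2] = hs
        merged[1::2] = to
        if np.any(np.diff(merged) <= 0) or merged[0] < 0:
            raise InvalidConfigError(
                "timing jitter too large: event ordering not preserved")
        for k in range(n_cycles):
            events.append(GaitEvent(leg, HEEL_STRIKE, float(hs[k])))
            events.append(GaitEvent(leg, TOE_OFF, float(to[k])))
        events.append(GaitEvent(leg, HEEL_STRIKE, float(hs[n_cycles])))

    events.sort(key=lambda e: (e.time, e.leg, e.event_type))
    return WalkTrial(
        subject_id=profile.subject_id,
        session=session,
        montage=montage,
        events=events,
        distance_m=config.walkway_distance,
        height_m=profile.height,
        affected_side=profile.affected_side,
        duration_s=duration,
    )


def synthesize_fsr_traces(
    trial: WalkTrial,
    sampling_rate: float = 500.0,
    pulse_amplitude: float = 1.0,
    onset_ramp: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[FsrTrace]:
    """Pressure traces for the three FSR channels of each shoe.

    Within each stance (heel-strike → toe-off), the heel channels load from
    heel-strike until 60% of stance (heel rise as the body advances) and
    the toe channel loads from 30% of stance until toe-off, so the earliest
    heel onset recovers the heel-strike and the latest offset the toe-off.
    Rising edges ramp linearly over ``onset_ramp`` seconds; additive
    Gaussian noise with SD ``noise_sd``.
    """
    if sampling_rate <= 0:
        raise InvalidConfigError("sampling_rate must be positive")
    if not trial.events:
        return []
    if noise_sd > 0 and pulse_amplitude <= noise_sd:
        logger.warning(
            "pulse amplitude %.3g <= noise SD %.3g: event recovery not guaranteed",
            pulse_amplitude, noise_sd)

    rng = np.random.default_rng(seed)
    t_end = max(e.time for e in trial.events) + 0.3
    n_samples = int(round(t_end * sampling_rate)) + 1
    times = np.arange(n_samples) / sampling_rate

    traces: list[FsrTrace] = []
    for leg in LEGS:
        leg_events = sorted(trial.events_for(leg), key=lambda e: e.time)
        stances: list[tuple[float, float]] = []
        pending_hs: float | None = None
        for e in leg_events:
            if e.event_type == HEEL_STRIKE:
                pending_hs = e.time
            elif pending_hs is not None:
                stances.append((pending_hs, e.time))
                pending_hs = None
        if not stances:
            continue
        windows = {
            "medial_heel": [(hs, hs + 0.6 * (to - hs)) for hs, to in stances],
            "lateral_heel": [(hs, hs + 0.6 * (to - hs)) for hs, to in stances],
            "toe": [(hs + 0.3 * (to - hs), to) for hs, to in stances],
        }
        for channel, wins in windows.items():
            samples = np.zeros(n_samples)
            for on, off in wins:
                mask = (times >= on) & (times < off)
                if onset_ramp > 0:
                    rise = np.clip((times[mask] - on) / onset_ramp, 0.0, 1.0)
                    samples[mask] = pulse_amplitude * rise
                else:
                    samples[mask] = pulse_amplitude
            if noise_sd > 0:
                samples = samples + rng.normal(0.0, noise_sd, size=n_samples)
            traces.append(FsrTrace(leg, channel, sampling_rate, samples))
    return traces


def generate_efield_matrix(
    profiles: dict[str, MontageProfile] | list[MontageProfile],
    cohort: list[SubjectProfile],
    seed: int = 0,
) -> pd.DataFrame:
    """Subject × montage rows of mean lobular field strength (V/m).

    Each row is its montage's mean vector plus an independent Gaussian
    per-subject perturbation, truncated at zero (field magnitudes cannot be
    negative).
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    labels = profiles[0].lobule_labels
    for p in profiles[1:]:
        if p.lobule_labels != labels:
            raise SchemaError("montage profiles disagree on lobule labels")

    rng = np.random.default_rng(seed)
    rows, index = [], []
    for subject in cohort:
        for p in profiles:
            mean = np.asarray(p.mean_field)
            sd = np.asarray(p.between_subject_sd)
            row = np.clip(mean + rng.normal(0.0, 1.0, size=mean.size) * sd, 0.0, None)
            rows.append(row)
            index.append((subject.subject_id, p.montage_id))
    return pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["subject", "montage"]),
        columns=list(labels),
    )


def random_planted_association(
    lobule_labels: tuple[str, ...] = DEFAULT_LOBULE_LABELS,
    parameters: tuple[str, ...] = GAIT_PARAMETERS,
    n_active: int = 4,
    coef_scale: float = 100.0,
    noise_sd: float | np.ndarray = 0.0,
    seed: int = 0,
) -> PlantedAssociation:
    """A sparse random E-field → gait-change map with ``n_active`` lobules.

    Active rows are i.i.d. Gaussian with SD ``coef_scale`` (percent change
    per V/m — field perturbations of a few hundredths of a V/m then move
    gait parameters by a few percent); inactive rows are zero.
    """
    if not 1 <= n_active <= len(lobule_labels):
        raise InvalidConfigError("n_active out of range")
    rng = np.random.default_rng(seed)
    active = tuple(sorted(rng.choice(len(lobule_labels), size=n_active, replace=False)))
    coef = np.zeros((len(lobule_labels), len(parameters)))
    for i in active:
        coef[i] = rng.normal(0.0, coef_scale, size=len(parameters))
    matrix = pd.DataFrame(coef, index=list(lobule_labels), columns=list(parameters))
    return PlantedAssociation(
        coefficient_matrix=matrix,
        noise_sd=noise_sd,
        seed=seed,
        active_lobules=tuple(lobule_labels[i] for i in active),
    )


def generate_clinical_records(
    cohort: list[SubjectProfile],
    montages: tuple[str, ...] = MONTAGES,
    seed: int = 0,
) -> list:
    """Plausible pre/post clinical assessments for each subject × montage.

    Baselines reflect chronic hemiparetic walkers (comfortable speed
    0.5–0.9 m/s, TUG 15–35 s, BBS 30–48); post values improve by amounts
    straddling each measure's MCID so both improvement outcomes occur.
    """
    from .clinical import ClinicalRecord

    rng = np.random.default_rng(seed)
    records = []
    for subject in cohort:
        for montage in montages:
            speed_pre = rng.uniform(0.5, 0.9)
            tug_pre = rng.uniform(15.0, 35.0)
            bbs_pre = float(rng.integers(30, 49))
            records.append(ClinicalRecord(
                subject_id=subject.subject_id,
                montage=montage,
                tmwt_speed_pre=speed_pre,
                tmwt_speed_post=speed_pre + rng.uniform(0.0, 0.25),
                tug_pre=tug_pre,
                tug_post=max(5.0, tug_pre - rng.uniform(0.0, 12.0)),
                bbs_pre=bbs_pre,
                bbs_post=min(56.0, bbs_pre + float(rng.integers(0, 16))),
            ))
    return records


def plant_gait_change(
    efield: pd.DataFrame,
    assoc: PlantedAssociation,
) -> pd.DataFrame:
    """Percent-change table implied by the planted linear map.

    ``change = (E - column means) @ B + noise`` — the association acts on
    centered predictors so the planted model matches what the PLS
    regression (which centers both blocks) can recover exactly at zero
    noise.
    """
    B = assoc.coefficient_matrix
    if list(efield.columns) != list(B.index):
        raise SchemaError("E-field lobule labels do not match coefficient rows")
    centered = efield - efield.mean(axis=0)
    signal = centered.to_numpy() @ B.to_numpy()
    rng = np.random.default_rng(assoc.seed)
    noise = rng.normal(0.0, 1.0, size=signal.shape) * np.asarray(assoc.noise_sd)
    return pd.DataFrame(signal + noise, index=efield.index, columns=list(B.columns))
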