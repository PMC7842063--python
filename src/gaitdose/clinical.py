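"""Clinical outcome records and MCID-based improvement flags.

Three standard post-stroke mobility assessments are carried alongside the
instrumented-gait indices, each with its minimal clinically important
difference (MCID): ten-meter walk test speed (0.10 m/s), timed up-and-go
time (8 s, improvement = time decrease), and Berg Balance Scale score
(12.5 points, 0–56 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

from .indices import InvalidInputError

MCID_TMWT_SPEED = 0.10  # m/s
MCID_TUG_TIME = 8.0     # s
MCID_BBS_SCORE = 12.5   # points
BBS_RANGE = (0.0, 56.0)


@dataclass(frozen=True)
class ClinicalRecord:
    subject_id: str
    montage: str
    tmwt_speed_pre: float
    tmwt_speed_post: float
    tug_pre: float
    tug_post: float
    bbs_pre: float
    bbs_post: float

    def __post_init__(self) -> None:
        for name in ("tmwt_speed_pre", "tmwt_speed_post", "tug_pre", "tug_post"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        for name in ("bbs_pre", "bbs_post"):
            value = getattr(self, name)
            if not BBS_RANGE[0] <= value <= BBS_RANGE[1]:
                raise InvalidInputError(f"{name}={value} outside BBS range 0-56")


def mcid_assessment(record: ClinicalRecord) -> dict[str, bool]:
    """Per-measure clinically-important-improvement flags.

    Walking speed and balance must increase by at least their MCID; the
    TUG must get *faster* by at least its MCID.
    """
    return {
        "tmwt_improved": (record.tmwt_speed_post - record.tmwt_speed_pre)
        >= MCID_TMWT_SPEED,
        "tug_improved": (record.tug_pre - record.tug_post) >= MCID_TUG_TIME,
        "bbs_improved": (record.bbs_post - record.bbs_pre) >= MCID_BBS_SCORE,
    }
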