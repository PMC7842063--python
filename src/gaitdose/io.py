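"""CSV readers and writers for the pipeline's tabular interchange formats.

Schemas (all with header rows):

* events:   subject, session, montage, leg, event_type, time_s
* trials:   subject, session, montage, distance_m, height_m, affected_side
* FSR:      subject, leg, channel, time_s, value
* E-field:  subject, montage, one column per lobule label
* clinical: subject, montage, tmwt_speed_pre/post, tug_pre/post, bbs_pre/post
* changes:  long (subject, montage, parameter, pre, post, change)
            or wide (subject, montage rows x parameter columns)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .clinical import ClinicalRecord
from .events import FsrTrace, GaitEvent, SchemaError, WalkTrial

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["subject", "session", "montage", "leg", "event_type", "time_s"]
TRIAL_META_COLUMNS = ["subject", "session", "montage",
                      "distance_m", "height_m", "affected_side", "duration_s"]
FSR_COLUMNS = ["subject", "leg", "channel", "time_s", "value"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def write_events_csv(trials: list[WalkTrial], path: str | Path) -> None:
    rows = [
        {"subject": t.subject_id, "session": t.session, "montage": t.montage,
         "leg": e.leg, "event_type": e.event_type, "time_s": e.time}
        for t in trials for e in t.events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def write_trial_meta_csv(trials: list[WalkTrial], path: str | Path) -> None:
    rows = [
        {"subject": t.subject_id, "session": t.session, "montage": t.montage,
         "distance_m": t.distance_m, "height_m": t.height_m,
         "affected_side": t.affected_side, "duration_s": t.duration}
        for t in trials
    ]
    pd.DataFrame(rows, columns=TRIAL_META_COLUMNS).to_csv(path, index=False)


def load_event_table(
    path: str | Path,
    meta_path: str | Path | None = None,
    default_distance: float = 10.0,
    default_height: float = 1.70,
    default_affected_side: str = "left",
) -> list[WalkTrial]:
    """Read an events CSV (plus optional trial-metadata CSV) into trials.

    Trials are grouped by subject/session/montage.  Malformed rows are
    dropped with a line-numbered warning; an empty file yields an empty
    collection with a warning.  Without a metadata file, the walkway
    distance, height and affected side fall back to the given defaults.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("events file %s is empty", path)
        return []
    _require_columns(df, EVENT_COLUMNS, "events CSV")

    meta: dict[tuple, dict] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path)
        _require_columns(mdf, TRIAL_META_COLUMNS, "trial metadata CSV")
        for _, row in mdf.iterrows():
            meta[(row["subject"], row["session"], row["montage"])] = row.to_dict()

    trials: list[WalkTrial] = []
    for key, group in df.groupby(["subject", "session", "montage"], sort=True):
        events: list[GaitEvent] = []
        for idx, row in group.iterrows():
            try:
                events.append(GaitEvent(str(row["leg"]), str(row["event_type"]),
                                        float(row["time_s"])))
            except (ValueError, TypeError) as exc:
                # +2: header line plus 1-based numbering
                logger.warning("dropping malformed row at line %d: %s", idx + 2, exc)
        events.sort(key=lambda e: e.time)
        info = meta.get(key, {})
        trials.append(WalkTrial(
            subject_id=str(key[0]), session=str(key[1]), montage=str(key[2]),
            events=events,
            distance_m=float(info.get("distance_m", default_distance)),
            height_m=float(info.get("height_m", default_height)),
            affected_side=str(info.get("affected_side", default_affected_side)),
            duration_s=(float(info["duration_s"])
                        if "duration_s" in info else None),
        ))
    return trials


def write_fsr_csv(traces: list[FsrTrace], subject: str, path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "subject": subject, "leg": tr.leg, "channel": tr.channel,
            "time_s": tr.times, "value": tr.samples,
        })
        for tr in traces
    ]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=FSR_COLUMNS))
    out.to_csv(path, index=False)


def read_fsr_csv(path: str | Path) -> list[FsrTrace]:
    """Reconstruct per-channel traces; sampling rate inferred from timestamps."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    _require_columns(df, FSR_COLUMNS, "FSR CSV")
    traces = []
    for (leg, channel), group in df.groupby(["leg", "channel"], sort=True):
        times = group["time_s"].to_numpy()
        if times.size < 2:
            raise SchemaError(f"channel {leg}/{channel} has fewer than 2 samples")
        dt = float(times[1] - times[0])
        traces.append(FsrTrace(str(leg), str(channel), 1.0 / dt,
                               group["value"].to_numpy()))
    return traces


def write_efield_csv(efield: pd.DataFrame, path: str | Path) -> None:
    efield.reset_index().to_csv(path, index=False)


def read_efield_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject", "montage"], "E-field CSV")
    return df.set_index(["subject", "montage"])


def write_change_long_csv(pre: pd.DataFrame, post: pd.DataFrame,
                          changes: pd.DataFrame, path: str | Path) -> None:
    rows = []
    for key in changes.index:
        for param in changes.columns:
            rows.append({
                "subject": key[0], "montage": key[1], "parameter": param,
                "pre": pre.loc[key, param], "post": post.loc[key, param],
                "change": changes.loc[key, param],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_change_wide_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject", "montage"], "change table CSV")
    return df.set_index(["subject", "montage"])


def write_change_wide_csv(changes: pd.DataFrame, path: str | Path) -> None:
    changes.reset_index().to_csv(path, index=False)


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    required = ["subject", "montage", "tmwt_speed_pre", "tmwt_speed_post",
                "tug_pre", "tug_post", "bbs_pre", "bbs_post"]
    _require_columns(df, required, "clinical CSV")
    return [
        ClinicalRecord(
            subject_id=str(row["subject"]), montage=str(row["montage"]),
            tmwt_speed_pre=float(row["tmwt_speed_pre"]),
            tmwt_speed_post=float(row["tmwt_speed_post"]),
            tug_pre=float(row["tug_pre"]), tug_post=float(row["tug_post"]),
            bbs_pre=float(row["bbs_pre"]), bbs_post=float(row["bbs_post"]),
        )
        for _, row in df.iterrows()
    ]


def write_clinical_csv(records: list[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {"subject": r.subject_id, "montage": r.montage,
         "tmwt_speed_pre": r.tmwt_speed_pre, "tmwt_speed_post": r.tmwt_speed_post,
         "tug_pre": r.tug_pre, "tug_post": r.tug_post,
         "bbs_pre": r.bbs_pre, "bbs_post": r.bbs_post}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
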