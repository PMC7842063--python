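"""End-to-end analysis runs: events → indices → changes → tests → PLS.

A run either simulates a full crossover study (each subject walks the
walkway pre and post stimulation under both montages) or loads event CSVs
from disk, then computes per-trial gait parameters, percent-normalized
changes, the per-parameter montage comparison, the PLS dose-response fit
against the lobular E-field matrix, and clinical MCID flags.  Every stage
writes its artifact to the output directory so any reported number can be
recomputed from the saved intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .changes import build_change_table, compare_montages
from .clinical import mcid_assessment
from .events import InvalidConfigError, WalkTrial
from .indices import GAIT_PARAMETERS, TrialContext, compute_index_set
from .pls import PLSEFieldRegressor, extract_loadings
from .synthetic import (
    MONTAGES,
    GaitGenConfig,
    SubjectProfile,
    default_montage_profiles,
    generate_clinical_records,
    generate_cohort,
    generate_efield_matrix,
    generate_gait_events,
    plant_gait_change,
    random_planted_association,
)

logger = logging.getLogger(__name__)

#: Qualitative montage effects on the post-stimulation gait generator:
#: dentate stimulation shortens the cycle (faster stepping, higher cadence)
#: and trims unaffected-side stance; leg-area stimulation does the reverse.
#: Magnitudes are set so the dentate-vs-leg *difference* (twice the
#: per-montage delta) is near one SD of a change score's session noise —
#: as in real small crossover studies, montage differences straddle the
#: edge of detectability rather than flagging every parameter.
DEFAULT_MONTAGE_EFFECTS: dict[str, dict[str, float]] = {
    "dentate": {"cycle_time": -0.007, "stance_fraction_unaffected": -0.004},
    "leg": {"cycle_time": +0.007, "stance_fraction_unaffected": +0.004},
}


@dataclass
class AnalysisConfig:
    """Everything a full run needs; serialized into the report metadata."""

    mode: str = "synthetic"             # synthetic | files
    n_subjects: int = 10
    seed: int = 0
    n_components: int = 10
    alpha: float = 0.05
    output_dir: str | None = None
    # synthetic-mode generator settings
    base_gait: dict = field(default_factory=lambda: {
        "cycle_time": 1.1,
        "stance_fraction_affected": 0.65,
        "stance_fraction_unaffected": 0.60,
        "walking_speed": 0.8,
        "walkway_distance": 10.0,
        "timing_jitter_sd": 0.01,
        "phase_offset": 0.5,
    })
    montage_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MONTAGE_EFFECTS.items()})
    session_noise_sd: dict = field(default_factory=lambda: {
        "cycle_time": 0.02, "stance_fraction": 0.005, "walking_speed": 0.03})
    pls_response: str = "planted"       # planted | empirical
    planted_n_active: int = 4
    planted_noise_sd: float = 2.0       # percent-change units
    trim_cycles: int = 1
    # file-mode inputs
    events_path: str | None = None
    trial_meta_path: str | None = None
    efield_path: str | None = None
    clinical_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidConfigError("alpha must lie in (0, 1)")
        if self.mode not in ("synthetic", "files"):
            raise InvalidConfigError("mode must be 'synthetic' or 'files'")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    indices: pd.DataFrame          # one row per trial, 17 parameters + speed
    changes: pd.DataFrame          # subject x montage rows, parameter columns
    ranksum: pd.DataFrame          # per-parameter montage comparison
    pls_summary: dict              # fitted-model summary
    mcid: pd.DataFrame | None      # per subject x montage improvement flags
    metadata: dict


def _simulate_trials(config: AnalysisConfig,
                     cohort: list[SubjectProfile]) -> list[WalkTrial]:
    rng = np.random.default_rng(config.seed + 1)
    trials: list[WalkTrial] = []
    for subject in cohort:
        base = dict(config.base_gait)
        # stable per-subject baseline variation
        base["cycle_time"] += rng.normal(0.0, config.session_noise_sd["cycle_time"])
        base["walking_speed"] += rng.normal(
            0.0, config.session_noise_sd["walking_speed"])
        for montage in MONTAGES:
            for session in ("pre", "post"):
                params = dict(base)
                if session == "post":
                    for key, delta in config.montage_effects.get(montage, {}).items():
                        params[key] = params.get(key, 0.0) + delta
                for key in ("cycle_time", "walking_speed"):
                    params[key] += rng.normal(
                        0.0, config.session_noise_sd[key] / 2.0)
                for key in ("stance_fraction_affected", "stance_fraction_unaffected"):
                    params[key] += rng.normal(
                        0.0, config.session_noise_sd["stance_fraction"])
                gait_cfg = GaitGenConfig(
                    seed=int(rng.integers(0, 2 ** 31 - 1)), **params)
                trials.append(generate_gait_events(
                    subject, gait_cfg, session=session, montage=montage))
    return trials


def _indices_table(trials: list[WalkTrial], heights: dict[str, float],
                   trim_cycles: int) -> pd.DataFrame:
    rows = []
    for trial in trials:
        context = TrialContext(
            walkway_distance=trial.distance_m,
            walk_duration=max(trial.duration, 1e-9),
            height=heights.get(trial.subject_id, trial.height_m),
            affected_side=trial.affected_side,
        )
        idx = compute_index_set(trial, context, trim_cycles=trim_cycles)
        row = {"subject": trial.subject_id, "session": trial.session,
               "montage": trial.montage, **idx.to_dict(),
               "errors": ";".join(idx.errors)}
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the complete pipeline and (optionally) write all artifacts."""
    t0 = time.perf_counter()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        cohort = generate_cohort(config.n_subjects, seed=config.seed)
        trials = _simulate_trials(config, cohort)
        profiles = default_montage_profiles()
        efield = generate_efield_matrix(profiles, cohort, seed=config.seed + 2)
        clinical = generate_clinical_records(cohort, seed=config.seed + 3)
        heights = {s.subject_id: s.height for s in cohort}
    else:
        if config.events_path is None:
            raise InvalidConfigError("file mode requires events_path")
        trials = gio.load_event_table(config.events_path, config.trial_meta_path)
        efield = (gio.read_efield_csv(config.efield_path)
                  if config.efield_path else None)
        clinical = (gio.read_clinical_csv(config.clinical_path)
                    if config.clinical_path else [])
        heights = {t.subject_id: t.height_m for t in trials}

    indices = _indices_table(trials, heights, config.trim_cycles)
    logger.info("indices: %d trials in %.2f s", len(indices),
                time.perf_counter() - t0)

    wide = indices.set_index(["subject", "montage", "session"])[
        list(GAIT_PARAMETERS)]
    pre = wide.xs("pre", level="session")
    post = wide.xs("post", level="session")
    changes = build_change_table(pre, post)
    ranksum = compare_montages(changes, alpha=config.alpha)

    pls_summary: dict = {}
    planted_meta: dict = {}
    model = None
    if efield is not None:
        if config.mode == "synthetic" and config.pls_response == "planted":
            assoc = random_planted_association(
                n_active=config.planted_n_active,
                noise_sd=config.planted_noise_sd,
                seed=config.seed + 4,
            )
            response = plant_gait_change(efield, assoc)
            planted_meta = {"planted_active_lobules": list(assoc.active_lobules),
                            "planted_noise_sd": config.planted_noise_sd}
        else:
            response = changes.reindex(efield.index).dropna()
            efield = efield.loc[response.index]
        model = PLSEFieldRegressor(n_components=config.n_components)
        model.fit(efield, response)
        pls_summary = {
            "n_components": int(model.n_components_),
            "r_squared": float(model.r_squared_),
            "cum_pct_var_y": float(model.pct_var_y_.sum()),
            "top_predictors": model.predictor_importance()
            .sort_values(ascending=False).head(8).index.tolist(),
            **planted_meta,
        }

    mcid = None
    if clinical:
        mcid = pd.DataFrame([
            {"subject": r.subject_id, "montage": r.montage,
             **mcid_assessment(r)}
            for r in clinical
        ])

    metadata = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_trials": len(trials),
        "runtime_s": round(time.perf_counter() - t0, 3),
    }

    if outdir:
        gio.write_events_csv(trials, outdir / "events.csv")
        gio.write_trial_meta_csv(trials, outdir / "trials.csv")
        indices.to_csv(outdir / "gait_indices.csv", index=False)
        gio.write_change_wide_csv(changes, outdir / "changes_wide.csv")
        gio.write_change_long_csv(pre, post, changes, outdir / "changes_long.csv")
        ranksum.to_csv(outdir / "ranksum.csv", index=False)
        if efield is not None:
            gio.write_efield_csv(efield, outdir / "efield.csv")
        if model is not None:
            (outdir / "pls_model.json").write_text(
                json.dumps(model.to_dict(), indent=1))
            tables = extract_loadings(model, efield)
            for name, table in tables.items():
                table.to_csv(outdir / f"pls_{name}.csv", index=False)
        if mcid is not None:
            mcid.to_csv(outdir / "mcid_flags.csv", index=False)
        (outdir / "report.json").write_text(json.dumps({
            "metadata": metadata,
            "ranksum": ranksum.to_dict(orient="records"),
            "pls": pls_summary,
            "mcid": (mcid.to_dict(orient="records") if mcid is not None else None),
        }, indent=1, default=str))

    return AnalysisReport(indices=indices, changes=changes, ranksum=ranksum,
                          pls_summary=pls_summary, mcid=mcid, metadata=metadata)
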