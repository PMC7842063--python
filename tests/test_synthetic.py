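"""Cohort, gait-event, FSR and E-field generators with planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from gaitdose import (
    GaitGenConfig,
    PlantedAssociation,
    SubjectProfile,
    default_montage_profiles,
    detect_contact_intervals,
    derive_gait_events,
    fit_pls,
    generate_cohort,
    generate_efield_matrix,
    generate_gait_events,
    plant_gait_change,
    random_planted_association,
    segment_gait_cycles,
    synthesize_fsr_traces,
)
from gaitdose.events import CHANNELS, HEEL_STRIKE, InvalidConfigError, SchemaError
from gaitdose.synthetic import DEFAULT_LOBULE_LABELS


class TestGenerateCohort:
    def test_affected_side_ratio_rounds_deterministically(self):
        cohort = generate_cohort(10, affected_side_ratio=0.4, seed=3)
        sides = [s.affected_side for s in cohort]
        assert sides.count("left") == 4
        assert sides.count("right") == 6

    def test_degenerate_height_range(self):
        cohort = generate_cohort(1, height_range=(1.7, 1.7), seed=0)
        assert cohort[0].height == pytest.approx(1.70)

    def test_heights_within_range(self):
        cohort = generate_cohort(50, height_range=(1.5, 1.9), seed=1)
        assert all(1.5 <= s.height <= 1.9 for s in cohort)

    def test_same_seed_reproduces_cohort(self):
        assert generate_cohort(10, seed=7) == generate_cohort(10, seed=7)

    @pytest.mark.parametrize("kwargs", [
        {"n_subjects": 0},
        {"n_subjects": 5, "height_range": (1.9, 1.5)},
        {"n_subjects": 5, "height_range": (-1.0, 1.5)},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            generate_cohort(**kwargs)


class TestGenerateGaitEvents:
    def test_covers_walk_duration(self, symmetric_trial):
        assert symmetric_trial.duration >= 10.0 - 1e-12

    def test_jitter_free_stance_exactly_planted(self, symmetric_trial):
        for leg in ("left", "right"):
            cycles = segment_gait_cycles(symmetric_trial.events_for(leg))
            assert cycles, "expected complete cycles"
            for c in cycles:
                assert c.stance_time == pytest.approx(0.6, abs=1e-12)
                assert c.cycle_time == pytest.approx(1.0, abs=1e-12)

    def test_events_strictly_increasing_per_leg(self, subject):
        config = GaitGenConfig(timing_jitter_sd=0.01, seed=5)
        trial = generate_gait_events(subject, config)
        for leg in ("left", "right"):
            times = [e.time for e in trial.events_for(leg)]
            assert all(b > a for a, b in zip(times, times[1:]))

    def test_same_seed_bit_identical(self, subject):
        config = GaitGenConfig(timing_jitter_sd=0.02, seed=11)
        t1 = generate_gait_events(subject, config)
        t2 = generate_gait_events(subject, config)
        assert [e.time for e in t1.events] == [e.time for e in t2.events]

    def test_asymmetric_stance_fractions_reach_each_leg(self, subject):
        config = GaitGenConfig(stance_fraction_affected=0.65,
                               stance_fraction_unaffected=0.60)
        trial = generate_gait_events(subject, config)  # affected = left
        stance = {
            leg: segment_gait_cycles(trial.events_for(leg))[0].stance_time
            for leg in ("left", "right")
        }
        assert stance["left"] == pytest.approx(0.65)
        assert stance["right"] == pytest.approx(0.60)

    def test_invalid_stance_fraction_rejected(self):
        with pytest.raises(InvalidConfigError):
            GaitGenConfig(stance_fraction_affected=1.0)


class TestSynthesizeFsrTraces:
    def test_rectangular_pulse_onsets_match_events(self, symmetric_trial):
        fs = 500.0
        traces = synthesize_fsr_traces(symmetric_trial, sampling_rate=fs)
        assert {t.channel for t in traces} == set(CHANNELS)
        heel = next(t for t in traces if t.leg == "left"
                    and t.channel == "medial_heel")
        intervals = detect_contact_intervals(heel)
        planted_hs = [e.time for e in symmetric_trial.events_for("left")
                      if e.event_type == HEEL_STRIKE]
        # one contact per complete footfall, onset at the heel-strike
        assert len(intervals) == len(planted_hs) - 1
        for iv, hs in zip(intervals, planted_hs):
            assert iv.onset == pytest.approx(hs, abs=1 / fs)

    def test_round_trip_recovers_planted_events(self, symmetric_trial):
        fs = 500.0
        traces = synthesize_fsr_traces(symmetric_trial, sampling_rate=fs)
        for leg in ("left", "right"):
            contacts = {t.channel: detect_contact_intervals(t)
                        for t in traces if t.leg == leg}
            recovered = derive_gait_events(contacts, leg)
            planted = sorted(symmetric_trial.events_for(leg),
                             key=lambda e: e.time)[: len(recovered)]
            for rec, ref in zip(recovered, planted):
                assert rec.event_type == ref.event_type
                assert rec.time == pytest.approx(ref.time, abs=1 / fs)

    def test_empty_trial_gives_empty_traces(self, symmetric_trial):
        empty = type(symmetric_trial)(
            "S01", "pre", "none", [], 10.0, 1.7, "left")
        assert synthesize_fsr_traces(empty) == []

    def test_amplitude_below_noise_warns(self, symmetric_trial, caplog):
        with caplog.at_level("WARNING"):
            synthesize_fsr_traces(symmetric_trial, pulse_amplitude=0.1,
                                  noise_sd=0.5, seed=0)
        assert any("event recovery" in r.message for r in caplog.records)


class TestEfieldMatrix:
    def test_zero_sd_rows_equal_montage_means(self):
        profiles = default_montage_profiles(between_subject_sd=0.0)
        cohort = generate_cohort(3, seed=0)
        ef = generate_efield_matrix(profiles, cohort, seed=0)
        for montage, profile in profiles.items():
            block = ef.xs(montage, level="montage")
            assert np.allclose(block.to_numpy(),
                               np.asarray(profile.mean_field))

    def test_printed_field_ranges_hold_for_default_profiles(self):
        """The default montage profiles satisfy the published inequalities:
        dentate montage reaches the dentate nuclei above 0.2 V/m, leg
        montage reaches lobules VIIb-IX above 0.08 V/m."""
        profiles = default_montage_profiles()
        dentate = dict(zip(profiles["dentate"].lobule_labels,
                           profiles["dentate"].mean_field))
        leg = dict(zip(profiles["leg"].lobule_labels,
                       profiles["leg"].mean_field))
        assert dentate["Contra_Dentate"] > 0.2
        assert dentate["Ipsi_Dentate"] > 0.2
        leg_cols = [c for c in leg
                    if c.endswith(("VIIb", "VIIIa", "VIIIb", "IX"))]
        assert leg_cols and all(leg[c] > 0.08 for c in leg_cols)

    def test_matrix_nonnegative_and_reproducible(self):
        cohort = generate_cohort(5, seed=2)
        profiles = default_montage_profiles(between_subject_sd=0.2)
        e1 = generate_efield_matrix(profiles, cohort, seed=9)
        e2 = generate_efield_matrix(profiles, cohort, seed=9)
        assert (e1.to_numpy() >= 0).all()
        pd.testing.assert_frame_equal(e1, e2)

    def test_label_mismatch_is_schema_error(self):
        profiles = list(default_montage_profiles().values())
        other = default_montage_profiles(
            lobule_labels=DEFAULT_LOBULE_LABELS[:-1])["leg"]
        with pytest.raises(SchemaError):
            generate_efield_matrix([profiles[0], other], generate_cohort(2))


class TestPlantGaitChange:
    @pytest.fixture
    def efield(self):
        cohort = generate_cohort(10, seed=1)
        return generate_efield_matrix(default_montage_profiles(), cohort, seed=1)

    def test_zero_noise_is_exact_linear_map(self, efield):
        assoc = random_planted_association(seed=0)
        change = plant_gait_change(efield, assoc)
        centered = efield - efield.mean(axis=0)
        expected = centered.to_numpy() @ assoc.coefficient_matrix.to_numpy()
        assert np.allclose(change.to_numpy(), expected)

    def test_zero_coefficients_give_pure_noise(self, efield):
        assoc = random_planted_association(seed=0)
        zero = PlantedAssociation(assoc.coefficient_matrix * 0.0,
                                  noise_sd=1.0, seed=4)
        change = plant_gait_change(efield, zero)
        assert abs(change.to_numpy().mean()) < 0.2

    def test_noise_free_full_component_fit_is_exact(self, efield):
        assoc = random_planted_association(seed=3)
        change = plant_gait_change(efield, assoc)
        model = fit_pls(efield, change, n_components=len(efield) - 1)
        assert model.r_squared_ == pytest.approx(1.0, abs=1e-10)

    def test_dimension_mismatch_is_schema_error(self, efield):
        assoc = random_planted_association(seed=0)
        with pytest.raises(SchemaError):
            plant_gait_change(efield.iloc[:, :-1], assoc)
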