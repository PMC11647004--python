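"""Synthetic cohort generator: determinism, anatomy, calibration."""

import numpy as np
import pytest

from dosurv.preprocess import aggregate_sessions
from dosurv.synthetic import (
    CohortConfig,
    draw_mean_doses,
    generate_cohort,
    generate_dose_course,
    generate_records,
    simulate_survival,
)
from dosurv.volume import SUBPARTS, WHOLE_HEART, ConfigurationError


class TestDoseCourse:
    def test_same_seed_identical_courses(self):
        cfg = CohortConfig(seed=42)
        a = generate_dose_course(cfg, "P000007", target_mean_dose=4.0)
        b = generate_dose_course(cfg, "P000007", target_mean_dose=4.0)
        assert a.n_sessions == b.n_sessions
        for (oa, va), (ob, vb) in zip(a.sessions, b.sessions):
            assert oa == ob
            np.testing.assert_array_equal(va.values, vb.values)

    def test_shapes_within_published_bound(self):
        cfg = CohortConfig(seed=0)
        for i in range(15):
            course = generate_dose_course(cfg, f"P{i:06d}")
            for _, vol in course.sessions:
                assert all(s <= m for s, m in zip(vol.shape, cfg.max_region_shape))

    def test_masks_disjoint_and_contained(self):
        cfg = CohortConfig(seed=5)
        course = generate_dose_course(cfg, "P000003", target_mean_dose=2.0)
        _, vol = course.sessions[0]
        whole = vol.masks[WHOLE_HEART]
        union = np.zeros_like(whole)
        for name in SUBPARTS:
            sub = vol.masks[name]
            assert sub.any(), f"{name} empty"
            assert not (union & sub).any(), "subparts overlap"
            union |= sub
        assert not (union & ~whole).any(), "subparts leak outside the heart"

    def test_in_window_sessions_hit_target_mean(self):
        cfg = CohortConfig(seed=11)
        for pid in ("P000001", "P000002", "P000009"):
            course = generate_dose_course(cfg, pid, target_mean_dose=7.5)
            agg = aggregate_sessions(course)
            assert agg.region_doses(WHOLE_HEART).mean() == pytest.approx(7.5, rel=1e-9)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(max_region_shape=(0, 10, 10))
        with pytest.raises(ConfigurationError):
            CohortConfig(min_region_shape=(50, 50, 50), max_region_shape=(20, 20, 20))


class TestMeanDoseDistribution:
    def test_summary_statistics(self, rng):
        cfg = CohortConfig()
        doses = draw_mean_doses(cfg, 10_000, rng)
        assert doses.max() < 50.0
        assert np.median(doses) < np.percentile(doses, 75)
        # point mass near zero: the non-irradiated fraction
        assert np.mean(doses == 0) == pytest.approx(cfg.zero_dose_fraction, abs=0.02)


class TestSimulateSurvival:
    def test_zero_coefficients_huge_scale_all_censored(self, rng):
        cfg = CohortConfig(hazard_coefficients={}, baseline_scale=1e9)
        time, event = simulate_survival({}, {}, cfg, rng=rng)
        assert event.sum() == 0

    def test_dose_effect_induces_positive_association(self, rng):
        from scipy.stats import kendalltau

        cfg = CohortConfig(hazard_coefficients={"mean_dose": 0.08})
        doses = draw_mean_doses(cfg, 20_000, rng)
        _, event = simulate_survival({}, {"mean_dose": doses}, cfg, rng=rng)
        assert kendalltau(doses, event).statistic > 0

    def test_missing_coefficient_key_raises(self, rng):
        cfg = CohortConfig(hazard_coefficients={"no_such_feature": 1.0})
        with pytest.raises(KeyError):
            simulate_survival({}, {}, cfg, rng=rng)

    def test_nonfinite_linear_predictor_raises(self, rng):
        cfg = CohortConfig(hazard_coefficients={"mean_dose": 1.0})
        with pytest.raises(ValueError):
            simulate_survival({}, {"mean_dose": np.array([np.inf, 1.0])}, cfg, rng=rng)


class TestCohortCalibration:
    def test_event_rate_near_target_at_20k(self):
        records = generate_records(CohortConfig(n_patients=20_000, seed=7))
        rate = np.mean([r.event for r in records])
        assert abs(rate - 0.05) < 0.01  # within one percentage point

    def test_censor_fraction_near_95pct_at_5k(self):
        records = generate_records(CohortConfig(n_patients=5_000, seed=13))
        censored = 1.0 - np.mean([r.event for r in records])
        assert abs(censored - 0.95) < 0.015

    def test_covariate_dependent_censoring_mode(self):
        """The optional mode shortens follow-up for the flagged exposure."""
        cfg = CohortConfig(
            n_patients=3000, seed=2, censoring_coefficients={"anthracyclines": 0.8}
        )
        recs = generate_records(cfg)
        t = np.array([r.time for r in recs])
        a = np.array([r.anthracyclines for r in recs])
        e = np.array([r.event for r in recs])
        assert np.median(t[(a == 1) & (e == 0)]) < np.median(t[(a == 0) & (e == 0)]) - 5

    def test_times_bounded_by_administrative_censoring(self):
        records = generate_records(CohortConfig(n_patients=500, seed=3))
        assert all(0 < r.time <= 60.0 for r in records)
        assert all(r.event in (0, 1) for r in records)


class TestGenerateCohort:
    def test_reproducible_from_seed(self):
        cfg = CohortConfig(
            n_patients=50, seed=99, min_region_shape=(10, 12, 12), max_region_shape=(20, 20, 20)
        )
        rec_a, courses_a = generate_cohort(cfg)
        rec_b, courses_b = generate_cohort(cfg)
        for a, b in zip(rec_a, rec_b):
            assert (a.patient_id, a.time, a.event, a.sex, a.age_category) == (
                b.patient_id,
                b.time,
                b.event,
                b.sex,
                b.age_category,
            )
        for pid in courses_a:
            for (_, va), (_, vb) in zip(courses_a[pid].sessions, courses_b[pid].sessions):
                np.testing.assert_array_equal(va.values, vb.values)

    def test_single_diagnosis_group_per_patient(self):
        records = generate_records(CohortConfig(n_patients=200, seed=1))
        for r in records:
            assert r.diagnosis_indicators.sum() == 1

    def test_too_small_cohort_raises(self):
        with pytest.raises(ConfigurationError):
            generate_records(CohortConfig(n_patients=1, seed=0))

    def test_associated_group_passes_chi2_screen(self):
        """A diagnosis group with a strong excess hazard survives the screen."""
        from dosurv.cohort import clinical_frame
        from dosurv.screening import select_diagnosis_indicators

        hits = 0
        for seed in range(5):
            cfg = CohortConfig(
                n_patients=4000,
                seed=100 + seed,
                hazard_coefficients={"mean_dose": 0.08, "diag_03": 1.6},
            )
            records = generate_records(cfg)
            clin = clinical_frame(records)
            events = np.array([r.event for r in records])
            kept = select_diagnosis_indicators(clin[[c for c in clin if c.startswith("diag_")]], events)
            hits += "diag_03" in kept
        assert hits >= 4
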