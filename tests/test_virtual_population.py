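"""Population sampling and disease scaling."""

import numpy as np
import pytest

from captopbpk import get_spec, sample_population
from captopbpk.errors import ConfigurationError, ValidationError
from captopbpk.virtual_population import (
    Variability,
    apply_chf_scaling,
    apply_ckd_scaling,
    apply_geriatric_scaling,
    builtin_specs,
    median_oral_bioavailability,
    realize_subject,
    sample_subject,
)
from conftest import STUDY_SEED


def typical_subject(drug, spec, **overrides):
    subject = sample_population(spec, drug, 1, 1, seed=1)[0]
    if overrides:
        import dataclasses

        subject = dataclasses.replace(subject, **overrides)
    return subject


class TestSampling:
    def test_no_variability_total_clearance_exact(self, drug, no_variability_healthy):
        subjects = sample_population(no_variability_healthy, drug, 2, 5, seed=3)
        assert all(s.cl_total == pytest.approx(49.5, abs=1e-12) for s in subjects)
        assert all(s.fa_i == 0.7 and s.ka_i == 1.75 for s in subjects)

    def test_fixed_seed_reproduces_subject_list(self, drug):
        spec = get_spec("healthy")
        a = sample_population(spec, drug, 3, 4, seed=11)
        b = sample_population(spec, drug, 3, 4, seed=11)
        assert a == b
        c = sample_population(spec, drug, 3, 4, seed=12)
        assert a != c

    def test_clearance_cv_matches_target(self, drug):
        """Lognormal sampling: 10,000 subjects carry the configured 30% CV
        on total clearance (one shared multiplier for both components)."""
        spec = get_spec("healthy")
        subjects = sample_population(spec, drug, 100, 100, seed=5)
        cl = np.array([s.cl_total for s in subjects])
        cv = cl.std(ddof=1) / cl.mean()
        assert abs(cv - 0.30) < 0.02

    def test_demographics_within_ranges(self, drug):
        spec = get_spec("healthy").with_(age_range=(20, 30), weight_range=(60, 70))
        subjects = sample_population(spec, drug, 5, 10, seed=2)
        assert all(20 <= s.age <= 30 and 60 <= s.weight <= 70 for s in subjects)
        assert all(100 <= s.gfr <= 140 for s in subjects)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ConfigurationError):
            get_spec("healthy").with_(age_range=(30, 20))

    def test_fraction_female_controls_sex(self, drug):
        spec = get_spec("healthy").with_(fraction_female=1.0)
        assert all(s.sex == "F" for s in sample_population(spec, drug, 2, 5, seed=4))


class TestCKDScaling:
    def test_severe_hepatic_scaling(self, drug, no_variability_healthy):
        spec = no_variability_healthy.with_(gfr_range=(22.5, 22.5))
        s = typical_subject(drug, spec)
        scaled = apply_ckd_scaling(s, "severe", drug)
        assert scaled.cl_h == pytest.approx(9.555)  # 0.35 x 27.3

    def test_moderate_gfr_proportional_renal_clearance(self, drug, no_variability_healthy):
        spec = no_variability_healthy.with_(gfr_range=(45.0, 45.0))
        scaled = apply_ckd_scaling(typical_subject(drug, spec), "moderate", drug)
        assert scaled.cl_r == pytest.approx(8.325)  # 22.2 x 45/120
        assert scaled.cl_h == pytest.approx(15.015)  # 0.55 x 27.3

    def test_vss_scaling_factor(self, drug, no_variability_healthy):
        spec = no_variability_healthy.with_(gfr_range=(75.0, 75.0))
        scaled = apply_ckd_scaling(typical_subject(drug, spec), "mild", drug)
        assert scaled.vss_per_kg == pytest.approx(0.267 * 2.51)
        assert scaled.vss_per_kg == pytest.approx(0.670, abs=5e-4)

    def test_gfr_outside_band_rejected(self, drug, no_variability_healthy):
        spec = no_variability_healthy.with_(gfr_range=(110.0, 110.0))
        with pytest.raises(ValidationError):
            apply_ckd_scaling(typical_subject(drug, spec), "severe", drug)

    def test_double_scaling_rejected(self, drug, no_variability_healthy):
        spec = no_variability_healthy.with_(gfr_range=(45.0, 45.0))
        scaled = apply_ckd_scaling(typical_subject(drug, spec), "moderate", drug)
        with pytest.raises(ValidationError):
            apply_ckd_scaling(scaled, "moderate", drug)

    def test_renal_clearance_gfr_ratio_constant(self, drug):
        spec = get_spec("ckd_moderate").with_(
            variability=Variability(0, 0, 0, 0, 0)
        )
        subjects = sample_population(spec, drug, 2, 10, seed=7)
        ratios = {round(s.cl_r / s.gfr, 12) for s in subjects}
        assert len(ratios) == 1  # cl_r strictly proportional to GFR at CV=0

    def test_severity_monotonicity_of_median_clearance(self, drug):
        medians = []
        for name in ("healthy", "ckd_mild", "ckd_moderate", "ckd_severe"):
            subjects = sample_population(get_spec(name), drug, 10, 10, seed=STUDY_SEED)
            medians.append(np.median([s.cl_total for s in subjects]))
        assert medians[0] > medians[1] > medians[2] > medians[3]


class TestCHFScaling:
    def test_moderate_flow_and_clearance(self, drug, no_variability_healthy):
        s = typical_subject(drug, no_variability_healthy)
        scaled = apply_chf_scaling(s, "moderate", drug)
        assert scaled.q_h == pytest.approx(48.6)  # 0.54 x 90
        assert scaled.cl_h == pytest.approx(15.015)  # 0.55 x 27.3
        assert scaled.cl_r == s.cl_r  # renal clearance unscaled by default
        assert scaled.flow_fractions == {"hepatic": 0.54, "renal": 0.55, "peripheral": 0.44}

    def test_renal_flow_switch(self, drug, no_variability_healthy):
        s = typical_subject(drug, no_variability_healthy)
        scaled = apply_chf_scaling(s, "severe", drug, scale_renal_flow=True)
        assert scaled.cl_r == pytest.approx(22.2 * 0.63)

    def test_unknown_severity_rejected(self, drug, no_variability_healthy):
        with pytest.raises(ValidationError):
            apply_chf_scaling(typical_subject(drug, no_variability_healthy), "extreme", drug)

    def test_severity_mix_deterministic(self, drug):
        spec = get_spec("chf")
        a = [s.severity_tag for s in sample_population(spec, drug, 5, 10, seed=9)]
        b = [s.severity_tag for s in sample_population(spec, drug, 5, 10, seed=9)]
        assert a == b
        assert set(a) == {"moderate", "severe"}


class TestGeriatricScaling:
    def test_age_forty_anchor_no_change(self, drug, no_variability_healthy):
        s = typical_subject(drug, no_variability_healthy, age=40.0)
        scaled = apply_geriatric_scaling(s, drug)
        assert scaled.gfr == s.gfr and scaled.q_h == s.q_h and scaled.cl_r == s.cl_r

    def test_one_percent_per_year_decline(self, drug, no_variability_healthy):
        s = typical_subject(drug, no_variability_healthy, age=70.0)
        scaled = apply_geriatric_scaling(s, drug)
        assert scaled.gfr / s.gfr == pytest.approx(0.70)
        assert scaled.q_h / s.q_h == pytest.approx(0.70)
        assert scaled.cl_h / s.cl_h == pytest.approx(0.70)
        assert scaled.fh == pytest.approx(s.fh)  # flow and clearance co-scale

    def test_decline_floor(self, drug, no_variability_healthy):
        s = typical_subject(drug, no_variability_healthy, age=100.0)
        scaled = apply_geriatric_scaling(s, drug)
        assert scaled.gfr / s.gfr == pytest.approx(0.50)

    def test_geriatric_apparent_clearance_below_healthy(self, drug):
        """Lower metabolic clearance at unchanged first-pass availability
        drags the geriatric median CL/F below the healthy-adult one."""
        healthy = sample_population(get_spec("healthy"), drug, 10, 10, seed=STUDY_SEED)
        geriatric = sample_population(get_spec("geriatric"), drug, 10, 10, seed=STUDY_SEED)
        clf_h = np.median([s.cl_total / s.f_oral for s in healthy])
        clf_g = np.median([s.cl_total / s.f_oral for s in geriatric])
        assert clf_g < clf_h

    def test_realize_dispatches_by_population(self, drug):
        rng = np.random.default_rng(0)
        assert realize_subject(get_spec("ckd_severe"), drug, rng).scaling_applied == "ckd_severe"
        rng = np.random.default_rng(0)
        assert realize_subject(get_spec("geriatric"), drug, rng).scaling_applied == "geriatric"
        rng = np.random.default_rng(0)
        assert realize_subject(get_spec("healthy"), drug, rng).scaling_applied is None


class TestBioavailability:
    def test_median_f_rounds_to_half(self, drug):
        subjects = sample_population(get_spec("healthy"), drug, 10, 10, seed=STUDY_SEED)
        assert round(median_oral_bioavailability(subjects), 1) == 0.5

    def test_builtin_registry_complete(self):
        assert set(builtin_specs()) == {
            "healthy", "geriatric", "ckd_mild", "ckd_moderate", "ckd_severe", "chf",
        }
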