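"""Minimal-PBPK ODE system: closed forms, mass balance, trial design."""

import dataclasses

import numpy as np
import pytest

from captopbpk import get_spec, run_trial_set, sample_population, simulate_profile
from captopbpk.errors import ValidationError
from captopbpk.pbpk_simulator import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    DoseRegimen,
    SamplingSchedule,
    _solve,
    default_schedule,
    profiles_to_frame,
)


@pytest.fixture
def typical(drug, no_variability_healthy):
    return sample_population(no_variability_healthy, drug, 1, 1, seed=1)[0]


class TestSchedules:
    def test_validation(self):
        with pytest.raises(ValidationError):
            SamplingSchedule((0.0, 1.0))  # too few
        with pytest.raises(ValidationError):
            SamplingSchedule((0.5, 1.0, 2.0))  # must start at 0
        with pytest.raises(ValidationError):
            SamplingSchedule((0.0, 2.0, 1.0))  # not increasing

    def test_short_schedule_warning(self):
        with pytest.warns(UserWarning, match="half-lives"):
            default_schedule(12.0).warn_if_short(terminal_half_life=3.0)


class TestODEContract:
    def test_central_volume_partition_rule(self, typical):
        # kin = kout = 0.25 splits Vss equally between central and SAC
        assert typical.vc == pytest.approx(typical.vss_total / 2.0)

    def test_iv_one_compartment_closed_form(self, drug, typical):
        """With the adjusting compartment off, an iv bolus is mono-
        exponential: C(t) = Dose/Vc * exp(-CL/Vc * t) to 1e-6 relative."""
        one_cmpt = dataclasses.replace(typical, kin=0.0, kout=0.25)
        schedule = default_schedule(6.0, 0.05)
        prof = simulate_profile(one_cmpt, drug, DoseRegimen("iv_bolus", 10.0), schedule)
        t = prof.t
        vc = one_cmpt.vc  # = Vss_total when kin = 0
        expected = 10.0 / vc * 1000.0 * np.exp(-one_cmpt.cl_total / vc * t)
        assert np.allclose(prof.c, expected, rtol=1e-6)

    def test_oral_mass_reaches_elimination(self, drug, typical):
        """With complete absorption and no first-pass loss the whole dose
        is eventually eliminated."""
        s = dataclasses.replace(typical, fa_i=1.0, cl_h=0.0)
        states = _solve(s, drug, DoseRegimen("oral", 10.0), np.array([0.0, 100.0]),
                        DEFAULT_RTOL, DEFAULT_ATOL)
        assert states[-1, 3] == pytest.approx(10.0, rel=1e-6)  # a_eliminated

    def test_first_pass_loss_accumulates(self, drug, typical):
        states = _solve(typical, drug, DoseRegimen("oral", 100.0),
                        np.array([0.0, 100.0]), DEFAULT_RTOL, DEFAULT_ATOL)
        delivered = typical.fa_i * 100.0
        eliminated, lost = states[-1, 3], states[-1, 4]
        assert lost == pytest.approx(delivered * (1 - typical.fh), rel=1e-5)
        assert eliminated + lost == pytest.approx(delivered, rel=1e-6)

    def test_mass_balance_at_every_output_time(self, drug):
        """depot + central + SAC + eliminated + first-pass loss equals the
        delivered dose within 10x solver tolerance at all timepoints."""
        spec = get_spec("healthy")
        subjects = sample_population(spec, drug, 1, 5, seed=8)
        times = np.array(default_schedule(12.0, 0.1).timepoints)
        for s in subjects:
            for regimen in (DoseRegimen("iv_bolus", 10.0), DoseRegimen("oral", 100.0)):
                states = _solve(s, drug, regimen, times, DEFAULT_RTOL, DEFAULT_ATOL)
                delivered = regimen.amount if regimen.route == "iv_bolus" else s.fa_i * regimen.amount
                err = np.abs(states.sum(axis=1) - delivered)
                assert err.max() <= 10.0 * (DEFAULT_RTOL * delivered + DEFAULT_ATOL)

    def test_dose_superposition(self, drug, typical):
        schedule = default_schedule(12.0, 0.2)
        low = simulate_profile(typical, drug, DoseRegimen("oral", 50.0), schedule)
        high = simulate_profile(typical, drug, DoseRegimen("oral", 100.0), schedule)
        mask = low.c > 0
        assert np.allclose(high.c[mask] / low.c[mask], 2.0, rtol=1e-6)

    def test_oral_profile_zero_before_lag(self, drug, typical):
        schedule = SamplingSchedule((0.0, 0.1, 0.2, 0.5, 1.0, 2.0, 4.0))
        prof = simulate_profile(typical, drug, DoseRegimen("oral", 100.0), schedule)
        assert prof.c[0] == 0.0 and prof.c[1] == 0.0  # before tlag = 0.2 h
        assert prof.c[3] > 0.0

    def test_iv_reports_initial_condition(self, drug, typical):
        prof = simulate_profile(typical, drug, DoseRegimen("iv_bolus", 10.0),
                                default_schedule(6.0, 0.5))
        assert prof.c[0] == pytest.approx(10.0 / typical.vc * 1000.0)

    def test_terminal_slope_one_compartment(self, drug, typical):
        """For kin = 0 the terminal slope equals CL/Vc within 0.5%."""
        from captopbpk.nca import estimate_lambda_z

        one_cmpt = dataclasses.replace(typical, kin=0.0)
        prof = simulate_profile(one_cmpt, drug, DoseRegimen("iv_bolus", 10.0),
                                default_schedule(4.0, 0.1))
        lam, _, _ = estimate_lambda_z(prof.t, prof.c)
        assert lam == pytest.approx(one_cmpt.cl_total / one_cmpt.vc, rel=5e-3)


class TestAUCInvariance:
    @pytest.mark.parametrize("kin,kout", [(0.0, 0.25), (0.25, 0.25), (0.5, 0.2)])
    def test_auc_independent_of_distribution(self, drug, typical, kin, kout):
        """NCA AUC0-inf on dense noise-free profiles equals
        dose * F_route / CL within 1% for any exchange rates."""
        from captopbpk.nca import run_nca

        s = dataclasses.replace(typical, kin=kin, kout=kout)
        t_end = 48.0 if kin > 0 else 12.0
        schedule = SamplingSchedule(tuple(np.concatenate([
            np.arange(0.0, 3.0, 0.01), np.arange(3.0, t_end + 0.05, 0.1)])))
        iv = run_nca(simulate_profile(s, drug, DoseRegimen("iv_bolus", 10.0), schedule))
        assert iv.auc_0_inf == pytest.approx(10.0 * 1e3 / s.cl_total, rel=0.01)
        assert iv.cl_over_f == pytest.approx(s.cl_total, rel=0.01)
        oral = run_nca(simulate_profile(s, drug, DoseRegimen("oral", 100.0), schedule))
        expected = 100.0 * 1e3 * s.f_oral / s.cl_total
        assert oral.auc_0_inf == pytest.approx(expected, rel=0.01)


class TestTrialSet:
    def test_design_yields_100_profiles(self, drug):
        ts = run_trial_set(get_spec("healthy"), drug, DoseRegimen("iv_bolus", 10.0),
                           default_schedule(12.0, 0.5), 10, 10, seed=1)
        assert len(ts.profiles) == 100
        assert len({(p.trial_id, p.subject_id) for p in ts.profiles}) == 100

    def test_bit_identical_under_seed(self, drug):
        spec = get_spec("ckd_moderate")
        kwargs = dict(n_trials=2, n_per_trial=3, seed=17)
        a = run_trial_set(spec, drug, DoseRegimen("oral", 100.0),
                          default_schedule(12.0, 0.5), **kwargs)
        b = run_trial_set(spec, drug, DoseRegimen("oral", 100.0),
                          default_schedule(12.0, 0.5), **kwargs)
        assert all(pa.concentrations == pb.concentrations
                   for pa, pb in zip(a.profiles, b.profiles))

    def test_no_variability_profiles_identical(self, drug, no_variability_healthy):
        ts = run_trial_set(no_variability_healthy, drug, DoseRegimen("oral", 25.0),
                           default_schedule(12.0, 0.5), 2, 5, seed=3)
        ref = ts.profiles[0].concentrations
        assert all(p.concentrations == ref for p in ts.profiles)

    def test_tidy_frame_shape(self, drug, no_variability_healthy):
        ts = run_trial_set(no_variability_healthy, drug, DoseRegimen("oral", 25.0),
                           default_schedule(2.0, 0.5), 2, 2, seed=3)
        df = profiles_to_frame(ts.profiles)
        assert list(df.columns) == ["trial_id", "subject_id", "time_h", "conc_ng_per_ml"]
        assert len(df) == 4 * 5
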