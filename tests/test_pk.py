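import math

import numpy as np
import pytest

from flupk import (
    ConfigError,
    DoseEvent,
    DoseRegimen,
    PKParameters,
    PopulationModel,
    Subject,
    ValidationError,
    concentration_profile,
    cumulative_auc,
    individual_parameters,
    ode_oracle,
)
from conftest import CL_POP_FIXTURE, random_params, random_regimen


class TestPopulationModel:
    def test_cl_pop_required(self):
        with pytest.raises((TypeError, ConfigError)):
            PopulationModel()  # noqa -- deliberately missing cl_pop
        with pytest.raises(ConfigError):
            PopulationModel(cl_pop=None)

    def test_default_omega_positive_definite(self, pop_model):
        om = pop_model.omega_matrix()
        corr = om[0, 1] / math.sqrt(om[0, 0] * om[1, 1])
        assert corr == pytest.approx(0.749, abs=0.001)
        assert np.all(np.linalg.eigvalsh(om) > 0)

    def test_correlation_reading_switch(self, pop_model):
        alt = pop_model.with_(omega_cl_vc_is_correlation=True)
        om = alt.omega_matrix()
        assert om[0, 1] == pytest.approx(0.141 * math.sqrt(0.117 * 0.303))

    def test_rejects_non_pd_omega(self):
        with pytest.raises(ConfigError):
            PopulationModel(cl_pop=3.0, omega=((0.1, 0.5), (0.5, 0.1)))


class TestIndividualParameters:
    def test_reference_subject_reproduces_scale_values(self, pop_model, ref_subject):
        p = individual_parameters(pop_model, ref_subject, (0.0, 0.0))
        # maturation is 1.0 to machine precision at age 30
        assert p.cl == CL_POP_FIXTURE
        assert p.vc == 11.5
        assert p.q == 1.47
        assert p.vp == 8.48

    def test_allometric_scaling(self, pop_model, ref_subject):
        big = Subject(id="big", age=30, sex="male", weight=60.0, height=160.0,
                      serum_creatinine=0.8, crcl=100.0, ffm=24.0)
        p = individual_parameters(pop_model, big)
        assert p.cl == pytest.approx(CL_POP_FIXTURE * 2 ** 0.75)
        assert p.vc == pytest.approx(23.0)
        assert p.q == pytest.approx(1.47 * 2 ** 0.75)
        assert p.vp == pytest.approx(16.96)

    def test_eta_acts_lognormally(self, pop_model, ref_subject):
        p0 = individual_parameters(pop_model, ref_subject)
        p = individual_parameters(pop_model, ref_subject, (math.log(2), 0.0))
        assert p.cl == pytest.approx(2 * p0.cl)
        assert p.vc == pytest.approx(p0.vc)

    def test_rejects_nonfinite_eta(self, pop_model, ref_subject):
        with pytest.raises(ValidationError):
            individual_parameters(pop_model, ref_subject, (math.nan, 0.0))


class TestConcentrationProfile:
    def test_zero_before_any_dose(self, daily_regimen):
        p = PKParameters(cl=5.0, vc=11.5, q=1.47, vp=8.48)
        c = concentration_profile(p, daily_regimen, [0.0])
        assert c[0] == 0.0

    def test_superposition_exact(self):
        p = PKParameters(cl=5.0, vc=11.5, q=1.47, vp=8.48)
        t = np.linspace(0, 72, 57)
        both = DoseRegimen((DoseEvent(40, 0.0), DoseEvent(25, 24.0)))
        first = DoseRegimen((DoseEvent(40, 0.0),))
        second = DoseRegimen((DoseEvent(25, 24.0),))
        c = concentration_profile(p, both, t)
        c1 = concentration_profile(p, first, t)
        c2 = concentration_profile(p, second, t)
        np.testing.assert_allclose(c, c1 + c2, rtol=1e-12, atol=1e-15)

    def test_bolus_limit_is_dose_over_vc(self):
        p = PKParameters(cl=5.0, vc=11.5, q=1.47, vp=8.48)
        dur = 1e-7
        reg = DoseRegimen((DoseEvent(100.0, 0.0, dur),))
        c = concentration_profile(p, reg, [dur])
        assert c[0] == pytest.approx(100.0 / 11.5, rel=1e-5)

    def test_rejects_negative_times(self, daily_regimen):
        p = PKParameters(cl=5.0, vc=11.5, q=1.47, vp=8.48)
        with pytest.raises(ValidationError):
            concentration_profile(p, daily_regimen, [-1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_ode_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        reg = random_regimen(rng)
        t = np.sort(rng.uniform(0.0, reg.last_end + 48.0, 40))
        ca = concentration_profile(p, reg, t)
        co = ode_oracle(p, reg, t)
        assert np.all(np.abs(ca - co) <= 1e-6 * np.abs(co) + 1e-12)


class TestOdeOracle:
    def test_zero_dose_gives_zero_profile(self):
        p = PKParameters(cl=5.0, vc=11.5, q=1.47, vp=8.48)
        c = ode_oracle(p, None, np.linspace(0, 48, 10))
        assert np.all(c == 0)

    def test_mass_balance(self):
        rng = np.random.default_rng(3)
        p = random_params(rng)
        reg = random_regimen(rng)
        t = np.array([reg.last_end + 30.0])
        _, states = ode_oracle(p, reg, t, full_output=True)
        total = states[0].sum()  # central + peripheral + eliminated
        assert total == pytest.approx(reg.total_dose, rel=1e-8)


class TestCumulativeAuc:
    def test_dose_over_cl_identity(self, daily_regimen):
        p = PKParameters(cl=5.0, vc=11.5, q=1.47, vp=8.48)
        summ = cumulative_auc(p, daily_regimen)
        assert summ.cauc == pytest.approx(120.0 / 5.0)
        assert summ.per_dose_auc == tuple([30.0 / 5.0] * 4)

    def test_linearity_in_dose(self):
        p = PKParameters(cl=5.0, vc=11.5, q=1.47, vp=8.48)
        a = cumulative_auc(p, DoseRegimen.daily(30, 4)).cauc
        b = cumulative_auc(p, DoseRegimen.daily(60, 4)).cauc
        assert b == pytest.approx(2 * a)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_matches_closed_form(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = random_params(rng)
        reg = random_regimen(rng)
        cf = cumulative_auc(p, reg, "closed_form").cauc
        tr = cumulative_auc(p, reg, "trapezoid").cauc
        assert tr == pytest.approx(cf, rel=5e-3)

    def test_closed_form_ignores_infusion_duration(self):
        p = PKParameters(cl=5.0, vc=11.5, q=1.47, vp=8.48)
        short = cumulative_auc(p, DoseRegimen.daily(30, 4, duration=0.5)).cauc
        long = cumulative_auc(p, DoseRegimen.daily(30, 4, duration=3.0)).cauc
        assert short == long

    def test_trapezoid_nearly_duration_invariant(self):
        p = PKParameters(cl=5.0, vc=11.5, q=1.47, vp=8.48)
        short = cumulative_auc(p, DoseRegimen.daily(30, 4, duration=0.5), "trapezoid").cauc
        long = cumulative_auc(p, DoseRegimen.daily(30, 4, duration=3.0), "trapezoid").cauc
        assert long == pytest.approx(short, rel=1e-3)

    def test_cauc_strictly_decreasing_in_crcl(self, pop_model):
        caucs = []
        for crcl in (60.0, 100.0, 150.0):
            s = Subject(id="s", age=30, sex="male", weight=40, height=140,
                        serum_creatinine=0.8, crcl=crcl, ffm=12.0)
            p = individual_parameters(pop_model, s)
            caucs.append(cumulative_auc(p, DoseRegimen.daily(30, 4)).cauc)
        assert caucs[0] > caucs[1] > caucs[2]


class TestRegimenValidation:
    def test_rejects_nonpositive_amount(self):
        with pytest.raises(ValidationError):
            DoseEvent(0.0, 0.0)

    def test_rejects_decreasing_starts(self):
        with pytest.raises(ValidationError):
            DoseRegimen((DoseEvent(10, 24.0), DoseEvent(10, 0.0)))
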