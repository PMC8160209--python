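from dataclasses import replace

import numpy as np
import pytest

import pbpkfit as pf
from pbpkfit.pbpk import SimulationError

DOSE = 10_000.0  # µg


def iv(amount=DOSE):
    return [pf.DoseEvent("iv_bolus", amount)]


class TestMassBalance:
    def test_zero_clearance_iv_conserves_dose(self, human, uniform_kp):
        c = pf.CompoundProfile(
            name="inert", logp=0.0, ionization=pf.IonizationSpec("neutral"),
            fup=1.0, bp_ratio=1.0, ka=1.0,
        )
        res = pf.simulate(c, human, uniform_kp, iv(1000.0), 48.0)
        total = res.total_in_body()
        assert np.max(np.abs(total - 1000.0)) < 1e-6 * 1000.0

    def test_with_clearance_body_plus_eliminated_equals_dose(
        self, human, uniform_kp, neutral_compound
    ):
        res = pf.simulate(neutral_compound, human, uniform_kp, iv(), 200.0)
        assert res.diagnostics["max_mass_residual"] < 1e-6

    def test_oral_bioavailability_limit(self, human, uniform_kp):
        c = pf.CompoundProfile(
            name="inert", logp=0.0, ionization=pf.IonizationSpec("neutral"),
            fup=1.0, bp_ratio=1.0, ka=1.0, f_oral=0.5,
        )
        res = pf.simulate(c, human, uniform_kp, [pf.DoseEvent("oral", 1000.0)], 100.0)
        assert res.total_in_body()[-1] == pytest.approx(500.0, rel=1e-4)
        assert res.amounts["elim_unabsorbed"][-1] == pytest.approx(500.0, rel=1e-4)

    def test_infusion_conserves_and_plateaus(self, human, uniform_kp, neutral_compound):
        # 3 L/h plasma clearance; plateau plasma conc = rate / CL_plasma
        rate = 300.0  # µg/h over 400 h
        doses = [pf.DoseEvent("iv_infusion", rate * 400.0, start_time=0.0, duration=400.0)]
        res = pf.simulate(neutral_compound, human, uniform_kp, doses, 400.0)
        assert res.diagnostics["max_mass_residual"] < 1e-6
        cl_plasma = 3.0 * neutral_compound.bp_ratio
        plasma = pf.venous_plasma_series(res, neutral_compound.bp_ratio)
        # venous plasma plateau sits slightly above rate/CL_plasma: clearance
        # acts on liver/kidney outflow blood, which at steady state is a few
        # percent below venous concentration (arteriovenous gradient)
        assert plasma.conc[-1] == pytest.approx(rate / cl_plasma, rel=0.04)


class TestDegenerateLimits:
    def test_one_compartment_closed_form(self, fast_flow_subject, uniform_kp):
        c = pf.CompoundProfile(
            name="onecpt", logp=0.0, ionization=pf.IonizationSpec("neutral"),
            fup=1.0, bp_ratio=1.0, cl_hepatic=10.0, ka=1.0,
        )
        v_total = sum(e.volume for e in fast_flow_subject.tissues.values())
        grid = np.geomspace(0.01, 24.0, 400)
        res = pf.simulate(c, fast_flow_subject, uniform_kp, iv(1000.0), 24.0, output_times=grid)
        plasma = pf.venous_plasma_series(res, 1.0)
        ref = 1000.0 / v_total * np.exp(-10.0 * grid / v_total)
        assert np.max(np.abs(plasma.conc - ref) / ref) < 0.005

    def test_iv_auc_identity_dose_over_blood_clearance(self, human, uniform_kp, neutral_compound):
        # NCA AUC0-inf on the blood profile = Dose / CL_blood in the
        # low-extraction limit (CL_total 0.75 vs liver flow ~79 L/h)
        c = replace(neutral_compound, cl_hepatic=0.5, cl_renal=0.25)
        vss = pf.analytic_vdss(human, uniform_kp, c)
        t_end = 12.0 * np.log(2.0) * vss / 0.75
        grid = np.geomspace(1e-3, t_end, 1500)
        res = pf.simulate(c, human, uniform_kp, iv(), t_end, output_times=grid)
        blood = pf.venous_plasma_series(res, 1.0)  # B:P 1 -> blood conc
        out = pf.compute_pk_outputs(blood)
        assert out.auc_inf == pytest.approx(DOSE / 0.75, rel=0.01)

    def test_route_consistency_oral_auc_is_f_times_iv(self, human, uniform_kp):
        c = pf.CompoundProfile(
            name="lowE", logp=0.0, ionization=pf.IonizationSpec("neutral"),
            fup=1.0, bp_ratio=1.0, cl_hepatic=1.0, ka=0.8, f_oral=0.6,
        )
        vss = pf.analytic_vdss(human, uniform_kp, c)
        t_end = 14.0 * np.log(2.0) * vss / 1.0
        grid = np.geomspace(1e-3, t_end, 1500)
        auc = {}
        for route in ("iv_bolus", "oral"):
            res = pf.simulate(c, human, uniform_kp, [pf.DoseEvent(route, DOSE)], t_end, output_times=grid)
            auc[route] = pf.compute_pk_outputs(pf.venous_plasma_series(res, 1.0)).auc_inf
        assert auc["oral"] == pytest.approx(0.6 * auc["iv_bolus"], rel=0.02)


class TestLinearity:
    def test_dose_doubling_doubles_concentrations(self, human, uniform_kp, neutral_compound):
        grid = np.geomspace(0.05, 48.0, 60)
        r1 = pf.simulate(neutral_compound, human, uniform_kp, iv(1000.0), 48.0, output_times=grid)
        r2 = pf.simulate(neutral_compound, human, uniform_kp, iv(2000.0), 48.0, output_times=grid)
        c1 = pf.venous_plasma_series(r1, 1.0).conc
        c2 = pf.venous_plasma_series(r2, 1.0).conc
        assert np.allclose(c2, 2.0 * c1, rtol=1e-6)

    def test_bp_ratio_scales_plasma_series(self, human, uniform_kp, neutral_compound):
        res = pf.simulate(neutral_compound, human, uniform_kp, iv(), 48.0)
        p1 = pf.venous_plasma_series(res, 1.0).conc
        p2 = pf.venous_plasma_series(res, 2.0).conc
        assert np.allclose(p2, p1 / 2.0)


class TestAnalyticVdss:
    def test_unit_kp_gives_total_volume(self, human, uniform_kp, neutral_compound):
        c = replace(neutral_compound, bp_ratio=1.0)
        v_total = sum(e.volume for e in human.tissues.values())
        assert pf.analytic_vdss(human, uniform_kp, c) == pytest.approx(v_total)

    def test_small_kp_limit_is_blood_referenced_volume(self, human, neutral_compound):
        tiny = pf.PartitionSet(kp={t: 1e-12 for t in pf.TISSUES}, method="kp_optimized")
        v_blood = (
            human.tissues["venous_blood"].volume + human.tissues["arterial_blood"].volume
        )
        vdss = pf.analytic_vdss(human, tiny, neutral_compound)
        assert vdss == pytest.approx(v_blood * neutral_compound.bp_ratio, rel=1e-6)

    def test_matches_nca_vdss_on_noiseless_iv(self, human, neutral_compound):
        rng = np.random.default_rng(7)
        kp = {t: float(10 ** rng.uniform(-0.5, 1.0)) for t in pf.TISSUES}
        ps = pf.PartitionSet(kp=kp, method="kp_optimized")
        vss = pf.analytic_vdss(human, ps, neutral_compound)
        t_end = 12.0 * np.log(2.0) * vss / 3.0
        grid = np.geomspace(1e-3, t_end, 2000)
        res = pf.simulate(neutral_compound, human, ps, iv(), t_end, output_times=grid)
        out = pf.compute_pk_outputs(pf.venous_plasma_series(res, neutral_compound.bp_ratio))
        assert out.vdss == pytest.approx(vss, rel=0.02)


class TestValidation:
    def test_missing_kp_is_configuration_error(self, human, neutral_compound):
        partial = pf.PartitionSet(kp={"muscle": 1.0}, method="kp_optimized")
        with pytest.raises(SimulationError, match="missing Kp"):
            pf.simulate(neutral_compound, human, partial, iv(), 10.0)

    def test_dose_event_contracts(self):
        with pytest.raises(ValueError):
            pf.DoseEvent("iv_bolus", 100.0, duration=1.0)
        with pytest.raises(ValueError):
            pf.DoseEvent("iv_infusion", 100.0, duration=0.0)
        with pytest.raises(ValueError):
            pf.DoseEvent("oral", -5.0)

    def test_fixed_step_mode_matches_adaptive(self, human, uniform_kp, neutral_compound):
        grid = np.linspace(0.5, 6.0, 8)
        ad = pf.simulate(neutral_compound, human, uniform_kp, iv(), 6.0, output_times=grid)
        fx = pf.simulate(
            neutral_compound, human, uniform_kp, iv(), 6.0, output_times=grid,
            fixed_step=0.002,
        )
        ca = pf.venous_plasma_series(ad, 1.0).conc
        cf = pf.venous_plasma_series(fx, 1.0).conc
        assert np.allclose(cf, ca, rtol=1e-4)
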