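"""Maternal-fetal PBPK core: clearance scaling, simulation, K_p,uu, AAFE."""

import numpy as np
import pytest

from fetalkp.pbpk import (
    DoseRegimen,
    PbpkParameterSet,
    aafe,
    effective_pd_clearance,
    first_steady_interval,
    kpuu_from_simulation,
    kpuu_steady_state,
    scale_passive_from_reference,
    simulate,
)


class TestClearanceScaling:
    @pytest.mark.parametrize("cl, q, expected", [(121, 45, 45), (47, 27.5, 27.5), (10, 45, 10)])
    def test_perfusion_cap(self, cl, q, expected):
        assert effective_pd_clearance(cl, q) == expected

    @pytest.mark.parametrize(
        "papp, expected",
        [(1.19e-5, 121.4), (1.25e-5, 127.6), (4.9e-5, 500.0)],
    )
    def test_midazolam_anchor_scaling(self, papp, expected):
        assert scale_passive_from_reference(500.0, papp, 4.9e-5) == \
            pytest.approx(expected, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            effective_pd_clearance(-1, 45)
        with pytest.raises(ValueError):
            scale_passive_from_reference(500, 1e-5, 0)


class TestAafe:
    def test_identical_vectors(self):
        assert aafe([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_uniform_twofold_error(self):
        obs = np.array([1.0, 5.0, 9.0])
        assert aafe(2 * obs, obs) == pytest.approx(2.0)

    def test_symmetric_over_and_under_prediction(self):
        # 10^((log 2 + log 2)/2) = 2
        assert aafe([2.0, 0.5], [1.0, 1.0]) == pytest.approx(2.0)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            aafe([1.0, 0.0], [1.0, 1.0])


class TestSimulation:
    def test_passive_only_equilibrates_to_unit_kpuu(self, drv_params, drv_regimen):
        sim = simulate(drv_params.replace(cl_pm=0.0), drv_regimen)
        assert kpuu_from_simulation(sim) == pytest.approx(1.0, rel=0.01)

    def test_extreme_efflux_drives_kpuu_to_zero(self, drv_params, drv_regimen):
        sim = simulate(drv_params.replace(cl_pm=1e6), drv_regimen, from_steady_state=True)
        assert kpuu_from_simulation(sim) < 1e-3

    def test_matches_closed_form_steady_state(self, drv_params, drv_regimen):
        sim = simulate(drv_params, drv_regimen, from_steady_state=True)
        assert kpuu_from_simulation(sim) == \
            pytest.approx(kpuu_steady_state(drv_params), rel=0.005)

    def test_closed_form_with_fetal_elimination(self, drv_params, drv_regimen):
        p = drv_params.replace(fetal_cl=5.0)
        sim = simulate(p, drv_regimen, from_steady_state=True)
        assert kpuu_from_simulation(sim) == pytest.approx(kpuu_steady_state(p), rel=0.005)
        assert kpuu_steady_state(p) < kpuu_steady_state(drv_params)

    @pytest.mark.parametrize("cl_pm", [0.0, 50.0, 500.0])
    def test_mass_balance(self, drv_params, drv_regimen, cl_pm):
        sim = simulate(drv_params.replace(cl_pm=cl_pm), drv_regimen)
        assert sim.mass_balance_rel_error < 1e-6

    def test_superposition_dose_linearity(self, drv_params, drv_regimen):
        import dataclasses
        sim1 = simulate(drv_params, drv_regimen)
        sim2 = simulate(drv_params, dataclasses.replace(drv_regimen,
                                                        dose_mg=2 * drv_regimen.dose_mg))
        np.testing.assert_allclose(sim2.maternal_mg_per_l, 2 * sim1.maternal_mg_per_l,
                                   rtol=1e-9)
        np.testing.assert_allclose(sim2.fetal_mg_per_l, 2 * sim1.fetal_mg_per_l,
                                   rtol=1e-9, atol=1e-15)

    def test_kpuu_monotone_in_efflux_and_passive(self, drv_params, drv_regimen):
        kpuus = [
            kpuu_from_simulation(simulate(drv_params.replace(cl_pm=c), drv_regimen,
                                          from_steady_state=True))
            for c in (0.0, 10.0, 50.0, 200.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(kpuus, kpuus[1:]))
        # increasing effective passive clearance raises kpuu at fixed efflux
        kpuus_pd = [
            kpuu_from_simulation(simulate(
                drv_params.replace(cl_int_pd_placenta=pd), drv_regimen,
                from_steady_state=True))
            for pd in (5.0, 15.0, 30.0, 45.0)
        ]
        assert all(a < b for a, b in zip(kpuus_pd, kpuus_pd[1:]))

    def test_exact_propagator_agrees_with_stiff_ode_route(self, drv_params):
        regimen = DoseRegimen(dose_mg=600, interval_h=12, n_doses=4)
        exact = simulate(drv_params, regimen, method="exact")
        ivp = simulate(drv_params, regimen, method="ivp")
        np.testing.assert_allclose(ivp.maternal_mg_per_l, exact.maternal_mg_per_l,
                                   rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(ivp.fetal_mg_per_l, exact.fetal_mg_per_l,
                                   rtol=1e-5, atol=1e-10)

    def test_steady_state_error_advises_more_doses(self, drv_params):
        sim = simulate(drv_params, DoseRegimen(dose_mg=600, interval_h=12, n_doses=2))
        with pytest.raises(RuntimeError, match="more doses"):
            kpuu_from_simulation(sim)

    @pytest.mark.parametrize("cl_maternal", [5.0, 10.0, 20.0])
    @pytest.mark.parametrize("v_maternal", [50.0, 100.0])
    def test_steady_state_detected_within_ten_intervals(self, drv_params, cl_maternal,
                                                        v_maternal):
        # maternal half-life ln2*V/CL < 3 * interval for this grid
        p = drv_params.replace(cl_maternal=cl_maternal, v_maternal=v_maternal)
        assert np.log(2) * v_maternal / cl_maternal < 3 * 12.0
        sim = simulate(p, DoseRegimen(dose_mg=600, interval_h=12, n_doses=12))
        k = first_steady_interval(sim)
        assert 0 < k <= 10

    def test_vanishing_placental_volume_reduces_to_direct_exchange(self, drv_params,
                                                                   drv_regimen):
        # quasi-steady placenta: unbound tissue concentration interpolates the
        # adjacent compartments; at steady state the direct-exchange model
        # gives kpuu = clmp/(clmp + cl_pm)
        p = drv_params.replace(v_placenta=1e-6)
        clmp = effective_pd_clearance(p.cl_int_pd_placenta, p.q_placenta_maternal)
        reduced = clmp / (clmp + p.cl_pm)
        sim = simulate(p, drv_regimen, from_steady_state=True)
        assert kpuu_from_simulation(sim) == pytest.approx(reduced, rel=0.01)


class TestParameterValidation:
    def test_fraction_bounds(self, drv_params):
        with pytest.raises(ValueError):
            drv_params.replace(fu_m=0.0)
        with pytest.raises(ValueError):
            drv_params.replace(f_oral=1.5)

    def test_negative_clearance_rejected(self, drv_params):
        with pytest.raises(ValueError):
            drv_params.replace(cl_pm=-1.0)

    def test_tlag_must_fit_in_interval(self, drv_params):
        with pytest.raises(ValueError, match="tlag"):
            simulate(drv_params.replace(tlag=13.0),
                     DoseRegimen(dose_mg=600, interval_h=12, n_doses=2))

    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            DoseRegimen(dose_mg=0, interval_h=12)
        with pytest.raises(ValueError):
            DoseRegimen(dose_mg=600, interval_h=12, n_doses=0)
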