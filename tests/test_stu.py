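"""Coupled STU system: dimensions, mass balance, porto-venous behaviour,
intra-sinusoidal gradients and indicator dilution."""

import numpy as np
import pytest
from dataclasses import replace

from hepstu.hormones import TransferFunctions
from hepstu.microcirculation import (STUGeometry, SystemicParams,
                                     perfused_systemic, rbc_transit_time)
from hepstu.stu import (STUSystem, assemble_stu, gamma_variate_input,
                        half_life_decay, indicator_dilution,
                        steady_state_stu)
from hepstu.zonation import ZonationProfile


def test_default_unit_has_889_state_variables(stu_system):
    assert stu_system.n_states == 889


def test_state_dimension_formula():
    for n in (15, 22, 25):
        geom = STUGeometry(length=15.0 * n, n_cells=n)
        system = assemble_stu(geom, ZonationProfile.default(n_cells=n))
        assert system.n_states == 30 * n + 7 * n + 6 * n + 28 + 1


def test_cell_count_mismatch_rejected(profile):
    geom = STUGeometry(length=225.0, n_cells=15)
    with pytest.raises(ValueError, match="cells"):
        STUSystem(geom, profile)


def test_inert_tube_passes_glucose_unchanged(stu_system):
    """All metabolic activity off and no hormone clearance: venous equals
    portal for every species."""
    prof = ZonationProfile(
        params_mh=stu_system.params.with_vmax(
            {r: 0.0 for r in ("GLUT2", "LACT")}),
        alpha={}, n_cells=20)
    tf = TransferFunctions(clear_ins=0.0, clear_gcg=0.0)
    inert = assemble_stu(profile=prof, transfer=tf)
    r = steady_state_stu(inert, 9.0)
    assert r.venous_glucose == pytest.approx(9.0, abs=1e-6)
    assert r.delta_glu_pv == pytest.approx(0.0, abs=1e-6)
    assert r.insulin_extraction == pytest.approx(0.0, abs=1e-8)
    assert r.glucagon_extraction == pytest.approx(0.0, abs=1e-8)


def test_glucose_mass_balance(stu_sweep):
    for r in stu_sweep.values():
        assert r.mass_balance_error < 1e-6


def test_porto_venous_difference_monotone_with_single_crossing(stu_sweep):
    glcs = sorted(stu_sweep)
    dpv = np.array([stu_sweep[g].delta_glu_pv for g in glcs])
    assert np.all(np.diff(dpv) > 0)
    assert dpv[0] < 0 < dpv[-1]
    assert np.sum(np.diff(np.sign(dpv)) != 0) == 1


def test_set_point_in_expected_window(stu_sweep):
    """The whole-unit zero crossing sits above both cellular set-points:
    net production still occurs at 7 mM, net uptake at 8 mM."""
    assert stu_sweep[7].delta_glu_pv < 0 < stu_sweep[8].delta_glu_pv


def test_net_producer_below_8mM(stu_sweep):
    for g in (3, 4, 5, 6, 7):
        assert stu_sweep[g].delta_glu_pv < 0


def test_intra_sinusoidal_glucose_cycle_exists(stu_sweep):
    """For some portal glucose in 6-8 mM, upstream cells produce while
    downstream cells consume."""
    found = False
    for g in (6, 7, 8):
        gef = stu_sweep[g].per_cell_gef
        if gef[0] < 0 < gef[-1]:
            found = True
    assert found


def test_upstream_production_at_the_cycle_point(stu_sweep):
    gef = stu_sweep[6].per_cell_gef
    assert gef[0] < 0          # periportal cell produces
    assert gef[-1] > 0         # pericentral cell consumes


def test_hormone_gradient_along_sinusoid(stu_sweep):
    """Clearance only removes: central-vein hormones never exceed portal."""
    from hepstu.stu import DISSE_SPECIES, VASC_SPECIES
    for r in stu_sweep.values():
        assert 0.0 <= r.insulin_extraction <= 1.0
        assert 0.0 <= r.glucagon_extraction <= 1.0
        system = r.system
        _, sin, _, bnd, _ = system.split(r.state)
        for sp in ("ins", "gcg"):
            j = VASC_SPECIES.index(sp)
            assert bnd[3, j] <= bnd[2, j] + 1e-9   # central <= portal
            assert np.all(np.diff(sin[:, j]) < 1e-9)


def test_extraction_increases_when_flow_halves(stu_system):
    slow = replace(stu_system.systemic,
                   p_portal=stu_system.systemic.p_central
                   + 0.5 * stu_system.systemic.delta_p)
    sys_slow = assemble_stu(systemic=slow)
    fast = steady_state_stu(stu_system, 7.0)
    halved = steady_state_stu(sys_slow, 7.0)
    assert halved.insulin_extraction > fast.insulin_extraction
    assert halved.glucagon_extraction > fast.glucagon_extraction


def test_gamma_relaxes_to_transfer_target(stu_sweep):
    """At steady state the dynamic phosphorylation states equal the
    hormone-phosphorylation transfer target of the local Disse hormones."""
    from hepstu.hormones import hpt
    from hepstu.species import N_SPECIES
    from hepstu.stu import DISSE_SPECIES
    r = stu_sweep[7]
    cells, _, dis, _, _ = r.system.split(r.state)
    gam = cells[:, N_SPECIES]
    ins = dis[:, DISSE_SPECIES.index("ins")]
    gcg = dis[:, DISSE_SPECIES.index("gcg")]
    target = np.array([hpt(i, g, r.system.transfer)["GS"]
                       for i, g in zip(ins, gcg)])
    np.testing.assert_allclose(gam, target, rtol=1e-5)


def test_variable_cell_numbers_integrate_over_48h():
    from scipy.integrate import solve_ivp
    for n in (15, 25):
        geom = STUGeometry(length=15.0 * n, n_cells=n)
        system = assemble_stu(geom, ZonationProfile.default(n_cells=n))
        c_in = system.inflow_vector(7.0)
        sol = solve_ivp(lambda t, y: system.rhs(y, c_in),
                        (0.0, 48.0 * 60.0), system.initial_state(7.0),
                        method="BDF", rtol=1e-8, atol=1e-10,
                        jac_sparsity=system.jac_sparsity())
        assert sol.success


@pytest.fixture(scope="module")
def perfused():
    return assemble_stu(systemic=perfused_systemic())


class TestIndicatorDilution:
    def test_unknown_tracer_rejected(self, perfused):
        with pytest.raises(ValueError, match="tracer"):
            indicator_dilution(perfused, "inulin")

    def test_plug_flow_delay_equals_transit_time(self, perfused):
        """Sharp bolus, zero diffusivity: the red-cell front arrives after
        the convective transit time (plus the small boundary-node delay)."""
        t, c = indicator_dilution(
            perfused, "rbc",
            input_function=lambda tt: np.where(np.asarray(tt) < 1.0, 1.0, 0.0),
            t_max=60.0, dt=0.05)
        transit = rbc_transit_time(perfused.geometry, perfused.systemic)
        t_peak = t[np.argmax(c)]
        v_boundary = 2 * perfused.v_disp + perfused.v_port + perfused.v_cent
        extra = v_boundary / (perfused.qv[0] / 60.0)
        assert t_peak == pytest.approx(1.0 + transit + extra, abs=1.5)

    def test_tracer_mass_conservation(self, perfused):
        """Injected mass = outflow mass + lymph export, to 1e-4 relative."""
        q_in = perfused.qv[0] / 60.0
        for tracer in ("rbc", "albumin"):
            t, c = indicator_dilution(perfused, tracer, t_max=600.0)
            q_out = perfused.qv[perfused.n_cells] / 60.0
            out_mass = np.trapezoid(c, t) * q_out
            if tracer != "rbc":
                out_mass *= 1.0 + perfused.ql / 60.0 / q_out  # lymph share
            in_mass = np.trapezoid(gamma_variate_input(t), t) * q_in
            assert out_mass == pytest.approx(in_mass, rel=1e-4)

    def test_curves_ordered_by_accessible_volume(self, perfused):
        peaks = {}
        for tracer in ("rbc", "albumin", "water"):
            t, c = indicator_dilution(perfused, tracer)
            peaks[tracer] = (t[np.argmax(c)], c.max())
        assert peaks["rbc"][0] <= peaks["albumin"][0] < peaks["water"][0]
        assert peaks["rbc"][1] >= peaks["albumin"][1] > peaks["water"][1]

    def test_water_half_life_in_measured_window(self, perfused):
        t, c = indicator_dilution(perfused, "water")
        assert 40.0 < half_life_decay(t, c) < 70.0
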