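"""Single-hepatocyte model: stoichiometric consistency, steady states,
glucose exchange flux, set-points and glycogen dynamics."""

import numpy as np
import pytest

from hepstu.hormones import gamma_from_glucose
from hepstu.metabolic import (ConfigurationError, EnzymeParameterSet,
                              ExternalMilieu, MetabolicState, cell_rhs,
                              glucose_exchange_flux, glycogen_timecourse,
                              reaction_rates, set_point, steady_state_cell)
from hepstu.species import (ER_SCALE, MITO_SCALE, REACTION_INDEX, REACTIONS,
                            SPECIES, stoichiometric_matrix)

# Independently hand-entered stoichiometry (species -> {reaction: coeff}),
# written down from the reaction scheme without consulting the builder.
HAND_STOICH = {
    "glc":    {"GLUT2": 1, "GLCT": 1, "GK": -1},
    "g6p":    {"GK": 1, "GPI": -1, "GLC6PT": -1, "PGM1": -1},
    "f6p":    {"GPI": 1, "PFK1": -1, "FBP1": 1, "FBP2": 1, "PFK2": -1},
    "f16bp":  {"PFK1": 1, "FBP1": -1, "ALD": -1},
    "grap":   {"ALD": 1, "TPI": 1, "GAPDH": -1},
    "dhap":   {"ALD": 1, "TPI": -1},
    "bpg13":  {"GAPDH": 1, "PGK": -1},
    "pg3":    {"PGK": 1, "PGM": -1},
    "pg2":    {"PGM": 1, "EN": -1},
    "pep":    {"EN": 1, "PK": -1, "PEPCK": 1, "PEPT": 1},
    "pyr":    {"PK": 1, "LDH": -1, "PYRT": -1},
    "lac":    {"LDH": 1, "LACT": 1},
    "mal":    {"MALT": 1, "MDH": -1},
    "oa":     {"MDH": 1, "PEPCK": -1},
    "g1p":    {"PGM1": 1, "GP": 1, "UGT": -1},
    "udpg":   {"UGT": 1, "GS": -1},
    "f26bp":  {"PFK2": 1, "FBP2": -1},
    "glyc":   {"GS": 1, "GP": -1},
    "glc_er": {"G6PP": ER_SCALE, "GLCT": -ER_SCALE},
    "g6p_er": {"GLC6PT": ER_SCALE, "G6PP": -ER_SCALE},
    "pyr_m":  {"PYRT": MITO_SCALE, "PC": -MITO_SCALE},
    "pep_m":  {"PEPT": -MITO_SCALE},
    "mal_m":  {"MDHM": MITO_SCALE, "MALT": -MITO_SCALE},
    "oa_m":   {"PC": MITO_SCALE, "MDHM": -MITO_SCALE},
}


def test_stoichiometric_matrix_matches_hand_entry():
    S = stoichiometric_matrix()
    expected = np.zeros_like(S)
    for sp, terms in HAND_STOICH.items():
        for rxn, coeff in terms.items():
            expected[SPECIES.index(sp), REACTION_INDEX[rxn]] = coeff
    np.testing.assert_allclose(S, expected, rtol=0, atol=1e-12)


def test_rhs_equals_stoichiometry_times_rates(params):
    state = MetabolicState.physiological(7.0)
    milieu = ExternalMilieu(glucose=7.0, gamma=gamma_from_glucose(7.0))
    v = reaction_rates(state, params, milieu)
    np.testing.assert_allclose(cell_rhs(state, params, milieu),
                               stoichiometric_matrix() @ v, rtol=1e-12)


def test_hexose_phosphate_moiety_changes_only_via_boundary(params):
    """The glucosyl/phospho-sugar carbon entering at GK/GP/transport can
    only leave through boundary reactions: the corresponding left-null
    vector of the internal stoichiometry annihilates S."""
    S = stoichiometric_matrix(volume_scaled=False)
    # carbon content (C6 units) of each species
    carbon = {s: 1.0 for s in SPECIES}
    for s in ("grap", "dhap", "bpg13", "pg3", "pg2", "pep", "pyr", "lac",
              "mal", "oa", "pyr_m", "pep_m", "mal_m", "oa_m"):
        carbon[s] = 0.5
    w = np.array([carbon[s] for s in SPECIES])
    flux_balance = w @ S
    boundary = {"GLUT2", "LACT"}
    for rxn, val in zip(REACTIONS, flux_balance):
        if rxn in boundary:
            assert abs(val) > 0.4
        else:
            assert val == pytest.approx(0.0, abs=1e-12)


def test_negative_concentration_rejected():
    vec = MetabolicState.physiological(6.0).values.copy()
    vec[3] = -0.1
    with pytest.raises(ValueError, match="negative concentration"):
        MetabolicState(vec)


def test_missing_kinetic_constant_names_enzyme(params):
    broken = EnzymeParameterSet(
        {k: v for k, v in params.constants.items() if k != "GK_Kglc"},
        params.vmax)
    state = MetabolicState.physiological(6.0)
    with pytest.raises(ConfigurationError, match="GK"):
        reaction_rates(state, broken, ExternalMilieu(glucose=6.0))


def test_glucose_below_validity_floor_rejected():
    with pytest.raises(ValueError, match="validity floor"):
        ExternalMilieu(glucose=0.05)


class TestSteadyState:
    def test_residual_below_tolerance(self, params):
        milieu = ExternalMilieu(glucose=6.0, gamma=gamma_from_glucose(6.0))
        res = steady_state_cell(params, milieu)
        assert res.converged
        assert res.residual < 1e-9
        rhs = cell_rhs(res.state, params, milieu)
        assert np.max(np.abs(rhs)) < 1e-9

    def test_restarting_at_steady_state_returns_it(self, params):
        milieu = ExternalMilieu(glucose=8.0, gamma=gamma_from_glucose(8.0))
        first = steady_state_cell(params, milieu)
        again = steady_state_cell(params, milieu, initial=first.state,
                                  integrate_first=0.0)
        np.testing.assert_allclose(again.state.values, first.state.values,
                                   rtol=1e-6)

    def test_multistart_agrees(self, params):
        """Two distinct physiological starting points give the same steady
        state (no bistability at the default parameters)."""
        milieu = ExternalMilieu(glucose=5.0, gamma=gamma_from_glucose(5.0))
        a = steady_state_cell(params, milieu,
                              initial=MetabolicState.physiological(3.0))
        b = steady_state_cell(
            params, milieu,
            initial=MetabolicState.physiological(12.0).replace(glyc=400.0))
        np.testing.assert_allclose(a.state.values, b.state.values, rtol=1e-5)

    def test_two_solution_routes_agree(self, params):
        """Long time integration and the Newton polish land on the same
        state."""
        from scipy.integrate import solve_ivp
        from hepstu.metabolic import _rhs_vec
        milieu = ExternalMilieu(glucose=9.0, gamma=gamma_from_glucose(9.0))
        newton = steady_state_cell(params, milieu)
        gam = milieu.gamma_vector()
        sol = solve_ivp(
            lambda t, y: _rhs_vec(np.maximum(y, 1e-12), params, gam,
                                  milieu.glucose, milieu.lactate),
            (0.0, 3e5), MetabolicState.physiological(9.0).values,
            method="BDF", rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(sol.y[:, -1], newton.state.values,
                                   rtol=1e-4, atol=1e-8)


class TestGlucoseExchange:
    def test_gef_monotone_nondecreasing(self, params):
        glcs = np.arange(3.0, 15.1, 1.0)
        gef = glucose_exchange_flux(params, glcs)
        assert np.all(np.diff(gef) > 0)

    def test_glut2_knockout_forces_zero_exchange(self, params):
        knockout = params.with_vmax({"GLUT2": 0.0})
        gef = glucose_exchange_flux(knockout, [4.0, 8.0, 12.0])
        np.testing.assert_allclose(gef, 0.0, atol=1e-12)

    def test_no_zonation_means_identical_set_points(self, params):
        from hepstu.zonation import ZonationProfile, endpoint_params
        prof = ZonationProfile(params_mh=params, alpha={}, n_cells=20)
        pph, pch = endpoint_params(prof)
        sp_pph, sp_pch = set_point(pph), set_point(pch)
        assert sp_pph == pytest.approx(sp_pch, abs=0.02)

    def test_set_point_requires_sign_change(self, params):
        # pure glycolysis (no glucose export): GEF positive everywhere
        no_gng = params.with_vmax({"G6PP": 0.0, "GP": 0.0})
        with pytest.raises(ValueError, match="set-point"):
            set_point(no_gng, glc_lo=8.0, glc_hi=12.0)


@pytest.fixture(scope="module")
def refeed(params):
    return glycogen_timecourse(params, [(24.0, 10.0), (24.0, 4.0)])


class TestGlycogenTimecourse:
    def test_rises_then_falls(self, refeed):
        t, glyc, _ = refeed
        i_switch = np.searchsorted(t, 24.0)
        assert glyc[i_switch - 1] > glyc[0] + 50.0
        assert glyc[-1] < glyc[: i_switch].max() - 50.0

    def test_constant_fast_stays_near_fasted_level(self, params):
        t, glyc, _ = glycogen_timecourse(params, [(24.0, 4.0)])
        assert np.max(np.abs(glyc - glyc[0])) < 0.2 * max(glyc[0], 30.0)

    def test_output_refinement_leaves_trajectory_unchanged(self, params):
        t1, g1, _ = glycogen_timecourse(params, [(6.0, 10.0)], output_dt=10.0)
        t2, g2, _ = glycogen_timecourse(params, [(6.0, 10.0)], output_dt=5.0)
        common = np.intersect1d(np.round(t1, 6), np.round(t2, 6))
        a = g1[np.isin(np.round(t1, 6), common)]
        b = g2[np.isin(np.round(t2, 6), common)]
        np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-4)

    def test_mean_hepatocyte_has_largest_amplitude(self, params, pph_pch):
        pph, pch = pph_pch
        amp = {}
        for name, ps in [("MH", params), ("PPH", pph), ("PCH", pch)]:
            _, glyc, _ = glycogen_timecourse(ps, [(24.0, 10.0), (24.0, 4.0)])
            amp[name] = glyc.max() - glyc.min()
        assert amp["MH"] > amp["PPH"]
        assert amp["MH"] > amp["PCH"]


def test_mean_hepatocyte_concentrations_in_physiological_ranges(params):
    """The MH steady state at euglycaemia falls inside the shipped
    physiological concentration ranges (compiled from hepatocyte
    literature; a synthetic stand-in for calibration-figure data)."""
    import importlib.resources
    import pandas as pd
    with importlib.resources.files("hepstu.params").joinpath(
            "metabolite_ranges.tsv").open() as fh:
        ranges = pd.read_csv(fh, sep="\t")
    milieu = ExternalMilieu(glucose=6.0, gamma=gamma_from_glucose(6.0))
    state = steady_state_cell(params, milieu).state
    for _, row in ranges.iterrows():
        val = state[row["species"]]
        assert row["low_mM"] <= val <= row["high_mM"], (
            f"{row['species']}={val:.4f} outside "
            f"[{row['low_mM']}, {row['high_mM']}]")
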