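"""Monte-Carlo sampling, sensitivities, tissue-scale refeeding and
perfusion-map functiograms."""

import numpy as np
import pytest

from hepstu.experiments import (ConversionConstants, ParameterDistributions,
                                functiogram, monte_carlo_dilution,
                                monte_carlo_porto_venous, sample_stu,
                                sensitivity, starvation_refeeding_stu,
                                synthetic_perfusion_map)
from hepstu.microcirculation import perfused_systemic
from hepstu.stu import assemble_stu


class TestSampling:
    def test_seed_reproducibility(self):
        d = ParameterDistributions()
        a = sample_stu(d, [7, 3])
        b = sample_stu(d, [7, 3])
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2].alpha == b[2].alpha

    def test_zero_variance_returns_default_unit(self):
        d = ParameterDistributions(
            vessel_diameter=(8.0, 0.0), disse_thickness=(1.5, 0.0),
            hepatocyte_thickness=(30.0, 0.0), fenestration=(0.07, 0.0),
            n_cells=(20, 0.0), delta_p_rel=(1.0, 0.0), alpha_uniform=False)
        geom, sysp, profile = sample_stu(d, 0)
        from hepstu.microcirculation import STUGeometry, SystemicParams
        assert geom == STUGeometry()
        assert sysp == SystemicParams()

    def test_sample_means_converge_to_distribution_means(self):
        d = ParameterDistributions()
        radii = [sample_stu(d, [0, i])[0].radius for i in range(600)]
        assert np.mean(radii) == pytest.approx(d.vessel_diameter[0] / 2,
                                               rel=0.01)

    def test_samples_physical(self):
        d = ParameterDistributions()
        for i in range(50):
            geom, sysp, profile = sample_stu(d, [99, i])
            assert geom.radius > 0 and geom.disse > 0
            assert 15 <= geom.n_cells <= 25
            assert sysp.delta_p > 0
            assert all(a > 0 for a in profile.alpha.values())


class TestMonteCarlo:
    def test_single_sample_has_zero_spread(self):
        mc = monte_carlo_dilution(n=1, seed=3)
        assert np.all(mc["sd_curve"] == 0.0)
        assert mc["failures"] == 0

    def test_water_half_life_band(self):
        mc = monte_carlo_dilution(n=30, seed=5)
        h = mc["half_lives"]
        assert np.all(np.isfinite(h))
        assert h.max() <= 70.0
        assert h.min() >= 30.0
        # the sampled band overlaps the measured 50-70 s window
        assert (h >= 50.0).any()

    def test_porto_venous_band_contains_default_curve(self, stu_sweep):
        grid = [4.0, 10.0]
        mc = monte_carlo_porto_venous(grid, n=12, seed=11)
        assert mc["failures"] == 0
        for k, g in enumerate(grid):
            default = stu_sweep[int(g)].delta_glu_pv
            assert mc["mean"][k] - 2.5 * mc["sd"][k] <= default \
                <= mc["mean"][k] + 2.5 * mc["sd"][k]

    def test_porto_venous_variability_scale(self):
        """Tissue and enzyme variability produces a relative spread of the
        porto-venous difference on the order of tens of percent."""
        mc = monte_carlo_porto_venous([10.0], n=16, seed=2)
        cv = mc["sd"][0] / abs(mc["mean"][0])
        assert 0.05 < cv < 0.6


def test_refeeding_amplitude_falls_from_periportal_to_pericentral(stu_system):
    t, glyc = starvation_refeeding_stu(stu_system)
    amp = glyc.max(axis=0) - glyc.min(axis=0)
    assert amp[0] > amp[-1]                     # PPH > PCH
    coarse = amp[::5]
    assert np.all(np.diff(coarse) < 0)          # decreasing along the axis
    assert np.all(np.diff(amp[:15]) < 0)


def test_refeeding_constant_glucose_stays_flat(stu_system):
    t, glyc = starvation_refeeding_stu(stu_system, schedule=((12.0, 4.0),))
    drift = np.abs(glyc[-1] - glyc[0])
    assert np.all(drift < 0.05 * np.maximum(glyc[0], 20.0))


@pytest.fixture(scope="module")
def perfused():
    return assemble_stu(systemic=perfused_systemic())


class TestSensitivity:
    def test_disconnected_parameter_has_zero_sensitivity(self, perfused):
        s = sensitivity(perfused, "alpha:GPI", 10.0)
        assert abs(s.value) < 0.02

    def test_pyruvate_carboxylase_controls_only_the_fasted_state(self,
                                                                 perfused):
        s4 = sensitivity(perfused, "vmax:PC", 4.0)
        s10 = sensitivity(perfused, "vmax:PC", 10.0)
        assert abs(s4.value) > 2.0 * abs(s10.value)
        assert abs(s4.value) > 0.1

    def test_structural_parameters_dominate(self, perfused):
        s_radius = sensitivity(perfused, "geometry:radius", 10.0)
        s_cell = sensitivity(perfused, "geometry:hepatocyte", 10.0)
        s_fen = sensitivity(perfused, "geometry:fenestration", 10.0)
        assert abs(s_radius.value) > 1.0
        assert abs(s_cell.value) > 1.0
        assert abs(s_fen.value) < 0.05

    def test_glycolytic_capacity_never_reduces_uptake_when_fed(self,
                                                               perfused):
        for rxn in ("GK", "PFK1", "PK"):
            s = sensitivity(perfused, f"vmax:{rxn}", 10.0)
            assert s.value > -1e-6


class TestPerfusionMap:
    def test_zero_sd_gives_uniform_map(self):
        pmap = synthetic_perfusion_map(sd=0.0, shape=(3, 3, 2))
        assert np.all(pmap.flow == 44.3)

    def test_seed_reproducibility_and_moments(self):
        a = synthetic_perfusion_map(seed=4, shape=(12, 12, 6))
        b = synthetic_perfusion_map(seed=4, shape=(12, 12, 6))
        np.testing.assert_array_equal(a.flow, b.flow)
        assert a.mean == pytest.approx(44.3, abs=2.0 * 6.1 / np.sqrt(a.flow.size))
        assert a.sd == pytest.approx(6.1, rel=0.15)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            synthetic_perfusion_map(sd=-1.0)


class TestFunctiogram:
    def test_variance_damping(self, stu_system):
        """The relative spread of the flux map is below the relative
        spread of the flow map (reciprocal flow-extraction relation)."""
        pmap = synthetic_perfusion_map(seed=8, shape=(4, 4, 2))
        flux, summary = functiogram(pmap, 10.0, system=stu_system,
                                    n_flow_bins=8)
        assert summary["cv_flux"] < summary["cv_flow"]

    def test_mass_consistency(self, stu_system):
        """The map-mean flux equals the voxel-average of per-voxel fluxes
        (each voxel represents the same tissue mass)."""
        pmap = synthetic_perfusion_map(seed=9, shape=(3, 3, 1))
        flux, summary = functiogram(pmap, 10.0, system=stu_system,
                                    n_flow_bins=6)
        assert summary["mean_flux"] == pytest.approx(
            np.nanmean(flux), rel=1e-9)

    def test_nonpositive_voxels_skipped_with_warning(self, stu_system):
        pmap = synthetic_perfusion_map(seed=1, shape=(2, 2, 1))
        pmap.flow[0, 0, 0] = -5.0
        with pytest.warns(UserWarning, match="skipped"):
            flux, _ = functiogram(pmap, 10.0, system=stu_system)
        assert np.isnan(flux[0, 0, 0])

    def test_per_sinusoid_flow_conversion(self):
        cc = ConversionConstants()
        assert cc.per_sinusoid_flow(44.3) == pytest.approx(492.2, rel=1e-3)
        assert cc.flux_umol_g_h(44.3, 2.0) == pytest.approx(53.16, rel=1e-9)
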