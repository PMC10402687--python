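"""SPR prediction models: I-value, Bethe, mass density, HLUT, SPR maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dectspr import (DEFAULT_SPECTRA, HLUT, BeamSpec, DeedzParams, IValueModel,
                     SPRMap, bethe_spr, deedz_mass_density, hlut_apply,
                     hlut_calibrate, i_value, override_spr, relative_residual,
                     spr_map)
from dectspr.synthetic import SpectralImageSet, generate_calibration_set


class TestIValue:
    def test_single_segment_midpoint(self):
        model = IValueModel(knots=((5.0, 60.0), (10.0, 110.0)))
        assert i_value(7.5, model) == pytest.approx(85.0)

    def test_knot_is_exact(self):
        model = IValueModel()
        for ean, i_ev in model.knots:
            assert i_value(ean, model) == i_ev

    def test_default_model_interpolates_between_shipped_knots(self):
        # hand interpolation of the shipped defaults:
        # 63.2 + (6.5-6.2)/(7.45-6.2)*(78.73-63.2) = 66.9272
        assert i_value(6.5) == pytest.approx(66.9272, abs=1e-10)

    def test_clamped_extrapolation(self):
        model = IValueModel()
        assert i_value(2.0, model) == model.knots[0][1]
        assert i_value(20.0, model) == model.knots[-1][1]

    def test_invalid_knots_rejected(self):
        with pytest.raises(ValueError):
            IValueModel(knots=((7.0, 70.0), (6.0, 60.0)))
        with pytest.raises(ValueError):
            IValueModel(knots=((6.0, -5.0), (7.0, 70.0)))


class TestBetheSPR:
    def test_water_identity(self):
        assert bethe_spr(1.0, 7.45) == pytest.approx(1.0)

    def test_linear_in_red_at_fixed_i(self):
        assert bethe_spr(2.0, 7.45) == pytest.approx(2.0)

    def test_stopping_number_ratio_against_scripted_oracle(self):
        # independent evaluation of both logarithms at 100 MeV/u, I = 70 eV
        ivm = IValueModel(knots=((5.0, 70.0), (10.0, 70.0)))
        assert bethe_spr(1.0, 7.0, ivm=ivm) == pytest.approx(
            1.0150792506668933, abs=1e-12)

    def test_log_argument_violation_rejected(self):
        ivm = IValueModel(knots=((5.0, 1e5), (10.0, 2e5)), i_water=78.73)
        beam = BeamSpec(kinetic_energy_per_nucleon=0.05)
        with pytest.raises(ValueError, match="argument"):
            bethe_spr(1.0, 7.0, beam=beam, ivm=ivm)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(red=st.floats(0.3, 2.0), delta=st.floats(0.01, 1.0))
    def test_strictly_increasing_in_red(self, red, delta):
        assert bethe_spr(red + delta, 8.0) > bethe_spr(red, 8.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ean=st.floats(6.3, 13.0), delta=st.floats(0.05, 0.4))
    def test_strictly_decreasing_in_i_value(self, ean, delta):
        # the default knot set is strictly increasing in I over this range
        assert bethe_spr(1.0, ean + delta) < bethe_spr(1.0, ean)

    def test_energy_insensitivity_80_to_200_mev(self):
        ean = np.linspace(6.0, 14.0, 33)
        for red in (0.3, 2.0):
            s80 = bethe_spr(red, ean, BeamSpec(80.0))
            s200 = bethe_spr(red, ean, BeamSpec(200.0))
            assert np.all(np.abs(s80 - s200) / s80 < 0.005)


class TestDeedzMassDensity:
    def test_reduces_to_red_with_zero_coefficients(self):
        p = DeedzParams(e=(0.0, 0.0, 0.0))
        for red, ean in ((0.3, 6.0), (1.0, 7.45), (1.7, 13.6)):
            assert deedz_mass_density(red, ean, p) == red

    def test_water_ean_gives_constant_term_only(self):
        p = DeedzParams(e=(0.01, 0.1, 0.01))
        assert deedz_mass_density(1.2, 7.45, p) == pytest.approx(1.2 * 1.01)

    def test_hand_expanded_polynomial(self):
        # x = (6.38/7.45)^3.3 - 1; rho = 1.154*(1 + 0.01 + 0.1 x + 0.01 x^2)
        p = DeedzParams(e=(0.01, 0.1, 0.01), m=3.3, z_eff_water=7.45)
        assert deedz_mass_density(1.154, 6.38, p) == pytest.approx(
            1.1211738101240858, abs=1e-12)


class TestHLUT:
    def test_node_is_exact_and_midpoint_is_mean(self):
        hlut = HLUT(nodes=[[-1000.0, 0.2], [0.0, 1.0], [1000.0, 1.6]])
        assert hlut_apply(0.0, hlut) == 1.0
        assert hlut_apply(500.0, hlut) == pytest.approx((1.0 + 1.6) / 2)

    def test_output_nondecreasing_and_clamped(self):
        hlut = HLUT(nodes=[[-1000.0, 0.2], [0.0, 1.0], [1500.0, 2.9]],
                    max_spr=2.347)
        ctn = np.linspace(-1200.0, 3071.0, 500)
        out = hlut.apply(ctn)
        assert np.all(np.diff(out) >= 0)
        assert out.max() <= 2.347
        assert hlut_apply(3071.0, hlut) == 2.347

    def test_non_monotone_nodes_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            HLUT(nodes=[[0.0, 1.0], [100.0, 0.9]])
        with pytest.raises(ValueError, match="increasing"):
            HLUT(nodes=[[0.0, 1.0], [0.0, 1.1]])

    def test_calibration_recovers_spectrum_parameters(self, calibration):
        mats, ctn = calibration
        hlut = hlut_calibrate(ctn, mats)
        truth = DEFAULT_SPECTRA["120kVp"]
        assert hlut.spectrum.k1 == pytest.approx(truth.k1, rel=1e-6)
        assert hlut.spectrum.k2 == pytest.approx(truth.k2, rel=1e-6)

    def test_water_node_forced(self, calibration):
        mats, ctn = calibration
        hlut = hlut_calibrate(ctn, mats)
        assert hlut_apply(0.0, hlut) == pytest.approx(1.0)

    @pytest.mark.parametrize("profile,clamp",
                             [("SE-140-SACT", 2.602), ("SE-120-DLCT", 2.347)])
    def test_saturated_ctn_maps_to_profile_clamp(self, calibration, profile,
                                                 clamp):
        mats, ctn = calibration
        hlut = hlut_calibrate(ctn, mats, max_spr=clamp, profile=profile)
        assert hlut_apply(3071.0, hlut) == clamp

    def test_too_few_materials_rejected(self, calibration):
        mats, ctn = calibration
        with pytest.raises(ValueError, match=">=3"):
            hlut_calibrate(ctn, mats[:2])


def _uniform_imageset(red, ean, ctn, shape=(4, 4, 4)):
    return SpectralImageSet(
        ctn_volumes={"120kVp": np.full(shape, float(ctn))},
        red_volume=np.full(shape, float(red)),
        ean_volume=np.full(shape, float(ean)),
        technique="DLCT",
    )


class TestSprMap:
    def test_water_image_gives_unit_spr_under_both_methods(self, calibration):
        mats, ctn = calibration
        hlut = hlut_calibrate(ctn, mats)
        imageset = _uniform_imageset(1.0, 7.45, 0.0)
        de = spr_map(imageset, "de-rhoz")
        se = spr_map(imageset, "se-hlut", hlut=hlut, kvp="120kVp")
        assert np.allclose(de.volume, 1.0)
        assert np.allclose(se.volume, 1.0)

    def test_pmma_de_rhoz_residual_matches_bench_cell(self):
        # DLCT PMMA maps (RED 1.152, EAN 6.50) vs measured SPR 1.169:
        # printed benchmark residual is 0.61%
        imageset = _uniform_imageset(1.152, 6.50, 125.0)
        pred = spr_map(imageset, "de-rhoz")
        residual = relative_residual(float(pred.volume[0, 0, 0]), 1.169)
        assert residual == pytest.approx(0.61, abs=0.5)

    def test_missing_maps_rejected(self):
        imageset = _uniform_imageset(1.0, 7.45, 0.0)
        imageset.red_volume = None
        with pytest.raises(ValueError, match="RED"):
            spr_map(imageset, "de-rhoz")

    def test_method_provenance_recorded(self, calibration):
        mats, ctn = calibration
        hlut = hlut_calibrate(ctn, mats, profile="SE-120-DLCT")
        imageset = _uniform_imageset(1.0, 7.45, 0.0)
        assert spr_map(imageset, "de-rhoz").method == "DE-RhoZ"
        assert "120kVp" in spr_map(imageset, "se-hlut", hlut=hlut,
                                   kvp="120kVp").method


class TestOverrideSpr:
    def _map(self):
        return SPRMap(volume=np.ones((5, 5, 5)), spacing=(1, 1, 1))

    def test_masked_voxels_take_exact_value(self):
        m = self._map()
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, :] = True
        out = override_spr(m, mask, 2.1, "tooth")
        assert np.all(out.volume[mask] == 2.1)
        assert np.all(out.volume[~mask] == 1.0)
        assert out.overrides == [("tooth", 2.1)]

    def test_disjoint_overrides_commute(self):
        m = self._map()
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        ab = override_spr(override_spr(m, a, 1.5), b, 2.5)
        ba = override_spr(override_spr(m, b, 2.5), a, 1.5)
        assert np.array_equal(ab.volume, ba.volume)

    def test_idempotent_for_same_mask_value(self):
        m = self._map()
        mask = np.zeros((5, 5, 5), bool)
        mask[1] = True
        once = override_spr(m, mask, 1.8)
        twice = override_spr(once, mask, 1.8)
        assert np.array_equal(once.volume, twice.volume)

    def test_empty_mask_warns_and_noops(self):
        m = self._map()
        with pytest.warns(UserWarning, match="empty"):
            out = override_spr(m, np.zeros((5, 5, 5), bool), 2.0)
        assert out is m
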