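"""Generators: determinism, ground-truth fidelity, parameter validation."""

import numpy as np
import pytest

from osteomech import phantoms
from osteomech.errors import ParameterError
from osteomech.nanoindent import hertz_force


class TestFemurPhantom:
    def test_deterministic_for_fixed_seed(self):
        p = phantoms.wt_params(seed=7, voxel_spacing_um=25.0)
        v1, _ = phantoms.make_femur_phantom(p)
        v2, _ = phantoms.make_femur_phantom(p)
        assert np.array_equal(v1.labels, v2.labels)

    def test_zero_bvtv_gives_empty_lattice(self):
        p = phantoms.wt_params(seed=0, voxel_spacing_um=25.0)
        p.trabecular_target_bvtv = 0.0
        p.plate_fraction = 0.0
        vol, truth = phantoms.make_femur_phantom(p)
        assert (vol.labels == 2).sum() == 0
        assert truth.true_bvtv == 0.0

    def test_voi_bvtv_tracks_target(self, wt_femur):
        from osteomech.morphometry import VOISpec, select_voi

        vol, truth = wt_femur
        sub = select_voi(vol, VOISpec())
        trab = sub.labels == 2
        region = trab | (sub.labels == 3)
        bvtv = trab.sum() / region.sum()
        assert abs(bvtv - 0.12) <= 0.01

    def test_default_lattice_bvtv_in_spec_band(self):
        # rod-only lattice, target 0.12, seed 1
        p = phantoms.PhantomParams(
            voxel_spacing_um=15.0, trabecular_target_bvtv=0.12, seed=1
        )
        vol, _ = phantoms.make_femur_phantom(p)
        from osteomech.morphometry import VOISpec, select_voi

        sub = select_voi(vol, VOISpec())
        trab = sub.labels == 2
        region = trab | (sub.labels == 3)
        assert 0.11 <= trab.sum() / region.sum() <= 0.13

    def test_cortical_ring_closed_in_diaphysis(self, wt_femur):
        from scipy import ndimage

        vol, _ = wt_femur
        k = vol.shape[2] - 10  # diaphyseal slice
        ring = vol.labels[:, :, k] == 1
        outside = np.zeros_like(ring)
        outside[0, 0] = True
        # flood from a corner must not reach the canal if the ring is closed
        free = ~ring
        lab, _ = ndimage.label(free)
        canal_label = lab[vol.shape[0] // 2, vol.shape[1] // 2]
        assert lab[0, 0] != canal_label

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ParameterError):
            phantoms.PhantomParams(strut_spacing_mm=0.05, strut_thickness_mm=0.06)

    def test_strut_thinner_than_two_voxels_rejected(self):
        with pytest.raises(ParameterError):
            phantoms.PhantomParams(voxel_spacing_um=40.0, strut_thickness_mm=0.06)


class TestPrismPhantom:
    @pytest.mark.parametrize(
        "shape,dims,expected_i",
        [
            ("circle", [0.5], np.pi * 0.5**4 / 4),
            ("annulus", [0.6, 0.4], np.pi * (0.6**4 - 0.4**4) / 4),
            ("square", [1.0], 1.0 / 12),
        ],
    )
    def test_closed_form_second_moment(self, shape, dims, expected_i):
        _, truth = phantoms.make_prism_phantom(shape, dims, 0.1, 20.0)
        assert truth.true_section_properties["imax_mm4"] == pytest.approx(expected_i)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ParameterError):
            phantoms.make_prism_phantom("hexagon", [1.0], 1.0, 20.0)

    def test_voxelization_converges_to_analytic_area(self):
        # digitization error oscillates slice to slice, so require only that
        # the finest grid beats the coarser ones and lands within 1%
        errs = []
        area_true = np.pi * 0.5**2
        for sp in (40.0, 20.0, 5.0):
            vol, _ = phantoms.make_prism_phantom("circle", [0.5], 0.1, sp)
            measured = (vol.labels > 0)[:, :, 0].sum() * (sp / 1000.0) ** 2
            errs.append(abs(measured - area_true) / area_true)
        assert errs[2] <= errs[0] and errs[2] <= errs[1]
        assert errs[2] < 0.01


class TestIndentationCurves:
    def test_hertz_forward_formula_unit_case(self):
        # E = 1, nu = 0, R = 1, delta = 1 -> F = 4/3
        assert hertz_force(1.0, 1.0, 0.0, 1.0) == pytest.approx(4.0 / 3.0)
        assert hertz_force(0.0, 1.0, 0.0, 1.0) == 0.0

    def test_noise_free_curve_satisfies_hertz_everywhere(self):
        c = phantoms.synth_indentation_curve(5.0, 0.3, 300.0, 50.0, 100)
        expected = hertz_force(c.depth_nm, 5.0, 0.3, 300.0)
        np.testing.assert_allclose(c.force_nN, expected, rtol=1e-12)
        assert np.all(np.diff(c.force_nN) > 0)  # strictly increasing for delta > 0

    def test_invalid_depth_rejected(self):
        with pytest.raises(ParameterError):
            phantoms.synth_indentation_curve(5.0, depth_max_nm=-1.0)

    def test_frequency_sweep_modulus_law(self):
        curves = phantoms.synth_frequency_sweep(10.0, 2.0, [1.0, 10.0, 100.0])
        moduli = [c.meta["true_modulus_gpa"] for c in curves]
        assert moduli[0] == pytest.approx(10.0)  # ln 1 = 0
        assert moduli[1] == pytest.approx(10.0 + 2.0 * np.log(10.0))

    def test_frequency_sweep_constant_when_slope_zero(self):
        curves = phantoms.synth_frequency_sweep(8.0, 0.0, [1.0, 10.0, 100.0])
        assert len({c.meta["true_modulus_gpa"] for c in curves}) == 1

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(ParameterError):
            phantoms.synth_frequency_sweep(1.0, -2.0, [1.0, 100.0])


class TestBendingCurves:
    def test_noise_free_elastic_slope_and_peak(self):
        c = phantoms.synth_bending_curve(
            stiffness_N_mm=120.0, yield_load_N=15.0, ultimate_load_N=25.0
        )
        d, f = c.displacement_mm, c.force_N
        w0, w1 = c.meta["truth"]["elastic_window"]
        slope = np.polyfit(d[w0:w1], f[w0:w1], 1)[0]
        assert slope == pytest.approx(120.0, rel=0.01)
        assert f.max() == pytest.approx(25.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            phantoms.synth_bending_curve(yield_load_N=30.0, ultimate_load_N=25.0)
        with pytest.raises(ParameterError):
            phantoms.synth_bending_curve(fracture_disp_mm=0.01)


class TestCalceinDataset:
    def test_mean_interlabel_distance_is_mar_times_interval(self):
        ds = phantoms.synth_calcein_dataset(1.0, 0.4, n_fields=4000, noise=0.1, seed=0)
        assert ds.interlabel_distances_um.mean() == pytest.approx(7.0, rel=0.02)

    def test_zero_mineralizing_surface(self):
        ds = phantoms.synth_calcein_dataset(1.0, 0.0, n_fields=10, seed=0)
        assert ds.dl_surface_mm == 0.0 and ds.sl_surface_mm == 0.0

    def test_msbs_recovered(self):
        from osteomech.histo import ms_bs

        ds = phantoms.synth_calcein_dataset(1.5, 0.4, n_fields=500, noise=0.05, seed=3)
        got = ms_bs(ds.dl_surface_mm, ds.sl_surface_mm, ds.total_bone_surface_mm)
        assert got == pytest.approx(0.4, rel=0.05)


class TestContrastOrdering:
    def test_wt_ko_pair_preserves_planned_orderings(self, wt_femur, ko_femur):
        (wv, wt_truth), (kv, ko_truth) = wt_femur, ko_femur
        assert ko_truth.true_bvtv < wt_truth.true_bvtv
        assert ko_truth.true_strut_thickness_mm > wt_truth.true_strut_thickness_mm
        assert (
            phantoms.KO_MODULI_GPA[1] < phantoms.WT_MODULI_GPA[1]
            and phantoms.KO_MODULI_GPA[2] < phantoms.WT_MODULI_GPA[2]
        )
        # diaphyseal outer radius reduced by design
        assert (kv.labels[:, :, -1] > 0).sum() < (wv.labels[:, :, -1] > 0).sum()
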