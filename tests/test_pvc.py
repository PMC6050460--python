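"""The three partial-volume corrections and the GTM solver."""

import json

import numpy as np
import pytest
from scipy import ndimage

from pvcsim.images import Image3D, make_mask
from pvcsim.psf import PSFModel, convolve_array, make_kernel
from pvcsim.pvc import (
    PVCResult,
    gtm_solve,
    insert_voi_into_parcellation,
    meltzer_correct,
    mmg_correct,
    no_correction,
    rbv_correct,
)
from conftest import grid_affine, make_slab_phantom, toy_parcellation

DELTA = PSFModel(fwhm_mm=(0.0, 0.0, 0.0))


def blur(img: Image3D, psf: PSFModel) -> Image3D:
    return img.with_data(convolve_array(img.data, make_kernel(psf, img.voxel_size_mm)))


@pytest.fixture(scope="module")
def default_phantom_module():
    from pvcsim.phantom import PhantomSpec, build_phantom

    spec = PhantomSpec()
    return (spec, *build_phantom(spec))


class TestMeltzer:
    def test_delta_psf_identity(self, default_phantom_module):
        _, truth, masks, _ = default_phantom_module
        result = meltzer_correct(truth, masks["brain"], DELTA)
        valid = result.validity.astype(bool)
        assert valid.sum() == masks["brain"].data.sum()
        np.testing.assert_allclose(
            result.corrected.data[valid], truth.data[valid], atol=1e-10
        )

    def test_uniform_brain_recovery(self, default_phantom_module):
        """Division by the smoothed mask restores a uniform activity A
        everywhere on the mask, including edge voxels."""
        _, truth, masks, _ = default_phantom_module
        A = 2.0
        uniform = truth.with_data(A * masks["brain"].data.astype(float))
        psf = PSFModel.isotropic(6.0)
        observed = blur(uniform, psf)
        result = meltzer_correct(observed, masks["brain"], psf)
        valid = result.validity.astype(bool)
        # edge voxels are attenuated before correction ...
        edge = masks["brain"].data.astype(bool) & (
            ndimage.binary_erosion(masks["brain"].data.astype(bool)) == 0
        )
        assert observed.data[edge].mean() < 0.95 * A
        # ... and restored after
        np.testing.assert_allclose(result.corrected.data[valid], A, rtol=1e-6)

    def test_corrected_never_below_observed(self, default_phantom_module):
        _, truth, masks, _ = default_phantom_module
        psf = PSFModel.isotropic(6.0)
        observed = blur(truth, psf)
        result = meltzer_correct(observed, masks["brain"], psf)
        valid = result.validity.astype(bool)
        assert np.all(result.corrected.data[valid] >= observed.data[valid] - 1e-12)

    @pytest.mark.parametrize("tau", [0.0, -0.5, 1.5])
    def test_tau_out_of_range(self, default_phantom_module, tau):
        _, truth, masks, _ = default_phantom_module
        with pytest.raises(ValueError):
            meltzer_correct(truth, masks["brain"], DELTA, tau=tau)


class TestGTM:
    def test_delta_psf_gives_identity_matrix(self, unit_affine):
        labelmap = np.zeros((6, 6, 6), dtype=np.int16)
        labelmap[:3] = 1
        labelmap[3:] = 2
        parc = toy_parcellation(labelmap, unit_affine)
        rng = np.random.default_rng(0)
        img = Image3D(data=rng.uniform(1, 2, (6, 6, 6)), affine=unit_affine)
        sol = gtm_solve(img, parc, DELTA)
        np.testing.assert_allclose(sol.omega, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(sol.true_means, sol.observed, atol=1e-12)

    def test_two_region_bar_recovery_with_hand_built_oracle(self):
        """Regions [0..4] and [5..9] along one axis with truths 10 and 2:
        the GTM solve recovers both from the blurred signal to 1e-8, and the
        matrix agrees with an independently assembled one."""
        affine = grid_affine()
        labelmap = np.zeros((10, 3, 3), dtype=np.int16)
        labelmap[:5] = 1
        labelmap[5:] = 2
        parc = toy_parcellation(labelmap, affine)
        truth = np.where(labelmap == 1, 10.0, 2.0)
        psf = PSFModel(fwhm_mm=(2.0, 0.0, 0.0))
        kernel = make_kernel(psf, (1, 1, 1))
        observed = Image3D(data=convolve_array(truth, kernel), affine=affine)

        # independent oracle: assemble omega and o by hand and solve
        m1 = convolve_array((labelmap == 1).astype(float), kernel)
        m2 = convolve_array((labelmap == 2).astype(float), kernel)
        omega = np.array(
            [
                [m1[labelmap == 1].mean(), m2[labelmap == 1].mean()],
                [m1[labelmap == 2].mean(), m2[labelmap == 2].mean()],
            ]
        )
        o = np.array(
            [observed.data[labelmap == 1].mean(), observed.data[labelmap == 2].mean()]
        )
        expected = np.linalg.solve(omega, o)
        np.testing.assert_allclose(expected, [10.0, 2.0], atol=1e-8)

        sol = gtm_solve(observed, parc, psf)
        np.testing.assert_allclose(sol.omega, omega, atol=1e-12)
        np.testing.assert_allclose(sol.true_means, [10.0, 2.0], atol=1e-8)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_recovery_on_random_phantoms(self, seed):
        """Noiseless piecewise-constant truth blurred with the matched PSF is
        recovered exactly (<= 1e-6 relative) whenever the transfer matrix is
        well conditioned."""
        rng = np.random.default_rng(seed)
        n_regions = rng.integers(2, 5)
        labelmap = rng.integers(0, n_regions + 1, size=(9, 9, 9)).astype(np.int16)
        present = sorted(set(labelmap.ravel().tolist()) - {0})
        if not present:
            pytest.skip("empty phantom draw")
        parc = toy_parcellation(labelmap, grid_affine())
        truths = {lab: rng.uniform(0.5, 10.0) for lab in present}
        truth = np.zeros(labelmap.shape)
        for lab, t in truths.items():
            truth[labelmap == lab] = t
        psf = PSFModel.isotropic(float(rng.uniform(0.0, 3.0)))
        kernel = make_kernel(psf, (1, 1, 1))
        observed = Image3D(data=convolve_array(truth, kernel), affine=grid_affine())
        sol = gtm_solve(observed, parc, psf)
        if sol.cond >= 1e3:
            pytest.skip("ill-conditioned draw")
        expected = np.array([truths[lab] for lab in sol.regions])
        np.testing.assert_allclose(sol.true_means, expected, rtol=1e-6)

    def test_omega_rows_bounded(self, default_phantom_module):
        _, truth, _, parc = default_phantom_module
        sol = gtm_solve(truth, parc, PSFModel.isotropic(6.0))
        assert np.all(sol.omega >= -1e-9)
        assert np.all(sol.omega.sum(axis=1) <= 1 + 1e-9)
        assert sol.cond < 1e3


class TestMMG:
    def test_delta_psf_identity(self):
        suv, gm, wm = make_slab_phantom()
        result = mmg_correct(suv, gm, wm, DELTA)
        valid = result.validity.astype(bool)
        np.testing.assert_array_equal(valid, gm.data.astype(bool))
        np.testing.assert_allclose(result.corrected.data[valid], suv.data[valid], atol=1e-10)

    def test_two_compartment_recovery_with_true_wm(self):
        """Piecewise-constant GM/WM slab, matched PSF, WM activity fixed to
        its true value: GM is recovered to well within 1 %."""
        a_gm, a_wm = 2.0, 1.5
        suv, gm, wm = make_slab_phantom(a_gm=a_gm, a_wm=a_wm)
        psf = PSFModel.isotropic(6.0)
        observed = blur(suv, psf)
        result = mmg_correct(observed, gm, wm, psf, wm_activity=a_wm)
        valid = result.validity.astype(bool)
        np.testing.assert_allclose(result.corrected.data[valid], a_gm, rtol=1e-2)

    def test_gtm2_wm_estimate_close_to_truth(self):
        a_gm, a_wm = 2.0, 1.5
        suv, gm, wm = make_slab_phantom(a_gm=a_gm, a_wm=a_wm)
        psf = PSFModel.isotropic(6.0)
        result = mmg_correct(blur(suv, psf), gm, wm, psf, wm_mode="gtm2")
        assert result.params["wm_activity"] == pytest.approx(a_wm, rel=1e-2)

    def test_erosion_mode_runs_and_falls_back(self):
        suv, gm, wm = make_slab_phantom()
        psf = PSFModel.isotropic(6.0)
        result = mmg_correct(blur(suv, psf), gm, wm, psf, wm_mode="erosion")
        assert result.params["wm_activity_source"] in ("erosion", "gtm2")

    def test_empty_wm_reduces_to_gm_meltzer(self):
        suv, gm, wm = make_slab_phantom()
        empty_wm = make_mask(np.zeros(wm.data.shape, dtype=np.uint8), wm.affine)
        psf = PSFModel.isotropic(6.0)
        observed = blur(suv, psf)
        result = mmg_correct(observed, gm, empty_wm, psf)
        reference = meltzer_correct(observed, gm, psf)
        both = result.validity.astype(bool) & reference.validity.astype(bool)
        assert both.any()
        np.testing.assert_allclose(
            result.corrected.data[both], reference.corrected.data[both], atol=1e-12
        )

    def test_overlapping_masks_rejected(self):
        suv, gm, _ = make_slab_phantom()
        with pytest.raises(ValueError, match="overlap"):
            mmg_correct(suv, gm, gm, DELTA)

    def test_negative_values_counted_and_clampable(self):
        suv, gm, wm = make_slab_phantom(a_gm=0.1, a_wm=3.0)
        psf = PSFModel.isotropic(8.0)
        observed = blur(suv, psf)
        kept = mmg_correct(observed, gm, wm, psf, wm_activity=5.0)
        assert kept.params["n_negative"] > 0
        assert (kept.corrected.data[kept.validity.astype(bool)] < 0).any()
        clamped = mmg_correct(
            observed, gm, wm, psf, wm_activity=5.0, clamp_negative=True
        )
        assert not (clamped.corrected.data[clamped.validity.astype(bool)] < 0).any()


class TestRBV:
    def test_delta_psf_identity(self, default_phantom_module):
        _, truth, _, parc = default_phantom_module
        result = rbv_correct(truth, parc, DELTA)
        valid = result.validity.astype(bool)
        np.testing.assert_array_equal(valid, parc.labelmap > 0)
        np.testing.assert_allclose(result.corrected.data[valid], truth.data[valid], atol=1e-10)

    def test_piecewise_constant_truth_recovered(self, default_phantom_module):
        """With truth matching the parcellation and a matched PSF, RBV is
        algebraically exact on labelled voxels."""
        _, truth, _, parc = default_phantom_module
        psf = PSFModel.isotropic(6.0)
        observed = blur(truth, psf)
        result = rbv_correct(observed, parc, psf)
        valid = result.validity.astype(bool)
        np.testing.assert_allclose(
            result.corrected.data[valid], truth.data[valid], rtol=1e-2
        )

    def test_region_means_match_gtm(self, default_phantom_module):
        _, truth, _, parc = default_phantom_module
        psf = PSFModel.isotropic(6.0)
        observed = blur(truth, psf)
        result = rbv_correct(observed, parc, psf)
        sol = gtm_solve(observed, parc, psf)
        for lab, t in zip(sol.regions, sol.true_means):
            region = (parc.labelmap == lab) & result.validity.astype(bool)
            assert result.corrected.data[region].mean() == pytest.approx(t, rel=2e-2)

    def test_uniform_truth_reduces_to_meltzer_on_union(self, unit_affine):
        labelmap = np.zeros((20, 20, 20), dtype=np.int16)
        labelmap[5:15, 5:15, 5:15] = 1
        labelmap[5:15, 5:15, 15:18] = 2
        parc = toy_parcellation(labelmap, unit_affine)
        truth = Image3D(data=3.0 * (labelmap > 0), affine=unit_affine)
        psf = PSFModel.isotropic(3.0)
        observed = blur(truth, psf)
        rbv = rbv_correct(observed, parc, psf)
        union = make_mask((labelmap > 0).astype(np.uint8), unit_affine)
        meltzer = meltzer_correct(observed, union, psf)
        both = rbv.validity.astype(bool) & meltzer.validity.astype(bool)
        np.testing.assert_allclose(
            rbv.corrected.data[both], meltzer.corrected.data[both], rtol=1e-6
        )

    def test_out_of_parcellation_passthrough(self, unit_affine):
        labelmap = np.zeros((12, 12, 12), dtype=np.int16)
        labelmap[3:9, 3:9, 3:9] = 1
        parc = toy_parcellation(labelmap, unit_affine)
        rng = np.random.default_rng(0)
        img = Image3D(data=rng.uniform(1, 2, (12, 12, 12)), affine=unit_affine)
        result = rbv_correct(img, parc, PSFModel.isotropic(2.0))
        outside = labelmap == 0
        np.testing.assert_array_equal(result.corrected.data[outside], img.data[outside])
        assert not result.validity[outside].any()


class TestInsertVOI:
    @pytest.fixture
    def parc(self, unit_affine):
        labelmap = np.zeros((10, 10, 1), dtype=np.int16)
        labelmap[:10, :10] = 1
        labelmap[:, 5:] = 2
        return toy_parcellation(labelmap, unit_affine)

    def test_split_sizes(self, parc, unit_affine):
        voi = np.zeros((10, 10, 1), dtype=np.uint8)
        voi[:3, :5] = 1  # 15 voxels inside region 1 (size 50)
        out = insert_voi_into_parcellation(parc, make_mask(voi, unit_affine))
        sizes = out.region_sizes()
        assert sizes[1] == 35
        new_label = max(out.labels)
        assert sizes[new_label] == 15
        assert out.region_table[new_label] == "r1+voi"

    def test_two_region_overlap_conserves_voxels(self, parc, unit_affine):
        voi = np.zeros((10, 10, 1), dtype=np.uint8)
        voi[4:6, 3:8] = 1  # straddles both regions
        out = insert_voi_into_parcellation(parc, make_mask(voi, unit_affine))
        assert sum(out.region_sizes().values()) == sum(parc.region_sizes().values())
        assert len(out.labels) == 4

    def test_swallowed_region_dropped(self, parc, unit_affine):
        voi = (parc.labelmap == 1).astype(np.uint8)
        out = insert_voi_into_parcellation(parc, make_mask(voi, unit_affine))
        assert 1 not in out.region_table
        assert sum(out.region_sizes().values()) == sum(parc.region_sizes().values())

    def test_disjoint_voi_rejected(self, parc, unit_affine):
        voi = np.zeros((10, 10, 1), dtype=np.uint8)
        with pytest.raises(ValueError):
            insert_voi_into_parcellation(parc, make_mask(voi, unit_affine))


class TestPVCResult:
    def test_sidecar_roundtrip(self, tmp_path, default_phantom_module):
        _, truth, masks, _ = default_phantom_module
        result = meltzer_correct(truth, masks["brain"], DELTA)
        result.write(tmp_path / "meltzer")
        assert (tmp_path / "meltzer.nii").exists()
        assert (tmp_path / "meltzer_validity.nii").exists()
        sidecar = json.loads((tmp_path / "meltzer.json").read_text())
        assert sidecar["method"] == "meltzer"
        assert sidecar["tau"] == 0.1

    def test_none_method_passthrough(self, default_phantom_module):
        _, truth, masks, _ = default_phantom_module
        result = no_correction(truth, masks["brain"])
        np.testing.assert_array_equal(result.corrected.data, truth.data)
        np.testing.assert_array_equal(result.validity, masks["brain"].data)
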