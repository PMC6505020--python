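import dataclasses

import numpy as np
import pytest

from susiq.grids import VoxelGrid, Volume
from susiq.phantom import (CohortConfig, PhantomCompartment, PhantomTruth,
                           add_noise, apply_misalignment, apply_psf,
                           background_voxel_counts, render_phantom,
                           simulate_cohort)

from conftest import SMALL_GEOMETRY, SMALL_GRID


def uniform_truth(rois, bpnd=5.0, **kw):
    geom = rois.geometry
    return PhantomTruth.uniform(
        bpnd=bpnd, putamen_volume_ml=geom.putamen_volume_ml,
        caudate_volume_ml=geom.caudate_volume_ml,
        ant_fraction=rois.anterior_fraction, **kw,
    )


class TestRenderPhantom:
    def test_zero_bpnd_uniform_over_brain(self, small_rois):
        truth = uniform_truth(small_rois, bpnd=0.0)
        vol = render_phantom(SMALL_GRID, small_rois, truth)
        bg = background_voxel_counts(SMALL_GRID, truth)
        brain = small_rois.mask("brain")
        assert np.all(vol.data[brain] == np.float32(bg))
        assert np.all(vol.data[~brain] == 0)

    def test_voxel_value_arithmetic(self, small_rois):
        # bpnd 5, concentration 1, count_scale 1, 2 mm voxels -> 6 * 8 counts
        truth = dataclasses.replace(uniform_truth(small_rois, bpnd=5.0),
                                    count_scale=1.0)
        vol, masks = render_phantom(SMALL_GRID, small_rois, truth, return_masks=True)
        put = vol.data.flat[masks["putamen_post_L"]]
        np.testing.assert_allclose(put, 6.0 * 8.0)

    def test_realized_volume_within_one_voxel(self, small_rois):
        truth = uniform_truth(small_rois)
        _, masks = render_phantom(SMALL_GRID, small_rois, truth, return_masks=True)
        vox_ml = SMALL_GRID.voxel_volume_ml
        for comp in truth.compartments:
            realized_ml = masks[comp.name].size * vox_ml
            assert abs(realized_ml - comp.volume_ml) <= vox_ml

    def test_total_specific_counts_identity(self, small_rois):
        # sum of specific counts = bpnd * Cnd * count_scale * Vs within 1%
        truth = uniform_truth(small_rois, bpnd=4.0)
        vol, masks = render_phantom(SMALL_GRID, small_rois, truth, return_masks=True)
        bg = background_voxel_counts(SMALL_GRID, truth)
        for comp in truth.compartments:
            specific = vol.data.flat[masks[comp.name]].sum() - bg * masks[comp.name].size
            expected = (comp.bpnd_true * truth.background_concentration
                        * truth.count_scale * comp.volume_ml * 1000.0)
            assert specific == pytest.approx(expected, rel=0.01)

    def test_subvoxel_compartment_rejected(self, small_rois):
        comps = (PhantomCompartment("caudate_L", 0.004, 1.0),)
        truth = PhantomTruth(compartments=comps)
        with pytest.raises(ValueError, match="smaller"):
            render_phantom(SMALL_GRID, small_rois, truth)


class TestApplyPsf:
    def test_zero_fwhm_identity(self, small_rois):
        vol = render_phantom(SMALL_GRID, small_rois, uniform_truth(small_rois))
        out = apply_psf(vol, 0.0)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_impulse_count_conservation(self):
        g = VoxelGrid((40, 40, 40), (2.0, 2.0, 2.0))
        data = np.zeros(g.shape, np.float64)
        data[20, 20, 20] = 1000.0
        for fwhm in (4.0, 8.0, 14.0):
            out = apply_psf(Volume(g, data), fwhm)
            assert out.total_counts == pytest.approx(1000.0, rel=1e-6)

    def test_phantom_count_conservation(self, small_rois):
        vol = render_phantom(SMALL_GRID, small_rois, uniform_truth(small_rois))
        for fwhm in (5.0, 7.0):
            out = apply_psf(vol, fwhm)
            assert out.total_counts == pytest.approx(vol.total_counts, rel=1e-6)

    def test_uniform_volume_unchanged_in_interior(self):
        g = VoxelGrid((30, 30, 30), (2.0, 2.0, 2.0))
        vol = Volume(g, np.full(g.shape, 7.0))
        out = apply_psf(vol, 8.0)
        interior = out.data[12:18, 12:18, 12:18]
        np.testing.assert_allclose(interior, 7.0, rtol=1e-6)

    def test_negative_fwhm_rejected(self, small_rois):
        vol = render_phantom(SMALL_GRID, small_rois, uniform_truth(small_rois))
        with pytest.raises(ValueError):
            apply_psf(vol, -1.0)


class TestAddNoise:
    def test_zero_volume_stays_zero(self):
        g = VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0))
        out = add_noise(Volume(g, np.zeros(g.shape)), seed=3)
        assert out.data.sum() == 0

    def test_seed_determinism(self, small_rois):
        vol = apply_psf(
            render_phantom(SMALL_GRID, small_rois, uniform_truth(small_rois)), 7.0
        )
        a = add_noise(vol, seed=11)
        b = add_noise(vol, seed=11)
        np.testing.assert_array_equal(a.data, b.data)
        c = add_noise(vol, seed=12)
        assert (a.data != c.data).any()

    def test_poisson_mean(self):
        # mean of 1000 noisy replicates of a voxel with mean 50: within 3 SE
        g = VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0))
        data = np.zeros(g.shape)
        data[4, 4, 4] = 50.0
        vol = Volume(g, data)
        draws = [add_noise(vol, seed=i).data[4, 4, 4] for i in range(1000)]
        se = np.sqrt(50.0 / 1000.0)
        assert np.mean(draws) == pytest.approx(50.0, abs=3 * se)

    def test_negative_intensity_rejected(self):
        g = VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            add_noise(Volume(g, np.full(g.shape, -1.0)), seed=0)


class TestMisalignment:
    @pytest.fixture()
    def blurred(self, small_rois):
        return apply_psf(
            render_phantom(SMALL_GRID, small_rois, uniform_truth(small_rois)), 7.0
        )

    def test_identity_transform(self, blurred):
        out = apply_misalignment(blurred, (0, 0, 0), (0, 0, 0))
        np.testing.assert_allclose(out.data, blurred.data, atol=1e-4)
        assert out.meta["applied_rigid"]["translation_mm"] == (0.0, 0.0, 0.0)

    def test_one_voxel_lattice_shift_exact(self, blurred):
        out = apply_misalignment(blurred, (2.0, 0, 0), (0, 0, 0))
        # content moves +x by one voxel: out[i] == in[i-1] in the interior
        np.testing.assert_allclose(out.data[1:, :, :], blurred.data[:-1, :, :],
                                   atol=1e-4)

    def test_translation_roundtrip(self, blurred):
        t = (3.7, -2.1, 1.9)
        back = apply_misalignment(
            apply_misalignment(blurred, t, (0, 0, 0)),
            tuple(-x for x in t), (0, 0, 0),
        )
        interior = blurred.data > 0
        mad = np.abs(back.data[interior] - blurred.data[interior]).mean()
        assert mad < 0.02 * blurred.data[interior].mean()

    def test_limits_enforced(self, blurred):
        with pytest.raises(ValueError):
            apply_misalignment(blurred, (25, 0, 0), (0, 0, 0))

    def test_fov_warning(self, small_rois):
        vol = render_phantom(SMALL_GRID, small_rois, uniform_truth(small_rois))
        near_edge = vol.copy()
        near_edge.meta["striatum_box_mm"] = ((30.0, 30.0, 30.0), (40.0, 40.0, 40.0))
        out = apply_misalignment(near_edge, (10, 10, 10), (0, 0, 0))
        assert out.meta.get("fov_warning") is True
        ok = apply_misalignment(vol, (2, 0, 0), (0, 0, 0))
        assert "fov_warning" not in ok.meta


class TestSimulateCohort:
    def small_config(self, **kw):
        base = dict(setting="MONO", n_disease=4, n_control=3, grid=SMALL_GRID,
                    geometry=SMALL_GEOMETRY, fwhm_mm=7.0,
                    putamen_volume_ml=(5.5 / 8, 0.7 / 8),
                    caudate_volume_ml=(4.0 / 8, 0.5 / 8),
                    min_volume_ml=0.06, seed=5)
        base.update(kw)
        return CohortConfig(**base)

    def test_no_disease_config(self, small_rois):
        subs = simulate_cohort(self.small_config(n_disease=0), small_rois)
        assert all(s.label == "control" for s in subs)

    def test_mono_shares_fwhm(self, small_rois):
        subs = simulate_cohort(self.small_config(), small_rois)
        assert len({s.fwhm_mm for s in subs}) == 1

    def test_multi_sites_draw_distinct_fwhm(self, small_rois):
        cfg = self.small_config(setting="MULTI", n_disease=4, n_control=4,
                                n_sites=8, fwhm_range_mm=(5.0, 8.0))
        subs = simulate_cohort(cfg, small_rois)
        fwhms = {s.fwhm_mm for s in subs}
        assert len(fwhms) == 8
        assert all(5.0 <= f <= 8.0 for f in fwhms)

    def test_bitwise_determinism(self, small_rois):
        cfg = self.small_config()
        a = simulate_cohort(cfg, small_rois)
        b = simulate_cohort(cfg, small_rois)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.volume.data, sb.volume.data)
            assert sa.truth == sb.truth
            assert (sa.label, sa.site, sa.fwhm_mm) == (sb.label, sb.site, sb.fwhm_mm)

    def test_fast_path_matches_op_composition(self, small_rois):
        cfg = self.small_config(noise=False)
        subs = simulate_cohort(cfg, small_rois)
        for s in subs[:3]:
            manual = apply_psf(
                render_phantom(SMALL_GRID, small_rois, s.truth), s.fwhm_mm
            )
            np.testing.assert_allclose(s.volume.data, manual.data, rtol=2e-5,
                                       atol=1e-3)

    def test_disease_group_asymmetric(self, small_rois):
        subs = simulate_cohort(self.small_config(n_disease=6, n_control=0),
                               small_rois)
        for s in subs:
            post_l = s.truth.compartment("putamen_post_L").bpnd_true
            post_r = s.truth.compartment("putamen_post_R").bpnd_true
            worse, better = min(post_l, post_r), max(post_l, post_r)
            assert better == pytest.approx(worse * 1.4)
            # anterior 1.6x posterior on both sides
            for side in ("L", "R"):
                ant = s.truth.compartment(f"putamen_ant_{side}").bpnd_true
                post = s.truth.compartment(f"putamen_post_{side}").bpnd_true
                assert ant == pytest.approx(post * 1.6)

    def test_invalid_distribution_rejected_before_rendering(self):
        with pytest.raises(ValueError):
            self.small_config(putamen_volume_ml=(5.5 / 8, -0.1))

    def test_mirror_symmetric_noiseless_phantom(self, small_rois):
        # symmetric truth: left/right compartment statistics agree exactly
        truth = uniform_truth(small_rois, bpnd=3.0)
        vol = apply_psf(render_phantom(SMALL_GRID, small_rois, truth), 7.0)
        left = vol.data[small_rois.mask("putamen_L")]
        right = vol.data[small_rois.mask("putamen_R")]
        assert left.sum() == pytest.approx(right.sum(), rel=2e-3)
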