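import numpy as np
import pytest

from chorovol import (
    OCTVolume,
    SurfacePair,
    ThresholdParams,
    VesselMask,
    combine,
    dice,
    flatten,
    global_mask,
    niblack_mask_bscan,
    niblack_mask_cscan,
    segment_vessels,
    slab_mask,
    stroma_mask,
)
from chorovol.segment import masked_niblack_threshold


def brute_force_niblack(img, mask, size, k):
    """Windowed masked mean/population-sd oracle, plain loops."""
    out = np.full(img.shape, np.inf)
    rb, ra, rz = (s // 2 for s in size)
    nb, na, nz = img.shape
    for b in range(nb):
        for a in range(na):
            for z in range(nz):
                sl = (
                    slice(max(b - rb, 0), min(b + rb + 1, nb)),
                    slice(max(a - ra, 0), min(a + ra + 1, na)),
                    slice(max(z - rz, 0), min(z + rz + 1, nz)),
                )
                vals = img[sl][mask[sl]]
                if vals.size:
                    out[b, a, z] = vals.mean() + k * vals.std()
    return out


def brute_force_otsu_mask(values, candidates):
    """Exhaustive between-class-variance maximisation."""
    best_t, best_v = None, -1.0
    for t in candidates:
        lo, hi = values[values < t], values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / values.size, hi.size / values.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def full_slab(shape):
    return SurfacePair(np.zeros(shape[:2], int), np.full(shape[:2], shape[2]))


class TestNiblack:
    def test_three_by_three_worked_example(self):
        img = np.arange(1.0, 10.0).reshape(1, 3, 3)
        t = masked_niblack_threshold(img, np.ones_like(img, bool), (1, 3, 3), k=-0.2)
        assert t[0, 1, 1] == pytest.approx(4.4836, abs=1e-3)
        # centre value 5 is above the threshold: not vessel
        assert not (img < t)[0, 1, 1]

    def test_k_zero_constant_image_has_no_vessels(self):
        vol = OCTVolume(np.full((2, 8, 8), 0.5), (1, 1, 1))
        s = full_slab(vol.shape)
        m = niblack_mask_bscan(vol, s, ThresholdParams(k=0.0, bscan_window_mm=(3, 3)))
        assert m.count() == 0  # strict inequality: ties go to stroma

    def test_k_zero_flags_exactly_below_local_mean(self, rng):
        arr = rng.random((1, 12, 12))
        vol = OCTVolume(arr, (1, 1, 1))
        s = full_slab(vol.shape)
        m = niblack_mask_bscan(vol, s, ThresholdParams(k=0.0, bscan_window_mm=(5, 5)))
        oracle_t = brute_force_niblack(arr, np.ones_like(arr, bool), (1, 5, 5), 0.0)
        np.testing.assert_array_equal(m.labels, arr < oracle_t)

    def test_masked_statistics_match_brute_force(self, rng):
        img = rng.random((1, 16, 16))
        mask = rng.random((1, 16, 16)) < 0.7
        t = masked_niblack_threshold(img, mask, (1, 5, 3), k=-0.2)
        oracle = brute_force_niblack(img, mask, (1, 5, 3), -0.2)
        np.testing.assert_allclose(t[mask], oracle[mask], rtol=1e-9)

    def test_unmasked_matches_skimage(self, rng):
        from skimage.filters import threshold_niblack

        img = rng.random((16, 16))
        t_ours = masked_niblack_threshold(
            img[None], np.ones((1, 16, 16), bool), (1, 5, 5), k=-0.3
        )[0]
        t_sk = threshold_niblack(img, window_size=5, k=0.3)
        # skimage uses T = m - k*s with positive k and reflected borders;
        # compare away from the border
        np.testing.assert_allclose(t_ours[2:-2, 2:-2], t_sk[2:-2, 2:-2], rtol=1e-7)

    def test_window_larger_than_plane_rejected(self):
        vol = OCTVolume(np.zeros((1, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="window"):
            niblack_mask_bscan(vol, full_slab(vol.shape), ThresholdParams(bscan_window_mm=(50, 50)))

    def test_noiseless_phantom_lumen_mostly_flagged(self, noiseless_truth):
        m = niblack_mask_bscan(noiseless_truth.volume, noiseless_truth.surfaces)
        truth = noiseless_truth.vessel_truth.labels
        assert (m.labels & truth).sum() / truth.sum() >= 0.90


class TestCscanView:
    def test_continuous_vessel_is_single_component(self, noiseless_truth):
        from scipy import ndimage

        flat = flatten(noiseless_truth.volume, noiseless_truth.surfaces)
        m = niblack_mask_cscan(flat)
        # the r=0.2 mm vessel crosses depth 0.55 mm (offset 25 below BM)
        plane = m.labels[:, :, 55]
        lab, n = ndimage.label(plane, structure=np.ones((3, 3), bool))
        sizes = np.bincount(lab.ravel())[1:]
        assert (sizes > 100).sum() >= 1  # one dominant connected band

    def test_uniform_slab_yields_empty_mask(self):
        arr = np.full((8, 20, 30), 0.5)
        vol = OCTVolume(arr, (0.1, 0.1, 0.1))
        s = SurfacePair(np.full((8, 20), 5), np.full((8, 20), 25))
        flat = flatten(vol, s)
        m = niblack_mask_cscan(flat, ThresholdParams(k=0.0, cscan_window_mm=(0.5, 0.5)))
        assert m.count() == 0


class TestGlobal:
    def test_two_level_example(self):
        arr = np.array([0.1] * 6 + [0.9] * 4).reshape(1, 1, 10)
        vol = OCTVolume(arr, (1, 1, 1))
        m = global_mask(vol, full_slab(vol.shape))
        assert m.count() == 6
        assert np.all(m.labels[arr < 0.5])

    def test_matches_exhaustive_search_on_discrete_slabs(self, rng):
        levels = np.array([0.1, 0.3, 0.55, 0.8])
        for _ in range(10):
            arr = levels[rng.integers(0, 4, (2, 6, 8))]
            vol = OCTVolume(arr, (1, 1, 1))
            s = full_slab(vol.shape)
            m = global_mask(vol, s)
            t = brute_force_otsu_mask(arr.ravel(), candidates=[0.2, 0.425, 0.675])
            np.testing.assert_array_equal(m.labels, arr < t)

    def test_bimodal_phantom_fraction_close_to_truth(self, noiseless_truth):
        m = global_mask(noiseless_truth.volume, noiseless_truth.surfaces)
        inside = slab_mask(noiseless_truth.volume.shape, noiseless_truth.surfaces)
        truth_frac = noiseless_truth.vessel_truth.count() / inside.sum()
        seg_frac = m.count() / inside.sum()
        assert seg_frac == pytest.approx(truth_frac, abs=0.05 * truth_frac + 0.02)

    def test_constant_slab_is_error(self):
        vol = OCTVolume(np.full((2, 2, 10), 0.5), (1, 1, 1))
        with pytest.raises(ValueError, match="constant"):
            global_mask(vol, full_slab(vol.shape))


def random_masks(rng, n=3, shape=(4, 6, 10)):
    s = full_slab(shape)
    return [VesselMask(rng.random(shape) < 0.4, s) for _ in range(n)], s


class TestCombine:
    def test_unanimous_masks_pass_through(self, rng):
        masks, _ = random_masks(rng, 1)
        same = [masks[0]] * 3
        for rule in ("majority", "union", "intersection"):
            out = combine(same, rule, min_component=0)
            np.testing.assert_array_equal(out.labels, masks[0].labels)

    def test_rule_semantics_two_of_three(self):
        shape = (1, 1, 3)
        s = full_slab(shape)
        a = VesselMask(np.array([[[1, 0, 0]]], bool), s)
        b = VesselMask(np.array([[[1, 0, 0]]], bool), s)
        c = VesselMask(np.array([[[0, 0, 0]]], bool), s)
        assert combine([a, b, c], "majority", 0).labels[0, 0, 0]
        assert not combine([a, b, c], "intersection", 0).labels[0, 0, 0]
        assert combine([a, b, c], "union", 0).labels[0, 0, 0]

    def test_small_components_removed(self):
        shape = (5, 5, 5)
        s = full_slab(shape)
        labels = np.zeros(shape, bool)
        labels[0, 0, 0:2] = True  # 2-voxel blob
        labels[3:5, 3:5, 3:5] = True  # 8-voxel blob
        m = VesselMask(labels, s)
        out = combine([m, m, m], "majority", min_component=5)
        assert out.labels.sum() == 8
        assert not out.labels[0, 0, 0]

    def test_majority_is_monotone(self, rng):
        masks, s = random_masks(rng)
        base = combine(masks, "majority", min_component=4)
        grown = [m.labels.copy() for m in masks]
        stroma_voxels = np.argwhere(~grown[0])
        for idx in stroma_voxels[rng.integers(0, len(stroma_voxels), 10)]:
            grown[0][tuple(idx)] = True
        bigger = combine([VesselMask(grown[0], s), masks[1], masks[2]], "majority", 4)
        assert np.all(bigger.labels | ~base.labels)  # base subset of bigger

    def test_intersection_subset_union(self, rng):
        masks, _ = random_masks(rng)
        inter = combine(masks, "intersection", 0).labels
        major = combine(masks, "majority", 0).labels
        union = combine(masks, "union", 0).labels
        assert np.all(~inter | major)
        assert np.all(~major | union)

    def test_shape_mismatch_rejected(self, rng):
        masks, _ = random_masks(rng, 2)
        other = VesselMask(np.zeros((2, 2, 4), bool), full_slab((2, 2, 4)))
        with pytest.raises(ValueError, match="congruent"):
            combine([masks[0], masks[1], other])


class TestStromaAndDice:
    def test_partition_on_random_masks(self, rng):
        for _ in range(10):
            bm = rng.integers(0, 3, (3, 4))
            s = SurfacePair(bm, bm + rng.integers(2, 6, (3, 4)))
            inside = slab_mask((3, 4, 10), s)
            m = VesselMask(inside & (rng.random((3, 4, 10)) < 0.5), s)
            st = stroma_mask(m)
            assert m.count() + st.count() == inside.sum()
            assert not np.any(m.labels & st.labels)

    def test_dice_examples(self, rng):
        shape = (2, 5, 20)
        s = full_slab(shape)
        a = np.zeros(shape, bool)
        a.ravel()[:100] = True
        b = np.zeros(shape, bool)
        b.ravel()[20:120] = True
        assert dice(VesselMask(a, s), VesselMask(a, s)) == 1.0
        assert dice(VesselMask(a, s), VesselMask(~a & slab_mask(shape, s), s)) == 0.0
        assert dice(VesselMask(a, s), VesselMask(b, s)) == pytest.approx(0.8)
        empty = VesselMask(np.zeros(shape, bool), s)
        assert dice(empty, empty) == 1.0


class TestEndToEnd:
    def test_composite_dice_and_enhancement_benefit(
        self, standard_truth, standard_enhanced, standard_mask
    ):
        """Default enhance + segment reaches Dice >= 0.80 on the standard
        phantom, and enhancement strictly improves over segmenting raw."""
        d_enh = dice(standard_mask, standard_truth.vessel_truth)
        assert d_enh >= 0.80
        raw_mask = segment_vessels(standard_truth.volume, standard_truth.surfaces)
        assert dice(raw_mask, standard_truth.vessel_truth) < d_enh
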