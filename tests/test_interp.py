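"""Shape-based interpolation backend: exactness, SDF oracle, degradation."""

import numpy as np
import pytest

from slicefill import build_schedule, complete_by_interpolation, mask_annotations
from slicefill.interp import structure_sdf
from slicefill.schedule import ScheduleError, SparseLabelMap
from slicefill.volume_io import KIDNEY, TUMOR, LabelMap
from slicefill.metrics import dice_per_structure


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def brute_force_sdf(mask):
    """All-pairs Euclidean distance to the nearest opposite-class pixel."""
    h, w = mask.shape
    out = np.zeros((h, w))
    pts_in = np.argwhere(mask)
    pts_out = np.argwhere(~mask)
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                d = np.sqrt(((pts_out - (i, j)) ** 2).sum(axis=1)).min()
                out[i, j] = -d
            else:
                d = np.sqrt(((pts_in - (i, j)) ** 2).sum(axis=1)).min()
                out[i, j] = d
    return out


class TestStructureSDF:
    def test_threshold_recovers_mask(self, rng):
        for _ in range(10):
            mask = rng.random((12, 12)) > 0.6
            if not mask.any():
                mask[3, 3] = True
            sdf = structure_sdf(mask)
            np.testing.assert_array_equal(sdf.to_mask(), mask)

    def test_full_mask_nonpositive(self):
        sdf = structure_sdf(np.ones((6, 6), bool))
        assert (sdf.field <= 0).all()

    def test_empty_mask_large_positive(self):
        sdf = structure_sdf(np.zeros((6, 6), bool))
        assert (sdf.field > 1e5).all()

    def test_matches_brute_force_on_small_masks(self, rng):
        for _ in range(5):
            mask = rng.random((8, 8)) > 0.5
            if not mask.any() or mask.all():
                continue
            got = structure_sdf(mask).field
            expected = brute_force_sdf(mask)
            # distance_transform_edt measures to the nearest opposite *pixel
            # center*; the brute force does the same, so agreement is exact
            np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_single_pixel_distance(self):
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True
        sdf = structure_sdf(mask).field
        assert sdf[0, 0] == pytest.approx(np.sqrt(32), abs=0.5)


def _sparse_from(labels, gap):
    lm = LabelMap(labels)
    return mask_annotations(lm, build_schedule(labels.shape[0], gap)), lm


class TestCompleteByInterpolation:
    @pytest.mark.parametrize("gap", range(1, 11))
    def test_constant_cylinder_is_exact(self, gap):
        n = 2 * (gap + 2) + 1
        sl = np.zeros((20, 20), np.int16)
        sl[disc_mask((20, 20), (10, 10), 6)] = TUMOR
        labels = np.repeat(sl[None], n, axis=0)
        sparse, lm = _sparse_from(labels, gap)
        out = complete_by_interpolation(sparse)
        np.testing.assert_array_equal(out.labels, labels)

    def test_linear_disc_growth_mid_radius(self):
        # radius grows 5 -> 15 over 11 slices; only slices 0 and 10 manual
        labels = np.zeros((11, 40, 40), np.int16)
        for z, r in ((0, 5), (10, 15)):
            labels[z][disc_mask((40, 40), (20, 20), r)] = TUMOR
        sparse, _ = _sparse_from(labels, 9)
        out = complete_by_interpolation(sparse)
        mid = out.labels[5] == TUMOR
        r_equiv = np.sqrt(mid.sum() / np.pi)
        assert r_equiv == pytest.approx(10.0, abs=1.0)

    def test_gap0_is_identity(self, small_labels):
        sparse = mask_annotations(small_labels, build_schedule(small_labels.n_slices, 0))
        out = complete_by_interpolation(sparse)
        np.testing.assert_array_equal(out.labels, small_labels.labels)

    def test_manual_slices_copied_verbatim(self, small_labels):
        sparse = mask_annotations(small_labels, build_schedule(small_labels.n_slices, 4))
        out = complete_by_interpolation(sparse)
        m = sparse.schedule.manual
        np.testing.assert_array_equal(out.labels[m], small_labels.labels[m])

    def test_two_structure_tie_break_deterministic(self):
        # kidney and tumor half-planes meeting mid-image: boundary pixels
        # must resolve identically on repeated runs
        sl = np.zeros((9, 20, 20), np.int16)
        sl[:, :, :10] = KIDNEY
        sl[:, :, 10:] = TUMOR
        sparse, lm = _sparse_from(sl, 3)
        a = complete_by_interpolation(sparse)
        b = complete_by_interpolation(sparse)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.labels, sl)  # constant -> exact

    def test_unbracketed_slice_rejected(self):
        labels = np.zeros((6, 8, 8), np.int16)
        labels[:, 2:5, 2:5] = TUMOR
        schedule = build_schedule(6, 1)
        manual = schedule.manual.copy()
        manual[-1] = False  # break the bracketing invariant by hand
        bad = SparseLabelMap(labels=np.where(manual[:, None, None], labels, 0),
                             schedule=type(schedule)(gap=1, n_slices=6, manual=manual),
                             spacing=(1, 1, 1))
        with pytest.raises(ScheduleError, match="not bracketed"):
            complete_by_interpolation(bad)

    def test_degradation_monotone_on_curved_profile(self):
        # sinusoidally varying radius: linear SDF interpolation degrades
        # more as the gap widens
        n = 25
        labels = np.zeros((n, 40, 40), np.int16)
        for z in range(n):
            r = 10 + 4 * np.sin(2 * np.pi * z / (n - 1))
            labels[z][disc_mask((40, 40), (20, 20), r)] = TUMOR
        lm = LabelMap(labels)
        dices = []
        for gap in (1, 3, 5, 7):
            sparse = mask_annotations(lm, build_schedule(n, gap))
            out = complete_by_interpolation(sparse)
            dices.append(dice_per_structure(out, lm, TUMOR,
                                            sparse.schedule.automatic_indices))
        assert all(a >= b for a, b in zip(dices, dices[1:]))
        assert dices[0] > 0.95
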