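"""Evaluation metrics vs brute-force oracles; statistical comparisons."""

import math

import numpy as np
import pytest

from eatseg.dataio import LabelStack
from eatseg.metrics import (
    BinaryMask,
    compare_distributions,
    dsc,
    evaluate_subject,
    msd,
    ppv,
    rse,
)


def bm(mask, spacing=(1.0, 1.0)):
    return BinaryMask(np.asarray(mask, dtype=bool), spacing)


def brute_force_contour(mask):
    """Oracle: mask pixel with any 8-neighbor (or image border) outside."""
    pts = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            on_border = r in (0, h - 1) or c in (0, w - 1)
            exposed = any(
                not mask[r + dr, c + dc]
                for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr or dc) and 0 <= r + dr < h and 0 <= c + dc < w
            )
            if on_border or exposed:
                pts.append((r, c))
    return pts


def brute_force_msd(a, b, spacing):
    ca = brute_force_contour(a)
    cb = brute_force_contour(b)
    sr, sc = spacing

    def d(p, pts):
        return min(math.hypot((p[0] - q[0]) * sr, (p[1] - q[1]) * sc)
                   for q in pts)

    total = sum(d(p, cb) for p in ca) + sum(d(q, ca) for q in cb)
    return total / (len(ca) + len(cb))


class TestDsc:
    def test_identity_and_disjoint(self):
        a = np.zeros((6, 6), bool)
        a[1:3, 1:3] = True
        b = np.zeros((6, 6), bool)
        b[4:6, 4:6] = True
        assert dsc(bm(a), bm(a)) == 1.0
        assert dsc(bm(a), bm(b)) == 0.0

    def test_two_squares_half_overlap(self):
        a = np.zeros((6, 6), bool)
        a[0:2, 0:2] = True
        b = np.zeros((6, 6), bool)
        b[0:2, 1:3] = True
        assert dsc(bm(a), bm(b)) == pytest.approx(2 * 2 / (4 + 4))

    def test_empty_conventions(self):
        empty = np.zeros((4, 4), bool)
        full = ~empty
        assert dsc(bm(empty), bm(empty)) == 1.0
        assert dsc(bm(empty), bm(full)) == 0.0

    def test_symmetric_and_spacing_invariant(self, rng):
        a = rng.random((12, 12)) < 0.4
        b = rng.random((12, 12)) < 0.4
        assert dsc(bm(a), bm(b)) == dsc(bm(b), bm(a))
        assert dsc(bm(a, (1.7, 1.3)), bm(b, (1.7, 1.3))) == dsc(bm(a), bm(b))

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            dsc(bm(np.zeros((4, 4), bool)), bm(np.zeros((5, 5), bool)))


class TestMsd:
    def test_identical_masks_zero(self, rng):
        a = rng.random((10, 10)) < 0.3
        a[0, 0] = True
        assert msd(bm(a), bm(a)) == 0.0

    def test_two_pixels_two_apart(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[3, 2] = True
        b[3, 4] = True
        assert msd(bm(a, (1.5, 1.5)), bm(b, (1.5, 1.5))) == pytest.approx(3.0)

    def test_empty_mask_flagged_missing(self):
        a = np.zeros((4, 4), bool)
        b = a.copy()
        b[1, 1] = True
        assert math.isnan(msd(bm(a), bm(b)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            a = rng.random((12, 12)) < 0.3
            b = rng.random((12, 12)) < 0.3
            if not a.any() or not b.any():
                continue
            spacing = (float(rng.uniform(0.8, 2.0)),
                       float(rng.uniform(0.8, 2.0)))
            expected = brute_force_msd(a, b, spacing)
            assert msd(bm(a, spacing), bm(b, spacing)) == pytest.approx(
                expected, abs=1e-9)

    def test_scales_linearly_with_spacing(self, rng):
        a = rng.random((12, 12)) < 0.35
        b = rng.random((12, 12)) < 0.35
        base = msd(bm(a), bm(b))
        assert msd(bm(a, (2.0, 2.0)), bm(b, (2.0, 2.0))) == pytest.approx(
            2.0 * base)


class TestRse:
    def test_hand_arithmetic(self):
        a = np.zeros((20, 20), bool)
        a[:10, :10] = True   # 100 px
        b = np.zeros((20, 20), bool)
        b[:10, :8] = True    # 80 px
        assert rse(bm(a), bm(b)) == pytest.approx(20.0)
        double = np.zeros((20, 20), bool)
        double[:10, :20] = True
        assert rse(bm(a), bm(double)) == pytest.approx(100.0)

    def test_equal_area_disjoint_is_zero(self):
        a = np.zeros((6, 6), bool)
        a[0:2, 0:2] = True
        b = np.zeros((6, 6), bool)
        b[4:6, 4:6] = True
        assert rse(bm(a), bm(b)) == 0.0

    def test_empty_manual_flagged(self):
        a = np.zeros((4, 4), bool)
        b = a.copy()
        b[0, 0] = True
        assert math.isnan(rse(bm(a), bm(b)))
        assert rse(bm(a), bm(a)) == 0.0


class TestPpv:
    def test_subset_and_disjoint(self):
        m = np.zeros((6, 6), bool)
        m[1:5, 1:5] = True
        sub = np.zeros((6, 6), bool)
        sub[2:4, 2:4] = True
        assert ppv(bm(m), bm(sub)) == 1.0
        off = np.zeros((6, 6), bool)
        off[0, 5] = True
        assert ppv(bm(m), bm(off)) == 0.0

    def test_dilated_to_double_area(self):
        m = np.zeros((8, 8), bool)
        m[2:4, 2:6] = True  # 8 px
        a = np.zeros((8, 8), bool)
        a[2:4, 2:6] = True
        a[4:6, 2:6] = True  # 16 px, contains m
        assert ppv(bm(m), bm(a)) == pytest.approx(0.5)

    def test_asymmetric(self):
        m = np.zeros((6, 6), bool)
        m[1:3, 1:3] = True
        a = np.zeros((6, 6), bool)
        a[1:5, 1:5] = True
        assert ppv(bm(m), bm(a)) != ppv(bm(a), bm(m))

    def test_empty_auto_flagged(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = True
        assert math.isnan(ppv(bm(m), bm(np.zeros((4, 4), bool))))


class TestEvaluateSubject:
    def _stacks(self):
        masks = np.zeros((4, 16, 16), dtype=np.int16)
        masks[:, 2:6, 2:6] = 3
        masks[:, 8:10, 2:6] = 1
        masks[:, 12:14, 2:6] = 2
        return LabelStack(masks), LabelStack(masks.copy())

    def test_perfect_agreement(self):
        manual, auto = self._stacks()
        rows = evaluate_subject(manual, auto, (1.5, 1.5),
                                {"systole": 2, "diastole": 0},
                                subject_id="x")
        assert len(rows) == 8  # 4 labels x 2 frames
        for row in rows:
            assert row.dsc == 1.0
            assert row.msd_mm == 0.0
            assert row.rse_percent == 0.0
            assert row.ppv == 1.0
        roles = {(r.frame_role, r.frame_index) for r in rows}
        assert roles == {("systole", 2), ("diastole", 0)}

    def test_merged_pericardial_fat_row(self):
        manual, auto = self._stacks()
        rows = evaluate_subject(manual, auto, (1.0, 1.0),
                                {"systole": 1, "diastole": 0})
        merged = [r for r in rows if r.label == "EAT+PAT"]
        assert merged and all(
            r.manual_area_cm2 == pytest.approx(2 * 8 / 100) for r in merged)

    def test_missing_frame_designation(self):
        manual, auto = self._stacks()
        with pytest.raises(ValueError, match="diastole"):
            evaluate_subject(manual, auto, (1, 1), {"systole": 0})


class TestCompareDistributions:
    def test_identical_paired_degenerate(self):
        vals = [0.8, 0.9, 0.7, 0.85]
        rep = compare_distributions(vals, list(vals), paired=True)
        assert rep.p_value == 1.0
        assert "zero" in rep.note

    def test_large_shift_detected(self, rng):
        a = rng.normal(0, 1, 20)
        b = a + 10.0
        rep = compare_distributions(a, b, paired=True)
        assert rep.p_value < 0.001
        rep2 = compare_distributions(a, b, paired=False)
        assert rep2.p_value < 0.001
        assert rep2.test_name == "wilcoxon_rank_sum"

    def test_unmatched_subjects_rejected(self):
        with pytest.raises(ValueError, match="matched"):
            compare_distributions([1, 2, 3], [1, 2, 3], paired=True,
                                  subjects_a=["a", "b", "c"],
                                  subjects_b=["a", "b", "d"])

    def test_subject_alignment(self):
        rep = compare_distributions(
            [1.0, 2.0, 3.0], [3.0, 1.0, 2.0], paired=True,
            subjects_a=["a", "b", "c"], subjects_b=["c", "a", "b"])
        assert rep.p_value == 1.0  # identical after alignment

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_distributions([1, 2], [1, 2, 3])
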