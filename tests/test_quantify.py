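from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from thgq import (
    ClassifierParams,
    FeatureRecord,
    IntensityImage,
    Label,
    ObjectClass,
    TriggeredRule,
    classify_image,
    classify_mosaic,
    compare_with_reference,
    compute_neuropil_density,
    compute_pos,
)
from thgq.datatypes import PhaseOrigin
from thgq.objects import make_object


def _record(cell_pos=0.0, nucleus_pos=0.0, **kw) -> FeatureRecord:
    kw.setdefault("image_id", "t")
    kw.setdefault("neuropil_density", 0.0)
    kw.setdefault("n_cells", 0)
    kw.setdefault("n_nuclei", 0)
    kw.setdefault("image_area_px", 10_000)
    return FeatureRecord(cell_pos=cell_pos, nucleus_pos=nucleus_pos, **kw)


class TestPos:
    def test_direct_ratio(self):
        m = np.zeros((100, 100), dtype=bool)
        m.ravel()[:300] = True
        assert compute_pos([m], 10_000) == pytest.approx(0.03)

    def test_empty_set_is_zero(self):
        assert compute_pos([], 10_000) == 0.0

    def test_overlap_counted_once(self):
        a = np.zeros((100, 100), dtype=bool)
        b = np.zeros((100, 100), dtype=bool)
        a.ravel()[:600] = True
        b.ravel()[400:1000] = True
        assert compute_pos([a, b], 10_000) == pytest.approx(0.10)

    def test_matches_loop_oracle_on_random_masks(self, rng):
        for _ in range(10):
            masks = [oracles.random_blob(rng, size=32) for _ in range(3)]
            assert compute_pos(masks, 32 * 32) == pytest.approx(
                oracles.pos_loop(masks, 32 * 32), abs=0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            compute_pos([], 0)

    def test_adding_mask_never_decreases_pos(self, rng):
        masks = [oracles.random_blob(rng, size=32) for _ in range(4)]
        values = [compute_pos(masks[: k + 1], 1024) for k in range(4)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestNeuropilDensity:
    def test_formula_and_additivity(self):
        m1 = np.zeros((10, 110), dtype=bool)
        m1[4:6, 5:105] = True
        f1 = make_object(m1, 0, PhaseOrigin.BRIGHT, ObjectClass.NEUROPIL)
        f2 = make_object(m1, 1, PhaseOrigin.BRIGHT, ObjectClass.NEUROPIL)
        assert compute_neuropil_density([]) == 0.0
        one = compute_neuropil_density([f1])
        assert one == pytest.approx(f1.perimeter / 100.0)
        assert compute_neuropil_density([f1, f2]) == pytest.approx(2 * one)

    def test_rejects_non_neuropil_objects(self):
        m = np.ones((5, 5), dtype=bool)
        o = make_object(m, 0, PhaseOrigin.BRIGHT, ObjectClass.NUCLEUS)
        with pytest.raises(ValueError):
            compute_neuropil_density([o])


class TestClassifier:
    @pytest.mark.parametrize("cell_pos", [0.10, 0.17, 0.18])
    @pytest.mark.parametrize("nucleus_pos", [0.00, 0.03, 0.05])
    def test_strict_or_rule_truth_table(self, cell_pos, nucleus_pos):
        res = classify_image(_record(cell_pos, nucleus_pos))
        expect_tumor = (cell_pos > 0.17) or (nucleus_pos > 0.03)
        assert (res.label is Label.TUMOR) is expect_tumor

    def test_triggered_rule_records_the_firing_clause(self):
        assert classify_image(_record(0.18, 0.00)).triggered_rule \
            is TriggeredRule.CELL_POS
        assert classify_image(_record(0.10, 0.05)).triggered_rule \
            is TriggeredRule.NUCLEUS_POS
        assert classify_image(_record(0.30, 0.05)).triggered_rule \
            is TriggeredRule.BOTH
        assert classify_image(_record(0.17, 0.03)).triggered_rule \
            is TriggeredRule.NONE

    @given(c1=st.floats(0, 1), c2=st.floats(0, 1), n=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_cell_pos(self, c1, c2, n):
        lo, hi = sorted((c1, c2))
        res_lo = classify_image(_record(lo, n))
        res_hi = classify_image(_record(hi, n))
        if res_lo.label is Label.TUMOR:
            assert res_hi.label is Label.TUMOR


class TestMosaic:
    def test_quarter_features_average_to_tile_features(self):
        # stub analysis returning preset quarter cell PoS
        values = iter([0.10, 0.10, 0.30, 0.30])

        def analyze(img):
            return _record(cell_pos=next(values),
                           image_area_px=img.pixels.size)

        tile = IntensityImage(np.zeros((400, 400)) + 0.5, pixel_size_um=1.5)
        results, grid, quarters = classify_mosaic(
            [tile], analyze, ClassifierParams(large_tile_um=500))
        assert results[0].features.cell_pos == pytest.approx(0.20)
        assert results[0].label is Label.TUMOR
        assert len(quarters[0]) == 4
        assert grid.shape == (1, 1)

    def test_small_tiles_not_quartered(self):
        calls = []

        def analyze(img):
            calls.append(img.pixels.shape)
            return _record(0.05)

        tile = IntensityImage(np.zeros((200, 200)) + 0.5, pixel_size_um=0.3)
        results, _, quarters = classify_mosaic([tile], analyze)
        assert calls == [(200, 200)]
        assert quarters == [[]]
        assert results[0].label is Label.NORMAL

    def test_mixed_tile_shapes_rejected(self):
        t1 = IntensityImage(np.zeros((100, 100)) + 0.5)
        t2 = IntensityImage(np.zeros((120, 120)) + 0.5)
        with pytest.raises(ValueError, match="mixed"):
            classify_mosaic([t1, t2], lambda im: _record())


class TestCompare:
    def test_perfect_prediction(self):
        t = [Label.TUMOR, Label.NORMAL, Label.TUMOR]
        m = compare_with_reference(t, t)
        assert m["sensitivity"] == m["specificity"] == 1.0
        assert m["percent_agreement"] == 1.0

    def test_all_wrong(self):
        pred = [Label.NORMAL] * 4
        truth = [Label.TUMOR] * 4
        m = compare_with_reference(pred, truth)
        assert m["sensitivity"] == 0.0
        assert m["percent_agreement"] == 0.0

    def test_hand_counted_confusion(self):
        truth = [Label.TUMOR] * 4 + [Label.NORMAL] * 6
        pred = ([Label.TUMOR] * 3 + [Label.NORMAL]
                + [Label.NORMAL] * 4 + [Label.TUMOR] * 2)
        m = compare_with_reference(pred, truth)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(4 / 6)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            compare_with_reference([], [])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_matches_loop_oracle(self, flags):
        pred = [Label.TUMOR if a else Label.NORMAL for a, _ in flags]
        truth = [Label.TUMOR if b else Label.NORMAL for _, b in flags]
        m = compare_with_reference(pred, truth)
        o = oracles.confusion_loop([p.value for p in pred],
                                   [t.value for t in truth])
        for key in ("sensitivity", "specificity", "percent_agreement"):
            if np.isnan(o[key]):
                assert np.isnan(m[key])
            else:
                assert m[key] == pytest.approx(o[key], abs=0)
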