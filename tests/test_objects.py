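from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk

import oracles
from thgq import (
    ObjectClass,
    assemble_cells,
    classify_bright_objects,
    compute_perimeter,
    compute_sphericity,
    extract_dark_objects,
    split_touching,
)
from thgq.datatypes import PhaseOrigin
from thgq.objects import (
    bright_object_class,
    dark_object_retained,
    make_object,
)
from thgq.segmentation import PhaseLabelMap
from thgq.datatypes import BACKGROUND, BRIGHT, DARK_HOLE


def _phases(dark=None, bright=None, shape=(300, 300)) -> PhaseLabelMap:
    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    if dark is not None:
        labels[dark] = DARK_HOLE
    if bright is not None:
        labels[bright] = BRIGHT
    return PhaseLabelMap(labels)


def _disc_mask(r, shape=None, center=None):
    shape = shape or (2 * r + 10, 2 * r + 10)
    center = center or (shape[0] // 2, shape[1] // 2)
    m = np.zeros(shape, dtype=bool)
    rr, cc = disk(center, r, shape=shape)
    m[rr, cc] = True
    return m


class TestShapeMetrics:
    def test_perimeter_matches_loop_oracle_on_random_blobs(self, rng):
        for _ in range(25):
            m = oracles.random_blob(rng)
            assert compute_perimeter(m) == pytest.approx(
                oracles.perimeter_loop(m), abs=1e-9)

    def test_sphericity_matches_loop_oracle_on_random_blobs(self, rng):
        for _ in range(25):
            m = oracles.random_blob(rng)
            assert compute_sphericity(m) == pytest.approx(
                oracles.sphericity_loop(m), abs=1e-9)

    def test_disc_sphericity_near_analytic_maximum(self):
        assert compute_sphericity(_disc_mask(30)) == pytest.approx(1.0, abs=0.05)

    def test_square_sphericity_between_disc_and_fiber(self):
        m = np.zeros((60, 60), dtype=bool)
        m[10:50, 10:50] = True
        # analytic pi/4 ~ 0.785; the Crofton estimator runs ~5% short on
        # axis-aligned edges, biasing the quotient high
        assert 0.7 < compute_sphericity(m) < 0.95

    def test_thin_bar_below_neuropil_gate(self):
        m = np.zeros((10, 210), dtype=bool)
        m[4:6, 5:205] = True
        assert compute_sphericity(m) < 0.1

    def test_single_pixel_has_no_division_blowup(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert compute_perimeter(m) >= 4.0
        assert 0 < compute_sphericity(m) <= 1.2

    def test_sphericity_decreases_with_elongation(self):
        values = []
        for length in (20, 60, 120):
            m = np.zeros((20, length + 10), dtype=bool)
            m[8:12, 5:5 + length] = True
            values.append(compute_sphericity(m))
        assert values[0] > values[1] > values[2]

    def test_perimeter_agrees_with_skimage_crofton_estimate(self, rng):
        from skimage.measure import perimeter_crofton

        for _ in range(10):
            m = oracles.random_blob(rng)
            assert compute_perimeter(m) == pytest.approx(
                perimeter_crofton(m, directions=4), rel=0.15)


class TestGates:
    @pytest.mark.parametrize("area,kept", [(999, False), (1000, True)])
    def test_dark_hole_size_gate_strict(self, area, kept):
        assert dark_object_retained(area) is kept

    @pytest.mark.parametrize(
        "area,sph,expected",
        [
            (499, 0.9, ObjectClass.GRANULE_OR_REJECTED),
            (500, 0.09, ObjectClass.NEUROPIL),
            (500, 0.11, ObjectClass.GRANULE_OR_REJECTED),
            (500, 0.49, ObjectClass.GRANULE_OR_REJECTED),
            (500, 0.51, ObjectClass.NUCLEUS),
            (9_999, 0.9, ObjectClass.NUCLEUS),
            (10_001, 0.9, ObjectClass.GRANULE_OR_REJECTED),
            (10_000, 0.9, ObjectClass.GRANULE_OR_REJECTED),  # strict <
        ],
    )
    def test_bright_object_gates_strict(self, area, sph, expected):
        assert bright_object_class(area, sph) is expected


class TestDarkObjects:
    def test_annulus_is_hole_filled_to_a_disc(self):
        outer = _disc_mask(25, shape=(80, 80))
        inner = _disc_mask(10, shape=(80, 80))
        phases = _phases(dark=outer & ~inner, shape=(80, 80))
        objs = extract_dark_objects(phases)
        assert len(objs) == 1
        assert objs[0].area == outer.sum()
        assert objs[0].object_class is ObjectClass.CELL_BODY

    def test_touching_discs_are_split_into_two(self):
        m = np.zeros((120, 200), dtype=bool)
        m |= _disc_mask(20, shape=(120, 200), center=(60, 70))
        m |= _disc_mask(20, shape=(120, 200), center=(60, 108))
        phases = _phases(dark=m, shape=(120, 200))
        objs = extract_dark_objects(phases)
        assert len(objs) == 2
        assert sum(o.area for o in objs) == m.sum()

    @pytest.mark.parametrize("side,kept", [(27, False), (40, True)])
    def test_size_gate_applies_to_extracted_components(self, side, kept):
        # 27x37=999 px rectangle vs 40x40
        m = np.zeros((100, 100), dtype=bool)
        m[10:10 + side, 10:10 + (37 if side == 27 else 40)] = True
        objs = extract_dark_objects(_phases(dark=m, shape=(100, 100)))
        assert (len(objs) == 1) is kept

    def test_empty_phase_gives_empty_set(self):
        assert extract_dark_objects(_phases(shape=(80, 80))) == []


class TestBrightObjects:
    def test_fiber_classified_as_neuropil(self):
        m = np.zeros((60, 420), dtype=bool)
        m[28:31, 10:410] = True
        objs = classify_bright_objects(_phases(bright=m, shape=(60, 420)))
        assert [o.object_class for o in objs] == [ObjectClass.NEUROPIL]

    def test_disc_classified_as_nucleus(self):
        m = _disc_mask(30, shape=(100, 100))
        objs = classify_bright_objects(_phases(bright=m, shape=(100, 100)))
        assert [o.object_class for o in objs] == [ObjectClass.NUCLEUS]

    def test_small_granule_rejected_regardless_of_shape(self):
        m = _disc_mask(12, shape=(60, 60))  # area ~452 < 500
        objs = classify_bright_objects(_phases(bright=m, shape=(60, 60)))
        assert [o.object_class for o in objs] == [ObjectClass.GRANULE_OR_REJECTED]

    def test_every_bright_component_gets_exactly_one_class(self, rng):
        labels = np.zeros((200, 200), dtype=np.uint8)
        for _ in range(8):
            r = int(rng.integers(3, 25))
            cy, cx = rng.integers(30, 170, 2)
            rr, cc = disk((cy, cx), r, shape=(200, 200))
            labels[rr, cc] = BRIGHT
        phases = PhaseLabelMap(labels)
        objs = classify_bright_objects(phases)
        total = sum(o.area for o in objs)
        assert total == (labels == BRIGHT).sum()
        assert all(o.object_class in {ObjectClass.NEUROPIL, ObjectClass.NUCLEUS,
                                      ObjectClass.GRANULE_OR_REJECTED}
                   for o in objs)

    def test_hough_candidates_pass_area_gate_only(self):
        small = make_object(_disc_mask(10, shape=(60, 60)), 0,
                            PhaseOrigin.HOUGH, ObjectClass.NUCLEUS_CANDIDATE)
        huge = make_object(_disc_mask(60, shape=(140, 140)), 1,
                           PhaseOrigin.HOUGH, ObjectClass.NUCLEUS_CANDIDATE)
        objs = classify_bright_objects(_phases(shape=(140, 140)),
                                       hough=[small, huge])
        by_origin = {o.id: o.object_class for o in objs}
        assert by_origin[0] is ObjectClass.NUCLEUS  # 314 px, bypasses 500 gate
        assert by_origin[1] is ObjectClass.GRANULE_OR_REJECTED  # >= 10000 px


class TestSplitting:
    def test_split_preserves_pixels(self, rng):
        for _ in range(10):
            m = oracles.random_blob(rng, size=64)
            labels = split_touching(m)
            assert (labels > 0).sum() == m.sum()
            assert not (labels[~m] > 0).any()

    def test_split_never_merges_distinct_parents(self):
        m = np.zeros((60, 140), dtype=bool)
        m |= _disc_mask(15, shape=(60, 140), center=(30, 30))
        m |= _disc_mask(15, shape=(60, 140), center=(30, 100))
        labels = split_touching(m)
        assert labels[30, 30] != labels[30, 100]


class TestAssembly:
    def _body(self, oid=0, center=(40, 40)):
        return make_object(_disc_mask(20, shape=(120, 120), center=center),
                           oid, PhaseOrigin.DARK_HOLE, ObjectClass.CELL_BODY)

    def _nucleus(self, oid=10, center=(40, 40), r=8):
        return make_object(_disc_mask(r, shape=(120, 120), center=center),
                           oid, PhaseOrigin.BRIGHT, ObjectClass.NUCLEUS)

    def test_contained_nucleus_merges_and_area_is_union(self):
        body, nuc = self._body(), self._nucleus()
        out = assemble_cells([body], [nuc], (120, 120))
        assert len(out) == 1
        union = body.full_mask((120, 120)) | nuc.full_mask((120, 120))
        assert out[0].combined_area == union.sum()
        assert out[0].nucleus_object_ids == [10]

    def test_distant_nucleus_stays_standalone(self):
        body = self._body(center=(30, 30))
        nuc = self._nucleus(center=(90, 90))
        out = assemble_cells([body], [nuc], (120, 120))
        assert len(out) == 2
        standalone = [a for a in out if a.cytoplasm_object_id is None]
        assert len(standalone) == 1
        assert standalone[0].nucleus_object_ids == [10]

    def test_equidistant_tie_goes_to_lower_body_id(self):
        r0 = np.zeros((120, 120), dtype=bool)
        r0[20:60, 10:51] = True  # right edge at col 50
        r1 = np.zeros((120, 120), dtype=bool)
        r1[20:60, 54:95] = True  # left edge at col 54
        b0 = make_object(r0, 0, PhaseOrigin.DARK_HOLE, ObjectClass.CELL_BODY)
        b1 = make_object(r1, 1, PhaseOrigin.DARK_HOLE, ObjectClass.CELL_BODY)
        nuc = self._nucleus(center=(40, 52), r=5)  # centroid 2 px from both
        out = assemble_cells([b0, b1], [nuc], (120, 120))
        assert len(out) == 2
        merged = {a.cytoplasm_object_id: a.nucleus_object_ids for a in out}
        assert merged[0] == [10]
        assert merged[1] == []
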