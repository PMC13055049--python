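"""Annotation resolution, tiling/stitching, and consensus voting."""

import collections

import numpy as np
import pytest
from skimage.draw import polygon2mask

from zfinject import segmentation as sg


def _rect(x0, y0, x1, y1):
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


class TestResolveOverlaps:
    def test_eye_wins_over_larva_body(self):
        ann = sg.AnnotationSet(
            regions=[(_rect(0, 0, 20, 20), "body"), (_rect(5, 5, 10, 10), "eye")]
        )
        lm = sg.resolve_overlaps(ann, (30, 30))
        assert lm.classes[lm.raster[7, 7]] == "eye"
        assert lm.classes[lm.raster[15, 15]] == "body"

    def test_uncovered_pixels_are_background(self):
        ann = sg.AnnotationSet(regions=[(_rect(5, 5, 10, 10), "yolk")])
        lm = sg.resolve_overlaps(ann, (20, 20))
        assert lm.classes[lm.raster[0, 0]] == "background"

    def test_triple_overlap_matches_brute_force(self, rng):
        for _ in range(10):
            names = list(rng.choice(
                ["body", "eye", "yolk", "swim_bladder", "duct_of_cuvier"], size=3,
                replace=False,
            ))
            regions = []
            for name in names:
                x0, y0 = rng.uniform(0, 15, 2)
                w, h = rng.uniform(5, 15, 2)
                regions.append((_rect(x0, y0, x0 + w, y0 + h), name))
            ann = sg.AnnotationSet(regions=regions)
            lm = sg.resolve_overlaps(ann, (32, 32))
            # brute force: per-pixel scan over per-region masks
            masks = [
                (polygon2mask((32, 32), np.asarray(p)[:, ::-1]), n)
                for p, n in regions
            ]
            rank = {c: i for i, c in enumerate(sg.PRIORITY)}
            for y in range(32):
                for x in range(32):
                    covering = [n for m, n in masks if m[y, x]]
                    expect = (
                        min(covering, key=rank.__getitem__)
                        if covering
                        else "background"
                    )
                    assert lm.classes[lm.raster[y, x]] == expect

    def test_order_independent_and_idempotent(self, rng):
        regions = [
            (_rect(0, 0, 25, 25), "body"),
            (_rect(3, 3, 12, 12), "eye"),
            (_rect(8, 8, 20, 20), "yolk"),
        ]
        base = sg.resolve_overlaps(sg.AnnotationSet(regions=list(regions)), (30, 30))
        for _ in range(5):
            perm = [regions[i] for i in rng.permutation(3)]
            again = sg.resolve_overlaps(sg.AnnotationSet(regions=perm), (30, 30))
            assert np.array_equal(base.raster, again.raster)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            sg.AnnotationSet(regions=[(np.array([[0, 0], [1, 1]]), "eye")])


class TestArgmax:
    def test_one_hot_is_identity(self, rng):
        labels = rng.integers(0, 4, size=(8, 8))
        prob = sg.ProbabilityMap(("a", "b", "c", "d"), np.eye(4)[labels])
        assert np.array_equal(sg.argmax_classes(prob).raster, labels)

    def test_picks_highest_score(self):
        prob = sg.ProbabilityMap(
            ("a", "b", "c"), np.array([[[0.2, 0.5, 0.3]]])
        )
        assert sg.argmax_classes(prob).raster[0, 0] == 1

    def test_tie_breaks_to_lowest_index(self):
        prob = sg.ProbabilityMap(("a", "b"), np.array([[[0.5, 0.5]]]))
        assert sg.argmax_classes(prob).raster[0, 0] == 0

    def test_non_finite_scores_rejected(self):
        prob = sg.ProbabilityMap(("a", "b"), np.array([[[np.nan, 0.5]]]))
        with pytest.raises(ValueError):
            sg.argmax_classes(prob)


class TestTiling:
    @pytest.mark.parametrize(
        "shape,expected_x,expected_y",
        [
            ((304, 304), [0], [0]),
            ((304, 812), [0, 254, 508], [0]),
            ((400, 400), [0, 96], [0, 96]),
        ],
    )
    def test_tile_offsets(self, shape, expected_x, expected_y):
        tiles = sg.tile_image(np.zeros(shape), sg.TilingScheme())
        assert sorted({t.offset[0] for t in tiles}) == expected_x
        assert sorted({t.offset[1] for t in tiles}) == expected_y
        assert all(t.data.shape == (304, 304) for t in tiles)

    def test_small_image_reflect_padded(self):
        tiles = sg.tile_image(np.zeros((100, 120)), sg.TilingScheme())
        assert len(tiles) == 1
        assert tiles[0].pad == (304 - 120, 304 - 100)
        assert tiles[0].data.shape == (304, 304)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            sg.TilingScheme(tile_size=100, overlap=100)


class TestStitching:
    def test_single_tile_identity(self, rng):
        pm = sg.ProbabilityMap(("a", "b"), rng.random((304, 304, 2)))
        out = sg.stitch_segmentations([(pm, (0, 0))], sg.TilingScheme(), (304, 304))
        assert np.array_equal(out.raster, pm.raster)

    def test_conflicting_tiles_split_at_midline(self):
        """Two overlapping constant tiles: assignment boundary at the
        midline between tile centers, verified per pixel by brute force."""
        scheme = sg.TilingScheme(tile_size=8, overlap=4)
        a = sg.ProbabilityMap(("a", "b"), np.tile([1.0, 0.0], (8, 8, 1)))
        b = sg.ProbabilityMap(("a", "b"), np.tile([0.0, 1.0], (8, 8, 1)))
        tiles = [(a, (0, 0)), (b, (4, 0))]
        out = sg.stitch_segmentations(tiles, scheme, (12, 8))
        labels = np.argmax(out.raster, axis=2)
        centers = [(0 + 3.5, 3.5), (4 + 3.5, 3.5)]
        for y in range(8):
            for x in range(12):
                covering = [
                    (i, (x - cx) ** 2 + (y - cy) ** 2)
                    for i, ((cx, cy), ox) in enumerate(zip(centers, [0, 4]))
                    if ox <= x < ox + 8
                ]
                best = min(covering, key=lambda t: t[1])[0]
                assert labels[y, x] == best

    def test_uncovered_pixel_rejected(self):
        pm = sg.ProbabilityMap(("a",), np.ones((8, 8, 1)))
        with pytest.raises(ValueError):
            sg.stitch_segmentations(
                [(pm, (0, 0))], sg.TilingScheme(tile_size=8, overlap=2), (20, 8)
            )

    def test_tiled_pipeline_equals_whole_image(self, segmenter, small_plate):
        """A pixel-wise segmenter is translation-consistent, so tile ->
        segment -> stitch must reproduce whole-image segmentation exactly."""
        whole = sg.argmax_classes(segmenter(small_plate.image))
        tiled = sg.argmax_classes(sg.segment_tiled(small_plate.image, segmenter))
        assert np.array_equal(whole.raster, tiled.raster)

    def test_stitch_never_invents_classes(self, segmenter, small_plate):
        tiled = sg.argmax_classes(sg.segment_tiled(small_plate.image, segmenter))
        whole = sg.argmax_classes(segmenter(small_plate.image))
        assert set(np.unique(tiled.raster)) <= set(np.unique(whole.raster))


def _positional_segmenter(classes=("background", "body", "eye")):
    """Deterministic but deliberately non-equivariant segmenter: scores
    depend on intensity and pixel position, so the six TTA branches
    disagree and ties genuinely occur."""

    n = len(classes)

    def seg(img):
        img = np.asarray(img, dtype=np.float64)
        h, w = img.shape
        yy, xx = np.mgrid[0:h, 0:w]
        raster = np.empty((h, w, n))
        for k in range(n):
            raster[..., k] = np.round(
                np.sin(img * 0.37 + xx * 0.11 + yy * 0.23 + k * 1.7), 1
            )
        return sg.ProbabilityMap(classes, raster)

    return seg


class TestTTAConsensus:
    def test_equivariant_segmenter_consensus_equals_plain(self, segmenter, small_plate):
        img = small_plate.image[:256, :256]
        plain = sg.argmax_classes(segmenter(img))
        cons = sg.tta_consensus(segmenter, img)
        assert np.array_equal(plain.raster, cons.raster)

    def test_majority_and_tie_rules(self):
        classes = ("background", "body", "eye", "yolk")
        votes = np.array([[[2]], [[2]], [[2]], [[2]], [[1]], [[1]]])
        assert sg.vote_consensus(votes.reshape(6, 1, 1), classes)[0, 0] == 2
        # 3-3 split between eye (idx 2) and body (idx 1): eye outranks
        votes = np.array([2, 2, 2, 1, 1, 1]).reshape(6, 1, 1)
        assert sg.vote_consensus(votes, classes)[0, 0] == 2

    def test_consensus_matches_brute_force_vote(self, rng):
        seg = _positional_segmenter()
        classes = ("background", "body", "eye")
        rank = {c: i for i, c in enumerate(sg.PRIORITY)}
        for trial in range(5):
            img = rng.integers(0, 255, size=(32, 32)).astype(float)
            got = sg.tta_consensus(seg, img)
            # brute force: redo the transform loop and vote with a Counter
            stacks = []
            for fwd, inv in sg.TTA_TRANSFORMS:
                labels = np.argmax(seg(fwd(img)).raster, axis=2)
                stacks.append(inv(labels))
            for y in range(32):
                for x in range(32):
                    c = collections.Counter(int(s[y, x]) for s in stacks)
                    top = max(c.values())
                    cands = [k for k, v in c.items() if v == top]
                    expect = min(cands, key=lambda i: rank[classes[i]])
                    assert got.raster[y, x] == expect

    def test_non_square_image_handled(self, segmenter, small_plate):
        img = small_plate.image[:200, :300]
        cons = sg.tta_consensus(segmenter, img)
        assert cons.raster.shape == (200, 300)
        plain = sg.argmax_classes(segmenter(img))
        assert np.array_equal(plain.raster, cons.raster)


class TestLargestComponent:
    def test_keeps_biggest_of_two(self):
        raster = np.zeros((20, 20), dtype=int)
        raster[1:3, 1:6] = 1  # 10 px
        raster[10:15, 10:15] = 1  # 25 px
        lm = sg.LabelMap(("background", "body"), raster)
        res = sg.largest_component(lm, "body")
        assert res.present and res.mask.sum() == 25
        assert res.mask[12, 12] and not res.mask[1, 1]

    def test_single_component_is_itself(self):
        raster = np.zeros((5, 5), dtype=int)
        raster[1:4, 1:4] = 1
        lm = sg.LabelMap(("background", "body"), raster)
        assert sg.largest_component(lm, "body").mask.sum() == 9

    def test_absent_class_flagged(self):
        lm = sg.LabelMap(("background", "body"), np.zeros((5, 5), dtype=int))
        res = sg.largest_component(lm, "body")
        assert not res.present and not res.mask.any()


class TestAugment:
    def test_same_seed_identical(self, single_larva_plate):
        p = single_larva_plate
        a = sg.augment(p.image, p.truth, seed=5)
        b = sg.augment(p.image, p.truth, seed=5)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1].raster, b[1].raster)

    def test_class_histogram_preserved(self, single_larva_plate):
        p = single_larva_plate
        _, lab = sg.augment(p.image, p.truth, seed=9)
        assert np.array_equal(
            np.bincount(lab.raster.ravel(), minlength=8),
            np.bincount(p.truth.raster.ravel(), minlength=8),
        )

    def test_geometry_applied_consistently(self, single_larva_plate):
        """Eye pixels stay dark after augmentation: image and labels moved
        together."""
        p = single_larva_plate
        img, lab = sg.augment(p.image.astype(float), p.truth, seed=3)
        eye = lab.mask("eye")
        assert img[eye].mean() < img[lab.mask("background")].mean() - 50
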