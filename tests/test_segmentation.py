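"""Thresholding, level-set evolution, staged segmentation and its evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from oracles import connected_components_oracle, li_oracle, otsu_oracle

from gliaquant import segmentation as seg
from gliaquant import synthetic as syn
from gliaquant.config import SegmentationConfig
from gliaquant.types import (
    MEMBRANE_MARKERS,
    CellRecord,
    ComponentImage,
    ConfigError,
    GliaquantError,
    LabelMask,
    LevelSetParams,
    MaskKind,
)


def membrane_image(plane, extra=None):
    """ComponentImage whose four membrane channels sum to `plane`."""
    planes = {m: np.asarray(plane, float) / 4.0 for m in MEMBRANE_MARKERS}
    if extra:
        planes.update(extra)
    return ComponentImage(planes=planes)


class TestThresholds:
    def test_otsu_bimodal_halves(self):
        img = np.zeros((20, 20)) + 10.0
        img[10:, :] = 200.0
        t, mask = seg.otsu_threshold(img)
        assert 10 < t < 200
        np.testing.assert_array_equal(mask, img == 200.0)

    @pytest.mark.parametrize("fn", [seg.otsu_threshold, seg.li_threshold])
    def test_constant_image_rejected(self, fn):
        with pytest.raises(GliaquantError):
            fn(np.full((8, 8), 7.0))

    def test_otsu_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            t_ref = otsu_oracle(img)
            t, mask = seg.otsu_threshold(img)
            np.testing.assert_array_equal(mask, img > t_ref)

    def test_li_matches_fixed_point_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            img = rng.integers(1, 256, (64, 64)).astype(np.uint8)
            t_ref = li_oracle(img)
            t, mask = seg.li_threshold(img)
            np.testing.assert_array_equal(mask, img > t_ref)

    def test_li_below_otsu_under_bright_outliers(self):
        img = np.full((64, 64), 10.0)
        img[10:60, 5:7] = 255.0  # small very bright structure
        img[30:36, 30:36] = 30.0  # dim blob of interest
        t_li, _ = seg.li_threshold(img)
        t_otsu, _ = seg.otsu_threshold(img)
        assert t_li < t_otsu

    def test_li_and_otsu_agree_on_clean_bimodal(self):
        img = np.where(np.indices((64, 64)).sum(0) % 2 == 0, 10.0, 200.0)
        _, m1 = seg.otsu_threshold(img)
        _, m2 = seg.li_threshold(img)
        np.testing.assert_array_equal(m1, m2)


def _disk_image(shape=(80, 80), radius=18, fg=200.0, bg=10.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    disk = (yy - shape[0] // 2) ** 2 + (xx - shape[1] // 2) ** 2 <= radius**2
    return np.where(disk, fg, bg), disk


class TestLevelSet:
    def test_recovers_clean_disk(self):
        img, disk = _disk_image()
        _, init = seg.otsu_threshold(img)
        mask = seg.evolve_level_set(img, init, LevelSetParams())
        assert seg.dice_index(mask, disk) >= 0.99

    def test_true_region_is_fixed_point(self):
        img, disk = _disk_image()
        mask = seg.evolve_level_set(img, disk, LevelSetParams())
        np.testing.assert_array_equal(mask, disk)

    def test_area_penalty_monotone(self):
        rng = np.random.default_rng(0)
        img, _ = _disk_image(fg=10.0, bg=2.0)
        img = np.clip(img + rng.normal(0, 1.5, img.shape), 0, None)
        _, init = seg.otsu_threshold(img)
        areas = [
            int(seg.evolve_level_set(img, init, LevelSetParams(nu=2.0, mu=mu)).sum())
            for mu in (2.0, 3.0, 6.0, 30.0)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_perimeter_penalty_smooths(self):
        from skimage.measure import perimeter

        rng = np.random.default_rng(0)
        img, _ = _disk_image(fg=10.0, bg=2.0)
        img = np.clip(img + rng.normal(0, 1.5, img.shape), 0, None)
        _, init = seg.otsu_threshold(img)
        rough = seg.evolve_level_set(img, init, LevelSetParams(nu=0.0, mu=0.0))
        smooth = seg.evolve_level_set(img, init, LevelSetParams(nu=30.0, mu=0.0))
        assert perimeter(smooth) <= perimeter(rough)

    def test_empty_init_rejected(self):
        img, _ = _disk_image()
        with pytest.raises(GliaquantError):
            seg.evolve_level_set(img, np.zeros_like(img, bool), LevelSetParams())


def _nuclei_image(radii, shape=(160, 160), amp=150.0):
    """DAPI plane with one disk per radius, on a faint background."""
    rng = np.random.default_rng(42)
    img = np.full(shape, 3.0)
    truth = np.zeros(shape, int)
    centers = [(25 + 35 * (i // 4), 25 + 35 * (i % 4)) for i in range(len(radii))]
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for i, (r, (cy, cx)) in enumerate(zip(radii, centers), start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[disk] = amp
        truth[disk] = i
    img = np.clip(img + rng.normal(0, 2.0, shape), 0, None)
    return img, truth


class TestNuclei:
    def test_large_nuclei_recovered(self):
        img, truth = _nuclei_image([5, 5, 6, 5, 6, 5, 5, 6, 5, 6])  # areas >= 60 px
        image = ComponentImage(planes={"DAPI": img})
        out = seg.segment_nuclei(image, SegmentationConfig())
        assert out.n_labels == 10
        for t in range(1, 11):
            tm = truth == t
            overlapping = np.unique(out.labels[tm])
            overlapping = overlapping[overlapping > 0]
            assert len(overlapping) == 1
            assert seg.dice_index(out.labels == overlapping[0], tm) >= 0.8

    def test_small_nucleus_filtered(self):
        # a ~25 px nucleus is below the 30 px minimum and must vanish
        img, truth = _nuclei_image([5, 5, 5, 2.6])
        assert 20 <= (truth == 4).sum() < 30
        image = ComponentImage(planes={"DAPI": img})
        out = seg.segment_nuclei(image, SegmentationConfig())
        assert out.n_labels == 3
        assert not out.binary()[truth == 4].any()

    def test_blank_plane_yields_empty_mask(self):
        image = ComponentImage(planes={"DAPI": np.zeros((32, 32))})
        out = seg.segment_nuclei(image, SegmentationConfig())
        assert out.n_labels == 0


class TestMembraneSum:
    def test_constant_planes(self):
        planes = {m: np.full((8, 8), v) for m, v in zip(MEMBRANE_MARKERS, (1.0, 2.0, 3.0, 4.0))}
        img = ComponentImage(planes=planes)
        np.testing.assert_array_equal(seg.membrane_sum(img), np.full((8, 8), 10.0))

    def test_single_nonzero_plane(self):
        rng = np.random.default_rng(0)
        ftl = rng.uniform(0, 5, (8, 8))
        planes = {m: np.zeros((8, 8)) for m in MEMBRANE_MARKERS}
        planes["FTL"] = ftl
        np.testing.assert_array_equal(seg.membrane_sum(ComponentImage(planes=planes)), ftl)

    def test_random_planes_match_elementwise_addition(self):
        rng = np.random.default_rng(1)
        planes = {m: rng.uniform(0, 9, (16, 16)) for m in MEMBRANE_MARKERS}
        expected = sum(planes.values())
        np.testing.assert_allclose(seg.membrane_sum(ComponentImage(planes=planes)), expected)

    def test_missing_plane_rejected(self):
        img = ComponentImage(planes={"FTL": np.ones((4, 4))})
        with pytest.raises(ConfigError):
            seg.membrane_sum(img)


def _soma_scene(n=8, radius=6, shape=(200, 200), amp=200.0, speck=False):
    img = np.full(shape, 5.0)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    centers = [(30 + 45 * (i // 4), 30 + 45 * (i % 4)) for i in range(n)]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = amp
    if speck:
        img[180:187, 180:187] = amp  # 49 px, below the 50 px soma minimum
    return img


class TestSomas:
    def test_eight_somas_recovered(self):
        image = membrane_image(_soma_scene())
        out = seg.segment_somas(image, SegmentationConfig())
        assert out.n_labels == 8

    def test_subminimum_speck_removed(self):
        image = membrane_image(_soma_scene(speck=True))
        out = seg.segment_somas(image, SegmentationConfig())
        assert out.n_labels == 8  # speck (49 px) filtered, 8 somas remain
        assert not out.binary()[180:187, 180:187].any()

    def test_separated_somas_get_distinct_labels(self):
        img = np.full((60, 60), 5.0)
        img[10:20, 10:20] = 200.0
        img[10:20, 25:35] = 200.0  # > 2 px gap
        out = seg.segment_somas(membrane_image(img), SegmentationConfig())
        assert out.n_labels == 2


class TestVessels:
    def test_size_rule_strictly_greater(self):
        af = np.full((200, 200), 5.0)
        af[10:60, 20:140] = 200.0  # 50x120 = 6000 px vessel
        af[100:110, 100:110] = 200.0  # 100 px speck
        image = ComponentImage(planes={"DAPI": np.zeros((200, 200)), "autofluorescence": af})
        out = seg.detect_vessels(image, SegmentationConfig())
        assert out.n_labels == 1
        assert (np.bincount(out.labels.ravel())[1:] > 4000).all()

        af2 = np.full((200, 200), 5.0)
        af2[10:60, 20:100] = 200.0  # exactly 50x80 = 4000 px: excluded
        image2 = ComponentImage(planes={"DAPI": np.zeros((200, 200)), "autofluorescence": af2})
        assert seg.detect_vessels(image2, SegmentationConfig()).n_labels == 0

    def test_missing_channel_gives_empty_mask(self):
        image = ComponentImage(planes={"DAPI": np.ones((16, 16))})
        assert seg.detect_vessels(image, SegmentationConfig()).n_labels == 0


class TestCytoplasm:
    def test_finer_pass_contains_somas(self):
        image = membrane_image(_soma_scene())
        cfg = SegmentationConfig()
        somas = seg.segment_somas(image, cfg)
        empty_vessels = LabelMask(np.zeros(image.shape, int), MaskKind.vessel)
        comps = seg.segment_cytoplasm(image, somas, empty_vessels, cfg)
        assert (comps.binary() & somas.binary()).sum() == somas.binary().sum()

    def test_vessel_pixels_excluded(self):
        plane = _soma_scene(n=4)
        af = np.full(plane.shape, 5.0)
        af[100:150, 20:180] = 220.0  # 8000 px vessel
        # vessel autofluorescence bleeds into the membrane channels
        image = membrane_image(plane + np.where(af > 100, 180.0, 0.0), extra={"autofluorescence": af})
        cfg = SegmentationConfig()
        somas = seg.segment_somas(image, cfg)
        vessels = seg.detect_vessels(image, cfg)
        assert vessels.n_labels == 1
        comps = seg.segment_cytoplasm(image, somas, vessels, cfg)
        assert not (comps.binary() & vessels.binary()).any()

    def test_blank_membrane_yields_empty(self):
        image = membrane_image(np.zeros((32, 32)))
        cfg = SegmentationConfig()
        empty = LabelMask(np.zeros((32, 32), int), MaskKind.vessel)
        somas = LabelMask(np.zeros((32, 32), int), MaskKind.soma)
        assert seg.segment_cytoplasm(image, somas, empty, cfg).n_labels == 0


class TestAssignment:
    def _masks(self, comp_labels, soma_labels):
        return (
            LabelMask(np.asarray(comp_labels), MaskKind.component),
            LabelMask(np.asarray(soma_labels), MaskKind.soma),
        )

    def test_single_component_with_soma(self):
        comp = np.zeros((10, 10), int)
        comp[2:8, 2:8] = 1
        soma = np.zeros((10, 10), int)
        soma[4:6, 4:6] = 1
        comps, somas = self._masks(comp, soma)
        res = seg.assign_components(comps, somas)
        assert len(res.orphans) == 0 and len(res.shared) == 0
        assert res.cells[1][2:8, 2:8].all()

    def test_orphan_component(self):
        comp = np.zeros((10, 20), int)
        comp[2:8, 2:8] = 1
        comp[2:8, 12:18] = 2
        soma = np.zeros((10, 20), int)
        soma[4:6, 4:6] = 1
        res = seg.assign_components(*self._masks(comp, soma))
        assert len(res.orphans) == 1
        assert res.orphans[0][2:8, 12:18].all()

    def test_shared_component_deferred(self):
        comp = np.zeros((10, 20), int)
        comp[2:8, 2:18] = 1
        soma = np.zeros((10, 20), int)
        soma[4:6, 3:5] = 1
        soma[4:6, 15:17] = 2
        res = seg.assign_components(*self._masks(comp, soma))
        assert len(res.shared) == 1
        assert 1 in res.cells and 2 in res.cells  # somas stay their own cells


class TestWatershed:
    def _dumbbell(self):
        yy, xx = np.mgrid[:40, :80]
        lobe1 = (yy - 20) ** 2 + (xx - 20) ** 2 <= 12**2
        lobe2 = (yy - 20) ** 2 + (xx - 60) ** 2 <= 12**2
        bridge = (np.abs(yy - 20) <= 2) & (xx >= 20) & (xx <= 60)
        comp = lobe1 | lobe2 | bridge
        soma = np.zeros((40, 80), int)
        soma[(yy - 20) ** 2 + (xx - 20) ** 2 <= 4**2] = 1
        soma[(yy - 20) ** 2 + (xx - 60) ** 2 <= 4**2] = 2
        return comp, LabelMask(soma, MaskKind.soma), lobe1, lobe2

    def test_dumbbell_splits_by_lobe(self):
        comp, somas, lobe1, lobe2 = self._dumbbell()
        parts = seg.split_shared_cytoplasm(comp, somas)
        assert not (lobe1 & ~parts[1]).any()
        assert not (lobe2 & ~parts[2]).any()

    def test_symmetric_split_balanced(self):
        comp, somas, _, _ = self._dumbbell()
        parts = seg.split_shared_cytoplasm(comp, somas)
        # symmetric geometry: sizes differ at most by the midline tie band
        assert abs(int(parts[1].sum()) - int(parts[2].sum())) <= 10

    def test_partition_conserves_pixels(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            blob = np.zeros((60, 60), bool)
            for _ in range(3):
                cy, cx = rng.integers(15, 45, 2)
                yy, xx = np.mgrid[:60, :60]
                blob |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rng.integers(8, 14) ** 2
            lab, n = ndi.label(blob, structure=ndi.generate_binary_structure(2, 2))
            comp = lab == np.argmax(np.bincount(lab.ravel())[1:]) + 1
            soma = np.zeros((60, 60), int)
            pts = np.argwhere(comp)
            for sid, i in enumerate(rng.choice(len(pts), 3, replace=False), start=1):
                cy, cx = pts[i]
                yy, xx = np.mgrid[:60, :60]
                soma[((yy - cy) ** 2 + (xx - cx) ** 2 <= 4) & comp] = sid
            ids = np.unique(soma[soma > 0])
            if len(ids) < 2:
                continue
            parts = seg.split_shared_cytoplasm(comp, LabelMask(soma, MaskKind.soma))
            union = np.zeros_like(comp)
            for a in parts.values():
                assert not (union & a).any()  # pairwise disjoint
                union |= a
            np.testing.assert_array_equal(union, comp)

    def test_single_soma_rejected(self):
        comp = np.ones((10, 10), bool)
        soma = np.zeros((10, 10), int)
        soma[4:6, 4:6] = 1
        with pytest.raises(GliaquantError):
            seg.split_shared_cytoplasm(comp, LabelMask(soma, MaskKind.soma))


class TestProcessAttachment:
    def _scene(self, orphan_col, soma2_col=None):
        shape = (40, 80)
        soma = np.zeros(shape, int)
        soma[18:23, 8:13] = 1  # soma 1, right edge at col 12
        if soma2_col is not None:
            soma[18:23, soma2_col : soma2_col + 5] = 2
        soma_mask = LabelMask(soma, MaskKind.soma)
        cells = {sid: soma == sid for sid in np.unique(soma[soma > 0])}
        orphan = np.zeros(shape, bool)
        orphan[20, orphan_col] = True
        return cells, [orphan], soma_mask

    def test_orphan_at_9px_attached(self):
        cells, orphans, soma_mask = self._scene(orphan_col=12 + 9)
        _, procs = seg.attach_processes(cells, orphans, soma_mask, radius_px=10.0)
        assert procs[1][20, 21]

    def test_orphan_at_11px_discarded(self):
        cells, orphans, soma_mask = self._scene(orphan_col=12 + 11)
        _, procs = seg.attach_processes(cells, orphans, soma_mask, radius_px=10.0)
        assert not procs[1].any()

    def test_equidistant_orphan_goes_to_lower_id(self):
        # soma 1 right edge col 12, soma 2 left edge col 28; orphan at col 20
        cells, orphans, soma_mask = self._scene(orphan_col=20, soma2_col=28)
        _, procs = seg.attach_processes(cells, orphans, soma_mask, radius_px=10.0)
        assert procs[1][20, 20]
        assert not procs[2].any()


class TestPlaques:
    def _plaque_scene(self, seed):
        rng = np.random.default_rng(seed)
        shape = (160, 160)
        abeta = np.full(shape, 4.0)
        truth = np.zeros(shape, int)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        for pid, (cy, cx, r) in enumerate([(40, 40, 12), (110, 60, 15), (60, 120, 10)], 1):
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            abeta[disk] = 150.0
            truth[disk] = pid
        abeta = np.clip(abeta + rng.normal(0, 3.0, shape), 0, None)
        planes = {m: np.zeros(shape) for m in MEMBRANE_MARKERS}
        planes["Abeta"] = abeta
        return ComponentImage(planes=planes), truth

    def test_threshold_mode_recovers_blobs(self):
        image, truth = self._plaque_scene(0)
        out = seg.identify_plaques(image, SegmentationConfig())
        assert out.n_labels == 3
        for t in range(1, 4):
            tm = truth == t
            lab = np.unique(out.labels[tm])
            lab = lab[lab > 0]
            assert len(lab) == 1
            assert seg.dice_index(out.labels == lab[0], tm) >= 0.8

    def test_blank_plane_empty_mask(self):
        planes = {m: np.zeros((32, 32)) for m in MEMBRANE_MARKERS}
        planes["Abeta"] = np.zeros((32, 32))
        out = seg.identify_plaques(ComponentImage(planes=planes), SegmentationConfig())
        assert out.n_labels == 0

    def test_classifier_generalizes_across_fixtures(self):
        train_img, train_truth = self._plaque_scene(1)
        test_img, test_truth = self._plaque_scene(2)
        fg = train_truth > 0
        bg = ndi.binary_dilation(fg, iterations=6) ^ fg
        bg |= np.random.default_rng(0).random(fg.shape) < 0.02
        bg &= ~fg
        clf = seg.PlaqueClassifier(seed=0).fit(
            [train_img.plane("Abeta")], [fg], [bg]
        )
        cfg = SegmentationConfig(plaque_mode="classifier")
        out = seg.identify_plaques(test_img, cfg, classifier=clf)
        # every truth plaque found, no spurious components above min area
        found = set()
        for t in np.unique(test_truth[test_truth > 0]):
            lab = np.unique(out.labels[test_truth == t])
            lab = lab[lab > 0]
            assert len(lab) >= 1
            found.update(int(v) for v in lab)
        assert found == set(int(v) for v in out.label_ids())

    def test_classifier_mode_requires_model(self):
        image, _ = self._plaque_scene(0)
        with pytest.raises(ConfigError):
            seg.identify_plaques(image, SegmentationConfig(plaque_mode="classifier"))


class TestDice:
    def test_hand_values(self):
        a = {(0, i) for i in range(4)}
        b = {(0, i) for i in range(1, 7)}
        assert seg.dice_index(a, b) == pytest.approx(0.6)
        assert seg.dice_index(a, a) == 1.0
        assert seg.dice_index(a, {(9, 9)}) == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(GliaquantError):
            seg.dice_index(set(), set())

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_bounded_and_identity(self, s):
        rng = np.random.default_rng(s)
        a = rng.random((12, 12)) < 0.4
        b = rng.random((12, 12)) < 0.4
        if not (a.any() or b.any()):
            return
        d = seg.dice_index(a, b)
        assert 0.0 <= d <= 1.0
        assert d == seg.dice_index(b, a)
        assert (d == 1.0) == np.array_equal(a, b)


def _cell_from_mask(mask, cell_id):
    return CellRecord(
        cell_id=cell_id,
        soma_pixels=frozenset(map(tuple, np.argwhere(mask))),
        cytoplasm_pixels=frozenset(),
        process_pixels=frozenset(),
        mean_intensity={m: 1.0 for m in MEMBRANE_MARKERS},
    )


class TestMatchCells:
    def test_perfect_predictions(self):
        labels = np.zeros((30, 30), int)
        for i in range(5):
            labels[6 * i : 6 * i + 4, 2:6] = i + 1
        truth = LabelMask(labels, MaskKind.cell)
        preds = [_cell_from_mask(labels == i + 1, i + 1) for i in range(5)]
        res = seg.match_cells(preds, truth)
        assert (res.n_correct, res.n_false_positive, res.n_false_negative) == (5, 0, 0)
        assert all(d == 1.0 for d in res.per_cell_dice)

    def test_no_predictions_all_false_negative(self):
        labels = np.zeros((30, 30), int)
        for i in range(5):
            labels[6 * i : 6 * i + 4, 2:6] = i + 1
        res = seg.match_cells([], LabelMask(labels, MaskKind.cell))
        assert res.n_false_negative == 5 and res.n_correct == 0

    def test_graded_overlaps(self):
        # three 20x20 truth squares; predictions shifted for Dice 0.9 / 0.7 / 0.2
        labels = np.zeros((30, 200), int)
        for i, col in enumerate((10, 70, 130), start=1):
            labels[0:20, col : col + 20] = i
        truth = LabelMask(labels, MaskKind.cell)
        shifts = {1: 2, 2: 6, 3: 16}
        preds = []
        for i, col in zip((1, 2, 3), (10, 70, 130)):
            m = np.zeros_like(labels, bool)
            m[shifts[i] : 20 + shifts[i], col : col + 20] = True
            preds.append(_cell_from_mask(m, i))
        res = seg.match_cells(preds, truth, match_dice_min=0.5)
        assert (res.n_correct, res.n_false_positive, res.n_false_negative) == (2, 1, 1)
        assert sorted(round(d, 6) for d in res.per_cell_dice) == [0.7, 0.9]


class TestSegmentImage:
    def test_pure_noise_yields_no_cells(self):
        image, _ = syn.generate_image((128, 128), [], noise_sd=4.0, seed=0)
        cells, plaques, vessels = seg.segment_image(image)
        assert cells == []

    def test_deterministic(self):
        image, _ = syn.generate_image(
            (192, 192), syn.default_cell_specs(5, np.random.default_rng(0)), seed=5
        )
        a, pa, va = seg.segment_image(image)
        b, pb, vb = seg.segment_image(image)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.all_pixels() == cb.all_pixels()
            assert ca.mean_intensity == cb.mean_intensity
        np.testing.assert_array_equal(pa.labels, pb.labels)

    def test_cells_are_pixel_disjoint(self, benchmark_results):
        for image, _, cells, _, _ in benchmark_results:
            owned = np.zeros(image.shape, dtype=np.int32)
            for cell in cells:
                for r, c in cell.all_pixels():
                    owned[r, c] += 1
            assert owned.max(initial=0) <= 1

    def test_connected_components_match_flood_fill_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            binary = rng.random((48, 48)) < 0.35
            lab = seg._label(binary, 8)
            sizes = sorted(np.bincount(lab.ravel())[1:])
            assert sizes == sorted(connected_components_oracle(binary, 8))
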