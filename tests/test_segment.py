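"""Six-step segmentation pipeline: each step's contract plus invariants."""

import numpy as np
import pytest

import colonymorph as cm
from colonymorph.segment import SegmentationConfig, train_texture_model

CFG = SegmentationConfig()


class TestFlattenBackground:
    def test_constant_image_maps_to_configured_grey(self):
        for level in (0, 50, 200):
            img = np.full((64, 64), level, dtype=np.uint8)
            out = cm.flatten_background(img, CFG)
            assert np.all(out == CFG.flatten_grey)

    def test_slow_linear_ramp_is_removed(self):
        ramp = np.linspace(40, 200, 128)[None, :].repeat(128, axis=0)
        out = cm.flatten_background(ramp.astype(np.uint8), CFG)
        interior = out[10:-10, 10:-10]
        assert np.abs(interior.astype(int) - CFG.flatten_grey).max() <= 2

    def test_texture_survives_while_gradient_is_suppressed(self):
        spec = cm.SceneSpec(
            image_size_px=(400, 400),
            colonies=(cm.ColonySpec(center_px=(200.0, 200.0), base_radius_px=120.0),),
            background_gradient_amplitude=30.0,
            noise_sd=0.0,
            seed=2,
        )
        image, gt = cm.render_scene(spec)
        out = cm.flatten_background(image, CFG)
        bg = gt.label_image == 0
        assert out[bg].astype(float).std() < image[bg].astype(float).std()

    def test_kernel_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="kernel"):
            cm.flatten_background(np.zeros((5, 5), dtype=np.uint8), CFG)


class TestReduceNoise:
    def _blob(self, shape, area, offset=(0, 0)):
        mask = np.zeros(shape, dtype=bool)
        side = int(np.ceil(np.sqrt(area)))
        r0, c0 = offset
        flat = np.zeros(side * side, dtype=bool)
        flat[:area] = True
        mask[r0 : r0 + side, c0 : c0 + side] = flat.reshape(side, side)
        return mask

    def test_small_speck_removed(self):
        mask = self._blob((200, 200), 100, (10, 10))
        assert not cm.reduce_noise(mask, CFG).any()

    def test_exact_threshold_component_survives(self):
        mask = self._blob((200, 200), 2046, (10, 10))
        out = cm.reduce_noise(mask, CFG)
        assert out.sum() == 2046

    def test_mixed_component_sizes(self):
        mask = (
            self._blob((600, 600), 500, (5, 5))
            | self._blob((600, 600), 3000, (100, 100))
            | self._blob((600, 600), 40000, (300, 300))
        )
        out = cm.reduce_noise(mask, CFG)
        from scipy import ndimage

        labels, n = ndimage.label(out, structure=np.ones((3, 3)))
        areas = sorted(np.bincount(labels.ravel())[1:])
        assert n == 2 and areas == [3000, 40000]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        mask = rng.random((300, 300)) > 0.4
        once = cm.reduce_noise(mask, CFG)
        assert np.array_equal(cm.reduce_noise(once, CFG), once)


class TestFillObjects:
    def _disk(self, shape=(200, 200), radius=60):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return np.hypot(yy - 100, xx - 100) <= radius

    def test_small_hole_filled(self):
        mask = self._disk()
        mask[98:101, 98:101] = False  # 9-px hole
        out = cm.fill_objects(mask, CFG)
        assert np.array_equal(out, self._disk())

    def test_large_hole_preserved(self):
        mask = self._disk()
        hole = self._disk(radius=15)
        mask &= ~hole
        out = cm.fill_objects(mask, CFG)
        assert np.array_equal(out, mask)

    def test_area_bookkeeping_on_random_masks(self):
        from scipy import ndimage

        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = ndimage.binary_dilation(rng.random((150, 150)) > 0.7)
            out = cm.fill_objects(mask, CFG)
            assert np.all(out >= mask)  # never loses foreground
            inv, _ = ndimage.label(
                ~mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
            )
            border = set(
                np.concatenate([inv[0], inv[-1], inv[:, 0], inv[:, -1]]).tolist()
            )
            areas = np.bincount(inv.ravel())
            fillable = sum(
                areas[lab]
                for lab in range(1, len(areas))
                if lab not in border and areas[lab] <= CFG.fill_hole_px
            )
            assert out.sum() - mask.sum() == fillable


class TestExtractAndGate:
    def test_exact_min_area_component_is_excluded(self):
        mask = np.zeros((400, 400), dtype=bool)
        mask[10:210, 10:160] = True  # 200x150 = 30,000 px exactly
        assert cm.extract_colonies(mask, CFG) == []
        mask[10:210, 10:161] = True  # 30,200 px
        out = cm.extract_colonies(mask, CFG)
        assert len(out) == 1 and out[0].area_px == 30200

    def test_empty_mask_gives_empty_list(self):
        assert cm.extract_colonies(np.zeros((50, 50), dtype=bool), CFG) == []

    def test_two_disjoint_large_disks(self):
        yy, xx = np.mgrid[0:1000, 0:1000]
        mask = (np.hypot(yy - 250, xx - 250) <= 113) | (
            np.hypot(yy - 700, xx - 700) <= 113
        )
        out = cm.extract_colonies(mask, CFG)
        assert len(out) == 2
        for col in out:
            assert col.area_px == pytest.approx(np.pi * 113**2, rel=0.01)
            assert col.area_px > CFG.colony_min_px
        # raster-scan labelling: upper-left component first
        assert out[0].centroid_px[0] < out[1].centroid_px[0]

    def test_exclusion_list_reproduces_manual_cleansing(self):
        yy, xx = np.mgrid[0:1000, 0:1000]
        mask = (np.hypot(yy - 250, xx - 250) <= 113) | (
            np.hypot(yy - 700, xx - 700) <= 113
        )
        out = cm.extract_colonies(mask, CFG, exclude_labels=[1])
        assert len(out) == 1 and out[0].label == 2

    def test_raising_min_area_never_increases_count(self):
        rng = np.random.default_rng(5)
        from scipy import ndimage

        mask = ndimage.binary_closing(rng.random((500, 500)) > 0.35, np.ones((9, 9)))
        counts = []
        for min_px in (500, 2000, 10000, 40000):
            cfg = SegmentationConfig(
                noise_min_px=400, fill_hole_px=30, colony_min_px=min_px
            )
            counts.append(len(cm.extract_colonies(mask, cfg)))
        assert counts == sorted(counts, reverse=True)


class TestSelectMature:
    def _colony(self, area):
        mask = np.zeros((10, 10), dtype=bool)
        return cm.ColonyObject(1, mask, area, (0.0, 0.0), "img")

    def test_equivalent_diameter_boundary_is_strict(self):
        # The 1 mm boundary at 2 um/px sits at pi*500^2/4 = 196,349.54 px:
        # 196,349 px (999.999 um) is excluded, 196,350 px (1000.001 um) and
        # anything clearly larger is included.
        assert cm.select_mature([self._colony(196349)], 2.0, CFG) == []
        assert len(cm.select_mature([self._colony(196350)], 2.0, CFG)) == 1
        assert len(cm.select_mature([self._colony(250000)], 2.0, CFG)) == 1

    def test_empty_input(self):
        assert cm.select_mature([], 2.0, CFG) == []

    def test_idempotent(self):
        cols = [self._colony(250000), self._colony(100000)]
        once = cm.select_mature(cols, 2.0, CFG)
        assert cm.select_mature(once, 2.0, CFG) == once


@pytest.fixture(scope="module")
def tiny_training():
    scenes = []
    for seed in (21, 22):
        spec = cm.SceneSpec(
            image_size_px=(256, 256),
            colonies=(
                cm.ColonySpec(center_px=(128.0, 128.0), base_radius_px=80.0),
            ),
            background_gradient_amplitude=5.0,
            noise_sd=2.0,
            seed=seed,
        )
        scenes.append(cm.render_scene(spec))
    images = [img for img, _ in scenes]
    masks = [gt.label_image > 0 for _, gt in scenes]
    return images, masks


class TestTextureModel:
    def test_training_is_deterministic_and_accurate(self, tiny_training):
        images, masks = tiny_training
        m1 = train_texture_model(images, masks, n_candidates=8, seed=3)
        m2 = train_texture_model(images, masks, n_candidates=8, seed=3)
        assert m1.feature_subset == m2.feature_subset
        assert m1.training_report == m2.training_report
        assert m1.training_report["held_out_accuracy"] >= 0.95

    def test_inverted_masks_swap_classes_with_same_accuracy(self, tiny_training):
        images, masks = tiny_training
        m_fg = train_texture_model(images, masks, n_candidates=5, seed=4)
        m_bg = train_texture_model(
            images, [~m for m in masks], n_candidates=5, seed=4
        )
        assert m_fg.training_report["held_out_accuracy"] == pytest.approx(
            m_bg.training_report["held_out_accuracy"], abs=0.02
        )
        pred_fg = cm.recognize(images[0], m_fg)
        pred_bg = cm.recognize(images[0], m_bg)
        agreement = np.mean(pred_fg == ~pred_bg)
        assert agreement > 0.95

    def test_single_candidate_degenerates_gracefully(self, tiny_training):
        images, masks = tiny_training
        model = train_texture_model(images, masks, n_candidates=1, seed=5)
        assert model.training_report["chosen_candidate"] == 0

    def test_single_class_training_errors(self, tiny_training):
        images, _ = tiny_training
        empty = [np.zeros_like(images[0], dtype=bool)]
        with pytest.raises(ValueError, match="class"):
            train_texture_model(images[:1], empty, n_candidates=2, seed=0)

    def test_model_roundtrip_preserves_predictions(self, tiny_training, tmp_path):
        images, masks = tiny_training
        model = train_texture_model(images, masks, n_candidates=3, seed=6)
        path = tmp_path / "model.pkl"
        model.save(path)
        loaded = cm.TextureModel.load(path)
        assert np.array_equal(
            cm.recognize(images[0], model), cm.recognize(images[0], loaded)
        )


class TestRecognition:
    def test_empty_scene_is_background_after_noise_reduction(self, texture_model):
        spec = cm.SceneSpec(
            image_size_px=(512, 512), colonies=(), noise_sd=3.0,
            background_gradient_amplitude=10.0, seed=8,
        )
        image, _ = cm.render_scene(spec)
        fg = cm.reduce_noise(cm.recognize(image, texture_model), CFG)
        assert not fg.any()

    def test_single_disk_overlap_with_ground_truth(
        self, texture_model, single_disk_scene
    ):
        _, image, gt = single_disk_scene
        fg = cm.fill_objects(
            cm.reduce_noise(cm.recognize(image, texture_model), CFG), CFG
        )
        truth = gt.label_image > 0
        jaccard = (fg & truth).sum() / (fg | truth).sum()
        assert jaccard >= 0.9

    def test_half_turn_rotation_commutes_with_recognition(
        self, texture_model, single_disk_scene
    ):
        _, image, _ = single_disk_scene
        a = cm.recognize(image[::-1, ::-1].copy(), texture_model)
        b = cm.recognize(image, texture_model)[::-1, ::-1]
        assert np.array_equal(a, b)


class TestEndToEnd:
    def test_noise_free_single_colony_recovers_ground_truth_area(
        self, texture_model, single_disk_scene
    ):
        _, image, gt = single_disk_scene
        colonies = cm.segment_image(image, texture_model, image_id="fixture")
        assert len(colonies) == 1
        assert colonies[0].area_px == pytest.approx(gt.area_of(1), rel=0.05)

    def test_segmentation_matches_after_image_half_turn(self, texture_model):
        spec = cm.make_two_population_scene_specs(1, 1.0, seed=31)[1]
        image, _ = cm.render_scene(spec)
        cols = cm.segment_image(image, texture_model)
        cols_rot = cm.segment_image(image[::-1, ::-1].copy(), texture_model)
        assert len(cols) == len(cols_rot) == 1
        assert cols[0].area_px == cols_rot[0].area_px

    def test_mask_containment_in_recognized_foreground(
        self, texture_model, single_disk_scene
    ):
        _, image, _ = single_disk_scene
        fg = cm.fill_objects(
            cm.reduce_noise(cm.recognize(image, texture_model), CFG), CFG
        )
        for colony in cm.segment_image(image, texture_model):
            assert np.all(fg[colony.mask])
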