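import numpy as np
import pytest

import floatscan.segmentation.network as net
from floatscan.evaluation import score, weighted_confusion
from floatscan.scenes import SceneParams, generate_scene
from floatscan.segmentation import (
    ResUNet,
    TileSet,
    TrainConfig,
    denormalize_bands,
    load_model,
    lr_schedule,
    normalize_bands,
    save_model,
    segment,
    select_tiles,
    tile,
    train_segmenter,
    untile,
    update_lr,
)


class TestNormalize:
    def test_clip_minimum_maps_to_zero(self, library):
        sc = generate_scene(64, 64, library, SceneParams(n_patches=0), seed=1)
        sc.bands[:] = 0.0
        stack, _ = normalize_bands(sc)
        np.testing.assert_allclose(stack[:7], 0.0)

    def test_clip_maximum_maps_to_one(self, library):
        sc = generate_scene(64, 64, library, SceneParams(n_patches=0), seed=1)
        sc.bands[:] = 0.25
        stack, _ = normalize_bands(sc)
        np.testing.assert_allclose(stack[:7], 1.0)

    def test_round_trip_inside_clip_range(self, library, clean_scene):
        stack, params = normalize_bands(clean_scene)
        back = denormalize_bands(stack, params)
        for i in range(7):
            lo, hi = params.clips[i]
            orig = clean_scene.bands[i]
            inside = (orig >= lo) & (orig <= hi)
            np.testing.assert_allclose(back[i][inside], orig[inside], atol=1e-12)

    def test_invalid_pixels_stay_missing(self, library):
        sc = generate_scene(64, 64, library, SceneParams(n_patches=0), seed=1)
        sc.valid_mask[5, 5] = False
        stack, _ = normalize_bands(sc)
        assert np.isnan(stack[:, 5, 5]).all()

    def test_has_eight_layers(self, clean_scene):
        stack, params = normalize_bands(clean_scene)
        assert stack.shape[0] == 8
        assert params.scaled == tuple([True] * 7 + [False])


class TestTiling:
    def test_exact_fit_single_tile(self):
        x = np.arange(256 * 256, dtype=float).reshape(1, 256, 256)
        ts = tile(x, tile_size=256)
        assert ts.tiles.shape[0] == 1
        assert not np.isnan(ts.tiles).any()

    def test_padding_round_trip(self, rng):
        x = rng.normal(size=(3, 300, 300))
        ts = tile(x, tile_size=256)
        assert ts.tiles.shape[0] == 4
        assert np.isnan(ts.tiles).any()  # padded cells carry the sentinel
        back = untile(ts)
        np.testing.assert_array_equal(back, x)

    def test_all_missing_input(self):
        x = np.full((2, 64, 64), np.nan)
        ts = tile(x, tile_size=32)
        assert np.isnan(ts.tiles).all()

    def test_minimum_tile_size(self):
        with pytest.raises(ValueError):
            tile(np.zeros((1, 64, 64)), tile_size=16)

    def test_pad_mask_marks_padding(self):
        ts = tile(np.zeros((1, 40, 40)), tile_size=32)
        assert not ts.pad_mask[0].any()  # top-left tile fully inside
        assert ts.pad_mask[-1].sum() == 32 * 32 - 8 * 8  # bottom-right mostly padding


class TestLearningRate:
    def test_single_decay_value(self):
        assert update_lr(0.05) == pytest.approx(0.0452419, abs=1e-7)

    def test_ten_applications(self):
        lr = 0.05
        for _ in range(10):
            lr = update_lr(lr)
        assert lr == pytest.approx(0.05 * np.exp(-1.0), rel=1e-12)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            update_lr(0.0)

    def test_schedule_closed_form(self):
        cfg = TrainConfig(lr_initial=0.05, lr_decay_start_epoch=11, max_epochs=50)
        for epoch in range(1, 51):
            expected = 0.05 * np.exp(-0.1 * max(0, epoch - 11 + 1))
            assert lr_schedule(epoch, cfg) == pytest.approx(expected, rel=1e-12)
        assert lr_schedule(10, cfg) == 0.05  # constant until decay starts
        assert lr_schedule(11, cfg) == pytest.approx(update_lr(0.05))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(split_fraction=1.2)
        with pytest.raises(ValueError):
            TrainConfig(lr_initial=-0.1)


class TestGradients:
    def test_backprop_matches_numeric_gradients(self):
        old = net.DTYPE
        net.DTYPE = np.float64
        try:
            rng = np.random.default_rng(0)
            model = net.ResUNet(in_channels=3, base_width=4, levels=2, seed=1)
            x = rng.normal(size=(2, 3, 8, 8))
            y = (rng.random((2, 8, 8)) < 0.3).astype(float)
            valid = np.ones((2, 8, 8), bool)

            def loss_of():
                logits = model.forward(x, train=True)[:, 0]
                return net.weighted_bce_with_logits(logits, y, valid, pos_weight=3.0)

            _, dl = loss_of()
            model.backward(dl[:, None])
            for layer in model.modules():
                for name, p in layer.params.items():
                    g = layer.grads[name]
                    idx = tuple(rng.integers(s) for s in p.shape)
                    eps = 1e-6
                    orig = p[idx]
                    p[idx] = orig + eps
                    l1, _ = loss_of()
                    p[idx] = orig - eps
                    l2, _ = loss_of()
                    p[idx] = orig
                    num = (l1 - l2) / (2 * eps)
                    assert num == pytest.approx(g[idx], abs=2e-7), (type(layer).__name__, name)
        finally:
            net.DTYPE = old


@pytest.fixture(scope="module")
def training_setup():
    from floatscan.scenes import default_library

    library = default_library()
    params = SceneParams(
        n_patches=6, chi_range=(0.01, 0.05), noise_sd=5e-5,
        cloud_fraction=0.04, shadow_fraction=0.02,
    )
    scenes = [generate_scene(64, 64, library, params, seed=500 + k) for k in range(48)]
    tiles = np.stack([normalize_bands(sc)[0] for sc in scenes])
    labels = np.stack([sc.truth.fa_mask.astype(float) for sc in scenes])
    return scenes, tiles, labels


SMALL = dict(batch_size=8, max_epochs=6, model_width=4, levels=2, lr_decay_start_epoch=4, seed=0)


@pytest.fixture(scope="module")
def trained(training_setup):
    """A small model trained long enough to be clearly better than chance."""
    _, tiles, labels = training_setup
    cfg = TrainConfig(batch_size=8, max_epochs=25, model_width=4, levels=2,
                      lr_decay_start_epoch=15, seed=0)
    model, _ = train_segmenter(tiles[:40], labels[:40], cfg)
    return model


class TestTraining:
    def test_loss_decreases(self, training_setup):
        _, tiles, labels = training_setup
        _, hist = train_segmenter(tiles[:32], labels[:32], TrainConfig(**SMALL))
        assert hist[-1]["loss"] < hist[0]["loss"]
        assert len(hist) <= 12

    def test_seeded_retraining_reproduces_history(self, training_setup):
        _, tiles, labels = training_setup
        _, h1 = train_segmenter(tiles[:16], labels[:16], TrainConfig(**SMALL))
        _, h2 = train_segmenter(tiles[:16], labels[:16], TrainConfig(**SMALL))
        assert h1 == h2

    def test_trained_beats_frozen_random(self, training_setup, trained):
        _, tiles, labels = training_setup
        model = trained
        frozen = ResUNet(in_channels=8, base_width=4, levels=2, seed=99)
        held_tiles, held_labels = tiles[40:], labels[40:].astype(bool)

        def iou_of(m):
            pred = m.predict_proba(held_tiles) >= 0.5
            tp, fp, fn = weighted_confusion(pred, held_labels)
            return score(tp, fp, fn).iou if tp + fp + fn > 0 else 0.0

        assert iou_of(model) > iou_of(frozen)

    def test_empty_tileset_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter(np.zeros((0, 8, 32, 32)), np.zeros((0, 32, 32)))

    def test_shape_mismatch_rejected(self, training_setup):
        _, tiles, labels = training_setup
        with pytest.raises(ValueError):
            train_segmenter(tiles[:4], labels[:4, :16, :16])

    def test_no_positive_labels_rejected(self, training_setup):
        _, tiles, _ = training_setup
        with pytest.raises(ValueError):
            train_segmenter(tiles[:4], np.zeros((4, 64, 64)))

    def test_validation_loss_reported(self, training_setup):
        _, tiles, labels = training_setup
        cfg = TrainConfig(**{**SMALL, "max_epochs": 3})
        _, hist = train_segmenter(tiles[:16], labels[:16], cfg,
                                  val_tiles=tiles[16:24], val_labels=labels[16:24])
        assert all("val_loss" in h for h in hist)

    def test_checkpoint_round_trip(self, training_setup, tmp_path):
        _, tiles, labels = training_setup
        cfg = TrainConfig(**{**SMALL, "max_epochs": 3})
        model, hist = train_segmenter(tiles[:16], labels[:16], cfg)
        path = tmp_path / "model.npz"
        save_model(model, hist, path)
        back, hist2 = load_model(path)
        np.testing.assert_allclose(
            back.predict_proba(tiles[16:20]), model.predict_proba(tiles[16:20]), atol=1e-6
        )
        assert hist2 == hist


class TestSegment:
    def test_all_water_scene_mostly_empty(self, library, trained):
        sc = generate_scene(64, 64, library, SceneParams(n_patches=0, noise_sd=5e-5), seed=77)
        mask = segment(sc, trained, tile_size=64)
        assert mask.mean() < 0.02  # false-positive rate bound

    def test_detects_high_chi_patches(self, library, trained):
        params = SceneParams(n_patches=6, chi_range=(0.02, 0.05), noise_sd=5e-5)
        sc = generate_scene(64, 64, library, params, seed=88)
        mask = segment(sc, trained, tile_size=64)
        truth = sc.truth.fa_mask
        recall = (mask & truth).sum() / truth.sum()
        assert recall > 0.5

    def test_tiling_offset_stability(self, library, trained):
        params = SceneParams(n_patches=4, chi_range=(0.02, 0.05), noise_sd=5e-5)
        sc = generate_scene(96, 96, library, params, seed=99)
        m64 = segment(sc, trained, tile_size=64)
        m32 = segment(sc, trained, tile_size=32)
        assert (m64 != m32).mean() < 0.01

    def test_excludes_invalid_pixels(self, library, trained):
        sc = generate_scene(64, 64, library, SceneParams(n_patches=3, chi_fixed=0.05), seed=5)
        sc.valid_mask[:, :10] = False
        mask = segment(sc, trained, tile_size=64)
        assert not mask[:, :10].any()


def test_select_tiles_keeps_features_and_confounders():
    tiles = np.zeros((3, 8, 16, 16))
    labels = np.zeros((3, 16, 16))
    labels[0, 4, 4] = 1.0  # has FA
    confs = np.zeros((3, 16, 16), dtype=int)
    confs[2, 3, 3] = 1  # has cloud
    keep = select_tiles(tiles, labels, confs)
    assert keep.tolist() == [0, 2]


def test_untile_of_probability_tiles():
    x = np.arange(4 * 40 * 40, dtype=float).reshape(4, 40, 40)[None].transpose(1, 0, 2, 3)
    ts = tile(x[0], tile_size=32)
    probs = np.zeros_like(ts.tiles[:, :1])
    probs[:] = ts.tiles[:, :1] * 2
    back = untile(TileSet(tiles=probs, origins=ts.origins, tile_size=32,
                          source_shape=ts.source_shape))
    np.testing.assert_allclose(back[0], x[0, 0] * 2)
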