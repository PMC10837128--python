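"""Patch extraction, regression training, tiled inference, evaluation.

Training tests run at miniature scale (16^3 patches, few filters) so the
whole module stays within seconds-to-minutes on one CPU; the full-scale
smoke lives in the acceptance suite.
"""

import numpy as np
import pytest

from lobule3d.core import VoxelGrid
from lobule3d.staining import (
    DegenerateTruthError,
    EmptyPatchSetError,
    PatchSet,
    PatchSizeError,
    TrainingDivergedError,
    UNet3D,
    UNet3DConfig,
    evaluate_prediction,
    extract_patches,
    load_model,
    predict_virtual_channel,
    save_model,
    train_virtual_stainer,
)


def _grids(shape=(64, 64, 64), seed=0):
    rng = np.random.default_rng(seed)
    x = rng.random(shape, dtype=np.float32)
    y = np.roll(x, 1, axis=0)
    return VoxelGrid(x, 0.3), VoxelGrid(y, 0.3)


class TestExtractPatches:
    def test_tiling_counts(self):
        x, y = _grids((128, 64, 64))
        ps = extract_patches(x, y, 64, val_fraction=0.0)
        assert ps.n_train == 2 and ps.n_val == 0
        x, y = _grids((128, 128, 128))
        ps = extract_patches(x, y, 64, val_fraction=0.0)
        assert ps.n_train == 8

    def test_val_fraction_zero_all_train(self):
        x, y = _grids()
        ps = extract_patches(x, y, 32, val_fraction=0.0)
        assert ps.n_val == 0 and ps.n_train == 8

    def test_split_deterministic(self):
        x, y = _grids()
        a = extract_patches(x, y, 32, 0.25, seed=3)
        b = extract_patches(x, y, 32, 0.25, seed=3)
        np.testing.assert_array_equal(a.train_x, b.train_x)
        np.testing.assert_array_equal(a.val_x, b.val_x)

    def test_patches_cover_image_once(self):
        x, y = _grids()
        ps = extract_patches(x, y, 32, 0.25, seed=0)
        total = np.concatenate([ps.train_x, ps.val_x]).sum()
        assert total == pytest.approx(x.data.sum(), rel=1e-6)

    def test_image_smaller_than_patch_rejected(self):
        x, y = _grids((16, 16, 16))
        with pytest.raises(PatchSizeError):
            extract_patches(x, y, 32)

    def test_max_patches_subsample(self):
        x, y = _grids()
        ps = extract_patches(x, y, 16, 0.1, seed=0, max_patches=20)
        assert ps.n_train + ps.n_val == 20


class TestConfig:
    def test_patch_divisibility_enforced(self):
        with pytest.raises(ValueError):
            UNet3DConfig(patch_size=36)

    def test_paper_scale_defaults(self):
        cfg = UNet3DConfig()
        assert cfg.n_blocks == 3 and cfg.filters == 64
        assert cfg.patch_size == 64 and cfg.batch_size == 8
        assert cfg.learning_rate == pytest.approx(0.05)
        assert cfg.momentum == pytest.approx(0.9)
        assert cfg.epochs == 100


def _identity_patchset(n=16, p=16, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.random((n, p, p, p), dtype=np.float32)
    return PatchSet(train_x=x, train_y=x.copy(), val_x=x[:2], val_y=x[:2],
                    patch_size=p)


class TestTraining:
    def test_identity_mapping_learned(self):
        """MSE on an identity task falls by >= 10x within a few epochs."""
        ps = _identity_patchset(n=40)
        cfg = UNet3DConfig(filters=8, patch_size=16, epochs=10, seed=0)
        _, rep = train_virtual_stainer(ps, cfg)
        assert rep.train_loss[-1] < rep.train_loss[0] / 10.0

    def test_empty_train_set_rejected(self):
        ps = PatchSet(
            train_x=np.zeros((0, 16, 16, 16), np.float32),
            train_y=np.zeros((0, 16, 16, 16), np.float32),
            val_x=np.zeros((0, 16, 16, 16), np.float32),
            val_y=np.zeros((0, 16, 16, 16), np.float32),
            patch_size=16,
        )
        with pytest.raises(EmptyPatchSetError):
            train_virtual_stainer(ps, UNet3DConfig(filters=4, patch_size=16))

    def test_divergence_detected(self):
        ps = _identity_patchset(n=8)
        ps.train_y = ps.train_y * 1e18  # force numeric blow-up
        cfg = UNet3DConfig(filters=4, patch_size=16, epochs=2, seed=0,
                           learning_rate=10.0)
        with pytest.raises(TrainingDivergedError):
            train_virtual_stainer(ps, cfg)

    def test_seeded_training_reproducible(self):
        ps = _identity_patchset(n=8)
        cfg = UNet3DConfig(filters=4, patch_size=16, epochs=2, seed=5)
        _, r1 = train_virtual_stainer(ps, cfg)
        _, r2 = train_virtual_stainer(ps, cfg)
        np.testing.assert_allclose(r1.train_loss, r2.train_loss, rtol=1e-6)

    def test_report_records_epochs(self):
        ps = _identity_patchset(n=8)
        cfg = UNet3DConfig(filters=4, patch_size=16, epochs=3, seed=0)
        _, rep = train_virtual_stainer(ps, cfg)
        assert len(rep.train_loss) == 3 == len(rep.val_loss)
        assert rep.augmentation == "none"


class TestPrediction:
    def test_constant_input_constant_output(self):
        model = UNet3D(UNet3DConfig(filters=4, patch_size=16, seed=0))
        grid = VoxelGrid(np.zeros((16, 16, 16), np.float32), 0.3)
        out = predict_virtual_channel(model, grid)
        assert out.shape == grid.shape
        assert np.ptp(out.data) <= 1e-4

    def test_single_tile_equals_direct(self):
        model = UNet3D(UNet3DConfig(filters=4, patch_size=32, seed=1))
        rng = np.random.default_rng(0)
        x = rng.random((32, 32, 32), dtype=np.float32)
        tiled = predict_virtual_channel(model, VoxelGrid(x, 0.3), tile=32)
        direct = model.forward(x[None])[0]
        np.testing.assert_allclose(tiled.data, direct, atol=1e-5)

    def test_tiled_inference_shape_and_determinism(self):
        model = UNet3D(UNet3DConfig(filters=4, patch_size=16, seed=1))
        rng = np.random.default_rng(0)
        x = rng.random((24, 40, 40), dtype=np.float32)
        a = predict_virtual_channel(model, VoxelGrid(x, 0.3), tile=16)
        b = predict_virtual_channel(model, VoxelGrid(x, 0.3), tile=16)
        assert a.shape == (24, 40, 40)
        np.testing.assert_array_equal(a.data, b.data)


class TestEvaluation:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        t = VoxelGrid(rng.random((32, 32, 32), dtype=np.float32), 0.3)
        m = evaluate_prediction(t, t)
        assert m["pearson_r"] == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(0)
        t = VoxelGrid(rng.random((64, 64, 64), dtype=np.float32), 0.3)
        p = VoxelGrid(rng.random((64, 64, 64), dtype=np.float32), 0.3)
        assert abs(evaluate_prediction(p, t)["pearson_r"]) < 0.1

    def test_constructed_sbr(self):
        t = np.zeros((24, 24, 24), np.float32)
        t[4:12, 4:12, 4:12] = 1.0
        p = np.full_like(t, 10.0)
        p[t > 0] = 100.0
        m = evaluate_prediction(VoxelGrid(p, 0.3), VoxelGrid(t, 0.3))
        assert m["signal_to_background"] == pytest.approx(10.0, abs=1e-6)

    def test_profile_sampling(self):
        t = np.zeros((16, 16, 32), np.float32)
        t[:, :, 16:] = 1.0
        m = evaluate_prediction(
            VoxelGrid(t, 0.3), VoxelGrid(t, 0.3),
            line=((8, 8, 0), (8, 8, 31)),
        )
        prof = m["intensity_profiles"]
        assert len(prof["pred"]) == 32
        assert prof["pred"][0] == 0.0 and prof["pred"][-1] == 1.0

    def test_constant_truth_rejected(self):
        t = VoxelGrid(np.ones((8, 8, 8), np.float32), 0.3)
        with pytest.raises(DegenerateTruthError):
            evaluate_prediction(t, t)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        model = UNet3D(UNet3DConfig(filters=4, patch_size=16, seed=2))
        norm = {"lo": 0.1, "hi": 0.9}
        save_model(model, tmp_path / "m.npz", norm)
        back, norm2 = load_model(tmp_path / "m.npz")
        assert norm2 == norm
        rng = np.random.default_rng(0)
        x = rng.random((16, 16, 16), dtype=np.float32)[None]
        np.testing.assert_allclose(model.forward(x), back.forward(x), atol=1e-7)
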