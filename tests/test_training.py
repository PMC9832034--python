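"""Loss, cyclic schedule, early stopping, optimisation sanity, HPT harness."""

import math

import numpy as np
import pytest

import octseg.training as training
from octseg.models import ModelConfig, build_model
from octseg.training import (
    STAGE1_LR_GRID,
    TrainConfig,
    combined_loss,
    cyclic_momentum,
    cyclic_schedule,
    run_hpt,
    stage_configs,
    train,
)


class TestCombinedLoss:
    def test_lambda_dice_zero_reduces_to_cross_entropy(self, rng):
        logits = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
        target = rng.integers(0, 4, size=(2, 8, 8))
        got = float(combined_loss(logits, target, 1.0, 0.0))
        # independent CE: explicit log-sum-exp per pixel
        lse = np.log(np.exp(logits).sum(axis=1))
        picked = np.take_along_axis(logits, target[:, None], axis=1)[:, 0]
        expected = float(np.mean(lse - picked))
        assert abs(got - expected) <= 1e-6

    def test_saturated_correct_prediction_has_near_zero_loss(self):
        target = np.zeros((1, 4, 4), dtype=int)
        target[0, 2:, :] = 3
        logits = np.full((1, 4, 4, 4), -50.0, dtype=np.float32)
        for c in range(4):
            logits[0, c][target[0] == c] = 50.0
        assert float(combined_loss(logits, target)) <= 1e-3

    def test_uniform_logits_closed_form(self):
        # 2x2 image, 4 classes, all-background target
        logits = np.zeros((1, 4, 2, 2), dtype=np.float32)
        target = np.zeros((1, 2, 2), dtype=int)
        ce = float(combined_loss(logits, target, 1.0, 0.0))
        assert abs(ce - math.log(4)) < 1e-6
        dice_term = float(combined_loss(logits, target, 0.0, 1.0))
        # hand-evaluated soft dice with eps = 1e-5 smoothing both terms:
        # class 0 -> (2*1 + eps)/(0.25 + 4 + eps); empty classes ->
        # eps/(0.25 + eps)
        eps = 1e-5
        expected = 1.0 - ((2.0 + eps) / (4.25 + eps) + 3 * eps / (0.25 + eps)) / 4.0
        assert abs(dice_term - expected) < 1e-6

    def test_loss_nonnegative_on_random_inputs(self, rng):
        for _ in range(10):
            logits = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
            target = rng.integers(0, 4, size=(1, 6, 6))
            assert float(combined_loss(logits, target)) >= 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros((1, 4, 4, 4)), np.zeros((1, 5, 5), dtype=int))


class TestCyclicSchedule:
    def test_triangular_waypoints(self):
        assert cyclic_schedule(0, 10, 0.1, 1.0) == 0.1
        assert cyclic_schedule(10, 10, 0.1, 1.0) == 1.0
        assert cyclic_schedule(20, 10, 0.1, 1.0) == 0.1

    def test_momentum_cycles_inversely(self):
        # momentum is at its maximum when the learning rate is lowest
        assert cyclic_momentum(0, 10, 0.8, 0.95) == 0.95
        assert cyclic_momentum(10, 10, 0.8, 0.95) == 0.8
        assert cyclic_momentum(20, 10, 0.8, 0.95) == 0.95

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            cyclic_schedule(0, 10, 1.0, 0.1)


class _ScriptedModel:
    """Stub model whose validation losses are scripted, for rule traces."""

    def __init__(self):
        self.params = {"w": np.zeros(1, dtype=np.float32)}

    def apply(self, x, params=None, train=False):
        w = (params or self.params)["w"]
        return np.zeros((x.shape[0], 4) + x.shape[2:], dtype=np.float32) + 0.0 * w[0]


class TestEarlyStopping:
    def _run(self, monkeypatch, losses, patience=6, max_epochs=50):
        seq = iter(losses)
        monkeypatch.setattr(training, "_val_metrics",
                            lambda *a, **k: (next(seq), {}, float("nan")))
        model = _ScriptedModel()
        x = np.zeros((2, 1, 4, 4), dtype=np.float32)
        y = np.zeros((2, 4, 4), dtype=int)
        cfg = TrainConfig(patience=patience, max_epochs=max_epochs, batch_size=2,
                          lr_base=0.0, lr_max=0.0)
        return train(model, (x, y), (x, y), cfg)

    def test_stops_after_exactly_patience_flat_epochs(self, monkeypatch):
        losses = [1.0, 0.9] + [0.9] * 20
        hist = self._run(monkeypatch, losses, patience=6)
        assert len(hist.epochs) == 8  # improves at 2, then 6 flat epochs
        assert hist.best_epoch == 2
        assert hist.stopped_early

    def test_monotone_improvement_runs_all_epochs(self, monkeypatch):
        losses = [1.0 - 0.01 * i for i in range(50)]
        hist = self._run(monkeypatch, losses, patience=6, max_epochs=12)
        assert len(hist.epochs) == 12
        assert not hist.stopped_early
        assert hist.best_epoch == 12

    def test_never_stops_before_patience_plus_one_epochs(self, monkeypatch):
        losses = [1.0] + [2.0] * 20  # worst case: never improves again
        hist = self._run(monkeypatch, losses, patience=4)
        assert len(hist.epochs) == 5
        assert hist.best_epoch == 1


class TestOptimisation:
    def test_tiny_swin_overfits_phantoms(self):
        # optimisation sanity: training loss halves on 8 images
        from octseg.phantom import PhantomSpec, generate_bscan, sample_presence

        spec = PhantomSpec(image_width=64, image_depth=64,
                           axial_resolution=3.87 * 496 / 64)
        rng = np.random.default_rng(7)
        imgs, msks = [], []
        for _ in range(8):
            scan, mask, _ = generate_bscan(spec, sample_presence(spec, rng), rng)
            imgs.append(scan.image.astype(np.float32) / 255.0)
            msks.append(mask.astype(np.int64))
        x, y = np.stack(imgs)[:, None], np.stack(msks)
        model = build_model(
            ModelConfig(feature_size=8, input_size=64, num_heads=(2, 4, 8, 16)), seed=1)
        cfg = TrainConfig(lr_base=5e-3, lr_max=5e-2, batch_size=8, max_epochs=30,
                          patience=30, cycle_epochs=10, seed=0)
        hist = train(model, (x, y), (x, y), cfg)
        df = hist.to_frame()
        assert df["train_loss"].iloc[-1] <= 0.5 * df["train_loss"].iloc[0]

    def test_seeded_runs_reproduce(self, tiny_phantom_batch):
        x, y = tiny_phantom_batch
        cfg = TrainConfig(lr_base=1e-2, lr_max=1e-1, batch_size=4, max_epochs=2,
                          patience=6, seed=3)
        runs = []
        for _ in range(2):
            model = build_model(ModelConfig(family="unet", input_size=32, base_width=4),
                                seed=5)
            hist = train(model, (x, y), (x, y), cfg)
            runs.append(hist.to_frame()["train_loss"].to_numpy())
        assert np.allclose(runs[0], runs[1], rtol=1e-6)


class TestHyperParameterSearch:
    def test_stage1_grid_has_six_configurations(self):
        cfgs = stage_configs(TrainConfig(), stage=1)
        assert len(cfgs) == 6 == len(STAGE1_LR_GRID)
        # the constant-LR control collapses the range
        consts = [c for c in cfgs if c.lr_base == c.lr_max]
        assert len(consts) == 1
        assert abs(consts[0].lr_base - 5 * 10**-3.5) < 1e-12

    def test_degenerate_grid_single_config_wins(self, tiny_phantom_batch):
        x, y = tiny_phantom_batch
        base = TrainConfig(batch_size=4, max_epochs=1, patience=6, seed=0)
        factory = lambda seed: build_model(
            ModelConfig(family="unet", input_size=32, base_width=2), seed=seed)
        table, winner = run_hpt(factory, (x, y), (x, y), base, stage=3,
                                grids={"weight_decay": [1e-4]})
        assert len(table) == 1 and bool(table["winner"].iloc[0])
        assert winner.weight_decay == 1e-4

    def test_nonzero_learning_rate_beats_zero(self, tiny_phantom_batch):
        # long enough for the net to escape the all-background minimum,
        # after which its Dice dwarfs the frozen (LR = 0) model's
        x, y = tiny_phantom_batch
        base = TrainConfig(batch_size=8, max_epochs=75, patience=75,
                           cycle_epochs=15, seed=0)
        factory = lambda seed: build_model(
            ModelConfig(family="unet", input_size=32, base_width=8), seed=seed)
        table, winner = run_hpt(factory, (x, y), (x, y), base, stage=1,
                                grids={"lr": [0.0, (5e-2, 5e-1)]})
        assert winner.lr_max == 5e-1
        assert table.loc[table["winner"], "lr_max"].iloc[0] == 5e-1


class TestTrainConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_base=1.0, lr_max=0.1)
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
        with pytest.raises(ValueError):
            TrainConfig(lambda_ce=-0.1)
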