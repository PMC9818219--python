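from dataclasses import replace

import numpy as np
import pytest

from uroscreen.backbone import TinyCNN
from uroscreen.errors import ContractError, InvalidConfigError, TrainingError
from uroscreen.inference import HeatmapGrid, predict_heatmap
from uroscreen.synthetic_slides import generate_cohort
from uroscreen.training import (
    AugmentJitter,
    HardMiningBuffer,
    TrainConfig,
    Trainer,
    TrainState,
    augment_tile,
    early_stop_update,
    lr_at_epoch,
    select_hard_tiles,
    trainable_parameter_mask,
    update_negative_weights,
)

from conftest import build_contexts


@pytest.fixture(scope="module")
def train_config():
    return TrainConfig(
        tile_size=128,
        min_tissue_fraction=0.001,
        batch_size=32,
        k_top_tiles=8,
        buffer_capacity_N=256,
        seed=3,
    )


@pytest.fixture(scope="module")
def small_cohort(toy_config, train_config):
    bundles = generate_cohort(3, 3, toy_config, seed=50)
    return bundles, build_contexts(bundles, train_config)


def heatmap_from(values):
    return HeatmapGrid(values=np.asarray(values, dtype=float), stride_px=64,
                       tile_size_px=128, slide_id="h")


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,expected", [(0, 0.001), (1, 0.001),
                                                (2, 0.00095), (3, 0.00095),
                                                (4, 0.0009025)])
    def test_decay_every_two_epochs(self, epoch, expected, train_config):
        assert lr_at_epoch(epoch, train_config) == pytest.approx(expected, rel=1e-12)

    def test_negative_epoch_rejected(self, train_config):
        with pytest.raises(ValueError):
            lr_at_epoch(-1, train_config)


class TestConfigInvariants:
    def test_k_larger_than_buffer_rejected(self):
        with pytest.raises(InvalidConfigError):
            TrainConfig(k_top_tiles=300, buffer_capacity_N=256)

    def test_buffer_not_divisible_by_batch_rejected(self):
        with pytest.raises(InvalidConfigError):
            TrainConfig(buffer_capacity_N=250, batch_size=32)


class TestNegativeWeights:
    def test_all_zero_probabilities_give_uniform(self):
        hm = heatmap_from([[0.0, 0.0], [0.0, 0.0]])
        weights = update_negative_weights({"s": hm})
        assert np.allclose(weights.per_slide["s"], 0.25)

    def test_hard_tile_ratio(self):
        hm = heatmap_from([[1.0, 0.0]])
        weights = update_negative_weights({"s": hm}, epsilon=0.01)
        w = weights.per_slide["s"]
        assert w[0] / w[1] == pytest.approx(101.0, rel=1e-12)

    def test_weights_sum_to_one_per_slide(self):
        rng = np.random.default_rng(0)
        heatmaps = {
            f"s{i}": heatmap_from(rng.uniform(size=(4, 5))) for i in range(10)
        }
        weights = update_negative_weights(heatmaps)
        for w in weights.per_slide.values():
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_heatmap_warns(self):
        hm = heatmap_from(np.full((2, 2), np.nan))
        with pytest.warns(UserWarning):
            weights = update_negative_weights({"s": hm})
        assert weights.per_slide["s"].size == 0


class TestSelectHardTiles:
    def test_top_two(self):
        hm = heatmap_from([[0.1, 0.9], [0.5, 0.7]])
        assert select_hard_tiles(hm, 2) == [(0, 1), (1, 1)]

    def test_tie_break_row_major(self):
        hm = heatmap_from(np.full((2, 3), 0.4))
        assert select_hard_tiles(hm, 3) == [(0, 0), (0, 1), (0, 2)]

    def test_fewer_than_k_returns_all(self):
        hm = heatmap_from([[0.2, 0.8]])
        assert len(select_hard_tiles(hm, 10)) == 2

    def test_empty_heatmap_warns_and_returns_nothing(self):
        hm = heatmap_from(np.full((2, 2), np.nan))
        with pytest.warns(UserWarning):
            assert select_hard_tiles(hm, 3) == []

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            values = rng.uniform(size=(6, 7))
            values[rng.uniform(size=(6, 7)) < 0.2] = np.nan
            hm = heatmap_from(values)
            got = select_hard_tiles(hm, 8)
            flat = [
                (-values[r, c], r * 7 + c, (r, c))
                for r in range(6)
                for c in range(7)
                if not np.isnan(values[r, c])
            ]
            want = [cell for _, _, cell in sorted(flat)[:8]]
            assert got == want


class TestAugment:
    def test_zero_jitter_is_identity(self):
        rng = np.random.default_rng(0)
        tile = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        out = augment_tile(tile, np.random.default_rng(1), AugmentJitter(0.0, 0.0, 0.0))
        assert np.array_equal(out, tile)

    def test_output_clipped_to_pixel_range(self):
        tile = np.full((8, 8, 3), 250, dtype=np.uint8)
        out = augment_tile(
            tile, np.random.default_rng(2), AugmentJitter(brightness=100, saturation=0.5, contrast=0.5)
        )
        assert out.dtype == np.uint8
        assert out.max() <= 255 and out.min() >= 0

    def test_same_seed_reproduces(self):
        tile = np.random.default_rng(0).integers(0, 256, (16, 16, 3)).astype(np.uint8)
        jitter = AugmentJitter(20, 0.3, 0.3)
        a = augment_tile(tile, np.random.default_rng(9), jitter)
        b = augment_tile(tile, np.random.default_rng(9), jitter)
        assert np.array_equal(a, b)


class TestParameterMask:
    def test_partial_mask_covers_norm_and_head_only(self):
        model = TinyCNN(input_size=16, pool_factor=2, channels=(4, 6))
        mask = trainable_parameter_mask(model, "partial")
        expected_on = {"bn1_gamma", "bn1_beta", "bn2_gamma", "bn2_beta", "head_W", "head_b"}
        assert {name for name, on in mask.items() if on} == expected_on

    def test_full_mask_covers_everything(self):
        model = TinyCNN(input_size=16, pool_factor=2)
        mask = trainable_parameter_mask(model, "full")
        assert all(mask.values())

    def test_model_without_head_errors(self):
        class HeadlessModel(TinyCNN):
            def parameter_groups(self):
                return {name: "other" for name in self.params}

        with pytest.raises(ContractError):
            trainable_parameter_mask(HeadlessModel(input_size=16, pool_factor=2), "partial")


class TestEarlyStopping:
    def test_monotone_improvement_never_stops(self):
        state = TrainState()
        for loss in (1.0, 0.9, 0.8):
            stop, best = early_stop_update(state, loss, patience=10)
            assert not stop
        assert best == 2

    def test_stop_after_patience_non_improvements(self):
        state = TrainState()
        early_stop_update(state, 0.5, patience=10)
        for i in range(10):
            stop, best = early_stop_update(state, 0.5, patience=10)
        assert stop and best == 0

    def test_best_is_argmin_mid_sequence(self):
        state = TrainState()
        losses = [1.0, 0.4, 0.7, 0.9, 0.8]
        for loss in losses:
            _, best = early_stop_update(state, loss, patience=10)
        assert best == int(np.argmin(losses))

    def test_nan_loss_raises(self):
        with pytest.raises(TrainingError):
            early_stop_update(TrainState(), float("nan"), patience=10)


class TestHardMiningBuffer:
    def test_capacity_respected(self):
        buf = HardMiningBuffer(capacity=4)
        for i in range(4):
            buf.push("s", (i, 0), 1)
        assert buf.is_full
        with pytest.raises(TrainingError):
            buf.push("s", (9, 9), 1)

    def test_drain_shuffles_batches_and_clears(self):
        buf = HardMiningBuffer(capacity=8)
        for i in range(8):
            buf.push("s", (i, 0), i % 2)
        batches = list(buf.drain(np.random.default_rng(0), batch_size=4))
        assert [len(b) for b in batches] == [4, 4]
        assert len(buf) == 0


class TestFsTraining:
    def test_batch_is_balanced_and_interleaved(self, small_cohort, train_config):
        _, contexts = small_cohort
        model = TinyCNN(input_size=128, seed=0)
        trainer = Trainer(model, contexts, contexts[:2], train_config)
        tiles, labels = trainer.make_fs_batch(augment=False)
        assert tiles.shape[0] == 32
        assert labels.sum() == 16
        assert np.array_equal(labels, np.tile([1, 0], 16))

    def test_positive_tiles_intersect_annotations(self, small_cohort, train_config):
        from uroscreen.annotation import tile_is_positive

        bundles, contexts = small_cohort
        ann_by_id = {b.record.slide_id: b.annotations for b in bundles}
        model = TinyCNN(input_size=128, seed=0)
        trainer = Trainer(model, contexts, contexts[:2], train_config)
        span = contexts[0].grid.level0_tile_span
        for ctx in contexts:
            if ctx.positive_anchor_idx is None:
                continue
            for i in ctx.positive_anchor_idx:
                anchor = ctx.grid.anchors[int(i)]
                assert tile_is_positive(anchor, (span, span), ann_by_id[ctx.slide_id])

    def test_unannotated_neoplastic_slide_rejected(self, small_cohort, train_config):
        _, contexts = small_cohort
        neo = next(c for c in contexts if c.record.is_neoplastic)
        saved = neo.positive_anchor_idx
        neo.positive_anchor_idx = None
        try:
            model = TinyCNN(input_size=128, seed=0)
            trainer = Trainer(model, contexts, contexts[:2], train_config)
            with pytest.raises(InvalidConfigError):
                trainer.make_fs_batch()
        finally:
            neo.positive_anchor_idx = saved

    def test_uniform_negative_sampling_frequencies(self, small_cohort, train_config):
        """10,000 weighted draws over 4 anchors, uniform weights: 3-sigma check."""
        rng = np.random.default_rng(0)
        w = np.full(4, 0.25)
        draws = rng.choice(4, size=10_000, p=w)
        counts = np.bincount(draws, minlength=4)
        sigma = np.sqrt(10_000 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 2500) < 3 * sigma)

    def test_fs_epoch_refreshes_weights(self, small_cohort, train_config):
        _, contexts = small_cohort
        model = TinyCNN(input_size=128, seed=0)
        cfg = replace(train_config, mode="FS")
        trainer = Trainer(model, contexts, contexts[:2], cfg)
        assert trainer.negative_weights.per_slide == {}
        entry = trainer.fs_epoch()
        n_neg = sum(not c.record.is_neoplastic for c in contexts)
        assert len(trainer.negative_weights.per_slide) == n_neg
        assert entry["steps"] >= 1

    def test_epoch_length_formula(self):
        # 64 qualifying positive anchors, batch 32 -> 64 / 16 = 4 steps
        assert max(1, 64 // (32 // 2)) == 4


class TestWsTraining:
    def test_buffer_contents_match_brute_force_topk(self, small_cohort, train_config):
        _, contexts = small_cohort
        model = TinyCNN(input_size=128, seed=1)
        cfg = replace(train_config, buffer_capacity_N=2048, batch_size=32,
                      k_top_tiles=8)
        # capacity far above 6 slides x 8 so no flush occurs: frozen model
        trainer = Trainer(model, contexts, contexts[:2], cfg)
        trainer.ws_epoch()
        got = {(sid, anchor) for sid, anchor, _ in trainer.buffer.entries}
        want = set()
        for ctx in contexts:
            hm = predict_heatmap(ctx.pyramid, model, ctx.grid)
            probs = hm.values[hm.evaluated]
            order = np.argsort(-probs, kind="stable")[:8]
            anchors = np.array(ctx.grid.anchors)
            want.update((ctx.slide_id, tuple(anchors[i])) for i in order)
        assert got == want

    def test_buffer_labels_equal_slide_labels(self, small_cohort, train_config):
        _, contexts = small_cohort
        label_by_id = {c.slide_id: c.label for c in contexts}
        model = TinyCNN(input_size=128, seed=1)
        cfg = replace(train_config, buffer_capacity_N=2048)
        trainer = Trainer(model, contexts, contexts[:2], cfg)
        trainer.ws_epoch()
        assert trainer.buffer.entries  # non-empty
        for sid, _, label in trainer.buffer.entries:
            assert label == label_by_id[sid]

    def test_buffer_fills_once_per_32_slides(self, toy_config, train_config):
        """32 slides x k=8 = N=256: exactly one flush per epoch, empty after."""
        from dataclasses import replace as dreplace

        small = dreplace(toy_config, n_normal_cells=40, n_debris=6, n_crystals=3,
                         width=512, height=512)
        bundles = generate_cohort(16, 16, small, seed=77)
        contexts = build_contexts(bundles, train_config)
        assert all(len(c.grid) >= 8 for c in contexts)
        model = TinyCNN(input_size=128, seed=2)
        trainer = Trainer(model, contexts, contexts[:2], train_config)
        entry = trainer.ws_epoch()
        assert entry["flushes"] == 1
        assert len(trainer.buffer) == 0

    def test_gradient_steps_per_cycle_is_n_over_batch(self, train_config):
        assert train_config.buffer_capacity_N // train_config.batch_size == 8


class TestPartialFineTuning:
    def test_frozen_parameters_bit_identical_after_steps(self, small_cohort, train_config):
        _, contexts = small_cohort
        cfg = replace(train_config, fine_tune="partial", mode="FS")
        model = TinyCNN(input_size=128, seed=4)
        trainer = Trainer(model, contexts, contexts[:2], cfg)
        before = model.get_params()
        for _ in range(5):
            tiles, labels = trainer.make_fs_batch()
            trainer._gradient_step(tiles, labels)
        groups = model.parameter_groups()
        for name, group in groups.items():
            same = np.array_equal(before[name], model.params[name])
            if group == "other":
                assert same, f"{name} should be frozen"
            else:
                assert not same, f"{name} should have trained"

    def test_full_mode_updates_everything(self, small_cohort, train_config):
        _, contexts = small_cohort
        cfg = replace(train_config, fine_tune="full", mode="FS")
        model = TinyCNN(input_size=128, seed=4)
        trainer = Trainer(model, contexts, contexts[:2], cfg)
        before = model.get_params()
        for _ in range(5):
            tiles, labels = trainer.make_fs_batch()
            trainer._gradient_step(tiles, labels)
        for name in model.params:
            assert not np.array_equal(before[name], model.params[name]), name


class TestFsThenWs:
    def test_fs_then_ws_runs_both_phases(self, small_cohort, train_config):
        _, contexts = small_cohort
        cfg = replace(train_config, mode="FS_then_WS", max_epochs=1,
                      early_stop_patience=1)
        model = TinyCNN(input_size=128, seed=5)
        trainer = Trainer(model, contexts, contexts[:2], cfg)
        trainer.fit()
        phases = [e["phase"] for e in trainer.log]
        assert "FS" in phases and "WS" in phases
        assert phases.index("FS") < phases.index("WS")
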