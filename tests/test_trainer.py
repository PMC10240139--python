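"""Two-phase training: descent, phase isolation, limits, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from retseg.network import LESIONS, NetworkConfig, build_network
from retseg.trainer import (
    ArrayDataset,
    LesionSegmentationModel,
    TrainConfig,
    pretrain_reconstruction,
    state_hash,
    train_all_primaries,
    train_supervised,
)


def tiny_cfg(**overrides) -> TrainConfig:
    base = dict(
        batch_size=4, epochs_unsup=2, epochs_sup=3, primary="EX", seed=11
    )
    base.update(overrides)
    return TrainConfig.desk_scale(**base)


class TestPretrain:
    def test_reconstruction_loss_decreases(self, tiny_synth, tiny_net_config):
        _, _, unlabeled = tiny_synth
        net = build_network(tiny_net_config, seed=0)
        state = pretrain_reconstruction(net, unlabeled, tiny_cfg(epochs_unsup=5))
        means = state.epoch_means("L_rec")
        assert means.iloc[-1] < means.iloc[0]

    def test_segmentation_decoders_untouched(self, tiny_synth, tiny_net_config):
        _, _, unlabeled = tiny_synth
        net = build_network(tiny_net_config, seed=0)
        before = state_hash(net.seg_decoders.state_dict())
        pretrain_reconstruction(net, unlabeled, tiny_cfg())
        assert state_hash(net.seg_decoders.state_dict()) == before

    def test_zero_epochs_leaves_network_unchanged(self, tiny_synth, tiny_net_config):
        _, _, unlabeled = tiny_synth
        net = build_network(tiny_net_config, seed=0)
        before = state_hash(net)
        pretrain_reconstruction(net, unlabeled, tiny_cfg(epochs_unsup=0))
        assert state_hash(net) == before

    def test_empty_pool_rejected(self, tiny_net_config):
        net = build_network(tiny_net_config, seed=0)
        empty = ArrayDataset(np.zeros((0, 3, 32, 32)))
        with pytest.raises(ValueError, match="empty"):
            pretrain_reconstruction(net, empty, tiny_cfg())


class TestSupervised:
    def test_primary_dice_loss_decreases(self, tiny_synth, tiny_net_config):
        train, val, _ = tiny_synth
        net = build_network(tiny_net_config, seed=0)
        state = train_supervised(net, train, val, tiny_cfg(epochs_sup=6))
        means = state.epoch_means("L_EX")
        assert means.iloc[-1] < means.iloc[0]
        assert state.best_val_dice is not None

    def test_recon_decoder_frozen_without_supervised_recon(
        self, tiny_synth, tiny_net_config
    ):
        train, _, _ = tiny_synth
        net = build_network(tiny_net_config, seed=0)
        before = state_hash(net.recon_decoder.state_dict())
        train_supervised(net, train, None, tiny_cfg(supervised_recon=False))
        assert state_hash(net.recon_decoder.state_dict()) == before

    def test_recon_decoder_updates_with_supervised_recon(
        self, tiny_synth, tiny_net_config
    ):
        train, _, _ = tiny_synth
        net = build_network(tiny_net_config, seed=0)
        before = state_hash(net.recon_decoder.state_dict())
        train_supervised(net, train, None, tiny_cfg(supervised_recon=True))
        assert state_hash(net.recon_decoder.state_dict()) != before

    def test_loss_history_steps_strictly_increase(self, tiny_synth, tiny_net_config):
        train, _, _ = tiny_synth
        net = build_network(tiny_net_config, seed=0)
        state = train_supervised(net, train, None, tiny_cfg())
        steps = state.history["step"].to_numpy()
        assert np.all(np.diff(steps) > 0)

    def test_unlabeled_data_rejected(self, tiny_synth, tiny_net_config):
        _, _, unlabeled = tiny_synth
        net = build_network(tiny_net_config, seed=0)
        with pytest.raises(ValueError, match="masks"):
            train_supervised(net, unlabeled, None, tiny_cfg())

    def test_unknown_primary_rejected(self, tiny_synth, tiny_net_config):
        train, _, _ = tiny_synth
        net = build_network(tiny_net_config, seed=0)
        with pytest.raises(ValueError, match="primary"):
            train_supervised(net, train, None, tiny_cfg(primary="NV"))


class TestBetaOneLimit:
    def test_encoder_update_matches_single_task_bitwise(self, tiny_synth):
        """With beta=1 the multi-task step must equal a single-task step."""
        train, _, _ = tiny_synth
        cfg = tiny_cfg(epochs_sup=2, supervised_recon=False)
        cfg = replace(cfg, weights=replace(cfg.weights, beta=1.0), primary="EX")
        multi_cfg = NetworkConfig(
            depth=3, base_channels=4, lesions=("EX", "MA", "HE", "SE")
        )
        single_cfg = NetworkConfig(depth=3, base_channels=4, lesions=("EX",))
        multi = build_network(multi_cfg, seed=3)
        single = build_network(single_cfg, seed=3)  # same encoder + first decoder draw
        train_supervised(multi, train, None, cfg)
        train_supervised(single, train, None, cfg)
        for (name, pm), (_, ps) in zip(
            multi.encoder.named_parameters(), single.encoder.named_parameters()
        ):
            np.testing.assert_array_equal(pm.data, ps.data, err_msg=name)
        for pm, ps in zip(
            multi.seg_decoders[0].parameters(), single.seg_decoders[0].parameters()
        ):
            np.testing.assert_array_equal(pm.data, ps.data)


class TestAlphaZeroLimit:
    def test_alpha_zero_equals_dropping_reconstruction_term(self, tiny_synth):
        train, _, _ = tiny_synth
        net_cfg = NetworkConfig(depth=3, base_channels=4)
        base = tiny_cfg(epochs_sup=2)
        with_zero_alpha = replace(
            base, weights=replace(base.weights, alpha=0.0), supervised_recon=True
        )
        without_recon = replace(base, supervised_recon=False)
        a = build_network(net_cfg, seed=5)
        b = build_network(net_cfg, seed=5)
        train_supervised(a, train, None, with_zero_alpha)
        train_supervised(b, train, None, without_recon)
        assert state_hash(a.encoder.state_dict()) == state_hash(b.encoder.state_dict())
        assert state_hash(a.seg_decoders.state_dict()) == state_hash(
            b.seg_decoders.state_dict()
        )


class TestDeterminism:
    def test_same_seed_same_loss_history(self, tiny_synth, tiny_net_config):
        train, val, unlabeled = tiny_synth
        histories = []
        for _ in range(2):
            model = LesionSegmentationModel(
                train, val, unlabeled, tiny_net_config, tiny_cfg()
            )
            res = model.fit()
            histories.append(res.loss_history)
        assert histories[0].equals(histories[1])


class TestTrainAllPrimaries:
    def test_registry_and_shared_snapshot(self, tiny_synth):
        train, val, unlabeled = tiny_synth
        cfg = tiny_cfg(epochs_sup=2, epochs_unsup=1)
        net_cfg = NetworkConfig(depth=3, base_channels=4)
        registry = train_all_primaries(train, val, unlabeled, cfg, net_cfg)
        assert set(registry) == set(LESIONS)
        for lesion, state in registry.items():
            assert state.config.primary == lesion
            assert state.best_val_dice is not None

    def test_training_beats_random_initialisation(self, tiny_synth):
        from retseg.trainer import _val_dice

        train, val, unlabeled = tiny_synth
        cfg = tiny_cfg(epochs_sup=6, epochs_unsup=2, primary="EX")
        net_cfg = NetworkConfig(depth=3, base_channels=4)
        init_net = build_network(net_cfg, seed=cfg.seed)
        init_dice = _val_dice(init_net, val, "EX")
        model = LesionSegmentationModel(train, val, unlabeled, net_cfg, cfg)
        res = model.fit()
        assert res.best_val_dice >= init_dice


class TestResultsObject:
    def test_summary_and_curves(self, tiny_synth, tiny_net_config, tmp_path):
        train, val, unlabeled = tiny_synth
        model = LesionSegmentationModel(
            train, val, unlabeled, tiny_net_config, tiny_cfg()
        )
        res = model.fit()
        text = res.summary()
        assert "primary lesion" in text and "EX" in text
        res.plot_learning_curves(tmp_path / "curves.png")
        assert (tmp_path / "curves.png").exists()
        res.save(tmp_path / "model.npz")
        assert (tmp_path / "model.npz").exists()

    def test_predictions_have_probability_semantics(self, tiny_synth, tiny_net_config):
        train, val, unlabeled = tiny_synth
        model = LesionSegmentationModel(
            train, val, unlabeled, tiny_net_config, tiny_cfg(epochs_sup=1)
        )
        res = model.fit()
        probs = res.predict_proba(val.images)
        for p in probs.values():
            assert p.min() >= 0.0 and p.max() <= 1.0
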