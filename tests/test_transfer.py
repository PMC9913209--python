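"""Transfer network: backbone, meta-networks, constraint, extraction."""

import numpy as np
import pytest

from tlradiomics import transfer
from tlradiomics.errors import DataError, LeakageError, ParameterError, ShapeError
from tlradiomics.nn import StageConvNet, softmax_cross_entropy
from tlradiomics.preprocessing import CtPatch

from conftest import toy_blob_images


def _as_patches(images, labels):
    return [
        CtPatch(pixels=img, label=int(lab), patient_id=f"P{i}")
        for i, (img, lab) in enumerate(zip(images, labels))
    ]


class TestBackbone:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = StageConvNet([3, 4], 2, rng)
        x = rng.standard_normal((2, 3, 8, 8)) * 0.5
        y = np.array([0, 1])
        logits, _ = net.forward(x)
        _, dl = softmax_cross_entropy(logits, y)
        grads = net.backward(dl)
        eps = 1e-6
        for name in ("conv0_W", "conv1_b", "head_W"):
            p = net.params[name]
            idx = tuple(0 for _ in p.shape)
            p[idx] += eps
            l1, _ = softmax_cross_entropy(net.forward(x, keep_cache=False)[0], y)
            p[idx] -= 2 * eps
            l2, _ = softmax_cross_entropy(net.forward(x, keep_cache=False)[0], y)
            p[idx] += eps
            assert (l1 - l2) / (2 * eps) == pytest.approx(grads[name][idx], abs=1e-6)

    def test_feature_width_conservation(self):
        for channels in [(5, 7), (8, 12, 16), (3,)]:
            cfg = transfer.NetworkConfig(stage_channels=channels, input_size=32)
            rng = np.random.default_rng(1)
            net = StageConvNet(cfg.scaled_channels, 2, rng)
            feats = net.features(rng.random((2, 3, 32, 32)))
            assert feats.shape == (2, sum(channels))

    def test_default_config_is_3904_wide(self):
        assert transfer.NetworkConfig().feature_width == 3904


class TestPretrain:
    def test_deterministic(self, tiny_net_cfg):
        imgs, labels, _ = toy_blob_images(16, 32, seed=0)
        a = transfer.pretrain_source(imgs, labels, tiny_net_cfg, seed=7, epochs=2)
        b = transfer.pretrain_source(imgs, labels, tiny_net_cfg, seed=7, epochs=2)
        assert a.history.task_loss == b.history.task_loss

    def test_zero_epochs_returns_initialisation(self, tiny_net_cfg):
        imgs, labels, _ = toy_blob_images(16, 32, seed=0)
        m = transfer.pretrain_source(imgs, labels, tiny_net_cfg, seed=3, epochs=0)
        init = StageConvNet(tiny_net_cfg.scaled_channels, 2, np.random.default_rng(3))
        for k in init.params:
            np.testing.assert_array_equal(m.net.params[k], init.params[k])

    def test_separable_toy_reaches_high_accuracy(self):
        cfg = transfer.NetworkConfig(input_size=32, width_scale=0.25)
        imgs, labels, _ = toy_blob_images(40, 32, seed=1)
        m = transfer.pretrain_source(imgs, labels, cfg, seed=0, epochs=20)
        acc = (m.net.predict_proba(imgs.transpose(0, 3, 1, 2)).argmax(1) == labels).mean()
        assert acc >= 0.95
        assert m.history.task_loss[-1] <= m.history.task_loss[0]

    def test_single_class_rejected(self, tiny_net_cfg):
        imgs, _, _ = toy_blob_images(8, 32, seed=0)
        with pytest.raises(DataError):
            transfer.pretrain_source(imgs, np.zeros(8, dtype=int), tiny_net_cfg, seed=0)


class TestMetaSelection:
    def test_zero_parameters_give_half_gates(self):
        state = transfer.MetaSelectionState.init([4, 6])
        gates = transfer.selection_gates(
            state, [np.random.default_rng(0).random((3, 4)),
                    np.random.default_rng(1).random((3, 6))]
        )
        for g, c in zip(gates, (4, 6)):
            assert len(g) == c
            np.testing.assert_allclose(g, 0.5)

    def test_gate_monotone_in_logit(self):
        state = transfer.MetaSelectionState.init([4])
        feats = [np.random.default_rng(0).random((5, 4))]
        g0 = transfer.selection_gates(state, feats)[0][1]
        state.gate_bias[0][1] += 0.3
        g1 = transfer.selection_gates(state, feats)[0][1]
        assert g1 > g0

    def test_channel_mismatch_raises(self):
        state = transfer.MetaSelectionState.init([4])
        with pytest.raises(ShapeError):
            transfer.selection_gates(state, [np.zeros((2, 5))])

    def test_constraint_loss_hand_value(self):
        # one stage, 2 channels: per-channel mean squared diffs 4 and 2,
        # gates (1, 0.5), lambda 1 -> (1*4 + 0.5*2) / 2 = 2.5
        state = transfer.MetaSelectionState.init([2], lam=1.0)
        t = np.zeros((1, 2, 2, 2))
        s = np.zeros((1, 2, 2, 2))
        s[0, 0] = 2.0        # msd 4
        s[0, 1] = np.sqrt(2)  # msd 2
        val = transfer.transfer_constraint_loss(
            [t], [s], state, gates=[np.array([1.0, 0.5])]
        )
        assert val == pytest.approx(2.5)

    def test_constraint_zero_cases(self):
        state = transfer.MetaSelectionState.init([2], lam=0.0)
        t = np.random.default_rng(0).random((1, 2, 3, 3))
        assert transfer.transfer_constraint_loss([t], [t + 1], state) == 0.0
        state2 = transfer.MetaSelectionState.init([2], lam=1.0)
        assert transfer.transfer_constraint_loss(
            [t], [t + 1], state2, gates=[np.zeros(2)]
        ) == pytest.approx(0.0)
        assert transfer.transfer_constraint_loss([t], [t.copy()], state2) == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ParameterError):
            transfer.MetaSelectionState.init([2], lam=-1.0)

    def test_probe_lowers_gates_for_noise_channels(self):
        """Channels carrying label signal keep higher gates than pure noise."""
        rng = np.random.default_rng(0)
        n, c = 60, 12
        y = np.array([0, 1] * (n // 2), dtype=float)
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            feats = rng.standard_normal((n, c))
            feats[:, :4] += 2.0 * y[:, None]  # first 4 channels informative
            state = transfer.MetaSelectionState.init([c])
            probe = transfer.MetaProbe(state, c)
            for _ in range(8):
                probe.update([feats], y)
            gates = transfer.selection_gates(state, [feats])[0]
            diffs.append(gates[:4].mean() - gates[4:].mean())
        from scipy.stats import wilcoxon

        assert np.mean(diffs) > 0
        assert wilcoxon(diffs, alternative="greater").pvalue < 0.05


class TestTargetTraining:
    def _toy_sets(self, seed=0, n=24):
        imgs, labels, _ = toy_blob_images(n, 32, seed=seed)
        patches = _as_patches(imgs, labels)
        # interleave so both splits contain both classes
        return (patches[::2], labels[::2], patches[1::2], labels[1::2])

    def test_lambda_zero_matches_nontransfer_trajectory(self, tiny_net_cfg):
        tr_p, tr_y, va_p, va_y = self._toy_sets()
        imgs, labels, _ = toy_blob_images(12, 32, seed=5)
        src = transfer.pretrain_source(imgs, labels, tiny_net_cfg, seed=2, epochs=1)
        with_t = transfer.train_target_with_transfer(
            tr_p, tr_y, va_p, va_y, src, tiny_net_cfg, lam=0.0, seed=4, epochs=2,
            freeze_gates=True, adapt_gates=False,
        )
        without = transfer.train_nontransfer(
            tr_p, tr_y, va_p, va_y, tiny_net_cfg, seed=4, epochs=2
        )
        assert with_t.history.task_loss == without.history.task_loss
        for k in with_t.net.params:
            np.testing.assert_array_equal(with_t.net.params[k], without.net.params[k])

    def test_patient_overlap_rejected(self, tiny_net_cfg):
        tr_p, tr_y, va_p, va_y = self._toy_sets()
        with pytest.raises(LeakageError):
            transfer.train_nontransfer(
                tr_p, tr_y, va_p, va_y, tiny_net_cfg, seed=0, epochs=1,
                train_ids=["A", "B"], val_ids=["B", "C"],
            )

    def test_nontransfer_overfits_on_average(self):
        """Training AUC >= validation AUC on average at n=100 over 10 seeds."""
        from tlradiomics.evaluation import auc
        from tlradiomics import fixtures

        cfg = transfer.NetworkConfig(input_size=32, width_scale=0.1)
        gaps = []
        for seed in range(10):
            spec = fixtures.SyntheticCohortSpec(n=100, patch_size=32, seed=300 + seed)
            patches, table = fixtures.generate_target_cohort(spec)
            y = table["label"].to_numpy()
            m = transfer.train_nontransfer(
                patches[:70], y[:70], patches[70:], y[70:], cfg, seed=seed, epochs=6
            )
            tr_scores = m.net.predict_proba(
                transfer.patches_to_array(patches[:70])
            )[:, 1]
            gaps.append(auc(tr_scores, y[:70]) - m.history.val_auc[-1])
        assert np.mean(gaps) > 0

    def test_noise_source_gates_fall(self, tiny_net_cfg):
        """With a fully mismatched source, adaptive gates drop below init."""
        from tlradiomics import fixtures

        spec = fixtures.SyntheticCohortSpec(n=60, patch_size=32, seed=21)
        patches, table = fixtures.generate_target_cohort(spec)
        y = table["label"].to_numpy()
        dom = fixtures.generate_source_domain(
            fixtures.SourceDomainSpec(kind="natural_like", n_classes=2, n=24,
                                      target_overlap=0.0, image_size=32, seed=2)
        )
        src = transfer.pretrain_source(dom, None, tiny_net_cfg, seed=5, epochs=2)
        m = transfer.train_target_with_transfer(
            patches[:40], y[:40], patches[40:], y[40:], src, tiny_net_cfg,
            lam=1.0, seed=0, epochs=4,
        )
        mean_gate = np.mean(
            [g for b in m.meta.gate_bias for g in 1 / (1 + np.exp(-b))]
        )
        assert mean_gate < 0.5


class TestExtraction:
    def test_row_alignment_and_determinism(self, small_cohort, tiny_net_cfg):
        patches, _ = small_cohort
        rng = np.random.default_rng(0)
        net = StageConvNet(tiny_net_cfg.scaled_channels, 2, rng)
        model = transfer.SourceModel(net=net, cfg=tiny_net_cfg, seed=0,
                                     history=transfer.TrainHistory())
        subset = patches[:6]
        fm = transfer.extract_features(model, subset)
        assert fm.values.shape == (6, tiny_net_cfg.feature_width)
        # permuting inputs permutes rows identically
        perm = [3, 1, 0, 5, 2, 4]
        fm_perm = transfer.extract_features(model, [subset[i] for i in perm])
        np.testing.assert_array_equal(fm_perm.values, fm.values[perm])
        # identical patches give identical rows
        fm_dup = transfer.extract_features(model, [subset[0], subset[0]])
        np.testing.assert_array_equal(fm_dup.values[0], fm_dup.values[1])


class TestHeatmap:
    def _model(self, cfg, seed=0):
        rng = np.random.default_rng(seed)
        net = StageConvNet(cfg.scaled_channels, 2, rng)
        return transfer.SourceModel(net=net, cfg=cfg, seed=seed,
                                    history=transfer.TrainHistory())

    def test_constant_input_flagged_constant(self, tiny_net_cfg):
        model = self._model(tiny_net_cfg)
        patch = CtPatch(pixels=np.full((32, 32, 3), 0.5))
        hm = transfer.filter_response_heatmap(model, patch, 0)
        assert hm.constant
        np.testing.assert_array_equal(hm.values, 0.0)

    def test_values_bounded(self, small_cohort, tiny_net_cfg):
        patches, _ = small_cohort
        model = self._model(tiny_net_cfg)
        hm = transfer.filter_response_heatmap(model, patches[0], 10)
        assert 0.0 <= hm.values.min() and hm.values.max() <= 1.0
        assert np.isfinite(hm.values).all()

    def test_invalid_channel_rejected(self, tiny_net_cfg):
        model = self._model(tiny_net_cfg)
        patch = CtPatch(pixels=np.zeros((32, 32, 3)))
        with pytest.raises(ParameterError):
            transfer.filter_response_heatmap(model, patch, 9999)

    def test_top_channel_localises_blob(self, tiny_net_cfg):
        """The strongest-responding filter peaks inside the bright blob."""
        hits = 0
        for seed in range(10):
            imgs, labels, blob_mask = toy_blob_images(12, 32, seed=seed)
            src = transfer.pretrain_source(imgs, labels, tiny_net_cfg,
                                           seed=seed, epochs=3)
            bright = imgs[labels == 1][0]
            patch = CtPatch(pixels=bright)
            feats = src.net.features(bright.transpose(2, 0, 1)[None])[0]
            top = int(np.argmax(feats))
            hm = transfer.filter_response_heatmap(src, patch, top)
            hits += bool(blob_mask[hm.max_location])
        assert hits >= 8
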