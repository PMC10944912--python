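import numpy as np
import pytest

import seqexpress as sx
from seqexpress.model import (
    Dataset,
    ModelConfig,
    ModelEnsemble,
    TrainConfig,
    build_model,
    make_dataset,
    predict,
    train,
    train_ensemble,
)
from seqexpress.pseudobulk import Standardizer


def tiny_config(**kw):
    defaults = dict(
        up_len=30, down_len=10, conv_blocks=((3, 5, 4), (2, 3, 2)),
        fc_hidden=(4,), dropout=0.0, n_tasks=2, seed=3,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def random_data(n, cfg, seed=0):
    rng = np.random.default_rng(seed)
    return Dataset(
        rng.random((n, 4, cfg.window_len)).astype(np.float32),
        rng.random((n, 5)).astype(np.float32),
        rng.random((n, cfg.n_tasks)).astype(np.float32),
        [f"g{i}" for i in range(n)],
    )


class TestBuildModel:
    def test_output_length_matches_task_count(self):
        cfg = tiny_config(n_tasks=7)
        net = build_model(cfg)
        out = net.forward(np.zeros((3, 4, 40), np.float32), np.zeros((3, 5), np.float32))
        assert out.shape == (3, 7)

    def test_identical_inputs_identical_outputs(self):
        net = build_model(tiny_config())
        x = np.random.default_rng(1).random((1, 4, 40)).astype(np.float32)
        h = np.ones((1, 5), np.float32)
        both = net.forward(np.concatenate([x, x]), np.concatenate([h, h]))
        np.testing.assert_array_equal(both[0], both[1])

    def test_sequence_channels_reach_the_output(self):
        """An all-N window and an all-A window must score differently under
        a random untrained network (the sequence pathway is live)."""
        cfg = tiny_config()
        net = build_model(cfg)
        all_n = sx.one_hot("N" * 40).values[None]
        all_a = sx.one_hot("A" * 40).values[None]
        h = np.zeros((1, 5), np.float32)
        assert not np.allclose(net.forward(all_n, h), net.forward(all_a, h))

    def test_excessive_pooling_is_config_error(self):
        with pytest.raises(ValueError, match="size 0|exceeds"):
            ModelConfig(up_len=10, down_len=10, conv_blocks=((4, 3, 50),),
                        n_tasks=1).flattened_size()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_blocks=(), n_tasks=1)
        with pytest.raises(ValueError):
            ModelConfig(n_tasks=0)
        with pytest.raises(ValueError):
            ModelConfig(conv_blocks=((0, 3, 2),), n_tasks=1)

    def test_numerical_gradients_match_backprop(self):
        """Central-difference check of the full backward pass (conv, pool,
        dense, multitask head) at float32 tolerance."""
        cfg = tiny_config()
        net = build_model(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((3, 4, 40)).astype(np.float32)
        h = rng.random((3, 5)).astype(np.float32)
        y = rng.random((3, 2)).astype(np.float32)

        def loss():
            p = net.forward(x, h)
            return float(np.mean((p - y) ** 2))

        p = net.forward(x, h)
        net.backward((2.0 / p.size) * (p - y))
        grads = [g.copy() for g in net.grads]
        for par, g in zip(net.params, grads):
            flat_idx = rng.integers(0, par.size, size=4)
            for fi in flat_idx:
                ix = np.unravel_index(fi, par.shape)
                old = par[ix]
                par[ix] = old + 1e-3
                lp = loss()
                par[ix] = old - 1e-3
                lm = loss()
                par[ix] = old
                num = (lp - lm) / 2e-3
                assert g[ix] == pytest.approx(num, abs=2e-3, rel=2e-2)


class TestTrain:
    def test_same_seed_reproduces_history_exactly(self):
        cfg = tiny_config()
        data = random_data(32, cfg)
        val = random_data(8, cfg, seed=1)
        val.gene_ids = [f"v{i}" for i in range(8)]
        runs = []
        for _ in range(2):
            net, hist = train(build_model(cfg), data, val,
                              TrainConfig(max_epochs=4, batch_size=8), seed=5)
            runs.append((hist, net.get_weights()))
        assert runs[0][0] == runs[1][0]
        for w1, w2 in zip(runs[0][1], runs[1][1]):
            np.testing.assert_array_equal(w1, w2)

    def test_constant_targets_fit_to_near_zero_mse(self):
        cfg = tiny_config(fc_hidden=())
        data = random_data(32, cfg)
        data.y[:] = 0.37
        val = random_data(8, cfg, seed=1)
        val.y[:] = 0.37
        val.gene_ids = [f"v{i}" for i in range(8)]
        net, hist = train(build_model(cfg), data, val,
                          TrainConfig(initial_lr=1e-2, max_epochs=40, batch_size=4),
                          seed=5)
        assert min(h["val_loss"] for h in hist) < 0.01  # target scale is 0.37^2


    def test_overlapping_train_val_rejected(self):
        cfg = tiny_config()
        data = random_data(16, cfg)
        with pytest.raises(ValueError, match="overlap"):
            train(build_model(cfg), data, data, TrainConfig(max_epochs=1), seed=0)

    def test_lr_drops_by_factor_after_patience(self):
        cfg = tiny_config()
        data = random_data(16, cfg)
        val = random_data(8, cfg, seed=1)
        val.gene_ids = [f"v{i}" for i in range(8)]
        tc = TrainConfig(max_epochs=20, batch_size=8, lr_patience=3)
        _, hist = train(build_model(cfg), data, val, tc, seed=5)
        lrs = sorted({h["lr"] for h in hist}, reverse=True)
        for a, b in zip(lrs, lrs[1:]):
            assert a / b == pytest.approx(tc.lr_factor)

    def test_train_config_paper_defaults(self):
        tc = TrainConfig()
        assert (tc.initial_lr, tc.lr_patience, tc.lr_factor, tc.max_epochs) == (
            5e-4, 5, 10.0, 40,
        )
        with pytest.raises(ValueError):
            TrainConfig(lr_factor=0.5)


class TestEnsemble:
    @pytest.fixture(scope="class")
    def trained(self):
        cfg = tiny_config()
        data = random_data(32, cfg)
        val = random_data(8, cfg, seed=1)
        val.gene_ids = [f"v{i}" for i in range(8)]
        ens = train_ensemble(
            data, val, cfg, TrainConfig(max_epochs=3, batch_size=8),
            task_names=["a", "b"], n_replicates=3, base_seed=11,
        )
        return cfg, data, ens

    def test_holds_one_history_per_replicate(self, trained):
        _, _, ens = trained
        assert ens.n_replicates == 3
        assert len(ens.histories) == 3

    def test_replicates_differ(self, trained):
        _, _, ens = trained
        w0 = ens.networks[0].get_weights()
        w1 = ens.networks[1].get_weights()
        assert any(not np.array_equal(a, b) for a, b in zip(w0, w1))

    def test_prediction_is_replicate_mean(self, trained):
        cfg, data, ens = trained
        x, h = data.x_seq[:4], data.x_hl[:4]
        manual = np.mean([net.predict(x, h) for net in ens.networks], axis=0)
        np.testing.assert_allclose(predict(ens, x, h), manual, atol=1e-7)

    def test_single_replicate_equals_its_network(self):
        cfg = tiny_config()
        data = random_data(16, cfg)
        val = random_data(8, cfg, seed=1)
        val.gene_ids = [f"v{i}" for i in range(8)]
        ens = train_ensemble(data, val, cfg, TrainConfig(max_epochs=2, batch_size=8),
                             n_replicates=1, base_seed=2)
        np.testing.assert_allclose(
            predict(ens, data.x_seq, data.x_hl),
            ens.networks[0].predict(data.x_seq, data.x_hl),
            atol=1e-7,
        )

    def test_identity_standardizer_is_a_no_op(self, trained):
        cfg, data, ens = trained
        std = predict(ens, data.x_seq[:4], data.x_hl[:4])
        unstd = predict(ens, data.x_seq[:4], data.x_hl[:4], unstandardized=True)
        np.testing.assert_allclose(std, unstd, atol=1e-7)

    def test_unstandardize_applies_stored_scaling(self, trained):
        cfg, data, ens = trained
        ens2 = ModelEnsemble(
            networks=ens.networks, config=ens.config, task_names=ens.task_names,
            standardizer=Standardizer(
                means=np.array([1.0, -1.0]), sds=np.array([2.0, 3.0]),
                populations=["a", "b"],
            ),
        )
        std = predict(ens2, data.x_seq[:4], data.x_hl[:4])
        unstd = predict(ens2, data.x_seq[:4], data.x_hl[:4], unstandardized=True)
        np.testing.assert_allclose(unstd, std * [2.0, 3.0] + [1.0, -1.0], atol=1e-6)

    def test_task_count_mismatch_with_standardizer_rejected(self, trained):
        cfg, data, ens = trained
        bad = ModelEnsemble(
            networks=ens.networks, config=ens.config, task_names=ens.task_names,
            standardizer=Standardizer.identity(["only_one"]),
        )
        with pytest.raises(ValueError, match="tasks"):
            predict(bad, data.x_seq[:2], data.x_hl[:2])

    def test_save_load_round_trip(self, trained, tmp_path):
        cfg, data, ens = trained
        ens.save(tmp_path / "ens")
        back = ModelEnsemble.load(tmp_path / "ens")
        np.testing.assert_allclose(
            predict(back, data.x_seq[:4], data.x_hl[:4]),
            predict(ens, data.x_seq[:4], data.x_hl[:4]),
            atol=0,
        )
        assert back.task_names == ens.task_names


class TestFeaturePathways:
    """Ablation checks mirroring the model's two input pathways: expression
    driven only by half-life features is learnable with shuffled sequence;
    expression driven only by motifs is learnable without half-life input."""

    @pytest.fixture(scope="class")
    def halflife_only_data(self):
        cfg = sx.SimConfig(
            n_genes=400, n_chromosomes=4, up_len=150, down_len=50, n_cells=30,
            motifs=(), placement_rate=0.0, gamma=(0.0, -0.3, -0.4, -0.2, 0.3),
            sigma=0.1, count_model="poisson", seed=21,
        )
        return cfg, sx.simulate(cfg)

    @pytest.fixture(scope="class")
    def motif_only_data(self):
        cfg = sx.SimConfig(
            n_genes=400, n_chromosomes=4, up_len=150, down_len=50, n_cells=30,
            motifs=(sx.Motif("TGACTCAGCG", (0.9, 0.9, 0.9)),),
            gamma=None, sigma=0.1, count_model="poisson", seed=22,
        )
        return cfg, sx.simulate(cfg)

    @staticmethod
    def _fit_and_score(res, shuffle_seq=False, zero_halflife=False, seed=0):
        import pandas as pd

        counts = pd.DataFrame(res.counts.toarray(), index=res.gene_ids,
                              columns=res.barcodes)
        pb = sx.standardize(
            sx.aggregate(sx.normalize_counts(counts, "tenx"), res.labels["population"])
        )
        hln, _ = sx.normalize_halflife(res.truth.halflife_raw)
        ds = make_dataset(res.windows, hln, pb.values, res.gene_ids)
        rng = np.random.default_rng(seed)
        if shuffle_seq:
            for i in range(len(ds)):  # destroy sequence info, keep composition
                ds.x_seq[i] = ds.x_seq[i][:, rng.permutation(ds.x_seq.shape[2])]
        if zero_halflife:
            ds.x_hl[:] = 0.0
        tr, va, te = (ds.subset(np.arange(320)), ds.subset(np.arange(320, 360)),
                      ds.subset(np.arange(360, 400)))
        mc = ModelConfig(up_len=150, down_len=50, conv_blocks=((32, 6, 200),),
                         dropout=0.0, n_tasks=3, seed=1)
        ens = train_ensemble(tr, va, mc, TrainConfig(batch_size=16),
                             n_replicates=1, base_seed=seed)
        preds = predict(ens, te.x_seq, te.x_hl)
        return np.mean(
            [np.corrcoef(te.y[:, j], preds[:, j])[0, 1] for j in range(3)]
        )

    def test_halflife_signal_survives_sequence_shuffling(self, halflife_only_data):
        _, res = halflife_only_data
        full = self._fit_and_score(res)
        shuffled = self._fit_and_score(res, shuffle_seq=True)
        assert full > 0.4
        assert shuffled == pytest.approx(full, abs=0.15)

    def test_motif_signal_survives_halflife_ablation(self, motif_only_data):
        _, res = motif_only_data
        full = self._fit_and_score(res)
        no_hl = self._fit_and_score(res, zero_halflife=True)
        assert full > 0.4
        assert no_hl > full - 0.15
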