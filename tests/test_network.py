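import numpy as np
import pytest

from iadep import (
    IADEP,
    ModelConfig,
    TraitConfig,
    fuse_omics,
    pcc,
    simulate_genotypes,
    simulate_omics,
    simulate_trait,
)
from iadep.embedding import embed_matrix
from iadep.network import _Network
from iadep.nn.autograd import Tensor
from iadep.priors import compute_priors


class TestFuseOmics:
    def test_zero_inputs_give_half(self):
        out = fuse_omics(np.zeros(4), np.zeros(4))
        np.testing.assert_allclose(out, 0.5)

    def test_residual_increment_in_unit_interval(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(100) * 10, rng.standard_normal(100) * 10
        inc = fuse_omics(a, b) - b
        assert np.all(inc > 0) and np.all(inc < 1)

    def test_large_input_asymptote(self):
        out = fuse_omics(np.array([1e6]), np.array([3.0]))
        np.testing.assert_allclose(out, 4.0, atol=1e-9)

    def test_width_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_omics(np.zeros(3), np.zeros(4))


def _fit_setup(n=160, m=120, h2=0.8, seed=0, omics=False):
    g = simulate_genotypes(n, m, seed=seed)
    pheno, truth = simulate_trait(g, TraitConfig(n_qtl_additive=10, h2_target=h2, seed=seed))
    y = pheno["y"].to_numpy()
    tab = compute_priors(g, y)
    emb = embed_matrix(g, tab)
    om = None
    if omics:
        om = simulate_omics(truth, n_features=12, seed=seed,
                            sample_ids=g.samples).to_numpy()
    return g, y, tab, emb, om


class TestFit:
    def test_training_reduces_loss(self, tiny_model_config):
        g, y, tab, emb, _ = _fit_setup()
        res = IADEP(y, emb, g.dosages - 1.0, priors=tab, config=tiny_model_config).fit()
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_same_seed_same_predictions(self, tiny_model_config):
        g, y, tab, emb, _ = _fit_setup()
        preds = []
        for _ in range(2):
            res = IADEP(y, emb, g.dosages - 1.0, priors=tab, config=tiny_model_config).fit()
            preds.append(res.predict(embedded=emb, raw_signed=g.dosages - 1.0))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_embedding_values_frozen_during_training(self, tiny_model_config):
        g, y, tab, emb, _ = _fit_setup()
        before = emb.values.copy()
        IADEP(y, emb, g.dosages - 1.0, priors=tab, config=tiny_model_config).fit()
        assert np.array_equal(emb.values, before)

    def test_stronger_l2_shrinks_parameters(self, tiny_model_config):
        import dataclasses

        g, y, tab, emb, _ = _fit_setup()
        norms = []
        for wd in (1e-5, 1e-3):
            cfg = dataclasses.replace(tiny_model_config, weight_decay=wd, epochs=15)
            res = IADEP(y, emb, g.dosages - 1.0, priors=tab, config=cfg).fit()
            norms.append(sum(float((p.data**2).sum()) for p in res.network.parameters()))
        assert norms[1] < norms[0]

    def test_nan_loss_aborts_with_diagnostics(self, tiny_model_config):
        import dataclasses

        g, y, tab, emb, _ = _fit_setup()
        cfg = dataclasses.replace(tiny_model_config, weight_decay=1e306)
        with np.errstate(over="ignore"), pytest.raises(RuntimeError, match="epoch"):
            IADEP(y, emb, g.dosages - 1.0, priors=tab, config=cfg).fit()

    def test_omics_fusion_trains(self, tiny_model_config):
        g, y, tab, emb, om = _fit_setup(omics=True)
        res = IADEP(y, emb, g.dosages - 1.0, omics=om, priors=tab,
                    config=tiny_model_config).fit()
        assert np.isfinite(res.loss_trace).all()
        yhat = res.predict(embedded=emb, raw_signed=g.dosages - 1.0, omics=om)
        assert yhat.shape == y.shape

    def test_trainable_embedding_updates_table(self, tiny_model_config):
        import dataclasses

        g, y, tab, emb, _ = _fit_setup()
        cfg = dataclasses.replace(tiny_model_config, trainable_embedding=True, epochs=3)
        model = IADEP(y, emb, g.dosages - 1.0, priors=tab, config=cfg)
        init = model._embedding_init(np.ones(3))
        res = model.fit()
        trained = res.network.embed_table.table.data
        assert trained.shape == init.shape
        assert not np.allclose(trained * res.channel_scale[None, None, :], init)


class TestPredict:
    def test_predicting_train_samples_reproduces_fitted_values(self, tiny_model_config):
        g, y, tab, emb, _ = _fit_setup()
        res = IADEP(y, emb, g.dosages - 1.0, priors=tab, config=tiny_model_config).fit()
        a = res.fittedvalues
        b = res.predict(embedded=emb, raw_signed=g.dosages - 1.0)
        np.testing.assert_array_equal(a, b)

    def test_dropout_off_at_prediction(self, tiny_model_config):
        g, y, tab, emb, _ = _fit_setup()
        res = IADEP(y, emb, g.dosages - 1.0, priors=tab, config=tiny_model_config).fit()
        p1 = res.predict(embedded=emb, raw_signed=g.dosages - 1.0)
        p2 = res.predict(embedded=emb, raw_signed=g.dosages - 1.0)
        np.testing.assert_array_equal(p1, p2)

    def test_batching_and_sample_order_do_not_change_outputs(self, tiny_model_config):
        g, y, tab, emb, _ = _fit_setup()
        res = IADEP(y, emb, g.dosages - 1.0, priors=tab, config=tiny_model_config).fit()
        full = res.predict(embedded=emb, raw_signed=g.dosages - 1.0, batch_size=256)
        single = res.predict(embedded=emb, raw_signed=g.dosages - 1.0, batch_size=1)
        np.testing.assert_allclose(full, single, atol=1e-6)
        perm = np.random.default_rng(3).permutation(len(y))
        from iadep.evaluation import _subset_embedded

        shuffled = res.predict(embedded=_subset_embedded(emb, perm),
                               raw_signed=(g.dosages - 1.0)[perm])
        np.testing.assert_allclose(shuffled, full[perm], atol=1e-5)

    def test_marker_mismatch_rejected(self, tiny_model_config):
        g, y, tab, emb, _ = _fit_setup()
        res = IADEP(y, emb, g.dosages - 1.0, priors=tab, config=tiny_model_config).fit()
        other = simulate_genotypes(10, 60, seed=99)
        with pytest.raises(ValueError, match="marker"):
            res.predict(genotypes=other)

    def test_end_to_end_signal_recovery(self):
        """Held-out accuracy is positive on a heritable trait (seed-averaged)."""
        scores = []
        for seed in range(3):
            g, y, tab, emb, _ = _fit_setup(n=220, m=150, h2=0.8, seed=seed)
            cfg = ModelConfig(conv_width=8, n_heads=2, stem_stride=4, block_strides=(2, 2),
                              global_hidden=16, n_global_tokens=2, mlp_hidden=(16, 8),
                              epochs=30, seed=seed)
            tr, te = np.arange(180), np.arange(180, 220)
            from iadep.evaluation import _subset_embedded

            res = IADEP(y[tr], _subset_embedded(emb, tr), (g.dosages - 1.0)[tr],
                        priors=tab, config=cfg).fit()
            yhat = res.predict(embedded=_subset_embedded(emb, te),
                               raw_signed=(g.dosages - 1.0)[te])
            scores.append(pcc(y[te], yhat))
        assert np.mean(scores) > 0


class TestArchitectureContracts:
    def test_residual_identity_when_value_projection_zeroed(self):
        cfg = ModelConfig(conv_width=8, n_heads=2, stem_stride=2, block_strides=(2, 2),
                          global_hidden=8, n_global_tokens=2, mlp_hidden=(8, 4), dropout=0.0)
        net = _Network(40, 3, 0, cfg, np.random.default_rng(6))
        net.cross_attn.wo.weight.data[:] = 0.0
        net.cross_attn.wo.bias.data[:] = 0.0
        rng = np.random.default_rng(7)
        raw = Tensor(rng.choice([-1.0, 0.0, 1.0], (4, 40)))
        emb = Tensor(rng.standard_normal((4, 40, 3)))
        tokens = net.local_encode(emb)
        fused = net.global_decode(raw, tokens)
        from iadep.nn.autograd import leaky_relu as tl

        z = net.glob2(tl(net.glob1(raw), cfg.leaky_a))
        np.testing.assert_allclose(fused.data, z.data, atol=1e-12)

    def test_token_count_matches_stride_schedule(self):
        for m, cfg in [
            (800, ModelConfig()),
            (300, ModelConfig(stem_stride=2, block_strides=(2, 2))),
            (64, ModelConfig(stem_stride=2, block_strides=(2, 1))),
        ]:
            net = _Network(m, 3, 0, cfg, np.random.default_rng(0))
            X = np.zeros((2, m, 3))
            raw = np.zeros((2, m))
            tokens = net.local_encode(Tensor(X))
            assert tokens.shape == (2, cfg.n_tokens(m), cfg.conv_width)

    def test_zero_input_finite_output(self):
        cfg = ModelConfig(conv_width=8, n_heads=2, stem_stride=2, block_strides=(2, 2),
                          global_hidden=8, n_global_tokens=2, mlp_hidden=(8, 4))
        net = _Network(50, 3, 0, cfg, np.random.default_rng(8))
        out = net.forward(np.zeros((3, 50, 3)), np.zeros((3, 50)), None,
                          np.random.default_rng(0), training=False)
        assert np.isfinite(out.data).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(conv_width=10, n_heads=4).validate()
        with pytest.raises(ValueError, match="leaky_a"):
            ModelConfig(leaky_a=-1).validate()
        with pytest.raises(ValueError, match="widths"):
            ModelConfig(global_hidden=0, n_heads=1, conv_width=1).validate()
        # zero-padding keeps at least one token for any panel length
        assert ModelConfig().n_tokens(8) >= 1


def test_checkpoint_round_trip(tmp_path, tiny_model_config):
    from iadep.checkpoint import load_predictor, save_results

    g, y, tab, emb, _ = _fit_setup()
    res = IADEP(y, emb, g.dosages - 1.0, priors=tab, config=tiny_model_config).fit()
    path = tmp_path / "model.npz"
    save_results(res, path)
    pred = load_predictor(path)
    np.testing.assert_allclose(pred.predict(g), res.predict(genotypes=g), atol=1e-12)
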