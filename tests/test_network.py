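"""Autoencoder + self-expressive layer: contracts, loss accounting, training."""

import numpy as np
import pytest

from scsem import autodiff as ad
from scsem.autodiff import Adam, Tensor
from scsem.data import CountMatrix, PreprocessedData
from scsem.errors import CapacityError
from scsem.network import (
    ModelConfig,
    composite_loss,
    forward,
    init_state,
    train,
    zinb_params_from_forward,
)
from scsem.preprocess import preprocess
from scsem.zinb import ZINBParams, zinb_log_pmf

from conftest import fast_model_config


def tiny_data(n=3, g=2, seed=0, counts=None, size_factors=None) -> PreprocessedData:
    rng = np.random.default_rng(seed)
    if counts is None:
        counts = rng.poisson(3.0, size=(n, g)) + np.eye(n, g, dtype=int)
    cm = CountMatrix(counts, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(g)])
    enc = rng.normal(size=(n, g))
    s = size_factors if size_factors is not None else rng.uniform(0.5, 2.0, n)
    return PreprocessedData(cm, enc, s, np.ones(g, dtype=bool))


class TestForward:
    def test_output_shapes_under_default_architecture(self):
        data = tiny_data(n=30, g=50, seed=1)
        cfg = ModelConfig(seed=0, dtype="float64")
        state = init_state(cfg, 30, 50)
        fw = forward(state, data)
        assert fw["Y"].shape == (30, 10)
        assert fw["Y_se"].shape == (30, 10)
        for k in ("X_hat", "mu", "theta", "pi"):
            assert fw[k].shape == (30, 50)

    def test_initial_effective_c_is_zero(self):
        data = tiny_data(n=5, g=4)
        cfg = fast_model_config(dtype="float64")
        state = init_state(cfg, 5, 4)
        fw = forward(state, data)
        np.testing.assert_array_equal(fw["C_eff"].data, np.zeros((5, 5)))
        np.testing.assert_array_equal(fw["Y_se"].data, np.zeros((5, cfg.embedding_dim)))
        parts = composite_loss(fw, data, cfg)
        assert parts["se"] == pytest.approx(0.5 * float((fw["Y"].data ** 2).sum()), rel=1e-10)
        assert parts["reg"] == 0.0

    def test_mean_head_scales_with_size_factors(self):
        counts = np.array([[1, 2], [3, 4], [5, 6]])
        data1 = tiny_data(counts=counts, size_factors=np.array([1.0, 1.0, 1.0]))
        data2 = tiny_data(counts=counts, size_factors=np.array([2.0, 1.0, 1.0]))
        cfg = fast_model_config(dtype="float64")
        state = init_state(cfg, 3, 2)
        mu1 = forward(state, data1)["mu"].data
        mu2 = forward(state, data2)["mu"].data
        np.testing.assert_allclose(mu2[0], 2.0 * mu1[0], rtol=1e-12)
        np.testing.assert_allclose(mu2[1:], mu1[1:], rtol=1e-12)

    def test_zinb_params_valid(self):
        data = tiny_data(n=6, g=5)
        cfg = fast_model_config(dtype="float64")
        state = init_state(cfg, 6, 5)
        params = zinb_params_from_forward(forward(state, data))
        assert isinstance(params, ZINBParams)
        assert (params.mean > 0).all() and (params.dispersion > 0).all()
        assert ((params.dropout > 0) & (params.dropout < 1)).all()


class TestCompositeLoss:
    def test_matches_term_by_term_oracle(self):
        """Hand-evaluate every loss term with plain numpy on a 3x2 fixture."""
        data = tiny_data(n=3, g=2, seed=3)
        cfg = ModelConfig(encoder_widths=[4, 3, 2], seed=1, dtype="float64")
        state = init_state(cfg, 3, 2)
        rng = np.random.default_rng(9)
        state.params["C"].data = rng.normal(size=(3, 3))
        fw = forward(state, data)
        parts = composite_loss(fw, data, cfg)

        # independent numpy re-evaluation of the whole forward pass
        p = {k: np.asarray(t.data) for k, t in state.params.items()}
        h = data.encoder_input
        h = np.maximum(h @ p["enc_W0"] + p["enc_b0"], 0)
        h = np.maximum(h @ p["enc_W1"] + p["enc_b1"], 0)
        y = h @ p["enc_W2"] + p["enc_b2"]
        c = p["C"] * (1 - np.eye(3))
        h = np.maximum(y @ p["dec_W0"] + p["dec_b0"], 0)
        d = np.maximum(h @ p["dec_W1"] + p["dec_b1"], 0)
        x_hat = d @ p["head_W_rec"] + p["head_b_rec"]
        mu = data.size_factors[:, None] * np.exp(
            np.clip(d @ p["head_W_mu"] + p["head_b_mu"], -30, 30)
        )
        theta = np.exp(np.clip(d @ p["head_W_theta"] + p["head_b_theta"], -30, 30))
        pi = 1 / (1 + np.exp(-(d @ p["head_W_pi"] + p["head_b_pi"])))
        mu = np.clip(mu, 1e-5, 1e6)
        theta = np.clip(theta, 1e-4, 1e4)
        pi = np.clip(pi, 1e-6, 1 - 1e-6)

        rec = 0.5 * ((data.encoder_input - x_hat) ** 2).sum()
        se = 0.5 * ((y - c @ y) ** 2).sum()
        reg = (c**2).sum()
        zinb = -zinb_log_pmf(data.raw.counts, mu, theta, pi).sum()
        total = (cfg.lambda1 * rec + cfg.lambda2 * se + cfg.lambda3 * reg) * 0.1 + zinb

        assert parts["rec"] == pytest.approx(rec, abs=1e-6)
        assert parts["se"] == pytest.approx(se, abs=1e-6)
        assert parts["reg"] == pytest.approx(reg, abs=1e-6)
        assert parts["zinb"] == pytest.approx(zinb, abs=1e-6)
        assert parts["total"].item() == pytest.approx(total, abs=1e-6)

    def test_zero_lambdas_reduce_to_zinb_nll(self):
        data = tiny_data(n=4, g=3, seed=5)
        cfg = ModelConfig(
            encoder_widths=[4, 3, 2], lambda1=0.0, lambda2=0.0, lambda3=0.0,
            seed=0, dtype="float64",
        )
        state = init_state(cfg, 4, 3)
        fw = forward(state, data)
        parts = composite_loss(fw, data, cfg)
        assert parts["total"].item() == parts["zinb"]

    def test_loss_parts_nonnegative(self):
        data = tiny_data(n=5, g=4, seed=6)
        cfg = fast_model_config(dtype="float64")
        state = init_state(cfg, 5, 4)
        parts = composite_loss(forward(state, data), data, cfg)
        for k in ("rec", "se", "reg", "zinb"):
            assert parts[k] >= 0.0

    def test_loss_toggles(self):
        data = tiny_data(n=4, g=3, seed=2)
        state_cfg = ModelConfig(encoder_widths=[4, 3, 2], seed=0, dtype="float64")
        state = init_state(state_cfg, 4, 3)
        fw = forward(state, data)
        no_rec = ModelConfig(encoder_widths=[4, 3, 2], use_rec=False, dtype="float64")
        no_zinb = ModelConfig(encoder_widths=[4, 3, 2], use_zinb=False, dtype="float64")
        p1 = composite_loss(fw, data, no_rec)
        p2 = composite_loss(forward(state, data), data, no_zinb)
        expected_no_rec = (
            no_rec.lambda2 * p1["se"] + no_rec.lambda3 * p1["reg"]
        ) * 0.1 + p1["zinb"]
        assert p1["total"].item() == pytest.approx(expected_no_rec, rel=1e-9)
        expected_no_zinb = (
            no_zinb.lambda1 * p2["rec"] + no_zinb.lambda2 * p2["se"]
            + no_zinb.lambda3 * p2["reg"]
        ) * 0.1
        assert p2["total"].item() == pytest.approx(expected_no_zinb, rel=1e-9)


class TestTrain:
    def test_loss_descends_within_each_phase(self, small_sim):
        data = preprocess(small_sim.counts, n_top=150)
        cfg = fast_model_config(pretrain_epochs=25, finetune_epochs=15)
        state = train(data, cfg)
        t1 = [e["total"] for e in state.loss_trace if e["phase"] == 1]
        t2 = [e["total"] for e in state.loss_trace if e["phase"] == 2]
        assert t1[-1] <= t1[0] * 1.001
        assert t2[-1] <= t2[0] * 1.001

    def test_same_seed_identical_traces_and_sem(self, small_sim):
        data = preprocess(small_sim.counts, n_top=100)
        cfg = fast_model_config(pretrain_epochs=8, finetune_epochs=5, seed=3)
        s1 = train(data, cfg)
        s2 = train(data, cfg)
        assert [e["total"] for e in s1.loss_trace] == [e["total"] for e in s2.loss_trace]
        np.testing.assert_array_equal(s1.sem, s2.sem)

    def test_effective_c_diagonal_zero_after_training(self, small_sim):
        data = preprocess(small_sim.counts, n_top=100)
        state = train(data, fast_model_config(pretrain_epochs=5, finetune_epochs=5))
        np.testing.assert_array_equal(np.diag(state.sem), 0.0)
        fw = forward(state, data)
        np.testing.assert_array_equal(np.diag(fw["C_eff"].data), 0.0)

    def test_within_group_coefficients_dominate(self, small_sim):
        data = preprocess(small_sim.counts, n_top=200)
        state = train(data, fast_model_config())
        c = np.abs(state.sem)
        g = small_sim.group_labels
        same = g[:, None] == g[None, :]
        np.fill_diagonal(same, False)
        assert c[same].mean() > c[~same].mean()

    def test_checkpoint_round_trip(self, small_sim, tmp_path):
        from scsem.network import ModelState

        data = preprocess(small_sim.counts, n_top=60)
        state = train(data, fast_model_config(pretrain_epochs=3, finetune_epochs=2))
        path = str(tmp_path / "ckpt.npz")
        state.save(path)
        loaded = ModelState.load(path)
        np.testing.assert_array_equal(loaded.sem, state.sem)
        assert loaded.config.pretrain_epochs == 3
        assert len(loaded.loss_trace) == len(state.loss_trace)
        fw1 = forward(state, data)
        fw2 = forward(loaded, data)
        np.testing.assert_array_equal(fw1["Y"].data, fw2["Y"].data)

    def test_capacity_guard(self, small_sim):
        data = preprocess(small_sim.counts, n_top=50)
        with pytest.raises(CapacityError):
            train(data, fast_model_config(max_cells=10))

    def test_cell_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(4.0, size=(30, 40))
        counts[0, 0] += 1
        cm = CountMatrix(counts, [f"c{i}" for i in range(30)],
                         [f"g{j}" for j in range(40)])
        data = preprocess(cm, n_top=40)
        perm = rng.permutation(30)
        cm_p = CountMatrix(
            counts[perm],
            [f"c{i}" for i in range(30)],
            [f"g{j}" for j in range(40)],
        )
        data_p = preprocess(cm_p, n_top=40)
        cfg = fast_model_config(
            encoder_widths=[16, 8, 4], pretrain_epochs=10, finetune_epochs=8,
            dtype="float64",
        )
        c1 = train(data, cfg).sem
        c2 = train(data_p, cfg).sem
        np.testing.assert_allclose(c2, c1[np.ix_(perm, perm)], atol=1e-6)


class TestSelfExpressionRidgeOracle:
    def test_gradient_trained_c_matches_closed_form(self):
        """With identity encoder/decoder, optimal C has a ridge closed form.

        Minimizing lambda2/2 ||Y - CY||_F^2 + lambda3 ||C||_F^2 subject to
        diag(C)=0 decouples by row: c_i solves
        (Y_-i Y_-i^T + (2 lambda3/lambda2) I) c = Y_-i y_i.
        """
        rng = np.random.default_rng(0)
        # two independent 2-D subspaces in R^6, 10 points each
        b1 = rng.normal(size=(2, 6))
        b2 = rng.normal(size=(2, 6))
        y = np.vstack([rng.normal(size=(10, 2)) @ b1, rng.normal(size=(10, 2)) @ b2])
        n = 20
        lam2, lam3 = 1.0, 0.5

        y_t = Tensor(y)
        mask = Tensor(1.0 - np.eye(n))
        c = Tensor(np.eye(n), requires_grad=True)
        opt = Adam([c], lr=0.02, clip_norm=None)
        for _ in range(4000):
            c_eff = c * mask
            loss = lam2 * 0.5 * ad.square_sum(y_t - c_eff @ y_t) + lam3 * ad.square_sum(c_eff)
            opt.zero_grad()
            loss.backward()
            opt.step()
        c_trained = c.data * (1 - np.eye(n))

        c_closed = np.zeros((n, n))
        ridge = 2.0 * lam3 / lam2
        for i in range(n):
            others = np.delete(np.arange(n), i)
            yo = y[others]
            sol = np.linalg.solve(yo @ yo.T + ridge * np.eye(n - 1), yo @ y[i])
            c_closed[i, others] = sol
        np.testing.assert_allclose(c_trained, c_closed, atol=1e-3)
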