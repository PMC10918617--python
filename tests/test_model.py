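"""Twin network: shapes, layer counts, loss contracts, stop-gradient, checkpoints."""

import numpy as np
import pytest

from ionrep.model import (
    ModelConfig,
    TwinModel,
    build_model,
    encode,
    load_checkpoint,
    negative_cosine,
    pad_to_multiple,
    save_checkpoint,
    simsiam_loss,
    simsiam_loss_and_grads,
)
from ionrep.msi_data import IonImage

SMALL = ModelConfig(repr_dim=32, proj_hidden=32, pred_hidden=8)


def _image(rng, side=32):
    return IonImage(pixels=rng.random((side, side)), mz=500.0, normalized=True)


class TestEncoder:
    def test_output_dimension_is_repr_dim(self, rng):
        model = build_model(ModelConfig(), seed=0)
        r = encode(_image(rng), model)
        assert r.shape == (512,)
        assert np.all(np.isfinite(r))

    def test_eval_mode_is_deterministic(self, rng):
        model = build_model(SMALL, seed=0)
        img = _image(rng)
        np.testing.assert_array_equal(encode(img, model), encode(img, model))

    def test_same_seed_same_model(self, rng):
        img = _image(rng)
        r1 = encode(img, build_model(SMALL, seed=9))
        r2 = encode(img, build_model(SMALL, seed=9))
        np.testing.assert_array_equal(r1, r2)

    def test_too_small_image_rejected(self, rng):
        model = build_model(SMALL, seed=0)
        with pytest.raises(ValueError, match="at least 8x8"):
            encode(IonImage(pixels=rng.random((4, 4)), normalized=True), model)

    def test_odd_sizes_are_padded(self, rng):
        model = build_model(SMALL, seed=0)
        r = encode(IonImage(pixels=rng.random((33, 47)), normalized=True), model)
        assert r.shape == (32,)

    def test_pad_to_multiple_reflects(self):
        x = np.arange(12.0).reshape(3, 4)
        out = pad_to_multiple(x, 4)
        assert out.shape == (4, 4)
        np.testing.assert_array_equal(out[3], out[1])  # reflected row


class TestHeads:
    def test_projector_has_three_fc_layers(self):
        model = build_model(ModelConfig(), seed=0)
        assert model.projector.n_fc_layers == 3

    def test_predictor_has_two_fc_layers(self):
        model = build_model(ModelConfig(), seed=0)
        assert model.predictor.n_fc_layers == 2

    def test_predictor_preserves_dimension(self, rng):
        model = build_model(SMALL, seed=0)
        h = rng.normal(size=(4, 32))
        p = model.predict_head(h)
        assert p.shape == h.shape

    def test_zero_vector_maps_to_finite_output(self):
        model = build_model(SMALL, seed=0)
        h = model.project(np.zeros((2, 32)))
        assert np.all(np.isfinite(h))

    def test_heads_deterministic(self, rng):
        model = build_model(SMALL, seed=0)
        r = rng.normal(size=(3, 32))
        np.testing.assert_array_equal(model.project(r), model.project(r))

    def test_nonfinite_input_rejected(self):
        model = build_model(SMALL, seed=0)
        bad = np.full((1, 32), np.nan)
        with pytest.raises(ValueError, match="finite"):
            model.project(bad)


class TestNegativeCosine:
    def test_aligned_gives_minus_one(self, rng):
        v = rng.normal(size=16)
        assert negative_cosine(v, v) == pytest.approx(-1.0)

    def test_orthogonal_gives_zero(self):
        assert negative_cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_anti_aligned_gives_plus_one(self, rng):
        v = rng.normal(size=16)
        assert negative_cosine(v, -v) == pytest.approx(1.0)

    def test_zero_norm_rejected_naming_branch(self):
        with pytest.raises(ValueError, match="second"):
            negative_cosine(np.ones(4), np.zeros(4))


class TestSimSiamLoss:
    def test_all_aligned_gives_minus_one(self, rng):
        h1, h2 = rng.normal(size=(2, 8))
        assert simsiam_loss(h2, h1, h1, h2) == pytest.approx(-1.0)

    def test_mutually_orthogonal_gives_zero(self):
        e = np.eye(4)
        assert simsiam_loss(e[0], e[1], e[2], e[3]) == pytest.approx(0.0)

    def test_bounded_and_symmetric(self, rng):
        """L in [-1, 1] always, and invariant under swapping the view indices."""
        for _ in range(200):
            p1, h1, p2, h2 = rng.normal(size=(4, 8))
            L = simsiam_loss(p1, h1, p2, h2)
            assert -1.0 - 1e-12 <= L <= 1.0 + 1e-12
            assert simsiam_loss(p2, h2, p1, h1) == pytest.approx(L)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            simsiam_loss(rng.normal(size=4), rng.normal(size=4),
                         rng.normal(size=5), rng.normal(size=5))


class TestStopGradient:
    def test_stopgrad_branch_gets_zero_gradient(self):
        """Two-parameter toy branch h_i = diag(a, b) x_i, fixed predictor P.

        The analytic gradient of the symmetric loss with respect to (a, b)
        must equal the finite difference of the surrogate in which the
        stop-gradient targets are frozen — and the target-only path must
        contribute exactly nothing."""
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=(2, 2))
        P = rng.normal(size=(2, 2))
        theta = np.array([0.7, -1.3])

        def branches(th):
            h1, h2 = th * x1, th * x2
            return h1, h2, P @ h1, P @ h2

        h1, h2, p1, p2 = branches(theta)
        _, dp1, dp2 = simsiam_loss_and_grads(p1, h1, p2, h2)
        # chain rule through the predictor path only (stop-grad on targets)
        analytic = (P.T @ dp1[0]) * x1 + (P.T @ dp2[0]) * x2

        h1c, h2c = h1.copy(), h2.copy()
        eps = 1e-7
        for j in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            Lp, _, _ = simsiam_loss_and_grads((P @ (tp * x1)), h1c, (P @ (tp * x2)), h2c)
            Lm, _, _ = simsiam_loss_and_grads((P @ (tm * x1)), h1c, (P @ (tm * x2)), h2c)
            assert analytic[j] == pytest.approx((Lp - Lm) / (2 * eps), abs=1e-6)

        # target-only path: perturbing theta inside the frozen targets while
        # keeping the predictions fixed must change nothing in the analytic
        # gradient model (the loss there is treated as constant in theta)
        Lb, g1, g2 = simsiam_loss_and_grads(p1, h1, p2, h2)
        Lb2, g1b, g2b = simsiam_loss_and_grads(p1, 2 * h1, p2, 2 * h2)
        # scaling targets changes neither the loss value nor the p-gradients'
        # direction of flow through the stopped branch
        assert Lb2 == pytest.approx(Lb)

    def test_full_network_gradients_match_finite_differences(self):
        """Backprop through encoder+projector+predictor agrees with central
        finite differences of the frozen-target surrogate loss."""
        cfg = ModelConfig(repr_dim=16, proj_hidden=16, pred_hidden=8)
        m = TwinModel(cfg, seed=3)
        x = np.random.default_rng(1).random((4, 3, 32, 32))

        def forward():
            r = m.encoder.forward(x, train=True)
            h = m.projector.forward(r, train=True)
            p = m.predictor.forward(h, train=True)
            return h, p

        h0, _ = forward()
        h0 = h0.copy()

        def surrogate():
            h, p = forward()
            L, _, _ = simsiam_loss_and_grads(p[:2], h0[:2], p[2:], h0[2:], eps=1e-12)
            return L

        for p_ in m.params():
            p_.zero_grad()
        h, p = forward()
        _, dp1, dp2 = simsiam_loss_and_grads(p[:2], h0[:2], p[2:], h0[2:], eps=1e-12)
        dh = m.predictor.backward(np.concatenate([dp1, dp2]))
        m.encoder.backward(m.projector.backward(dh))

        params = m.params()
        rngi = np.random.default_rng(7)
        for pi in rngi.choice(len(params), size=10, replace=False):
            par = params[pi]
            idx = tuple(rngi.integers(0, s) for s in par.value.shape)
            eps = 1e-6
            old = par.value[idx]
            par.value[idx] = old + eps
            Lp = surrogate()
            par.value[idx] = old - eps
            Lm = surrogate()
            par.value[idx] = old
            fd = (Lp - Lm) / (2 * eps)
            assert par.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestCheckpoint:
    def test_round_trip_reproduces_encoding(self, rng, tmp_path):
        model = build_model(SMALL, seed=5)
        # perturb running stats so buffers are exercised too
        model.encode_batch(rng.random((4, 3, 32, 32)), train=True)
        img = _image(rng)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.config == model.config
        np.testing.assert_array_equal(encode(img, back), encode(img, model))
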