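"""tgcn_model module: cell equations, encoding, heads, losses, checkpoints."""

import numpy as np
import pytest

import _oracles
from dtgcn.eeg import EEGClip, PredefinedGraph, build_dist_graph, ElectrodeLayout
from dtgcn.model import (DTGCN, ModelConfig, ModelOutput, TGCNParams,
                         classify, encode_clip, load_checkpoint, save_checkpoint,
                         tgcn_cell, total_loss)
from dtgcn.nn import Tensor


def tiny_graph(m=3, rng=None):
    rng = rng or np.random.default_rng(0)
    coords = rng.normal(size=(m, 3))
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    return build_dist_graph(ElectrodeLayout([f"e{i}" for i in range(m)], coords),
                            sigma=1.0, kappa=0.0)


def tiny_model(seed=0, m=3, **kw):
    defaults = dict(n_channels=m, d_model=8, n_heads=2, window_K=3,
                    avg_steps_n=2, hidden_size=4, diffusion_dim=3,
                    k_edges=2, seed=seed)
    defaults.update(kw)
    return DTGCN(ModelConfig(**defaults), tiny_graph(m))


def make_clip(rng, n=30, m=3, seize=False):
    fine = np.zeros(n, dtype=int)
    if seize:
        fine[n // 3: 2 * n // 3] = 1
    return EEGClip(signal=rng.normal(size=(n, m)), fine_labels=fine,
                   coarse_label=int(fine.max()),
                   seizure_class="GN" if seize else "none",
                   clip_seconds=n, fs=1.0)


class TestCell:
    def test_update_gate_one_freezes_hidden(self, rng):
        params = TGCNParams.init(feat_dim=2, hidden=3, rng=rng)
        params.b_u.data[:] = 20.0       # u -> 1
        h_prev = rng.normal(size=(4, 3))
        adj = np.abs(rng.normal(size=(4, 4)))
        state = tgcn_cell(rng.normal(size=(4, 2)), h_prev, adj, params)
        assert np.abs(state.hidden - h_prev).max() < 1e-6

    def test_update_gate_zero_gives_candidate(self, rng):
        params = TGCNParams.init(feat_dim=2, hidden=3, rng=rng)
        params.b_u.data[:] = -20.0      # u -> 0
        h_prev = rng.normal(size=(4, 3))
        adj = np.abs(rng.normal(size=(4, 4)))
        state = tgcn_cell(rng.normal(size=(4, 2)), h_prev, adj, params)
        assert np.abs(state.hidden - state.candidate).max() < 1e-6

    def test_matches_pencil_and_paper_loops(self, rng):
        params = TGCNParams.init(feat_dim=2, hidden=2, rng=rng)
        feats = rng.normal(size=(2, 2))
        h_prev = rng.normal(size=(2, 2))
        adj = np.array([[0.0, 0.8], [0.0, 0.0]])
        state = tgcn_cell(feats, h_prev, adj, params)
        h, u, r, c = _oracles.tgcn_cell_loops(
            feats, h_prev, adj, params.w_u.data, params.b_u.data,
            params.w_r.data, params.b_r.data, params.w_c.data, params.b_c.data)
        assert np.allclose(state.hidden, h, atol=1e-10)
        assert np.allclose(state.update_gate, u, atol=1e-10)
        assert np.allclose(state.reset_gate, r, atol=1e-10)
        assert np.allclose(state.candidate, c, atol=1e-10)

    def test_gate_ranges(self, rng):
        params = TGCNParams.init(feat_dim=3, hidden=4, rng=rng)
        state = tgcn_cell(rng.normal(size=(5, 3)) * 10,
                          rng.normal(size=(5, 4)),
                          np.abs(rng.normal(size=(5, 5))), params)
        assert ((state.update_gate > 0) & (state.update_gate < 1)).all()
        assert ((state.reset_gate > 0) & (state.reset_gate < 1)).all()
        assert (np.abs(state.candidate) <= 1).all()

    def test_hidden_is_convex_combination(self, rng):
        params = TGCNParams.init(feat_dim=2, hidden=3, rng=rng)
        h_prev = rng.normal(size=(4, 3))
        state = tgcn_cell(rng.normal(size=(4, 2)), h_prev,
                          np.abs(rng.normal(size=(4, 4))), params)
        bound = np.maximum(np.abs(h_prev), 1.0) + 1e-12
        assert (np.abs(state.hidden) <= bound).all()

    def test_shape_mismatch_rejected(self, rng):
        params = TGCNParams.init(feat_dim=2, hidden=3, rng=rng)
        with pytest.raises(ValueError):
            tgcn_cell(np.zeros((4, 2)), np.zeros((4, 3)),
                      np.zeros((3, 3)), params)


class TestEncode:
    def test_single_step_clip(self, rng):
        model = tiny_model()
        clip = make_clip(rng, n=1)
        h = encode_clip(clip, model)
        assert h.shape == (3, 4)
        assert np.isfinite(h).all()

    def test_deterministic_across_runs(self, rng):
        clip = make_clip(rng, n=40)
        h1 = encode_clip(clip, tiny_model(seed=7))
        h2 = encode_clip(clip, tiny_model(seed=7))
        assert np.array_equal(h1, h2)

    def test_19_channel_deterministic(self, rng, dist_graph):
        cfg = ModelConfig(d_model=16, n_heads=2, hidden_size=4,
                          diffusion_dim=4, seed=3)
        model = DTGCN(cfg, dist_graph)
        sig = rng.normal(size=(100, 19))
        clip = EEGClip(signal=sig, fine_labels=np.zeros(100, dtype=int),
                       coarse_label=0, clip_seconds=100, fs=1.0)
        assert np.array_equal(encode_clip(clip, model),
                              encode_clip(clip, model))

    def test_channel_permutation_equivariance(self, rng):
        """Permuting channels, layout and channel-indexed parameters
        permutes the rows of h_N identically."""
        m = 4
        perm = np.array([2, 0, 3, 1])
        coords = rng.normal(size=(m, 3))
        coords /= np.linalg.norm(coords, axis=1, keepdims=True)

        def build(coord_mat):
            g = build_dist_graph(
                ElectrodeLayout([f"e{i}" for i in range(m)], coord_mat),
                sigma=1.0, kappa=0.0)
            return DTGCN(ModelConfig(n_channels=m, d_model=8, n_heads=2,
                                     window_K=2, hidden_size=3,
                                     diffusion_dim=3, k_edges=2, seed=5), g)

        model = build(coords)
        model_p = build(coords[perm])
        # channel-indexed parameters must move with the permutation
        model_p.attention.w_q.data = model.attention.w_q.data[perm]
        model_p.attention.w_k.data = model.attention.w_k.data[perm]
        model_p.attention.w_v.data = model.attention.w_v.data[perm]
        model_p.attention.w_out.data = model.attention.w_out.data[:, perm]
        for src, dst in ((model.diffusion, model_p.diffusion),
                         (model.tgcn, model_p.tgcn)):
            for ps, pd in zip(src.parameters(), dst.parameters()):
                pd.data = ps.data.copy()

        x = rng.normal(size=(20, m))
        clip = EEGClip(signal=x, fine_labels=np.zeros(20, dtype=int),
                       coarse_label=0, clip_seconds=20, fs=1.0)
        clip_p = EEGClip(signal=x[:, perm], fine_labels=np.zeros(20, dtype=int),
                         coarse_label=0, clip_seconds=20, fs=1.0)
        h = encode_clip(clip, model)
        h_p = encode_clip(clip_p, model_p)
        assert np.allclose(h_p, h[perm], atol=1e-8)

    def test_empty_clip_rejected(self, rng):
        model = tiny_model()
        clip = make_clip(rng, n=5)
        clip.signal = np.zeros((0, 3))
        clip.fine_labels = np.zeros(0, dtype=int)
        with pytest.raises(ValueError):
            encode_clip(clip, model)


class TestClassify:
    def test_zero_hidden_zero_bias_uniform(self):
        model = tiny_model()
        model.w_det.data[:] = 0.0
        out = classify(np.zeros((3, 4)), model, "detection")
        assert np.allclose(out.class_probabilities, 0.5)

    def test_probabilities_sum_to_one(self, rng):
        model = tiny_model()
        out = classify(rng.normal(size=(3, 4)), model, "classification")
        assert np.isclose(out.class_probabilities.sum(), 1.0)
        assert out.class_probabilities.shape == (4,)

    def test_argmax_matches_logits(self, rng):
        model = tiny_model()
        out = classify(rng.normal(size=(3, 4)), model, "detection")
        assert out.class_probabilities.argmax() == out.logits.argmax()

    def test_unknown_head_rejected(self, rng):
        model = tiny_model()
        with pytest.raises(ValueError):
            classify(np.zeros((3, 4)), model, "segmentation")


class TestTotalLoss:
    def test_perfect_prediction_zero_loss(self):
        out = ModelOutput(logits=np.array([100.0, -100.0]),
                          class_probabilities=np.array([1.0, 0.0]))
        assert total_loss(out, 0, 0.0, 0.3).total == 0.0

    def test_hand_value(self):
        out = ModelOutput(logits=np.zeros(2),
                          class_probabilities=np.array([0.5, 0.5]))
        terms = total_loss(out, 0, l_re=2.0, lambda_=0.3)
        assert np.isclose(terms.total, -np.log(0.5) + 0.6, atol=1e-4)
        assert np.isclose(terms.total, 1.2931, atol=1e-4)

    def test_lambda_zero_is_plain_cross_entropy(self):
        out = ModelOutput(logits=np.zeros(2),
                          class_probabilities=np.array([0.25, 0.75]))
        terms = total_loss(out, 1, l_re=5.0, lambda_=0.0)
        assert np.isclose(terms.total, -np.log(0.75))

    def test_zero_probability_clamped_with_warning(self):
        out = ModelOutput(logits=np.zeros(2),
                          class_probabilities=np.array([0.0, 1.0]))
        with pytest.warns(UserWarning):
            terms = total_loss(out, 0, 0.0, 0.3)
        assert np.isfinite(terms.total)


class TestAblations:
    def test_no_seizure_attention_passes_input_through(self, rng):
        model = tiny_model(no_seizure_attention=True)
        x = Tensor(rng.normal(size=(10, 3)))
        assert model.reconstruct(x) is x

    def test_static_graph_encoding_differs_from_dynamic(self, rng):
        clip = make_clip(rng, n=30)
        h_dyn = encode_clip(clip, tiny_model(seed=1))
        h_static = encode_clip(clip, tiny_model(seed=1, static_dist_graph=True))
        assert not np.allclose(h_dyn, h_static)


class TestCheckpoint:
    def test_roundtrip_bit_identical_forward(self, tmp_path, rng):
        model = tiny_model(seed=11)
        model.tau = 0.37
        clip = make_clip(rng, n=25)
        h_before = encode_clip(clip, model)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        restored = load_checkpoint(path)
        assert restored.tau == 0.37
        assert np.array_equal(encode_clip(clip, restored), h_before)


class TestGradientCheck:
    def test_finite_difference_agreement_on_full_loss(self, rng):
        """Autodiff vs central differences for the combined objective."""
        from dtgcn.model import cross_entropy_t
        from dtgcn.attention import constrained_loss_t

        model = tiny_model(seed=2)
        model.tau = 1.0
        x = rng.normal(size=(2, 12, 3))
        y = np.array([0, 1])
        fine = np.zeros((2, 12), dtype=int)
        fine[1, 3:9] = 1

        def full_loss() -> float:
            xt = Tensor(x)
            h, xp = model.encode(xt)
            loss = cross_entropy_t(model.logits(h, "detection"), y)
            loss = loss + constrained_loss_t(xt, xp, fine, model.tau, 0.1) * 0.3
            return loss

        loss = full_loss()
        loss.backward()
        params = model.parameters()
        rng2 = np.random.default_rng(0)
        eps = 1e-5
        checked = 0
        for p in params:
            if p.grad is None:
                continue
            flat = p.data.ravel()
            gflat = p.grad.ravel()
            # a random ~5% subset of each parameter tensor
            n_pick = max(1, flat.size // 20)
            for idx in rng2.choice(flat.size, size=n_pick, replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                hi = float(full_loss().data)
                flat[idx] = old - eps
                lo = float(full_loss().data)
                flat[idx] = old
                num = (hi - lo) / (2 * eps)
                denom = max(abs(num), abs(gflat[idx]), 1e-6)
                assert abs(num - gflat[idx]) / denom < 1e-4, \
                    f"param grad mismatch: {num} vs {gflat[idx]}"
                checked += 1
        assert checked >= 10
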