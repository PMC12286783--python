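"""Autodiff core and layer-level oracles."""

import numpy as np
import pytest

from volseg.nn import (
    AdamW,
    ConvBlock,
    LayerNorm,
    Linear,
    Mlp,
    Module,
    MultiHeadSelfAttention,
    PatchMerge,
    SpectralMixer,
    Tensor,
    no_grad,
    ops,
)


def numeric_grad(f, t: Tensor, eps: float = 1e-6) -> np.ndarray:
    num = np.zeros_like(t.data)
    it = np.nditer(t.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = t.data[i]
        t.data[i] = orig + eps
        lp = float(f().data)
        t.data[i] = orig - eps
        lm = float(f().data)
        t.data[i] = orig
        num[i] = (lp - lm) / (2 * eps)
    return num


def assert_grads_match(f, tensors, tol=1e-5):
    out = f()
    out.backward()
    for t in tensors:
        num = numeric_grad(f, t)
        rel = np.abs(num - t.grad) / (np.abs(num) + np.abs(t.grad) + 1e-10)
        assert rel.max() < tol, f"gradient mismatch: max rel {rel.max()}"
        t.zero_grad()


@pytest.fixture
def r64():
    return np.random.default_rng(7)


class TestOpGradients:
    def test_elementwise_and_reductions(self, r64):
        a = Tensor(r64.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(r64.normal(size=(4,)), requires_grad=True)
        t = Tensor(r64.normal(size=(3, 4)))
        f = lambda: ops.sum(ops.mul(ops.gelu(ops.add(ops.mul(a, b), 0.3)), t))
        assert_grads_match(f, [a, b])

    def test_matmul_softmax_layernorm(self, r64):
        x = Tensor(r64.normal(size=(4, 3)), requires_grad=True)
        w = Tensor(r64.normal(size=(3, 5)), requires_grad=True)
        g = Tensor(np.ones(5), requires_grad=True)
        bias = Tensor(np.zeros(5), requires_grad=True)
        t = Tensor(r64.normal(size=(4, 5)))
        f = lambda: ops.sum(ops.mul(
            ops.softmax(ops.layer_norm(ops.matmul(x, w), g, bias)), t))
        assert_grads_match(f, [x, w, g, bias])

    def test_spectral_mix_gradients(self, r64):
        x = Tensor(r64.normal(size=(4, 2, 3, 2)), requires_grad=True)
        wr = Tensor(r64.normal(size=(4, 2, 3, 2)), requires_grad=True)
        wi = Tensor(r64.normal(size=(4, 2, 3, 2)), requires_grad=True)
        t = Tensor(r64.normal(size=(4, 2, 3, 2)))
        f = lambda: ops.sum(ops.mul(ops.spectral_mix(x, wr, wi), t))
        assert_grads_match(f, [x, wr, wi])

    def test_conv_and_upconv_gradients(self, r64):
        x = Tensor(r64.normal(size=(3, 3, 3, 2)), requires_grad=True)
        w = Tensor(r64.normal(size=(27 * 2, 2)), requires_grad=True)
        b = Tensor(r64.normal(size=(2,)), requires_grad=True)
        uw = Tensor(r64.normal(size=(2, 8 * 1)), requires_grad=True)
        t = Tensor(r64.normal(size=(6, 6, 6, 1)))
        f = lambda: ops.sum(ops.mul(
            ops.up_conv3d(ops.conv3d(x, w, b), uw), t))
        assert_grads_match(f, [x, w, b, uw])

    def test_log_softmax_and_concat(self, r64):
        a = Tensor(r64.normal(size=(2, 2, 2, 2)), requires_grad=True)
        b = Tensor(r64.normal(size=(2, 2, 2, 1)), requires_grad=True)
        t = Tensor(r64.normal(size=(2, 2, 2, 3)))
        f = lambda: ops.sum(ops.mul(
            ops.log_softmax(ops.concat([a, b], axis=-1)), t))
        assert_grads_match(f, [a, b])


class TestSpectralMixOp:
    def test_unit_filter_is_identity(self, r64):
        x = r64.normal(size=(4, 4, 4, 3))
        out = ops.spectral_mix(Tensor(x), Tensor(np.ones_like(x)),
                               Tensor(np.zeros_like(x)))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_translation_equivariance(self, r64):
        """Circular convolution commutes with circular grid shifts."""
        x = r64.normal(size=(6, 5, 4, 2))
        w_re = r64.normal(size=(6, 5, 4, 2))
        w_im = r64.normal(size=(6, 5, 4, 2))

        def mix(v):
            return ops.spectral_mix(Tensor(v), Tensor(w_re), Tensor(w_im)).data

        shift = (2, 3, 1)
        shifted_then_mixed = mix(np.roll(x, shift, axis=(0, 1, 2)))
        mixed_then_shifted = np.roll(mix(x), shift, axis=(0, 1, 2))
        np.testing.assert_allclose(shifted_then_mixed, mixed_then_shifted,
                                   atol=1e-10)


class TestAttention:
    def test_matches_hand_rolled_oracle(self, r64):
        n, k = 3, 4
        attn = MultiHeadSelfAttention(k, heads=1, rng=r64, dtype=np.float64)
        z = r64.normal(size=(n, k))
        out = attn(Tensor(z)).data

        wqkv = attn.qkv.weight.data
        q, kk, v = np.split(z @ wqkv, 3, axis=1)
        scores = q @ kk.T / np.sqrt(k)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        expected = (a @ v) @ attn.proj.weight.data
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_single_token_softmax_is_one(self, r64):
        k = 4
        attn = MultiHeadSelfAttention(k, heads=2, rng=r64, dtype=np.float64)
        z = r64.normal(size=(1, k))
        out = attn(Tensor(z)).data
        # softmax over one key is 1, so attention returns V directly
        qkv = z @ attn.qkv.weight.data
        v = qkv[:, 2 * k:]
        expected = v @ attn.proj.weight.data
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_zero_projections_contribute_nothing(self, r64):
        attn = MultiHeadSelfAttention(4, heads=1, rng=r64)
        attn.proj.weight.data[:] = 0.0
        z = r64.normal(size=(5, 4))
        np.testing.assert_array_equal(attn(Tensor(z)).data, 0.0)

    def test_indivisible_heads_rejected(self, r64):
        with pytest.raises(ValueError):
            MultiHeadSelfAttention(5, heads=2, rng=r64)


class TestMlpAndNorm:
    def test_zero_second_layer_is_zero_map(self, r64):
        mlp = Mlp(4, r64, ratio=2.0)
        mlp.fc2.weight.data[:] = 0.0
        z = r64.normal(size=(6, 4))
        np.testing.assert_array_equal(mlp(Tensor(z)).data, 0.0)

    def test_identity_affines_linear_activation_give_norm(self, r64):
        mlp = Mlp(3, r64, ratio=1.0, activation="linear", dtype=np.float64)
        mlp.fc1.weight.data = np.eye(3)
        mlp.fc2.weight.data = np.eye(3)
        norm = LayerNorm(3, dtype=np.float64)
        z = Tensor(r64.normal(size=(5, 3)))
        # pre-norm MLP residual: out = z + MLP(Norm(z)) = z + Norm(z)
        out = ops.add(z, mlp(norm(z))).data
        expected = z.data + norm(z).data
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestPatchMerge:
    def test_halves_grid_and_projects_channels(self, r64):
        pm = PatchMerge(48, 96, r64)
        x = Tensor(r64.normal(size=(4, 4, 4, 48)).astype(np.float32))
        assert pm(x).shape == (2, 2, 2, 96)
        pm2 = PatchMerge(4, 8, r64)
        assert pm2(Tensor(r64.normal(size=(2, 2, 2, 4)))).shape == (1, 1, 1, 8)

    def test_averaging_stencil_gives_neighbourhood_means(self, r64):
        c = 3
        pm = PatchMerge(c, c, r64, dtype=np.float64)
        # reduce matrix averaging the 8 neighbours per channel
        w = np.zeros((8 * c, c))
        for o in range(8):
            w[o * c:(o + 1) * c] = np.eye(c) / 8.0
        pm.reduce.weight.data = w
        pm.reduce.bias.data[:] = 0.0
        x = r64.normal(size=(4, 4, 4, c))
        out = pm(Tensor(x)).data
        expected = x.reshape(2, 2, 2, 2, 2, 2, c).mean(axis=(1, 3, 5))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_odd_axis_padded(self, r64):
        pm = PatchMerge(2, 4, r64)
        out = pm(Tensor(r64.normal(size=(3, 4, 5, 2))))
        assert out.shape == (2, 2, 3, 4)


class TestSpectralMixerLayer:
    def test_identity_at_init_with_identity_projection(self, r64):
        mixer = SpectralMixer((4, 4, 4), 2, r64, dtype=np.float64)
        mixer.proj.weight.data = np.eye(2)
        mixer.proj.bias.data[:] = 0.0
        x = r64.normal(size=(4, 4, 4, 2))
        np.testing.assert_allclose(mixer(Tensor(x)).data, x, atol=1e-12)

    def test_other_grid_sizes_resample_filter(self, r64):
        mixer = SpectralMixer((8, 8, 8), 2, r64, dtype=np.float64)
        mixer.proj.weight.data = np.eye(2)
        mixer.proj.bias.data[:] = 0.0
        x = r64.normal(size=(6, 6, 6, 2))
        # identity filter resampled anywhere is still the identity
        np.testing.assert_allclose(mixer(Tensor(x)).data, x, atol=1e-12)


class TestOptimizerAndModule:
    def test_adamw_minimises_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = AdamW({"p": p}, lr=0.2, weight_decay=0.0)
        for _ in range(200):
            opt.zero_grad()
            loss = ops.sum(ops.mul(p, p))
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_decoupled_weight_decay_shrinks_without_gradient(self):
        p = Tensor(np.array([1.0]), requires_grad=True)
        opt = AdamW({"p": p}, lr=0.1, weight_decay=0.5)
        p.grad = np.array([0.0])
        opt.step()
        assert p.data[0] == pytest.approx(1.0 - 0.1 * 0.5 * 1.0)

    def test_state_dict_round_trip(self, r64):
        m1 = Mlp(4, r64)
        m2 = Mlp(4, np.random.default_rng(99))
        m2.load_state_dict(m1.state_dict())
        z = Tensor(r64.normal(size=(3, 4)).astype(np.float32))
        np.testing.assert_array_equal(m1(z).data, m2(z).data)

    def test_no_grad_disables_taping(self, r64):
        lin = Linear(3, 3, r64)
        with no_grad():
            out = lin(Tensor(r64.normal(size=(2, 3)).astype(np.float32)))
        assert not out.requires_grad and out._parents == ()
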