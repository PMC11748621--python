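import numpy as np
import pytest

from chemimage.dscnn import (
    ARCHITECTURE_NAMES,
    ArchitectureSpec,
    LayerSpec,
    ShapeError,
    build_architecture,
    conv2d_collapse_forward,
    dsc_type1_forward,
    dsc_type2_forward,
    realize,
)
from chemimage.dscnn.layers import BatchNorm, Dense, DscType1, MaxPool3d
from oracles import conv2d_collapse_loops, dsc_type1_loops, dsc_type2_loops


class TestConv2dCollapse:
    def test_delta_kernel_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 1, 6, 6))
        w = np.zeros((1, 1, 3, 3)); w[0, 0, 1, 1] = 1.0
        out = conv2d_collapse_forward(x, w, np.zeros(1))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_all_ones_summation(self):
        """All-ones 3x3 kernel over an all-ones 5x5x2 input: every interior
        (valid) output value is 3*3*2 = 18."""
        x = np.ones((1, 2, 5, 5))
        w = np.ones((1, 2, 3, 3))
        out = conv2d_collapse_forward(x, w, np.zeros(1))
        assert out[0, 0, 2, 2] == pytest.approx(18.0)
        # same padding: corners see only 4 of 9 taps per channel
        assert out[0, 0, 0, 0] == pytest.approx(8.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(8):
            c = int(rng.integers(1, 7))
            f = int(rng.integers(1, 4))
            k = int(rng.choice([1, 3, 5]))
            x = rng.standard_normal((2, c, 8, 8))
            w = rng.standard_normal((f, c, k, k))
            b = rng.standard_normal(f)
            got = conv2d_collapse_forward(x, w, b)
            want = conv2d_collapse_loops(x, w, b)
            assert np.abs(got - want).max() <= 1e-6

    def test_folds_3d_stream(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 3, 6, 6, 4))  # M=3, D=4 -> C=12
        w = rng.standard_normal((2, 12, 3, 3))
        got = conv2d_collapse_forward(x, w, np.zeros(2))
        x2d = np.moveaxis(x, 4, 2).reshape(2, 12, 6, 6)
        want = conv2d_collapse_loops(x2d, w, np.zeros(2))
        assert np.abs(got - want).max() <= 1e-6


class TestDscType1:
    def test_delta_factorization_is_identity(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 1, 5, 5, 6))
        ws = np.zeros((1, 3, 3)); ws[0, 1, 1] = 1.0
        wz = np.zeros((2, 3)); wz[:, 1] = 1.0
        out = dsc_type1_forward(x, ws, wz)
        for f in range(2):
            np.testing.assert_allclose(out[:, f], x[:, 0], atol=1e-12)

    def test_separable_summation_interior_value(self):
        """All-ones 5x5 spatial and length-5 spectral kernels on an all-ones
        volume: an interior voxel sums 25*5 = 125."""
        x = np.ones((1, 1, 9, 9, 9))
        ws = np.ones((1, 5, 5))
        wz = np.ones((1, 5))
        out = dsc_type1_forward(x, ws, wz)
        assert out[0, 0, 4, 4, 4] == pytest.approx(125.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(6):
            m = int(rng.integers(1, 4))
            f = int(rng.integers(1, 5))
            x = rng.standard_normal((2, m, 8, 8, 10))
            ws = rng.standard_normal((m, 3, 3))
            wz = rng.standard_normal((f, 3))
            bs = float(rng.standard_normal())
            bz = rng.standard_normal(f)
            got = dsc_type1_forward(x, ws, wz, bs, bz)
            want = dsc_type1_loops(x, ws, bs, wz, bz)
            assert np.abs(got - want).max() <= 1e-5

    def test_linearity_pre_activation(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((1, 2, 6, 6, 8))
        ws = rng.standard_normal((2, 3, 3))
        wz = rng.standard_normal((3, 3))
        a = 2.7
        np.testing.assert_allclose(
            dsc_type1_forward(a * x, ws, wz), a * dsc_type1_forward(x, ws, wz),
            atol=1e-10,
        )


class TestDscType2:
    def test_five_by_three_gives_fifteen_maps(self):
        """S=5 spatial and T=3 spectral filters produce exactly 15 output
        volumes."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 1, 6, 6, 8))
        out = dsc_type2_forward(
            x, rng.standard_normal((5, 1, 5, 5)), rng.standard_normal((5, 3, 5))
        )
        assert out.shape == (1, 15, 6, 6, 8)

    def test_s1_t1_delta_identity(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((1, 1, 5, 5, 6))
        ws = np.zeros((1, 1, 3, 3)); ws[0, 0, 1, 1] = 1.0
        wz = np.zeros((1, 1, 3)); wz[0, 0, 1] = 1.0
        out = dsc_type2_forward(x, ws, wz)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(6):
            m = int(rng.integers(1, 3))
            s, t = int(rng.integers(1, 3)), int(rng.integers(1, 3))
            x = rng.standard_normal((2, m, 7, 7, 9))
            ws = rng.standard_normal((s, m, 3, 3))
            wz = rng.standard_normal((s, t, 3))
            bs = rng.standard_normal(s)
            bz = rng.standard_normal((s, t))
            got = dsc_type2_forward(x, ws, wz, bs, bz)
            want = dsc_type2_loops(x, ws, bs, wz, bz)
            assert np.abs(got - want).max() <= 1e-5


class TestArchitectures:
    @pytest.mark.parametrize("name", ARCHITECTURE_NAMES)
    @pytest.mark.parametrize("shape", [(64, 64, 40), (256, 256, 106)])
    def test_shape_algebra_validates(self, name, shape):
        arch = build_architecture(name, shape)
        shapes = arch.shapes()
        assert shapes[-1] == ("flat", 1)

    @pytest.mark.parametrize("name", ARCHITECTURE_NAMES)
    def test_realized_params_equal_symbolic_count(self, name):
        """The instantiated parameter arrays total exactly the symbolic
        count_params — for every architecture, with and without batch norm."""
        for bn in (False, True):
            arch = build_architecture(name, (32, 32, 40), use_batch_norm=bn)
            net = realize(arch, seed=0)
            assert net.n_params == arch.n_params()

    def test_realized_shapes_match_symbolic(self):
        """Forward activations of a realized model equal the symbolic shape
        algebra layer by layer."""
        arch = build_architecture("model2", (32, 32, 16))
        net = realize(arch, seed=1)
        x = np.random.default_rng(0).standard_normal((2, 32, 32, 16))
        out = x[:, None]
        for layer, stream in zip(net.layers, arch.shapes()):
            out = layer.forward(out)
            if stream[0] == "3d":
                assert out.shape == (2, stream[1], stream[2], stream[3], stream[4])
            elif stream[0] == "2d":
                assert out.shape == (2, stream[1], stream[2], stream[3])
            else:
                assert out.shape == (2, stream[1])

    def test_dsc_type1_hand_count(self):
        """(k_s^2*M_in + 1) + F*(k_z + 1) with k=3, M=1, F=4 gives 26."""
        spec = LayerSpec("dsc_type1", filters=4, k_spatial=3, k_spectral=3)
        arch = ArchitectureSpec("t", (16, 16, 8), (
            spec, LayerSpec("global_avgpool3d"), LayerSpec("output_sigmoid", units=1),
        ))
        dsc_params = arch.n_params() - (4 + 1)  # minus the output layer
        assert dsc_params == 26

    def test_model4_minimal_among_models_2_to_5(self):
        """Global average pooling removes the flatten->dense block, making
        Model 4 the lightest of Models 2-5 (the reported ordering)."""
        for shape in [(64, 64, 40), (256, 256, 106)]:
            counts = {
                n: build_architecture(n, shape).n_params()
                for n in ("model2", "model3", "model4", "model5")
            }
            assert min(counts, key=counts.get) == "model4"

    def test_model5_first_layer_emits_15_maps(self):
        arch = build_architecture("model5", (64, 64, 40))
        assert arch.shapes()[0] == ("3d", 15, 64, 64, 40)

    def test_model4_penultimate_vector_length_50(self):
        arch = build_architecture("model4", (64, 64, 40))
        kinds = [l.kind for l in arch.layers]
        i = kinds.index("global_avgpool3d")
        assert arch.shapes()[i] == ("flat", 50)

    def test_single_dense_layer_count(self):
        arch = ArchitectureSpec("d", (16, 16, 10), (
            LayerSpec("avgpool1d_spectral"), LayerSpec("flatten"),
            LayerSpec("output_sigmoid", units=1),
        ))
        # flatten gives 16*16 = 256 features; (256+1)*1 = 257
        assert arch.n_params() == 257

    def test_shape_failure_names_layer(self):
        with pytest.raises(ShapeError, match="layer"):
            ArchitectureSpec("bad", (16, 16, 8), (
                LayerSpec("maxpool3d", pool=(2, 2, 16)),
                LayerSpec("flatten"), LayerSpec("output_sigmoid", units=1),
            )).shapes()

    def test_json_round_trip(self):
        arch = build_architecture("model5", (64, 64, 40), use_batch_norm=True)
        back = ArchitectureSpec.from_json(arch.to_json())
        assert back == arch
        assert back.n_params() == arch.n_params()

    def test_batch_norm_insertion(self):
        plain = build_architecture("model2", (32, 32, 16))
        bn = build_architecture("model2", (32, 32, 16), use_batch_norm=True)
        kinds = [l.kind for l in bn.layers]
        assert kinds.count("batch_norm") == 4  # one per DSC->pool pair
        assert bn.n_params() > plain.n_params()

    def test_describe_mentions_every_layer(self):
        arch = build_architecture("lenet5_mod", (64, 64, 40))
        text = arch.describe()
        assert "conv2d_collapse" in text and "total params" in text


class TestBackwardPasses:
    def _numeric_check(self, layer, x, n_checks=6, tol=1e-5):
        rng = np.random.default_rng(0)
        out = layer.forward(x, train=True)
        dout = rng.standard_normal(out.shape)
        dx = layer.backward(dout)

        def objective():
            return float((dout * layer.forward(x, train=True)).sum())

        for idx in rng.choice(x.size, n_checks, replace=False):
            eps = 1e-6
            flat = x.ravel()
            old = flat[idx]
            flat[idx] = old + eps; up = objective()
            flat[idx] = old - eps; dn = objective()
            flat[idx] = old
            num = (up - dn) / (2 * eps)
            assert dx.ravel()[idx] == pytest.approx(num, abs=tol * (1 + abs(num)))
        for name, p in layer.params.items():
            g = layer.grads[name]
            for idx in rng.choice(p.size, min(3, p.size), replace=False):
                eps = 1e-6
                flat = p.ravel()
                old = flat[idx]
                flat[idx] = old + eps; up = objective()
                flat[idx] = old - eps; dn = objective()
                flat[idx] = old
                num = (up - dn) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(num, abs=tol * (1 + abs(num)))

    def test_dsc_type1_gradients(self):
        rng = np.random.default_rng(1)
        layer = DscType1(2, 3, k_spatial=3, k_spectral=3, apply_relu=False)
        layer.init_params(rng)
        self._numeric_check(layer, rng.standard_normal((2, 2, 6, 6, 8)))

    def test_maxpool3d_gradients(self):
        rng = np.random.default_rng(2)
        self._numeric_check(MaxPool3d((2, 2, 2)), rng.standard_normal((2, 3, 6, 6, 8)))

    def test_dense_and_batchnorm_gradients(self):
        rng = np.random.default_rng(3)
        d = Dense(10, 4, apply_relu=False)
        d.init_params(rng)
        self._numeric_check(d, rng.standard_normal((5, 10)))
        self._numeric_check(BatchNorm(3), rng.standard_normal((6, 3, 4, 4)), tol=1e-4)

    def test_whole_model_gradient_smooth_path(self):
        """End-to-end finite-difference check on an average-pooling variant
        (no max-pool/ReLU switching discontinuities)."""
        from chemimage.train_eval import _weighted_bce_and_grad

        rng = np.random.default_rng(4)
        arch = ArchitectureSpec("smooth", (16, 16, 16), (
            LayerSpec("dsc_type1", filters=4, k_spatial=3, k_spectral=3),
            LayerSpec("avgpool3d", pool=(2, 2, 2)),
            LayerSpec("dsc_type2", s_filters=2, t_filters=2, k_spatial=3, k_spectral=3),
            LayerSpec("avgpool3d", pool=(2, 2, 2)),
            LayerSpec("conv2d_collapse", filters=4, k_spatial=3),
            LayerSpec("batch_norm"),
            LayerSpec("flatten"),
            LayerSpec("dense", units=8),
            LayerSpec("output_sigmoid", units=1),
        ))
        net = realize(arch, seed=1)
        x = rng.standard_normal((3, 16, 16, 16))
        y = np.array([0.0, 1.0, 1.0])
        w = {0: 1.0, 1: 1.0}

        def loss():
            z = net.forward(x, train=True)
            return _weighted_bce_and_grad(z, y, w)

        l0, dz = loss()
        net.backward(dz)
        checked = 0
        for layer in net.layers:
            for name, p in layer.params.items():
                g = layer.grads[name].copy()
                flat = p.ravel()
                for idx in rng.choice(flat.size, min(2, flat.size), replace=False):
                    eps = 1e-6
                    old = flat[idx]
                    flat[idx] = old + eps; up, _ = loss()
                    flat[idx] = old - eps; dn, _ = loss()
                    flat[idx] = old
                    num = (up - dn) / (2 * eps)
                    assert g.ravel()[idx] == pytest.approx(num, abs=1e-5 * (1 + abs(num)))
                    checked += 1
        assert checked >= 10
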