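"""Architecture arithmetic, shape tracing, and the executable network."""

import numpy as np
import pytest

from msres.errors import ConfigurationError
from msres.model import (
    MsResConfig,
    block_conv_params,
    build_model,
    count_parameters,
    model_graph,
    residual_block_forward,
    stem_conv_params,
    trace_shapes,
)
from msres.model.layers import MaxPool1d, SameConv1d


class TestLayerParamFormulas:
    @pytest.mark.parametrize("kernel,filters,expected", [
        (5, 32, 192), (7, 32, 256), (9, 32, 320), (1, 1, 2), (13, 32, 448),
    ])
    def test_stem_conv_params(self, kernel, filters, expected):
        assert stem_conv_params(kernel, filters) == expected

    @pytest.mark.parametrize("filters,kernel,expected", [
        (32, 3, 3104), (1, 1, 2), (16, 3, 784),
    ])
    def test_block_conv_params(self, filters, kernel, expected):
        assert block_conv_params(filters, kernel) == expected

    @pytest.mark.parametrize("kernel,filters", [(13, 32), (3, 16)])
    def test_formula_matches_built_single_layer(self, kernel, filters, rng):
        stem_weights = stem_conv_params(kernel, filters)
        from msres.model.layers import StemConv1d

        layer = StemConv1d(kernel, filters, 3, rng)
        assert sum(p.data.size for p in layer.params) == stem_weights
        conv = SameConv1d(3, filters, filters, rng)
        assert sum(p.data.size for p in conv.params) == block_conv_params(filters, 3)


class TestTraceShapes:
    def test_stem_length_for_kernel_9(self):
        trace = trace_shapes(MsResConfig())
        assert trace["streams"][9][0] == ("stem_conv(k=9,s=3)", 898)

    def test_pool_cascade_ends_at_four(self):
        trace = trace_shapes(MsResConfig())
        # lengths after each of the 7 pools for the kernel-9 stream
        pools = [n for name, n in trace["streams"][9] if "pool" in name]
        assert pools == [447, 222, 109, 53, 25, 11, 4]
        assert trace["final_lens"] == {5: 4, 7: 4, 9: 4}

    def test_flatten_is_128_per_stream(self):
        for ks in [(5,), (3, 5), (5, 7, 9), (3, 5, 7, 9, 11), (5, 7, 9, 11, 13)]:
            trace = trace_shapes(MsResConfig(kernel_sizes=ks))
            assert trace["flatten_len"] == 128 * len(ks)

    def test_pool_boundary(self):
        pool = MaxPool1d(5, 2)
        assert pool.out_len(5) == 1
        with pytest.raises(ValueError):
            pool.out_len(4)

    def test_collapsing_cascade_raises_naming_layer(self):
        with pytest.raises(ConfigurationError, match="block.*pool"):
            trace_shapes(MsResConfig(kernel_sizes=(5,), input_len=200, n_blocks=7))


class TestParameterCounts:
    @pytest.mark.parametrize("kernels,expected", [
        ((5, 7, 9), 158_401),
        ((3, 5), 106_305),
        ((5, 9), 106_497),
        ((3, 5, 7), 158_209),
        ((3, 5, 7, 9), 210_177),
        ((3, 5, 7, 9, 11), 262_209),
        ((5, 7, 9, 11, 13), 262_529),
    ])
    def test_published_totals(self, kernels, expected):
        assert count_parameters(MsResConfig(kernel_sizes=kernels)) == expected

    def test_closed_form_for_default_geometry(self):
        # total = 32*sum(k) + 51,680*n + 2,689 at default geometry
        for ks in [(3,), (5, 7), (3, 9, 13), (3, 5, 7, 9, 11, 13)]:
            expected = 32 * sum(ks) + 51_680 * len(ks) + 2_689
            assert count_parameters(MsResConfig(kernel_sizes=ks)) == expected

    def test_stream_order_equivariance(self):
        a = count_parameters(MsResConfig(kernel_sizes=(5, 7, 9)))
        b = count_parameters(MsResConfig(kernel_sizes=(9, 5, 7)))
        assert a == b

    def test_graph_total_is_sum_of_layers(self):
        graph = model_graph(MsResConfig())
        assert graph.total_parameters == sum(l.params for l in graph.layers)
        assert graph.flatten_len == 384
        dense_params = [l.params for l in graph.layers if l.kind == "dense"]
        assert dense_params == [24_640, 2_080, 528, 17]

    def test_graph_serialization_roundtrips_totals(self):
        text = model_graph(MsResConfig()).to_text()
        assert "158401" in text
        assert "conv1d" in text and "maxpool1d" in text


class TestExecutableNetwork:
    def test_outputs_are_probabilities(self, rng):
        model = build_model(MsResConfig(), seed=0)
        p = model.predict_proba(rng.random((7, 2700)))
        assert p.shape == (7,)
        assert np.all((p > 0) & (p < 1))

    def test_backend_count_equals_symbolic_for_default(self):
        model = build_model(MsResConfig(), seed=0)
        assert model.num_parameters == 158_401

    def test_seeded_initialization_reproducible(self):
        a = build_model(MsResConfig(kernel_sizes=(3,), n_blocks=2, input_len=300), seed=5)
        b = build_model(MsResConfig(kernel_sizes=(3,), n_blocks=2, input_len=300), seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_wrong_input_length_rejected(self, rng):
        model = build_model(MsResConfig(kernel_sizes=(3,), n_blocks=1, input_len=300))
        with pytest.raises(ValueError, match="shape"):
            model.forward(rng.random((2, 100)))


class TestResidualBlock:
    def test_zero_weights_reduce_to_maxpool(self, rng):
        x = rng.normal(size=(20, 8))
        C = 8
        zeros_w = np.zeros((3, C, C))
        zeros_b = np.zeros(C)
        out = residual_block_forward(x, zeros_w, zeros_b, zeros_w, zeros_b)
        expected = MaxPool1d(5, 2).forward(x[None])[0]
        np.testing.assert_array_equal(out, expected)

    def test_output_length_formula(self, rng):
        x = rng.normal(size=(898, 4))
        w = rng.normal(size=(3, 4, 4)) * 0.1
        out = residual_block_forward(x, w, np.zeros(4), w, np.zeros(4))
        assert out.shape == (447, 4)

    def test_skip_path_carries_gradient_with_zero_conv_weights(self, rng):
        # numerical gradient of sum(output) w.r.t. one input element is
        # nonzero even when both conv branches are zeroed
        x = rng.normal(size=(12, 2))
        zeros_w = np.zeros((3, 2, 2))
        zeros_b = np.zeros(2)

        def f(x_):
            return residual_block_forward(x_, zeros_w, zeros_b, zeros_w, zeros_b).sum()

        i = np.unravel_index(np.argmax(x[:5]), x.shape)  # an early max survives pooling
        h = 1e-6
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        grad = (f(xp) - f(xm)) / (2 * h)
        assert abs(grad) > 0.5

    def test_short_input_rejected(self, rng):
        with pytest.raises(ValueError):
            residual_block_forward(rng.normal(size=(3, 2)), np.zeros((3, 2, 2)),
                                   np.zeros(2), np.zeros((3, 2, 2)), np.zeros(2))


class TestGradients:
    def test_full_network_gradients_match_finite_differences(self):
        from msres.model.network import _sigmoid
        from msres.train import bce_loss

        cfg = MsResConfig(kernel_sizes=(3, 5), n_blocks=2, filters=4,
                          dense_units=(6, 3), input_len=60, dropout=0.0)
        model = build_model(cfg, seed=3, dtype=np.float64)
        rng = np.random.default_rng(0)
        X = rng.random((5, 60))
        y = rng.integers(0, 2, 5).astype(float)

        logits = model.forward(X, train=True, rng=rng)
        model.zero_grad()
        model.backward((_sigmoid(logits) - y) / len(y))

        def loss():
            return bce_loss(y, _sigmoid(model.forward(X)))

        h = 1e-6
        for p in model.parameters():
            flat = p.data.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + h
                lp = loss()
                flat[i] = old - h
                lm = loss()
                flat[i] = old
                numeric = (lp - lm) / (2 * h)
                analytic = p.grad.ravel()[i]
                assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-9)

    def test_same_conv_matches_scipy_correlate(self, rng):
        from scipy.signal import correlate

        conv = SameConv1d(3, 4, 5, rng, np.float64)
        x = rng.random((3, 20, 4))
        y = conv.forward(x)
        for b in range(3):
            for f in range(5):
                ref = sum(
                    correlate(x[b, :, c], conv.w.data[:, c, f], mode="same")
                    for c in range(4)
                ) + conv.b.data[f]
                np.testing.assert_allclose(y[b, :, f], ref, atol=1e-12)


class TestSymbolicVsBackend:
    def test_count_parameters_equals_backend_on_random_configs(self):
        # 20 random feasible configurations; ledger count == weight sizes
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 20:
            ks = tuple(sorted(rng.choice([3, 5, 7, 9, 11, 13],
                                         size=rng.integers(1, 4), replace=False)))
            cfg_kwargs = dict(
                kernel_sizes=ks,
                n_blocks=int(rng.integers(1, 6)),
                filters=int(rng.choice([4, 8, 16])),
                dense_units=tuple(int(u) for u in rng.choice([8, 16, 32],
                                                             size=rng.integers(1, 4))),
                input_len=int(rng.integers(300, 1200)),
            )
            try:
                cfg = MsResConfig(**cfg_kwargs)
                expected = count_parameters(cfg)
            except ConfigurationError:
                continue  # pooling cascade infeasible; draw again
            model = build_model(cfg, seed=int(rng.integers(0, 1000)))
            assert model.num_parameters == expected
            checked += 1
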