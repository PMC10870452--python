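"""Model-layer contracts: quantization laws, dilated convolution,
attention algebra, parameter accounting, and gradient correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltyseiz.ltycnn import (
    LTYCNN, ModelConfig, count_parameters, dilated_conv, forward,
    multihead_attention, parallel_branches, quantization_error, quantize,
    quantized_dilated_conv, receptive_field,
)
from oracles import conv1d_same_oracle

TINY = ModelConfig(input_dim=8, seq_len=12, branch_kernels=(3, 3, 2),
                   branch_channels=(2, 2, 2), dilated_out=8, attn_dim=8,
                   attn_heads=2, dilated_kernel=3, dilation=2)


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_printed_examples():
    xq, spec = quantize(np.array([0.0]), 8)
    assert xq[0] == 0.0
    xq, spec = quantize(np.array([0.75, 2.0]), 2)  # max|x|=2, n=2 -> step 1
    assert spec.delta == 1.0
    assert xq[0] == 1.0


def test_quantize_zero_tensor_is_zero_safe():
    xq, spec = quantize(np.zeros(10), 8)
    assert np.all(xq == 0.0)
    assert spec.delta > 0


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(min_value=1, max_value=12), st.integers(0, 2**31 - 1))
def test_quantization_laws(n_bits, seed):
    """|x - Q(x)| <= step/2, idempotence, and <= 2^n + 1 distinct levels."""
    x = np.random.default_rng(seed).normal(scale=3.0, size=257)
    xq, spec = quantize(x, n_bits)
    assert np.abs(x - xq).max() <= spec.delta / 2 + 1e-12
    xqq, _ = quantize(xq, n_bits)
    np.testing.assert_allclose(xqq, xq, atol=1e-12)
    assert len(np.unique(xq)) <= 2**n_bits + 1


def test_error_zero_on_grid_points():
    _, spec = quantize(np.array([4.0]), 3)
    grid = spec.delta * np.arange(-4, 5)
    assert quantization_error(grid, 3) == pytest.approx(0.0, abs=1e-15)


def test_error_of_uniform_input_is_quarter_step(rng):
    """E[|x - Q(x)|] for uniform density ~ step/4 (Monte-Carlo oracle)."""
    x = rng.uniform(-3.0, 3.0, size=200_000)
    x[0], x[1] = -3.0, 3.0  # pin the dynamic range
    _, spec = quantize(x, 6)
    assert quantization_error(x, 6) == pytest.approx(spec.delta / 4, rel=0.02)


def test_error_nonincreasing_in_bits(rng):
    x = rng.normal(size=1000)
    errors = [quantization_error(x, n) for n in (2, 4, 8)]
    assert errors[0] >= errors[1] >= errors[2]


def test_quantize_rejects_zero_bits():
    with pytest.raises(ValueError):
        quantize(np.ones(3), 0)


# ---------------------------------------------------------------------------
# receptive field & dilated convolution
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k,d,expected", [(3, 1, 3), (3, 2, 5), (5, 3, 13)])
def test_receptive_field_formula(k, d, expected):
    assert receptive_field(k, d) == expected


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(min_value=1, max_value=15))
def test_receptive_field_collapses_without_dilation(k):
    assert receptive_field(k, 1) == k


def test_dilated_conv_d1_matches_oracle_on_random_tensors(rng):
    for _ in range(100):
        c_in, c_out = rng.integers(1, 4, size=2)
        k = int(rng.integers(1, 5))
        t = int(rng.integers(k, 20))
        x = rng.normal(size=(c_in, t))
        w = rng.normal(size=(c_out, c_in, k))
        np.testing.assert_allclose(dilated_conv(x, w, d=1),
                                   conv1d_same_oracle(x, w, d=1), atol=1e-6)


def test_dilated_conv_matches_oracle_with_dilation(rng):
    for d in (2, 3):
        x = rng.normal(size=(3, 30))
        w = rng.normal(size=(2, 3, 3))
        np.testing.assert_allclose(dilated_conv(x, w, d=d),
                                   conv1d_same_oracle(x, w, d=d), atol=1e-10)


def test_impulse_response_support_is_receptive_field():
    t = 31
    x = np.zeros((1, t))
    x[0, t // 2] = 1.0
    w = np.ones((1, 1, 3))
    out = dilated_conv(x, w, d=2)
    nz = np.flatnonzero(out[0]) - t // 2
    assert set(nz.tolist()) == {-2, 0, 2}  # R = 3 + 2*1 = 5, spaced by d


def test_identity_kernel_mixes_channels_only(rng):
    x = rng.normal(size=(2, 10))
    w = np.zeros((2, 2, 1))
    w[0, 1, 0] = 1.0
    w[1, 0, 0] = 2.0
    out = dilated_conv(x, w, d=3)
    np.testing.assert_allclose(out[0], x[1])
    np.testing.assert_allclose(out[1], 2 * x[0])


def test_receptive_field_exceeding_length_rejected():
    with pytest.raises(ValueError, match="receptive field"):
        dilated_conv(np.zeros((1, 4)), np.zeros((1, 1, 3)), d=2)


def test_quantized_conv_zero_weights_and_grid_exactness(rng):
    x = rng.normal(size=(2, 20))
    assert np.all(quantized_dilated_conv(x, np.zeros((3, 2, 3)), 2, 8) == 0.0)
    # values already on the n-bit grid pass through Q unchanged
    xq, _ = quantize(x, 4)
    w = rng.normal(size=(2, 2, 3))
    wq, _ = quantize(w, 4)
    np.testing.assert_allclose(quantized_dilated_conv(xq, wq, 2, 4),
                               dilated_conv(xq, wq, 2), atol=1e-10)


def test_quantized_conv_error_within_analytic_bound(rng):
    """|O_q - O| bounded by the per-product quantization error bound
    |Q(a)Q(w) - aw| <= |Q(a)| dW/2 + |w| dA/2, summed over taps."""
    x = rng.normal(size=(3, 40))
    w = rng.normal(size=(2, 3, 3))
    n_bits = 16
    xq, sa = quantize(x, n_bits)
    wq, sw = quantize(w, n_bits)
    full = dilated_conv(x, w, 2)
    quant = quantized_dilated_conv(x, w, 2, n_bits)
    k_terms = w.shape[1] * w.shape[2]
    bound = k_terms * (np.abs(xq).max() * sw.delta / 2
                       + np.abs(w).max() * sa.delta / 2)
    assert np.abs(quant - full).max() <= bound + 1e-12


# ---------------------------------------------------------------------------
# parallel branches & attention
# ---------------------------------------------------------------------------

def _branch_params(config, seed=0):
    return LTYCNN(config, seed=seed).params


def test_branches_concatenate_channels(rng):
    cfg = ModelConfig()
    params = _branch_params(cfg)
    out = parallel_branches(rng.normal(size=(64, 127)), cfg, params)
    assert out.shape == (12, 127)
    assert (out >= 0).all()  # ReLU


def test_branches_zero_input_zero_biases():
    cfg = ModelConfig()
    params = _branch_params(cfg)
    out = parallel_branches(np.zeros((64, 127)), cfg, params)
    assert np.all(out == 0.0)


def test_branch_permutation_permutes_blocks(rng):
    cfg = ModelConfig(branch_kernels=(7, 5, 3))
    params = _branch_params(cfg)
    x = rng.normal(size=(64, 127))
    out = parallel_branches(x, cfg, params)
    swapped_cfg = ModelConfig(branch_kernels=(3, 5, 7))
    swapped = {
        "branch0_W": params["branch2_W"], "branch0_b": params["branch2_b"],
        "branch1_W": params["branch1_W"], "branch1_b": params["branch1_b"],
        "branch2_W": params["branch0_W"], "branch2_b": params["branch0_b"],
    }
    out_swapped = parallel_branches(x, swapped_cfg, swapped)
    np.testing.assert_allclose(out_swapped[:4], out[8:12])
    np.testing.assert_allclose(out_swapped[8:12], out[:4])


def test_branch_kernel_longer_than_sequence_rejected(rng):
    cfg = ModelConfig()
    with pytest.raises(ValueError, match="kernel"):
        parallel_branches(rng.normal(size=(64, 5)), cfg, _branch_params(cfg))


def _attn_params(dim, seed=0):
    rr = np.random.default_rng(seed)
    p = {}
    for name in ("Wq", "Wk", "Wv", "Wo"):
        p[name] = rr.normal(size=(dim, dim)) / np.sqrt(dim)
    for name in ("bq", "bk", "bv", "bo"):
        p[name] = rr.normal(size=dim) * 0.1
    return p


def test_attention_rows_are_probability_vectors(rng):
    p = _attn_params(8)
    x = rng.normal(size=(20, 8))
    out, attn = multihead_attention(x, p, n_heads=2, return_weights=True)
    assert out.shape == (20, 8)
    assert (attn >= 0).all()
    np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


def test_attention_single_step_is_value_projection(rng):
    p = _attn_params(8)
    x = rng.normal(size=(1, 8))
    out = multihead_attention(x, p, n_heads=2)
    v = x @ p["Wv"] + p["bv"]
    np.testing.assert_allclose(out, v @ p["Wo"] + p["bo"], atol=1e-10)


def test_attention_constant_keys_average_values(rng):
    p = _attn_params(8)
    p["Wk"] = np.zeros((8, 8))  # all key projections equal the bias
    x = rng.normal(size=(15, 8))
    out, attn = multihead_attention(x, p, n_heads=2, return_weights=True)
    np.testing.assert_allclose(attn, 1.0 / 15, atol=1e-12)
    v = x @ p["Wv"] + p["bv"]
    expected = np.tile(v.mean(axis=0), (15, 1)) @ p["Wo"] + p["bo"]
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_attention_rejects_indivisible_heads(rng):
    with pytest.raises(ValueError, match="divisible"):
        multihead_attention(rng.normal(size=(5, 9)), _attn_params(9), n_heads=2)


# ---------------------------------------------------------------------------
# full forward & parameter accounting
# ---------------------------------------------------------------------------

def test_forward_scores_shape_and_determinism(rng):
    model = LTYCNN(ModelConfig(), seed=1)
    x = rng.normal(size=(127, 64))
    a = model.forward(x)
    b = model.forward(x.copy())
    assert a.shape == (2,)
    assert np.array_equal(a, b)
    probs = np.exp(a - a.max())
    probs /= probs.sum()
    assert probs.sum() == pytest.approx(1.0)
    assert (probs >= 0).all()


def test_functional_forward_matches_class(rng):
    model = LTYCNN(TINY, seed=2)
    x = rng.normal(size=(4, 12, 8))
    np.testing.assert_array_equal(forward(x, TINY, model.params),
                                  model.forward(x))


def test_time_order_matters(rng):
    model = LTYCNN(ModelConfig(), seed=3)
    x = rng.normal(size=(127, 64))
    shuffled = x[rng.permutation(127)]
    assert not np.allclose(model.forward(x), model.forward(shuffled))


def test_parameter_count_reference_architecture():
    cfg = ModelConfig()
    total = count_parameters(cfg)
    assert total == 23_118
    assert total <= cfg.parameter_budget
    sizes = LTYCNN(cfg).parameter_sizes()
    assert sizes["Wc"] + sizes["bc"] == 130  # 64*2 + 2
    attn = sum(sizes[k] for k in ("Wq", "Wk", "Wv", "Wo", "bq", "bk", "bv", "bo"))
    assert attn == 16_640  # 3*(64*64+64) + (64*64+64)


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(attn_heads=5)
    with pytest.raises(ValueError):
        ModelConfig(q_bits=0)
    with pytest.raises(ValueError):
        ModelConfig(dilated_out=32)  # stream width mismatch


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def _loss_and_grads(model, x, y):
    from ltyseiz.traineval import _cross_entropy

    logits = model.forward(x, cache=True)
    loss, dlogits = _cross_entropy(logits, y)
    return loss, model.backward(dlogits)


def test_full_precision_gradients_match_finite_differences(rng):
    """With quantization disabled the network is smooth; analytic
    gradients agree with central differences everywhere."""
    from ltyseiz.traineval import _cross_entropy

    model = LTYCNN(TINY, seed=3)
    model.fake_quant = False
    x = rng.normal(size=(4, 12, 8))
    y = np.array([0, 1, 1, 0])
    _, grads = _loss_and_grads(model, x, y)
    eps = 1e-6
    for name, p in model.params.items():
        for _ in range(3):
            idx = tuple(rng.integers(s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = _cross_entropy(model.forward(x), y)
            p[idx] = orig - eps
            lm, _ = _cross_entropy(model.forward(x), y)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[name][idx]
            assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), name


def test_straight_through_gradients_finite_on_quantized_path(rng):
    model = LTYCNN(TINY, seed=4)
    x = rng.normal(size=(4, 12, 8))
    y = np.array([0, 1, 0, 1])
    _, grads = _loss_and_grads(model, x, y)
    for name in ("dilated_W", "branch0_W"):
        assert np.isfinite(grads[name]).all()
        assert np.abs(grads[name]).sum() > 0
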