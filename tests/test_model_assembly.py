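"""Whole-network assembly: shapes, parameter accounting, determinism, checkpoints."""

import numpy as np
import pytest

from afnnet import (
    AFNNet,
    ModelConfig,
    build_afn_net,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
)
from afnnet.errors import ConfigurationError
from afnnet.nn import Conv2d, Module, Tensor


def symbolic_param_count(cfg: ModelConfig) -> int:
    """Closed-form per-layer parameter sum for the assembled network."""
    k2 = cfg.dscom_kernel**2
    dk2 = cfg.dscom_dw_kernel**2
    fk2 = cfg.wfeu_kernel**2
    w = cfg.widths

    def conv(cin, cout, kk):
        return kk * cin * cout + cout

    def dscom(cin, cout):
        return (conv(cin, cout, k2) + (dk2 * cout + cout) + 2 * cout
                + conv(cout, cout, k2) + (dk2 * cout + cout) + 2 * cout)

    def txf_stage(cin, dim, depth):
        total = conv(cin, dim, 9)  # 3x3 patch embedding
        per_block = (2 * dim                      # norm1
                     + dim * 3 * dim + 3 * dim    # qkv
                     + dim * dim + dim            # attn proj
                     + 2 * dim                    # norm2
                     + dim * cfg.mlp_ratio * dim + cfg.mlp_ratio * dim
                     + cfg.mlp_ratio * dim * dim + dim)
        return total + depth * per_block

    def wfeu(enc, dec, out):
        cc = enc + dec
        return (conv(cc, out, fk2) * 2          # gate + feat
                + conv(out, out, fk2)           # enhance
                + conv(cc, out, 1))             # 1x1 align

    def refine(ch):
        return conv(ch, ch, 9) + 2 * ch

    total = dscom(cfg.in_channels, w[0]) + dscom(w[0], w[1])
    total += txf_stage(w[1], w[2], cfg.depths[0])
    total += txf_stage(w[2], w[3], cfg.depths[1])
    total += txf_stage(w[3], w[4], cfg.depths[2])
    for hi, lo in ((4, 3), (3, 2), (2, 1), (1, 0)):
        total += conv(w[hi], w[lo], 9)          # upsample conv
        total += wfeu(w[lo], w[lo], w[lo])
        total += refine(w[lo])
    total += conv(w[0], 1, 1)                   # head
    return total


def test_tiny_model_end_to_end_shape(tiny_model):
    x = np.random.default_rng(0).normal(size=(2, 3, 64, 64)).astype(np.float32)
    out = tiny_model(Tensor(x))
    assert out.shape == (2, 1, 64, 64)
    assert np.isfinite(out.data).all()


def test_bottleneck_is_sixteenth_of_input_resolution(tiny_model):
    x = Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
    e1 = tiny_model.enc1(x)
    from afnnet.nn import maxpool2x2

    e2 = tiny_model.enc2(maxpool2x2(e1))
    e5 = tiny_model.enc5(tiny_model.enc4(tiny_model.enc3(e2)))
    assert e5.shape[2:] == (4, 4)  # 64 / 16


def test_indivisible_input_rejected_before_compute(tiny_model):
    with pytest.raises(ConfigurationError, match="divisible by 16"):
        tiny_model(Tensor(np.zeros((1, 3, 60, 60), dtype=np.float32)))


def test_parameter_count_matches_symbolic_sum():
    for cfg in (ModelConfig.tiny(), ModelConfig()):
        model = build_afn_net(cfg)
        assert count_parameters(model) == symbolic_param_count(cfg)


def test_count_parameters_basic_cases():
    assert count_parameters(Module()) == 0
    conv = Conv2d(3, 16, 3)
    assert count_parameters(conv) == 3 * 16 * 9 + 16


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ModelConfig(widths=(4, 8, 16, 16))
    with pytest.raises(ConfigurationError):
        ModelConfig(widths=(4, 8, 16, 16, -1))
    with pytest.raises(ConfigurationError):
        ModelConfig(widths=(4, 8, 15, 16, 16))  # not divisible by heads


def test_forward_deterministic_in_eval_mode(tiny_model):
    x = np.random.default_rng(3).normal(size=(1, 3, 32, 32)).astype(np.float32)
    p1 = tiny_model.predict_proba(x)
    p2 = tiny_model.predict_proba(x)
    assert np.array_equal(p1, p2)


def test_same_seed_builds_identical_models():
    a = build_afn_net(ModelConfig.tiny(seed=11))
    b = build_afn_net(ModelConfig.tiny(seed=11))
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb and np.array_equal(pa.data, pb.data)


def test_checkpoint_roundtrip_and_mismatch(tmp_path, tiny_model):
    path = tmp_path / "model.npz"
    save_checkpoint(path, tiny_model, extra={"note": "test"})
    loaded = load_checkpoint(path)
    assert isinstance(loaded, AFNNet)
    for (na, pa), (nb, pb) in zip(tiny_model.named_parameters(), loaded.named_parameters()):
        assert na == nb and np.array_equal(pa.data, pb.data)
    x = np.random.default_rng(5).normal(size=(1, 3, 32, 32)).astype(np.float32)
    assert np.array_equal(tiny_model.predict_proba(x), loaded.predict_proba(x))
    with pytest.raises(ConfigurationError, match="mismatch"):
        load_checkpoint(path, config=ModelConfig())


def test_end_to_end_gradient_matches_finite_difference():
    """Analytic d(sum logits)/d(one pixel) vs central differences, float64."""
    model = build_afn_net(ModelConfig.tiny(seed=2)).astype(np.float64).eval()
    rng = np.random.default_rng(4)
    x0 = rng.normal(size=(1, 3, 16, 16))
    x = Tensor(x0.copy(), requires_grad=True)
    out = model(x)
    out.sum().backward()
    eps = 1e-6
    idx = (0, 1, 7, 9)
    xp = x0.copy()
    xp[idx] += eps
    xm = x0.copy()
    xm[idx] -= eps
    from afnnet.nn import no_grad

    with no_grad():
        fp = model(Tensor(xp)).data.sum()
        fm = model(Tensor(xm)).data.sum()
    num = (fp - fm) / (2 * eps)
    rel = abs(num - x.grad[idx]) / max(abs(num), 1e-8)
    assert rel < 1e-3
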