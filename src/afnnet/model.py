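"""Adaptive-fusion nucleus segmentation network.

A five-level U-Net-family encoder–decoder for binary nucleus masks:

* encoder levels 1–2 are double-stage channel optimization (DSCOM) blocks —
  two repetitions of standard conv → depthwise conv → batch norm → ReLU —
  which keep high-resolution detail cheap to extract;
* encoder levels 3–5 are transformer stages (strided-conv patch embedding
  followed by pre-norm self-attention + MLP blocks);
* every one of the four skip connections is fused by a Weighted Feature
  Enhancement Unit (WFEU): the concatenated encoder/decoder features pass
  through a sigmoid-gated interaction (WFIU) and an enhancement + 1×1
  channel-alignment residual sum (FEU);
* the decoder upsamples bilinearly, fuses, refines with a conv block, and a
  1×1 head emits one logit channel at input resolution.

All forward passes consume and produce ``afnnet.nn.Tensor`` feature maps in
(batch, channel, row, col) layout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .errors import ConfigurationError, ContractViolation

__all__ = [
    "ModelConfig",
    "WFIU",
    "FEU",
    "WFEU",
    "DSCOM",
    "TransformerStage",
    "AFNNet",
    "build_afn_net",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The five `widths` are the per-level channel counts; levels 1–2 are
    convolutional (DSCOM), levels 3–5 transformer stages.  Defaults put the
    model in the single-digit-million parameter range.
    """

    widths: tuple = (16, 32, 128, 160, 256)
    in_channels: int = 3
    heads: int = 4
    mlp_ratio: int = 4
    depths: tuple = (1, 2, 2)  # transformer blocks at levels 3, 4, 5
    wfeu_kernel: int = 3
    dscom_kernel: int = 3
    dscom_dw_kernel: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.widths) != 5:
            raise ConfigurationError(f"expected 5 level widths, got {len(self.widths)}")
        if any(w <= 0 for w in self.widths):
            raise ConfigurationError(f"channel widths must be positive: {self.widths}")
        if len(self.depths) != 3:
            raise ConfigurationError("depths covers the three transformer levels")
        for w in self.widths[2:]:
            if w % self.heads:
                raise ConfigurationError(
                    f"transformer width {w} not divisible by {self.heads} heads"
                )

    @classmethod
    def tiny(cls, seed: int = 0) -> "ModelConfig":
        """A test-scale model (≈50k parameters) usable on 64×64 tiles."""
        return cls(widths=(4, 8, 16, 16, 16), depths=(1, 1, 1), seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["widths"] = list(d["widths"])
        d["depths"] = list(d["depths"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["widths"] = tuple(d["widths"])
        d["depths"] = tuple(d["depths"])
        return cls(**d)


def _check_channels(x: Tensor, expected: int, where: str):
    if x.shape[1] != expected:
        raise ContractViolation(
            f"{where}: expected {expected} input channels, got {x.shape[1]}"
        )


class WFIU(nn.Module):
    """Weighted Feature Interaction Unit.

    A sigmoid branch produces a dynamic weight map, a GELU branch a
    nonlinear transform of the same input; their elementwise product is the
    interaction feature:  x3 = σ(W1∗x+b1) ⊙ GELU(W2∗x+b2).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng):
        super().__init__()
        self.in_ch = in_ch
        pad = kernel // 2
        self.gate = nn.Conv2d(in_ch, out_ch, kernel, padding=pad, rng=rng)
        self.feat = nn.Conv2d(in_ch, out_ch, kernel, padding=pad, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_channels(x, self.in_ch, "WFIU")
        return nn.sigmoid(self.gate(x)) * nn.gelu(self.feat(x))


class FEU(nn.Module):
    """Feature Enhancement Unit.

    Enhances the interaction feature and adds a 1×1-aligned copy of the raw
    input:  out = GELU(W3∗x3+b3) + (W4∗x+b4).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng):
        super().__init__()
        pad = kernel // 2
        self.enhance = nn.Conv2d(out_ch, out_ch, kernel, padding=pad, rng=rng)
        self.align = nn.Conv2d(in_ch, out_ch, 1, rng=rng)

    def forward(self, x: Tensor, x3: Tensor) -> Tensor:
        if x.shape[2:] != x3.shape[2:]:
            raise ContractViolation(
                f"FEU: spatial mismatch between input {x.shape[2:]} "
                f"and interaction feature {x3.shape[2:]}"
            )
        return nn.gelu(self.enhance(x3)) + self.align(x)


class WFEU(nn.Module):
    """Weighted Feature Enhancement Unit fusing one skip connection.

    Concatenates the encoder feature (first) with the decoder feature
    (second) along channels, then applies WFIU followed by FEU.
    """

    def __init__(self, enc_ch: int, dec_ch: int, out_ch: int, kernel: int, rng):
        super().__init__()
        self.wfiu = WFIU(enc_ch + dec_ch, out_ch, kernel, rng)
        self.feu = FEU(enc_ch + dec_ch, out_ch, kernel, rng)

    def forward(self, encoder_feat: Tensor, decoder_feat: Tensor) -> Tensor:
        if encoder_feat.shape[0] != decoder_feat.shape[0] or \
                encoder_feat.shape[2:] != decoder_feat.shape[2:]:
            raise ContractViolation(
                f"WFEU: encoder {encoder_feat.shape} and decoder "
                f"{decoder_feat.shape} disagree in batch/spatial dims"
            )
        x = nn.concatenate([encoder_feat, decoder_feat], axis=1)
        return self.feu(x, self.wfiu(x))


class DSCOM(nn.Module):
    """Double-Stage Channel Optimization Module.

    Two stages, each: standard conv → depthwise conv → batch norm → ReLU.
    Stage 1 maps Cin→Cout; stage 2 refines at Cout.  Spatial size is
    preserved (3×3 kernels, padding 1).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dw_kernel: int, rng):
        super().__init__()
        self.in_ch = in_ch
        p, pdw = kernel // 2, dw_kernel // 2
        self.conv1 = nn.Conv2d(in_ch, out_ch, kernel, padding=p, rng=rng)
        self.dw1 = nn.Conv2d(out_ch, out_ch, dw_kernel, padding=pdw, groups=out_ch, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, kernel, padding=p, rng=rng)
        self.dw2 = nn.Conv2d(out_ch, out_ch, dw_kernel, padding=pdw, groups=out_ch, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        _check_channels(x, self.in_ch, "DSCOM")
        z1 = nn.relu(self.bn1(self.dw1(self.conv1(x))))
        return nn.relu(self.bn2(self.dw2(self.conv2(z1))))


class TransformerBlock(nn.Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: int, rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = nn.MultiHeadSelfAttention(dim, heads, rng=rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, mlp_ratio * dim, rng=rng)
        self.fc2 = nn.Linear(mlp_ratio * dim, dim, rng=rng)

    def forward(self, tokens: Tensor) -> Tensor:
        tokens = tokens + self.attn(self.norm1(tokens))
        return tokens + self.fc2(nn.gelu(self.fc1(self.norm2(tokens))))


class TransformerStage(nn.Module):
    """Strided-conv patch embedding followed by pre-norm transformer blocks.

    Tokens are the flattened spatial positions of the embedded feature map;
    the output is reshaped back to (batch, dim, H, W).
    """

    def __init__(self, in_ch: int, dim: int, depth: int, heads: int,
                 mlp_ratio: int, rng, stride: int = 2):
        super().__init__()
        self.embed = nn.Conv2d(in_ch, dim, 3, stride=stride, padding=1, rng=rng)
        self.blocks = [TransformerBlock(dim, heads, mlp_ratio, rng) for _ in range(depth)]

    def forward(self, x: Tensor) -> Tensor:
        x = self.embed(x)
        N, C, H, W = x.shape
        tokens = x.reshape(N, C, H * W).transpose(0, 2, 1)
        for blk in self.blocks:
            tokens = blk(tokens)
        return tokens.transpose(0, 2, 1).reshape(N, C, H, W)


class _UpBlock(nn.Module):
    """Bilinear 2× upsampling followed by a 3×3 conv changing width."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(nn.upsample_bilinear2x(x))


class _RefineBlock(nn.Module):
    """Post-fusion decoder refinement: 3×3 conv → batch norm → ReLU."""

    def __init__(self, ch: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(ch, ch, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(ch)

    def forward(self, x: Tensor) -> Tensor:
        return nn.relu(self.bn(self.conv(x)))


class AFNNet(nn.Module):
    """Five-level encoder–decoder with WFEU skip fusion (see module docstring)."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.widths
        k, dk = config.dscom_kernel, config.dscom_dw_kernel

        # encoder
        self.enc1 = DSCOM(config.in_channels, w[0], k, dk, rng)
        self.enc2 = DSCOM(w[0], w[1], k, dk, rng)
        self.enc3 = TransformerStage(w[1], w[2], config.depths[0], config.heads,
                                     config.mlp_ratio, rng)
        self.enc4 = TransformerStage(w[2], w[3], config.depths[1], config.heads,
                                     config.mlp_ratio, rng)
        self.enc5 = TransformerStage(w[3], w[4], config.depths[2], config.heads,
                                     config.mlp_ratio, rng)

        # decoder: up from level i+1, WFEU-fuse with encoder level i, refine
        self.up4 = _UpBlock(w[4], w[3], rng)
        self.fuse4 = WFEU(w[3], w[3], w[3], config.wfeu_kernel, rng)
        self.ref4 = _RefineBlock(w[3], rng)
        self.up3 = _UpBlock(w[3], w[2], rng)
        self.fuse3 = WFEU(w[2], w[2], w[2], config.wfeu_kernel, rng)
        self.ref3 = _RefineBlock(w[2], rng)
        self.up2 = _UpBlock(w[2], w[1], rng)
        self.fuse2 = WFEU(w[1], w[1], w[1], config.wfeu_kernel, rng)
        self.ref2 = _RefineBlock(w[1], rng)
        self.up1 = _UpBlock(w[1], w[0], rng)
        self.fuse1 = WFEU(w[0], w[0], w[0], config.wfeu_kernel, rng)
        self.ref1 = _RefineBlock(w[0], rng)

        self.head = nn.Conv2d(w[0], 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        _check_channels(x, self.config.in_channels, "AFNNet")
        H, W = x.shape[2:]
        if H % 16 or W % 16:
            raise ConfigurationError(
                f"input spatial size {H}x{W} must be divisible by 16 "
                "(four 2x reductions)"
            )
        e1 = self.enc1(x)                      # (N, w0, H, W)
        e2 = self.enc2(nn.maxpool2x2(e1))      # (N, w1, H/2, W/2)
        e3 = self.enc3(e2)                     # (N, w2, H/4, W/4)
        e4 = self.enc4(e3)                     # (N, w3, H/8, W/8)
        e5 = self.enc5(e4)                     # (N, w4, H/16, W/16)

        d4 = self.ref4(self.fuse4(e4, self.up4(e5)))
        d3 = self.ref3(self.fuse3(e3, self.up3(d4)))
        d2 = self.ref2(self.fuse2(e2, self.up2(d3)))
        d1 = self.ref1(self.fuse1(e1, self.up1(d2)))
        return self.head(d1)                   # logits (N, 1, H, W)

    def predict_proba(self, x) -> np.ndarray:
        """Inference-mode foreground probabilities (no graph recorded)."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                logits = self.forward(Tensor(np.asarray(x)))
        finally:
            self.train(was_training)
        from scipy.special import expit
        return expit(logits.data)


def build_afn_net(config: ModelConfig | None = None) -> AFNNet:
    return AFNNet(config or ModelConfig())


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(path, model: AFNNet, extra: dict | None = None):
    """Serialize parameters + running stats + config into one ``.npz``."""
    state = model.state_dict()
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path, config: ModelConfig | None = None) -> AFNNet:
    """Rebuild a model from a checkpoint; verifies config/shape agreement."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    saved = ModelConfig.from_dict(meta["config"])
    if config is not None and config != saved:
        diff = [f for f in dataclasses.fields(ModelConfig)
                if getattr(config, f.name) != getattr(saved, f.name)]
        raise ConfigurationError(
            "checkpoint/config mismatch in fields: " + ", ".join(f.name for f in diff)
        )
    model = AFNNet(saved)
    model.load_state_dict(state)
    return model
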