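"""Independent scalar reference implementations used as test oracles.

Everything here is written as plain per-pixel loops (or exhaustive
enumeration), deliberately independent of the package's vectorized code
paths.
"""

import numpy as np
from scipy.special import erf, expit


def conv2d_ref(x, w, b, stride=1, padding=1, groups=1):
    """Per-output-position scalar cross-correlation."""
    N, Cin, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((N, Cout, Ho, Wo))
    og = Cout // groups
    for n in range(N):
        for o in range(Cout):
            gidx = o // og
            for y in range(Ho):
                for xx in range(Wo):
                    acc = 0.0
                    for ci in range(Cg):
                        c = gidx * Cg + ci
                        for i in range(kh):
                            for j in range(kw):
                                acc += w[o, ci, i, j] * xp[n, c, y * stride + i, xx * stride + j]
                    out[n, o, y, xx] = acc + (b[o] if b is not None else 0.0)
    return out


def gelu_ref(v):
    return v * 0.5 * (1.0 + erf(v / np.sqrt(2.0)))


def wfiu_ref(x, w1, b1, w2, b2):
    """x3 = sigmoid(W1*x+b1) ⊙ GELU(W2*x+b2), scalar loops."""
    a = conv2d_ref(x, w1, b1)
    c = conv2d_ref(x, w2, b2)
    return expit(a) * gelu_ref(c)


def feu_ref(x, x3, w3, b3, w4, b4):
    """out = GELU(W3*x3+b3) + (W4*x+b4), W4 a 1x1 conv."""
    enh = gelu_ref(conv2d_ref(x3, w3, b3))
    ali = conv2d_ref(x, w4, b4, padding=0)
    return enh + ali


def dscom_ref(x, params, eps=1e-5):
    """Two stages of conv→depthwise→batchnorm(identity stats)→ReLU."""
    w1, b1, w2, b2, g1, be1, w3, b3, w4, b4, g2, be2 = params
    z = conv2d_ref(x, w1, b1)
    z = conv2d_ref(z, w2, b2, groups=z.shape[1])
    z = (z - 0.0) / np.sqrt(1.0 + eps)  # identity running stats
    z = z * g1[None, :, None, None] + be1[None, :, None, None]
    z = np.maximum(z, 0.0)
    z2 = conv2d_ref(z, w3, b3)
    z2 = conv2d_ref(z2, w4, b4, groups=z2.shape[1])
    z2 = (z2 - 0.0) / np.sqrt(1.0 + eps)
    z2 = z2 * g2[None, :, None, None] + be2[None, :, None, None]
    return np.maximum(z2, 0.0)


def boundary_ref(mask):
    """Inner boundary by explicit 4-neighborhood enumeration."""
    H, W = mask.shape
    out = np.zeros_like(mask)
    for r in range(H):
        for c in range(W):
            if mask[r, c] != 1:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] != mask[r, c]:
                    out[r, c] = 1
                    break
    return out


def distance_map_ref(boundary):
    """Exhaustive min Euclidean distance to any boundary pixel."""
    H, W = boundary.shape
    pts = np.argwhere(boundary == 1)
    out = np.zeros((H, W))
    if len(pts) == 0:
        return out
    for r in range(H):
        for c in range(W):
            out[r, c] = np.sqrt(((pts - (r, c)) ** 2).sum(axis=1).min())
    return out


def gradient_magnitude_ref(p):
    """Forward differences, replicate padding at last row/col, scalar loops."""
    H, W = p.shape
    out = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            dx = p[r, c + 1] - p[r, c] if c + 1 < W else 0.0
            dy = p[r + 1, c] - p[r, c] if r + 1 < H else 0.0
            out[r, c] = np.sqrt(dx * dx + dy * dy)
    return out


def bce_ref(logits, mask):
    """Per-pixel scalar evaluation of binary cross-entropy on logits."""
    total, n = 0.0, 0
    for P, G in zip(logits.ravel(), mask.ravel()):
        s = expit(P)
        total += -(G * np.log(s) + (1 - G) * np.log(1 - s))
        n += 1
    return total / n
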