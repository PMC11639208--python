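"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit Python loops over plain numpy
arrays and shares no code with the package kernels it checks.
"""

import numpy as np


def conv_naive(x, w, b=None):
    """Zero-padded 'same' cross-correlation, explicit loops.

    x: (Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    """
    cout, cin, kh, kw = w.shape
    _, H, W = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((cout, H, W))
    for o in range(cout):
        for i in range(H):
            for j in range(W):
                out[o, i, j] = np.sum(xp[:, i : i + kh, j : j + kw] * w[o])
        if b is not None:
            out[o] += b[o]
    return out


def depthwise_naive(x, w, b=None):
    """Per-channel 'same' cross-correlation; w: (C, kh, kw)."""
    C, H, W = x.shape
    _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((C, H, W))
    for c in range(C):
        for i in range(H):
            for j in range(W):
                out[c, i, j] = np.sum(xp[c, i : i + kh, j : j + kw] * w[c])
        if b is not None:
            out[c] += b[c]
    return out


def sliding_dot(q, protos):
    """Triple-loop sliding-window dot product of prototypes over a query.

    q: (C, H, W); protos: (N, C, k, k) -> (N, H, W)."""
    n = protos.shape[0]
    return np.stack([conv_naive(q, protos[i : i + 1])[0] for i in range(n)])


def stamp(r, protos):
    """Accumulate a prototype-shaped stamp at every similarity value.

    r: (N, H, W); protos: (N, C, k, k) -> (C, H, W)."""
    n_ex, H, W = r.shape
    _, C, k, _ = protos.shape
    rad = k // 2
    out = np.zeros((C, H, W))
    for n in range(n_ex):
        for i in range(H):
            for j in range(W):
                for di in range(-rad, rad + 1):
                    for dj in range(-rad, rad + 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < H and 0 <= jj < W:
                            out[:, ii, jj] += r[n, i, j] * protos[n, :, di + rad, dj + rad]
    return out


def layer_norm_naive(x, gain, shift, eps=1e-5):
    """Channel layer norm at every spatial position; x: (C, H, W)."""
    out = np.zeros_like(x)
    for i in range(x.shape[1]):
        for j in range(x.shape[2]):
            v = x[:, i, j]
            out[:, i, j] = gain * (v - v.mean()) / np.sqrt(v.var() + eps) + shift
    return out


def map_features_naive(x, w, b, gain, shift):
    """1x1 projection then layer norm; x: (C, H, W)."""
    _, H, W = x.shape
    y = np.einsum("oc,chw->ohw", w, x) + b[:, None, None]
    return layer_norm_naive(y, gain, shift)


def exemplar_norm_naive(r, divisor):
    """Direct softmax over the exemplar axis, no stability shift."""
    e = np.exp(r / divisor)
    return e / e.sum(axis=0, keepdims=True)


def spatial_norm_naive(r, divisor):
    """Direct exp-over-spatial-max, no stability shift (small inputs only)."""
    e = np.exp(r / divisor)
    return e / e.max(axis=(1, 2), keepdims=True)


def spatial_attention_naive(fr, w, b):
    """Channel mean/max stack, 7x7 conv, sigmoid, multiply."""
    stack = np.stack([fr.mean(axis=0), fr.max(axis=0)])
    att = 1.0 / (1.0 + np.exp(-conv_naive(stack, w, b)[0]))
    return fr * att[None]


def fuse_naive(frs, fusion, conv_attention=True):
    """Stage-by-stage strip-attention fusion on numpy weights.

    fusion: dict of numpy arrays mirroring EnhanceParams.fusion.
    """
    fc = np.concatenate(frs, axis=0)
    if conv_attention:
        base = depthwise_naive(fc, fusion["dw5_w"], fusion["dw5_b"])
        agg = base.copy()
        for wa, wb in fusion["strips"]:
            agg += depthwise_naive(depthwise_naive(base, wa), wb)
        att = conv_naive(agg, fusion["att_w"], fusion["att_b"])
        fc = fc * att
    return conv_naive(fc, fusion["red_w"], fusion["red_b"])


def enhance_naive(fq, fc, h, ln):
    """Two 3x3 convs with ReLU between, residual add, layer norm."""
    y = conv_naive(fc, h["w1"], h["b1"])
    y = np.maximum(y, 0.0)
    y = conv_naive(y, h["w2"], h["b2"])
    return layer_norm_naive(fq + y, ln["gain"], ln["shift"])
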