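"""Minimal differentiable building blocks on numpy + autograd.

No deep-learning framework is assumed: parameters live in a flat
``dict[str, ndarray]`` and every forward function is written with
``autograd.numpy`` so gradients of a scalar loss with respect to the whole
parameter dict come from ``autograd.grad``.  Everything runs in float64 on
one CPU, which is ample at the desk scales this package targets.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

__all__ = [
    "silu",
    "sigmoid",
    "linear",
    "conv2d",
    "adaptive_pool",
    "count_parameters",
    "init_weights",
]


def sigmoid(x):
    # tanh form: stable for large |x|, unlike 1/(1+exp(-x))
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def silu(x):
    return x * sigmoid(x)


def linear(params: dict, name: str, x):
    return anp.dot(x, params[f"{name}_W"]) + params[f"{name}_b"]


def _pad2d(x, pad: int):
    """Zero-pad the two leading spatial dims of an (H, W, C) tensor."""
    if pad == 0:
        return x
    h, w, c = x.shape
    zr = anp.zeros((pad, w, c))
    x = anp.concatenate([zr, x, zr], axis=0)
    zc = anp.zeros((h + 2 * pad, pad, c))
    return anp.concatenate([zc, x, zc], axis=1)


def conv2d(x, weight, bias, stride: int = 1, pad: int = 0):
    """2-D convolution on an (H, W, Cin) tensor with an (kh, kw, Cin, Cout) kernel.

    Implemented as patch extraction by integer indexing followed by a
    tensordot, both of which autograd differentiates.
    """
    kh, kw = weight.shape[0], weight.shape[1]
    xp = _pad2d(x, pad)
    hp, wp = xp.shape[0], xp.shape[1]
    h_out = (hp - kh) // stride + 1
    w_out = (wp - kw) // stride + 1
    # one strided slice + matmul per kernel offset: cheap and autograd-friendly
    out = None
    for di in range(kh):
        for dj in range(kw):
            sl = xp[di : di + h_out * stride : stride, dj : dj + w_out * stride : stride]
            term = anp.dot(sl, weight[di, dj])  # (H', W', Cout)
            out = term if out is None else out + term
    return out + bias


def adaptive_pool(feats, target_len: int):
    """Adaptive average pooling along the first axis to ``target_len`` rows.

    Output row ``t`` is the mean of input rows ``floor(t*L/T)`` through
    ``ceil((t+1)*L/T) - 1``; the identity when ``L == target_len``.  Works on
    both plain arrays and autograd boxes.
    """
    L = feats.shape[0]
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    if L == target_len:
        return feats
    rows = []
    for t in range(target_len):
        start = (t * L) // target_len
        end = -((-(t + 1) * L) // target_len)  # ceil((t+1)*L/T)
        rows.append(anp.mean(feats[start:end], axis=0))
    return anp.stack(rows, axis=0)


def count_parameters(params: dict) -> int:
    """Exact count of trainable scalars in a parameter dict (or model)."""
    if hasattr(params, "params"):
        params = params.params
    return int(sum(np.asarray(v).size for v in params.values()))


def init_weights(shapes: dict[str, tuple], seed: int, sigma: float = 0.02) -> dict:
    """Draw every trainable scalar i.i.d. Normal(0, sigma), reproducibly.

    Keys are initialized in sorted order so the draw is independent of dict
    insertion order.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    return {
        name: rng.standard_normal(shapes[name]) * sigma for name in sorted(shapes)
    }
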