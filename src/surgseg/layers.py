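"""Temporal network primitives in NumPy, with explicit backward passes.

Every layer is a pair of functions ``*_forward(x, params...) -> (y, cache)``
and ``*_backward(dy, cache) -> (dx, grads)`` operating on float64 arrays of
shape ``T x channels``.  Gradients are returned in dictionaries keyed like
the parameter dictionaries, so a network is just a composition of these
pairs plus a flat ``dict[str, ndarray]`` of parameters.  Analytic gradients
are validated against central finite differences in the test suite.

Convolutions are acausal (centered): a dilated kernel of odd width ``k``
and rate ``s`` is padded with ``s * (k - 1) / 2`` zeros on each side so the
temporal length is preserved at every dilation rate.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dilated_conv_forward",
    "dilated_conv_backward",
    "dilated_residual_forward",
    "dilated_residual_backward",
    "max_pool_forward",
    "max_pool_backward",
    "unpool_forward",
    "unpool_backward",
    "positional_encoding",
    "scaled_dot_product_attention",
    "attention_forward",
    "attention_backward",
    "attention_block_forward",
    "attention_block_backward",
    "layer_norm_forward",
    "layer_norm_backward",
    "linear_forward",
    "linear_backward",
    "softmax",
]


def _check_finite(x: np.ndarray, where: str) -> None:
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(f"non-finite activations in {where}")


# ---------------------------------------------------------------------------
# dense / convolutional layers
# ---------------------------------------------------------------------------

def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Per-frame affine map: ``y = x @ W + b``."""
    return x @ W + b, (x, W)


def linear_backward(dy: np.ndarray, cache):
    x, W = cache
    return dy @ W.T, {"W": x.T @ dy, "b": dy.sum(axis=0)}


def dilated_conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, dilation: int):
    """Acausal 1-D dilated convolution.

    Parameters
    ----------
    x : (T, f_in)
    W : (k, f_in, f_out) with odd k
    b : (f_out,)
    dilation : tap spacing s >= 1

    Zero-padding of ``s * (k - 1) / 2`` frames on each side keeps the
    output length equal to T for every dilation rate.
    """
    k = W.shape[0]
    if k % 2 == 0:
        raise ValueError("kernel width must be odd for acausal convolution")
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    if x.shape[1] != W.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, weights expect {W.shape[1]}")
    T = x.shape[0]
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((pad, pad), (0, 0)))
    y = np.broadcast_to(b, (T, W.shape[2])).copy()
    for j in range(k):
        y += xp[j * dilation:j * dilation + T] @ W[j]
    return y, (xp, W, dilation, T)


def dilated_conv_backward(dy: np.ndarray, cache):
    xp, W, dilation, T = cache
    k = W.shape[0]
    pad = dilation * (k - 1) // 2
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for j in range(k):
        seg = slice(j * dilation, j * dilation + T)
        dW[j] = xp[seg].T @ dy
        dxp[seg] += dy @ W[j].T
    dx = dxp[pad:pad + T] if pad else dxp
    return dx, {"W": dW, "b": dy.sum(axis=0)}


def dilated_residual_forward(x: np.ndarray, params: dict, dilation: int):
    """Dilated residual layer: ``out = x + W2 * ReLU(W1 (*) x + b1) + b2``.

    ``(*)`` is the acausal dilated convolution; ``W2`` is a 1x1 (pointwise)
    convolution.  The residual connection makes the layer an exact identity
    when both convolution branches are zero.
    """
    z, conv_cache = dilated_conv_forward(x, params["W1"], params["b1"], dilation)
    a = np.maximum(z, 0.0)
    y = x + a @ params["W2"] + params["b2"]
    return y, (conv_cache, z, a, params["W2"])


def dilated_residual_backward(dy: np.ndarray, cache):
    conv_cache, z, a, W2 = cache
    da = dy @ W2.T
    dz = da * (z > 0)
    dx_conv, conv_grads = dilated_conv_backward(dz, conv_cache)
    grads = {
        "W1": conv_grads["W"],
        "b1": conv_grads["b"],
        "W2": a.T @ dy,
        "b2": dy.sum(axis=0),
    }
    return dy + dx_conv, grads


# ---------------------------------------------------------------------------
# temporal pooling
# ---------------------------------------------------------------------------

def max_pool_forward(x: np.ndarray, pool: int):
    """Temporal max-pool by ``pool``; output length ``ceil(T / pool)``.

    When T is not a multiple of the pool factor the sequence is right-padded
    by replicating the last frame, so no frame is dropped.
    """
    T, f = x.shape
    n = -(-T // pool)  # ceil
    if T % pool:
        x_padded = np.concatenate(
            [x, np.broadcast_to(x[-1], (n * pool - T, f))], axis=0)
    else:
        x_padded = x
    windows = x_padded.reshape(n, pool, f)
    arg = windows.argmax(axis=1)                      # (n, f)
    y = np.take_along_axis(windows, arg[:, None, :], axis=1)[:, 0, :]
    return y, (arg, T, pool, f)


def max_pool_backward(dy: np.ndarray, cache):
    arg, T, pool, f = cache
    n = dy.shape[0]
    dxp = np.zeros((n * pool, f))
    rows = np.arange(n)[:, None] * pool + arg
    cols = np.broadcast_to(np.arange(f), (n, f))
    # every (row, col) pair is unique: one winner per window per channel
    dxp[rows, cols] = dy
    dx = dxp[:T].copy()
    if n * pool > T:
        dx[T - 1] += dxp[T:].sum(axis=0)  # replicate-padding routes to the last frame
    return dx


def unpool_forward(h: np.ndarray, pool: int, T: int):
    """Nearest-neighbour unpooling: repeat each frame ``pool`` times, crop to T."""
    n = h.shape[0]
    if n != -(-T // pool):
        raise ValueError(f"bottleneck length {n} inconsistent with T={T}, pool={pool}")
    y = np.repeat(h, pool, axis=0)[:T]
    return y, (n, pool, T, h.shape[1])


def unpool_backward(dy: np.ndarray, cache):
    n, pool, T, f = cache
    if n * pool > T:
        dy = np.concatenate([dy, np.zeros((n * pool - T, f))], axis=0)
    return dy.reshape(n, pool, f).sum(axis=1)


# ---------------------------------------------------------------------------
# attention bottleneck
# ---------------------------------------------------------------------------

def positional_encoding(T: int, f: int) -> np.ndarray:
    """Fixed sinusoidal position code, values in [-1, 1].

    Channel pair ``(2i, 2i+1)`` oscillates at wavelength ``10000**(2i/f)``:
    ``pe[t, 2i] = sin(t / 10000**(2i/f))``, ``pe[t, 2i+1] = cos(...)``.
    """
    if T < 1 or f < 1:
        raise ValueError("positional encoding needs T >= 1 and f >= 1")
    pos = np.arange(T, dtype=float)[:, None]
    i = np.arange(0, f, 2, dtype=float)
    angle = pos / (10000.0 ** (i / f))
    pe = np.empty((T, f))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : f // 2])
    return pe


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_product_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray):
    """``Softmax(Q K^T / sqrt(d_k)) V``; returns (output, attention weights).

    The 1/sqrt(d_k) scaling keeps the logits of the softmax in a range
    where gradients do not explode for high-dimensional keys.
    """
    d_k = Q.shape[1]
    if d_k == 0:
        raise ValueError("d_k must be positive")
    if Q.shape[0] != K.shape[0] or K.shape[0] != V.shape[0]:
        raise ValueError("Q, K, V must have the same number of rows (self-attention)")
    A = softmax(Q @ K.T / np.sqrt(d_k), axis=1)
    return A @ V, A


def attention_forward(h: np.ndarray, p: dict):
    """Single-head self-attention with learned Q/K/V/output projections."""
    Q = h @ p["Wq"] + p["bq"]
    K = h @ p["Wk"] + p["bk"]
    V = h @ p["Wv"] + p["bv"]
    out, A = scaled_dot_product_attention(Q, K, V)
    y = out @ p["Wo"] + p["bo"]
    return y, (h, Q, K, V, A, out, p)


def attention_backward(dy: np.ndarray, cache):
    h, Q, K, V, A, out, p = cache
    d_k = Q.shape[1]
    dout = dy @ p["Wo"].T
    dA = dout @ V.T
    dV = A.T @ dout
    dS = A * (dA - (dA * A).sum(axis=1, keepdims=True))  # softmax rows
    scale = 1.0 / np.sqrt(d_k)
    dQ = dS @ K * scale
    dK = dS.T @ Q * scale
    grads = {
        "Wq": h.T @ dQ, "bq": dQ.sum(0),
        "Wk": h.T @ dK, "bk": dK.sum(0),
        "Wv": h.T @ dV, "bv": dV.sum(0),
        "Wo": out.T @ dy, "bo": dy.sum(0),
    }
    dh = dQ @ p["Wq"].T + dK @ p["Wk"].T + dV @ p["Wv"].T
    return dh, grads


_LN_EPS = 1e-6


def layer_norm_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def layer_norm_backward(dy: np.ndarray, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
    )
    return dx, {"g": (dy * xhat).sum(0), "b": dy.sum(0)}


def attention_block_forward(h: np.ndarray, p: dict):
    """Attention block: two residual connections, each followed by layer norm.

        h1 = LN1(h + SelfAttention(h))
        y  = LN2(h1 + FFN(h1)),   FFN = W_f2 ReLU(W_f1 x + c1) + c2
    """
    att, att_cache = attention_forward(h, p)
    r1 = h + att
    h1, ln1_cache = layer_norm_forward(r1, p["ln1_g"], p["ln1_b"])
    z = h1 @ p["Wf1"] + p["cf1"]
    a = np.maximum(z, 0.0)
    ffn = a @ p["Wf2"] + p["cf2"]
    y, ln2_cache = layer_norm_forward(h1 + ffn, p["ln2_g"], p["ln2_b"])
    return y, (att_cache, ln1_cache, h1, z, a, ln2_cache, p)


def attention_block_backward(dy: np.ndarray, cache):
    att_cache, ln1_cache, h1, z, a, ln2_cache, p = cache
    dr2, ln2_grads = layer_norm_backward(dy, ln2_cache)
    # FFN branch
    da = dr2 @ p["Wf2"].T
    dz = da * (z > 0)
    dh1 = dr2 + dz @ p["Wf1"].T
    grads = {
        "Wf2": a.T @ dr2, "cf2": dr2.sum(0),
        "Wf1": h1.T @ dz, "cf1": dz.sum(0),
        "ln2_g": ln2_grads["g"], "ln2_b": ln2_grads["b"],
    }
    dr1, ln1_grads = layer_norm_backward(dh1, ln1_cache)
    grads["ln1_g"] = ln1_grads["g"]
    grads["ln1_b"] = ln1_grads["b"]
    datt, att_grads = attention_backward(dr1, att_cache)
    grads.update(att_grads)
    return dr1 + datt, grads
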