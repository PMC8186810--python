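"""Backpropagation through time for stacked BRC/nBRC/GRU layers.

The forward pass caches per-step activations (gates, candidate, states); the
backward pass replays them in reverse, accumulating parameter gradients and a
gradient with respect to the layer's input sequence, which is then passed down
to the layer below.  Arrays are time-major: an input sequence has shape
``(T, B, dim)``.

Gradient correctness is property-tested against central finite differences;
there is no autodiff framework behind this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cells import AnyWeights, CellWeights, GRUWeights, _sigmoid

__all__ = ["LayerCache", "forward_layer", "backward_layer", "Adam"]


@dataclass
class LayerCache:
    """Activations of one layer over a sequence, kept for the backward pass."""

    xs: np.ndarray        # (T, B, d) layer input
    hs: np.ndarray        # (T + 1, B, H): hs[0] is the initial state
    a: Optional[np.ndarray] = None   # BRC/nBRC feedback gate (T, B, H)
    c: Optional[np.ndarray] = None   # BRC/nBRC update gate
    e: Optional[np.ndarray] = None   # candidate tanh
    z: Optional[np.ndarray] = None   # GRU update gate
    r: Optional[np.ndarray] = None   # GRU reset gate
    s: Optional[np.ndarray] = None   # GRU recurrent drive W_h h


def forward_layer(w: AnyWeights, xs: np.ndarray, h0: Optional[np.ndarray] = None) -> LayerCache:
    """Run one layer over ``xs`` (time-major ``(T, B, d)``), caching
    everything the backward pass needs."""
    T, B, _ = xs.shape
    H = w.hidden
    hs = np.zeros((T + 1, B, H), dtype=xs.dtype)
    if h0 is not None:
        hs[0] = h0
    if isinstance(w, GRUWeights):
        z = np.empty((T, B, H), dtype=xs.dtype)
        r = np.empty_like(z)
        e = np.empty_like(z)
        s = np.empty_like(z)
        # hoist the input-kernel matmuls out of the time loop
        xz = xs @ w.U_z + w.b_z
        xr = xs @ w.U_r + w.b_r
        xh = xs @ w.U_h + w.b_h
        for t in range(T):
            h = hs[t]
            z[t] = _sigmoid(xz[t] + h @ w.W_z)
            r[t] = _sigmoid(xr[t] + h @ w.W_r)
            s[t] = h @ w.W_h
            e[t] = np.tanh(xh[t] + r[t] * s[t])
            hs[t + 1] = z[t] * h + (1.0 - z[t]) * e[t]
        return LayerCache(xs=xs, hs=hs, z=z, r=r, e=e, s=s)
    a = np.empty((T, B, H), dtype=xs.dtype)
    c = np.empty_like(a)
    e = np.empty_like(a)
    xa = xs @ w.U_a + w.b_a
    xc = xs @ w.U_c + w.b_c
    xh = xs @ w.U + w.b
    diag = w.kind == "brc"
    for t in range(T):
        h = hs[t]
        pa = xa[t] + (w.w_a * h if diag else h @ w.W_a)
        pc = xc[t] + (w.w_c * h if diag else h @ w.W_c)
        a[t] = 1.0 + np.tanh(pa)
        c[t] = _sigmoid(pc)
        e[t] = np.tanh(xh[t] + a[t] * h)
        hs[t + 1] = c[t] * h + (1.0 - c[t]) * e[t]
    return LayerCache(xs=xs, hs=hs, a=a, c=c, e=e)


def backward_layer(
    w: AnyWeights, cache: LayerCache, ghs: np.ndarray
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Backward pass through one layer.

    ``ghs`` holds the loss gradient w.r.t. the layer's *output* states, shape
    ``(T, B, H)`` (zero wherever the loss does not read the state).  Returns
    ``(param_grads, gxs)`` with ``gxs`` the gradient w.r.t. the input
    sequence.
    """
    T, B, _ = cache.xs.shape
    grads = {n: np.zeros_like(getattr(w, n)) for n in w.param_names()}
    gxs = np.empty_like(cache.xs)
    gh = np.zeros((B, w.hidden), dtype=cache.xs.dtype)
    if isinstance(w, GRUWeights):
        gpz_all = np.empty((T, B, w.hidden), dtype=cache.xs.dtype)
        gpr_all = np.empty_like(gpz_all)
        gph_all = np.empty_like(gpz_all)
        for t in range(T - 1, -1, -1):
            gh = gh + ghs[t]
            h, z, r, e, s = cache.hs[t], cache.z[t], cache.r[t], cache.e[t], cache.s[t]
            gz = gh * (h - e)
            ge = gh * (1.0 - z)
            gh_prev = gh * z
            gph = ge * (1.0 - e * e)
            gr = gph * s
            gs = gph * r
            gh_prev += gs @ w.W_h.T
            grads["W_h"] += h.T @ gs
            gpz = gz * z * (1.0 - z)
            gpr = gr * r * (1.0 - r)
            gh_prev += gpz @ w.W_z.T + gpr @ w.W_r.T
            grads["W_z"] += h.T @ gpz
            grads["W_r"] += h.T @ gpr
            gpz_all[t], gpr_all[t], gph_all[t] = gpz, gpr, gph
            gh = gh_prev
        # input-kernel and bias grads batched over all steps
        X = cache.xs.reshape(T * B, -1)
        grads["U_z"] += X.T @ gpz_all.reshape(T * B, -1)
        grads["U_r"] += X.T @ gpr_all.reshape(T * B, -1)
        grads["U_h"] += X.T @ gph_all.reshape(T * B, -1)
        grads["b_z"] += gpz_all.sum((0, 1))
        grads["b_r"] += gpr_all.sum((0, 1))
        grads["b_h"] += gph_all.sum((0, 1))
        gxs[:] = gpz_all @ w.U_z.T + gpr_all @ w.U_r.T + gph_all @ w.U_h.T
        return grads, gxs
    diag = w.kind == "brc"
    gpa_all = np.empty((T, B, w.hidden), dtype=cache.xs.dtype)
    gpc_all = np.empty_like(gpa_all)
    gph_all = np.empty_like(gpa_all)
    for t in range(T - 1, -1, -1):
        gh = gh + ghs[t]
        h, a, c, e = cache.hs[t], cache.a[t], cache.c[t], cache.e[t]
        gc = gh * (h - e)
        ge = gh * (1.0 - c)
        gh_prev = gh * c
        gph = ge * (1.0 - e * e)
        ga = gph * h
        gh_prev += gph * a
        am1 = a - 1.0
        gpa = ga * (1.0 - am1 * am1)
        gpc = gc * c * (1.0 - c)
        if diag:
            grads["w_a"] += (gpa * h).sum(0)
            grads["w_c"] += (gpc * h).sum(0)
            gh_prev += gpa * w.w_a + gpc * w.w_c
        else:
            grads["W_a"] += h.T @ gpa
            grads["W_c"] += h.T @ gpc
            gh_prev += gpa @ w.W_a.T + gpc @ w.W_c.T
        gpa_all[t], gpc_all[t], gph_all[t] = gpa, gpc, gph
        gh = gh_prev
    X = cache.xs.reshape(T * B, -1)
    grads["U_a"] += X.T @ gpa_all.reshape(T * B, -1)
    grads["U_c"] += X.T @ gpc_all.reshape(T * B, -1)
    grads["U"] += X.T @ gph_all.reshape(T * B, -1)
    if w.use_bias:
        grads["b_a"] += gpa_all.sum((0, 1))
        grads["b_c"] += gpc_all.sum((0, 1))
        grads["b"] += gph_all.sum((0, 1))
    gxs[:] = gpa_all @ w.U_a.T + gpc_all @ w.U_c.T + gph_all @ w.U.T
    return grads, gxs


class Adam:
    """Plain Adam over a list of parameter arrays, updated in place."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
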