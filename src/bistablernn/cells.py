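"""Recurrent cell updates: the bistable recurrent cell (BRC), its recurrently
neuromodulated variant (nBRC), and a gated recurrent unit (GRU) baseline.

A BRC neuron keeps memory at the *cellular* level: the only recurrent path into
its hidden state ``h`` is its own past value.  The candidate activation is
``tanh(U x_t + a_t * h_{t-1})`` where the feedback gate

    a_t = 1 + tanh(U_a x_t + w_a * h_{t-1})        (BRC, elementwise)
    a_t = 1 + tanh(U_a x_t + W_a h_{t-1})          (nBRC, full kernel)

takes values in the open interval (0, 2).  For ``a > 1`` the scalar update map
is bistable (two stable fixed points of opposite sign), which gives the cell a
memory that does not fade with time; for ``a < 1`` the state relaxes to zero.
The update gate

    c_t = sigmoid(U_c x_t + w_c * h_{t-1})         (or ``W_c h_{t-1}`` for nBRC)

is the convex-combination weight between the previous state and the candidate
and plays the role of a membrane capacitance: it sets the convergence speed.
The state update itself is identical for both cells and stays elementwise in
``h_{t-1}``:

    h_t = c_t * h_{t-1} + (1 - c_t) * tanh(U x_t + a_t * h_{t-1})

The nBRC relaxes the cellular constraint only in the *gates*: ``a_t`` and
``c_t`` may be neuromodulated by every neuron of the layer, which adds network
memory on top of the cellular memory while keeping the state path local.

All operations broadcast over arbitrary leading batch dimensions: ``x`` has
shape ``(..., input_dim)`` and ``h`` shape ``(..., hidden)``.

Additive biases (``b``, ``b_a``, ``b_c``) are included as standard deep-learning
plumbing and initialised to zero, so a freshly initialised cell computes the
bias-free update exactly; pass ``bias=False`` to :func:`init_weights` to omit
them altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "CellWeights",
    "GRUWeights",
    "GateValues",
    "GateTrace",
    "brc_gates",
    "brc_step",
    "nbrc_gates",
    "nbrc_step",
    "gru_step",
    "step",
    "unroll",
    "init_weights",
    "save_weights",
    "load_weights",
]

CELL_KINDS = ("brc", "nbrc", "gru")


class DimensionError(ValueError):
    """Raised when array shapes are inconsistent with the declared dims."""


@dataclass
class GateValues:
    """Gate activations of one step: feedback gate ``a`` in (0, 2) and update
    gate ``c`` in (0, 1), one entry per neuron."""

    a: np.ndarray
    c: np.ndarray


@dataclass
class CellWeights:
    """Trainable arrays of one BRC or nBRC layer.

    ``w_a``/``w_c`` are the per-neuron recurrent gains of the BRC;
    ``W_a``/``W_c`` are the full recurrent kernels of the nBRC.  Exactly one of
    the two families is set, according to ``kind``.
    """

    kind: str
    input_dim: int
    hidden: int
    U: np.ndarray
    U_a: np.ndarray
    U_c: np.ndarray
    b: np.ndarray
    b_a: np.ndarray
    b_c: np.ndarray
    w_a: Optional[np.ndarray] = None
    w_c: Optional[np.ndarray] = None
    W_a: Optional[np.ndarray] = None
    W_c: Optional[np.ndarray] = None
    use_bias: bool = True  # False freezes the (zero) biases: literal update rule

    def __post_init__(self) -> None:
        if self.kind not in ("brc", "nbrc"):
            raise ValueError(f"kind must be 'brc' or 'nbrc', got {self.kind!r}")
        d, h = self.input_dim, self.hidden
        for name in ("U", "U_a", "U_c"):
            arr = getattr(self, name)
            if arr.shape != (d, h):
                raise DimensionError(f"{name}: expected {(d, h)}, got {arr.shape}")
        for name in ("b", "b_a", "b_c"):
            if getattr(self, name).shape != (h,):
                raise DimensionError(f"{name}: expected {(h,)}")
        if self.kind == "brc":
            if self.w_a is None or self.w_c is None:
                raise DimensionError("BRC weights need per-neuron gains w_a, w_c")
            if self.w_a.shape != (h,) or self.w_c.shape != (h,):
                raise DimensionError("w_a/w_c must have shape (hidden,)")
        else:
            if self.W_a is None or self.W_c is None:
                raise DimensionError("nBRC weights need recurrent kernels W_a, W_c")
            if self.W_a.shape != (h, h) or self.W_c.shape != (h, h):
                raise DimensionError("W_a/W_c must have shape (hidden, hidden)")
        for arr in self.param_list():
            if not np.all(np.isfinite(arr)):
                raise ValueError("cell weights must be finite")

    def param_names(self) -> List[str]:
        base = ["U", "U_a", "U_c"]
        if self.use_bias:
            base += ["b", "b_a", "b_c"]
        rec = ["w_a", "w_c"] if self.kind == "brc" else ["W_a", "W_c"]
        return base + rec

    def param_list(self) -> List[np.ndarray]:
        return [getattr(self, n) for n in self.param_names()]


@dataclass
class GRUWeights:
    """Trainable arrays of one GRU layer (update gate z, reset gate r)."""

    input_dim: int
    hidden: int
    U_z: np.ndarray
    U_r: np.ndarray
    U_h: np.ndarray
    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray
    kind: str = field(default="gru")

    def __post_init__(self) -> None:
        d, h = self.input_dim, self.hidden
        for name in ("U_z", "U_r", "U_h"):
            if getattr(self, name).shape != (d, h):
                raise DimensionError(f"{name}: expected {(d, h)}")
        for name in ("W_z", "W_r", "W_h"):
            if getattr(self, name).shape != (h, h):
                raise DimensionError(f"{name}: expected {(h, h)}")
        for name in ("b_z", "b_r", "b_h"):
            if getattr(self, name).shape != (h,):
                raise DimensionError(f"{name}: expected {(h,)}")

    def param_names(self) -> List[str]:
        return ["U_z", "U_r", "U_h", "W_z", "W_r", "W_h", "b_z", "b_r", "b_h"]

    def param_list(self) -> List[np.ndarray]:
        return [getattr(self, n) for n in self.param_names()]


AnyWeights = Union[CellWeights, GRUWeights]


@dataclass
class GateTrace:
    """Recorded gate activations per layer: lists (one entry per layer) of
    arrays of shape ``(T, ..., hidden)``."""

    a: List[np.ndarray]
    c: List[np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-sided form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _check_shapes(x: np.ndarray, h: np.ndarray, w: AnyWeights) -> None:
    if x.shape[-1] != w.input_dim:
        raise DimensionError(
            f"input dim {x.shape[-1]} != declared input_dim {w.input_dim}"
        )
    if h.shape[-1] != w.hidden:
        raise DimensionError(f"state dim {h.shape[-1]} != declared hidden {w.hidden}")


def brc_gates(x: np.ndarray, h_prev: np.ndarray, w: CellWeights) -> GateValues:
    """Feedback and update gates of the BRC.

    The recurrent contribution is elementwise: neuron ``i``'s gates depend on
    ``h_prev[i]`` only.
    """
    x = np.asarray(x)
    h_prev = np.asarray(h_prev)
    _check_shapes(x, h_prev, w)
    a = 1.0 + np.tanh(x @ w.U_a + w.w_a * h_prev + w.b_a)
    c = _sigmoid(x @ w.U_c + w.w_c * h_prev + w.b_c)
    return GateValues(a=a, c=c)


def nbrc_gates(x: np.ndarray, h_prev: np.ndarray, w: CellWeights) -> GateValues:
    """Recurrently neuromodulated gates: full kernels ``W_a``, ``W_c`` let the
    gates of neuron ``i`` depend on every neuron of the layer."""
    x = np.asarray(x)
    h_prev = np.asarray(h_prev)
    _check_shapes(x, h_prev, w)
    a = 1.0 + np.tanh(x @ w.U_a + h_prev @ w.W_a + w.b_a)
    c = _sigmoid(x @ w.U_c + h_prev @ w.W_c + w.b_c)
    return GateValues(a=a, c=c)


def _bistable_update(
    x: np.ndarray, h_prev: np.ndarray, w: CellWeights, g: GateValues
) -> np.ndarray:
    cand = np.tanh(x @ w.U + g.a * h_prev + w.b)
    return g.c * h_prev + (1.0 - g.c) * cand


def brc_step(x: np.ndarray, h_prev: np.ndarray, w: CellWeights) -> np.ndarray:
    """One BRC state update.  The Jacobian of ``h_t`` w.r.t. ``h_{t-1}`` is
    diagonal: all temporal connections are from a neuron to itself."""
    x = np.asarray(x)
    h_prev = np.asarray(h_prev)
    return _bistable_update(x, h_prev, w, brc_gates(x, h_prev, w))


def nbrc_step(x: np.ndarray, h_prev: np.ndarray, w: CellWeights) -> np.ndarray:
    """One nBRC state update: BRC update rule with neuromodulated gates.  The
    direct ``h``-to-``h`` path stays elementwise; only the gate paths mix
    neurons."""
    x = np.asarray(x)
    h_prev = np.asarray(h_prev)
    return _bistable_update(x, h_prev, w, nbrc_gates(x, h_prev, w))


def gru_step(x: np.ndarray, h_prev: np.ndarray, w: GRUWeights) -> np.ndarray:
    """Standard GRU update (baseline):

        z = sigmoid(U_z x + W_z h),  r = sigmoid(U_r x + W_r h)
        h_t = z * h + (1 - z) * tanh(U_h x + r * (W_h h))
    """
    x = np.asarray(x)
    h_prev = np.asarray(h_prev)
    _check_shapes(x, h_prev, w)
    z = _sigmoid(x @ w.U_z + h_prev @ w.W_z + w.b_z)
    r = _sigmoid(x @ w.U_r + h_prev @ w.W_r + w.b_r)
    cand = np.tanh(x @ w.U_h + r * (h_prev @ w.W_h) + w.b_h)
    return z * h_prev + (1.0 - z) * cand


def step(kind: str, x: np.ndarray, h_prev: np.ndarray, w: AnyWeights) -> np.ndarray:
    """Dispatch a single state update by cell kind."""
    if kind == "brc":
        return brc_step(x, h_prev, w)
    if kind == "nbrc":
        return nbrc_step(x, h_prev, w)
    if kind == "gru":
        return gru_step(x, h_prev, w)
    raise ValueError(f"unknown cell kind {kind!r}")


def unroll(
    kind: str,
    sequence: Union[np.ndarray, Sequence[np.ndarray]],
    layers: Sequence[AnyWeights],
    h0: Optional[Sequence[np.ndarray]] = None,
    record_gates: bool = False,
) -> Tuple[List[np.ndarray], List[np.ndarray], Optional[GateTrace]]:
    """Run a stack of recurrent layers over a full input sequence.

    Parameters
    ----------
    sequence:
        Array of shape ``(T, ..., input_dim)`` (leading batch dims allowed) or
        a list of per-step input arrays.
    layers:
        One weight object per layer; layer ``k``'s input dim must equal layer
        ``k-1``'s hidden size.
    h0:
        Optional initial states, one per layer; defaults to zeros (the initial
        state is a constant, not trained).
    record_gates:
        If true (BRC/nBRC only), record the gate values of every layer, neuron
        and time step.  Off by default: the trace costs memory.

    Returns
    -------
    (final_states, trajectories, trace):
        ``final_states[k]`` is layer ``k``'s state after the last step;
        ``trajectories[k]`` stacks its states over time, shape
        ``(T, ..., hidden_k)``; ``trace`` is a :class:`GateTrace` or ``None``.
    """
    xs = np.asarray(sequence, dtype=float) if not isinstance(sequence, np.ndarray) else sequence
    if xs.ndim < 2 or xs.shape[0] == 0:
        raise ValueError("sequence must be non-empty with shape (T, ..., input_dim)")
    if len(layers) == 0:
        raise ValueError("need at least one layer")
    if record_gates and kind == "gru":
        raise ValueError("gate recording is defined for BRC/nBRC only")
    dim_in = xs.shape[-1]
    for k, w in enumerate(layers):
        if w.input_dim != dim_in:
            raise DimensionError(
                f"layer {k} expects input dim {w.input_dim}, got {dim_in}"
            )
        dim_in = w.hidden
    T = xs.shape[0]
    batch_shape = xs.shape[1:-1]
    trajectories: List[np.ndarray] = []
    finals: List[np.ndarray] = []
    trace_a: List[np.ndarray] = []
    trace_c: List[np.ndarray] = []
    inp = xs
    for k, w in enumerate(layers):
        h = (
            np.zeros(batch_shape + (w.hidden,), dtype=xs.dtype)
            if h0 is None
            else np.broadcast_to(h0[k], batch_shape + (w.hidden,)).astype(xs.dtype)
        )
        traj = np.empty((T,) + batch_shape + (w.hidden,), dtype=xs.dtype)
        if record_gates:
            ta = np.empty_like(traj)
            tc = np.empty_like(traj)
        for t in range(T):
            if record_gates:
                g = brc_gates(inp[t], h, w) if kind == "brc" else nbrc_gates(inp[t], h, w)
                h = _bistable_update(inp[t], h, w, g)
                ta[t] = g.a
                tc[t] = g.c
            else:
                h = step(kind, inp[t], h, w)
            traj[t] = h
        trajectories.append(traj)
        finals.append(h)
        if record_gates:
            trace_a.append(ta)
            trace_c.append(tc)
        inp = traj
    trace = GateTrace(a=trace_a, c=trace_c) if record_gates else None
    return finals, trajectories, trace


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def init_weights(
    kind: str,
    input_dim: int,
    hidden: int,
    seed: Union[int, np.random.Generator],
    bias: bool = True,
    dtype=np.float64,
) -> AnyWeights:
    """Seeded weight initialisation.

    Input kernels use variance scaling (normal with std ``1/sqrt(input_dim)``);
    full recurrent kernels (nBRC gates, all GRU kernels) are orthogonal; the
    BRC per-neuron recurrent gains are small uniform in ``(-0.1, 0.1)``.
    Biases start at zero, so at initialisation the cell computes the bias-free
    update exactly; ``bias=False`` removes them (they stay frozen at zero).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    std = 1.0 / np.sqrt(input_dim)

    def inp() -> np.ndarray:
        return (rng.standard_normal((input_dim, hidden)) * std).astype(dtype)

    zeros = lambda: np.zeros(hidden, dtype=dtype)
    if kind == "gru":
        return GRUWeights(
            input_dim=input_dim,
            hidden=hidden,
            U_z=inp(), U_r=inp(), U_h=inp(),
            W_z=_orthogonal(rng, hidden).astype(dtype),
            W_r=_orthogonal(rng, hidden).astype(dtype),
            W_h=_orthogonal(rng, hidden).astype(dtype),
            b_z=zeros(), b_r=zeros(), b_h=zeros(),
        )
    if kind == "brc":
        return CellWeights(
            kind="brc", input_dim=input_dim, hidden=hidden,
            U=inp(), U_a=inp(), U_c=inp(),
            b=zeros(), b_a=zeros(), b_c=zeros(),
            w_a=rng.uniform(-0.1, 0.1, hidden).astype(dtype),
            w_c=rng.uniform(-0.1, 0.1, hidden).astype(dtype),
            use_bias=bias,
        )
    if kind == "nbrc":
        return CellWeights(
            kind="nbrc", input_dim=input_dim, hidden=hidden,
            U=inp(), U_a=inp(), U_c=inp(),
            b=zeros(), b_a=zeros(), b_c=zeros(),
            W_a=_orthogonal(rng, hidden).astype(dtype),
            W_c=_orthogonal(rng, hidden).astype(dtype),
            use_bias=bias,
        )
    raise ValueError(f"unknown cell kind {kind!r}")


def save_weights(path, layers: Sequence[AnyWeights]) -> None:
    """Serialise a stack of layers to an NPZ file with named arrays
    (``layer{k}/{field}``)."""
    arrays = {}
    kinds = []
    for k, w in enumerate(layers):
        kinds.append(w.kind)
        for name in w.param_names():
            arrays[f"layer{k}/{name}"] = getattr(w, name)
    arrays["kinds"] = np.array(kinds)
    np.savez(path, **arrays)


def load_weights(path) -> List[AnyWeights]:
    """Load a stack of layers saved by :func:`save_weights`."""
    with np.load(path, allow_pickle=False) as data:
        kinds = [str(k) for k in data["kinds"]]
        layers: List[AnyWeights] = []
        for k, kind in enumerate(kinds):
            get = lambda name: data[f"layer{k}/{name}"]
            if kind == "gru":
                d, h = get("U_z").shape
                layers.append(GRUWeights(
                    input_dim=d, hidden=h,
                    **{n: get(n) for n in
                       ("U_z", "U_r", "U_h", "W_z", "W_r", "W_h", "b_z", "b_r", "b_h")},
                ))
            else:
                d, h = get("U").shape
                kw = {n: get(n) for n in ("U", "U_a", "U_c", "b", "b_a", "b_c")}
                if kind == "brc":
                    kw.update(w_a=get("w_a"), w_c=get("w_c"))
                else:
                    kw.update(W_a=get("W_a"), W_c=get("W_c"))
                layers.append(CellWeights(kind=kind, input_dim=d, hidden=h, **kw))
    return layers
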