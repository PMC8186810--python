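"""Gate-dynamics introspection of trained bistable-cell networks.

A neuron is *bistable* at a given step when its feedback gate exceeds 1
(strictly: at exactly 1 the scalar map is at its pitchfork and still
monostable).  Recording the gates of every layer over a single input sequence
and summarising them — the per-layer fraction of bistable neurons and the
per-layer mean update gate c — exposes how a trained network uses bistability:
the bistable fraction grows while information must be held, and the mean c
dips sharply at the steps where a relevant input arrives, making the network
momentarily highly sensitive to its input.  Those dips are strong enough that
the relevant steps can be read off the summary alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .benchgen import BenchmarkSample
from .cells import GateTrace, unroll
from .training import RecurrentNetwork

__all__ = [
    "GateSummary",
    "record_gates",
    "summarize_gates",
    "export_summary",
    "read_summary",
    "detect_relevant_steps",
]


@dataclass
class GateSummary:
    """Per-layer, per-step gate statistics.

    ``bistable_fraction[k][t]`` is the fraction of layer ``k``'s neurons with
    feedback gate a > 1 at step ``t``; ``mean_c[k][t]`` is the layer's mean
    update gate.  Both are lists of length-``T`` arrays, one per layer.
    """

    bistable_fraction: List[np.ndarray]
    mean_c: List[np.ndarray]

    @property
    def n_layers(self) -> int:
        return len(self.mean_c)

    @property
    def n_steps(self) -> int:
        return self.mean_c[0].shape[0]


def record_gates(net: RecurrentNetwork,
                 sample: Union[BenchmarkSample, np.ndarray]) -> GateTrace:
    """Run one input sequence through the network with gate recording on.

    ``sample`` is a :class:`BenchmarkSample` or a raw ``(T, input_dim)``
    array.  Returns one (a, c) array of shape ``(T, hidden_k)`` per layer.
    Deterministic: re-running yields bit-identical traces.
    """
    if net.kind not in ("brc", "nbrc"):
        raise ValueError("gate recording is defined for BRC/nBRC networks")
    xs = sample.inputs if isinstance(sample, BenchmarkSample) else np.asarray(sample)
    if xs.ndim != 2:
        raise ValueError("expected a single sequence of shape (T, input_dim)")
    _, _, trace = unroll(net.kind, xs.astype(net.W_out.dtype), net.layers,
                         record_gates=True)
    return trace


def summarize_gates(trace: GateTrace) -> GateSummary:
    """Reduce a gate trace to the per-layer bistable fraction (a > 1,
    strictly) and mean update gate."""
    frac = [np.mean(a > 1.0, axis=-1) for a in trace.a]
    mean_c = [np.mean(c, axis=-1) for c in trace.c]
    return GateSummary(bistable_fraction=frac, mean_c=mean_c)


def export_summary(summary: GateSummary, path) -> None:
    """Write a summary as CSV with columns (layer, step, bistable_fraction,
    mean_c)."""
    rows = []
    for k in range(summary.n_layers):
        for t in range(summary.n_steps):
            rows.append({"layer": k, "step": t,
                         "bistable_fraction": float(summary.bistable_fraction[k][t]),
                         "mean_c": float(summary.mean_c[k][t])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summary(path) -> GateSummary:
    """Load a summary written by :func:`export_summary`."""
    df = pd.read_csv(path)
    frac, mean_c = [], []
    for k in sorted(df["layer"].unique()):
        sub = df[df["layer"] == k].sort_values("step")
        frac.append(sub["bistable_fraction"].to_numpy())
        mean_c.append(sub["mean_c"].to_numpy())
    return GateSummary(bistable_fraction=frac, mean_c=mean_c)


def detect_relevant_steps(summary: GateSummary, k: int = 5,
                          layer: Optional[int] = None) -> np.ndarray:
    """Recover candidate relevant-input steps from the update-gate trace
    alone: the ``k`` largest downward excursions of the layer-wise mean c.

    A step's dip score is how far its mean c falls below the average of its
    two neighbours (a local V-shape), summed over layers unless ``layer``
    selects one.  Returns the ``k`` top-scoring steps in ascending order.
    """
    layers = range(summary.n_layers) if layer is None else [layer]
    T = summary.n_steps
    score = np.zeros(T)
    for j in layers:
        c = summary.mean_c[j]
        pad = np.concatenate([[c[0]], c, [c[-1]]])
        score += 0.5 * (pad[:-2] + pad[2:]) - c
    return np.sort(np.argsort(score)[::-1][:k])
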