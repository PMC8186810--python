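"""Training and evaluation of stacked recurrent networks on the benchmarks.

The reference protocol is the one used throughout the benchmark study: two
layers of 128 neurons, Adam with learning rate 1e-3, mini-batches of 100,
50 epochs, metrics averaged over three seeds.  All of these are plain
:class:`TrainConfig` fields, so scaled-down protocols (fewer epochs or
samples, smaller layers) are configured rather than coded.

The readout is a single affine layer applied to the top recurrent layer's
state at the prediction step(s) only: the final step for copy-style
regression and classification, the last five steps for the denoising
sequence-to-sequence output, or a per-sample marker step for variable-length
sequences.  Classification uses softmax cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from . import bptt
from .benchgen import BenchmarkSet, denoise_loss
from .cells import AnyWeights, init_weights, load_weights, save_weights
from .bptt import Adam, backward_layer, forward_layer

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "RecurrentNetwork",
    "TrainingDiverged",
    "build_network",
    "train",
    "run_experiment",
    "evaluate_regression",
    "evaluate_classification",
    "save_network",
    "load_network",
]

TASKS = ("regression-last-step", "regression-last-5", "classification-last-step")


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    """Protocol hyper-parameters (defaults = the reference protocol)."""

    cell: str = "nbrc"
    hidden: Tuple[int, ...] = (128, 128)
    lr: float = 1e-3
    batch_size: int = 100
    epochs: int = 50
    seeds: Tuple[int, ...] = (0, 1, 2)
    task: str = "regression-last-step"
    clip_norm: Optional[float] = None  # off by default: the protocol uses none
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.epochs < 1 or self.batch_size < 1 or not self.hidden:
            raise ValueError("epochs, batch_size and hidden must be positive")
        if len(self.seeds) < 1:
            raise ValueError("need at least one seed")


@dataclass
class MetricsReport:
    """Per-seed final metrics, their mean and standard deviation (over
    seeds), and the per-epoch training curves."""

    task: str
    per_seed: Dict[int, Dict[str, float]]
    mean: Dict[str, float]
    std: Dict[str, float]
    curves: pd.DataFrame  # columns: seed, epoch, split, metric, value

    def to_json(self) -> str:
        payload = {
            "task": self.task,
            "per_seed": {str(k): v for k, v in self.per_seed.items()},
            "mean": self.mean,
            "std": self.std,
        }
        return json.dumps(payload, indent=2)


class RecurrentNetwork:
    """A stack of recurrent layers plus an affine readout."""

    def __init__(self, kind: str, layers: List[AnyWeights],
                 W_out: np.ndarray, b_out: np.ndarray):
        self.kind = kind
        self.layers = layers
        self.W_out = W_out
        self.b_out = b_out

    @property
    def output_dim(self) -> int:
        return self.W_out.shape[1]

    def param_list(self) -> List[np.ndarray]:
        params: List[np.ndarray] = []
        for w in self.layers:
            params.extend(w.param_list())
        params.extend([self.W_out, self.b_out])
        return params

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.param_list())

    def forward(self, xs: np.ndarray) -> List[bptt.LayerCache]:
        """Time-major forward pass through the whole stack."""
        caches = []
        inp = xs
        for w in self.layers:
            cache = forward_layer(w, inp)
            caches.append(cache)
            inp = cache.hs[1:]
        return caches

    def outputs_at(self, caches: List[bptt.LayerCache],
                   steps: np.ndarray) -> np.ndarray:
        """Readout at the given shared step indices: shape
        ``(len(steps), B, output_dim)``."""
        hs = caches[-1].hs[1:]
        return hs[np.asarray(steps)] @ self.W_out + self.b_out


def build_network(cfg: TrainConfig, input_dim: int, output_dim: int,
                  seed: int) -> RecurrentNetwork:
    """Seeded network construction: stacked cells of ``cfg.hidden`` sizes and
    a variance-scaled affine readout."""
    dtype = np.dtype(cfg.dtype)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(cfg.hidden) + 1)]
    layers: List[AnyWeights] = []
    d = input_dim
    for h, rng in zip(cfg.hidden, rngs[:-1]):
        layers.append(init_weights(cfg.cell, d, h, rng, dtype=dtype))
        d = h
    rng = rngs[-1]
    W_out = (rng.standard_normal((d, output_dim)) / np.sqrt(d)).astype(dtype)
    b_out = np.zeros(output_dim, dtype=dtype)
    return RecurrentNetwork(cfg.cell, layers, W_out, b_out)


def _output_steps(task: str, T: int) -> np.ndarray:
    if task == "regression-last-5":
        return np.arange(T - 5, T)
    return np.array([T - 1])


def _loss_and_grad_out(task: str, outs: np.ndarray, targets: np.ndarray
                       ) -> Tuple[float, np.ndarray]:
    """Loss at the readout and its gradient w.r.t. the readout outputs."""
    if task == "regression-last-step":
        pred = outs[0, :, 0]
        diff = pred - targets
        loss = float(np.mean(diff**2))
        g = np.zeros_like(outs)
        g[0, :, 0] = 2.0 * diff / diff.shape[0]
        return loss, g
    if task == "regression-last-5":
        pred = outs[:, :, 0].T  # (B, 5)
        diff = pred - targets
        loss = float(np.mean(diff**2))
        g = np.zeros_like(outs)
        g[:, :, 0] = (2.0 * diff / diff.size).T
        return loss, g
    # classification: softmax cross-entropy at the (single) prediction step
    logits = outs[0]
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    B = logits.shape[0]
    labels = targets.astype(int)
    loss = float(-np.mean(np.log(probs[np.arange(B), labels] + 1e-30)))
    g = np.zeros_like(outs)
    gout = probs
    gout[np.arange(B), labels] -= 1.0
    g[0] = gout / B
    return loss, g


def _train_batch(net: RecurrentNetwork, opt: Adam, xs: np.ndarray,
                 targets: np.ndarray, task: str,
                 clip_norm: Optional[float]) -> float:
    T = xs.shape[0]
    steps = _output_steps(task, T)
    caches = net.forward(xs)
    hs_top = caches[-1].hs[1:]
    outs = hs_top[steps] @ net.W_out + net.b_out
    loss, g_out = _loss_and_grad_out(task, outs, targets)
    if not np.isfinite(loss):
        raise TrainingDiverged(f"non-finite loss {loss!r}")
    # readout grads
    sel = hs_top[steps]  # (k, B, H)
    k, B, H = sel.shape
    gW_out = sel.reshape(k * B, H).T @ g_out.reshape(k * B, -1)
    gb_out = g_out.sum((0, 1))
    ghs = np.zeros_like(hs_top)
    np.add.at(ghs, steps, g_out @ net.W_out.T)
    # backprop down the stack
    grad_lists: List[List[np.ndarray]] = []
    for w, cache in zip(reversed(net.layers), reversed(caches)):
        grads, gxs = backward_layer(w, cache, ghs)
        grad_lists.append([grads[n] for n in w.param_names()])
        ghs = gxs
    flat: List[np.ndarray] = []
    for gl in reversed(grad_lists):
        flat.extend(gl)
    flat.extend([gW_out, gb_out])
    if clip_norm is not None:
        norm = float(np.sqrt(sum(float((g * g).sum()) for g in flat)))
        if norm > clip_norm:
            scale = clip_norm / norm
            flat = [g * scale for g in flat]
    opt.step(flat)
    return loss


def _predict(net: RecurrentNetwork, inputs: np.ndarray, task: str,
             batch: int = 500, steps_per_sample: Optional[np.ndarray] = None
             ) -> np.ndarray:
    """Chunked forward-only predictions.  ``inputs`` is batch-major
    ``(n, T, d)``; returns ``(n,)``, ``(n, 5)`` or ``(n, classes)``."""
    n, T, _ = inputs.shape
    dtype = net.W_out.dtype
    outs = []
    for i in range(0, n, batch):
        xs = np.ascontiguousarray(inputs[i:i + batch].swapaxes(0, 1), dtype=dtype)
        caches = net.forward(xs)
        hs_top = caches[-1].hs[1:]
        if steps_per_sample is not None:
            idx = steps_per_sample[i:i + batch]
            sel = hs_top[idx, np.arange(xs.shape[1])]  # (B, H)
            o = sel @ net.W_out + net.b_out
        else:
            steps = _output_steps(task, T)
            o = hs_top[steps] @ net.W_out + net.b_out  # (k, B, out)
            if task == "regression-last-step":
                o = o[0, :, 0]
            elif task == "regression-last-5":
                o = o[:, :, 0].T
            else:
                o = o[0]
        outs.append(o)
    return np.concatenate(outs, axis=0)


def evaluate_regression(net: RecurrentNetwork, dataset: BenchmarkSet,
                        task: Optional[str] = None, batch: int = 500) -> float:
    """Mean squared error over a test set.  For the denoising task this is
    the five-output error (outputs at the last five steps only)."""
    task = task or ("regression-last-5" if dataset.kind == "denoise"
                    else "regression-last-step")
    preds = _predict(net, dataset.inputs, task, batch=batch)
    if task == "regression-last-5":
        return denoise_loss(preds, dataset.targets)
    return float(np.mean((preds - dataset.targets) ** 2))


def evaluate_classification(net: RecurrentNetwork, dataset: BenchmarkSet,
                            batch: int = 500) -> Tuple[float, float]:
    """Accuracy and macro-averaged F1 (unweighted mean of per-class F1) of
    argmax predictions at the final step, or at each sample's own marker step
    for variable-length sequences."""
    steps = None
    if dataset.lengths is not None:
        steps = dataset.lengths.astype(int) - 1
    logits = _predict(net, dataset.inputs, "classification-last-step",
                      batch=batch, steps_per_sample=steps)
    pred = logits.argmax(axis=1)
    y = dataset.targets.astype(int)
    acc = float(np.mean(pred == y))
    f1 = float(f1_score(y, pred, average="macro", zero_division=0))
    return acc, f1


def train(net: RecurrentNetwork, train_set: BenchmarkSet,
          test_set: Optional[BenchmarkSet], cfg: TrainConfig, seed: int,
          log_every_epoch: bool = True) -> pd.DataFrame:
    """Train one network in place; returns per-epoch curves (long format:
    seed, epoch, split, metric, value).

    Mini-batch order is reshuffled every epoch from a generator derived from
    ``seed``, so a (config, seed) pair fully determines the run.
    """
    dtype = np.dtype(cfg.dtype)
    inputs = train_set.inputs.astype(dtype, copy=False)
    targets = train_set.targets
    n = inputs.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB15)))
    opt = Adam(net.param_list(), lr=cfg.lr)
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xs = np.ascontiguousarray(inputs[idx].swapaxes(0, 1))
            loss = _train_batch(net, opt, xs, targets[idx], cfg.task,
                                cfg.clip_norm)
            losses.append(loss)
        rows.append({"seed": seed, "epoch": epoch, "split": "train",
                     "metric": "loss", "value": float(np.mean(losses))})
        if log_every_epoch and test_set is not None:
            if cfg.task.startswith("regression"):
                mse = evaluate_regression(net, test_set, cfg.task)
                rows.append({"seed": seed, "epoch": epoch, "split": "test",
                             "metric": "mse", "value": mse})
            else:
                acc, f1 = evaluate_classification(net, test_set)
                rows.append({"seed": seed, "epoch": epoch, "split": "test",
                             "metric": "accuracy", "value": acc})
                rows.append({"seed": seed, "epoch": epoch, "split": "test",
                             "metric": "macro_f1", "value": f1})
    return pd.DataFrame(rows, columns=["seed", "epoch", "split", "metric", "value"])


def run_experiment(cfg: TrainConfig, train_set: BenchmarkSet,
                   test_set: BenchmarkSet,
                   log_every_epoch: bool = False) -> MetricsReport:
    """Full protocol: one training run per seed, metrics aggregated as
    mean +/- standard deviation over seeds."""
    input_dim = train_set.inputs.shape[-1]
    if cfg.task == "classification-last-step":
        output_dim = int(train_set.targets.max()) + 1
    else:
        output_dim = 1
    per_seed: Dict[int, Dict[str, float]] = {}
    curve_frames = []
    for seed in cfg.seeds:
        net = build_network(cfg, input_dim, output_dim, seed)
        curves = train(net, train_set, test_set, cfg, seed,
                       log_every_epoch=log_every_epoch)
        curve_frames.append(curves)
        if cfg.task.startswith("regression"):
            per_seed[seed] = {"mse": evaluate_regression(net, test_set, cfg.task)}
        else:
            acc, f1 = evaluate_classification(net, test_set)
            per_seed[seed] = {"accuracy": acc, "macro_f1": f1}
    metrics = sorted(next(iter(per_seed.values())).keys())
    mean = {m: float(np.mean([per_seed[s][m] for s in cfg.seeds])) for m in metrics}
    std = {m: float(np.std([per_seed[s][m] for s in cfg.seeds])) for m in metrics}
    return MetricsReport(task=cfg.task, per_seed=per_seed, mean=mean, std=std,
                         curves=pd.concat(curve_frames, ignore_index=True))


def save_network(net: RecurrentNetwork, path) -> None:
    """Persist layers + readout as NPZ (named arrays, plus the cell kind)."""
    arrays = {"kinds": np.array([w.kind for w in net.layers]),
              "W_out": net.W_out, "b_out": net.b_out}
    for k, w in enumerate(net.layers):
        for name in w.param_names():
            arrays[f"layer{k}/{name}"] = getattr(w, name)
    np.savez(path, **arrays)


def load_network(path) -> RecurrentNetwork:
    from .cells import CellWeights, GRUWeights

    with np.load(path, allow_pickle=False) as data:
        kinds = [str(k) for k in data["kinds"]]
        layers: List[AnyWeights] = []
        for k, kind in enumerate(kinds):
            get = lambda name: data[f"layer{k}/{name}"]
            if kind == "gru":
                d, h = get("U_z").shape
                layers.append(GRUWeights(
                    input_dim=d, hidden=h,
                    **{n: get(n) for n in ("U_z", "U_r", "U_h", "W_z", "W_r",
                                           "W_h", "b_z", "b_r", "b_h")}))
            else:
                d, h = get("U").shape
                kw = {n: get(n) for n in ("U", "U_a", "U_c", "b", "b_a", "b_c")}
                if kind == "brc":
                    kw.update(w_a=get("w_a"), w_c=get("w_c"))
                else:
                    kw.update(W_a=get("W_a"), W_c=get("W_c"))
                layers.append(CellWeights(kind=kind, input_dim=d, hidden=h, **kw))
        return RecurrentNetwork(kinds[0], layers, data["W_out"], data["b_out"])
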