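"""Synthetic long-memory benchmarks and sequential-MNIST transforms.

Two fully synthetic benchmarks probe long-term memory:

* **copy-first-input** — a 1-D Gaussian white-noise series ``x_0 .. x_T``
  (length ``T + 1``); after receiving ``x_T`` the network must output ``x_0``.
  Guessing the mean (0) gives an expected squared error of 1, the variance of
  the standard normal, so 1 is the chance level.
* **denoising** — a 2-D series of the same length.  Channel 0 is a marker
  stream: +1 at five relevant steps ``t_1 < .. < t_5``, 0 at step ``T - 4``
  (the cue that predictions start counting), and -1 elsewhere.  Channel 1 is
  Gaussian data, zeroed over the last five steps.  The targets are the five
  data values at the marked steps, to be emitted in order at steps
  ``T - 4 .. T``.  The forgetting period ``N`` forces all relevant steps into
  the first ``T - N`` steps (``t_i < T - N``), so the network must hold the
  values across at least ``N`` irrelevant steps.

The sequential-MNIST transforms (fixed pixel permutation, line-by-line
feeding with black-line padding, end-of-sequence marker line) are provided as
pure functions plus an IDX reader; the image benchmarks themselves require an
external MNIST download.

All generators are pure functions of their arguments and a seed: identical
calls return bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "BenchmarkSample",
    "BenchmarkSet",
    "gen_copy",
    "gen_denoise",
    "denoise_loss",
    "make_permutation",
    "permute_pixels",
    "to_line_sequence",
    "sample_variable_padding",
    "write_dataset",
    "read_dataset",
    "read_idx",
    "DatasetFormatError",
]

MARKER_LINE_VALUE = 2.0  # above the white-pixel value 1.0, so never in an image


class DatasetFormatError(ValueError):
    """Raised when a persisted dataset file is malformed."""


@dataclass
class BenchmarkSample:
    """One sequence plus its target(s)."""

    inputs: np.ndarray  # (T_steps, dim)
    target: np.ndarray  # () scalar, (5,) denoise, or () int class label
    meta: Dict = field(default_factory=dict)


@dataclass
class BenchmarkSet:
    """A benchmark dataset held as dense arrays.

    ``inputs`` has shape ``(n, T_steps, dim)``; ``targets`` ``(n,)`` or
    ``(n, 5)``.  ``lengths`` (optional) gives true sequence lengths for
    variable-length data padded with zeros.  Iterating or indexing yields
    :class:`BenchmarkSample` views.
    """

    kind: str
    inputs: np.ndarray
    targets: np.ndarray
    meta: Dict = field(default_factory=dict)
    lengths: Optional[np.ndarray] = None
    relevant_steps: Optional[np.ndarray] = None  # (n, 5) t_i for denoising

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def __getitem__(self, i: int) -> BenchmarkSample:
        meta = dict(self.meta)
        if self.relevant_steps is not None:
            meta["relevant_steps"] = self.relevant_steps[i]
        if self.lengths is not None:
            meta["length"] = int(self.lengths[i])
        return BenchmarkSample(inputs=self.inputs[i], target=self.targets[i], meta=meta)

    def __iter__(self):
        return (self[i] for i in range(len(self)))


def gen_copy(T: int, n: int, seed: int, dtype=np.float64) -> BenchmarkSet:
    """Copy-first-input benchmark: ``n`` i.i.d. standard-normal series with
    steps indexed ``0 .. T`` (length ``T + 1``); the target is ``x_0``."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, T + 1, 1)).astype(dtype)
    return BenchmarkSet(kind="copy", inputs=x, targets=x[:, 0, 0].copy(),
                        meta={"T": T})


def gen_denoise(T: int, N: int, n: int, seed: int, dtype=np.float64) -> BenchmarkSet:
    """Denoising benchmark with forgetting period ``N``.

    Five distinct relevant steps are drawn without replacement from
    ``{0, .., T - N - 1}`` and sorted, so the targets are paired with the
    output steps in temporal order.  ``N`` must lie in ``{5, .., T - 4}``.
    """
    if T < 10:
        raise ValueError("T must be >= 10")
    if not 5 <= N <= T - 4:
        raise ValueError(f"N must lie in [5, T-4] = [5, {T - 4}], got {N}")
    rng = np.random.default_rng(seed)
    steps = T + 1  # indices 0 .. T, as for the copy benchmark
    x = np.empty((n, steps, 2), dtype=dtype)
    x[:, :, 0] = -1.0
    x[:, T - 4, 0] = 0.0
    data = rng.standard_normal((n, steps)).astype(dtype)
    data[:, T - 4:] = 0.0
    x[:, :, 1] = data
    # five distinct marker steps per sample, all strictly below T - N
    t_rel = np.empty((n, 5), dtype=np.int64)
    for i in range(n):
        t_rel[i] = np.sort(rng.choice(T - N, size=5, replace=False))
    x[np.arange(n)[:, None], t_rel, 0] = 1.0
    targets = data[np.arange(n)[:, None], t_rel].copy()
    return BenchmarkSet(kind="denoise", inputs=x, targets=targets,
                        meta={"T": T, "N": N}, relevant_steps=t_rel)


def denoise_loss(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Error of the denoising benchmark: squared error of the five outputs at
    steps ``T-4 .. T`` against the five remembered values, averaged over the
    five outputs (and over samples if batched)."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape or outputs.shape[-1] != 5:
        raise ValueError("outputs and targets must both have trailing dim 5")
    return float(np.mean((outputs - targets) ** 2))


def make_permutation(seed: int, n: int = 784) -> np.ndarray:
    """The fixed pixel permutation shared by a whole dataset."""
    return np.random.default_rng(seed).permutation(n)


def permute_pixels(image: np.ndarray, seed: int) -> np.ndarray:
    """Apply the seed-determined fixed permutation to an image's pixels
    (bijective; the same seed always yields the same shuffle)."""
    img = np.asarray(image)
    flat = img.reshape(-1)
    return flat[make_permutation(seed, flat.size)].reshape(img.shape)


def to_line_sequence(
    image: np.ndarray,
    n_black: int = 0,
    marker: Optional[float] = None,
) -> np.ndarray:
    """Feed an image line by line: rows of the (28 x 28) image, then
    ``n_black`` all-zero lines as a forgetting period, then optionally one
    marker line whose entries all equal ``marker`` (use a value above 1.0,
    the white pixel, so the line cannot occur in a real image)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D (rows x columns)")
    if n_black < 0:
        raise ValueError("n_black must be >= 0")
    rows, cols = img.shape
    extra = n_black + (1 if marker is not None else 0)
    seq = np.zeros((rows + extra, cols), dtype=float)
    seq[:rows] = img
    if marker is not None:
        seq[-1] = marker
    return seq


def sample_variable_padding(X: int, seed: int, n: int = 1) -> np.ndarray:
    """Draw the per-sample number of black padding lines uniformly from
    ``{0, .., X}``."""
    if X < 0:
        raise ValueError("X must be >= 0")
    out = np.random.default_rng(seed).integers(0, X + 1, size=n)
    return out


def write_dataset(dataset: BenchmarkSet, path) -> None:
    """Persist a dataset as NPZ with named arrays; variable-length data keep a
    ``lengths`` vector alongside the zero-padded ``inputs``."""
    arrays = {
        "kind": np.array(dataset.kind),
        "inputs": dataset.inputs,
        "targets": dataset.targets,
        "meta_keys": np.array(list(dataset.meta.keys())),
        "meta_vals": np.array([float(v) for v in dataset.meta.values()]),
    }
    if dataset.lengths is not None:
        arrays["lengths"] = dataset.lengths
    if dataset.relevant_steps is not None:
        arrays["relevant_steps"] = dataset.relevant_steps
    np.savez_compressed(path, **arrays)


def read_dataset(path) -> BenchmarkSet:
    """Load a dataset written by :func:`write_dataset`."""
    try:
        with np.load(path, allow_pickle=False) as data:
            keys = set(data.files)
            if not {"kind", "inputs", "targets"} <= keys:
                raise DatasetFormatError(
                    f"{path}: missing required arrays (found {sorted(keys)})"
                )
            meta_keys = [str(k) for k in data["meta_keys"]]
            meta_vals = data["meta_vals"]
            meta = {k: (int(v) if float(v).is_integer() else float(v))
                    for k, v in zip(meta_keys, meta_vals)}
            return BenchmarkSet(
                kind=str(data["kind"]),
                inputs=data["inputs"],
                targets=data["targets"],
                meta=meta,
                lengths=data["lengths"] if "lengths" in keys else None,
                relevant_steps=(data["relevant_steps"]
                                if "relevant_steps" in keys else None),
            )
    except (OSError, ValueError, KeyError) as exc:
        if isinstance(exc, DatasetFormatError):
            raise
        raise DatasetFormatError(f"{path}: not a valid dataset file ({exc})") from exc


def read_idx(path) -> np.ndarray:
    """Read an IDX file (the standard MNIST container): big-endian magic
    ``0 0 dtype ndim``, then the dimension sizes as uint32, then raw data."""
    dtype_map = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.int16,
                 0x0C: np.int32, 0x0D: np.float32, 0x0E: np.float64}
    with open(path, "rb") as fh:
        magic = np.frombuffer(fh.read(4), dtype=">u1")
        if magic.size != 4 or magic[0] != 0 or magic[1] != 0:
            raise DatasetFormatError(f"{path}: bad IDX magic")
        code, ndim = int(magic[2]), int(magic[3])
        if code not in dtype_map:
            raise DatasetFormatError(f"{path}: unknown IDX dtype 0x{code:02x}")
        shape = tuple(int(s) for s in np.frombuffer(fh.read(4 * ndim), dtype=">u4"))
        data = np.frombuffer(fh.read(), dtype=np.dtype(dtype_map[code]).newbyteorder(">"))
    if data.size != int(np.prod(shape)):
        raise DatasetFormatError(f"{path}: size mismatch against header {shape}")
    return data.reshape(shape)
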