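"""Fixed-point and bifurcation analysis of the scalar bistable-cell map.

A single neuron with frozen gates evolves by the one-dimensional map

    h_t = F(h_{t-1}) = c * h_{t-1} + (1 - c) * tanh(u + a * h_{t-1})

with update gate ``c`` in [0, 1], feedback gain ``a >= 0`` and input drive
``u`` (the scalar ``U x_t``).  For ``u = 0`` the map undergoes a supercritical
pitchfork bifurcation at ``a = 1``: below it the origin is the unique stable
fixed point, above it the origin loses stability and two symmetric stable
fixed points ``+/- h1`` appear.  A fixed point ``h*`` is stable when
``F'(h*)`` lies in [0, 1), singular when ``F'(h*) = 1`` and unstable when
``F'(h*) > 1`` (``F'`` is nonnegative for ``a >= 0``).

The module also exposes the current-voltage relationship
``I = v - alpha * tanh(v)`` of the underlying neuronal feedback picture: a
region of negative slope (``alpha > 1``) is the circuit-level signature of
bistability, mirrored by the feedback gate exceeding 1 in the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ScalarMapParams",
    "FixedPoint",
    "FixedPointSet",
    "BifurcationDiagram",
    "PitchforkReport",
    "map_rhs",
    "map_derivative",
    "find_fixed_points",
    "bifurcation_diagram",
    "pitchfork_conditions",
    "iv_curve",
    "step_response",
]

SINGULAR_TOL = 1e-9  # |F'(h*) - 1| below this is labelled "singular"


@dataclass(frozen=True)
class ScalarMapParams:
    """Parameters of the scalar map: feedback gain ``a >= 0``, update gate
    ``c`` in [0, 1], input drive ``u``."""

    a: float
    c: float
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("feedback gain a must be >= 0")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("update gate c must lie in [0, 1]")


@dataclass(frozen=True)
class FixedPoint:
    h: float
    stability: str  # "stable" | "unstable" | "singular"
    derivative: float


@dataclass
class FixedPointSet:
    """Fixed points of the scalar map, sorted by location."""

    points: List[FixedPoint]
    params: ScalarMapParams

    @property
    def stable(self) -> List[FixedPoint]:
        return [p for p in self.points if p.stability == "stable"]

    @property
    def unstable(self) -> List[FixedPoint]:
        return [p for p in self.points if p.stability == "unstable"]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BifurcationDiagram:
    """Fixed-point branches against the feedback gain at fixed ``c`` and
    ``u``.  ``branches[i]`` lists (h*, stability) for ``a_grid[i]``."""

    a_grid: np.ndarray
    branches: List[List[Tuple[float, str]]]
    critical_a: Optional[float]
    c: float
    u: float

    def to_frame(self):
        """Long-format table (a, h, stability, derivative-free)."""
        import pandas as pd

        rows = [
            {"a": float(a), "h": h, "stability": s}
            for a, pts in zip(self.a_grid, self.branches)
            for h, s in pts
        ]
        return pd.DataFrame(rows, columns=["a", "h", "stability"])


def map_rhs(h: Union[float, np.ndarray], p: ScalarMapParams) -> Union[float, np.ndarray]:
    """Right-hand side ``F(h) = c h + (1 - c) tanh(u + a h)``."""
    return p.c * h + (1.0 - p.c) * np.tanh(p.u + p.a * h)


def map_derivative(h: Union[float, np.ndarray], p: ScalarMapParams) -> Union[float, np.ndarray]:
    """``F'(h) = c + (1 - c) a (1 - tanh^2(u + a h))``; at the origin with
    ``u = 0`` this is ``c + (1 - c) a``, the linearised gain that crosses 1 at
    the pitchfork."""
    t = np.tanh(p.u + p.a * h)
    return p.c + (1.0 - p.c) * p.a * (1.0 - t * t)


def _classify(deriv: float, singular_tol: float = SINGULAR_TOL) -> str:
    if abs(deriv - 1.0) < singular_tol:
        return "singular"
    return "stable" if deriv < 1.0 else "unstable"


def find_fixed_points(
    p: ScalarMapParams,
    grid_n: int = 2001,
    tol: float = 1e-12,
    singular_tol: float = SINGULAR_TOL,
) -> FixedPointSet:
    """Locate all fixed points of the map by a sign-change scan of
    ``G(h) = h - F(h)`` on ``[-1 - |u|, 1 + |u|]`` refined by root bracketing.

    ``F`` maps the real line into ``(-(1+|u|), 1+|u|)`` (convex combination of
    ``h`` and a tanh value), so every fixed point lies inside the scan
    interval.  Each root is labelled by the linearised gain ``F'(h*)``.
    """
    if grid_n < 100:
        raise ValueError("grid_n must be >= 100 to resolve nearby roots")
    lo, hi = -1.0 - abs(p.u), 1.0 + abs(p.u)
    grid = np.linspace(lo, hi, grid_n)
    g = grid - map_rhs(grid, p)
    roots: List[float] = []

    def add(r: float) -> None:
        if not any(abs(r - r0) < 1e-8 for r0 in roots):
            roots.append(r)

    exact = np.flatnonzero(np.abs(g) < tol)
    for i in exact:
        add(float(grid[i]))
    sign = np.sign(g)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        r = brentq(lambda h: h - map_rhs(h, p), grid[i], grid[i + 1],
                   xtol=tol, rtol=8.9e-16)
        add(float(r))
    roots.sort()
    pts = [
        FixedPoint(h=r, derivative=float(map_derivative(r, p)),
                   stability=_classify(float(map_derivative(r, p)), singular_tol))
        for r in roots
    ]
    return FixedPointSet(points=pts, params=p)


def _n_stable(a: float, c: float, u: float, grid_n: int) -> int:
    return len(find_fixed_points(ScalarMapParams(a=a, c=c, u=u), grid_n=grid_n).stable)


def bifurcation_diagram(
    c: float,
    u: float = 0.0,
    a_min: float = 0.0,
    a_max: float = 2.0,
    steps: int = 201,
    grid_n: int = 2001,
    refine_tol: float = 1e-6,
) -> BifurcationDiagram:
    """Sweep the feedback gain and collect fixed-point branches.

    The critical gain is detected as the first grid transition in the number
    of stable fixed points and refined by bisection on that count to
    ``refine_tol``.  For ``u = 0`` and any ``c`` in [0, 1) this lands on the
    pitchfork at ``a = 1``.
    """
    a_grid = np.linspace(a_min, a_max, steps)
    branches = []
    counts = []
    for a in a_grid:
        fps = find_fixed_points(ScalarMapParams(a=float(a), c=c, u=u), grid_n=grid_n)
        branches.append([(pt.h, pt.stability) for pt in fps.points])
        counts.append(len(fps.stable))
    critical = None
    for i in range(1, len(counts)):
        if counts[i] != counts[i - 1]:
            lo, hi = float(a_grid[i - 1]), float(a_grid[i])
            n_lo = counts[i - 1]
            while hi - lo > refine_tol:
                mid = 0.5 * (lo + hi)
                if _n_stable(mid, c, u, grid_n) == n_lo:
                    lo = mid
                else:
                    hi = mid
            critical = 0.5 * (lo + hi)
            break
    return BifurcationDiagram(a_grid=a_grid, branches=branches,
                              critical_a=critical, c=c, u=u)


@dataclass
class PitchforkReport:
    """Values of the six pitchfork conditions for ``G(h) = h - F(h)`` at the
    origin equilibrium and critical gain ``a = 1`` (input drive 0).

    The four zero conditions (``G``, ``dG/dh``, ``d2G/dh2``, ``dG/da``) must
    vanish; the cubic term ``d3G/dh3 = 2(1-c)`` must be positive and the mixed
    term ``d2G/(dh da) = c - 1`` negative — together the signature of a
    supercritical pitchfork.
    """

    c: float
    G: float
    dG_dh: float
    d2G_dh2: float
    dG_da: float
    d3G_dh3: float
    d2G_dhda: float

    @property
    def zero_conditions(self) -> Tuple[float, float, float, float]:
        return (self.G, self.dG_dh, self.d2G_dh2, self.dG_da)

    @property
    def is_supercritical_pitchfork(self) -> bool:
        return (
            all(abs(v) < 1e-12 for v in self.zero_conditions)
            and self.d3G_dh3 > 0
            and self.d2G_dhda < 0
        )


def pitchfork_conditions(c: float) -> PitchforkReport:
    """Evaluate the pitchfork conditions analytically at ``(h, a) = (0, 1)``.

    With ``t = tanh(a h)`` and ``G(h) = h - c h - (1 - c) tanh(a h)``:

        G               = (1-c) (h - t)                  -> 0
        dG/dh           = (1-c) (1 - a (1 - t^2))        -> (1-c)(1-a) = 0
        d2G/dh2         = (1-c) 2 a^2 t (1 - t^2)        -> 0
        dG/da           = -(1-c) h (1 - t^2)             -> 0
        d3G/dh3         = (1-c)(2a^3 (1-t^2)^2 + 4a^3 t^2 (t^2-1))|_{t=0}
                        = 2 (1-c) > 0
        d2G/(dh da)     = (1-c)(-(1-t^2) + 2 a h t (1 - t^2))|_{h=0}
                        = c - 1 < 0
    """
    if not 0.0 <= c < 1.0:
        raise ValueError("c must lie in [0, 1) for a nondegenerate pitchfork")
    a_pf, h0 = 1.0, 0.0
    t = np.tanh(a_pf * h0)  # = 0
    one_c = 1.0 - c
    return PitchforkReport(
        c=c,
        G=one_c * (h0 - t),
        dG_dh=one_c * (1.0 - a_pf * (1.0 - t * t)),
        d2G_dh2=one_c * 2.0 * a_pf**2 * t * (1.0 - t * t),
        dG_da=-one_c * h0 * (1.0 - t * t),
        d3G_dh3=one_c * (2.0 * a_pf**3 * (1.0 - t * t) ** 2
                         + 4.0 * a_pf**3 * t * t * (t * t - 1.0)),
        d2G_dhda=one_c * (-(1.0 - t * t) + 2.0 * a_pf * h0 * t * (1.0 - t * t)),
    )


def iv_curve(v_grid: np.ndarray, alpha: float) -> np.ndarray:
    """Intrinsic current ``I = v - alpha * tanh(v)`` of the neuronal feedback
    model.  Monotone increasing (one zero) for ``alpha`` in (0, 1]; for
    ``alpha > 1`` a region of negative slope around 0 yields three zeros —
    two stable voltages separated by an unstable one."""
    v = np.asarray(v_grid, dtype=float)
    return v - alpha * np.tanh(v)


def step_response(
    a: Union[float, Sequence[float]],
    c: Union[float, Sequence[float]],
    inputs: Sequence[float],
    h0: float = 0.0,
) -> np.ndarray:
    """Iterate the scalar map under a piecewise input schedule.

    ``a`` and ``c`` may be scalars or per-step sequences (broadcast against
    ``inputs``).  Returns the state trajectory, one entry per input step.  A
    pulse followed by zero drive latches to a nonzero branch when ``a > 1``
    and relaxes to 0 when ``a < 1``.
    """
    u = np.asarray(inputs, dtype=float)
    T = u.shape[0]
    a_seq = np.broadcast_to(np.asarray(a, dtype=float), (T,))
    c_seq = np.broadcast_to(np.asarray(c, dtype=float), (T,))
    h = float(h0)
    traj = np.empty(T)
    for t in range(T):
        h = c_seq[t] * h + (1.0 - c_seq[t]) * np.tanh(u[t] + a_seq[t] * h)
        traj[t] = h
    return traj
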