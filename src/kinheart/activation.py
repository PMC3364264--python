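"""Activation model: time-contraction curves, phase-shift delays, and the
per-region anisotropic contraction matrix.

The contraction state of a region at time t is a scalar c(t) in [0, 1]
read from a periodic piecewise-linear time-contraction curve, optionally
phase-shifted per region to emulate excitation propagation.  The scaling
along the fiber is s_f = 1 - A_mc * c(t), where A_mc in [0, 1) is the
maximum contraction rate (A_mc = 0.2 means 20% shortening at c = 1, i.e.
a fiber-direction scale of 0.8).  The full contraction matrix scales by
s_f along the fiber and by 1/sqrt(s_f) in both transverse directions, so
each locally scaled region keeps its rest volume (det = 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .mesh import MeshError, TetMesh

__all__ = [
    "ContractionCurve",
    "ContractionSchedule",
    "ContractionMatrix",
    "TRAPEZOID_KNOTS",
    "eval_curve",
    "fiber_scale",
    "build_contraction_matrix",
    "contraction_matrices",
    "build_phase_shift_field",
]

#: ramp up 0.25-0.5 of the cycle, full activation 0.5-0.75, ramp down to 1.
TRAPEZOID_KNOTS = ((0.0, 0.0), (0.25, 0.0), (0.5, 1.0), (0.75, 1.0), (1.0, 0.0))


@dataclass
class ContractionCurve:
    """Periodic piecewise-linear contraction profile.

    ``knots`` are (phase, c) pairs with phases strictly increasing in
    [0, 1] and c in [0, 1]; evaluation wraps modulo the cycle.
    """

    knots: tuple = TRAPEZOID_KNOTS

    def __post_init__(self):
        k = np.asarray(self.knots, float)
        if k.ndim != 2 or k.shape[1] != 2 or len(k) == 0:
            raise ValueError("knots must be a nonempty sequence of (phase, c)")
        if (np.diff(k[:, 0]) <= 0).any():
            raise ValueError("knot phases must be strictly increasing")
        if k[:, 0].min() < 0 or k[:, 0].max() > 1:
            raise ValueError("knot phases must lie in [0, 1]")
        if k[:, 1].min() < 0 or k[:, 1].max() > 1:
            raise ValueError("contraction values must lie in [0, 1]")
        self._phases = k[:, 0]
        self._values = k[:, 1]

    def __call__(self, phase):
        """Evaluate at phase(s) in [0, 1), periodic."""
        ph = np.asarray(phase, float) % 1.0
        return np.interp(ph, self._phases, self._values, period=1.0)


def eval_curve(curve: ContractionCurve, t, cycle_T: float, delay=0.0):
    """c at absolute time t with per-region delay: the curve is read at
    phase ((t - delay) mod cycle_T) / cycle_T."""
    if cycle_T <= 0:
        raise ValueError("cycle_T must be positive")
    return curve(((np.asarray(t, float) - delay) % cycle_T) / cycle_T)


def fiber_scale(c, a_mc):
    """Scaling ratio along the fiber: s_f = 1 - A_mc * c, in (0, 1]."""
    c = np.asarray(c, float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("contraction c must be in [0, 1]")
    if not 0 <= a_mc < 1:
        raise ValueError("maximum contraction rate A_mc must be in [0, 1)")
    return 1.0 - a_mc * c


@dataclass
class ContractionMatrix:
    """Anisotropic volume-preserving scaling about a fiber direction."""

    matrix: np.ndarray
    fiber: np.ndarray
    scales: tuple


def build_contraction_matrix(fiber, s_f: float) -> ContractionMatrix:
    """T = s_f f f^T + s_f^{-1/2} (I - f f^T); det(T) = 1.

    The two transverse scales are equal (the symmetric volume-preserving
    choice), so T is basis-independent given the fiber alone.
    """
    f = np.asarray(fiber, float)
    if abs(np.linalg.norm(f) - 1.0) > 1e-8:
        raise ValueError("fiber must be a unit vector")
    if s_f <= 0:
        raise ValueError("fiber scale must be positive")
    s_t = 1.0 / np.sqrt(s_f)
    proj = np.outer(f, f)
    mat = s_f * proj + s_t * (np.eye(3) - proj)
    return ContractionMatrix(mat, f, (s_f, s_t, s_t))


def contraction_matrices(fibers: np.ndarray, s_f: np.ndarray) -> np.ndarray:
    """Batched contraction matrices, (n, 3, 3), for per-region s_f."""
    f = np.asarray(fibers, float)
    s = np.asarray(s_f, float)
    proj = f[:, :, None] * f[:, None, :]
    s_t = 1.0 / np.sqrt(s)
    eye = np.eye(3)
    return (
        s[:, None, None] * proj
        + s_t[:, None, None] * (eye[None] - proj)
    )


@dataclass
class ContractionSchedule:
    """Everything the engine needs to evaluate T_r(t).

    ``curves`` maps region labels to time-contraction curves; regions
    labeled 'excluded' always read c = 0.  ``delays`` are per-region
    phase shifts in seconds (default: synchronous activation).
    """

    curves: dict = field(default_factory=lambda: {
        "ventricular": ContractionCurve(),
        "atrial": ContractionCurve(),
    })
    cycle_T: float = 1.1
    a_mc: float = 0.5
    delays: np.ndarray | None = None

    def __post_init__(self):
        if self.cycle_T <= 0:
            raise ValueError("cycle_T must be positive")
        if not 0 <= self.a_mc < 1:
            raise ValueError("a_mc must be in [0, 1)")
        if self.delays is not None:
            self.delays = np.asarray(self.delays, float)
            if (self.delays < 0).any():
                raise ValueError("delays must be nonnegative")

    def contraction(self, labels: np.ndarray, t: float) -> np.ndarray:
        """Per-region c(t) honouring labels and delays."""
        n = len(labels)
        delays = np.zeros(n) if self.delays is None else self.delays
        c = np.zeros(n)
        for lab, curve in self.curves.items():
            m = labels == lab
            if m.any():
                c[m] = eval_curve(curve, t, self.cycle_T, delays[m])
        return c  # 'excluded' stays 0

    def fiber_scales(self, labels: np.ndarray, t: float) -> np.ndarray:
        return fiber_scale(self.contraction(labels, t), self.a_mc)


def build_phase_shift_field(
    mesh: TetMesh, sources, speed: float
) -> np.ndarray:
    """Per-region activation delays: edge-length-weighted graph geodesic
    distance from the nearest source, divided by the propagation speed."""
    sources = np.atleast_1d(np.asarray(sources, np.int64))
    if sources.size == 0:
        raise MeshError("phase-shift field needs at least one source vertex")
    if speed <= 0:
        raise MeshError("propagation speed must be positive")
    e = mesh.edges()
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    graph = sp.csr_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    if np.isinf(dist).any():
        unreachable = np.flatnonzero(np.isinf(dist))
        raise MeshError(
            f"{len(unreachable)} vertices unreachable from phase sources "
            f"(first: {int(unreachable[0])}); mesh has disconnected components"
        )
    return dist / speed
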