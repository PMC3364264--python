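"""Myocardial fiber orientation fields.

Two construction routes mirror practice in ventricular modeling:
rule-based helix/transverse angles on layered solids (the classic +60°
endocardial to -60° epicardial transmural helix), and programmatic
constraint interpolation (a harmonic depth field plus harmonic
interpolation of sparse orientation constraints) for arbitrary meshes.

A fiber field attaches one unit vector to every local region; regions and
vertices are in bijection, so fields are stored per vertex.  Region labels
(atrial / ventricular / excluded) select which time-contraction curve
drives each region; 'excluded' regions never contract.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import MeshError, TetMesh

log = logging.getLogger("kinheart")

__all__ = [
    "FiberField",
    "AngleRule",
    "rule_based_fibers",
    "solve_depth_field",
    "interpolate_fiber_field",
    "save_fiber_field",
    "load_fiber_field",
]

LABELS = ("atrial", "ventricular", "excluded")


@dataclass
class FiberField:
    """One unit fiber vector + one label per local region (= per vertex)."""

    vectors: np.ndarray
    labels: np.ndarray  # array of strings from LABELS

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, float)
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MeshError("fiber vectors must be unit length")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.vectors):
            raise MeshError("one label per fiber vector required")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise MeshError(f"unknown region labels: {sorted(bad)}")

    def __len__(self):
        return len(self.vectors)


@dataclass
class AngleRule:
    """Helix/transverse angle rule, degrees.

    alpha_helix interpolates linearly from ``alpha_helix_endo`` at depth 0
    to ``alpha_helix_epi`` at depth 1; the default is the classic +60° to
    -60° transmural variation with no transverse angle.
    """

    alpha_trans: float = 0.0
    alpha_helix_endo: float = 60.0
    alpha_helix_epi: float = -60.0

    def __post_init__(self):
        for name in ("alpha_trans", "alpha_helix_endo", "alpha_helix_epi"):
            v = getattr(self, name)
            if not -90.0 <= v <= 90.0:
                raise MeshError(f"{name} must be in [-90, 90] degrees, got {v}")

    def helix_at(self, depth):
        return self.alpha_helix_endo + np.asarray(depth) * (
            self.alpha_helix_epi - self.alpha_helix_endo
        )


def rule_based_fibers(
    mesh: TetMesh,
    depth: np.ndarray,
    axis=(0.0, 0.0, 1.0),
    rule: AngleRule | None = None,
    label: str = "ventricular",
) -> FiberField:
    """Angle-rule fibers on a layered solid.

    At each vertex a local orthonormal frame (circumferential,
    longitudinal, radial) is built from the long axis and the radial
    direction; the fiber is the circumferential direction inclined by
    alpha_helix(depth) toward the longitudinal axis and tilted by
    alpha_trans toward the radial one.  Vertices on the axis (undefined
    radial direction) fall back to the longitudinal direction.
    """
    rule = rule or AngleRule()
    depth = np.asarray(depth, float)
    if depth.shape != (mesh.n_vertices,):
        raise MeshError("depth must give one value per vertex")
    ax = np.asarray(axis, float)
    nrm = np.linalg.norm(ax)
    if nrm == 0:
        raise MeshError("axis must be nonzero")
    ax = ax / nrm

    p = mesh.vertices
    radial = p - np.outer(p @ ax, ax)
    rn = np.linalg.norm(radial, axis=1)
    scale = np.linalg.norm(p, axis=1).max() or 1.0
    on_axis = rn < 1e-9 * scale
    if on_axis.any():
        log.warning(
            "%d vertices lie on the long axis; their fibers fall back to "
            "the longitudinal direction", int(on_axis.sum()),
        )
    # placeholder frame on the axis; the fiber there is overwritten below
    fallback = np.array([1.0, 0.0, 0.0]) if abs(ax[0]) < 0.9 \
        else np.array([0.0, 1.0, 0.0])
    radial[on_axis] = fallback - (fallback @ ax) * ax
    radial /= np.linalg.norm(radial, axis=1)[:, None]
    circ = np.cross(ax, radial)
    circ /= np.linalg.norm(circ, axis=1)[:, None]

    ah = np.radians(rule.helix_at(depth))[:, None]
    at = np.radians(rule.alpha_trans)
    fib = np.cos(at) * (np.cos(ah) * circ + np.sin(ah) * ax) + np.sin(at) * radial
    fib[on_axis] = ax
    fib /= np.linalg.norm(fib, axis=1)[:, None]
    return FiberField(fib, np.full(mesh.n_vertices, label, dtype=object))


def _graph_laplacian(mesh: TetMesh) -> sp.csr_matrix:
    """Piecewise-linear FEM stiffness matrix (the 3D cotangent Laplacian).

    Chosen over uniform graph weights because it reproduces linear fields
    exactly on any tetrahedral mesh, which the depth-field construction
    relies on (a slab with 0/1 plates must yield a linear profile).
    """
    v = mesh.vertices
    t = mesh.tets
    a, b, c, d = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]], v[t[:, 3]]
    vol = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0
    # inward-scaled face normals: grad of hat function i is n_i / (3 V)
    # with n_i the area vector of the face opposite vertex i
    grads = np.empty((len(t), 4, 3))
    grads[:, 0] = np.cross(d - b, c - b) / 2.0
    grads[:, 1] = np.cross(c - a, d - a) / 2.0
    grads[:, 2] = np.cross(d - a, b - a) / 2.0
    grads[:, 3] = np.cross(b - a, c - a) / 2.0
    grads /= (3.0 * vol)[:, None, None]
    local = np.einsum("tid,tjd->tij", grads, grads) * vol[:, None, None]
    rows = np.repeat(t, 4, axis=1).reshape(-1)
    cols = np.tile(t, (1, 4)).reshape(-1)
    lap = sp.csr_matrix((local.reshape(-1), (rows, cols)),
                        shape=(mesh.n_vertices,) * 2)
    lap.sum_duplicates()
    return lap


def _harmonic_solve(
    mesh: TetMesh, fixed_idx: np.ndarray, fixed_val: np.ndarray
) -> np.ndarray:
    """Solve the graph-Laplace equation with Dirichlet values at fixed_idx.

    fixed_val may be (k,) or (k, d); the result matches its trailing shape.
    """
    n = mesh.n_vertices
    if len(fixed_idx) == 0:
        raise MeshError("harmonic interpolation needs at least one constraint")
    lap = _graph_laplacian(mesh).tolil()
    free = np.setdiff1d(np.arange(n), fixed_idx)
    vals = np.zeros((n,) + fixed_val.shape[1:])
    vals[fixed_idx] = fixed_val
    if len(free) == 0:
        return vals
    a = lap[free][:, free].tocsc()
    b = -(lap[free][:, fixed_idx].tocsr() @ vals[fixed_idx])
    sol = spla.spsolve(a, b)
    vals[free] = sol.reshape((len(free),) + fixed_val.shape[1:])
    return vals


def solve_depth_field(mesh: TetMesh, boundary_values: dict[int, float]) -> np.ndarray:
    """Smooth per-vertex scalar field from sparse Dirichlet values.

    Discrete Laplace equation with piecewise-linear FEM weights; linear
    profiles are reproduced exactly, and interior values stay within the
    range of the constraints (discrete maximum principle, up to mesh
    quality).
    """
    if len(boundary_values) < 1:
        raise MeshError("depth field needs at least one boundary value")
    idx = np.fromiter(boundary_values.keys(), np.int64, len(boundary_values))
    val = np.fromiter(boundary_values.values(), float, len(boundary_values))
    return _harmonic_solve(mesh, idx, val)


def interpolate_fiber_field(
    mesh: TetMesh,
    constraints: dict[int, np.ndarray],
    labels=None,
) -> FiberField:
    """Componentwise harmonic interpolation of sparse unit-vector
    constraints, renormalized per vertex."""
    if not constraints:
        raise MeshError("fiber interpolation needs at least one constraint")
    idx = np.fromiter(constraints.keys(), np.int64, len(constraints))
    val = np.asarray([constraints[int(i)] for i in idx], float)
    val /= np.linalg.norm(val, axis=1)[:, None]
    vec = _harmonic_solve(mesh, idx, val)
    norms = np.linalg.norm(vec, axis=1)
    if (norms < 1e-12).any():
        bad = int(np.flatnonzero(norms < 1e-12)[0])
        raise MeshError(
            f"interpolated fiber vanishes at vertex {bad}; add constraints"
        )
    vec /= norms[:, None]
    if labels is None:
        labels = np.full(mesh.n_vertices, "ventricular", dtype=object)
    return FiberField(vec, labels)


def save_fiber_field(fibers: FiberField, path) -> None:
    """CSV sidecar: vertex index, fx, fy, fz, label."""
    with open(path, "w") as fh:
        fh.write("vertex,fx,fy,fz,label\n")
        for i, (v, lab) in enumerate(zip(fibers.vectors, fibers.labels)):
            fh.write(f"{i},{v[0]:.17g},{v[1]:.17g},{v[2]:.17g},{lab}\n")


def load_fiber_field(path) -> FiberField:
    import csv

    vecs, labs = [], []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            vecs.append([float(row["fx"]), float(row["fy"]), float(row["fz"])])
            labs.append(row["label"])
    return FiberField(np.asarray(vecs), np.asarray(labs, dtype=object))
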