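"""Tetrahedral mesh core: containers, TetGen I/O, surface extraction,
volume computation and 1-ring local-region construction.

All meshes are stored 0-based with tetrahedra oriented to positive signed
volume; TetGen's 1-based convention is converted at the file boundary.
Coordinates are millimetres throughout the package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

log = logging.getLogger("kinheart")

__all__ = [
    "TetMesh",
    "MeshError",
    "MeshParseError",
    "LocalRegion",
    "LocalRegions",
    "SimState",
    "load_tet_mesh",
    "write_tet_mesh",
    "total_volume",
    "signed_tet_volumes",
    "lumped_masses",
    "build_local_regions",
    "write_frame",
    "read_vtk_frame",
]


class MeshError(ValueError):
    """Structural problem with a tetrahedral mesh."""


class MeshParseError(MeshError):
    """Malformed TetGen/VTK file; message names the offending line."""


# Faces of a positively oriented tet (a,b,c,d), wound so normals point
# outward (away from the opposite vertex).
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])


def signed_tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each tet, (b-a)x(c-a).(d-a)/6."""
    a, b, c, d = (vertices[tets[:, k]] for k in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


@dataclass
class TetMesh:
    """Tetrahedral solid with derived outward-oriented boundary surface.

    Tets are re-wound on construction so every signed volume is positive;
    the boundary is required to be manifold (every face in one or two tets).
    """

    vertices: np.ndarray
    tets: np.ndarray
    surface_tris: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be an (m, 4) array")
        n = len(self.vertices)
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= n):
            raise MeshError("tet vertex index out of range")
        vols = signed_tet_volumes(self.vertices, self.tets)
        inverted = vols < 0
        if inverted.any():
            log.info("repairing %d inverted tets by vertex swap", inverted.sum())
            self.tets[inverted] = self.tets[inverted][:, [0, 1, 3, 2]]
        self.surface_tris = self._extract_surface()

    # -- derived structure -------------------------------------------------

    def _extract_surface(self) -> np.ndarray:
        faces = self.tets[:, _TET_FACES].reshape(-1, 3)  # oriented
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        if (counts > 2).any():
            raise MeshError("non-manifold boundary: a face is shared by >2 tets")
        boundary = faces[counts[inv] == 1]
        return np.ascontiguousarray(boundary)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) array, i < j."""
        pairs = self.tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]]
        pairs = pairs.reshape(-1, 2)
        pairs.sort(axis=1)
        return np.unique(pairs, axis=0)

    def vertex_adjacency(self) -> sp.csr_matrix:
        e = self.edges()
        n = self.n_vertices
        data = np.ones(len(e) * 2, dtype=np.int8)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def total_volume(mesh: TetMesh, positions: np.ndarray | None = None) -> float:
    """Total volume in mm^3 as the sum of signed tet volumes.

    ``positions`` defaults to the rest vertices; degenerate tets contribute 0.
    """
    pos = mesh.vertices if positions is None else np.asarray(positions, float)
    return float(signed_tet_volumes(pos, mesh.tets).sum())


def surface_volume(mesh: TetMesh, positions: np.ndarray | None = None) -> float:
    """Enclosed volume via the divergence theorem over the boundary surface."""
    pos = mesh.vertices if positions is None else np.asarray(positions, float)
    p0, p1, p2 = (pos[mesh.surface_tris[:, k]] for k in range(3))
    return float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)


def lumped_masses(mesh: TetMesh, density: float = 1.0) -> np.ndarray:
    """Vertex masses: each tet's volume x density split equally over its
    4 corners.  Only relative masses matter to the integrator."""
    vols = signed_tet_volumes(mesh.vertices, mesh.tets)
    m = np.zeros(mesh.n_vertices)
    np.add.at(m, mesh.tets.ravel(), np.repeat(vols * density / 4.0, 4))
    if (m <= 0).any():
        raise MeshError("vertex with nonpositive lumped mass (isolated vertex?)")
    return m


# -- TetGen ASCII I/O ------------------------------------------------------


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                yield lineno, line.split()


def load_tet_mesh(node_path, ele_path) -> TetMesh:
    """Read a TetGen ASCII .node/.ele pair.

    Both 0- and 1-based files are accepted (the base is declared by the
    first record's index, as TetGen does); inverted tets are repaired.
    """
    lines = _data_lines(node_path)
    try:
        lineno, header = next(lines)
    except StopIteration:
        raise MeshParseError(f"{node_path}: empty file") from None
    try:
        n_pts, dim = int(header[0]), int(header[1])
    except (IndexError, ValueError):
        raise MeshParseError(f"{node_path}:{lineno}: bad .node header") from None
    if dim != 3:
        raise MeshParseError(f"{node_path}:{lineno}: expected dimension 3, got {dim}")
    idx = np.empty(n_pts, dtype=np.int64)
    pts = np.empty((n_pts, 3))
    for k in range(n_pts):
        try:
            lineno, tok = next(lines)
            idx[k] = int(tok[0])
            pts[k] = [float(tok[1]), float(tok[2]), float(tok[3])]
        except StopIteration:
            raise MeshParseError(
                f"{node_path}: expected {n_pts} point records, got {k}"
            ) from None
        except (IndexError, ValueError):
            raise MeshParseError(f"{node_path}:{lineno}: bad point record") from None
    base = int(idx[0]) if n_pts else 0
    if base not in (0, 1):
        raise MeshParseError(f"{node_path}: first node index must be 0 or 1")
    order = np.argsort(idx)
    pts = pts[order]

    lines = _data_lines(ele_path)
    try:
        lineno, header = next(lines)
        n_ele, npt = int(header[0]), int(header[1])
    except StopIteration:
        raise MeshParseError(f"{ele_path}: empty file") from None
    except (IndexError, ValueError):
        raise MeshParseError(f"{ele_path}:{lineno}: bad .ele header") from None
    if npt != 4:
        raise MeshParseError(f"{ele_path}:{lineno}: only 4-node tets supported")
    tets = np.empty((n_ele, 4), dtype=np.int64)
    for k in range(n_ele):
        try:
            lineno, tok = next(lines)
            tets[k] = [int(tok[1]), int(tok[2]), int(tok[3]), int(tok[4])]
        except StopIteration:
            raise MeshParseError(
                f"{ele_path}: expected {n_ele} tet records, got {k}"
            ) from None
        except (IndexError, ValueError):
            raise MeshParseError(f"{ele_path}:{lineno}: bad tet record") from None
    return TetMesh(pts, tets - base)


def write_tet_mesh(mesh: TetMesh, node_path, ele_path) -> None:
    """Write a TetGen ASCII .node/.ele pair (1-based, TetGen's default)."""
    with open(node_path, "w") as fh:
        fh.write(f"{mesh.n_vertices} 3 0 0\n")
        for i, p in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    with open(ele_path, "w") as fh:
        fh.write(f"{mesh.n_tets} 4 0\n")
        for i, t in enumerate(mesh.tets + 1, start=1):
            fh.write(f"{i} {t[0]} {t[1]} {t[2]} {t[3]}\n")


# -- legacy VTK frame export ----------------------------------------------


def write_frame(mesh: TetMesh, positions: np.ndarray, path) -> None:
    """Write current positions as a legacy-VTK unstructured grid (cell
    type 10 = tetrahedron) for animation playback in standard viewers."""
    pos = np.asarray(positions, float)
    if pos.shape != (mesh.n_vertices, 3):
        raise MeshError("positions must match mesh vertex count")
    try:
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("kinheart frame\nASCII\nDATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {len(pos)} double\n")
            for p in pos:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            fh.write(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}\n")
            for t in mesh.tets:
                fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
            fh.write(f"CELL_TYPES {mesh.n_tets}\n")
            fh.writelines("10\n" for _ in range(mesh.n_tets))
    except OSError as exc:
        raise MeshError(f"cannot write frame to {path}: {exc}") from exc


def read_vtk_frame(path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a legacy-VTK tet grid written by :func:`write_frame`.

    Returns (points, tets).
    """
    with open(path) as fh:
        tokens = fh.read().split()
    try:
        i = tokens.index("POINTS")
        n = int(tokens[i + 1])
        pts = np.array(tokens[i + 3 : i + 3 + 3 * n], float).reshape(n, 3)
        j = tokens.index("CELLS")
        m = int(tokens[j + 1])
        cells = np.array(tokens[j + 3 : j + 3 + 5 * m], np.int64).reshape(m, 5)
    except (ValueError, IndexError):
        raise MeshParseError(f"{path}: not a kinheart VTK tet grid") from None
    return pts, cells[:, 1:]


# -- simulation state ------------------------------------------------------


@dataclass
class SimState:
    """Per-vertex kinematic state of a simulation.

    positions mm, velocities mm/s, time s, masses from the lumped uniform-
    density model (only relative masses matter), ext_forces persistent
    user-applied forces (mass * mm/s^2).
    """

    positions: np.ndarray
    velocities: np.ndarray
    time: float
    masses: np.ndarray
    ext_forces: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        self.masses = np.asarray(self.masses, float)
        self.ext_forces = np.asarray(self.ext_forces, float)
        n = len(self.positions)
        for name in ("velocities", "masses", "ext_forces"):
            if len(getattr(self, name)) != n:
                raise MeshError(f"{name} must have one entry per vertex")
        if (self.masses <= 0).any():
            raise MeshError("vertex masses must be strictly positive")


# -- local regions ---------------------------------------------------------


@dataclass
class LocalRegion:
    """One vertex-centred overlapping region: the vertex plus its 1-ring.

    ``rest_rel`` are member rest positions relative to the weighted rest
    centroid; weights are normalized to sum 1.
    """

    center: int
    members: np.ndarray
    weights: np.ndarray
    rest_centroid: np.ndarray
    rest_rel: np.ndarray


class LocalRegions:
    """All 1-ring regions of a mesh in flat CSR-style arrays.

    ``members``/``weights``/``rest_rel`` are flat over all region entries,
    ``ptr`` delimits regions, ``region_of_entry`` maps entries back to
    their region.  Sparse operators for centroid computation and per-vertex
    goal blending are prebuilt.
    """

    def __init__(self, mesh: TetMesh, members, ptr, weights):
        self.mesh = mesh
        self.members = np.asarray(members, np.int64)
        self.ptr = np.asarray(ptr, np.int64)
        self.weights = np.asarray(weights, float)
        n = mesh.n_vertices
        self.n_regions = len(ptr) - 1
        counts = np.diff(self.ptr)
        self.region_of_entry = np.repeat(np.arange(self.n_regions), counts)
        # weighted-centroid operator: (n_regions x n_vertices)
        self._cent_op = sp.csr_matrix(
            (self.weights, (self.region_of_entry, self.members)),
            shape=(self.n_regions, n),
        )
        # blend operator: per-vertex weighted sum over all containing regions
        self._blend_op = sp.csr_matrix(
            (self.weights, (self.members, np.arange(len(self.members)))),
            shape=(n, len(self.members)),
        )
        self.blend_norm = np.asarray(self._blend_op.sum(axis=1)).ravel()
        if (self.blend_norm <= 0).any():
            raise MeshError("vertex not covered by any region")
        self.rest_centroid = self.centroids(mesh.vertices)
        self.rest_rel = mesh.vertices[self.members] - self.rest_centroid[
            self.region_of_entry
        ]

    def __len__(self) -> int:
        return self.n_regions

    def __getitem__(self, r: int) -> LocalRegion:
        s = slice(self.ptr[r], self.ptr[r + 1])
        return LocalRegion(
            center=r,
            members=self.members[s],
            weights=self.weights[s],
            rest_centroid=self.rest_centroid[r],
            rest_rel=self.rest_rel[s],
        )

    def centroids(self, positions: np.ndarray) -> np.ndarray:
        """Weighted mass centre of every region at the given positions."""
        return self._cent_op @ positions

    def blend(self, entry_values: np.ndarray) -> np.ndarray:
        """Blend per-entry goal positions into per-vertex values using the
        region weights, renormalized per vertex (affine combination)."""
        return (self._blend_op @ entry_values) / self.blend_norm[:, None]


def build_local_regions(
    mesh: TetMesh,
    fibers=None,
    weight_mode: str = "anisotropic",
    eps: float = 0.05,
    exponent: float = 1.0,
) -> LocalRegions:
    """Construct one overlapping local region per vertex (itself + 1-ring).

    ``fibers`` is a FiberField (or raw (n,3) unit-vector array); it is
    required for the anisotropic weight mode.  Weight semantics live in
    :func:`kinheart.engine.compute_region_weights`.
    """
    from .engine import compute_region_weights  # deferred: avoids cycle

    adj = mesh.vertex_adjacency()
    indptr, indices = adj.indptr, adj.indices
    n = mesh.n_vertices
    if (np.diff(indptr) == 0).any():
        bad = int(np.flatnonzero(np.diff(indptr) == 0)[0])
        raise MeshError(f"isolated vertex {bad}: empty 1-ring")

    vectors = None
    if fibers is not None:
        vectors = getattr(fibers, "vectors", fibers)
        vectors = np.asarray(vectors, float)
    elif weight_mode == "anisotropic":
        raise MeshError("anisotropic weight mode requires a fiber field")

    members_parts = []
    ptr = np.empty(n + 1, np.int64)
    ptr[0] = 0
    for i in range(n):
        ring = indices[indptr[i] : indptr[i + 1]]
        mem = np.concatenate(([i], ring))
        members_parts.append(mem)
        ptr[i + 1] = ptr[i] + len(mem)
    members = np.concatenate(members_parts)

    weights = np.empty(len(members))
    verts = mesh.vertices
    for i in range(n):
        s = slice(ptr[i], ptr[i + 1])
        mem = members[s]
        rel0 = verts[mem] - verts[mem].mean(axis=0)
        fib = vectors[i] if vectors is not None else None
        weights[s] = compute_region_weights(
            rel0, fib, mode=weight_mode, eps=eps, exponent=exponent
        )
    return LocalRegions(mesh, members, ptr, weights)
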