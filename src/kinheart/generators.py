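"""Procedural test solids: thick sheet, thick-walled cylinder, idealized LV.

Every experiment in the package runs on geometry built here, so no external
mesh data is needed.  All generators emit structured hexahedral grids split
into tetrahedra with the Freudenthal/Kuhn 6-tet decomposition, which is
conforming on structured grids (shared faces always receive the same
diagonal), including across the circumferential wrap seam.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshError, TetMesh, write_tet_mesh

__all__ = [
    "CylinderSpec",
    "SheetSpec",
    "GeneratedMesh",
    "make_thick_cylinder",
    "make_thick_sheet",
    "make_idealized_lv",
    "write_generated",
    "load_sidecar",
]

# Kuhn split: corner indices (bit2,bit1,bit0) = (axis0,axis1,axis2) offsets,
# one tet per monotone lattice path from corner 0 to corner 7.
_KUHN = np.array(
    [[0, 4, 6, 7], [0, 4, 5, 7], [0, 2, 6, 7], [0, 2, 3, 7], [0, 1, 5, 7], [0, 1, 3, 7]]
)


@dataclass
class CylinderSpec:
    """Thick-walled cylinder, axis along z, base at z=0.

    Defaults follow the simplified-LV benchmark: 45 mm inner diameter,
    10 mm wall, 50 mm axial length, at a 1200-vertex discretization
    (6 transmural vertex layers x 20 around x 10 axial planes — the
    transmural direction gets the most layers because the linear helix
    angle variation across the wall is the feature the benchmark probes;
    see the mesh-convergence table in the methods note).
    """

    inner_diameter: float = 45.0
    wall_thickness: float = 10.0
    axial_length: float = 50.0
    n_radial: int = 5
    n_circumferential: int = 20
    n_axial: int = 9

    def __post_init__(self):
        if min(self.inner_diameter, self.wall_thickness, self.axial_length) <= 0:
            raise MeshError("cylinder dimensions must be positive")
        if min(self.n_radial, self.n_axial) < 1 or self.n_circumferential < 8:
            raise MeshError(
                "element counts must be >=1 (radial/axial) and >=8 (circumferential)"
            )


@dataclass
class SheetSpec:
    """Axis-aligned box, corner at the origin."""

    x_len: float = 100.0
    y_len: float = 100.0
    z_len: float = 20.0
    n_x: int = 10
    n_y: int = 10
    n_z: int = 2

    def __post_init__(self):
        if min(self.x_len, self.y_len, self.z_len) <= 0:
            raise MeshError("sheet dimensions must be positive")
        if min(self.n_x, self.n_y, self.n_z) < 1:
            raise MeshError("sheet element counts must be >=1")


@dataclass
class GeneratedMesh:
    """A generated solid plus its semantic annotations.

    ``labels`` maps surface-patch names to vertex-index arrays; ``depth``
    is a per-vertex transmural coordinate in [0,1] where defined.
    """

    mesh: TetMesh
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    depth: np.ndarray | None = None


def _split_hexes(points: np.ndarray, hexes: np.ndarray) -> TetMesh:
    """Kuhn-split hex cells (m,8 corner vertex ids) into tets, dropping
    degenerate elements produced by collapsed (apex) corners."""
    tets = hexes[:, _KUHN].reshape(-1, 4)
    distinct = (
        (tets[:, 0] != tets[:, 1])
        & (tets[:, 0] != tets[:, 2])
        & (tets[:, 0] != tets[:, 3])
        & (tets[:, 1] != tets[:, 2])
        & (tets[:, 1] != tets[:, 3])
        & (tets[:, 2] != tets[:, 3])
    )
    tets = tets[distinct]
    a, b, c, d = (points[tets[:, k]] for k in range(4))
    vols = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0
    scale = float(np.abs(points).max()) or 1.0
    tets = tets[np.abs(vols) > 1e-12 * scale**3]
    return TetMesh(points, tets)


def make_thick_cylinder(spec: CylinderSpec | None = None) -> GeneratedMesh:
    """Thick-walled cylinder with surface labels {inner, outer, top, bottom}
    and a linear-in-radius transmural depth (0 inner wall, 1 outer wall)."""
    spec = spec or CylinderSpec()
    r_in = spec.inner_diameter / 2.0
    r_out = r_in + spec.wall_thickness
    nr, nc, nz = spec.n_radial + 1, spec.n_circumferential, spec.n_axial + 1

    i, j, k = np.meshgrid(
        np.arange(nr), np.arange(nc), np.arange(nz), indexing="ij"
    )
    radius = r_in + i / spec.n_radial * (r_out - r_in)
    theta = 2.0 * np.pi * j / nc
    z = k / spec.n_axial * spec.axial_length
    points = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), z], axis=-1
    ).reshape(-1, 3)

    def vid(ii, jj, kk):
        return (ii * nc + (jj % nc)) * nz + kk

    ci, cj, ck = np.meshgrid(
        np.arange(spec.n_radial), np.arange(nc), np.arange(spec.n_axial), indexing="ij"
    )
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    hexes = np.stack(
        [vid(ci + di, cj + dj, ck + dk)
         for di in (0, 1) for dj in (0, 1) for dk in (0, 1)],
        axis=1,
    )
    mesh = _split_hexes(points, hexes)

    ii = i.reshape(-1)
    kk = k.reshape(-1)
    labels = {
        "inner": np.flatnonzero(ii == 0),
        "outer": np.flatnonzero(ii == spec.n_radial),
        "bottom": np.flatnonzero(kk == 0),
        "top": np.flatnonzero(kk == spec.n_axial),
    }
    depth = (ii / spec.n_radial).astype(float)
    return GeneratedMesh(mesh, labels, depth)


def make_thick_sheet(spec: SheetSpec | None = None) -> GeneratedMesh:
    """Axis-aligned tetrahedralized box; label ``top`` lists the maximal-z
    face vertices for pinning."""
    spec = spec or SheetSpec()
    nx, ny, nz = spec.n_x + 1, spec.n_y + 1, spec.n_z + 1
    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    points = np.stack(
        [
            i / spec.n_x * spec.x_len,
            j / spec.n_y * spec.y_len,
            k / spec.n_z * spec.z_len,
        ],
        axis=-1,
    ).reshape(-1, 3)

    def vid(ii, jj, kk):
        return (ii * ny + jj) * nz + kk

    ci, cj, ck = np.meshgrid(
        np.arange(spec.n_x), np.arange(spec.n_y), np.arange(spec.n_z), indexing="ij"
    )
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    hexes = np.stack(
        [vid(ci + di, cj + dj, ck + dk)
         for di in (0, 1) for dj in (0, 1) for dk in (0, 1)],
        axis=1,
    )
    mesh = _split_hexes(points, hexes)
    labels = {
        "top": np.flatnonzero(k.reshape(-1) == spec.n_z),
        "bottom": np.flatnonzero(k.reshape(-1) == 0),
    }
    return GeneratedMesh(mesh, labels)


def make_idealized_lv(
    base_radius: float = 25.0,
    wall: float = 10.0,
    length: float = 70.0,
    n_wall: int = 3,
    n_long: int = 12,
    n_circ: int = 24,
) -> GeneratedMesh:
    """Idealized left ventricle: a thick-walled truncated half-ellipsoid
    with closed apex and open base in the z=0 plane, apex pointing to -z.

    This is a synthetic stand-in for image-derived anatomy: ``base_radius``
    and ``length`` are the endocardial semi-axes (short and long), ``wall``
    the uniform wall thickness.  Labels: endocardium / epicardium / base;
    ``depth`` is 0 on the endocardium and 1 on the epicardium.
    """
    if not 0 < wall < base_radius:
        raise MeshError("need 0 < wall < base_radius")
    if min(base_radius, length) <= 0 or min(n_wall, n_long) < 1 or n_circ < 8:
        raise MeshError("invalid idealized-LV parameters")

    nd = n_wall + 1
    ring_stride = n_long * n_circ + 1  # n_long rings + 1 apex per layer
    points = np.empty((nd * ring_stride, 3))
    for d in range(nd):
        frac = d / n_wall
        a = base_radius + frac * wall
        c = length + frac * wall
        base = d * ring_stride
        for m in range(n_long):
            u = np.pi / 2 + (m / n_long) * (np.pi / 2)
            th = 2 * np.pi * np.arange(n_circ) / n_circ
            s = slice(base + m * n_circ, base + (m + 1) * n_circ)
            points[s, 0] = a * np.sin(u) * np.cos(th)
            points[s, 1] = a * np.sin(u) * np.sin(th)
            points[s, 2] = c * np.cos(u)
        points[base + n_long * n_circ] = (0.0, 0.0, -c)  # apex

    def vid(d, m, j):
        if m == n_long:
            return d * ring_stride + n_long * n_circ
        return d * ring_stride + m * n_circ + (j % n_circ)

    hexes = []
    for d in range(n_wall):
        for m in range(n_long):
            for j in range(n_circ):
                hexes.append(
                    [vid(d + dd, m + dm, j + dj)
                     for dd in (0, 1) for dm in (0, 1) for dj in (0, 1)]
                )
    mesh = _split_hexes(points, np.asarray(hexes))

    layer = np.arange(nd * ring_stride) // ring_stride
    within = np.arange(nd * ring_stride) % ring_stride
    labels = {
        "endocardium": np.flatnonzero(layer == 0),
        "epicardium": np.flatnonzero(layer == n_wall),
        "base": np.flatnonzero((within < n_circ)),  # m == 0 ring, every layer
    }
    depth = (layer / n_wall).astype(float)
    return GeneratedMesh(mesh, labels, depth)


# -- serialization ---------------------------------------------------------


def write_generated(gen: GeneratedMesh, stem) -> None:
    """Write <stem>.node/.ele plus a JSON sidecar with labels and depth."""
    stem = str(stem)
    write_tet_mesh(gen.mesh, stem + ".node", stem + ".ele")
    sidecar = {"labels": {k: v.tolist() for k, v in gen.labels.items()}}
    if gen.depth is not None:
        sidecar["depth"] = np.asarray(gen.depth).tolist()
    with open(stem + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_sidecar(path) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
    with open(path) as fh:
        data = json.load(fh)
    labels = {k: np.asarray(v, np.int64) for k, v in data.get("labels", {}).items()}
    depth = np.asarray(data["depth"], float) if "depth" in data else None
    return labels, depth
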