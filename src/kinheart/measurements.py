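"""Shape measurements for the cylinder benchmark and the ejection fraction.

The four cylinder measurements: wall thickness W (mean outer minus mean
inner surface radius in a mid-height band), vertical length L (axial
extent), spatial volume V (cavity enclosed by the inner surface closed
with planar rim caps), and the external slant angle S_ext (mean angle of
originally axis-parallel outer edges against the current best-fit axis,
quantifying twist).  LVEF is computed from a cavity-volume time series as
100 * (V_ED - V_ES) / V_ED with ED/ES the cycle extrema.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import MeshError, TetMesh

__all__ = [
    "MeasurementSeries",
    "wall_thickness",
    "vertical_length",
    "cavity_volume",
    "slant_angle",
    "ejection_fraction",
]


@dataclass
class MeasurementSeries:
    """Time series of the four cylinder measurements."""

    times: np.ndarray
    W: np.ndarray
    L: np.ndarray
    V: np.ndarray
    S_ext: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        for name in ("W", "L", "V", "S_ext"):
            arr = np.asarray(getattr(self, name), float)
            if len(arr) != len(self.times):
                raise MeshError(f"series {name} length != times length")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "W": self.W, "L": self.L,
             "V": self.V, "S_ext": self.S_ext}
        )

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_records(cls, records) -> "MeasurementSeries":
        arr = np.asarray(records, float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])


def wall_thickness(
    mesh: TetMesh, positions: np.ndarray,
    inner: np.ndarray, outer: np.ndarray,
    band: float = 0.2, axis: int = 2,
) -> float:
    """W: mean current radius of outer-band vertices minus inner-band ones.

    The band is the central ``band`` fraction of the rest axial extent
    (membership decided on rest positions so the sample is stable over
    time); radii are measured about the axial coordinate axis.
    """
    if len(inner) == 0 or len(outer) == 0:
        raise MeshError("wall thickness needs nonempty inner and outer labels")
    if not 0 < band <= 1:
        raise MeshError("band must be a fraction in (0, 1]")
    z = mesh.vertices[:, axis]
    mid = 0.5 * (z.min() + z.max())
    half = 0.5 * band * (z.max() - z.min())
    in_band = np.abs(z - mid) <= half + 1e-12

    def _select(label):
        sel = label[in_band[label]]
        if len(sel) == 0:
            # coarse axial discretizations may have no plane inside the
            # band; fall back to the plane(s) nearest mid-height
            dist = np.abs(z[label] - mid)
            sel = label[dist <= dist.min() + 1e-9]
        return sel

    sel_i, sel_o = _select(inner), _select(outer)
    if len(sel_i) == 0 or len(sel_o) == 0:
        raise MeshError("mid-height band contains no labeled surface vertices")
    planar = [k for k in range(3) if k != axis]
    pos = np.asarray(positions, float)
    r_i = np.linalg.norm(pos[np.ix_(sel_i, planar)], axis=1).mean()
    r_o = np.linalg.norm(pos[np.ix_(sel_o, planar)], axis=1).mean()
    return float(r_o - r_i)


def vertical_length(positions: np.ndarray, axis: int = 2) -> float:
    """L: extent of the deformed shape along the axial coordinate."""
    pos = np.asarray(positions, float)
    if len(pos) == 0:
        raise MeshError("vertical length of an empty point set")
    return float(pos[:, axis].max() - pos[:, axis].min())


def _inner_surface(mesh: TetMesh, inner: np.ndarray) -> np.ndarray:
    mask = np.zeros(mesh.n_vertices, bool)
    mask[inner] = True
    tris = mesh.surface_tris[mask[mesh.surface_tris].all(axis=1)]
    if len(tris) == 0:
        raise MeshError("no surface triangles lie entirely on the inner label")
    return tris


def _rim_loops(tris: np.ndarray) -> list[np.ndarray]:
    """Open-boundary loops of an oriented triangle patch, as vertex cycles
    following the induced boundary orientation."""
    edges: dict[tuple[int, int], int] = {}
    for tri in tris:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edges[key] = edges.get(key, 0) + 1
    boundary = set()
    for tri in tris:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if edges[(min(a, b), max(a, b))] == 1:
                boundary.add((int(a), int(b)))
    succ = {}
    for a, b in boundary:
        if a in succ:
            raise MeshError("inner surface rim is not a simple loop")
        succ[a] = b
    loops = []
    seen = set()
    for start in list(succ):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            if cur in seen or cur not in succ:
                raise MeshError("inner surface rim does not close; cavity "
                                "cannot be capped")
            loop.append(cur)
            seen.add(cur)
            cur = succ[cur]
        loops.append(np.asarray(loop, np.int64))
    return loops


def cavity_volume(mesh: TetMesh, positions: np.ndarray, inner: np.ndarray) -> float:
    """V: volume enclosed by the inner-labeled surface patch, closed with a
    planar fan cap at each open rim (fanned from the rim centroid with the
    orientation induced by the patch, so the closed surface is consistent)."""
    pos = np.asarray(positions, float)
    tris = _inner_surface(mesh, inner)
    p0, p1, p2 = pos[tris[:, 0]], pos[tris[:, 1]], pos[tris[:, 2]]
    vol = np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0
    for loop in _rim_loops(tris):
        c = pos[loop].mean(axis=0)
        a = pos[loop]
        b = pos[np.roll(loop, -1)]
        # cap triangle (c, b, a) reverses each boundary edge (a -> b)
        vol += np.einsum("ij,ij->i", np.broadcast_to(c, a.shape),
                         np.cross(b, a)).sum() / 6.0
    v = float(abs(vol))
    if v <= 0:
        raise MeshError("capped inner surface encloses no volume")
    return v


def slant_angle(
    mesh: TetMesh, rest_positions: np.ndarray, current_positions: np.ndarray,
    outer: np.ndarray, axis: int = 2, parallel_tol: float = 1e-6,
) -> float:
    """S_ext in degrees: mean inclination, against the current best-fit
    axis, of outer-surface edges that were axis-parallel at rest.

    The current axis is the rest axis carried by the best-fit rigid
    rotation of the outer vertices (so rigid motions read exactly 0 deg;
    on an axially symmetric deformation it coincides with the fixed axis).
    """
    rest = np.asarray(rest_positions, float)
    cur = np.asarray(current_positions, float)
    mask = np.zeros(mesh.n_vertices, bool)
    mask[outer] = True
    e = mesh.edges()
    e = e[mask[e].all(axis=1)]
    vec0 = rest[e[:, 1]] - rest[e[:, 0]]
    ln0 = np.linalg.norm(vec0, axis=1)
    unit_axis = np.zeros(3)
    unit_axis[axis] = 1.0
    vertical = np.abs(np.abs(vec0 @ unit_axis) / ln0 - 1.0) < parallel_tol
    e = e[vertical]
    if len(e) == 0:
        raise MeshError("outer surface has no rest-vertical edges")
    from .engine import fit_rotation  # deferred: engine imports this module's sibling

    p = rest[outer] - rest[outer].mean(axis=0)
    q = cur[outer] - cur[outer].mean(axis=0)
    rot = fit_rotation(p, q, np.full(len(p), 1.0 / len(p)))
    ax = rot @ unit_axis
    vec = cur[e[:, 1]] - cur[e[:, 0]]
    cosang = np.abs(vec @ ax) / np.linalg.norm(vec, axis=1)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(angles.mean())


def ejection_fraction(series) -> float:
    """LVEF percent over the recorded span: 100 (V_ED - V_ES) / V_ED with
    V_ED = max V and V_ES = min V.  Accepts a MeasurementSeries or a raw
    volume sequence."""
    v = np.asarray(getattr(series, "V", series), float)
    if len(v) == 0:
        raise MeshError("ejection fraction of an empty series")
    v_ed, v_es = float(v.max()), float(v.min())
    if v_ed <= 0:
        raise MeshError("nonpositive end-diastolic volume")
    return 100.0 * (v_ed - v_es) / v_ed
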