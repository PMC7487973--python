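"""Surface-deformation analyses: signed distance maps, PCA alignment,
per-vertex bulge values, and width/depth profiles.

Bulging is quantified by building a signed distance map of the resting
surface on a regular grid (negative inside), aligning the deformed surface
to the resting one by principal component analysis, and interpolating the
rest map at the deformed vertices: positive values are outward bulge.

Plane sections, watertightness checks and surface I/O are delegated to
``trimesh``; exact point-to-triangle distances and the winding-number sign
are computed here (vectorised numpy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh",
    "DistanceMap",
    "distance_map",
    "pca_align",
    "bulge_values",
    "width_depth_profile",
    "TopologyError",
    "PaddingError",
    "DegenerateAxesWarning",
]


class TopologyError(ValueError):
    """Surface is not watertight / consistently oriented."""


class PaddingError(ValueError):
    """A query vertex fell outside the distance-map grid."""


class DegenerateAxesWarning(UserWarning):
    """Principal axes are nearly degenerate; PCA alignment is ambiguous."""


@dataclass
class SurfaceMesh:
    """Closed triangulated surface (outward normals)."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3)

    @classmethod
    def from_hex_boundary(cls, mesh, u: np.ndarray | None = None) -> "SurfaceMesh":
        """Boundary surface of a hex mesh (face-set quads split into
        triangles), optionally deformed by nodal displacements ``u``."""
        quads = np.vstack([mesh.face_sets[k] for k in sorted(mesh.face_sets)])
        tris = np.vstack([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])
        verts = mesh.nodes + (0.0 if u is None else u)
        used = np.unique(tris)
        remap = -np.ones(verts.shape[0], dtype=np.int64)
        remap[used] = np.arange(len(used))
        return cls(vertices=verts[used].copy(), faces=remap[tris])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        tm = trimesh.load(path, force="mesh")
        return cls(vertices=np.asarray(tm.vertices, dtype=float), faces=np.asarray(tm.faces, dtype=np.int64))

    def save(self, path) -> None:
        """Export as STL or PLY (ASCII variants) based on the extension."""
        path = str(path)
        tm = self.to_trimesh()
        if path.endswith(".stl"):
            with open(path, "wb") as fh:
                fh.write(trimesh.exchange.stl.export_stl_ascii(tm).encode())
        elif path.endswith(".ply"):
            with open(path, "wb") as fh:
                fh.write(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
        else:
            tm.export(path)


@dataclass
class DistanceMap:
    """Signed distances on a regular grid (negative inside the surface)."""

    origin: np.ndarray  # (3,)
    spacing: float
    values: np.ndarray  # (nx, ny, nz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at arbitrary points (m, 3)."""
        axes = [self.origin[i] + self.spacing * np.arange(self.shape[i]) for i in range(3)]
        interp = RegularGridInterpolator(axes, self.values, method="linear", bounds_error=True)
        try:
            return interp(np.asarray(points, dtype=float))
        except ValueError as exc:
            raise PaddingError("query point outside the distance-map grid; increase padding") from exc


def _closest_point_distance(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Exact distance from each point to the nearest of the triangles.

    Vectorised closest-point-on-triangle (barycentric region clamping);
    ``points`` (n,3), ``tris`` (m,3,3) -> distances (n,).
    """
    A, B, C = tris[:, 0], tris[:, 1], tris[:, 2]
    ab, ac = B - A, C - A
    P = points[:, None, :]  # (n,1,3)
    ap = P - A
    d1 = np.einsum("mj,nmj->nm", ab, ap)
    d2 = np.einsum("mj,nmj->nm", ac, ap)
    bp = P - B
    d3 = np.einsum("mj,nmj->nm", ab, bp)
    d4 = np.einsum("mj,nmj->nm", ac, bp)
    cp = P - C
    d5 = np.einsum("mj,nmj->nm", ab, cp)
    d6 = np.einsum("mj,nmj->nm", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        s_ab = d1 / (d1 - d3)
        t_ac = d2 / (d2 - d6)
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = 1.0 / (va + vb + vc)
        s_in, t_in = vb * denom, vc * denom
    conds = [
        (d1 <= 0) & (d2 <= 0),                       # vertex A
        (d3 >= 0) & (d4 <= d3),                      # vertex B
        (d6 >= 0) & (d5 <= d6),                      # vertex C
        (vc <= 0) & (d1 >= 0) & (d3 <= 0),           # edge AB
        (vb <= 0) & (d2 >= 0) & (d6 <= 0),           # edge AC
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),  # edge BC
    ]
    zero = np.zeros_like(d1)
    one = np.ones_like(d1)
    # edge BC parametrises closest = B + t_bc (C - B) = A + (1 - t_bc) ab + t_bc ac
    s = np.select(conds, [zero, one, zero, s_ab, zero, 1.0 - t_bc], default=s_in)
    t = np.select(conds, [zero, zero, one, zero, t_ac, t_bc], default=t_in)
    closest = A + s[..., None] * ab + t[..., None] * ac
    d = np.linalg.norm(P - closest, axis=-1)
    return d.min(axis=1)


def _winding_number(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Generalised winding number (sum of signed solid angles / 4 pi)."""
    a = tris[:, 0] - points[:, None, :]
    b = tris[:, 1] - points[:, None, :]
    c = tris[:, 2] - points[:, None, :]
    la = np.linalg.norm(a, axis=-1)
    lb = np.linalg.norm(b, axis=-1)
    lc = np.linalg.norm(c, axis=-1)
    num = np.einsum("nmj,nmj->nm", a, np.cross(b, c))
    den = la * lb * lc + np.einsum("nmj,nmj->nm", a, b) * lc \
        + np.einsum("nmj,nmj->nm", b, c) * la + np.einsum("nmj,nmj->nm", c, a) * lb
    return np.sum(2.0 * np.arctan2(num, den), axis=1) / (4.0 * np.pi)


def signed_distance(surface: SurfaceMesh, points: np.ndarray, chunk: int = 1024) -> np.ndarray:
    """Signed distance to the surface at arbitrary points, negative inside."""
    tris = surface.vertices[surface.faces]
    points = np.asarray(points, dtype=float)
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk]
        d = _closest_point_distance(p, tris)
        inside = np.abs(_winding_number(p, tris)) > 0.5
        out[lo:lo + chunk] = np.where(inside, -d, d)
    return out


def distance_map(surface: SurfaceMesh, spacing: float = 0.5e-3, padding: int = 5) -> DistanceMap:
    """Exact signed point-to-surface distances on a regular grid.

    ``spacing`` is the grid step in metres (default 0.5 mm); the grid extends
    ``padding`` spacings beyond the surface bounding box on every side.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    tm = surface.to_trimesh()
    if not tm.is_watertight:
        raise TopologyError("distance map requires a watertight surface")
    lo = tm.bounds[0] - padding * spacing
    hi = tm.bounds[1] + padding * spacing
    axes = [np.arange(lo[i], hi[i] + 0.5 * spacing, spacing) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = signed_distance(surface, grid)
    shape = tuple(len(a) for a in axes)
    return DistanceMap(origin=lo.copy(), spacing=spacing, values=vals.reshape(shape))


def _principal_axes(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = vertices.mean(axis=0)
    cov = np.cov((vertices - c).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return c, evals[order], evecs[:, order]


def pca_align(moving: SurfaceMesh, reference: SurfaceMesh) -> SurfaceMesh:
    """Rigidly align ``moving`` to ``reference`` by principal axes.

    The moving surface is translated to the reference centroid and rotated so
    its principal axes coincide with the reference's.  Axis-sign ambiguity is
    resolved by choosing, among the four proper rotations (det = +1), the one
    minimising the mean nearest-vertex distance; reflections are never applied.
    """
    c_ref, ev_ref, V_ref = _principal_axes(reference.vertices)
    c_mov, ev_mov, V_mov = _principal_axes(moving.vertices)
    if np.any(ev_ref[:-1] / np.maximum(ev_ref[1:], 1e-300) < 1.0 + 1e-6):
        warnings.warn("near-degenerate principal axes; alignment may be ambiguous",
                      DegenerateAxesWarning, stacklevel=2)
    tree = cKDTree(reference.vertices)
    best, best_cost = None, np.inf
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            D = np.diag([s1, s2, 1.0])
            R = V_ref @ D @ V_mov.T
            if np.linalg.det(R) < 0:
                R = V_ref @ D @ np.diag([1.0, 1.0, -1.0]) @ V_mov.T
            verts = (moving.vertices - c_mov) @ R.T + c_ref
            cost = float(np.mean(tree.query(verts)[0]))
            if cost < best_cost:
                best, best_cost = verts, cost
    return SurfaceMesh(vertices=best, faces=moving.faces.copy())


def bulge_values(deformed: SurfaceMesh, rest_map: DistanceMap) -> np.ndarray:
    """Signed distance of each deformed vertex to the resting surface (m).

    Interpolates the rest distance map trilinearly at the deformed vertices;
    positive values indicate outward bulge.  The deformed surface should be
    PCA-aligned to the resting surface first.
    """
    return rest_map.interpolate(deformed.vertices)


def width_depth_profile(surface: SurfaceMesh, n_stations: int = 10):
    """Width and depth of yz cross-sections along the length of the surface.

    Sections are taken at ``n_stations`` stations evenly spaced along x (at
    the centres of equal-length intervals).  Width is the maximal y-extent of
    the section; depth is the section area divided by the width.  Returns a
    pandas DataFrame with columns station, x, width, depth.
    """
    import pandas as pd

    tm = surface.to_trimesh()
    x_lo, x_hi = tm.bounds[0][0], tm.bounds[1][0]
    rows = []
    for i in range(n_stations):
        frac = (i + 0.5) / n_stations
        x0 = x_lo + frac * (x_hi - x_lo)
        segs = trimesh.intersections.mesh_plane(tm, plane_normal=[1.0, 0.0, 0.0],
                                                plane_origin=[x0, 0.0, 0.0])
        if len(segs) == 0:
            warnings.warn(f"empty section at station {i}; skipped", stacklevel=2)
            continue
        yz = segs[:, :, 1:]  # project to the yz plane
        width = float(yz[..., 0].max() - yz[..., 0].min())
        area = _section_area(yz)
        rows.append({"station": i, "x": x0, "width": width, "depth": area / width})
    return pd.DataFrame(rows)


def _section_area(yz: np.ndarray) -> float:
    """Total enclosed area of a set of 2D segments forming closed loops.

    Segment endpoints from plane sections agree only to roundoff, so they are
    quantised before chaining; the area of each loop is the shoelace formula.
    """
    extent = max(float(np.ptp(yz[..., 0])), float(np.ptp(yz[..., 1])), 1e-300)
    tol = 1e-6 * extent
    q = np.round(yz / tol).astype(np.int64)
    node_id: dict[tuple[int, int], int] = {}
    coords: list[np.ndarray] = []

    def nid(k, xy):
        key = (int(k[0]), int(k[1]))
        if key not in node_id:
            node_id[key] = len(coords)
            coords.append(xy)
        return node_id[key]

    adj: dict[int, list[int]] = {}
    for s in range(len(yz)):
        a = nid(q[s, 0], yz[s, 0])
        b = nid(q[s, 1], yz[s, 1])
        if a == b:
            continue
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    visited: set[tuple[int, int]] = set()
    area = 0.0
    for start in adj:
        for nxt in adj[start]:
            if (min(start, nxt), max(start, nxt)) in visited:
                continue
            loop = [start]
            prev, cur = start, nxt
            visited.add((min(start, nxt), max(start, nxt)))
            while cur != start:
                loop.append(cur)
                nbrs = [n for n in adj[cur] if n != prev]
                if not nbrs:
                    loop = None
                    break
                prev, cur = cur, nbrs[0]
                visited.add((min(prev, cur), max(prev, cur)))
            if loop is None or len(loop) < 3:
                continue
            pts = np.array([coords[n] for n in loop])
            x, y = pts[:, 0], pts[:, 1]
            area += 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area)
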