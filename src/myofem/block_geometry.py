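"""Hexahedral block meshes with tagged faces and fibre orientation fields.

Blocks span ``[0, Lx] x [0, Ly] x [0, Lz]`` with the x-axis longitudinal
(the muscle line of action).  Coordinates are SI metres internally; configs
use millimetres.  Elements are 8-node trilinear hexahedra with a 2x2x2 Gauss
rule (8 quadrature points per element).  Fibres lie in the xz plane at an
initial pennation angle ``beta0`` from the x-axis.

Meshes round-trip through GMSH v2.2 ASCII files with the six face sets stored
as quad elements in named physical groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BlockSpec",
    "HexMesh",
    "FibreField",
    "build_block",
    "assign_uniform_fibres",
    "read_gmsh",
    "write_gmsh",
    "UnsupportedElementError",
    "GmshParseError",
]

FACE_NAMES = ("-x", "+x", "-y", "+y", "-z", "+z")

# reference-element node coordinates, GMSH/VTK hexahedron ordering
_XI_NODES = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


class UnsupportedElementError(ValueError):
    """A mesh file contains cells other than 8-node hexahedra / 4-node quads."""


class GmshParseError(ValueError):
    """Malformed GMSH file."""


def gauss_points_2x2x2() -> tuple[np.ndarray, np.ndarray]:
    """Reference coordinates and weights of the 2x2x2 Gauss rule."""
    g = 1.0 / np.sqrt(3.0)
    pts = _XI_NODES * g
    wts = np.ones(8)
    return pts, wts


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for points xi of shape (...,3)."""
    xi = np.asarray(xi, dtype=float)
    s = _XI_NODES  # (8,3)
    return np.prod(1.0 + xi[..., None, :] * s, axis=-1) / 8.0


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """d N_a / d xi_j at points xi; returns shape (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    s = _XI_NODES
    out = np.empty(xi.shape[:-1] + (8, 3))
    for j in range(3):
        terms = [1.0 + xi[..., None, k] * s[:, k] for k in range(3) if k != j]
        out[..., j] = s[:, j] / 8.0 * terms[0] * terms[1]
    return out


@dataclass(frozen=True)
class BlockSpec:
    """Cuboid muscle block: dimensions (m), initial pennation (deg), resolution."""

    Lx: float = 0.030
    Ly: float = 0.010
    Lz: float = 0.010
    beta0: float = 0.0
    nx: int = 12
    ny: int = 4
    nz: int = 4

    def __post_init__(self):
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ValueError("block edge lengths must be positive")
        if not (0 <= self.beta0 < 90):
            raise ValueError("beta0 must lie in [0, 90) degrees")
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("element counts must be >= 1")

    @property
    def csa(self) -> float:
        """Cross-sectional area of the yz face (m^2)."""
        return self.Ly * self.Lz

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.Lz


@dataclass
class HexMesh:
    """8-node hexahedral mesh with named boundary face sets.

    ``face_sets`` maps each of the six face names to an (n,4) array of node
    quads ordered with outward normals.  Quadrature caches (shape-function
    gradients in reference configuration, Jacobian determinants) are built
    lazily and reused by assembly and post-processing.
    """

    nodes: np.ndarray  # (n_nodes, 3)
    elems: np.ndarray  # (n_elems, 8)
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)

    _qp_cache: dict | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    @property
    def n_qp(self) -> int:
        return 8 * self.n_elems

    def face_nodes(self, name: str) -> np.ndarray:
        """Sorted unique node ids of a named face set."""
        if name not in self.face_sets:
            raise KeyError(f"unknown face set {name!r}")
        return np.unique(self.face_sets[name])

    def quadrature(self) -> dict:
        """Per-element quadrature data: dN/dX (ne,8qp,8a,3), detJ0 (ne,8qp),
        reference qp positions (ne,8qp,3) and weights (8,)."""
        if self._qp_cache is None:
            pts, wts = gauss_points_2x2x2()
            dNdxi = shape_gradients(pts)  # (8qp, 8a, 3)
            N = shape_functions(pts)  # (8qp, 8a)
            Xe = self.nodes[self.elems]  # (ne, 8a, 3)
            # J0[e,q,i,j] = d X_i / d xi_j
            J0 = np.einsum("eai,qaj->eqij", Xe, dNdxi)
            detJ0 = np.linalg.det(J0)
            if np.any(detJ0 <= 0):
                raise ValueError("mesh contains elements with non-positive Jacobian")
            J0inv = np.linalg.inv(J0)
            dNdX = np.einsum("qaj,eqji->eqai", dNdxi, J0inv)
            xq = np.einsum("qa,eai->eqi", N, Xe)
            object.__setattr__(self, "_qp_cache", {"dNdX": dNdX, "detJ0": detJ0, "x_qp": xq, "weights": wts})
        return self._qp_cache

    def volume_by_quadrature(self) -> float:
        q = self.quadrature()
        return float(np.sum(q["weights"][None, :] * q["detJ0"]))

    def qp_positions(self) -> np.ndarray:
        """Reference positions of all quadrature points, shape (ne, 8, 3)."""
        return self.quadrature()["x_qp"]


@dataclass(frozen=True)
class FibreField:
    """Unit fibre direction at every quadrature point, shape (ne, 8, 3)."""

    a0: np.ndarray

    def __post_init__(self):
        norms = np.linalg.norm(self.a0, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("fibre directions must be unit vectors")


def build_block(spec: BlockSpec) -> HexMesh:
    """Structured mesh of the block ``[0,Lx] x [0,Ly] x [0,Lz]``."""
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    xs = np.linspace(0.0, spec.Lx, nx + 1)
    ys = np.linspace(0.0, spec.Ly, ny + 1)
    zs = np.linspace(0.0, spec.Lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, Jj, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = I.ravel(), Jj.ravel(), K.ravel()
    elems = np.column_stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ]
    ).astype(np.int64)

    face_sets: dict[str, np.ndarray] = {}
    # quads ordered so the right-hand rule gives the outward normal
    jj, kk = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    jj, kk = jj.ravel(), kk.ravel()
    face_sets["-x"] = np.column_stack([nid(0, jj, kk), nid(0, jj, kk + 1), nid(0, jj + 1, kk + 1), nid(0, jj + 1, kk)])
    face_sets["+x"] = np.column_stack([nid(nx, jj, kk), nid(nx, jj + 1, kk), nid(nx, jj + 1, kk + 1), nid(nx, jj, kk + 1)])
    ii, kk = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
    ii, kk = ii.ravel(), kk.ravel()
    face_sets["-y"] = np.column_stack([nid(ii, 0, kk), nid(ii + 1, 0, kk), nid(ii + 1, 0, kk + 1), nid(ii, 0, kk + 1)])
    face_sets["+y"] = np.column_stack([nid(ii, ny, kk), nid(ii, ny, kk + 1), nid(ii + 1, ny, kk + 1), nid(ii + 1, ny, kk)])
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    face_sets["-z"] = np.column_stack([nid(ii, jj, 0), nid(ii, jj + 1, 0), nid(ii + 1, jj + 1, 0), nid(ii + 1, jj, 0)])
    face_sets["+z"] = np.column_stack([nid(ii, jj, nz), nid(ii + 1, jj, nz), nid(ii + 1, jj + 1, nz), nid(ii, jj + 1, nz)])

    return HexMesh(nodes=nodes, elems=elems, face_sets=face_sets)


def assign_uniform_fibres(mesh: HexMesh, beta0: float) -> FibreField:
    """Uniform fibre field at pennation ``beta0`` (deg) in the xz plane:
    ``a0 = (cos beta0, 0, sin beta0)`` at every quadrature point."""
    if not (0 <= beta0 < 90):
        raise ValueError("beta0 must lie in [0, 90) degrees")
    b = np.deg2rad(beta0)
    a0 = np.array([np.cos(b), 0.0, np.sin(b)])
    return FibreField(a0=np.broadcast_to(a0, (mesh.n_elems, 8, 3)).copy())


# ---------------------------------------------------------------------------
# GMSH v2.2 ASCII I/O
# ---------------------------------------------------------------------------

_GMSH_HEX = 5
_GMSH_QUAD = 3


def write_gmsh(mesh: HexMesh, path) -> None:
    """Write a hex mesh as GMSH v2.2 ASCII, face sets as quad physical groups."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    names = list(mesh.face_sets)
    lines.append("$PhysicalNames")
    lines.append(str(len(names) + 1))
    for i, nm in enumerate(names, start=1):
        lines.append(f'2 {i} "{nm}"')
    lines.append(f'3 {len(names) + 1} "volume"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} {z:.17g}")
    lines.append("$EndNodes")
    n_face = sum(len(q) for q in mesh.face_sets.values())
    lines.append("$Elements")
    lines.append(str(mesh.n_elems + n_face))
    eid = 1
    for i, nm in enumerate(names, start=1):
        for quad in mesh.face_sets[nm]:
            ns = " ".join(str(n + 1) for n in quad)
            lines.append(f"{eid} {_GMSH_QUAD} 2 {i} {i} {ns}")
            eid += 1
    vol_tag = len(names) + 1
    for el in mesh.elems:
        ns = " ".join(str(n + 1) for n in el)
        lines.append(f"{eid} {_GMSH_HEX} 2 {vol_tag} {vol_tag} {ns}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gmsh(path) -> HexMesh:
    """Read a GMSH v2.2 ASCII mesh of 8-node hexahedra.

    Quad elements in physical groups become face sets (named via
    ``$PhysicalNames`` when present).  Any other cell type raises
    :class:`UnsupportedElementError`.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)

    phys_names: dict[int, str] = {}
    nodes = None
    hexes: list[list[int]] = []
    quads: dict[int, list[list[int]]] = {}
    try:
        for line in it:
            line = line.strip()
            if line == "$MeshFormat":
                fmt = next(it).split()
                if not fmt or not fmt[0].startswith("2"):
                    raise GmshParseError(f"unsupported GMSH format version {fmt[:1]}")
                while next(it).strip() != "$EndMeshFormat":
                    pass
            elif line == "$PhysicalNames":
                n = int(next(it))
                for _ in range(n):
                    parts = next(it).split(maxsplit=2)
                    phys_names[int(parts[1])] = parts[2].strip().strip('"')
                if next(it).strip() != "$EndPhysicalNames":
                    raise GmshParseError("unterminated $PhysicalNames block")
            elif line == "$Nodes":
                n = int(next(it))
                nodes = np.empty((n, 3))
                for i in range(n):
                    parts = next(it).split()
                    nodes[int(parts[0]) - 1] = [float(parts[1]), float(parts[2]), float(parts[3])]
                if next(it).strip() != "$EndNodes":
                    raise GmshParseError("unterminated $Nodes block")
            elif line == "$Elements":
                n = int(next(it))
                for _ in range(n):
                    parts = [int(t) for t in next(it).split()]
                    etype, ntags = parts[1], parts[2]
                    conn = parts[3 + ntags :]
                    if etype == _GMSH_HEX:
                        if len(conn) != 8:
                            raise GmshParseError("hexahedron with wrong node count")
                        hexes.append(conn)
                    elif etype == _GMSH_QUAD:
                        tag = parts[3] if ntags >= 1 else 0
                        quads.setdefault(tag, []).append(conn)
                    else:
                        raise UnsupportedElementError(f"unsupported GMSH element type {etype}")
                if next(it).strip() != "$EndElements":
                    raise GmshParseError("unterminated $Elements block")
    except UnsupportedElementError:
        raise
    except (StopIteration, IndexError, ValueError) as exc:
        raise GmshParseError("malformed or truncated GMSH file") from exc
    if nodes is None or not hexes:
        raise GmshParseError("mesh contains no nodes or no hexahedra")

    face_sets = {}
    for tag, qs in quads.items():
        name = phys_names.get(tag, str(tag))
        face_sets[name] = np.asarray(qs, dtype=np.int64) - 1
    return HexMesh(nodes=nodes, elems=np.asarray(hexes, dtype=np.int64) - 1, face_sets=face_sets)
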