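"""Scalars reported for each simulated block.

Forces are reactions on the constrained faces; stresses divide the face force
by the deformed face area.  Strains are changes in the (area-weighted) mean
separation of opposite faces.  Strain energies are integrated over the
reference volume, and overall energy *densities* are means over quadrature
points weighted by the local dilation; all energies are relative to the
undeformed state, so the active-fibre component is negative when the fibres
have shortened.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .block_geometry import HexMesh, FibreField
from .constitutive import TissueMaterial, pk2_stress_components, fibre_energy_density, base_energy_density
from .fem_core import SystemState, deformation_measures, internal_forces, external_force_vector

__all__ = [
    "EnergyReport",
    "BlockResult",
    "face_force",
    "face_strain",
    "mean_fibre_state",
    "integrate_energy",
    "centre_plane_stress_decomposition",
    "volume_change",
    "deformed_face_area",
    "block_result",
]

_AXIS_FACES = {0: ("-x", "+x"), 1: ("-y", "+y"), 2: ("-z", "+z")}


@dataclass(frozen=True)
class EnergyReport:
    """Strain-energy decomposition: densities (J/m^3) and potentials (J)."""

    psi_active: float
    psi_passive: float
    psi_base: float
    psi_vol: float
    U_active: float
    U_passive: float
    U_base: float
    U_vol: float

    @property
    def U_int(self) -> float:
        return self.U_active + self.U_passive + self.U_base + self.U_vol


@dataclass(frozen=True)
class BlockResult:
    """Post-processed scalars for one block at one activation level."""

    activation: float
    F_x: float  # longitudinal force on the +x face, N
    sigma_x: float  # x-stress on the +x face, current area, Pa
    eps_y: float
    eps_z: float
    l_hat: float
    mean_lambda_tot: float
    mean_beta: float  # degrees
    volume_change: float  # (V - V0)/V0
    energy: EnergyReport

    def to_row(self) -> dict:
        row = asdict(self)
        row.update(row.pop("energy"))
        row["U_int"] = self.energy.U_int
        return row


def _face_node_weights(mesh: HexMesh, face: str) -> tuple[np.ndarray, np.ndarray]:
    """Reference-area weights per face node (each quad spreads its area over
    its four corners)."""
    quads = mesh.face_sets[face]
    v0, v1, v2, v3 = (mesh.nodes[quads[:, i]] for i in range(4))
    area = 0.5 * (
        np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
        + np.linalg.norm(np.cross(v2 - v0, v3 - v0), axis=1)
    )
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, quads.ravel(), np.repeat(area / 4.0, 4))
    nodes = np.unique(quads)
    return nodes, w[nodes]


def _face_mean_coordinate(mesh: HexMesh, u: np.ndarray, face: str, axis: int) -> float:
    nodes, w = _face_node_weights(mesh, face)
    x = mesh.nodes[nodes, axis] + u[nodes, axis]
    return float(np.sum(w * x) / np.sum(w))


def face_force(state: SystemState, mesh: HexMesh, fibres: FibreField, material: TissueMaterial,
               face: str = "+x", axis: int = 0, tractions=None) -> float:
    """Axis component of the reaction force on a (constrained) face, N.

    Sums internal-minus-external nodal forces over the face node set, which
    equals the integral of the traction over the deformed face at equilibrium.
    """
    if face not in mesh.face_sets:
        raise KeyError(f"unknown face set {face!r}")
    f_int, _, _ = internal_forces(mesh, fibres, material, state.u, state.activation)
    f = f_int - external_force_vector(mesh, tractions)
    nodes = mesh.face_nodes(face)
    return float(np.sum(f[3 * nodes + axis]))


def deformed_face_area(mesh: HexMesh, u: np.ndarray, face: str) -> float:
    quads = mesh.face_sets[face]
    x = mesh.nodes + u
    v0, v1, v2, v3 = (x[quads[:, i]] for i in range(4))
    return float(np.sum(
        0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
        + 0.5 * np.linalg.norm(np.cross(v2 - v0, v3 - v0), axis=1)
    ))


def face_strain(state: SystemState, mesh: HexMesh, axis: int) -> float:
    """Strain of the face pair along ``axis``: change in mean face separation
    over the reference separation."""
    lo, hi = _AXIS_FACES[axis]
    zeros = np.zeros_like(state.u)
    d0 = _face_mean_coordinate(mesh, zeros, hi, axis) - _face_mean_coordinate(mesh, zeros, lo, axis)
    d = _face_mean_coordinate(mesh, state.u, hi, axis) - _face_mean_coordinate(mesh, state.u, lo, axis)
    return (d - d0) / d0


def mean_fibre_state(state: SystemState, mesh: HexMesh, fibres: FibreField) -> tuple[float, float]:
    """Unweighted means of fibre stretch and pennation angle (deg) over all
    quadrature points."""
    meas = deformation_measures(mesh, fibres, state.u)
    return float(np.mean(meas.lambda_tot)), float(np.mean(meas.beta))


def volume_change(state: SystemState, mesh: HexMesh, fibres: FibreField) -> float:
    """(V - V0)/V0 from the quadrature-integrated deformed volume."""
    meas = deformation_measures(mesh, fibres, state.u)
    q = mesh.quadrature()
    V0 = np.sum(q["weights"][None, :] * q["detJ0"])
    V = np.sum(q["weights"][None, :] * q["detJ0"] * meas.J_det)
    return float(V / V0 - 1.0)


def integrate_energy(state: SystemState, mesh: HexMesh, fibres: FibreField,
                     material: TissueMaterial) -> EnergyReport:
    """Energy potentials (reference-volume integrals) and dilation-weighted
    mean densities for the four components.

    The volumetric density at a quadrature point is the penalty evaluated at
    its element's condensed dilation, so element potentials are exactly
    ``U(J_bar_e) V0_e`` and the component potentials sum to ``U_int``.
    """
    meas = deformation_measures(mesh, fibres, state.u)
    q = mesh.quadrature()
    w, detJ0 = q["weights"], q["detJ0"]
    V0e = np.einsum("q,eq->e", w, detJ0)
    J_bar = np.einsum("q,eq,eq->e", w, detJ0, meas.J_det) / V0e

    lam_bar = meas.J_det ** (-1.0 / 3.0) * meas.lambda_tot  # isochoric stretch
    psi_a, psi_p = fibre_energy_density(lam_bar, state.activation, material)
    i1_bar = meas.J_det ** (-2.0 / 3.0) * np.einsum("eqii->eq", meas.C)
    psi_b = base_energy_density(i1_bar, material)
    psi_v = np.broadcast_to(material.vol.energy(J_bar)[:, None], psi_b.shape)

    dV0 = w[None, :] * detJ0
    wdil = dV0 * meas.J_det  # dilation weighting for mean densities
    W = np.sum(wdil)

    def mean_density(psi):
        return float(np.sum(psi * wdil) / W)

    def potential(psi):
        return float(np.sum(psi * dV0))

    return EnergyReport(
        psi_active=mean_density(psi_a),
        psi_passive=mean_density(psi_p),
        psi_base=mean_density(psi_b),
        psi_vol=mean_density(psi_v),
        U_active=potential(psi_a),
        U_passive=potential(psi_p),
        U_base=potential(psi_b),
        U_vol=float(np.sum(material.vol.energy(J_bar) * V0e)),
    )


def centre_plane_stress_decomposition(state: SystemState, mesh: HexMesh, fibres: FibreField,
                                      material: TissueMaterial) -> dict[str, float]:
    """Fibre-normal Cauchy stress components on the centre plane.

    Samples quadrature points within half an element width of the plane
    through the deformed block centre whose normal is the mean deformed fibre
    direction; for each strain-energy component the traction component along
    that normal is averaged.  Positive values act to shorten the fibres
    (tensile along the fibre direction).
    """
    meas = deformation_measures(mesh, fibres, state.u)
    v = np.einsum("eqij,eqj->eqi", meas.F, fibres.a0)
    n_mean = np.mean(v.reshape(-1, 3), axis=0)
    n_mean /= np.linalg.norm(n_mean)

    q = mesh.quadrature()
    N = np.einsum("qa,eai->eqi", _qp_shape_values(), mesh.nodes[mesh.elems] + state.u[mesh.elems])
    centre = np.mean(state.u, axis=0) + 0.5 * (mesh.nodes.min(axis=0) + mesh.nodes.max(axis=0))
    dist = np.einsum("eqi,i->eq", N - centre, n_mean)
    h = 0.5 * (mesh.volume_by_quadrature() / mesh.n_elems) ** (1.0 / 3.0)
    mask = np.abs(dist) <= h
    if not np.any(mask):
        raise ValueError("no quadrature points found near the centre plane")

    comps = pk2_stress_components(meas.F, state.p[:, None], fibres.a0, state.activation, material)
    out = {}
    for key in ("active", "passive", "base", "volumetric", "total"):
        sigma = np.einsum("eqik,eqkl,eqjl->eqij", meas.F, comps[key], meas.F) / meas.J_det[..., None, None]
        t_n = np.einsum("i,eqij,j->eq", n_mean, sigma, n_mean)
        out[key] = float(np.mean(t_n[mask]))
    return out


def _qp_shape_values():
    from .block_geometry import shape_functions, gauss_points_2x2x2

    pts, _ = gauss_points_2x2x2()
    return shape_functions(pts)


def block_result(state: SystemState, mesh: HexMesh, fibres: FibreField, material: TissueMaterial,
                 tractions=None) -> BlockResult:
    """All reported scalars for one converged state."""
    lam, beta = mean_fibre_state(state, mesh, fibres)
    Fx = face_force(state, mesh, fibres, material, "+x", 0, tractions=tractions)
    area = deformed_face_area(mesh, state.u, "+x")
    lo, hi = _AXIS_FACES[0]
    zeros = np.zeros_like(state.u)
    L0 = _face_mean_coordinate(mesh, zeros, hi, 0) - _face_mean_coordinate(mesh, zeros, lo, 0)
    L = _face_mean_coordinate(mesh, state.u, hi, 0) - _face_mean_coordinate(mesh, state.u, lo, 0)
    return BlockResult(
        activation=state.activation,
        F_x=Fx,
        sigma_x=Fx / area,
        eps_y=face_strain(state, mesh, 1),
        eps_z=face_strain(state, mesh, 2),
        l_hat=L / L0,
        mean_lambda_tot=lam,
        mean_beta=beta,
        volume_change=volume_change(state, mesh, fibres),
        energy=integrate_energy(state, mesh, fibres, material),
    )
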