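"""Three-field nonlinear equilibrium solver.

The discrete problem seeks a stationary point of the total strain energy
``E_tot(u, p, J) = U_int - W_ext`` over nodal displacements ``u``,
element-wise pressures ``p`` and element-wise dilations ``J``.  With
trilinear displacements and element-constant pressure/dilation
(Q1-P0-P0, the classical mean-dilatation treatment) the two local fields
can be statically condensed: stationarity in ``p`` makes the element
dilation the volume average of ``det F``, and stationarity in ``J`` makes
the pressure the derivative of the volumetric penalty at that average,

    J_bar_e = <det F>_e,      p_e = kappa (J_bar_e - 1).

What remains is a nonlinear system in ``u`` alone, solved by Newton's
method with backtracking line search.  The consistent tangent (including
the condensation coupling) is obtained by complex-step differentiation of
the element residual, which is exact to machine precision.

External loads are dead nominal tractions on named face sets; fixed-end
contractions constrain both x-faces in all three directions while the
activation is ramped linearly (the ramp doubles as load continuation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .block_geometry import HexMesh, FibreField
from .constitutive import (
    TissueMaterial,
    VolumetricPenalty,
    ElementInversionError,
    pk2_stress_components,
    fibre_energy_density,
    base_energy_density,
    det33,
)

__all__ = [
    "SystemState",
    "SolverConfig",
    "DeformationMeasures",
    "DirichletBC",
    "NonConvergenceError",
    "ElementInversionError",
    "fixed_end_dirichlet",
    "face_dirichlet",
    "deformation_measures",
    "assemble",
    "internal_forces",
    "internal_energy",
    "newton_solve",
    "kappa_continuation_solve",
    "run_activation_ramp",
    "apply_length_change",
    "external_force_vector",
    "save_states",
    "load_states",
]

logger = logging.getLogger(__name__)

_CSTEP = 1e-100  # complex-step size; no subtractive cancellation, so tiny is safe


@dataclass
class SolverConfig:
    """Newton/ramp settings.  ``newton_tol`` is a residual norm in newtons."""

    newton_tol: float = 1e-8
    max_newton_iters: int = 30
    ramp_steps: int = 10
    line_search: bool = True
    max_backtracks: int = 15

    def __post_init__(self):
        if self.ramp_steps < 1:
            raise ValueError("ramp_steps must be >= 1")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")


@dataclass
class SystemState:
    """Converged (or last attempted) state of the three-field problem."""

    u: np.ndarray  # (n_nodes, 3) displacements, m
    p: np.ndarray  # (n_elems,) element pressures, Pa
    J_field: np.ndarray  # (n_elems,) element dilations
    activation: float
    converged: bool = True
    residual_norm: float = 0.0
    newton_iters: int = 0

    @classmethod
    def reference(cls, mesh: HexMesh) -> "SystemState":
        return cls(
            u=np.zeros((mesh.n_nodes, 3)),
            p=np.zeros(mesh.n_elems),
            J_field=np.ones(mesh.n_elems),
            activation=0.0,
        )


@dataclass
class DeformationMeasures:
    """Kinematic quantities at every quadrature point (arrays shaped (ne, 8, ...))."""

    F: np.ndarray
    C: np.ndarray
    J_det: np.ndarray
    lambda_tot: np.ndarray
    beta: np.ndarray  # degrees, in [0, 90]


class NonConvergenceError(RuntimeError):
    """Newton failed; carries the last converged states of the protocol."""

    def __init__(self, message: str, last_states: list | None = None, last_activation: float | None = None):
        super().__init__(message)
        self.last_states = last_states or []
        self.last_activation = last_activation


@dataclass(frozen=True)
class DirichletBC:
    """Prescribed displacement dofs (global dof ids) and their values."""

    dofs: np.ndarray
    values: np.ndarray

    def merge(self, other: "DirichletBC") -> "DirichletBC":
        dofs = np.concatenate([self.dofs, other.dofs])
        vals = np.concatenate([self.values, other.values])
        # later entries win on duplicates
        _, idx = np.unique(dofs[::-1], return_index=True)
        idx = len(dofs) - 1 - idx
        return DirichletBC(dofs[idx], vals[idx])


def face_dirichlet(mesh: HexMesh, face: str, axes=(0, 1, 2), u: np.ndarray | None = None) -> DirichletBC:
    """Constrain ``axes`` of all nodes of a face set, at 0 or at current ``u``."""
    nodes = mesh.face_nodes(face)
    dofs, vals = [], []
    for ax in axes:
        dofs.append(3 * nodes + ax)
        vals.append(np.zeros(len(nodes)) if u is None else u[nodes, ax])
    return DirichletBC(np.concatenate(dofs), np.concatenate(vals))


def fixed_end_dirichlet(mesh: HexMesh, u: np.ndarray | None = None) -> DirichletBC:
    """Both x-faces fully constrained in all three directions."""
    return face_dirichlet(mesh, "-x", u=u).merge(face_dirichlet(mesh, "+x", u=u))


# ---------------------------------------------------------------------------
# kinematics and element-level residual
# ---------------------------------------------------------------------------


def _gradients(mesh: HexMesh, u_e: np.ndarray):
    """Deformation gradient at all quadrature points from element displacements."""
    q = mesh.quadrature()
    gradu = np.einsum("eqaj,eai->eqij", q["dNdX"], u_e)
    F = gradu.copy()
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    F[..., 2, 2] += 1.0
    return F


def deformation_measures(mesh: HexMesh, fibres: FibreField, u: np.ndarray) -> DeformationMeasures:
    """F, C, det F, fibre stretch and 3D pennation angle at every quadrature point.

    The pennation angle is the 3D angle between the deformed fibre direction
    ``F a0`` and the x-axis, in degrees.
    """
    u_e = u[mesh.elems]
    F = _gradients(mesh, u_e)
    J = det33(F)
    if np.any(J <= 0):
        e, qp = np.argwhere(J <= 0)[0]
        raise ElementInversionError(f"inverted element {e} at quadrature point {qp}")
    C = np.einsum("eqki,eqkj->eqij", F, F)
    lam = np.sqrt(np.einsum("eqi,eqij,eqj->eq", fibres.a0, C, fibres.a0))
    v = np.einsum("eqij,eqj->eqi", F, fibres.a0)
    beta = np.degrees(np.arccos(np.clip(np.abs(v[..., 0]) / np.linalg.norm(v, axis=-1), 0.0, 1.0)))
    return DeformationMeasures(F=F, C=C, J_det=J, lambda_tot=lam, beta=beta)


def _element_internal(mesh: HexMesh, fibres: FibreField, material: TissueMaterial, u_e: np.ndarray, activation: float):
    """Element internal force array (ne, 8, 3) plus condensed (J, J_bar, p).

    Works for real or complex ``u_e`` (complex-step differentiation).
    """
    q = mesh.quadrature()
    w, detJ0 = q["weights"], q["detJ0"]
    F = _gradients(mesh, u_e)
    J = det33(F)
    if np.any(J.real <= 0):
        raise ElementInversionError("inverted element during assembly")
    V0e = np.einsum("q,eq->e", w, detJ0)
    J_bar = np.einsum("q,eq,eq->e", w, detJ0, J) / V0e
    p = material.vol.denergy(J_bar)  # kappa (J_bar - 1)
    S = pk2_stress_components(F, p[:, None], fibres.a0, activation, material)["total"]
    P = np.einsum("eqik,eqkj->eqij", F, S)  # first Piola-Kirchhoff
    f = np.einsum("eqij,eqaj,q,eq->eai", P, q["dNdX"], w, detJ0)
    return f, J, J_bar, p


def internal_forces(mesh, fibres, material, u, activation):
    """Assembled global internal force vector (3*n_nodes,) and (J_bar, p)."""
    u_e = u[mesh.elems]
    f_e, _, J_bar, p = _element_internal(mesh, fibres, material, u_e, activation)
    f = np.zeros(3 * mesh.n_nodes)
    np.add.at(f, (3 * mesh.elems[:, :, None] + np.arange(3)).ravel(), f_e.ravel())
    return f, J_bar, p


def internal_energy(mesh, fibres, material, u, activation) -> float:
    """Total internal strain energy U_int (J) at displacement ``u``.

    The mixed term ``p (J - J_bar)`` integrates to zero element-wise for the
    mean-dilatation condensation, so U_int is the sum of fibre, base and
    volumetric energies alone.
    """
    meas = deformation_measures(mesh, fibres, u)
    q = mesh.quadrature()
    w, detJ0 = q["weights"], q["detJ0"]
    V0e = np.einsum("q,eq->e", w, detJ0)
    J_bar = np.einsum("q,eq,eq->e", w, detJ0, meas.J_det) / V0e
    lam_bar = meas.J_det ** (-1.0 / 3.0) * meas.lambda_tot
    psi_a, psi_p = fibre_energy_density(lam_bar, activation, material)
    i1_bar = meas.J_det ** (-2.0 / 3.0) * np.einsum("eqii->eq", meas.C)
    psi_b = base_energy_density(i1_bar, material)
    U_fib = np.einsum("q,eq,eq->", w, detJ0, psi_a + psi_p + psi_b)
    U_vol = float(np.sum(material.vol.energy(J_bar) * V0e))
    return float(U_fib) + U_vol


def external_force_vector(mesh: HexMesh, tractions: dict[str, np.ndarray] | None) -> np.ndarray:
    """Consistent nodal forces for dead nominal tractions (Pa) on face sets.

    The traction is per unit *reference* area, so the load vector is constant.
    """
    f = np.zeros(3 * mesh.n_nodes)
    if not tractions:
        return f
    # 2x2 Gauss on the reference quad
    g = 1.0 / np.sqrt(3.0)
    qp2 = np.array([[-g, -g], [g, -g], [g, g], [-g, g]])
    s2 = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    N2 = np.stack([(1 + qp2[:, 0, None] * s2[:, 0]) * (1 + qp2[:, 1, None] * s2[:, 1]) / 4.0])[0]  # (4qp, 4a)
    dN2 = np.empty((4, 4, 2))
    dN2[..., 0] = s2[:, 0] / 4.0 * (1 + qp2[:, 1, None] * s2[:, 1])
    dN2[..., 1] = s2[:, 1] / 4.0 * (1 + qp2[:, 0, None] * s2[:, 0])
    for face, t in tractions.items():
        t = np.asarray(t, dtype=float)
        quads = mesh.face_sets[face]
        Xq = mesh.nodes[quads]  # (nq, 4a, 3)
        tang = np.einsum("qad,nai->nqdi", dN2, Xq)  # (nq, 4qp, 2, 3)
        nvec = np.cross(tang[:, :, 0, :], tang[:, :, 1, :])
        dA = np.linalg.norm(nvec, axis=-1)  # (nq, 4qp)
        fq = np.einsum("qa,nq,i->nai", N2, dA, t)  # weight 1 each
        np.add.at(f, (3 * quads[:, :, None] + np.arange(3)).ravel(), fq.ravel())
    return f


def assemble(state: SystemState, mesh: HexMesh, fibres: FibreField, material: TissueMaterial,
             tractions: dict[str, np.ndarray] | None = None):
    """Global residual vector and consistent tangent matrix at ``state``.

    The residual is the discrete first variation of ``E_tot`` in ``u`` after
    static condensation of the element pressure and dilation; the tangent is
    its exact derivative, assembled per element by complex step.
    """
    R, J_bar, p = internal_forces(mesh, fibres, material, state.u, state.activation)
    R -= external_force_vector(mesh, tractions)
    K = _tangent(mesh, fibres, material, state.u, state.activation)
    return R, K


def _tangent(mesh, fibres, material, u, activation) -> sp.csr_matrix:
    u_e = u[mesh.elems].astype(complex)
    ne = mesh.n_elems
    K_e = np.empty((ne, 24, 24))
    for col in range(24):
        a, i = divmod(col, 3)
        u_pert = u_e.copy()
        u_pert[:, a, i] += 1j * _CSTEP
        f_e, *_ = _element_internal(mesh, fibres, material, u_pert, activation)
        K_e[:, :, col] = f_e.reshape(ne, 24).imag / _CSTEP
    edof = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(ne, 24)
    rows = np.broadcast_to(edof[:, :, None], (ne, 24, 24)).ravel()
    cols = np.broadcast_to(edof[:, None, :], (ne, 24, 24)).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_matrix((K_e.ravel(), (rows, cols)), shape=(n, n)).tocsr()


# ---------------------------------------------------------------------------
# Newton solver
# ---------------------------------------------------------------------------


def newton_solve(mesh, fibres, material, bcs: DirichletBC, activation: float,
                 u0: np.ndarray | None = None, tractions=None,
                 config: SolverConfig | None = None) -> SystemState:
    """Solve the condensed equilibrium at a fixed activation level.

    Dirichlet values are imposed exactly before the first iteration; Newton
    updates then act on the free dofs only, with backtracking line search on
    the residual norm.
    """
    config = config or SolverConfig()
    n = 3 * mesh.n_nodes
    u = np.zeros((mesh.n_nodes, 3)) if u0 is None else u0.copy()
    u.reshape(-1)[bcs.dofs] = bcs.values
    free = np.setdiff1d(np.arange(n), bcs.dofs)
    f_ext = external_force_vector(mesh, tractions)

    def residual(u_flat):
        f, J_bar, p = internal_forces(mesh, fibres, material, u_flat.reshape(-1, 3), activation)
        return f - f_ext, J_bar, p

    R, J_bar, p = residual(u.reshape(-1))
    norm = np.linalg.norm(R[free])
    it = 0
    while norm > config.newton_tol:
        if it >= config.max_newton_iters:
            raise NonConvergenceError(
                f"Newton did not converge at activation {activation:.3f} "
                f"(residual {norm:.3e} N after {it} iterations)")
        K = _tangent(mesh, fibres, material, u.reshape(-1, 3), activation)
        du = np.zeros(n)
        du[free] = spla.spsolve(K[np.ix_(free, free)].tocsc(), -R[free])
        alpha, accepted = 1.0, False
        for _ in range(config.max_backtracks if config.line_search else 1):
            u_try = u.reshape(-1) + alpha * du
            try:
                R_try, J_bar, p = residual(u_try)
            except ElementInversionError:
                alpha *= 0.5
                continue
            norm_try = np.linalg.norm(R_try[free])
            if norm_try < norm or not config.line_search:
                u = u_try.reshape(-1, 3)
                R, norm = R_try, norm_try
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            raise NonConvergenceError(
                f"line search failed at activation {activation:.3f} (residual {norm:.3e} N)")
        it += 1
        logger.debug("newton: a=%.3f iter=%d residual=%.3e N", activation, it, norm)
    return SystemState(u=u, p=p, J_field=J_bar, activation=activation,
                       converged=True, residual_norm=float(norm), newton_iters=it)


def run_activation_ramp(mesh, fibres, material, config: SolverConfig | None = None,
                        bcs: DirichletBC | None = None, a_max: float = 1.0,
                        initial_state: SystemState | None = None,
                        tractions=None) -> list[SystemState]:
    """Quasi-static activation ramp 0 -> ``a_max`` in ``ramp_steps`` steps.

    Default boundary conditions are fixed ends (both x-faces fully clamped).
    Returns one converged state per ramp step; on Newton failure raises
    :class:`NonConvergenceError` carrying the states converged so far.
    """
    config = config or SolverConfig()
    if bcs is None:
        bcs = fixed_end_dirichlet(mesh)
    states: list[SystemState] = []
    u = initial_state.u.copy() if initial_state is not None else None
    levels = np.linspace(0.0, a_max, config.ramp_steps + 1)[1:]
    for a in levels:
        try:
            st = newton_solve(mesh, fibres, material, bcs, float(a), u0=u,
                              tractions=tractions, config=config)
        except NonConvergenceError as exc:
            last_a = states[-1].activation if states else 0.0
            logger.warning("ramp stopped at activation %.2f: %s", last_a, exc)
            raise NonConvergenceError(str(exc), last_states=states, last_activation=last_a) from exc
        logger.info("activation %.2f converged in %d iterations (residual %.2e N)",
                    a, st.newton_iters, st.residual_norm)
        states.append(st)
        u = st.u
    return states


def kappa_continuation_solve(mesh, fibres, material: TissueMaterial, activation: float,
                             bcs: DirichletBC | None = None, kappa_start: float = 1e6,
                             steps_per_decade: int = 2,
                             config: SolverConfig | None = None) -> SystemState:
    """Equilibrium at a stiff bulk modulus via continuation in kappa.

    For kappa well above ~1e8 Pa a Newton step from a distant iterate
    overshoots quadratically in the penalty term, so the solve first ramps
    activation at ``kappa_start`` and then stiffens kappa geometrically up to
    the target, re-converging (warm-started) at each level.
    """
    from dataclasses import replace as _replace

    config = config or SolverConfig()
    if bcs is None:
        bcs = fixed_end_dirichlet(mesh)
    target = material.vol.kappa
    soft = _replace(material, vol=VolumetricPenalty(min(kappa_start, target)))
    states = run_activation_ramp(mesh, fibres, soft, config=config, bcs=bcs, a_max=activation)
    st = states[-1]
    if target <= kappa_start:
        return st
    n_steps = max(1, int(np.ceil(steps_per_decade * np.log10(target / kappa_start))))
    for k in np.geomspace(kappa_start, target, n_steps + 1)[1:]:
        mk = _replace(material, vol=VolumetricPenalty(float(k)))
        st = newton_solve(mesh, fibres, mk, bcs, activation, u0=st.u, config=config)
    return st


# ---------------------------------------------------------------------------
# length-change protocol (traction then hold)
# ---------------------------------------------------------------------------


def _face_separation(mesh: HexMesh, u: np.ndarray, axis: int = 0) -> float:
    """Area-weighted mean separation of opposite faces along ``axis``."""
    from .postprocess import _face_mean_coordinate

    names = {0: ("-x", "+x"), 1: ("-y", "+y"), 2: ("-z", "+z")}[axis]
    lo = _face_mean_coordinate(mesh, u, names[0], axis)
    hi = _face_mean_coordinate(mesh, u, names[1], axis)
    return hi - lo


def apply_length_change(mesh, fibres, material, target_l_hat: float,
                        config: SolverConfig | None = None, tol: float = 1e-8) -> SystemState:
    """Passively stretch or shorten the block to a normalized length.

    A uniform nominal x-traction on the +x face (the -x face stays clamped)
    is adjusted by a secant iteration until the block length reaches
    ``target_l_hat``; the returned passive state is then meant to be *held*,
    i.e. used with :func:`fixed_end_dirichlet` (frozen face displacements)
    for a subsequent activation ramp.
    """
    if not (0.7 <= target_l_hat <= 1.3):
        raise ValueError("target normalized length must lie in [0.7, 1.3]")
    config = config or SolverConfig()
    bcs = face_dirichlet(mesh, "-x", axes=(0, 1, 2))
    L0 = _face_separation(mesh, np.zeros((mesh.n_nodes, 3)))
    if abs(target_l_hat - 1.0) < tol:
        return SystemState.reference(mesh)

    def solve(tau, u0):
        st = newton_solve(mesh, fibres, material, bcs, activation=0.0, u0=u0,
                          tractions={"+x": np.array([tau, 0.0, 0.0])}, config=config)
        return st, _face_separation(mesh, st.u) / L0

    tau0, l0 = 0.0, 1.0
    # modest initial guess from a small-strain estimate of the passive modulus
    tau1 = 1.0e5 * (target_l_hat - 1.0)
    st, l1 = solve(tau1, None)
    for _ in range(40):
        if abs(l1 - target_l_hat) < tol:
            return st
        dtau = (target_l_hat - l1) * (tau1 - tau0) / (l1 - l0)
        tau0, l0 = tau1, l1
        tau1 = tau1 + dtau
        st, l1 = solve(tau1, st.u)
    raise NonConvergenceError(f"length targeting did not converge (l_hat={l1:.6f})")


# ---------------------------------------------------------------------------
# HDF5 checkpoints
# ---------------------------------------------------------------------------


def save_states(path, states: list[SystemState]) -> None:
    """Checkpoint a sequence of states (nodal u, element p/J, activation)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i, st in enumerate(states):
            g = fh.create_group(f"state_{i:03d}")
            g.create_dataset("u", data=st.u)
            g.create_dataset("p", data=st.p)
            g.create_dataset("J", data=st.J_field)
            g.attrs["activation"] = st.activation
            g.attrs["converged"] = st.converged
            g.attrs["residual_norm"] = st.residual_norm


def load_states(path) -> list[SystemState]:
    import h5py

    states = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh):
            g = fh[key]
            states.append(SystemState(
                u=g["u"][()], p=g["p"][()], J_field=g["J"][()],
                activation=float(g.attrs["activation"]),
                converged=bool(g.attrs["converged"]),
                residual_norm=float(g.attrs["residual_norm"]),
            ))
    return states
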