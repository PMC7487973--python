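"""Constitutive laws for muscle and aponeurosis tissue.

Both tissues are fibre-reinforced, transversely isotropic and nearly
incompressible.  The strain-energy density at a material point splits into
four additive components:

* **active fibre** -- Hill-type contractile element.  The nominal (first
  Piola-Kirchhoff) fibre stress is ``sigma_max * a * f_act(lambda)`` where
  ``a`` is the activation level and ``f_act`` a force--length curve peaking
  at 1 for the optimal stretch ``lambda = 1``.  Its energy density is the
  path integral of the nominal stress from ``lambda = 1``, hence *negative*
  when the fibres shorten below optimal length.
* **passive fibre** -- parallel elastic element (titin-like), zero in
  compression, stiffening in tension.
* **base material** -- isotropic cubic Yeoh law on the isochoric invariant
  ``I1_bar = J^(-2/3) tr C``, representing intra/extracellular tissue.
* **volumetric** -- quadratic penalty ``(kappa/2) (J-1)^2`` on the dilation.

All functions are ``numpy``-vectorised and accept complex input so that the
assembly code can differentiate element residuals by complex step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "FibreForceLengthCurves",
    "YeohCoefficients",
    "VolumetricPenalty",
    "TissueMaterial",
    "eval_fibre_stress",
    "fibre_energy_density",
    "base_energy_density",
    "volumetric_energy_density",
    "pk2_stress_components",
    "fit_yeoh_uniaxial",
    "MUSCLE_BASE_CONTROL_POINTS",
    "APONEUROSIS_BASE_CONTROL_POINTS",
]

_I1_TOL = 1e-9


def _real(x):
    """Branch-selection helper: piecewise masks use the real part so that
    complex-step perturbations never switch branches."""
    return np.real(np.asarray(x))


# ---------------------------------------------------------------------------
# fibre force-length curves
# ---------------------------------------------------------------------------

# Active curve: raised-cosine ascending limb on [0.5, 0.95], plateau at 1 on
# [0.95, 1.05], raised-cosine descending limb on [1.05, 1.6].  Continuously
# differentiable, exactly 1 at lambda = 1.  The plateau around optimal length
# and the steeper ascent than descent follow published mammalian (rabbit)
# force-length data; the original trigonometric-polynomial coefficients are
# unpublished, so this shape is the package's own documented fit (synthetic
# digitisation).
_ACT_LO, _ACT_P0, _ACT_P1, _ACT_HI = 0.5, 0.95, 1.05, 1.6

# Passive muscle curve: quadratic toe from lambda=1 to the toe end, then a C1
# linear continuation.  Normalised passive stress reaches 0.5 at lambda=1.4
# and 1.0 at lambda=1.6, in line with rabbit passive data.
_PAS_MUSCLE_TOE_END = 1.4
_PAS_MUSCLE_A = 3.125  # 0.5 / (0.4)^2

# Aponeurosis passive fibres are tendon-like collagen: short toe region then
# a steep linear branch (normalised slope ~ E_tendon / sigma_max).
_PAS_APO_TOE_END = 1.03
_PAS_APO_A = 66666.666666666664  # slope 4000 at toe end


def _active_muscle(lam):
    lam = np.asarray(lam)
    lr = _real(lam)
    wa = _ACT_P0 - _ACT_LO
    wd = _ACT_HI - _ACT_P1
    out = np.zeros_like(lam)
    asc = (lr >= _ACT_LO) & (lr < _ACT_P0)
    plat = (lr >= _ACT_P0) & (lr <= _ACT_P1)
    dsc = (lr > _ACT_P1) & (lr <= _ACT_HI)
    out = np.where(asc, 0.5 * (1.0 - np.cos(np.pi * (lam - _ACT_LO) / wa)), out)
    out = np.where(plat, np.ones_like(lam), out)
    out = np.where(dsc, 0.5 * (1.0 + np.cos(np.pi * (lam - _ACT_P1) / wd)), out)
    return out


def _active_muscle_integral(lam):
    """Closed-form path integral of the active curve from lambda = 1."""
    lam = np.asarray(lam)
    lr = _real(lam)
    wa = _ACT_P0 - _ACT_LO
    wd = _ACT_HI - _ACT_P1
    # clip outside each piece: the integral continues affinely/constantly, and
    # clipping to a real constant kills complex-step derivatives, as it must
    lam_a = np.where((lr >= _ACT_LO) & (lr <= _ACT_P0), lam, np.clip(lr, _ACT_LO, _ACT_P0))
    lam_p = np.where((lr >= _ACT_P0) & (lr <= _ACT_P1), lam, np.clip(lr, _ACT_P0, _ACT_P1))
    lam_d = np.where((lr >= _ACT_P1) & (lr <= _ACT_HI), lam, np.clip(lr, _ACT_P1, _ACT_HI))
    # antiderivative of each limb, measured from the nearer plateau edge
    A_asc = 0.5 * ((lam_a - _ACT_P0) - (wa / np.pi) * np.sin(np.pi * (lam_a - _ACT_LO) / wa))
    A_dsc = 0.5 * ((lam_d - _ACT_P1) + (wd / np.pi) * np.sin(np.pi * (lam_d - _ACT_P1) / wd))
    below = A_asc + (_ACT_P0 - 1.0)
    above = A_dsc + (_ACT_P1 - 1.0)
    mid = lam_p - 1.0
    return np.where(lr < _ACT_P0, below, np.where(lr > _ACT_P1, above, mid))


def _passive_piecewise(lam, toe_end, a_coef):
    lam = np.asarray(lam)
    lr = _real(lam)
    toe = (lr > 1.0) & (lr <= toe_end)
    lin = lr > toe_end
    dt = toe_end - 1.0
    slope = 2.0 * a_coef * dt
    out = np.zeros_like(lam)
    out = np.where(toe, a_coef * (lam - 1.0) ** 2, out)
    out = np.where(lin, a_coef * dt**2 + slope * (lam - toe_end), out)
    return out


def _passive_piecewise_integral(lam, toe_end, a_coef):
    lam = np.asarray(lam)
    lr = _real(lam)
    dt = toe_end - 1.0
    slope = 2.0 * a_coef * dt
    lam_t = np.where((lr > 1.0) & (lr <= toe_end), lam, np.clip(lr, 1.0, toe_end))
    out = a_coef * (lam_t - 1.0) ** 3 / 3.0
    lin = lr > toe_end
    out = np.where(
        lin,
        a_coef * dt**3 / 3.0 + a_coef * dt**2 * (lam - toe_end) + 0.5 * slope * (lam - toe_end) ** 2,
        out,
    )
    return out


def _zero_curve(lam):
    return np.zeros_like(np.asarray(lam))


@dataclass(frozen=True)
class FibreForceLengthCurves:
    """Normalised active and passive fibre curves (peak active stress = 1).

    ``active_curve(1.0) == 1.0`` exactly; the active response vanishes outside
    ``active_support``.  The passive curve is zero for ``lambda <= 1`` and C1
    at its piecewise joins.  ``*_integral`` return the closed-form path
    integrals from ``lambda = 1`` used by the energy densities.
    """

    active_curve: Callable = field(repr=False)
    passive_curve: Callable = field(repr=False)
    active_integral: Callable = field(repr=False)
    passive_integral: Callable = field(repr=False)
    active_support: tuple[float, float] = (_ACT_LO, _ACT_HI)

    @classmethod
    def muscle(cls) -> "FibreForceLengthCurves":
        return cls(
            active_curve=_active_muscle,
            passive_curve=lambda lam: _passive_piecewise(lam, _PAS_MUSCLE_TOE_END, _PAS_MUSCLE_A),
            active_integral=_active_muscle_integral,
            passive_integral=lambda lam: _passive_piecewise_integral(lam, _PAS_MUSCLE_TOE_END, _PAS_MUSCLE_A),
        )

    @classmethod
    def aponeurosis(cls) -> "FibreForceLengthCurves":
        """Tendon-like passive collagen fibres; no active response."""
        return cls(
            active_curve=_zero_curve,
            passive_curve=lambda lam: _passive_piecewise(lam, _PAS_APO_TOE_END, _PAS_APO_A),
            active_integral=_zero_curve,
            passive_integral=lambda lam: _passive_piecewise_integral(lam, _PAS_APO_TOE_END, _PAS_APO_A),
            active_support=(1.0, 1.0),
        )


# ---------------------------------------------------------------------------
# base material (Yeoh) and volumetric penalty
# ---------------------------------------------------------------------------

# Digitised control points for the across-fibre tensile response used to fit
# the Yeoh coefficients: (stretch, nominal stress in Pa).  These are a
# synthetic digitisation of published across-fibre tension data for skeletal
# muscle (stiff, J-shaped response) and for aponeurosis transverse loading.
MUSCLE_BASE_CONTROL_POINTS = np.array(
    [[1.05, 4e3], [1.10, 12e3], [1.15, 25e3], [1.20, 45e3], [1.25, 72e3], [1.30, 110e3]]
)
APONEUROSIS_BASE_CONTROL_POINTS = np.array(
    [[1.02, 20e3], [1.05, 90e3], [1.08, 250e3], [1.10, 450e3]]
)

# Frozen NNLS fits of the cubic Yeoh form to the control points above
# (see fit_yeoh_uniaxial; a regression test re-runs the fit).
_MUSCLE_YEOH = (14440.525, 138255.041, 0.0)
_APONEUROSIS_YEOH = (1.6176334e5, 9.6550305e6, 4.8772859e7)


def fit_yeoh_uniaxial(points: np.ndarray) -> tuple[float, float, float]:
    """Non-negative least-squares fit of cubic Yeoh coefficients to uniaxial
    incompressible nominal stress--stretch control points ``(lambda, P)``.

    P(lambda) = 2 (lambda - lambda^-2) (c1 + 2 c2 x + 3 c3 x^2),
    x = lambda^2 + 2/lambda - 3.
    """
    from scipy.optimize import nnls

    lam = np.asarray(points)[:, 0]
    sig = np.asarray(points)[:, 1]
    x = lam**2 + 2.0 / lam - 3.0
    g = 2.0 * (lam - lam**-2)
    design = np.column_stack([g, 2 * g * x, 3 * g * x**2])
    coefs, _ = nnls(design, sig)
    return tuple(float(c) for c in coefs)


@dataclass(frozen=True)
class YeohCoefficients:
    """Cubic Yeoh law ``psi = sum_i c_i (I1_bar - 3)^i`` (coefficients in Pa)."""

    c1: float
    c2: float
    c3: float

    def __post_init__(self):
        if min(self.c1, self.c2, self.c3) < 0:
            raise ValueError("Yeoh coefficients must be non-negative")

    def energy(self, i1_bar):
        x = np.asarray(i1_bar) - 3.0
        return self.c1 * x + self.c2 * x**2 + self.c3 * x**3

    def denergy(self, i1_bar):
        """d psi / d I1_bar."""
        x = np.asarray(i1_bar) - 3.0
        return self.c1 + 2.0 * self.c2 * x + 3.0 * self.c3 * x**2


@dataclass(frozen=True)
class VolumetricPenalty:
    """Quadratic near-incompressibility penalty ``U(J) = (kappa/2)(J-1)^2``."""

    kappa: float = 1e6

    def energy(self, J):
        return 0.5 * self.kappa * (np.asarray(J) - 1.0) ** 2

    def denergy(self, J):
        return self.kappa * (np.asarray(J) - 1.0)


@dataclass(frozen=True)
class TissueMaterial:
    """All constitutive parameters of one tissue.

    ``s_base`` scales only the Yeoh (base-material) energy; aponeurosis has a
    zero active response (collagen fibres are purely passive).
    """

    kind: str
    sigma_max: float
    fibre_curves: FibreForceLengthCurves
    yeoh: YeohCoefficients
    vol: VolumetricPenalty
    s_base: float = 1.0

    def __post_init__(self):
        if self.kind not in ("muscle", "aponeurosis"):
            raise ValueError(f"unknown tissue kind {self.kind!r}")
        if self.s_base <= 0:
            raise ValueError("s_base must be positive")

    @classmethod
    def muscle(cls, sigma_max: float = 200e3, kappa: float = 1e6, s_base: float = 1.0) -> "TissueMaterial":
        return cls(
            kind="muscle",
            sigma_max=sigma_max,
            fibre_curves=FibreForceLengthCurves.muscle(),
            yeoh=YeohCoefficients(*_MUSCLE_YEOH),
            vol=VolumetricPenalty(kappa),
            s_base=s_base,
        )

    @classmethod
    def aponeurosis(cls, sigma_max: float = 200e3, kappa: float = 1e8, s_base: float = 1.0) -> "TissueMaterial":
        return cls(
            kind="aponeurosis",
            sigma_max=sigma_max,
            fibre_curves=FibreForceLengthCurves.aponeurosis(),
            yeoh=YeohCoefficients(*_APONEUROSIS_YEOH),
            vol=VolumetricPenalty(kappa),
            s_base=s_base,
        )

    def with_s_base(self, s_base: float) -> "TissueMaterial":
        return replace(self, s_base=s_base)

    @classmethod
    def from_config(cls, cfg: dict) -> "TissueMaterial":
        """Build a material from a flat key/value mapping (e.g. parsed TOML).

        Recognised keys: kind, sigma_max, kappa, s_base, yeoh = [c1, c2, c3].
        """
        kind = cfg.get("kind", "muscle")
        base = cls.muscle if kind == "muscle" else cls.aponeurosis
        mat = base(
            sigma_max=float(cfg.get("sigma_max", 200e3)),
            kappa=float(cfg.get("kappa", 1e6 if kind == "muscle" else 1e8)),
            s_base=float(cfg.get("s_base", 1.0)),
        )
        if "yeoh" in cfg:
            mat = replace(mat, yeoh=YeohCoefficients(*[float(c) for c in cfg["yeoh"]]))
        return mat


# ---------------------------------------------------------------------------
# scalar constitutive operations
# ---------------------------------------------------------------------------


def _check_stretch(lambda_tot):
    lr = _real(lambda_tot)
    if not np.all(np.isfinite(lr)) or np.any(lr <= 0):
        raise ValueError("fibre stretch must be finite and positive")


def _check_activation(activation):
    a = np.asarray(activation, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("activation must lie in [0, 1]")


def eval_fibre_stress(lambda_tot, activation, material: TissueMaterial):
    """Nominal (first Piola-Kirchhoff) fibre stress in Pa.

    ``sigma_max * (a * f_act(lambda) + f_pass(lambda))``; the active term is
    identically zero for aponeurosis.
    """
    _check_stretch(lambda_tot)
    _check_activation(activation)
    c = material.fibre_curves
    return material.sigma_max * (np.asarray(activation) * c.active_curve(lambda_tot) + c.passive_curve(lambda_tot))


def fibre_energy_density(lambda_tot, activation, material: TissueMaterial):
    """(psi_active, psi_passive) in J/m^3, path integrals from lambda = 1.

    psi_active is signed: negative when the fibres have shortened below
    optimal length (energies are relative to the undeformed state).
    """
    _check_stretch(lambda_tot)
    _check_activation(activation)
    c = material.fibre_curves
    psi_a = material.sigma_max * np.asarray(activation) * c.active_integral(lambda_tot)
    psi_p = material.sigma_max * c.passive_integral(lambda_tot)
    return psi_a, psi_p


def base_energy_density(i1_bar, material: TissueMaterial):
    """Base-material (Yeoh) energy density ``s_base * sum c_i (I1_bar-3)^i``."""
    if np.any(_real(i1_bar) < 3.0 - _I1_TOL):
        raise ValueError("I1_bar < 3 is unattainable for unit-determinant tensors")
    return material.s_base * material.yeoh.energy(i1_bar)


class ElementInversionError(ValueError):
    """Raised when det F <= 0 (inverted element / invalid dilation)."""


def volumetric_energy_density(J, material: TissueMaterial):
    """Volumetric penalty energy ``(kappa/2)(J-1)^2``."""
    if np.any(_real(J) <= 0):
        raise ElementInversionError("dilation J must be positive")
    return material.vol.energy(J)


# ---------------------------------------------------------------------------
# tensor algebra helpers (vectorised, complex-safe)
# ---------------------------------------------------------------------------


def det33(A):
    """Determinant of (...,3,3) arrays, closed form (complex-safe)."""
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def inv33(A, det=None):
    """Inverse of (...,3,3) arrays via the adjugate (complex-safe)."""
    if det is None:
        det = det33(A)
    adj = np.empty_like(A)
    adj[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    adj[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    adj[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    adj[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    adj[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    adj[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    adj[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    adj[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    adj[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return adj / det[..., None, None]


def pk2_stress_components(F, p, a0, activation, material: TissueMaterial):
    """Second Piola-Kirchhoff stress, split by energy component.

    Parameters
    ----------
    F : (...,3,3) deformation gradient (det F > 0)
    p : (...) pressure conjugate to the dilation (Pa); the volumetric
        component is ``p J C^{-1}`` of the mixed formulation
    a0 : (...,3) unit reference fibre direction
    activation : scalar or (...) activation fraction

    Returns
    -------
    dict with keys ``active``, ``passive``, ``base``, ``volumetric``,
    ``total`` mapping to (...,3,3) PK2 tensors.  Each component is the
    derivative of its energy term with respect to the Green-Lagrange strain.
    Fibre and base energies act on isochoric deformation measures (isochoric
    fibre stretch and ``I1_bar``), so those components are deviatoric in
    Cauchy terms; the volumetric component ``p J C^{-1}`` of the mixed
    formulation carries all hydrostatic stress.
    """
    F = np.asarray(F)
    a0 = np.asarray(a0)
    p = np.asarray(p)
    J = det33(F)
    if np.any(_real(J) <= 0):
        raise ElementInversionError("det F must be positive")
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cinv = inv33(C, det=J**2)
    lam = np.sqrt(np.einsum("...i,...ij,...j->...", a0, C, a0))
    _check_activation(activation)

    curves = material.fibre_curves
    aa = np.einsum("...i,...j->...ij", a0, a0)
    act = np.asarray(activation)
    # fibre energies act on the isochoric stretch, so the active and passive
    # stresses are deviatoric (in Cauchy terms) and all hydrostatic stress is
    # carried by the volumetric penalty -- the decoupled treatment that makes
    # activation drive transverse expansion of nearly incompressible tissue
    lam_bar = J ** (-1.0 / 3.0) * lam
    s_act = material.sigma_max * act * curves.active_curve(lam_bar)
    s_pas = material.sigma_max * curves.passive_curve(lam_bar)
    dev_dir = aa / (lam**2)[..., None, None] - Cinv / 3.0
    S_active = (s_act * lam_bar)[..., None, None] * dev_dir
    S_passive = (s_pas * lam_bar)[..., None, None] * dev_dir

    I1 = C[..., 0, 0] + C[..., 1, 1] + C[..., 2, 2]
    Jm23 = J ** (-2.0 / 3.0)
    i1_bar = Jm23 * I1
    dpsi = material.s_base * material.yeoh.denergy(i1_bar)
    eye = np.zeros_like(C)
    eye[..., 0, 0] = eye[..., 1, 1] = eye[..., 2, 2] = 1.0
    S_base = 2.0 * (dpsi * Jm23)[..., None, None] * (eye - (I1 / 3.0)[..., None, None] * Cinv)

    S_vol = (p * J)[..., None, None] * Cinv

    total = S_active + S_passive + S_base + S_vol
    return {
        "active": S_active,
        "passive": S_passive,
        "base": S_base,
        "volumetric": S_vol,
        "total": total,
    }
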