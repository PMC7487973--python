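"""Simulation campaigns over families of muscle blocks.

The default sweep crosses initial pennation angles 0-37 degrees at the
standard 30 x 10 x 10 mm size, plus +/-15% cross-sectional-area and volume
variants at selected angles (>= 20 blocks).  Blocks with beta0 <= 5 degrees
use a base-material stiffness scale s_base = 1.5 so that the parallel-fibred
cases reach full activation; all others use s_base = 1.  The pipeline is
fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .block_geometry import BlockSpec, build_block, assign_uniform_fibres
from .constitutive import TissueMaterial
from .fem_core import SolverConfig, NonConvergenceError, run_activation_ramp, apply_length_change, fixed_end_dirichlet
from .postprocess import block_result

__all__ = [
    "SweepConfig",
    "default_sweep",
    "run_block_sweep",
    "run_length_sweep",
    "fit_linear_r2",
    "S_BASE_LOW_PENNATION",
    "LOW_PENNATION_MAX_DEG",
]

logger = logging.getLogger(__name__)

# stiffness boost needed for convergence of near-parallel-fibred blocks
S_BASE_LOW_PENNATION = 1.5
LOW_PENNATION_MAX_DEG = 5.0

STANDARD_BETA0 = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 37.0)
VARIANT_BETA0 = (0.0, 20.0, 30.0)


def s_base_for(beta0: float) -> float:
    """s_base rule of the block campaigns: 1.5 at beta0 <= 5 deg, else 1."""
    return S_BASE_LOW_PENNATION if beta0 <= LOW_PENNATION_MAX_DEG else 1.0


@dataclass
class SweepConfig:
    """Block list, material overrides and solver settings for a sweep."""

    blocks: list[BlockSpec]
    sigma_max: float = 200e3
    kappa: float = 1e6
    solver: SolverConfig = field(default_factory=SolverConfig)
    a_max: float = 1.0
    apply_s_base_rule: bool = True

    def material_for(self, beta0: float) -> TissueMaterial:
        s = s_base_for(beta0) if self.apply_s_base_rule else 1.0
        if self.apply_s_base_rule and s != 1.0:
            logger.info("beta0=%.1f deg: applying s_base=%.2f", beta0, s)
        return TissueMaterial.muscle(sigma_max=self.sigma_max, kappa=self.kappa, s_base=s)


def default_sweep(nx: int = 12, ny: int = 4, nz: int = 4) -> SweepConfig:
    """Standard-size blocks across all pennation angles plus CSA/Vol variants."""
    Lx, Ly, Lz = 0.030, 0.010, 0.010
    blocks = [BlockSpec(Lx, Ly, Lz, b, nx, ny, nz) for b in STANDARD_BETA0]
    for b in VARIANT_BETA0:
        for f in (1.15, 1.0 / 1.15):
            s = np.sqrt(f)
            # CSA variant at constant volume
            blocks.append(BlockSpec(Lx / f, Ly * s, Lz * s, b, nx, ny, nz))
            # volume variant at constant CSA
            blocks.append(BlockSpec(Lx * f, Ly, Lz, b, nx, ny, nz))
    return SweepConfig(blocks=blocks)


def _block_rows(spec: BlockSpec, states, mesh, fibres, material) -> list[dict]:
    rows = []
    for st in states:
        row = block_result(st, mesh, fibres, material).to_row()
        row.update(
            beta0=spec.beta0, Lx=spec.Lx, Ly=spec.Ly, Lz=spec.Lz,
            csa=spec.csa, volume=spec.volume, s_base=material.s_base,
            converged=st.converged,
        )
        rows.append(row)
    return rows


def run_block_sweep(config: SweepConfig) -> pd.DataFrame:
    """Fixed-end activation ramp for every block; one row per activation step.

    Per-block non-convergence is logged and recorded (rows up to the last
    converged activation), not fatal to the sweep.
    """
    frames: list[dict] = []
    for spec in config.blocks:
        mesh = build_block(spec)
        fibres = assign_uniform_fibres(mesh, spec.beta0)
        material = config.material_for(spec.beta0)
        try:
            states = run_activation_ramp(mesh, fibres, material, config=config.solver, a_max=config.a_max)
        except NonConvergenceError as exc:
            logger.warning("block beta0=%.1f: stopped at activation %.2f", spec.beta0, exc.last_activation)
            states = exc.last_states
        frames.extend(_block_rows(spec, states, mesh, fibres, material))
    return pd.DataFrame(frames)


def run_length_sweep(l_hats=None, spec: BlockSpec | None = None,
                     config: SweepConfig | None = None) -> pd.DataFrame:
    """Length-change protocol for the parallel-fibred block.

    Each target normalized length is reached passively by traction on the
    +x face, the block is then held there while activation ramps to 100%.
    Records F_x and the centre-plane stress decomposition at full activation.
    """
    from .postprocess import centre_plane_stress_decomposition

    if l_hats is None:
        l_hats = np.arange(0.8, 1.2001, 0.05)
    spec = spec or BlockSpec(beta0=0.0)
    config = config or SweepConfig(blocks=[spec], apply_s_base_rule=True)
    material = config.material_for(spec.beta0)
    mesh = build_block(spec)
    fibres = assign_uniform_fibres(mesh, spec.beta0)
    rows = []
    for l_hat in np.asarray(l_hats, dtype=float):
        pre = apply_length_change(mesh, fibres, material, l_hat, config=config.solver)
        bcs = fixed_end_dirichlet(mesh, u=pre.u)
        try:
            states = run_activation_ramp(mesh, fibres, material, config=config.solver,
                                         bcs=bcs, a_max=config.a_max, initial_state=pre)
        except NonConvergenceError as exc:
            logger.warning("l_hat=%.2f: stopped at activation %.2f", l_hat, exc.last_activation)
            states = exc.last_states
        if not states:
            continue
        final = states[-1]
        row = block_result(final, mesh, fibres, material).to_row()
        row["target_l_hat"] = float(l_hat)
        for key, val in centre_plane_stress_decomposition(final, mesh, fibres, material).items():
            row[f"stress_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def fit_linear_r2(x, y) -> float:
    """Coefficient of determination of an ordinary least-squares line."""
    from scipy.stats import linregress

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("undefined fit: x is constant")
    if np.ptp(y) == 0:
        return 0.0
    res = linregress(x, y)
    return float(res.rvalue**2)
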