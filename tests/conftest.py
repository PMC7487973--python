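"""Shared fixtures: desk-scale block simulations reused across tests.

All simulated inputs are generated programmatically; the standard block is
30 x 10 x 10 mm at 12 x 4 x 4 elements with a 10-step activation ramp, which
resolves the block forces to well under 1% of their mesh-converged values.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from myofem import (
    BlockSpec,
    TissueMaterial,
    assign_uniform_fibres,
    build_block,
    block_result,
    run_activation_ramp,
)
from myofem.experiments import s_base_for

STANDARD_BETA0 = (0, 5, 10, 15, 20, 25, 30, 37)


def standard_block(beta0: float, nx: int = 12, ny: int = 4, nz: int = 4):
    spec = BlockSpec(beta0=float(beta0), nx=nx, ny=ny, nz=nz)
    mesh = build_block(spec)
    fibres = assign_uniform_fibres(mesh, float(beta0))
    material = TissueMaterial.muscle(s_base=s_base_for(beta0))
    return mesh, fibres, material


@pytest.fixture(scope="session")
def muscle():
    return TissueMaterial.muscle()


@pytest.fixture(scope="session")
def small_block30():
    """Coarse (6x2x2) pennate block with its full-activation state."""
    mesh, fibres, material = standard_block(30, nx=6, ny=2, nz=2)
    states = run_activation_ramp(mesh, fibres, material)
    return mesh, fibres, material, states


@pytest.fixture(scope="session")
def standard_sweep():
    """Full-activation results for the standard-size blocks across beta0.

    Returns (results, elapsed_seconds) where results maps beta0 to the
    full-activation BlockResult plus its (mesh, fibres, material, state).
    """
    results = {}
    t0 = time.time()
    for b0 in STANDARD_BETA0:
        mesh, fibres, material = standard_block(b0)
        states = run_activation_ramp(mesh, fibres, material)
        results[b0] = {
            "mesh": mesh,
            "fibres": fibres,
            "material": material,
            "state": states[-1],
            "result": block_result(states[-1], mesh, fibres, material),
        }
    return results, time.time() - t0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200831)
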