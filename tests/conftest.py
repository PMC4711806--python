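"""Shared fixtures: published parameter sets and ODE oracles.

The oracles here are independent of the library's solution paths: they
integrate the raw differential equations with scipy's adaptive solvers at
tight tolerance and are used to validate both the closed-form cascade and
the compiled batch integrator.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dsbkin import reference
from dsbkin.models import RDParams, TLKParams
from dsbkin.protocols import ExposureProtocol


@pytest.fixture(scope="session")
def rd_sparse() -> RDParams:
    return reference.RD_SPARSE


@pytest.fixture(scope="session")
def tlk_sparse() -> TLKParams:
    return reference.TLK_SPARSE


@pytest.fixture(scope="session")
def rd_dense() -> RDParams:
    return reference.RD_DENSE


@pytest.fixture(scope="session")
def tlk_dense() -> TLKParams:
    return reference.TLK_DENSE


def _protocol_pieces(protocol: ExposureProtocol):
    pieces = [(s.dose_rate, s.duration) for s in protocol.segments]
    if protocol.measurement_time > 0:
        pieces.append((0.0, protocol.measurement_time))
    return pieces


def rd_oracle_total(p: RDParams, protocol: ExposureProtocol, rtol=1e-11, atol=1e-13) -> float:
    """Adaptive-ODE reference solution of the radiation-dependent system."""

    def rhs(t, y, r):
        x1, x2, x3 = y
        return [
            p.k1 * r - (p.v1 + p.q1 * r) * x1,
            p.k2 * r - (p.v2 + p.q2 * r) * x2 + p.q1 * r * x1,
            p.k3 * r + p.q2 * r * x2,
        ]

    y = [0.0, 0.0, 0.0]
    for r, dur in _protocol_pieces(protocol):
        sol = solve_ivp(rhs, (0.0, dur), y, args=(r,), method="LSODA", rtol=rtol, atol=atol)
        assert sol.success
        y = sol.y[:, -1]
    return float(sum(y))


def tlk_oracle_total(p: TLKParams, protocol: ExposureProtocol, rtol=1e-10, atol=1e-12) -> float:
    """Adaptive-ODE reference solution of the two-lesion kinetic system."""

    def rhs(t, y, r):
        x1, x2, x3 = y
        quad1 = (p.eta1 * x1 + p.eta12 * x2) * x1
        quad2 = (p.eta2 * x2 + p.eta12 * x1) * x2
        return [
            p.c1 * r - (p.epsilon1 + p.lambda1) * x1 - quad1,
            p.c2 * r - (p.epsilon2 + p.lambda2) * x2 - quad2,
            p.c3 * r + p.epsilon1 * x1 + p.epsilon2 * x2,
        ]

    y = [0.0, 0.0, 0.0]
    for r, dur in _protocol_pieces(protocol):
        sol = solve_ivp(rhs, (0.0, dur), y, args=(r,), method="LSODA", rtol=rtol, atol=atol)
        assert sol.success
        y = sol.y[:, -1]
    return float(sum(y))


def random_rd_params(rng: np.random.Generator) -> RDParams:
    """Log-uniform draws spanning the plausible magnitudes of each kind."""
    k = 10 ** rng.uniform(-4, 0, 3)
    v = 10 ** rng.uniform(-3, 1, 2)
    q = 10 ** rng.uniform(-6, -2, 2)
    return RDParams(k[0], k[1], k[2], v[0], v[1], q[0], q[1])


def random_protocol(rng: np.random.Generator) -> ExposureProtocol:
    rate = 10 ** rng.uniform(1, 4)
    dose = 10 ** rng.uniform(1, 3.4)
    t = rng.uniform(0.0, 72.0)
    if rng.random() < 0.5:
        return ExposureProtocol.single_dose(dose, rate, t)
    return ExposureProtocol.split_dose(dose, rate, rng.uniform(1.0, 48.0), rng.uniform(0.0, 24.0))
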