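"""Shared fixtures: synthetic parameter sets and random oscillator systems.

Tests use synthetic parameters throughout, so the suite verifies the model
independently of any particular amide parameterization.
"""

from __future__ import annotations

import numpy as np
import pytest

from dipolecd.chromophore import (
    ChromophorePoint, IsotropicPoint, PolarizableUnitSet,
)
from dipolecd.params import DispersiveParams, IsotropicParams, ParameterSet


@pytest.fixture
def synth_params() -> ParameterSet:
    """A synthetic parameter set; values chosen for convenience, not physics."""
    return ParameterSet(
        name="synthetic",
        dispersive=DispersiveParams(
            nu0=50000.0, D=1.0e9, theta=30.0,
            static_components=(0.5, 0.4, 0.3),
        ),
        isotropic=IsotropicParams(alphas={
            "C_aliphatic": 0.9, "O_alcohol": 0.5,
            "H_aliphatic": 0.14, "H_alcohol": 0.14, "H_amide": 0.16,
        }),
        placement="o",
        bandwidth=5000.0,
    )


def make_chromophore(position, u, nu0=50000.0, D=1.0e9, static=None):
    u = np.asarray(u, float)
    u = u / np.linalg.norm(u)
    return ChromophorePoint(
        position=np.asarray(position, float),
        u=u,
        alpha_static=np.zeros((3, 3)) if static is None else np.asarray(static),
        params=DispersiveParams(nu0=nu0, D=D, theta=0.0),
    )


def random_unit_set(
    rng: np.random.Generator,
    n_disp: int,
    n_iso: int = 0,
    box: float = 12.0,
    min_sep: float = 3.0,
    uniform_nu0: bool = False,
    with_static: bool = False,
) -> PolarizableUnitSet:
    """Random well-separated oscillator system (rejection-sampled positions)."""
    n = n_disp + n_iso
    positions = []
    while len(positions) < n:
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in positions):
            positions.append(cand)
    units = PolarizableUnitSet(p=n_disp + 1)
    for i in range(n_disp):
        u = rng.normal(size=3)
        nu0 = 50000.0 if uniform_nu0 else rng.uniform(45000.0, 58000.0)
        static = None
        if with_static:
            vals = rng.uniform(0.2, 0.8, size=3)
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            static = q @ np.diag(vals) @ q.T
        units.chromophores.append(
            make_chromophore(positions[i], u, nu0=nu0,
                             D=rng.uniform(0.5e9, 2.5e9), static=static)
        )
    for j in range(n_iso):
        units.isotropics.append(
            IsotropicPoint(position=positions[n_disp + j],
                           alpha=rng.uniform(0.3, 1.2), species="C_aliphatic")
        )
    return units


def rigid_transform(units: PolarizableUnitSet, R: np.ndarray,
                    shift: np.ndarray) -> PolarizableUnitSet:
    """Apply a proper rigid motion to every point and direction."""
    out = PolarizableUnitSet(p=units.p)
    for c in units.chromophores:
        out.chromophores.append(
            ChromophorePoint(
                position=R @ c.position + shift,
                u=R @ c.u,
                alpha_static=R @ c.alpha_static @ R.T,
                params=c.params,
            )
        )
    for a in units.isotropics:
        out.isotropics.append(
            IsotropicPoint(position=R @ a.position + shift, alpha=a.alpha,
                           species=a.species)
        )
    return out
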