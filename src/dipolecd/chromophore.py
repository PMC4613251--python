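"""Amide chromophore placement, local frames, and the polarizable unit set.

Each peptide bond is reduced to a single anisotropic point near the middle
of the N-C' bond.  The point carries one dispersive (Lorentzian) oscillator
polarized in the amide plane, plus an optional frequency-independent
residual tensor.  The local right-handed frame is

    e1 = unit(N -> C'),
    e3 = unit normal of the N-C'-O plane,
    e2 = e3 x e1   (in-plane, pointing toward the carbonyl-oxygen side),

and the oscillator direction is u = cos(theta) e1 + sin(theta) e2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, ParameterError
from .params import DispersiveParams, ParameterSet
from .structure import UnitClassification

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class AmideFrame:
    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    def rotation_matrix(self) -> np.ndarray:
        """Columns are (e1, e2, e3): maps local coordinates to lab."""
        return np.column_stack([self.e1, self.e2, self.e3])


@dataclass
class ChromophorePoint:
    position: np.ndarray
    u: np.ndarray
    alpha_static: np.ndarray      # 3x3 symmetric, lab frame, A^3
    params: DispersiveParams
    frame: AmideFrame | None = None


@dataclass
class IsotropicPoint:
    position: np.ndarray
    alpha: float
    species: str = ""


@dataclass
class PolarizableUnitSet:
    chromophores: list[ChromophorePoint] = field(default_factory=list)
    isotropics: list[IsotropicPoint] = field(default_factory=list)
    p: int = 0

    @property
    def q(self) -> int:
        return len(self.chromophores)

    def positions(self) -> np.ndarray:
        """Stacked positions, chromophores first."""
        pts = [c.position for c in self.chromophores]
        pts += [a.position for a in self.isotropics]
        return np.array(pts).reshape(-1, 3)


def place_amide_point(
    N: np.ndarray, Cprime: np.ndarray, O: np.ndarray, placement: str = "o"
) -> np.ndarray:
    """Position of the amide point for placement convention o / x / y.

    ``o`` is the midpoint of the N-C' bond; ``x`` shifts it 0.1 A along the
    bond toward the carbonyl carbon; ``y`` shifts it 0.1 A perpendicular to
    the bond, within the NC'O plane, toward the carbonyl oxygen.
    """
    N = np.asarray(N, float)
    Cprime = np.asarray(Cprime, float)
    O = np.asarray(O, float)
    bond = Cprime - N
    blen = np.linalg.norm(bond)
    normal = np.cross(bond, O - N)
    if blen < _COLLINEAR_TOL or np.linalg.norm(normal) < _COLLINEAR_TOL * blen:
        raise GeometryError("amide N, C', O atoms are collinear or coincident")
    mid = 0.5 * (N + Cprime)
    if placement == "o":
        return mid
    if placement == "x":
        return mid + 0.1 * bond / blen
    if placement == "y":
        e1 = bond / blen
        e3 = normal / np.linalg.norm(normal)
        e2 = np.cross(e3, e1)  # in-plane, toward O by construction
        return mid + 0.1 * e2
    raise ParameterError(f"unknown placement {placement!r}")


def amide_frame(
    N: np.ndarray, Cprime: np.ndarray, O: np.ndarray, placement: str = "o"
) -> AmideFrame:
    """Orthonormal right-handed local frame of one amide group."""
    N = np.asarray(N, float)
    Cprime = np.asarray(Cprime, float)
    O = np.asarray(O, float)
    origin = place_amide_point(N, Cprime, O, placement)
    bond = Cprime - N
    e1 = bond / np.linalg.norm(bond)
    normal = np.cross(bond, O - N)
    e3 = normal / np.linalg.norm(normal)
    e2 = np.cross(e3, e1)
    return AmideFrame(origin=origin, e1=e1, e2=e2, e3=e3)


def oscillator_direction(frame: AmideFrame, theta: float) -> np.ndarray:
    """In-plane unit vector at ``theta`` degrees from e1 toward e2."""
    t = np.deg2rad(theta)
    return np.cos(t) * frame.e1 + np.sin(t) * frame.e2


def euler_angles(reference: AmideFrame, other: AmideFrame) -> tuple[float, float, float]:
    """z-y-z Euler angles (degrees) of the rotation taking ``reference``
    onto ``other``, expressed in the reference frame.

    At the gimbal singularity (theta = 0 or 180) the angles are reported
    with psi = 0 and the full turn folded into phi.
    """
    rel = reference.rotation_matrix().T @ other.rotation_matrix()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        phi, theta, psi = Rotation.from_matrix(rel).as_euler("ZYZ", degrees=True)
    if abs(theta) < 1e-9 or abs(abs(theta) - 180.0) < 1e-9:
        phi, psi = phi + psi, 0.0
        phi = (phi + 180.0) % 360.0 - 180.0
    return float(phi), float(theta), float(psi)


def static_tensor_lab(frame: AmideFrame, params: DispersiveParams) -> np.ndarray:
    """Residual nondispersive amide tensor rotated into the lab frame."""
    a1, a2, a3 = params.static_components
    local = np.diag([a1, a2, a3])
    if params.static_phi:
        t = np.deg2rad(params.static_phi)
        rz = np.array([[np.cos(t), -np.sin(t), 0.0],
                       [np.sin(t), np.cos(t), 0.0],
                       [0.0, 0.0, 1.0]])
        local = rz @ local @ rz.T
    R = frame.rotation_matrix()
    return R @ local @ R.T


def build_unit_set(
    classification: UnitClassification, params: ParameterSet
) -> PolarizableUnitSet:
    """Turn a classified structure into the model's polarizable points.

    One chromophore point per amide triad (position and oscillator direction
    per the parameter set's placement and theta conventions) and one
    isotropic point per parameterized atom.
    """
    units = PolarizableUnitSet(p=classification.p)
    for triad in classification.amide_triads:
        frame = amide_frame(
            triad.n.position, triad.c.position, triad.o.position,
            placement=params.placement,
        )
        units.chromophores.append(
            ChromophorePoint(
                position=frame.origin,
                u=oscillator_direction(frame, params.dispersive.theta),
                alpha_static=static_tensor_lab(frame, params.dispersive),
                params=params.dispersive,
                frame=frame,
            )
        )
    for atom, species in classification.isotropic_atoms:
        if species not in params.isotropic:
            raise ParameterError(f"no isotropic polarizability for {species!r}")
        units.isotropics.append(
            IsotropicPoint(
                position=atom.position.copy(),
                alpha=params.isotropic[species],
                species=species,
            )
        )
    return units


def write_unit_set(units: PolarizableUnitSet, path: str | Path) -> None:
    """Dump the unit set as TSV for debugging and cross-implementation diffs."""
    lines = ["index\tkind\tx\ty\tz\tdetail"]
    for i, c in enumerate(units.chromophores):
        lines.append(
            f"{i}\tdispersive\t{c.position[0]:.6f}\t{c.position[1]:.6f}\t"
            f"{c.position[2]:.6f}\tu=({c.u[0]:.6f},{c.u[1]:.6f},{c.u[2]:.6f}) "
            f"nu0={c.params.nu0} D={c.params.D}"
        )
    for i, a in enumerate(units.isotropics):
        lines.append(
            f"{units.q + i}\tisotropic\t{a.position[0]:.6f}\t{a.position[1]:.6f}\t"
            f"{a.position[2]:.6f}\talpha={a.alpha} species={a.species}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
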