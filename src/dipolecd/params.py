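"""Polarizability parameter sets.

A parameter set couples the dispersive amide oscillator (Lorentzian
wavenumber, dipole-strength constant, in-plane polarization angle, and the
residual static polarizability of the amide point) with the scalar
polarizabilities of the nondispersive atom species, plus the chromophore
placement convention and the Lorentzian half-peak bandwidth.

Three named families ship with the package:

* ``OL`` -- general-purpose amide parameters,
* ``H``  -- parameters tuned for alpha-helical structures,
* ``J``  -- parameters tuned for polyproline-II-like structures.

All files are plain TOML and user-editable; units are commented inside each
file.  The bandwidth is the single value that may be defaulted on load
(6000 cm^-1, the bandwidth that tracks experimental far-UV band shapes most
closely); every other physics number must be present explicitly.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import ParameterError

DEFAULT_BANDWIDTH = 6000.0  # cm^-1
VALID_PLACEMENTS = ("o", "x", "y")

#: nondispersive species the model parameterizes
ISOTROPIC_SPECIES = (
    "C_aliphatic",
    "O_alcohol",
    "H_aliphatic",
    "H_alcohol",
    "H_amide",
)


@dataclass(frozen=True)
class DispersiveParams:
    """Amide pi-pi* oscillator parameters.

    nu0
        Isolated-oscillator wavenumber, cm^-1.
    D
        Dipole-strength constant of the Lorentzian polarizability,
        A^3 cm^-2 (so that D / nu0^2 is the zero-frequency polarizability
        volume contributed by the transition).
    theta
        In-plane polar angle of the oscillator axis, degrees, measured in
        the local amide frame from the N->C' direction toward the
        carbonyl-oxygen side.
    static_components
        Principal values (A^3) of the residual nondispersive polarizability
        of the amide point, along the local frame axes (e1, e2, e3).
    static_phi
        In-plane rotation (degrees, about e3) of the static principal axes
        relative to the local frame.
    """

    nu0: float
    D: float
    theta: float
    static_components: tuple[float, float, float] = (0.0, 0.0, 0.0)
    static_phi: float = 0.0

    def validate(self) -> None:
        if not self.nu0 > 0:
            raise ParameterError(f"dispersive nu0 must be > 0, got {self.nu0}")
        if not self.D > 0:
            raise ParameterError(f"dispersive D must be > 0, got {self.D}")
        if not -180.0 <= self.theta <= 180.0:
            raise ParameterError(
                f"dispersive theta must lie in [-180, 180], got {self.theta}"
            )
        if len(self.static_components) != 3:
            raise ParameterError("static_components must have three entries")
        if any(a < 0 for a in self.static_components):
            raise ParameterError(
                "static_components must be non-negative, got "
                f"{self.static_components}"
            )


@dataclass(frozen=True)
class IsotropicParams:
    """Scalar polarizabilities (A^3) for the nondispersive atom species."""

    alphas: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for species in ISOTROPIC_SPECIES:
            if species not in self.alphas:
                raise ParameterError(f"isotropic species {species!r} missing")
        for species, alpha in self.alphas.items():
            if not alpha > 0:
                raise ParameterError(
                    f"isotropic alpha for {species!r} must be > 0, got {alpha}"
                )

    def __getitem__(self, species: str) -> float:
        return self.alphas[species]

    def __contains__(self, species: str) -> bool:
        return species in self.alphas


@dataclass(frozen=True)
class ParameterSet:
    name: str
    dispersive: DispersiveParams
    isotropic: IsotropicParams
    placement: str = "o"
    bandwidth: float = DEFAULT_BANDWIDTH

    def validate(self) -> None:
        if self.placement not in VALID_PLACEMENTS:
            raise ParameterError(
                f"placement must be one of {VALID_PLACEMENTS}, got "
                f"{self.placement!r}"
            )
        if not self.bandwidth > 0:
            raise ParameterError(
                f"bandwidth must be > 0, got {self.bandwidth}"
            )
        self.dispersive.validate()
        self.isotropic.validate()


def _require(table: Mapping, key: str, where: str):
    if key not in table:
        raise ParameterError(f"required field {key!r} missing from {where}")
    return table[key]


def parameter_set_from_dict(data: Mapping, source: str = "<dict>") -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from a parsed mapping."""
    disp_tab = _require(data, "dispersive", source)
    iso_tab = _require(data, "isotropic", source)
    dispersive = DispersiveParams(
        nu0=float(_require(disp_tab, "nu0", f"{source}[dispersive]")),
        D=float(_require(disp_tab, "D", f"{source}[dispersive]")),
        theta=float(_require(disp_tab, "theta", f"{source}[dispersive]")),
        static_components=tuple(
            float(a) for a in disp_tab.get("static_components", (0.0, 0.0, 0.0))
        ),
        static_phi=float(disp_tab.get("static_phi", 0.0)),
    )
    isotropic = IsotropicParams(
        alphas={k: float(v) for k, v in iso_tab.items()}
    )
    ps = ParameterSet(
        name=str(_require(data, "name", source)),
        dispersive=dispersive,
        isotropic=isotropic,
        placement=str(data.get("placement", "o")),
        bandwidth=float(data.get("bandwidth", DEFAULT_BANDWIDTH)),
    )
    ps.validate()
    return ps


def load_parameter_set(
    path: str | Path | None = None, name: str | None = None
) -> ParameterSet:
    """Load a parameter set from a TOML file or from the bundled families.

    Exactly one of ``path`` (a user config file) or ``name`` (one of the
    bundled families ``OL`` / ``H`` / ``J``) selects the source; giving both
    loads ``path`` and renames the result.
    """
    if path is None:
        if name is None:
            raise ParameterError("either a path or a set name is required")
        key = name.lower()
        ref = resources.files("dipolecd.data").joinpath(f"{key}.toml")
        if not ref.is_file():
            raise ParameterError(f"no bundled parameter set named {name!r}")
        data = tomllib.loads(ref.read_text())
        return parameter_set_from_dict(data, source=f"bundled set {name}")
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError:
        raise ParameterError(f"parameter file not found: {path}")
    except tomllib.TOMLDecodeError as exc:
        raise ParameterError(f"cannot parse parameter file {path}: {exc}")
    ps = parameter_set_from_dict(data, source=str(path))
    if name is not None:
        ps = replace(ps, name=name)
    return ps


def save_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as TOML (round-trips through ``load``)."""
    ps.validate()
    d = ps.dispersive
    lines = [
        f'name = "{ps.name}"',
        f'placement = "{ps.placement}"',
        f"bandwidth = {ps.bandwidth!r}  # cm^-1",
        "",
        "[dispersive]",
        f"nu0 = {d.nu0!r}  # cm^-1",
        f"D = {d.D!r}  # A^3 cm^-2",
        f"theta = {d.theta!r}  # degrees from N->C' toward carbonyl O",
        f"static_components = [{d.static_components[0]!r}, "
        f"{d.static_components[1]!r}, {d.static_components[2]!r}]  # A^3",
        f"static_phi = {d.static_phi!r}  # degrees",
        "",
        "[isotropic]",
    ]
    for species, alpha in ps.isotropic.alphas.items():
        lines.append(f"{species} = {alpha!r}  # A^3")
    Path(path).write_text("\n".join(lines) + "\n")
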