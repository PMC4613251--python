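"""Comparison of calculated and experimental CD spectra.

Experimental spectra (e.g. processed synchrotron-CD exports) are two-column
text: wavelength in nm and delta-epsilon in M^-1 cm^-1.  They are linearly
interpolated onto the calculated grid, compared by the root mean square
deviation over a wavelength window (default 180-210 nm, the pi-pi* region),
and -- across a panel of proteins -- by the Spearman rank correlation of
calculated against experimental delta-epsilon at a fixed wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DipoleCDError, WindowError
from .spectra import Spectrum

DEFAULT_WINDOW = (180.0, 210.0)  # nm


@dataclass
class SpectrumPair:
    experimental: Spectrum
    calculated: Spectrum

    def __post_init__(self):
        lo = max(self.experimental.wavelength_nm[0],
                 self.calculated.wavelength_nm[0])
        hi = min(self.experimental.wavelength_nm[-1],
                 self.calculated.wavelength_nm[-1])
        if hi <= lo:
            raise WindowError("spectra have no overlapping wavelength range")


@dataclass
class ComparisonResult:
    rmsd: float                     # M^-1 cm^-1
    window: tuple[float, float]     # nm
    n_lambda: int

    def __post_init__(self):
        if self.rmsd < 0:
            raise DipoleCDError("rmsd cannot be negative")


def load_experimental(path: str | Path) -> Spectrum:
    """Two-column whitespace- or comma-separated text, ``#`` comments.

    Extra columns (as in processed databank exports) are ignored beyond the
    first two.  Rows are sorted by wavelength.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     header=None, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise DipoleCDError(f"{path}: expected two numeric columns")
    df = df.apply(pd.to_numeric, errors="coerce").dropna(subset=[0, 1])
    if df.empty:
        raise DipoleCDError(f"{path}: no numeric rows")
    df = df.sort_values(0)
    return Spectrum(
        wavelength_nm=df[0].to_numpy(float),
        epsilon=None,
        delta_epsilon=df[1].to_numpy(float),
        metadata={"source": str(path)},
    )


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid``; extrapolation is refused."""
    grid = np.asarray(grid, float)
    lam = spectrum.wavelength_nm
    if grid.min() < lam[0] or grid.max() > lam[-1]:
        raise WindowError(
            f"grid [{grid.min():g}, {grid.max():g}] nm extends beyond the "
            f"spectrum range [{lam[0]:g}, {lam[-1]:g}] nm"
        )
    eps = (np.interp(grid, lam, spectrum.epsilon)
           if spectrum.epsilon is not None else None)
    return Spectrum(
        wavelength_nm=grid,
        epsilon=eps,
        delta_epsilon=np.interp(grid, lam, spectrum.delta_epsilon),
        metadata=dict(spectrum.metadata),
    )


def rmsd(pair: SpectrumPair,
         window: tuple[float, float] = DEFAULT_WINDOW) -> ComparisonResult:
    """RMSD = sqrt( sum_i (exp(l_i) - calc(l_i))^2 / n_lambda ).

    Evaluated on the calculated grid points inside ``window``, with the
    experimental spectrum interpolated onto them.
    """
    lo, hi = min(window), max(window)
    calc = pair.calculated
    exp_lam = pair.experimental.wavelength_nm
    mask = ((calc.wavelength_nm >= lo) & (calc.wavelength_nm <= hi)
            & (calc.wavelength_nm >= exp_lam[0])
            & (calc.wavelength_nm <= exp_lam[-1]))
    if int(mask.sum()) < 2:
        raise WindowError(
            f"fewer than 2 common points in window [{lo:g}, {hi:g}] nm"
        )
    grid = calc.wavelength_nm[mask]
    exp_on_grid = resample(pair.experimental, grid).delta_epsilon
    diff = exp_on_grid - calc.delta_epsilon[mask]
    value = float(np.sqrt(np.mean(diff**2)))
    return ComparisonResult(rmsd=value, window=(lo, hi), n_lambda=int(mask.sum()))


def spearman_at_wavelength(pairs: list[SpectrumPair], lam: float) -> float:
    """Spearman rank correlation of calc vs exp delta-epsilon at one
    wavelength, across proteins (ties get averaged ranks)."""
    if len(pairs) < 3:
        raise DipoleCDError(
            f"need at least 3 spectrum pairs, got {len(pairs)}"
        )
    calc_vals, exp_vals = [], []
    for pair in pairs:
        grid = np.array([lam])
        calc_vals.append(float(resample(pair.calculated, grid).delta_epsilon[0]))
        exp_vals.append(float(resample(pair.experimental, grid).delta_epsilon[0]))
    rho = stats.spearmanr(calc_vals, exp_vals).statistic
    return float(rho)
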