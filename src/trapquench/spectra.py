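"""Spectral overlap integral J between donor emission and acceptor absorption.

For homotransfer (identical donor and acceptor) the overlap integral

    J = \\int F_em(lambda) eps(lambda) lambda^4 dlambda

with the emission spectrum area-normalized and the absorption spectrum in
molar-extinction units (M^-1 cm^-1) and wavelengths in nm gives J in
M^-1 cm^-1 nm^4 — the units consumed by the Förster-radius prefactor in
:mod:`trapquench.core`.  Quadrature is trapezoidal on the union wavelength
grid with linear interpolation between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike

__all__ = [
    "Spectrum",
    "normalize_emission",
    "overlap_integral_J",
    "make_gaussian_spectrum",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed absorption or emission curve.

    ``wavelength_nm`` must be strictly increasing; ``value`` is molar
    extinction (M^-1 cm^-1) for ``kind="absorption"`` or arbitrary units for
    ``kind="emission"`` (the overlap integral normalizes emission itself).
    """

    wavelength_nm: np.ndarray
    value: np.ndarray
    kind: str  # "absorption" | "emission"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        val = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", val)
        if self.kind not in ("absorption", "emission"):
            raise ValueError("kind must be 'absorption' or 'emission'")
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectrum needs at least 2 wavelength points")
        if val.shape != wl.shape:
            raise ValueError("wavelength and value arrays must match")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(val < 0):
            raise ValueError("spectral values must be >= 0")

    @property
    def area(self) -> float:
        """Trapezoidal integral of the curve over its grid."""
        return float(np.trapezoid(self.value, self.wavelength_nm))


def normalize_emission(s: Spectrum) -> Spectrum:
    """Rescale an emission spectrum to unit area (trapezoidal rule)."""
    if s.kind != "emission":
        raise ValueError("normalize_emission expects an emission spectrum")
    a = s.area
    if a <= 0:
        raise ValueError("cannot normalize an all-zero emission spectrum")
    return Spectrum(s.wavelength_nm, s.value / a, "emission")


def overlap_integral_J(emission: Spectrum, absorption: Spectrum) -> float:
    """Overlap integral J in M^-1 cm^-1 nm^4.

    Both spectra are linearly interpolated onto the union of their grids
    restricted to the common support; the emission curve is area-normalized
    over its *full* grid first, so rescaling the input emission leaves J
    unchanged.  Disjoint supports yield 0 with a warning.
    """
    if emission.kind != "emission" or absorption.kind != "absorption":
        raise ValueError("arguments must be (emission, absorption) spectra")
    em = normalize_emission(emission)

    lo = max(em.wavelength_nm[0], absorption.wavelength_nm[0])
    hi = min(em.wavelength_nm[-1], absorption.wavelength_nm[-1])
    if lo >= hi:
        warnings.warn("spectra have disjoint wavelength support; J = 0")
        return 0.0

    grid = np.union1d(em.wavelength_nm, absorption.wavelength_nm)
    grid = grid[(grid >= lo) & (grid <= hi)]
    f = np.interp(grid, em.wavelength_nm, em.value)
    eps = np.interp(grid, absorption.wavelength_nm, absorption.value)
    return float(np.trapezoid(f * eps * grid**4, grid))


def make_gaussian_spectrum(
    mu_nm: float,
    sigma_nm: float,
    peak: float,
    kind: str = "emission",
    grid_nm: ArrayLike | None = None,
    step_nm: float = 1.0,
    span_sigmas: float = 6.0,
) -> Spectrum:
    """Deterministic Gaussian spectral profile, for tests and synthetic runs.

    By default the grid spans ``mu +/- span_sigmas*sigma`` at ``step_nm``
    resolution; pass ``grid_nm`` for full control.
    """
    if sigma_nm <= 0:
        raise ValueError("sigma must be positive")
    if grid_nm is None:
        grid = np.arange(
            mu_nm - span_sigmas * sigma_nm,
            mu_nm + span_sigmas * sigma_nm + step_nm / 2,
            step_nm,
        )
    else:
        grid = np.asarray(grid_nm, dtype=float)
    value = peak * np.exp(-0.5 * ((grid - mu_nm) / sigma_nm) ** 2)
    return Spectrum(grid, value, kind)


def read_spectrum_csv(path: str | Path, kind: str) -> Spectrum:
    """Read a 2-column (wavelength_nm, value) CSV as a :class:`Spectrum`."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("spectrum CSV needs two columns: wavelength_nm, value")
    return Spectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), kind)


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a 2-column CSV."""
    pd.DataFrame(
        {"wavelength_nm": s.wavelength_nm, "value": s.value}
    ).to_csv(path, index=False)
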