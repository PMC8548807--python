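"""Visual-pigment and screening-pigment absorbance templates.

Rhodopsin and metarhodopsin absorbance spectra are generated from the
Govardovskii A1 nomogram: a peak-normalized alpha band parametrized only by
the peak wavelength ``lambda_max``, plus an optional Gaussian beta band in
the UV.  The perirhabdomal red screening pigment, for which no tabulated
spectrum is available, is represented by a surrogate logistic long-pass
absorbance curve: ~1 well below the half-fall wavelength, 0.5 at it, and ~0
above, so green light is blocked and red light transmitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "PigmentSpec",
    "ScreeningPigmentSpec",
    "AbsorbanceTemplate",
    "rhodopsin_template",
    "screening_template",
    "read_spectrum_table",
    "write_spectrum_table",
]

# Supported range of the A1 nomogram parametrization.
_LAMBDA_MAX_RANGE = (330.0, 700.0)

# Alpha-band constants of the A1 nomogram.
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


@dataclass(frozen=True)
class WavelengthGrid:
    """Regular wavelength grid in nm (default 300-700 nm at 1 nm)."""

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not (self.step > 0 and self.stop > self.start):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.start < 250 or self.stop > 800:
            raise ValueError("wavelength grid must lie within [250, 800] nm")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass(frozen=True)
class PigmentSpec:
    """A rhodopsin/metarhodopsin isoform pair.

    ``alpha_R`` and ``alpha_M`` are the peak absorption coefficients in
    mm^-1 of the two photo-interconvertible isoforms.
    """

    lambda_max_R: float
    lambda_max_M: float
    alpha_R: float = 6.0
    alpha_M: float = 7.5

    def __post_init__(self) -> None:
        if self.alpha_R <= 0 or self.alpha_M <= 0:
            raise ValueError("peak absorption coefficients must be > 0")

    @property
    def name(self) -> str:
        return f"R{self.lambda_max_R:g}/M{self.lambda_max_M:g}"


@dataclass(frozen=True)
class ScreeningPigmentSpec:
    """Non-bleaching perirhabdomal screening pigment.

    ``lambda_half`` is the wavelength at which absorbance has fallen to 0.5,
    ``steepness`` the logistic rate in nm^-1, ``alpha_S`` the peak absorption
    coefficient in mm^-1 and ``z_range`` the depth interval (um) over which
    the pigment is apposed to the rhabdom.
    """

    lambda_half: float = 600.0
    steepness: float = 0.05
    alpha_S: float = 10.0
    z_range: tuple[float, float] = (230.0, 420.0)

    def __post_init__(self) -> None:
        if self.alpha_S < 0:
            raise ValueError("alpha_S must be >= 0")
        if self.z_range[1] <= self.z_range[0]:
            raise ValueError("z_range must be an increasing interval")


@dataclass(frozen=True)
class AbsorbanceTemplate:
    """Relative absorbance sampled on a wavelength grid, peak-normalized."""

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.grid),):
            raise ValueError("template values do not match the grid")
        object.__setattr__(self, "values", values)

    def __call__(self, wavelength) -> np.ndarray | float:
        """Linear interpolation at arbitrary wavelengths inside the grid."""
        return np.interp(wavelength, self.grid.wavelengths, self.values)


def _alpha_band(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    x = lambda_max / wavelengths
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )


def _beta_band(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    lam_beta = 189.0 + 0.315 * lambda_max
    bandwidth = -40.5 + 0.195 * lambda_max
    return 0.26 * np.exp(-(((wavelengths - lam_beta) / bandwidth) ** 2))


def rhodopsin_template(
    lambda_max: float,
    grid: WavelengthGrid | None = None,
    include_beta_band: bool = True,
) -> AbsorbanceTemplate:
    """A1 nomogram absorbance template for a visual pigment.

    Parameters
    ----------
    lambda_max
        Peak wavelength of the alpha band, nm.  Must lie in [330, 700].
    grid
        Wavelength grid; defaults to 300-700 nm at 1 nm.
    include_beta_band
        Add the UV beta band (on by default).

    Returns
    -------
    AbsorbanceTemplate
        Peak-normalized absorbance; the maximum over the grid equals 1.
    """
    lo, hi = _LAMBDA_MAX_RANGE
    if not (lo <= lambda_max <= hi):
        raise ValueError(
            f"lambda_max={lambda_max} nm outside the supported range "
            f"[{lo:g}, {hi:g}] nm"
        )
    if grid is None:
        grid = WavelengthGrid()
    wl = grid.wavelengths
    values = _alpha_band(wl, lambda_max)
    if include_beta_band:
        values = values + _beta_band(wl, lambda_max)
    values = values / values.max()
    return AbsorbanceTemplate(grid=grid, values=values)


def screening_template(
    spec: ScreeningPigmentSpec, grid: WavelengthGrid | None = None
) -> AbsorbanceTemplate:
    """Logistic long-pass-blocking absorbance of the red screening pigment."""
    if grid is None:
        grid = WavelengthGrid()
    wl = grid.wavelengths
    values = 1.0 / (1.0 + np.exp(spec.steepness * (wl - spec.lambda_half)))
    return AbsorbanceTemplate(grid=grid, values=values)


def write_spectrum_table(path, grid: WavelengthGrid, values, value_name="value"):
    """Write a (wavelength_nm, value) delimited-text table with a header."""
    df = pd.DataFrame({"wavelength_nm": grid.wavelengths, value_name: values})
    df.to_csv(path, index=False, float_format="%.6g")


def read_spectrum_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (wavelength_nm, value) table; returns (wl, values)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("spectrum table must have two columns and a header")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
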