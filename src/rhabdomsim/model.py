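"""Longitudinal slab model of light transport in a fused rhabdom.

The rhabdom is treated as a stack of absorbing slabs.  Nine photoreceptors
(R1-R9) contribute microvilli with depth-dependent cross-section fractions
rho(z, r); each expresses one rhodopsin/metarhodopsin isoform pair whose
absorbance follows the A1 nomogram.  A non-bleaching red screening pigment
can be apposed to the rhabdom over a depth window, and the tapetum at the
base reflects the remaining light back up, doubling the light path and
producing the eyeshine.

Downwelling flux is attenuated slab by slab (Beer-Lambert), reflected at
the tapetum and propagated back up.  The bidirectional (actinic) flux
drives photoconversion between rhodopsin and metarhodopsin; the
photoequilibrium is found either by fixed-point iteration of
``f_R = k_M / (k_R + k_M)`` or by integrating the photoconversion ODE.
The converged state yields each receptor's effective (light-adapted)
spectral sensitivity via its rhodopsin quantum catch per slab.

Units: depths in um, absorption coefficients in mm^-1 (dz is converted to
mm inside the propagation so kappa*dz is dimensionless); the source flux
is normalized to 1 at every wavelength (isoquantal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .spectra import spectrum_summary
from .templates import (
    AbsorbanceTemplate,
    PigmentSpec,
    ScreeningPigmentSpec,
    WavelengthGrid,
    rhodopsin_template,
    screening_template,
)

__all__ = [
    "DepthGrid",
    "ReceptorGeometry",
    "RhabdomConfig",
    "FluxField",
    "SensitivityResult",
    "default_geometry",
    "default_config",
    "perturb_geometry",
    "absorption_coefficients",
    "propagate_flux",
    "photochemical_rates",
    "solve_equilibrium_fixed_point",
    "solve_equilibrium_ode",
    "effective_sensitivity",
    "eyeshine_spectrum",
    "sensitivity_log_ratio",
    "run_summary_table",
    "equilibrium_fraction",
    "model_target_summary",
    "dark_state",
    "ConvergenceError",
    "DEFAULT_ALPHA_S",
    "DISTAL_F_WINDOW",
    "BASAL_F_WINDOW",
    "DISTAL_CATCH_WINDOW",
    "BASAL_CATCH_WINDOW",
]

N_RECEPTORS = 9

# Peak absorption coefficient (mm^-1) of the screening pigment in the
# default red-ommatidium configuration; calibrated once so that the
# modelled R9 sensitivity peaks at 620 nm, the measured peak of the red
# opponent unit (see docs/methods.md for the calibration rationale).
DEFAULT_ALPHA_S = 20.0

# Depth windows (um) used for the distal/basal summaries.  The equilibrium
# fractions are averaged over thick distal/basal regions; the partial
# quantum catches use thin end-windows because self-screening shifts the
# catch spectrum continuously with depth (docs/methods.md).
DISTAL_F_WINDOW = (0.0, 230.0)
BASAL_F_WINDOW = (350.0, 450.0)
DISTAL_CATCH_WINDOW = (0.0, 50.0)
BASAL_CATCH_WINDOW = (350.0, 400.0)


class ConvergenceError(RuntimeError):
    """Raised when the photoequilibrium solver fails to converge."""


@dataclass(frozen=True)
class DepthGrid:
    """Slab discretisation of the rhabdom (length and dz in um)."""

    length: float = 450.0
    dz: float = 5.0

    def __post_init__(self) -> None:
        if self.dz <= 0:
            raise ValueError("dz must be > 0")
        n = self.length / self.dz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("rhabdom length must be an integral number of slabs")

    @property
    def n_slabs(self) -> int:
        return int(round(self.length / self.dz))

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_slabs) + 0.5) * self.dz

    @property
    def dz_mm(self) -> float:
        return self.dz / 1000.0


@dataclass(frozen=True)
class ReceptorGeometry:
    """Cross-section area fraction rho(z, r) of each receptor per slab."""

    depth: DepthGrid
    rho: np.ndarray = field(repr=False)  # (n_slabs, 9)

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (self.depth.n_slabs, N_RECEPTORS):
            raise ValueError("rho must have shape (n_slabs, 9)")
        if (rho < 0).any():
            raise ValueError("rho must be non-negative")
        if (rho.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("rho fractions must sum to <= 1 in every slab")
        object.__setattr__(self, "rho", rho)


def default_geometry(
    depth: DepthGrid | None = None,
    r9_window: tuple[float, float] = (400.0, 450.0),
) -> ReceptorGeometry:
    """Default microvillar cross-section profile.

    Distally (z < 250 um) R1&2 contribute 15% each and R3&4 20% each, with
    R5-8 sharing the remaining 30%.  Where R1&2 vacate the rhabdom, R3&4
    rise to 25% each and R5-8 share the other half.  The basal receptor R9
    occupies the full cross-section inside its depth window.
    """
    depth = depth or DepthGrid()
    z = depth.centers
    rho = np.zeros((depth.n_slabs, N_RECEPTORS))
    in_r9 = (z >= r9_window[0]) & (z <= r9_window[1])
    distal = z < 250.0
    rho[distal, 0] = rho[distal, 1] = 0.15
    rho[distal, 2] = rho[distal, 3] = 0.20
    rho[distal, 4:8] = 0.30 / 4
    proximal = ~distal & ~in_r9
    rho[proximal, 2] = rho[proximal, 3] = 0.25
    rho[proximal, 4:8] = 0.50 / 4
    rho[in_r9, :] = 0.0
    rho[in_r9, 8] = 1.0
    return ReceptorGeometry(depth=depth, rho=rho)


def perturb_geometry(
    geometry: ReceptorGeometry, rel: float, rng: np.random.Generator
) -> ReceptorGeometry:
    """Multiply each receptor's profile by a random factor within +-rel.

    Slabs whose perturbed fractions would exceed 1 are renormalized; used
    for robustness checks against the uncertain morphology.
    """
    factors = 1.0 + rel * rng.uniform(-1.0, 1.0, size=N_RECEPTORS)
    rho = geometry.rho * factors[None, :]
    sums = rho.sum(axis=1)
    over = sums > 1.0
    rho[over] /= sums[over, None]
    return ReceptorGeometry(depth=geometry.depth, rho=rho)


@dataclass(frozen=True)
class RhabdomConfig:
    """Complete parametrization of one model run."""

    wavelength_grid: WavelengthGrid = WavelengthGrid()
    depth: DepthGrid = DepthGrid()
    pigments: tuple[PigmentSpec, ...] = ()
    screening: ScreeningPigmentSpec | None = None
    tapetum_reflectance: float = 1.0
    source: np.ndarray | None = None  # photon flux per nm; default isoquantal 1
    geometry: ReceptorGeometry | None = None
    include_beta_band: bool = True

    def __post_init__(self) -> None:
        if len(self.pigments) != N_RECEPTORS:
            raise ValueError("exactly one PigmentSpec per receptor is required")
        if self.source is not None:
            src = np.asarray(self.source, dtype=float)
            if src.shape != (len(self.wavelength_grid),):
                raise ValueError("source spectrum does not match the grid")
            if (src < 0).any():
                raise ValueError("source flux must be non-negative")
            object.__setattr__(self, "source", src)

    @property
    def source_flux(self) -> np.ndarray:
        if self.source is None:
            return np.ones(len(self.wavelength_grid))
        return self.source

    def resolved_geometry(self) -> ReceptorGeometry:
        return self.geometry or default_geometry(self.depth)


def default_config(
    red_pigment: bool = True,
    alpha_S: float = DEFAULT_ALPHA_S,
    depth: DepthGrid | None = None,
    geometry: ReceptorGeometry | None = None,
) -> RhabdomConfig:
    """The default red-ommatidium model (or its no-red-pigment variant).

    R1/2 carry the R515/M495 isoform pair; R3-9 the main R545/M505 pair,
    with peak absorption coefficients 6 and 7.5 mm^-1.  The screening
    pigment spans 230-420 um; ``red_pigment=False`` sets its coefficient
    to zero.
    """
    green = PigmentSpec(lambda_max_R=515.0, lambda_max_M=495.0)
    lw = PigmentSpec(lambda_max_R=545.0, lambda_max_M=505.0)
    pigments = (green, green) + (lw,) * 7
    screening = ScreeningPigmentSpec(alpha_S=alpha_S if red_pigment else 0.0)
    return RhabdomConfig(
        depth=depth or DepthGrid(),
        pigments=pigments,
        screening=screening,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# internal precomputation


@dataclass(frozen=True)
class _ModelArrays:
    """Templates and geometry broadcast onto the run's grids."""

    wavelengths: np.ndarray  # (W,)
    gamma_R: np.ndarray  # (9, W)
    gamma_M: np.ndarray  # (9, W)
    alpha_R: np.ndarray  # (9,)
    alpha_M: np.ndarray  # (9,)
    rho: np.ndarray  # (Z, 9)
    kappa_screen: np.ndarray  # (Z, W) non-bleaching absorber, mm^-1
    dz_mm: float
    source: np.ndarray  # (W,)
    reflectance: float


def _prepare(config: RhabdomConfig) -> _ModelArrays:
    grid = config.wavelength_grid
    geom = config.resolved_geometry()
    if geom.depth != config.depth:
        raise ValueError("geometry and config use different depth grids")
    gamma_R = np.stack(
        [
            rhodopsin_template(p.lambda_max_R, grid, config.include_beta_band).values
            for p in config.pigments
        ]
    )
    gamma_M = np.stack(
        [
            rhodopsin_template(p.lambda_max_M, grid, config.include_beta_band).values
            for p in config.pigments
        ]
    )
    z = config.depth.centers
    kappa_screen = np.zeros((config.depth.n_slabs, len(grid)))
    if config.screening is not None and config.screening.alpha_S > 0:
        tmpl = screening_template(config.screening, grid)
        lo, hi = config.screening.z_range
        mask = (z >= lo) & (z <= hi)
        kappa_screen[mask] = config.screening.alpha_S * tmpl.values[None, :]
    return _ModelArrays(
        wavelengths=grid.wavelengths,
        gamma_R=gamma_R,
        gamma_M=gamma_M,
        alpha_R=np.array([p.alpha_R for p in config.pigments]),
        alpha_M=np.array([p.alpha_M for p in config.pigments]),
        rho=geom.rho,
        kappa_screen=kappa_screen,
        dz_mm=config.depth.dz_mm,
        source=config.source_flux,
        reflectance=config.tapetum_reflectance,
    )


def dark_state(config: RhabdomConfig) -> np.ndarray:
    """Dark-adapted pigment state: f_R = 1 in every slab and receptor."""
    return np.ones((config.depth.n_slabs, N_RECEPTORS))


def absorption_coefficients(
    f_R: np.ndarray, arrays_or_config
) -> tuple[np.ndarray, np.ndarray]:
    """Effective absorption coefficients kappa = alpha * rho * f per isoform.

    Returns (kappa_R, kappa_M), each of shape (n_slabs, 9) in mm^-1.  The
    screening pigment is handled separately as a non-bleaching absorber.
    """
    arrays = (
        arrays_or_config
        if isinstance(arrays_or_config, _ModelArrays)
        else _prepare(arrays_or_config)
    )
    f_R = np.asarray(f_R, dtype=float)
    if f_R.shape != arrays.rho.shape:
        raise ValueError("pigment state and geometry grids do not match")
    kappa_R = arrays.alpha_R[None, :] * arrays.rho * f_R
    kappa_M = arrays.alpha_M[None, :] * arrays.rho * (1.0 - f_R)
    return kappa_R, kappa_M


def _total_attenuation(arrays: _ModelArrays, kappa_R, kappa_M) -> np.ndarray:
    """Spectral attenuation coefficient c(z, lambda) in mm^-1."""
    c = (
        kappa_R @ arrays.gamma_R
        + kappa_M @ arrays.gamma_M
        + arrays.kappa_screen
    )
    return c


@dataclass(frozen=True)
class FluxField:
    """Down- and upwelling photon flux per slab and wavelength.

    ``mean_down``/``mean_up`` are the path-averaged fluxes inside each slab
    (exact for exponential attenuation); their sum is the bidirectional
    (actinic) flux that drives photoconversion.
    """

    wavelengths: np.ndarray
    down_in: np.ndarray  # (Z, W) flux entering each slab from above
    up_in: np.ndarray  # (Z, W) flux entering each slab from below
    mean_down: np.ndarray
    mean_up: np.ndarray
    exiting: np.ndarray  # (W,) upwelling flux leaving the distal face
    at_tapetum: np.ndarray  # (W,) downwelling flux reaching the tapetum
    source: np.ndarray

    @property
    def actinic(self) -> np.ndarray:
        return self.mean_down + self.mean_up

    @property
    def absorbed(self) -> np.ndarray:
        """Total absorbed flux per wavelength (both passes)."""
        lost_down = self.source - self.at_tapetum
        lost_up = self.up_in[-1] - self.exiting
        return lost_down + lost_up


def _mean_flux(flux_in: np.ndarray, transmit: np.ndarray, c_dz: np.ndarray):
    """Path-averaged flux over a slab: (I_in - I_out) / (c dz)."""
    out = flux_in * transmit
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(c_dz > 1e-12, (flux_in - out) / np.where(c_dz > 0, c_dz, 1.0), flux_in)
    return mean, out


def propagate_flux(
    config_or_arrays, f_R: np.ndarray | None = None
) -> FluxField:
    """Propagate the corneal flux down, reflect at the tapetum, and back up."""
    arrays = (
        config_or_arrays
        if isinstance(config_or_arrays, _ModelArrays)
        else _prepare(config_or_arrays)
    )
    if f_R is None:
        f_R = np.ones_like(arrays.rho)
    kappa_R, kappa_M = absorption_coefficients(f_R, arrays)
    c = _total_attenuation(arrays, kappa_R, kappa_M)  # (Z, W)
    c_dz = c * arrays.dz_mm
    transmit = np.exp(-c_dz)

    n_slabs, n_wl = c.shape
    down_in = np.empty((n_slabs, n_wl))
    up_in = np.empty((n_slabs, n_wl))
    mean_down = np.empty((n_slabs, n_wl))
    mean_up = np.empty((n_slabs, n_wl))

    flux = arrays.source.copy()
    for iz in range(n_slabs):
        down_in[iz] = flux
        mean_down[iz], flux = _mean_flux(flux, transmit[iz], c_dz[iz])
    at_tapetum = flux
    flux = arrays.reflectance * flux
    for iz in range(n_slabs - 1, -1, -1):
        up_in[iz] = flux
        mean_up[iz], flux = _mean_flux(flux, transmit[iz], c_dz[iz])
    return FluxField(
        wavelengths=arrays.wavelengths,
        down_in=down_in,
        up_in=up_in,
        mean_down=mean_down,
        mean_up=mean_up,
        exiting=flux,
        at_tapetum=at_tapetum,
        source=arrays.source.copy(),
    )


def photochemical_rates(
    arrays_or_config, f_R: np.ndarray, flux: FluxField
) -> tuple[np.ndarray, np.ndarray]:
    """Photoconversion rates k_R, k_M per (slab, receptor).

    k = integral over wavelength of kappa * template * actinic flux,
    evaluated with the trapezoid rule on the run's grid.
    """
    arrays = (
        arrays_or_config
        if isinstance(arrays_or_config, _ModelArrays)
        else _prepare(arrays_or_config)
    )
    kappa_R, kappa_M = absorption_coefficients(f_R, arrays)
    g_R, g_M = _template_weighted_flux(arrays, flux)
    return kappa_R * g_R, kappa_M * g_M


def _template_weighted_flux(
    arrays: _ModelArrays, flux: FluxField
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(slab, receptor) integrals of template * actinic flux over lambda."""
    actinic = flux.actinic  # (Z, W)
    wl = arrays.wavelengths
    g_R = np.trapezoid(actinic[:, None, :] * arrays.gamma_R[None, :, :], wl, axis=2)
    g_M = np.trapezoid(actinic[:, None, :] * arrays.gamma_M[None, :, :], wl, axis=2)
    return g_R, g_M


def _unit_rates(
    arrays: _ModelArrays, flux: FluxField
) -> tuple[np.ndarray, np.ndarray]:
    """Conversion rates per unit isoform fraction: alpha * rho * integral."""
    g_R, g_M = _template_weighted_flux(arrays, flux)
    base = arrays.rho
    return arrays.alpha_R[None, :] * base * g_R, arrays.alpha_M[None, :] * base * g_M


def solve_equilibrium_fixed_point(
    config: RhabdomConfig,
    tolerance: float = 1e-3,
    max_iter: int = 100,
) -> tuple[np.ndarray, FluxField, int]:
    """Photoequilibrium by fixed-point iteration from the dark state.

    Alternates flux propagation, rate evaluation and the equilibrium update
    f_R = k_M / (k_R + k_M) until max |delta f_R| < tolerance.  Slabs a
    receptor does not occupy keep the dark state f_R = 1.

    Returns (f_R field, flux at the converged state, iteration count).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    arrays = _prepare(config)
    f_R = np.ones_like(arrays.rho)
    occupied = arrays.rho > 0
    for iteration in range(1, max_iter + 1):
        flux = propagate_flux(arrays, f_R)
        # conversion rates per unit isoform fraction, so the equilibrium
        # update is independent of the current split
        k_R_unit, k_M_unit = _unit_rates(arrays, flux)
        total = k_R_unit + k_M_unit
        f_new = np.where(occupied & (total > 0),
                         np.divide(k_M_unit, np.where(total > 0, total, 1.0)),
                         f_R)
        delta = float(np.max(np.abs(f_new - f_R)))
        f_R = f_new
        if delta < tolerance:
            flux = propagate_flux(arrays, f_R)
            return f_R, flux, iteration
    raise ConvergenceError(
        f"photoequilibrium not reached in {max_iter} iterations "
        f"(last max |delta f_R| = {delta:.3e})"
    )


def solve_equilibrium_ode(
    config: RhabdomConfig,
    duration: float = 400.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    n_eval: int = 9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Photoequilibrium by integrating df_R/dt = k_M f_M - k_R f_R.

    The flux is recomputed as the state evolves, coupling all slabs.  Time
    is in normalized units: rates are scaled so that the largest initial
    conversion rate equals 1 per time unit (the model has no absolute
    photon-to-rate constant).

    Returns (times, trajectory of f_R with shape (t, n_slabs, 9), final state).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    arrays = _prepare(config)
    shape = arrays.rho.shape
    f0 = np.ones(shape)

    flux0 = propagate_flux(arrays, f0)
    k_R0, _ = photochemical_rates(arrays, f0, flux0)
    k_max = float(k_R0.max())
    if k_max == 0.0:
        times = np.linspace(0.0, duration, n_eval)
        traj = np.repeat(f0[None], n_eval, axis=0)
        return times, traj, f0

    def rhs(_t, y):
        f = np.clip(y.reshape(shape), 0.0, 1.0)
        flux = propagate_flux(arrays, f)
        k_R_unit, k_M_unit = _unit_rates(arrays, flux)
        df = (k_M_unit * (1.0 - f) - k_R_unit * f) / k_max
        return df.ravel()

    sol = solve_ivp(
        rhs,
        (0.0, duration),
        f0.ravel(),
        method="RK45",
        t_eval=np.linspace(0.0, duration, n_eval),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise ConvergenceError(f"ODE integration failed: {sol.message}")
    traj = sol.y.T.reshape(-1, *shape)
    return sol.t, traj, traj[-1]


@dataclass(frozen=True)
class SensitivityResult:
    """Per-receptor effective spectral sensitivities (quantum catches)."""

    wavelengths: np.ndarray
    quantum_catch: np.ndarray  # (9, W), per unit corneal flux
    receptor_labels: tuple[str, ...] = tuple(f"R{i}" for i in range(1, 10))

    @property
    def normalized(self) -> np.ndarray:
        peaks = self.quantum_catch.max(axis=1, keepdims=True)
        safe = np.where(peaks > 0, peaks, 1.0)
        return self.quantum_catch / safe

    def receptor(self, label: str) -> np.ndarray:
        return self.quantum_catch[self.receptor_labels.index(label)]


def effective_sensitivity(
    config_or_arrays,
    f_R: np.ndarray,
    flux: FluxField,
    z_range: tuple[float, float] | None = None,
) -> SensitivityResult:
    """Rhodopsin quantum catch per receptor and wavelength.

    Q_r(lambda) = sum over slabs of actinic flux * kappa_R * template * dz,
    i.e. the photons absorbed by the rhodopsin isoform per unit corneal
    flux.  ``z_range`` (um) restricts the sum to a depth window, giving the
    distal or basal partial catch.
    """
    arrays = (
        config_or_arrays
        if isinstance(config_or_arrays, _ModelArrays)
        else _prepare(config_or_arrays)
    )
    kappa_R, _ = absorption_coefficients(f_R, arrays)
    actinic = flux.actinic  # (Z, W)
    n_slabs = arrays.rho.shape[0]
    dz_um = arrays.dz_mm * 1000.0
    z = (np.arange(n_slabs) + 0.5) * dz_um
    mask = np.ones(n_slabs, bool)
    if z_range is not None:
        mask = (z >= z_range[0]) & (z <= z_range[1])
    # (Z, 9, W): flux * kappa * template * dz
    contrib = (
        actinic[mask, None, :]
        * kappa_R[mask, :, None]
        * arrays.gamma_R[None, :, :]
        * arrays.dz_mm
    )
    catch = contrib.sum(axis=0)
    return SensitivityResult(wavelengths=arrays.wavelengths, quantum_catch=catch)


def eyeshine_spectrum(flux: FluxField) -> tuple[np.ndarray, np.ndarray]:
    """Upwelling flux exiting the distal face relative to the source.

    Returns (wavelengths, reflectance-like spectrum in [0, 1]).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(flux.source > 0, flux.exiting / np.where(flux.source > 0, flux.source, 1.0), 0.0)
    return flux.wavelengths, refl


def sensitivity_log_ratio(
    result: SensitivityResult, receptor_a: str, receptor_b: str
) -> float:
    """log10 of the ratio of unnormalized peak quantum catches (a over b)."""
    qa = result.receptor(receptor_a).max()
    qb = result.receptor(receptor_b).max()
    if qa <= 0 or qb <= 0:
        raise ValueError("log ratio undefined: a receptor has zero peak catch")
    return float(np.log10(qa / qb))


def equilibrium_fraction(
    config: RhabdomConfig,
    f_R: np.ndarray,
    z_range: tuple[float, float],
    receptors: tuple[int, ...] = tuple(range(2, 9)),
) -> float:
    """rho-weighted mean rhodopsin fraction over a depth window.

    Averages f_R over the given receptors (default: the R545-expressing
    R3-R9) and the slabs whose centers fall inside ``z_range``, weighting
    by the cross-section fraction so absent receptors do not contribute.
    """
    geom = config.resolved_geometry()
    z = config.depth.centers
    mask = (z >= z_range[0]) & (z <= z_range[1])
    rho = geom.rho[mask][:, receptors]
    f = np.asarray(f_R)[mask][:, receptors]
    w = rho.sum()
    if w == 0:
        raise ValueError("no receptor cross-section inside the depth window")
    return float((f * rho).sum() / w)


def model_target_summary(
    config: RhabdomConfig, tolerance: float = 1e-3
) -> dict[str, float]:
    """Headline quantities of one equilibrium run of the slab model.

    Returns the distal/basal equilibrium rhodopsin fractions of the
    R545-expressing receptors, the distal/basal partial-catch peak
    wavelengths of R3, the R1:R9 peak-catch log ratio, the modelled R9
    peak wavelength and the solver iteration count.
    """
    from .spectra import find_peak

    f_R, flux, iterations = solve_equilibrium_fixed_point(config, tolerance)
    arrays = _prepare(config)
    full = effective_sensitivity(arrays, f_R, flux)
    distal = effective_sensitivity(arrays, f_R, flux, z_range=DISTAL_CATCH_WINDOW)
    basal = effective_sensitivity(arrays, f_R, flux, z_range=BASAL_CATCH_WINDOW)
    wl = arrays.wavelengths
    peak_distal, _ = find_peak(wl, distal.receptor("R3"))
    peak_basal, _ = find_peak(wl, basal.receptor("R3"))
    peak_r9, _ = find_peak(wl, full.receptor("R9"))
    return {
        "f_distal": equilibrium_fraction(config, f_R, DISTAL_F_WINDOW),
        "f_basal": equilibrium_fraction(config, f_R, BASAL_F_WINDOW),
        "peak_r3_distal_nm": peak_distal,
        "peak_r3_basal_nm": peak_basal,
        "peak_r9_nm": peak_r9,
        "log_ratio_r1_r9": sensitivity_log_ratio(full, "R1", "R9"),
        "iterations": float(iterations),
    }


def run_summary_table(result: SensitivityResult):
    """Per-receptor (lambda_max, FWHM, log10 relative sensitivity) table."""
    import pandas as pd

    peaks = result.quantum_catch.max(axis=1)
    ref = peaks.max()
    rows = []
    for label, q, peak in zip(result.receptor_labels, result.quantum_catch, peaks):
        if peak <= 0:
            rows.append((label, np.nan, np.nan, -np.inf))
            continue
        summ = spectrum_summary(result.wavelengths, q)
        rows.append((label, summ.lambda_max, summ.fwhm, float(np.log10(peak / ref))))
    return pd.DataFrame(
        rows, columns=["receptor", "lambda_max_nm", "fwhm_nm", "log10_rel_sensitivity"]
    )
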