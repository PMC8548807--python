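"""Analysis of intracellular photoreceptor recordings.

Implements the standard reverse-transformation workflow for sharp-electrode
recordings from insect photoreceptors:

1. fit the intensity-response function V(I) with a sigmoid (Naka-Rushton
   form) ``V = V0 * I^n / (I^n + R^n)``;
2. convert response amplitudes to isoquantal flashes into sensitivities by
   inverting the fitted sigmoid (the equivalent-intensity transform);
3. parametrize polarization runs with a squared-cosine fit (angle of
   maximal sensitivity Phi, sensitivity ratio Psi = S_max/S_min);
4. decompose colour-opponent cells into their depolarizing (G+) and
   hyperpolarizing (R-) components using selective-adaptation runs, with
   the hyperpolarizing branch reverse-transformed through its own
   intensity-response fit.

Amplitudes are voltages relative to the dark resting potential:
depolarizations positive, hyperpolarizations negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .spectra import SpectralSummary, spectrum_summary as _summary

__all__ = [
    "EphysRun",
    "SigmoidFit",
    "SensitivitySpectrumEstimate",
    "PSFit",
    "OpponentDecomposition",
    "FitError",
    "SaturationError",
    "fit_intensity_response",
    "response_to_sensitivity",
    "decompose_opponent",
    "fit_polarization",
    "spectrum_summary",
    "fit_template_lambda_max",
    "fit_gaussian_peak",
    "summarize_cells",
]

RUN_COLUMNS = [
    "stimulus_wavelength_nm",
    "polarizer_angle_deg",
    "log10_intensity",
    "adaptation_label",
    "injected_current_nA",
    "response_mV",
]


class FitError(RuntimeError):
    """A model fit failed or the input carries no curvature to fit."""


class SaturationError(ValueError):
    """Response amplitudes at or above the fitted saturating voltage."""


@dataclass
class EphysRun:
    """One recording run: a table of stimuli and response amplitudes."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RUN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"run table missing columns: {missing}")
        if not np.isfinite(self.table["response_mV"]).all():
            raise ValueError("response amplitudes must be finite")

    def averaged(self) -> "EphysRun":
        """Average responses over repeated presentations of the same stimulus."""
        keys = [c for c in RUN_COLUMNS if c != "response_mV"]
        table = (
            self.table.groupby(keys, as_index=False, sort=True)["response_mV"]
            .mean()
        )
        return EphysRun(table=table[RUN_COLUMNS], metadata=dict(self.metadata))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path, **metadata) -> "EphysRun":
        return cls(table=pd.read_csv(path), metadata=metadata)


@dataclass(frozen=True)
class SigmoidFit:
    """Parameters of the sigmoid intensity-response function.

    ``V0`` is the saturating amplitude in mV (negative for hyperpolarizing
    responses), ``logR`` the log10 intensity at half-maximal response and
    ``n`` the slope exponent.
    """

    V0: float
    logR: float
    n: float
    rmse: float
    branch: str  # "depolarizing" | "hyperpolarizing"

    def __post_init__(self) -> None:
        if self.V0 == 0:
            raise ValueError("V0 must be nonzero")
        if self.n <= 0:
            raise ValueError("slope n must be > 0")

    def response(self, intensity) -> np.ndarray:
        """Evaluate the fitted V(I) at linear intensity."""
        I = np.asarray(intensity, dtype=float)
        R = 10.0**self.logR
        In = I**self.n
        return self.V0 * In / (In + R**self.n)


@dataclass(frozen=True)
class SensitivitySpectrumEstimate:
    """Signed relative sensitivities; the larger-magnitude peak is +1."""

    stimulus: np.ndarray  # wavelength (nm) or polarizer angle (deg)
    sensitivity: np.ndarray
    branch: str
    n_excluded_saturated: int = 0


@dataclass(frozen=True)
class PSFit:
    """Squared-cosine polarization fit: S(theta)=S_min+(S_max-S_min)cos^2."""

    phi_deg: float | None  # angle of maximal sensitivity, mod 180; None if flat
    psi: float  # polarization sensitivity ratio S_max/S_min, >= 1
    rmse: float
    degenerate: bool = False


def _sigmoid(log_I: np.ndarray, V0: float, logR: float, n: float) -> np.ndarray:
    # evaluated against log10 intensity for numerical stability
    x = n * (log_I - logR)
    return V0 / (1.0 + 10.0**(-x))


def fit_intensity_response(
    run: EphysRun | pd.DataFrame,
    exclude_above_log: float | None = None,
    exclude_below_log: float | None = None,
) -> SigmoidFit:
    """Least-squares sigmoid fit of the intensity-response function.

    The fit is performed on voltage versus linear intensity (the sigmoid is
    evaluated through log10 intensity, which is equivalent and better
    conditioned).  An optional exclusion window on log10 intensity drops
    e.g. supersaturating flashes from the fit.

    Raises
    ------
    ValueError
        Fewer than 4 intensity levels.
    FitError
        Responses carry no curvature (all equal) or the optimizer fails.
    """
    table = run.table if isinstance(run, EphysRun) else run
    log_I = table["log10_intensity"].to_numpy(float)
    V = table["response_mV"].to_numpy(float)
    keep = np.ones(len(V), bool)
    if exclude_above_log is not None:
        keep &= log_I <= exclude_above_log
    if exclude_below_log is not None:
        keep &= log_I >= exclude_below_log
    log_I, V = log_I[keep], V[keep]
    if len(np.unique(log_I)) < 4:
        raise ValueError("need at least 4 intensity levels to fit a sigmoid")
    if np.ptp(V) == 0:
        raise FitError("responses are constant; no intensity dependence to fit")

    branch = "hyperpolarizing" if V[np.argmax(np.abs(V))] < 0 else "depolarizing"
    sign = -1.0 if branch == "hyperpolarizing" else 1.0
    v0_guess = sign * 1.05 * np.max(np.abs(V))
    # half-max crossing as the initial logR
    half = np.abs(V) >= 0.5 * np.max(np.abs(V))
    logR_guess = float(log_I[half][0]) if half.any() else float(np.median(log_I))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _sigmoid,
                log_I,
                V,
                p0=(v0_guess, logR_guess, 1.0),
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
            )
    except RuntimeError as err:  # pragma: no cover - rare optimizer failure
        raise FitError(f"sigmoid fit did not converge: {err}") from err
    V0, logR, n = popt
    if n < 0:  # (V0, logR, n) -> equivalent with n > 0 has V0 -> 0 limit only
        raise FitError(f"sigmoid fit degenerate (n={n:.3g} <= 0)")
    resid = V - _sigmoid(log_I, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if (V0 > 0) != (sign > 0):
        branch = "depolarizing" if V0 > 0 else "hyperpolarizing"
    return SigmoidFit(V0=float(V0), logR=float(logR), n=float(n), rmse=rmse, branch=branch)


def equivalent_intensity(amplitudes, fit: SigmoidFit) -> np.ndarray:
    """Invert the fitted sigmoid: the intensity that would evoke each V.

    ``I_eq = R * (V / (V0 - V))**(1/n)``; amplitudes of the opposite sign
    to V0 map to 0.
    """
    V = np.asarray(amplitudes, dtype=float)
    r = V / fit.V0  # fractional response, positive on the fit's branch
    r = np.where(r > 0, r, 0.0)
    R = 10.0**fit.logR
    with np.errstate(divide="ignore", invalid="ignore"):
        I_eq = R * (r / (1.0 - r)) ** (1.0 / fit.n)
    return np.where(r > 0, I_eq, 0.0)


def response_to_sensitivity(
    run_or_amplitudes,
    fit: SigmoidFit,
    stimulus: np.ndarray | None = None,
    saturation_fraction: float = 0.98,
    normalize: bool = True,
) -> SensitivitySpectrumEstimate:
    """Reverse-transform response amplitudes into relative sensitivities.

    Each amplitude is mapped to the equivalent intensity through the
    fitted sigmoid; since the stimuli are isoquantal flashes of one common
    intensity, the sensitivity is proportional to that equivalent
    intensity.  Hyperpolarizing-branch sensitivities are reported as
    negative values.  Amplitudes at or beyond ``saturation_fraction * V0``
    cannot be inverted reliably: they are excluded with a warning, and
    amplitudes at or above V0 itself raise ``SaturationError``.
    """
    if isinstance(run_or_amplitudes, EphysRun):
        table = run_or_amplitudes.table
        V = table["response_mV"].to_numpy(float)
        if stimulus is None:
            wl = table["stimulus_wavelength_nm"].to_numpy(float)
            ang = table["polarizer_angle_deg"].to_numpy(float)
            stimulus = ang if np.ptp(wl) == 0 and np.ptp(ang) > 0 else wl
    else:
        V = np.asarray(run_or_amplitudes, dtype=float)
        if stimulus is None:
            stimulus = np.arange(len(V), dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)

    frac = V / fit.V0
    if (frac >= 1.0).any():
        offending = stimulus[frac >= 1.0]
        raise SaturationError(
            f"amplitudes reach the saturating voltage V0 at stimuli {offending}"
        )
    saturated = frac >= saturation_fraction
    if saturated.any():
        warnings.warn(
            f"{int(saturated.sum())} near-saturated amplitudes "
            f"(V >= {saturation_fraction:g} V0) excluded from the reverse transform",
            stacklevel=2,
        )
    I_eq = equivalent_intensity(V, fit)
    sens = np.where(saturated, np.nan, I_eq)
    if fit.branch == "hyperpolarizing":
        sens = -sens
    if normalize:
        peak = np.nanmax(np.abs(sens))
        if peak > 0:
            sens = sens / peak
    return SensitivitySpectrumEstimate(
        stimulus=stimulus,
        sensitivity=sens,
        branch=fit.branch,
        n_excluded_saturated=int(saturated.sum()),
    )


@dataclass(frozen=True)
class OpponentDecomposition:
    """G+ and R- component spectra of a colour-opponent cell.

    ``g_plus`` is normalized to +1; ``r_minus`` is negative-going on the
    same relative-intensity scale; ``combined`` is their sum re-normalized
    so the larger-magnitude peak equals +1.
    """

    wavelengths: np.ndarray
    g_plus: np.ndarray
    r_minus: np.ndarray
    combined: np.ndarray


def decompose_opponent(
    red_adapted: EphysRun,
    green_adapted: EphysRun,
    depol_fit: SigmoidFit,
    hyperpol_fit: SigmoidFit | None,
) -> OpponentDecomposition:
    """Isolate the G+ and R- components with selective adaptation.

    The G+ spectrum is the depolarizing sensitivity under red (R- silencing)
    adaptation; the R- spectrum is obtained from the hyperpolarizing
    amplitudes under green (G+ suppressing) adaptation, reverse-transformed
    through the hyperpolarizing-branch intensity-response fit.  A cell with
    no hyperpolarizing pathway may pass ``hyperpol_fit=None``, in which
    case the R- component is identically zero.
    """
    red_adapted = red_adapted.averaged()
    green_adapted = green_adapted.averaged()
    wl_g = red_adapted.table["stimulus_wavelength_nm"].to_numpy(float)
    wl_r = green_adapted.table["stimulus_wavelength_nm"].to_numpy(float)
    if not np.array_equal(np.sort(wl_g), np.sort(wl_r)):
        raise ValueError("adaptation runs must share the stimulus wavelengths")
    if hyperpol_fit is not None and hyperpol_fit.branch != "hyperpolarizing":
        raise ValueError("hyperpol_fit must be a hyperpolarizing-branch fit")

    g_est = response_to_sensitivity(red_adapted, depol_fit, normalize=True)
    g_plus = np.nan_to_num(g_est.sensitivity)

    V_r = green_adapted.table["response_mV"].to_numpy(float)
    if hyperpol_fit is None or not (V_r < 0).any():
        r_minus = np.zeros_like(wl_r)
    else:
        r_est = response_to_sensitivity(
            green_adapted, hyperpol_fit, normalize=False
        )
        r_minus = np.nan_to_num(r_est.sensitivity)
        peak = np.abs(r_minus).max()
        if peak > 0:
            r_minus = r_minus / peak
    order_g = np.argsort(wl_g)
    order_r = np.argsort(wl_r)
    wl = wl_g[order_g]
    g_plus, r_minus = g_plus[order_g], r_minus[order_r]
    combined = g_plus + r_minus
    scale = np.abs(combined).max()
    if scale > 0:
        combined = combined / scale
    return OpponentDecomposition(
        wavelengths=wl, g_plus=g_plus, r_minus=r_minus, combined=combined
    )


def fit_polarization(run: EphysRun, fit: SigmoidFit) -> PSFit:
    """Squared-cosine fit of a rotating-polarizer run.

    Amplitudes are first reverse-transformed into sensitivities, then
    ``S(theta) = S_min + (S_max - S_min) cos^2(theta - Phi)`` is fitted in
    closed form via harmonic regression on cos(2 theta) and sin(2 theta).
    Phi is reported modulo 180 deg (microvillar axes have no direction).
    A flat run is flagged degenerate: Psi = 1 and Phi undefined.
    """
    angles = run.table["polarizer_angle_deg"].to_numpy(float)
    unique = np.sort(np.unique(angles))
    step = float(np.median(np.diff(unique))) if len(unique) > 1 else 0.0
    if np.ptp(angles) + step < 360.0 - 1e-9:
        raise ValueError("polarization fit needs at least one full rotation")
    V = run.table["response_mV"].to_numpy(float)

    # harmonic regression of the voltage oscillation (period 180 deg);
    # cos^2(theta - phi) is exactly a0 + amp*cos(2(theta - phi))
    theta = np.deg2rad(angles)
    X = np.column_stack([np.ones_like(theta), np.cos(2 * theta), np.sin(2 * theta)])
    coef, *_ = np.linalg.lstsq(X, V, rcond=None)
    c0, a1, b1 = coef
    amp = float(np.hypot(a1, b1))
    resid = V - X @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))

    if amp < 1e-9 or amp < 1e-6 * abs(c0):
        return PSFit(phi_deg=None, psi=1.0, rmse=rmse, degenerate=True)

    # reverse-transform the fitted extreme voltages into sensitivities
    v_hi, v_lo = c0 + amp, c0 - amp
    phase = np.rad2deg(0.5 * np.arctan2(b1, a1)) % 180.0
    if fit.branch == "hyperpolarizing":
        # maximal sensitivity where the response is most negative
        v_resp_max, v_resp_min = v_lo, v_hi
        phi = (phase + 90.0) % 180.0
    else:
        v_resp_max, v_resp_min = v_hi, v_lo
        phi = phase
    s_max, s_min = equivalent_intensity([v_resp_max, v_resp_min], fit)
    if s_min <= 0:
        # modulation reaches zero response: the sensitivity ratio is unbounded
        s_min = 1e-12 * max(s_max, 1.0)
    return PSFit(phi_deg=float(phi), psi=float(s_max / s_min), rmse=rmse)


def spectrum_summary(
    estimate_or_wl, values=None, window_frac: float | None = None
) -> SpectralSummary:
    """Peak wavelength and FWHM of a sensitivity spectrum.

    Accepts either a ``SensitivitySpectrumEstimate`` or explicit
    (wavelengths, values) arrays; the summary is computed on the magnitude
    of the spectrum (see ``rhabdomsim.spectra.spectrum_summary``).
    ``window_frac`` selects the windowed-quadratic peak estimator, which is
    preferable on the coarse LED wavelength grid.
    """
    if isinstance(estimate_or_wl, SensitivitySpectrumEstimate):
        wl = estimate_or_wl.stimulus
        values = np.nan_to_num(estimate_or_wl.sensitivity)
    else:
        wl = estimate_or_wl
    return _summary(wl, values, window_frac=window_frac)


def fit_template_lambda_max(
    wavelengths, values, bounds: tuple[float, float] = (400.0, 620.0)
) -> float:
    """Peak wavelength by least-squares fit of a visual-pigment template.

    The standard way to assign a lambda_max to a measured spectral
    sensitivity of a single-pigment cell: fit the A1 nomogram (free peak
    wavelength and amplitude) to all sampled points.  Unbiased where the
    spectrum really is template-shaped; for blended (dual-peak) spectra
    use :func:`spectrum_summary` instead.
    """
    from .templates import WavelengthGrid, rhodopsin_template

    wl = np.asarray(wavelengths, float)
    v = np.abs(np.asarray(values, float))
    grid = WavelengthGrid(min(300.0, wl.min()), max(700.0, wl.max()), 1.0)

    def model(x, lam, scale):
        return scale * rhodopsin_template(lam, grid)(x)

    lam0 = float(wl[np.argmax(v)])
    lam0 = min(max(lam0, bounds[0]), bounds[1])
    popt, _ = curve_fit(
        model, wl, v, p0=(lam0, v.max()), bounds=([bounds[0], 0], [bounds[1], np.inf])
    )
    return float(popt[0])


def fit_gaussian_peak(wavelengths, values) -> tuple[float, float]:
    """Peak wavelength and FWHM by least-squares fit of a Gaussian band.

    Suited to the narrow band-shaped opponent (R-) components; uses every
    sampled point instead of only the neighbourhood of the grid maximum,
    so it is far less sensitive to sparse sampling than interpolation.
    Returns (lambda_max, fwhm).
    """
    wl = np.asarray(wavelengths, float)
    v = np.abs(np.asarray(values, float))

    def model(x, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    i = int(np.argmax(v))
    p0 = (v[i], wl[i], 20.0)
    popt, _ = curve_fit(model, wl, v, p0=p0, maxfev=10000)
    _, mu, sigma = popt
    return float(mu), float(abs(sigma) * 2.0 * np.sqrt(2.0 * np.log(2.0)))


def summarize_cells(spectra: list[np.ndarray]) -> pd.DataFrame:
    """Mean +- s.e. over cells of per-cell normalized spectra (not pooled)."""
    arr = np.vstack(spectra)
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    return pd.DataFrame({"mean": mean, "sem": se})
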