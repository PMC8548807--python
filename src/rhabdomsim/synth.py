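"""Seeded forward generator of colour-opponent photoreceptor recordings.

Emulates intracellular recordings from green-sensitive photoreceptors that
receive a delayed hyperpolarizing synaptic input from a red-sensitive unit:

* depolarizing green responses with a sigmoid intensity-response function;
* an opponent component driven by the red unit's own sigmoid, scaled by
  the driving force ``(V_hold - E_rev) / (V_rest - E_rev)`` so that
  injected current amplifies the hyperpolarization or reverses its sign at
  the ~-70 mV reversal potential;
* divisive chromatic adaptation (a steady background suppresses each unit
  in proportion to that unit's sensitivity at the adapting wavelength);
* cos^2-modulated polarization sensitivity per unit;
* additive Gaussian voltage noise.

The generator is deterministic given (cell, protocol, seed) and, run
noise-free, is exactly invertible by :mod:`rhabdomsim.ephys` - which is
what the parameter-recovery tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ephys import EphysRun, RUN_COLUMNS
from .templates import WavelengthGrid, rhodopsin_template

__all__ = [
    "UnitParams",
    "OpponentCellSpec",
    "StimulusProtocol",
    "LED_WAVELENGTHS",
    "SPECIES_PRESETS",
    "gaussian_spectrum",
    "template_spectrum",
    "make_cell",
    "simulate_flash_response",
    "generate_run",
    "make_benchmark_suite",
]

# Peak wavelengths (nm) of the LED-based spectral stimulator channels.
LED_WAVELENGTHS = (
    365, 375, 390, 402, 423, 437, 452, 470, 495, 512, 525,
    543, 560, 576, 592, 600, 619, 630, 660, 672, 685,
)


@dataclass(frozen=True)
class UnitParams:
    """One spectral unit: sensitivity spectrum, sigmoid and PS parameters."""

    wavelengths: np.ndarray
    sensitivity: np.ndarray  # peak-normalized, >= 0
    V0: float  # saturating amplitude magnitude, mV
    logR: float  # log10 intensity at half-max
    n: float  # sigmoid slope
    phi_deg: float = 90.0  # angle of maximal polarization sensitivity
    psi: float = 1.0  # polarization sensitivity ratio

    def __post_init__(self) -> None:
        if self.psi < 1:
            raise ValueError("psi must be >= 1")
        sens = np.asarray(self.sensitivity, float)
        peak = sens.max()
        object.__setattr__(self, "sensitivity", sens / peak if peak > 0 else sens)
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))

    def catch(self, wavelength: float) -> float:
        return float(np.interp(wavelength, self.wavelengths, self.sensitivity))

    def ps_modulation(self, angle_deg: float | None) -> float:
        if angle_deg is None:
            return 1.0
        c2 = np.cos(np.deg2rad(angle_deg - self.phi_deg)) ** 2
        return float((1.0 + (self.psi - 1.0) * c2) / self.psi)

    def response(self, effective_intensity: float) -> float:
        """Sigmoid response magnitude (mV) to an effective intensity."""
        if effective_intensity <= 0:
            return 0.0
        R = 10.0**self.logR
        In = effective_intensity**self.n
        return self.V0 * In / (In + R**self.n)


@dataclass(frozen=True)
class OpponentCellSpec:
    """A G+R- cell: a green unit plus an optional red opponent unit.

    Sigmoid defaults follow the intensity-response fits measured in these
    cells (half-max at -2.51 log for the depolarizing green unit, -1.21
    for the hyperpolarizing red pathway; slopes 0.86 and 1.05), the
    reversal potential of the opponent conductance is -70 mV, and the PS
    defaults are the vertical-microvilli values of the R1/2 and R9
    positions.
    """

    green: UnitParams
    red: UnitParams | None = None
    resting_potential_mV: float = -60.0
    E_rev_mV: float = -70.0
    input_resistance_MOhm: float = 20.0
    synaptic_delay_ms: float = 20.0
    noise_sd_mV: float = 0.5
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.E_rev_mV >= self.resting_potential_mV:
            raise ValueError("E_rev must be below the resting potential")
        if self.noise_sd_mV < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """A batch of flashes along one stimulus axis."""

    kind: str  # "spectral_series" | "intensity_series" | "polarizer_rotation"
    wavelengths: tuple = LED_WAVELENGTHS
    log_intensity: float = -1.5
    log_intensity_range: tuple[float, float, int] = (-4.0, 0.0, 17)
    angles_step_deg: float = 18.0
    n_rotations: int = 5
    n_repeats: int = 1  # repeated presentations of a spectral series
    adaptation_label: str = "dark"
    injected_current_nA: float = 0.0

    def __post_init__(self) -> None:
        kinds = {"spectral_series", "intensity_series", "polarizer_rotation"}
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {sorted(kinds)}")
        if self.kind != "intensity_series" and len(self.wavelengths) == 0:
            raise ValueError("stimulus list must be non-empty")


def gaussian_spectrum(
    peak_nm: float, fwhm_nm: float, grid: WavelengthGrid | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian sensitivity spectrum with the given peak and FWHM."""
    grid = grid or WavelengthGrid()
    wl = grid.wavelengths
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return wl, np.exp(-0.5 * ((wl - peak_nm) / sigma) ** 2)


def template_spectrum(
    peaks_nm, weights=None, grid: WavelengthGrid | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Visual-pigment template spectrum, optionally a weighted blend.

    Dual-peaked cells (opsin co-expression) are modelled as weighted sums
    of two templates.
    """
    grid = grid or WavelengthGrid()
    peaks = np.atleast_1d(np.asarray(peaks_nm, float))
    weights = np.ones_like(peaks) if weights is None else np.asarray(weights, float)
    values = np.zeros(len(grid))
    for peak, w in zip(peaks, weights):
        values = values + w * rhodopsin_template(peak, grid).values
    return grid.wavelengths, values / values.max()


def _adaptation(label: str) -> tuple[float, float] | None:
    """Parse an adaptation label into (wavelength, intensity).

    Labels: "dark", or "<colour>_<wavelength>" e.g. "green_500", "red_650";
    an optional third field gives log10 adapting intensity ("green_500_-1").
    """
    if label in (None, "", "dark"):
        return None
    parts = str(label).split("_")
    if len(parts) < 2:
        raise ValueError(f"cannot parse adaptation label {label!r}")
    wavelength = float(parts[1])
    log_I = float(parts[2]) if len(parts) > 2 else 0.0
    return wavelength, 10.0**log_I


def _unit_gain(unit: UnitParams, adaptation: tuple[float, float] | None) -> float:
    """Divisive adaptation gain: 1 / (1 + catch at the background / R)."""
    if adaptation is None:
        return 1.0
    wl_adapt, I_adapt = adaptation
    background = unit.catch(wl_adapt) * I_adapt / 10.0**unit.logR
    return 1.0 / (1.0 + background)


def simulate_flash_response(
    cell: OpponentCellSpec,
    wavelength: float,
    log10_intensity: float,
    adaptation: str = "dark",
    injected_current_nA: float = 0.0,
    polarizer_angle_deg: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Sustained response amplitude (mV, relative to rest) to one flash."""
    adapt = _adaptation(adaptation)
    I = 10.0**log10_intensity

    gain_g = _unit_gain(cell.green, adapt)
    eff_g = cell.green.catch(wavelength) * cell.green.ps_modulation(polarizer_angle_deg)
    v_dep = cell.green.response(eff_g * I * gain_g)

    v_opp = 0.0
    if cell.red is not None:
        gain_r = _unit_gain(cell.red, adapt)
        eff_r = cell.red.catch(wavelength) * cell.red.ps_modulation(polarizer_angle_deg)
        magnitude = cell.red.response(eff_r * I * gain_r)
        v_hold = (
            cell.resting_potential_mV
            + injected_current_nA * cell.input_resistance_MOhm
        )
        driving = (v_hold - cell.E_rev_mV) / (
            cell.resting_potential_mV - cell.E_rev_mV
        )
        v_opp = -magnitude * driving

    noise = float(rng.normal(0.0, cell.noise_sd_mV)) if rng is not None and cell.noise_sd_mV > 0 else 0.0
    return v_dep + v_opp + noise


def response_time_course(
    cell: OpponentCellSpec,
    wavelength: float,
    log10_intensity: float,
    duration_ms: float = 200.0,
    dt_ms: float = 1.0,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Step-like time course: the opponent component lags by the synaptic delay."""
    cell_nored = replace(cell, red=None)
    v_dep = simulate_flash_response(cell_nored, wavelength, log10_intensity, **kwargs)
    v_total = simulate_flash_response(cell, wavelength, log10_intensity, **kwargs)
    v_opp = v_total - v_dep
    t = np.arange(0.0, duration_ms, dt_ms)
    tau = 10.0  # ms, onset time constant of the graded response
    v = v_dep * (1.0 - np.exp(-t / tau))
    delayed = t >= cell.synaptic_delay_ms
    v[delayed] += v_opp * (1.0 - np.exp(-(t[delayed] - cell.synaptic_delay_ms) / tau))
    return t, v


def generate_run(
    cell: OpponentCellSpec, protocol: StimulusProtocol, seed: int
) -> EphysRun:
    """Batch flashes into one recording run; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    rows = []
    if protocol.kind == "spectral_series":
        for _rep in range(protocol.n_repeats):
            for wl in protocol.wavelengths:
                rows.append((float(wl), 0.0, protocol.log_intensity))
    elif protocol.kind == "intensity_series":
        lo, hi, n = protocol.log_intensity_range
        wl = float(protocol.wavelengths[0])
        for _rep in range(protocol.n_repeats):
            for log_I in np.linspace(lo, hi, int(n)):
                rows.append((wl, 0.0, float(log_I)))
    else:  # polarizer_rotation
        wl = float(protocol.wavelengths[0])
        n_steps = int(round(360.0 / protocol.angles_step_deg))
        for _rot in range(protocol.n_rotations):
            for i in range(n_steps):
                rows.append((wl, i * protocol.angles_step_deg, protocol.log_intensity))

    records = []
    for wl, angle, log_I in rows:
        amp = simulate_flash_response(
            cell,
            wl,
            log_I,
            adaptation=protocol.adaptation_label,
            injected_current_nA=protocol.injected_current_nA,
            polarizer_angle_deg=angle if protocol.kind == "polarizer_rotation" else None,
            rng=rng,
        )
        records.append(
            (wl, angle, log_I, protocol.adaptation_label, protocol.injected_current_nA, amp)
        )
    table = pd.DataFrame(records, columns=RUN_COLUMNS)
    return EphysRun(
        table=table,
        metadata={
            "cell": cell.label,
            "kind": protocol.kind,
            "seed": int(seed),
        },
    )


# ---------------------------------------------------------------------------
# species presets (R- lambda_max / FWHM and G+ peak(s) as measured in the
# eight opponent-cell species, plus two negative controls without an R- unit)

SPECIES_PRESETS: dict[str, dict] = {
    "Archaeoprepona demophon": {"r_peak": 620, "r_fwhm": 47, "g_peaks": (530,)},
    "Argynnis paphia": {"r_peak": 620, "r_fwhm": 45, "g_peaks": (535,)},
    "Charaxes jasius": {"r_peak": 620, "r_fwhm": 40, "g_peaks": (535,)},
    "Danaus plexippus": {"r_peak": 610, "r_fwhm": 45, "g_peaks": (440, 510), "g_weights": (1.0, 1.0)},
    "Heliconius erato": {"r_peak": 620, "r_fwhm": 50, "g_peaks": (465, 545), "g_weights": (1.0, 1.0)},
    "Melitaea athalia": {"r_peak": 610, "r_fwhm": 40, "g_peaks": (450,)},
    "Morpho peleides": {"r_peak": 610, "r_fwhm": 60, "g_peaks": (500,)},
    "Speyeria aglaja": {"r_peak": 620, "r_fwhm": 50, "g_peaks": (530,)},
    "Apatura ilia": {"r_peak": None, "r_fwhm": None, "g_peaks": (530,)},
    "Vanessa atalanta": {"r_peak": None, "r_fwhm": None, "g_peaks": (530,)},
}

# default sigmoid / PS parameters of the two units (measured values)
GREEN_SIGMOID = {"V0": 25.0, "logR": -2.51, "n": 0.86}
RED_SIGMOID = {"V0": 10.0, "logR": -1.21, "n": 1.05}
GREEN_PS = {"phi_deg": 103.0, "psi": 1.2}
RED_PS = {"phi_deg": 96.0, "psi": 2.0}


def make_cell(
    species: str | None = None,
    g_peaks=None,
    g_weights=None,
    r_peak: float | None = 620.0,
    r_fwhm: float | None = 45.0,
    r_spectrum: tuple[np.ndarray, np.ndarray] | None = None,
    noise_sd_mV: float = 0.5,
    grid: WavelengthGrid | None = None,
    **overrides,
) -> OpponentCellSpec:
    """Build an opponent-cell spec from a species preset or raw parameters.

    The G+ unit uses visual-pigment templates (a weighted blend for the
    dual-peaked, opsin-co-expressing cells); the R- unit defaults to a
    Gaussian with the preset peak/FWHM, or any explicit (wavelength,
    sensitivity) pair such as a modelled R9 spectrum.
    """
    grid = grid or WavelengthGrid()
    if species is not None:
        preset = SPECIES_PRESETS[species]
        g_peaks = preset["g_peaks"]
        g_weights = preset.get("g_weights")
        r_peak, r_fwhm = preset["r_peak"], preset["r_fwhm"]
    if g_peaks is None:
        g_peaks = (520.0,)
    wl, g_sens = template_spectrum(g_peaks, g_weights, grid)
    green = UnitParams(wavelengths=wl, sensitivity=g_sens, **GREEN_SIGMOID, **GREEN_PS)

    red = None
    if r_spectrum is not None:
        red = UnitParams(
            wavelengths=r_spectrum[0], sensitivity=r_spectrum[1], **RED_SIGMOID, **RED_PS
        )
    elif r_peak is not None:
        wl_r, r_sens = gaussian_spectrum(r_peak, r_fwhm, grid)
        red = UnitParams(wavelengths=wl_r, sensitivity=r_sens, **RED_SIGMOID, **RED_PS)
    return OpponentCellSpec(
        green=green,
        red=red,
        noise_sd_mV=noise_sd_mV,
        label=species or "synthetic",
        **overrides,
    )


def standard_protocols(
    adapt_green: str = "green_500_1", adapt_red: str = "red_650_0"
) -> dict[str, StimulusProtocol]:
    """The protocol set recorded for each cell in the benchmark suite.

    Adapting backgrounds are set the way an experimenter would: a strong
    green background (10x the flash cap) to fully suppress the sensitive
    depolarizing unit, and a moderate red background that silences the
    less sensitive red unit without acting on the green unit through its
    long-wavelength template tail.  Flash intensities keep each unit on
    the steep part of its own intensity-response function.
    """
    return {
        "spectral_dark": StimulusProtocol(
            "spectral_series", log_intensity=-2.0, n_repeats=3, adaptation_label="dark"
        ),
        "spectral_green_adapted": StimulusProtocol(
            "spectral_series", log_intensity=-1.0, n_repeats=5, adaptation_label=adapt_green
        ),
        "spectral_red_adapted": StimulusProtocol(
            "spectral_series", log_intensity=-1.5, n_repeats=5, adaptation_label=adapt_red
        ),
        "intensity_green": StimulusProtocol(
            "intensity_series", wavelengths=(525,), n_repeats=3, adaptation_label="dark"
        ),
        "intensity_red": StimulusProtocol(
            "intensity_series", wavelengths=(625,), n_repeats=3, adaptation_label=adapt_green
        ),
        "ps_green": StimulusProtocol(
            "polarizer_rotation", wavelengths=(525,), log_intensity=-2.5,
            adaptation_label="dark",
        ),
        "ps_red": StimulusProtocol(
            "polarizer_rotation", wavelengths=(625,), log_intensity=-1.0,
            adaptation_label=adapt_green,
        ),
    }


@dataclass(frozen=True)
class BenchmarkCell:
    """One synthetic cell with its recording runs and generative truth."""

    species: str
    replicate: int
    cell: OpponentCellSpec
    runs: dict[str, EphysRun]
    truth: dict


def make_benchmark_suite(
    n_cells: int = 1,
    species: tuple[str, ...] | None = None,
    seed: int = 0,
    noise_sd_mV: float = 0.5,
) -> list[BenchmarkCell]:
    """Generate the species-preset benchmark: cells, runs and a truth manifest.

    ``n_cells`` replicates per species differ only in their noise streams.
    Deterministic given the seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    species = tuple(species or SPECIES_PRESETS)
    protocols = standard_protocols()
    out = []
    seed_seq = np.random.SeedSequence(seed)
    for name in species:
        preset = SPECIES_PRESETS[name]
        for rep in range(n_cells):
            cell = make_cell(species=name, noise_sd_mV=noise_sd_mV)
            child = seed_seq.spawn(1)[0]
            run_seeds = child.generate_state(len(protocols)) % (2**31)
            runs = {
                key: generate_run(cell, proto, int(s))
                for (key, proto), s in zip(protocols.items(), run_seeds)
            }
            truth = {
                "species": name,
                "replicate": rep,
                "r_minus_lambda_max_nm": preset["r_peak"],
                "r_minus_fwhm_nm": preset["r_fwhm"],
                "g_plus_peaks_nm": list(preset["g_peaks"]),
                "sigmoid_green": dict(GREEN_SIGMOID),
                "sigmoid_red": dict(RED_SIGMOID) if preset["r_peak"] else None,
                "ps_green": dict(GREEN_PS),
                "ps_red": dict(RED_PS) if preset["r_peak"] else None,
                "noise_sd_mV": noise_sd_mV,
            }
            out.append(
                BenchmarkCell(
                    species=name, replicate=rep, cell=cell, runs=runs, truth=truth
                )
            )
    return out
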