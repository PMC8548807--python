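"""Peak and bandwidth estimation for sensitivity spectra.

Shared numerics: peak localisation by parabolic interpolation around the
grid maximum, FWHM from linear interpolation of the half-maximum crossings,
and detection of secondary peaks.  Works on non-uniform wavelength grids
(e.g. the 21 LED stimulus wavelengths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralSummary", "find_peak", "full_width_half_max", "spectrum_summary"]


@dataclass(frozen=True)
class SpectralSummary:
    """Peak wavelength and bandwidth of a sensitivity spectrum."""

    lambda_max: float
    fwhm: float | None
    secondary_peak: float | None = None
    edge_peak: bool = False
    one_sided_fwhm: bool = False


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through points (i-1, i, i+1); non-uniform x."""
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate curvature; fall back to the grid maximum
        return float(x1)
    return float(-b / (2 * a))


def find_peak(wavelengths, values, window_frac: float | None = None) -> tuple[float, bool]:
    """Peak wavelength by parabolic interpolation.

    By default the parabola passes through the grid maximum and its two
    neighbours.  With ``window_frac`` set (e.g. 0.75), a least-squares
    quadratic is fitted to all contiguous samples above that fraction of
    the maximum - more robust for noisy, coarsely sampled spectra.

    Returns (lambda_max, edge_flag); the flag is set when the grid maximum
    sits on the first or last sample, where interpolation is impossible.
    """
    wl = np.asarray(wavelengths, float)
    v = np.asarray(values, float)
    i = int(np.argmax(v))
    if i == 0 or i == len(v) - 1:
        return float(wl[i]), True
    if window_frac is not None:
        lo = i
        while lo > 0 and v[lo - 1] >= window_frac * v[i]:
            lo -= 1
        hi = i
        while hi < len(v) - 1 and v[hi + 1] >= window_frac * v[i]:
            hi += 1
        if hi - lo >= 2:
            x = wl[lo : hi + 1] - wl[i]
            coef = np.polyfit(x, v[lo : hi + 1], 2)
            if coef[0] < 0:
                vertex = wl[i] - coef[1] / (2 * coef[0])
                vertex = min(max(vertex, wl[lo]), wl[hi])
                return float(vertex), False
    vertex = _parabolic_vertex(wl, v, i)
    # keep the vertex inside the bracketing interval
    vertex = min(max(vertex, wl[i - 1]), wl[i + 1])
    return vertex, False


def full_width_half_max(wavelengths, values) -> tuple[float | None, bool]:
    """FWHM around the main peak by linear interpolation of 50% crossings.

    Returns (fwhm, one_sided_flag).  If a 50% crossing is missing on one
    side, the available half-width is doubled and the flag set; if both are
    missing, fwhm is None.
    """
    wl = np.asarray(wavelengths, float)
    v = np.asarray(values, float)
    i = int(np.argmax(v))
    half = v[i] / 2.0

    left = None
    for j in range(i, 0, -1):
        if v[j - 1] <= half <= v[j]:
            left = np.interp(half, [v[j - 1], v[j]], [wl[j - 1], wl[j]])
            break
    right = None
    for j in range(i, len(v) - 1):
        if v[j + 1] <= half <= v[j]:
            right = np.interp(half, [v[j + 1], v[j]], [wl[j + 1], wl[j]])
            break

    peak_wl, _ = find_peak(wl, v)
    if left is not None and right is not None:
        return float(right - left), False
    if left is not None:
        return float(2 * (peak_wl - left)), True
    if right is not None:
        return float(2 * (right - peak_wl)), True
    return None, True


def _local_maxima(values: np.ndarray) -> list[int]:
    idx = []
    for i in range(1, len(values) - 1):
        if values[i] >= values[i - 1] and values[i] > values[i + 1]:
            idx.append(i)
    return idx


def spectrum_summary(wavelengths, values, window_frac: float | None = None) -> SpectralSummary:
    """Summarize a (possibly signed) sensitivity spectrum.

    The summary is computed on the magnitude of the spectrum, so opponent
    (negative-going) components report a positive bandwidth.  A secondary
    peak is reported when another local maximum exceeds 50% of the main one
    and is separated from it by a trough.  ``window_frac`` is forwarded to
    :func:`find_peak` for noisy coarse grids.
    """
    wl = np.asarray(wavelengths, float)
    v = np.abs(np.asarray(values, float))
    if len(v) < 3:
        raise ValueError("need at least 3 samples to summarize a spectrum")
    lam, edge = find_peak(wl, v, window_frac=window_frac)
    fwhm, one_sided = full_width_half_max(wl, v)

    secondary = None
    i_main = int(np.argmax(v))
    best = 0.0
    for i in _local_maxima(v):
        if i == i_main:
            continue
        lo, hi = sorted((i, i_main))
        trough = v[lo : hi + 1].min()
        if v[i] >= 0.5 * v[i_main] and trough < 0.8 * v[i] and v[i] > best:
            secondary = _parabolic_vertex(wl, v, i)
            best = v[i]
    return SpectralSummary(
        lambda_max=lam,
        fwhm=fwhm,
        secondary_peak=secondary,
        edge_peak=edge,
        one_sided_fwhm=one_sided,
    )
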