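"""Trace conditioning and peak measurement.

The conditioning chain mirrors what CE analysis software does before any
genotyping logic runs: set the baseline to zero (rolling low-percentile
estimate, robust to sparse peaks), undo spectral crosstalk between dye
channels (per-scan linear solve against the known mixing matrix), then find
and measure peaks (sub-scan apex by log-parabolic interpolation, FWHM by
interpolated half-height crossings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .simulate import Electropherogram

__all__ = ["Peak", "correct_baseline", "color_correct", "detect_peaks"]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass(frozen=True)
class Peak:
    """A detected peak: apex (sub-scan), height above baseline, area, width."""

    channel: int
    apex_scan: float
    height: float
    area: float
    fwhm_scans: float
    saturated: bool = False


def correct_baseline(trace: Electropherogram, window: int = 201,
                     percentile: float = 10.0) -> Electropherogram:
    """Subtract a per-channel rolling-percentile baseline estimate.

    The window (default 201 scans, ~20x a typical peak FWHM) is wide enough
    that peaks occupy a minority of it, so a low percentile tracks the
    baseline and not the peaks. Idempotent within tolerance.
    """
    values = np.asarray(trace.values, dtype=float)
    baseline = np.empty_like(values)
    for c in range(values.shape[1]):
        baseline[:, c] = scipy.ndimage.percentile_filter(
            values[:, c], percentile, size=window, mode="nearest")
    return trace.copy_with(values - baseline)


def color_correct(trace: Electropherogram, crosstalk: np.ndarray) -> Electropherogram:
    """Invert the spectral mixing so each channel estimates one dye's signal.

    Solves ``observed = M @ pure`` per scan for the pure dye signals. Raises
    on a singular (or numerically singular) matrix.
    """
    m = np.asarray(crosstalk, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("crosstalk must be a square matrix")
    if m.shape[0] != trace.n_channels:
        raise ValueError(
            f"crosstalk is {m.shape[0]}x{m.shape[0]} but trace has "
            f"{trace.n_channels} channels")
    if np.linalg.cond(m) > 1e12:
        raise np.linalg.LinAlgError("crosstalk matrix is singular")
    pure = np.linalg.solve(m, trace.values.T).T
    return trace.copy_with(pure)


def _refine_apex(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-scan apex and height from the 3 samples around a local maximum.

    Uses log-parabolic (Gaussian) interpolation when all three samples are
    positive — exact for a noiseless Gaussian — and falls back to an
    ordinary parabola otherwise.
    """
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    if min(y0, y1, y2) > 0:
        l0, l1, l2 = np.log([y0, y1, y2])
    else:
        l0, l1, l2 = y0, y1, y2
    denom = l0 - 2 * l1 + l2
    if denom >= 0:  # not concave at the apex; keep the grid point
        return float(i), float(y1)
    delta = 0.5 * (l0 - l2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    if min(y0, y1, y2) > 0:
        height = float(np.exp(l1 - 0.25 * delta * (l0 - l2)))
    else:
        height = float(y1 - 0.25 * delta * (y0 - y2))
    return i + delta, height


def detect_peaks(trace: Electropherogram, min_height: float,
                 min_fwhm_scans: float = 2.0,
                 saturation: float | None = None,
                 channels: list[int] | None = None) -> list[Peak]:
    """Find local maxima above ``min_height`` with FWHM >= ``min_fwhm_scans``.

    Plateau maxima (e.g. clipped peaks) use the plateau midpoint as apex;
    a plateau longer than 3 scans at or above ``saturation`` marks the peak
    saturated. Area is the Gaussian-equivalent ``height * sigma * sqrt(2*pi)``
    with sigma inferred from the measured FWHM.
    """
    peaks: list[Peak] = []
    use = range(trace.n_channels) if channels is None else channels
    for c in use:
        y = np.asarray(trace.values[:, c], dtype=float)
        idx, props = scipy.signal.find_peaks(y, height=min_height,
                                             plateau_size=(1, None))
        if len(idx) == 0:
            continue
        widths, _, _, _ = scipy.signal.peak_widths(y, idx, rel_height=0.5)
        for j, i in enumerate(idx):
            fwhm = float(widths[j])
            if fwhm < min_fwhm_scans:
                continue
            plateau = int(props["plateau_sizes"][j])
            if plateau > 1:
                apex = 0.5 * (float(props["left_edges"][j])
                              + float(props["right_edges"][j]))
                height = float(y[i])
            else:
                apex, height = _refine_apex(y, int(i))
            saturated = bool(saturation is not None and plateau > 3
                             and y[i] >= saturation - 1e-9)
            sigma = fwhm / _FWHM_PER_SIGMA
            peaks.append(Peak(channel=c, apex_scan=apex, height=height,
                              area=height * sigma * np.sqrt(2 * np.pi),
                              fwhm_scans=fwhm, saturated=saturated))
    return peaks
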