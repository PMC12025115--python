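"""Raman spectrum preprocessing, peak detection and mineral calls.

Calcite and magnesian calcite are identified jointly by three
characteristic windows: the lattice mode at 281-283 cm^-1, the nu4
in-plane carbonate bend at 707-720 cm^-1, and the diagnostic nu1
symmetric carbonate stretch at 1087-1088 cm^-1. A spectrum is called
``calcite_family`` iff a detected peak falls in the (tolerance-widened)
nu1 window; missing lattice or nu4 peaks give a ``partial`` call, as
these modes are weakly expressed in some spicules. The two polymorph
variants are not distinguished — Mg content is an elemental (EDX)
question, not a shift question at this resolution.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .composition import CompositionError

__all__ = [
    "Spectrum",
    "PeakSet",
    "MineralCall",
    "CALCITE_WINDOWS",
    "read_spectrum",
    "subtract_baseline",
    "detect_peaks",
    "match_mineral",
]

#: Characteristic calcite-family windows (cm^-1), by mode name.
CALCITE_WINDOWS: dict[str, tuple[float, float]] = {
    "nu_lattice": (281.0, 283.0),
    "nu4": (707.0, 720.0),
    "nu1": (1087.0, 1088.0),
}


@dataclasses.dataclass
class Spectrum:
    """Raman shift grid (cm^-1, strictly increasing) with intensities."""

    shift: np.ndarray
    intensity: np.ndarray
    meta: str = ""

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift.shape != self.intensity.shape or self.shift.ndim != 1:
            raise CompositionError("shift and intensity must be equal-length 1-D")
        if self.shift.size == 0:
            raise CompositionError("empty spectrum")
        if np.any(np.diff(self.shift) <= 0):
            raise CompositionError("shift grid must be strictly increasing")

    def __len__(self) -> int:
        return self.shift.size


@dataclasses.dataclass
class PeakSet:
    """Detected peaks: (position cm^-1, height, prominence), plus the
    noise scale the prominence threshold was based on."""

    peaks: list[tuple[float, float, float]]
    noise_estimate: float

    @property
    def positions(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])


@dataclasses.dataclass
class MineralCall:
    label: str  # "calcite_family" | "unidentified"
    windows_matched: tuple[str, ...]
    partial: bool


def read_spectrum(path: str | Path, meta: str | None = None) -> Spectrum:
    """Read a two-column (shift, intensity) text spectrum.

    Accepts whitespace- or comma-delimited files, with or without a
    header line.
    """
    path = Path(path)
    try:
        data = np.genfromtxt(path, delimiter=None, comments="#")
        if data.ndim != 2 or data.shape[1] < 2 or np.isnan(data).any():
            data = np.genfromtxt(path, delimiter=",", comments="#", skip_header=0)
    except (OSError, ValueError) as e:
        raise CompositionError(f"cannot read spectrum {path}: {e}") from e
    data = np.atleast_2d(data)
    # drop a header row that failed to parse
    if np.isnan(data[0]).any():
        data = data[1:]
    if data.shape[1] < 2 or np.isnan(data[:, :2]).any():
        raise CompositionError(f"{path.name}: expected two numeric columns")
    order = np.argsort(data[:, 0])
    return Spectrum(data[order, 0], data[order, 1], meta or path.name)


def subtract_baseline(s: Spectrum, half_window: int = 50) -> Spectrum:
    """Remove a slowly varying baseline.

    A rolling-minimum envelope of width ``2 * half_window + 1`` grid
    points, smoothed by a moving average of the same width, is
    subtracted. Parameter-light and adequate for the smooth fluorescence
    baselines of biomineral spectra; the input spectrum is not modified.
    """
    if half_window < 1:
        raise CompositionError("half_window must be >= 1")
    w = 2 * half_window + 1
    if w > len(s):
        raise CompositionError(
            f"window ({w} points) exceeds the spectrum length ({len(s)})"
        )
    env = minimum_filter1d(s.intensity, size=w, mode="nearest")
    baseline = uniform_filter1d(env, size=w, mode="nearest")
    return Spectrum(s.shift.copy(), s.intensity - baseline, s.meta)


def _noise_scale(intensity: np.ndarray) -> float:
    """Robust noise scale from first differences (MAD-based)."""
    d = np.diff(intensity)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2))


def detect_peaks(
    s: Spectrum,
    min_prominence_snr: float = 5.0,
    smooth_window: int = 9,
) -> PeakSet:
    """Find local maxima with prominence and height above an SNR threshold.

    The noise level is the robust scale of the first differences of the
    (baseline-corrected) input intensities. Candidate maxima are found
    on a lightly Savitzky-Golay-smoothed copy (quadratic, window
    ``smooth_window`` points; set to 0 to disable) and must exceed
    ``min_prominence_snr`` times the noise in both prominence and
    height — a baseline-corrected spectrum has a near-zero background,
    so a real peak clears both. Positions are refined by 3-point
    parabolic interpolation around each maximum.
    """
    if len(s) < 3:
        raise CompositionError("spectrum too short for peak detection")
    noise = _noise_scale(s.intensity)
    threshold = min_prominence_snr * noise if noise > 0 else 0.0
    y = s.intensity
    if smooth_window and smooth_window >= 3 and len(s) > smooth_window:
        w = smooth_window + (smooth_window + 1) % 2  # force odd
        y = signal.savgol_filter(y, w, polyorder=2)
    idx, props = signal.find_peaks(
        y, prominence=max(threshold, 1e-300), height=threshold or None
    )
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        pos = s.shift[i]
        if 0 < i < len(s) - 1:
            y0, y1, y2 = y[i - 1 : i + 2]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                frac = 0.5 * (y0 - y2) / denom
                frac = float(np.clip(frac, -0.5, 0.5))
                pos = pos + frac * (s.shift[min(i + 1, len(s) - 1)] - s.shift[max(i - 1, 0)]) / 2
        peaks.append((float(pos), float(y[i]), float(prom)))
    return PeakSet(peaks=peaks, noise_estimate=noise)


def match_mineral(p: PeakSet, tolerance: float = 4.0) -> MineralCall:
    """Classify a peak set against the calcite-family windows.

    A window counts as matched if any peak falls within it after
    widening by ``tolerance`` cm^-1 on each side (the default 4 cm^-1
    reflects typical grating resolution and the natural spread of the
    nu4 mode). The call is ``calcite_family`` iff the nu1 window is
    matched; ``partial`` flags a calcite call missing the lattice or
    nu4 peak.
    """
    matched = []
    pos = p.positions
    for name, (lo, hi) in CALCITE_WINDOWS.items():
        if pos.size and np.any((pos >= lo - tolerance) & (pos <= hi + tolerance)):
            matched.append(name)
    is_calcite = "nu1" in matched
    return MineralCall(
        label="calcite_family" if is_calcite else "unidentified",
        windows_matched=tuple(matched),
        partial=is_calcite and len(matched) < len(CALCITE_WINDOWS),
    )
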