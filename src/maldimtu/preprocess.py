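"""Raw-spectrum conditioning and peak detection.

Fixed stage order: :func:`smooth` -> :func:`subtract_baseline` ->
:func:`normalize_tic` -> :func:`detect_peaks`.  Replicate spots are averaged
with :func:`average_replicates` (after interpolation to a common grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import savgol_filter

from maldimtu.errors import DegenerateInputError, ParameterError
from maldimtu.io import Spectrum


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError(f"peak intensity must be > 0, got {self.intensity}")
        if self.snr < 0:
            raise ValueError(f"peak snr must be >= 0, got {self.snr}")


@dataclass
class PeakList:
    """Detected peaks of one spectrum, ascending in m/z."""

    spectrum_id: str
    peaks: list[Peak]
    isolate_id: str = ""
    group: str = "isolate"
    target_id: str = ""
    noise_level: float = 0.0
    infinite_snr: bool = False  # zero-noise sentinel: snr fields are +inf
    warp_coeffs: tuple[float, float] | None = None  # (a, b) of mz' = a*mz + b
    warp_flagged: bool = False  # too few reference matches; returned unwarped

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs):
            self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @property
    def snr(self) -> np.ndarray:
        return np.array([p.snr for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "spectrum_id": self.spectrum_id,
                "mz": self.mz,
                "intensity": self.intensity,
                "snr": self.snr,
            }
        )


@dataclass(frozen=True)
class ParamSet:
    """The seven tunable preprocessing/alignment parameters."""

    smooth_halfwindow: int
    baseline_halfwindow: int
    align_halfwindow: int
    align_tolerance: float  # relative mass tolerance (0.002 = 2000 ppm)
    align_snr: float
    peak_halfwindow: int
    peak_snr: float

    def __post_init__(self) -> None:
        for name in ("smooth_halfwindow", "baseline_halfwindow",
                     "align_halfwindow", "peak_halfwindow"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.align_tolerance <= 0:
            raise ParameterError("align_tolerance must be > 0")
        if self.align_snr <= 0 or self.peak_snr <= 0:
            raise ParameterError("SNR thresholds must be > 0")

    def as_dict(self) -> dict:
        return {
            "smooth_halfwindow": self.smooth_halfwindow,
            "baseline_halfwindow": self.baseline_halfwindow,
            "align_halfwindow": self.align_halfwindow,
            "align_tolerance": self.align_tolerance,
            "align_snr": self.align_snr,
            "peak_halfwindow": self.peak_halfwindow,
            "peak_snr": self.peak_snr,
        }


def smooth(spectrum: Spectrum, half_window: int) -> Spectrum:
    """Savitzky-Golay smoothing (order 3, window ``2*half_window + 1``).

    Negative fitted intensities are clipped to zero.
    """
    if half_window < 2:
        raise ParameterError("smooth half_window must be >= 2 for an order-3 fit")
    window = 2 * half_window + 1
    if window > len(spectrum):
        raise ParameterError(
            f"smoothing window {window} longer than spectrum ({len(spectrum)} points)"
        )
    out = savgol_filter(spectrum.intensity, window_length=window, polyorder=3)
    return spectrum.replace_intensity(np.clip(out, 0.0, None))


def subtract_baseline(spectrum: Spectrum, half_window: int) -> Spectrum:
    """TopHat baseline removal: subtract the morphological opening.

    The opening (erosion then dilation, flat structuring element of
    ``2*half_window + 1`` points) tracks the slowly varying floor and is
    everywhere <= the signal, so the output is non-negative.
    """
    if half_window < 1:
        raise ParameterError("baseline half_window must be >= 1")
    size = 2 * half_window + 1
    if size > len(spectrum):
        raise ParameterError(
            f"baseline window {size} longer than spectrum ({len(spectrum)} points)"
        )
    eroded = minimum_filter1d(spectrum.intensity, size=size, mode="nearest")
    opened = maximum_filter1d(eroded, size=size, mode="nearest")
    return spectrum.replace_intensity(spectrum.intensity - opened)


def normalize_tic(spectrum: Spectrum) -> Spectrum:
    """Scale intensities to unit total ion current."""
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise DegenerateInputError(
            f"{spectrum.spectrum_id}: total intensity is zero, cannot normalize"
        )
    return spectrum.replace_intensity(spectrum.intensity / total)


def estimate_noise(spectrum: Spectrum) -> float:
    """Robust noise level: 1.4826 x median absolute deviation about the median."""
    if len(spectrum) < 10:
        raise ParameterError("noise estimation needs >= 10 points")
    intensity = spectrum.intensity
    return float(1.4826 * np.median(np.abs(intensity - np.median(intensity))))


def detect_peaks(spectrum: Spectrum, half_window: int, snr: float) -> PeakList:
    """Local-maximum peak picking with an SNR floor.

    A point is a peak iff it is the maximum within +-*half_window* points
    (ties broken toward lower m/z) and its intensity is at least
    ``snr * noise_level``.  With zero noise and nonzero signal, peaks are
    returned with ``snr = +inf`` and the list is flagged.
    """
    if half_window < 1:
        raise ParameterError("peak half_window must be >= 1")
    intensity = spectrum.intensity
    n = intensity.size
    noise = estimate_noise(spectrum)
    threshold = snr * noise
    size = 2 * half_window + 1
    window_max = maximum_filter1d(intensity, size=size, mode="nearest")
    candidates = np.flatnonzero(
        (intensity > 0) & (intensity >= threshold) & (intensity == window_max)
    )
    kept = []
    for i in candidates:
        lo = max(0, i - half_window)
        # tie toward lower m/z: reject i if an equal value sits earlier in its window
        if np.any(intensity[lo:i] == intensity[i]):
            continue
        kept.append(int(i))
    infinite = noise == 0.0 and len(kept) > 0
    peaks = [
        Peak(
            mz=float(spectrum.mz[i]),
            intensity=float(intensity[i]),
            snr=float(intensity[i] / noise) if noise > 0 else float("inf"),
        )
        for i in kept
    ]
    return PeakList(
        spectrum_id=spectrum.spectrum_id,
        peaks=peaks,
        isolate_id=spectrum.isolate_id,
        group=spectrum.group,
        target_id=spectrum.target_id,
        noise_level=noise,
        infinite_snr=infinite,
    )


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra on the grid of the first one.

    Spectra on different grids are linearly interpolated onto the first
    grid before averaging.  The output spectrum_id concatenates the source
    ids with ``+``.
    """
    if not spectra:
        raise ParameterError("average_replicates needs at least one spectrum")
    first = spectra[0]
    if len(spectra) == 1:
        return first
    grid = first.mz
    stack = np.empty((len(spectra), grid.size))
    for k, sp in enumerate(spectra):
        if sp.mz.size == grid.size and np.array_equal(sp.mz, grid):
            stack[k] = sp.intensity
        else:
            stack[k] = np.interp(grid, sp.mz, sp.intensity)
    mean = stack.mean(axis=0)
    return Spectrum(
        spectrum_id="+".join(sp.spectrum_id for sp in spectra),
        isolate_id=first.isolate_id,
        group=first.group,
        target_id=first.target_id,
        mz=grid,
        intensity=mean,
        mass_range=first.mass_range,
    )


def preprocess_spectrum(
    spectrum: Spectrum, params: ParamSet, normalize: str = "tic"
) -> PeakList:
    """Run the fixed pipeline smooth -> baseline -> normalize -> detect."""
    sp = smooth(spectrum, params.smooth_halfwindow)
    sp = subtract_baseline(sp, params.baseline_halfwindow)
    if normalize == "tic":
        sp = normalize_tic(sp)
    return detect_peaks(sp, params.peak_halfwindow, params.peak_snr)
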