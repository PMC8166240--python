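"""Cross-spectrum peak alignment (linear mass warping) and binning."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from maldimtu.errors import ParameterError, ValidationError
from maldimtu.preprocess import Peak, PeakList


@dataclass
class FeatureMatrix:
    """Spectra x aligned-peak-bin intensity matrix with a presence mask."""

    bin_mz: np.ndarray  # bin centers, strictly ascending
    spectrum_ids: list[str]
    intensity: np.ndarray  # spectra x bins, 0 = absent
    presence: np.ndarray  # boolean, same shape
    n_input_peaks: int = 0
    n_dropped: int = 0  # same-spectrum bin conflicts resolved by dropping

    def __post_init__(self) -> None:
        self.bin_mz = np.asarray(self.bin_mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.presence = np.asarray(self.presence, dtype=bool)
        n, b = len(self.spectrum_ids), self.bin_mz.size
        if self.intensity.shape != (n, b) or self.presence.shape != (n, b):
            raise ValidationError("feature matrix shapes inconsistent")
        if b > 1 and not np.all(np.diff(self.bin_mz) > 0):
            raise ValidationError("bin centers must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValidationError("feature intensities must be >= 0")
        if not np.array_equal(self.presence, self.intensity > 0):
            raise ValidationError("presence mask must equal (intensity > 0)")

    @property
    def n_spectra(self) -> int:
        return len(self.spectrum_ids)

    @property
    def n_bins(self) -> int:
        return int(self.bin_mz.size)

    def subset_rows(self, indices) -> "FeatureMatrix":
        indices = list(indices)
        return FeatureMatrix(
            bin_mz=self.bin_mz.copy(),
            spectrum_ids=[self.spectrum_ids[i] for i in indices],
            intensity=self.intensity[indices].copy(),
            presence=self.presence[indices].copy(),
        )

    def subset_cols(self, indices) -> "FeatureMatrix":
        """Column subset; duplicated columns allowed (bootstrap resampling)."""
        idx = np.asarray(indices, dtype=int)
        order = np.argsort(self.bin_mz[idx], kind="stable")
        idx = idx[order]
        # de-duplicate centers so the ascending invariant holds; bootstrap
        # weights are carried by repeating intensities into distinct columns
        centers = self.bin_mz[idx]
        jitter = np.arange(centers.size) * 1e-9
        return FeatureMatrix(
            bin_mz=centers + jitter,
            spectrum_ids=list(self.spectrum_ids),
            intensity=self.intensity[:, idx].copy(),
            presence=self.presence[:, idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.intensity,
            index=pd.Index(self.spectrum_ids, name="spectrum_id"),
            columns=[repr(float(m)) for m in self.bin_mz],
        )
        return frame

    @classmethod
    def read_csv(cls, path: str) -> "FeatureMatrix":
        # round_trip parser: bitwise-exact write/read cycles
        return cls.from_frame(
            pd.read_csv(path, index_col=0, float_precision="round_trip")
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        intensity = frame.to_numpy(dtype=float)
        return cls(
            bin_mz=np.array([float(c) for c in frame.columns]),
            spectrum_ids=[str(i) for i in frame.index],
            intensity=intensity,
            presence=intensity > 0,
        )


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


def _group_by_tolerance(entries: list[tuple[float, float, int]], tolerance: float):
    """Greedy largest-gap splitting of (mz, intensity, spectrum) tuples.

    A group is acceptable when every member lies within ``tolerance * mean``
    of the group mean and no spectrum contributes two members.  Groups that
    cannot be split further (all identical m/z) resolve same-spectrum
    conflicts by keeping the most intense member; the dropped count is
    returned alongside the groups.
    """
    entries = sorted(entries, key=lambda e: (e[0], e[2]))
    dropped = 0
    out: list[list[tuple[float, float, int]]] = []
    stack = [entries] if entries else []
    while stack:
        group = stack.pop()
        mzs = np.array([e[0] for e in group])
        mean = mzs.mean()
        specs = [e[2] for e in group]
        within_tol = np.all(np.abs(mzs - mean) <= tolerance * mean)
        no_conflict = len(set(specs)) == len(specs)
        if within_tol and no_conflict:
            out.append(group)
            continue
        gaps = np.diff(mzs)
        if gaps.size == 0 or gaps.max() == 0:
            # unsplittable: resolve conflicts by intensity
            best: dict[int, tuple[float, float, int]] = {}
            for e in group:
                if e[2] not in best or e[1] > best[e[2]][1]:
                    best[e[2]] = e
            dropped += len(group) - len(best)
            out.append(sorted(best.values(), key=lambda e: e[0]))
            continue
        cut = int(np.argmax(gaps)) + 1
        stack.append(group[:cut])
        stack.append(group[cut:])
    out.sort(key=lambda g: np.mean([e[0] for e in g]))
    return out, dropped


def warp_spectra(
    peaklists: list[PeakList],
    align_halfwindow: int,
    align_tolerance: float,
    align_snr: float,
    min_frequency: float = 0.9,
) -> list[PeakList]:
    """Linear mass-drift correction against consensus reference peaks.

    Anchor peaks (snr >= *align_snr*) present in at least *min_frequency*
    of the spectra define reference masses; each spectrum then gets a
    least-squares linear correction ``mz' = a*mz + b`` fitted on its
    matched reference peaks and applied to all its peaks.  Spectra with
    fewer than two matches are returned unwarped and flagged.
    """
    if len(peaklists) < 2:
        raise ParameterError("warping needs at least 2 peak lists")
    if align_halfwindow < 1 or align_tolerance <= 0 or align_snr <= 0:
        raise ParameterError("invalid alignment parameters")
    n = len(peaklists)
    anchors: list[tuple[float, float, int]] = []
    for k, pl in enumerate(peaklists):
        for p in pl.peaks:
            if p.snr >= align_snr or pl.infinite_snr:
                anchors.append((p.mz, p.intensity, k))
    groups, _ = _group_by_tolerance(anchors, align_tolerance)
    references = [g for g in groups if len(g) >= min_frequency * n]
    if not references:
        warnings.warn("no reference peaks found; returning identity warp for all")
        return [
            replace(pl, warp_coeffs=(1.0, 0.0), warp_flagged=False)
            for pl in peaklists
        ]
    ref_mz = np.array([np.mean([e[0] for e in g]) for g in references])
    out: list[PeakList] = []
    for k, pl in enumerate(peaklists):
        obs, ref = [], []
        for g, r in zip(references, ref_mz):
            members = [e for e in g if e[2] == k]
            if members:
                obs.append(members[0][0])
                ref.append(r)
        if len(obs) < 2:
            out.append(replace(pl, warp_coeffs=None, warp_flagged=True))
            continue
        design = np.vstack([np.asarray(obs), np.ones(len(obs))]).T
        (a, b), *_ = np.linalg.lstsq(design, np.asarray(ref), rcond=None)
        warped = [
            Peak(mz=float(a * p.mz + b), intensity=p.intensity, snr=p.snr)
            for p in pl.peaks
        ]
        out.append(replace(pl, peaks=warped, warp_coeffs=(float(a), float(b)),
                           warp_flagged=False))
    return out


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_peaks(peaklists: list[PeakList], tolerance: float) -> FeatureMatrix:
    """Strict binning of warped peak lists into a shared feature matrix.

    All peaks are pooled, sorted by m/z and greedily split at the largest
    gap until each bin is within *tolerance* of its mean and holds at most
    one peak per spectrum; unsplittable same-spectrum conflicts keep the
    more intense peak.  Bin centers are member means.
    """
    if tolerance <= 0:
        raise ParameterError("binning tolerance must be > 0")
    entries: list[tuple[float, float, int]] = []
    for k, pl in enumerate(peaklists):
        for p in pl.peaks:
            entries.append((p.mz, p.intensity, k))
    n = len(peaklists)
    if not entries:
        return FeatureMatrix(
            bin_mz=np.empty(0),
            spectrum_ids=[pl.spectrum_id for pl in peaklists],
            intensity=np.zeros((n, 0)),
            presence=np.zeros((n, 0), dtype=bool),
        )
    groups, dropped = _group_by_tolerance(entries, tolerance)
    centers = np.array([np.mean([e[0] for e in g]) for g in groups])
    intensity = np.zeros((n, len(groups)))
    for j, g in enumerate(groups):
        for mz, inten, k in g:
            intensity[k, j] = inten
    return FeatureMatrix(
        bin_mz=centers,
        spectrum_ids=[pl.spectrum_id for pl in peaklists],
        intensity=intensity,
        presence=intensity > 0,
        n_input_peaks=len(entries),
        n_dropped=dropped,
    )
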