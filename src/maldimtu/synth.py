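"""Synthetic linear-mode MALDI-TOF libraries with known ground truth.

Species carry fixed peak templates; strains inherit most template peaks and
add private ones; each rendered spectrum gets Gaussian peak shapes on a
regular m/z grid, a decaying-exponential baseline, i.i.d. Gaussian noise
and a per-target multiplicative mass drift.  A matching 16S-style percent
identity matrix is generated directly (the pipeline only ever consumes
identities, never sequences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from maldimtu.errors import ParameterError
from maldimtu.io import IdentityMatrix, Spectrum


@dataclass(frozen=True)
class SynthConfig:
    n_species: int = 20
    strains_per_species: int = 3
    peaks_per_species: int = 30
    shared_peak_fraction: float = 0.9  # within-species template retention
    between_shared_fraction: float = 0.1  # template peaks from a global pool
    mass_range: tuple[float, float] = (1880.0, 20000.0)
    peak_sigma: float = 3.0  # Da
    drift_per_target: float = 5e-4  # relative, multiplicative
    noise_sd: float = 1.0
    baseline_amplitude: float = 20.0
    baseline_decay: float = 2000.0  # Da
    grid_step: float = 1.0
    n_targets: int = 2
    bts_n_peaks: int = 21
    within_identity: float = 99.5
    between_identity: float = 85.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shared_peak_fraction", "between_shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.mass_range[0] >= self.mass_range[1]:
            raise ParameterError("mass_range must be (low, high) with low < high")
        for name in ("n_species", "strains_per_species", "peaks_per_species",
                     "n_targets", "bts_n_peaks"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        lo, hi = self.mass_range
        return np.arange(lo, hi + self.grid_step / 2, self.grid_step)


def _draw_template(rng: np.random.Generator, cfg: SynthConfig, n_peaks: int,
                   pool: np.ndarray | None = None,
                   pool_fraction: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Peak masses (sorted) and log-normal intensities for one template."""
    lo, hi = cfg.mass_range
    margin = 50.0 * cfg.peak_sigma
    n_pool = int(round(pool_fraction * n_peaks)) if pool is not None else 0
    n_pool = min(n_pool, 0 if pool is None else pool.size)
    masses = []
    if n_pool:
        masses.append(rng.choice(pool, size=n_pool, replace=False))
    masses.append(rng.uniform(lo + margin, hi - margin, size=n_peaks - n_pool))
    mz = np.sort(np.concatenate(masses))
    if np.any(np.diff(mz) < 4 * cfg.peak_sigma):
        warnings.warn("template peaks closer than 4 sigma; bins may merge")
    intensity = rng.lognormal(mean=np.log(100.0), sigma=0.7, size=mz.size)
    return mz, intensity


def render_spectrum(
    peak_mz: np.ndarray,
    peak_intensity: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator,
    drift: float = 0.0,
    spectrum_id: str = "synthetic",
    isolate_id: str = "synthetic",
    group: str = "isolate",
    target_id: str = "T1",
    noise_sd: float | None = None,
) -> Spectrum:
    """Render Gaussian peaks + baseline + noise onto the configured grid."""
    grid = cfg.grid
    signal = np.zeros_like(grid)
    shifted = np.asarray(peak_mz, dtype=float) * (1.0 + drift)
    sigma = cfg.peak_sigma
    for m, a in zip(shifted, peak_intensity):
        lo = np.searchsorted(grid, m - 6 * sigma)
        hi = np.searchsorted(grid, m + 6 * sigma)
        window = grid[lo:hi]
        signal[lo:hi] += a * np.exp(-0.5 * ((window - m) / sigma) ** 2)
    baseline = cfg.baseline_amplitude * np.exp(-(grid - grid[0]) / cfg.baseline_decay)
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    noise = rng.normal(0.0, sd, size=grid.size) if sd > 0 else 0.0
    intensity = np.clip(signal + baseline + noise, 0.0, None)
    return Spectrum(
        spectrum_id=spectrum_id,
        isolate_id=isolate_id,
        group=group,
        target_id=target_id,
        mz=grid,
        intensity=intensity,
        mass_range=cfg.mass_range,
    )


def generate_library(
    cfg: SynthConfig,
) -> tuple[list[Spectrum], pd.DataFrame, IdentityMatrix]:
    """Generate one spectrum per strain plus truth labels and identities.

    Returns ``(spectra, truth, identity)`` where *truth* has columns
    ``spectrum_id, isolate_id, species, target_id``.  Fully reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mass_range
    margin = 50.0 * cfg.peak_sigma
    pool = rng.uniform(lo + margin, hi - margin,
                       size=max(cfg.peaks_per_species, 30))
    drifts = rng.uniform(-cfg.drift_per_target, cfg.drift_per_target,
                         size=cfg.n_targets)
    spectra: list[Spectrum] = []
    rows = []
    isolate_ids: list[str] = []
    species_of: list[int] = []
    k = 0
    for s in range(cfg.n_species):
        t_mz, t_int = _draw_template(
            rng, cfg, cfg.peaks_per_species, pool, cfg.between_shared_fraction
        )
        for strain in range(cfg.strains_per_species):
            n_keep = int(round(cfg.shared_peak_fraction * t_mz.size))
            # strain variation hits minor peaks: the intense half of the
            # template is always retained, losses come from the weak half
            order_int = np.argsort(t_int)[::-1]
            n_top = min((t_mz.size + 1) // 2, n_keep)
            top, rest = order_int[:n_top], order_int[n_top:]
            extra = rng.choice(rest, size=n_keep - n_top, replace=False) \
                if n_keep > n_top else np.empty(0, dtype=int)
            keep = np.concatenate([top, extra])
            p_mz, p_int = _draw_template(rng, cfg, t_mz.size - n_keep)
            mz = np.concatenate([t_mz[keep], p_mz])
            # strain-private peaks are minor relative to the species template
            inten = np.concatenate(
                [t_int[keep] * rng.lognormal(0.0, 0.15, size=n_keep), 0.3 * p_int]
            )
            order = np.argsort(mz)
            isolate = f"S{s + 1:02d}R{strain + 1}"
            target = f"T{(k % cfg.n_targets) + 1}"
            spectra.append(
                render_spectrum(
                    mz[order], inten[order], cfg, rng,
                    drift=drifts[k % cfg.n_targets],
                    spectrum_id=f"{isolate}_sp1",
                    isolate_id=isolate,
                    target_id=target,
                )
            )
            rows.append({"spectrum_id": f"{isolate}_sp1", "isolate_id": isolate,
                         "species": f"species_{s + 1:02d}", "target_id": target})
            isolate_ids.append(isolate)
            species_of.append(s)
            k += 1
    identity = _identity_matrix(rng, cfg, isolate_ids, species_of)
    return spectra, pd.DataFrame(rows), identity


def _identity_matrix(rng: np.random.Generator, cfg: SynthConfig,
                     isolate_ids: list[str], species_of: list[int]) -> IdentityMatrix:
    n = len(isolate_ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            if species_of[i] == species_of[j]:
                v = cfg.within_identity + rng.uniform(-0.3, 0.3)
            else:
                v = cfg.between_identity + rng.uniform(-3.0, 3.0)
            v = float(np.clip(v, 70.0, 100.0))
            values[i, j] = values[j, i] = v
    return IdentityMatrix(list(isolate_ids), values)


def generate_bts(
    cfg: SynthConfig,
    n_targets: int = 2,
    replicates_per_target: int = 2,
    target_drifts: np.ndarray | None = None,
) -> list[Spectrum]:
    """Replicate reference-standard spectra from one fixed peak template.

    The template (``cfg.bts_n_peaks`` peaks) depends only on ``cfg.seed``;
    each target applies its own mass drift (drawn from
    ``cfg.drift_per_target`` unless *target_drifts* is given) and each
    replicate its own noise.
    """
    rng = np.random.default_rng(cfg.seed + 10_000)
    lo, hi = cfg.mass_range
    margin = 50.0 * cfg.peak_sigma
    mz = np.sort(rng.uniform(lo + margin, hi - margin, size=cfg.bts_n_peaks))
    inten = rng.lognormal(mean=np.log(150.0), sigma=0.5, size=cfg.bts_n_peaks)
    if target_drifts is None:
        target_drifts = rng.uniform(-cfg.drift_per_target, cfg.drift_per_target,
                                    size=n_targets)
    target_drifts = np.asarray(target_drifts, dtype=float)
    if target_drifts.size != n_targets:
        raise ParameterError("target_drifts length must equal n_targets")
    spectra = []
    for t in range(n_targets):
        for r in range(replicates_per_target):
            spectra.append(
                render_spectrum(
                    mz, inten, cfg, rng, drift=float(target_drifts[t]),
                    spectrum_id=f"BTS_T{t + 1}_r{r + 1}",
                    isolate_id="BTS",
                    group="bts_reference",
                    target_id=f"T{t + 1}",
                )
            )
    return spectra


def generate_qc_set(
    cfg: SynthConfig, n_good: int = 114, n_bad: int = 8
) -> tuple[list[Spectrum], list[str]]:
    """A library with deliberately degraded spectra planted in it.

    Good spectra are strong-signal renderings of per-isolate templates;
    bad ones either carry too few peaks or signal barely above the noise,
    so they fail the peak-count or SNR quality rule.  Returns the spectra
    and the ids of the planted failures.
    """
    rng = np.random.default_rng(cfg.seed + 77)
    spectra: list[Spectrum] = []
    bad_ids: list[str] = []
    for i in range(n_good + n_bad):
        sid = f"QC{i + 1:03d}"
        bad = i >= n_good
        if bad and i % 2 == 0:
            n_peaks = int(rng.integers(3, 8))  # fails the >= 13 peak rule
            scale = 1.0
        elif bad:
            n_peaks = 30
            scale = 0.012  # signal ~ noise: fails the median-SNR rule
        else:
            n_peaks = 30
            scale = 1.0
        mz, inten = _draw_template(rng, cfg, n_peaks)
        spectra.append(
            render_spectrum(
                mz, inten * scale, cfg, rng,
                spectrum_id=sid, isolate_id=sid,
                noise_sd=max(cfg.noise_sd, 1.0),
            )
        )
        if bad:
            bad_ids.append(sid)
    return spectra, bad_ids
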