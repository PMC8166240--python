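"""Random-search tuning of the seven pipeline parameters, plus spectrum QC.

Loop 1 maximizes the mean pairwise Jaccard coefficient between per-target
average reference (BTS) peak sets — a pure reproducibility objective.
Between the loops, spectra failing the quality rule (median SNR of the 10
largest peaks >= 15 and at least 13 peaks) are pruned.  Loop 2 then
minimizes the overlap in similarity values between pairs of isolates that
are practically identical by 16S (>= 99% identity) and all other pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from maldimtu.align import bin_peaks, warp_spectra
from maldimtu.errors import MaldimtuError, ParameterError, ValidationError
from maldimtu.io import IdentityMatrix, Spectrum
from maldimtu.preprocess import ParamSet, PeakList, average_replicates, preprocess_spectrum
from maldimtu.similarity import cosine_matrix, jaccard_matrix

_INT_FIELDS = ("smooth_halfwindow", "baseline_halfwindow", "align_halfwindow",
               "peak_halfwindow")
_LOG_FIELDS = ("align_tolerance",)
_FLOAT_FIELDS = ("align_snr", "peak_snr")


@dataclass(frozen=True)
class ParamRanges:
    """(low, high) sampling bounds for each tunable parameter.

    Integer half-windows are sampled uniformly on integers, SNR thresholds
    uniformly on reals, and the alignment tolerance log-uniformly.
    """

    smooth_halfwindow: tuple[int, int] = (2, 25)
    baseline_halfwindow: tuple[int, int] = (10, 200)
    align_halfwindow: tuple[int, int] = (5, 50)
    align_tolerance: tuple[float, float] = (2e-4, 1e-2)
    align_snr: tuple[float, float] = (1.0, 10.0)
    peak_halfwindow: tuple[int, int] = (5, 50)
    peak_snr: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        for name in _INT_FIELDS + _LOG_FIELDS + _FLOAT_FIELDS:
            lo, hi = getattr(self, name)
            if lo <= 0:
                raise ParameterError(f"{name}: bounds must be positive")
            if lo > hi:
                raise ParameterError(f"{name}: low must not exceed high")


def sample_params(ranges: ParamRanges, rng_seed) -> ParamSet:
    """Draw one ParamSet; deterministic given the seed (or Generator)."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    values: dict[str, float] = {}
    for name in _INT_FIELDS:
        lo, hi = getattr(ranges, name)
        values[name] = int(rng.integers(int(lo), int(hi) + 1))
    for name in _LOG_FIELDS:
        lo, hi = getattr(ranges, name)
        values[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    for name in _FLOAT_FIELDS:
        lo, hi = getattr(ranges, name)
        values[name] = float(rng.uniform(lo, hi))
    return ParamSet(**values)


# ---------------------------------------------------------------------------
# shared pipeline step
# ---------------------------------------------------------------------------


def build_feature_matrix(spectra: list[Spectrum], params: ParamSet,
                         normalize: str = "tic"):
    """Preprocess, warp and bin a list of spectra under one ParamSet."""
    peaklists = [preprocess_spectrum(sp, params, normalize=normalize)
                 for sp in spectra]
    if len(peaklists) >= 2 and any(len(pl) for pl in peaklists):
        peaklists = warp_spectra(
            peaklists, params.align_halfwindow, params.align_tolerance,
            params.align_snr,
        )
    return bin_peaks(peaklists, params.align_tolerance), peaklists


# ---------------------------------------------------------------------------
# loop 1: BTS reproducibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BTSObjective:
    mean_jaccard: float
    shared_peaks: int
    total_bins: int
    failed: bool = False


def objective_bts(bts_spectra: list[Spectrum], params: ParamSet) -> BTSObjective:
    """Mean pairwise Jaccard between per-target average BTS peak sets.

    Replicate BTS spots on the same target are averaged first.  Any stage
    failing under extreme parameters scores 0 with ``failed=True`` so the
    random search can continue.
    """
    targets: dict[str, list[Spectrum]] = {}
    for sp in bts_spectra:
        targets.setdefault(sp.target_id, []).append(sp)
    if len(targets) < 2:
        raise ParameterError("objective_bts needs BTS spectra on >= 2 targets")
    try:
        averages = [average_replicates(group) for group in targets.values()]
        fm, _ = build_feature_matrix(averages, params)
        if fm.n_bins == 0:
            return BTSObjective(0.0, 0, 0, failed=True)
        jac = jaccard_matrix(fm)
        iu = np.triu_indices(fm.n_spectra, k=1)
        mean_j = float(jac[iu].mean())
        best = np.unravel_index(np.argmax(np.where(np.eye(fm.n_spectra, dtype=bool),
                                                   -1.0, jac)), jac.shape)
        shared = int(np.sum(fm.presence[best[0]] & fm.presence[best[1]]))
        return BTSObjective(mean_j, shared, fm.n_bins)
    except MaldimtuError:
        return BTSObjective(0.0, 0, 0, failed=True)


def run_loop1(
    spectra: list[Spectrum],
    ranges: ParamRanges,
    n_iter: int,
    seed: int,
) -> tuple[pd.DataFrame, ParamSet]:
    """Random search maximizing the BTS reproducibility objective."""
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    best_params: ParamSet | None = None
    best_key = (-1.0, -1)
    for it in range(n_iter):
        params = sample_params(ranges, rng)
        res = objective_bts(spectra, params)
        rows.append({"iteration": it, **params.as_dict(),
                     "mean_jaccard": res.mean_jaccard,
                     "shared_peaks": res.shared_peaks,
                     "total_bins": res.total_bins,
                     "failed": res.failed})
        key = (res.mean_jaccard, res.shared_peaks)
        if key > best_key:  # strict: ties keep the earlier iteration
            best_key, best_params = key, params
    assert best_params is not None
    return pd.DataFrame(rows), best_params


# ---------------------------------------------------------------------------
# QC filter between the loops
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Per-spectrum peak-count / SNR quality decisions."""

    frame: pd.DataFrame  # spectrum_id, n_peaks, median_snr_top10, passed
    snr_threshold: float
    top_k: int
    min_peaks: int

    @property
    def passed_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["passed"], "spectrum_id"])

    @property
    def failed_ids(self) -> list[str]:
        return list(self.frame.loc[~self.frame["passed"], "spectrum_id"])

    @property
    def n_failed(self) -> int:
        return int((~self.frame["passed"]).sum())

    def to_frame(self) -> pd.DataFrame:
        return self.frame


def qc_filter(
    peaklists: list[PeakList],
    snr_threshold: float = 15.0,
    top_k: int = 10,
    min_peaks: int = 13,
) -> QCReport:
    """Prune noisy spectra by median top-SNR and minimum peak count.

    A spectrum passes iff the median SNR of its *top_k* most intense peaks
    is >= *snr_threshold* and it has at least *min_peaks* peaks.  Spectra
    with fewer than *top_k* peaks use the median over all their peaks; an
    empty peak list simply fails.
    """
    rows = []
    for pl in peaklists:
        n = len(pl)
        if n == 0:
            med = 0.0
        else:
            order = np.argsort(pl.intensity)[::-1][:top_k]
            med = float(np.median(pl.snr[order]))
        passed = bool(med >= snr_threshold and n >= min_peaks)
        rows.append({"spectrum_id": pl.spectrum_id, "n_peaks": n,
                     "median_snr_top10": med, "passed": passed})
    return QCReport(pd.DataFrame(rows), snr_threshold, top_k, min_peaks)


# ---------------------------------------------------------------------------
# loop 2: within/between discrimination
# ---------------------------------------------------------------------------


def pair_labels_from_identity(
    isolate_ids: list[str],
    identity: IdentityMatrix,
    threshold: float = 99.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Label each spectrum pair as within-species (identity >= threshold).

    Returns boolean matrices ``(within, valid)``; pairs involving an
    isolate absent from the identity matrix are invalid.
    """
    n = len(isolate_ids)
    idx = {sid: k for k, sid in enumerate(identity.sequence_ids)}
    pos = np.array([idx.get(i, -1) for i in isolate_ids])
    valid = (pos[:, None] >= 0) & (pos[None, :] >= 0)
    within = np.zeros((n, n), dtype=bool)
    ok = np.where(valid)
    within[ok] = identity.identity[pos[ok[0]], pos[ok[1]]] >= threshold
    np.fill_diagonal(valid, False)
    return within, valid


def objective_discrimination(similarity: np.ndarray, within: np.ndarray,
                             valid: np.ndarray | None = None) -> float:
    """Balanced misclassification rate of the best single threshold.

    ``overlap = min_t [P(within < t) + P(between >= t)] / 2``; 0 means the
    two similarity distributions are perfectly separable, 0.5 means they
    are indistinguishable.  Invariant under monotone transforms.
    """
    similarity = np.asarray(similarity, dtype=float)
    within = np.asarray(within, dtype=bool)
    if valid is None:
        valid = ~np.eye(similarity.shape[0], dtype=bool)
    iu = np.triu_indices(similarity.shape[0], k=1)
    use = valid[iu]
    sims, labels = similarity[iu][use], within[iu][use]
    w = sims[labels]
    b = sims[~labels]
    if w.size == 0:
        raise ValidationError("no within-class pairs to discriminate")
    if b.size == 0:
        raise ValidationError("no between-class pairs to discriminate")
    candidates = np.unique(np.concatenate([sims, [sims.max() + 1.0]]))
    best = 0.5
    for t in candidates:
        rate = (np.mean(w < t) + np.mean(b >= t)) / 2.0
        best = min(best, float(rate))
    return best


def run_loop2(
    spectra: list[Spectrum],
    identity: IdentityMatrix,
    ranges: ParamRanges,
    n_iter: int,
    seed: int,
    identity_threshold: float = 99.0,
    use_weighted: bool = False,
) -> tuple[pd.DataFrame, ParamSet]:
    """Random search minimizing the within/between similarity overlap.

    By default the raw cosine matrix is the discriminated similarity;
    ``use_weighted=True`` switches to the Jaccard-weighted cosine.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    best_params: ParamSet | None = None
    best_key = (2.0, -1.0)  # (overlap, -mean within jaccard)
    for it in range(n_iter):
        params = sample_params(ranges, rng)
        overlap, within_j, total_bins, failed = 1.0, 0.0, 0, True
        try:
            fm, _ = build_feature_matrix(spectra, params)
            if fm.n_bins > 0:
                isolate_ids = [sp.isolate_id for sp in spectra]
                within, valid = pair_labels_from_identity(
                    isolate_ids, identity, identity_threshold)
                jac = jaccard_matrix(fm)
                if use_weighted:
                    from maldimtu.similarity import fit_hyperbolic, weight_cosine

                    cos = cosine_matrix(fm)
                    model = fit_hyperbolic(jac, cos)
                    sim = weight_cosine(cos, jac, model)
                else:
                    sim = cosine_matrix(fm)
                overlap = objective_discrimination(sim, within, valid)
                iu = np.triu_indices(fm.n_spectra, k=1)
                mask = within[iu] & valid[iu]
                within_j = float(jac[iu][mask].mean()) if mask.any() else 0.0
                total_bins = fm.n_bins
                failed = False
        except MaldimtuError:
            pass
        rows.append({"iteration": it, **params.as_dict(), "overlap": overlap,
                     "mean_within_jaccard": within_j, "total_bins": total_bins,
                     "failed": failed})
        key = (overlap, -within_j)
        if key < best_key:  # strict: ties keep the earlier iteration
            best_key, best_params = key, params
    assert best_params is not None
    return pd.DataFrame(rows), best_params
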