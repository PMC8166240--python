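"""Pairwise spectral similarity: Jaccard, cosine, and the weighted combination.

Cosine similarities over aligned bin intensities are optimistic for pairs
that share very few peaks, so they are down-weighted by a hyperbolic
function of the Jaccard coefficient, ``y(x) = y0 + x / (x + 0.2)``, whose
intercept ``y0`` is the average cosine of near-disjoint pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from maldimtu.align import FeatureMatrix
from maldimtu.errors import ParameterError, ValidationError

SATURATION = 0.2  # fixed saturation constant of the hyperbolic model

COMBINERS = ("multiply", "min", "geometric_mean")


@dataclass(frozen=True)
class HyperbolicModel:
    """Predicted cosine as a hyperbolic function of Jaccard similarity."""

    y0: float
    saturation: float = SATURATION

    def __post_init__(self) -> None:
        if not 0.0 <= self.y0 <= 1.0:
            raise ValidationError(f"y0 must lie in [0, 1], got {self.y0}")

    def predict(self, jaccard) -> np.ndarray:
        x = np.asarray(jaccard, dtype=float)
        return self.y0 + x / (x + self.saturation)


@dataclass
class SimilarityBundle:
    spectrum_ids: list[str]
    jaccard: np.ndarray
    cosine: np.ndarray
    weighted: np.ndarray

    def __post_init__(self) -> None:
        for name in ("jaccard", "cosine", "weighted"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, m)
            n = len(self.spectrum_ids)
            if m.shape != (n, n):
                raise ValidationError(f"{name} matrix shape mismatch")
            if not np.allclose(m, m.T):
                raise ValidationError(f"{name} matrix not symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValidationError(f"{name} diagonal must be 1")
            if m.min() < -1e-12 or m.max() > 1 + 1e-12:
                raise ValidationError(f"{name} values must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        n = len(self.spectrum_ids)
        return n * (n - 1) // 2

    def pairs(self, which: str = "weighted") -> np.ndarray:
        m = getattr(self, which)
        iu = np.triu_indices(len(self.spectrum_ids), k=1)
        return m[iu]

    def to_frame(self, which: str = "weighted") -> pd.DataFrame:
        frame = pd.DataFrame(
            getattr(self, which), index=self.spectrum_ids, columns=self.spectrum_ids
        )
        frame.index.name = "spectrum_id"
        return frame


def jaccard_matrix(fm: FeatureMatrix) -> np.ndarray:
    """Presence-set Jaccard similarity, ``|A & B| / |A | B|``, per pair.

    Pairs with an empty union get 0 by convention (a warning is emitted).
    """
    if fm.n_spectra < 2:
        raise ParameterError("jaccard_matrix needs >= 2 spectra")
    p = fm.presence.astype(float)
    inter = p @ p.T
    counts = p.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    if np.any(union == 0):
        warnings.warn("pairs with empty bin union set to Jaccard 0")
    np.fill_diagonal(jac, 1.0)
    return jac


def cosine_matrix(fm: FeatureMatrix) -> np.ndarray:
    """Cosine similarity of bin-intensity vectors; zero vectors give 0."""
    if fm.n_spectra < 2:
        raise ParameterError("cosine_matrix needs >= 2 spectra")
    x = fm.intensity
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if np.any(zero):
        warnings.warn("spectra with all-zero intensity vectors set to cosine 0")
    safe = np.where(zero, 1.0, norms)
    unit = x / safe[:, None]
    cos = np.clip(unit @ unit.T, 0.0, 1.0)
    cos[zero, :] = 0.0
    cos[:, zero] = 0.0
    np.fill_diagonal(cos, 1.0)
    return cos


def fit_hyperbolic(
    jaccard: np.ndarray, cosine: np.ndarray, epsilon: float = 0.05
) -> HyperbolicModel:
    """Estimate the model intercept y0 from near-disjoint pairs.

    y0 is the mean observed cosine over pairs with Jaccard < *epsilon*.
    If fewer than 10 such pairs exist, the lowest decile of Jaccard values
    is used instead (with a warning).
    """
    jaccard = np.asarray(jaccard, dtype=float)
    cosine = np.asarray(cosine, dtype=float)
    if jaccard.shape != cosine.shape:
        raise ValidationError("jaccard/cosine shape mismatch")
    iu = np.triu_indices(jaccard.shape[0], k=1)
    j, c = jaccard[iu], cosine[iu]
    low = j < epsilon
    if low.sum() >= 10:
        y0 = float(c[low].mean())
    else:
        warnings.warn(
            f"fewer than 10 pairs with Jaccard < {epsilon}; "
            "using lowest decile of Jaccard instead"
        )
        cutoff = np.quantile(j, 0.1)
        y0 = float(c[j <= cutoff].mean())
    return HyperbolicModel(y0=min(max(y0, 0.0), 1.0))


def weight_cosine(
    cosine: np.ndarray,
    jaccard: np.ndarray,
    model: HyperbolicModel,
    combiner: str = "multiply",
) -> np.ndarray:
    """Down-weight cosine similarities by the predicted hyperbolic factor.

    Default combiner multiplies observed cosine by ``clamp(y(J), 0, 1)``;
    ``min`` and ``geometric_mean`` are alternatives.  Result is clipped to
    [0, 1] with unit diagonal.
    """
    cosine = np.asarray(cosine, dtype=float)
    jaccard = np.asarray(jaccard, dtype=float)
    if cosine.shape != jaccard.shape:
        raise ValidationError("cosine/jaccard shape mismatch")
    if combiner not in COMBINERS:
        raise ParameterError(f"unknown combiner {combiner!r}; choose from {COMBINERS}")
    factor = np.clip(model.predict(jaccard), 0.0, 1.0)
    if combiner == "multiply":
        w = cosine * factor
    elif combiner == "min":
        w = np.minimum(cosine, factor)
    else:
        w = np.sqrt(cosine * factor)
    w = np.clip(w, 0.0, 1.0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return w


def similarity_bundle(
    fm: FeatureMatrix, epsilon: float = 0.05, combiner: str = "multiply"
) -> tuple[SimilarityBundle, HyperbolicModel]:
    """Convenience wrapper: Jaccard + cosine + fitted model + weighted matrix."""
    jac = jaccard_matrix(fm)
    cos = cosine_matrix(fm)
    model = fit_hyperbolic(jac, cos, epsilon=epsilon)
    weighted = weight_cosine(cos, jac, model, combiner=combiner)
    return (
        SimilarityBundle(list(fm.spectrum_ids), jac, cos, weighted),
        model,
    )
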