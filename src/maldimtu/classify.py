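"""Supervised assignment of spectra to MTUs with accuracy and Cohen's kappa.

The default learner is a nearest-centroid classifier on cosine distance
over bin intensities (deterministic, no tuning); a decision tree is
available as an alternative.  Singleton MTUs must be removed before
training.  Both resubstitution and leave-one-out evaluation are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from maldimtu.align import FeatureMatrix
from maldimtu.errors import ParameterError, ValidationError

METHODS = ("nearest_centroid", "tree")
SCHEMES = ("resubstitution", "leave_one_out")


@dataclass
class ClassifierReport:
    """Confusion matrix plus the derived agreement statistics."""

    classes: list
    confusion: np.ndarray  # true x predicted counts; may carry a reject column
    accuracy: float
    kappa: float
    scheme: str
    method: str
    n_rejected: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_items(self) -> int:
        return int(self.confusion.sum())

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.classes) + (["<reject>"] if self.n_rejected else [])
        frame = pd.DataFrame(self.confusion, index=self.classes, columns=cols)
        frame.index.name = "true"
        return frame


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e).

    ``p_o`` is the diagonal fraction, ``p_e`` the expected agreement from
    the row/column marginals.  When ``p_e == 1`` the statistic is defined
    as 1 for perfect agreement and is an error otherwise.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValidationError("confusion matrix must hold non-negative counts")
    total = c.sum()
    if total <= 0:
        raise ValidationError("confusion matrix is empty")
    p_o = np.trace(c) / total
    p_e = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / total**2)
    if p_e >= 1.0 - 1e-15:
        if np.isclose(p_o, 1.0):
            return 1.0
        raise ValidationError("kappa undefined: expected agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class _CentroidModel:
    classes: list
    centroids: np.ndarray  # unit-normalized per class

    def predict(self, X: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(X, axis=1)
        norms = np.where(norms == 0, 1.0, norms)
        scores = (X / norms[:, None]) @ self.centroids.T
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]


@dataclass
class _TreeModel:
    classes: list
    tree: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.tree.predict(X)


def train_classifier(fm: FeatureMatrix, labels, method: str = "nearest_centroid",
                     seed: int = 0, _allow_singletons: bool = False):
    """Fit an MTU classifier on bin intensities.

    Every class needs >= 2 members (drop singleton MTUs first).  The
    nearest-centroid model stores the mean of the unit-normalized class
    rows; ``method="tree"`` fits a seeded decision tree instead.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != fm.n_spectra:
        raise ValidationError("labels must align with feature-matrix rows")
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2) and not _allow_singletons:
        bad = classes[counts < 2][0]
        raise ParameterError(
            f"class {bad!r} has a single member; remove singleton MTUs before training"
        )
    X = fm.intensity
    if method == "nearest_centroid":
        cents = []
        for cls in classes:
            rows = X[labels == cls]
            norms = np.linalg.norm(rows, axis=1)
            norms = np.where(norms == 0, 1.0, norms)
            mean = (rows / norms[:, None]).mean(axis=0)
            mnorm = np.linalg.norm(mean)
            cents.append(mean / mnorm if mnorm > 0 else mean)
        return _CentroidModel(list(classes), np.vstack(cents))
    from sklearn.tree import DecisionTreeClassifier

    tree = DecisionTreeClassifier(random_state=seed).fit(X, labels)
    return _TreeModel(list(classes), tree)


def evaluate(model, fm: FeatureMatrix, labels, scheme: str = "resubstitution",
             method: str = "nearest_centroid", seed: int = 0) -> ClassifierReport:
    """Confusion matrix, accuracy and kappa under the requested scheme.

    ``leave_one_out`` refits on all-but-one rows per item (the passed
    *model* provides the method/classes only).  Predictions outside the
    known classes land in a reject column and are flagged.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != fm.n_spectra:
        raise ValidationError("labels must align with feature-matrix rows")
    if scheme not in SCHEMES:
        raise ParameterError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    classes = sorted(set(labels.tolist()), key=str)
    index = {c: k for k, c in enumerate(classes)}
    if scheme == "resubstitution":
        predictions = model.predict(fm.intensity)
    else:
        predictions = np.empty(fm.n_spectra, dtype=object)
        for i in range(fm.n_spectra):
            keep = [j for j in range(fm.n_spectra) if j != i]
            sub = fm.subset_rows(keep)
            # leaving one item out may reduce a 2-member class to one;
            # that is fine for the refit, the full model was validated
            refit = train_classifier(sub, labels[keep], method=method,
                                     seed=seed, _allow_singletons=True)
            predictions[i] = refit.predict(fm.intensity[i : i + 1])[0]
    k = len(classes)
    confusion = np.zeros((k, k + 1), dtype=int)
    for true, pred in zip(labels, predictions):
        j = index.get(pred, k)
        confusion[index[true], j] += 1
    n_rejected = int(confusion[:, k].sum())
    square = confusion[:, :k]
    accuracy = float(np.trace(square) / confusion.sum())
    kappa = cohen_kappa(square if n_rejected == 0 else _padded(confusion, k))
    return ClassifierReport(
        classes=classes,
        confusion=confusion if n_rejected else square,
        accuracy=accuracy,
        kappa=kappa,
        scheme=scheme,
        method=method,
        n_rejected=n_rejected,
    )


def _padded(confusion: np.ndarray, k: int) -> np.ndarray:
    """Square up a confusion matrix holding a reject column."""
    out = np.zeros((k + 1, k + 1), dtype=int)
    out[:k, :] = confusion
    return out
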