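"""MTU definition: sigmoid threshold calibration, hierarchical clustering,
and bootstrap support for dendrogram nodes.

Isolates are clustered on distance ``1 - W`` (W = weighted cosine) with
average linkage and cut at ``1 - threshold``.  The operating threshold can
be derived from a four-parameter logistic fit of 16S percent identity
against weighted cosine similarity: the rule is midpoint minus 0.01,
rounded to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import curve_fit
from scipy.spatial.distance import squareform
from scipy.stats import norm

from maldimtu.align import FeatureMatrix
from maldimtu.errors import FitError, ParameterError, ValidationError


@dataclass
class MTUTable:
    """Flat cluster assignments at a similarity threshold."""

    spectrum_ids: list[str]
    mtu_ids: np.ndarray  # integer >= 1, parallel to spectrum_ids
    threshold: float

    def __post_init__(self) -> None:
        self.mtu_ids = np.asarray(self.mtu_ids, dtype=int)
        if self.mtu_ids.shape != (len(self.spectrum_ids),):
            raise ValidationError("mtu_ids length mismatch")
        if self.mtu_ids.min(initial=1) < 1:
            raise ValidationError("mtu ids must be >= 1")

    @property
    def n_mtus(self) -> int:
        return int(np.unique(self.mtu_ids).size)

    @property
    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.mtu_ids, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    @property
    def singletons(self) -> int:
        return int(sum(1 for c in self.sizes.values() if c == 1))

    @property
    def replicated(self) -> int:
        return int(sum(1 for c in self.sizes.values() if c > 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"spectrum_id": self.spectrum_ids, "mtu_id": self.mtu_ids}
        )


@dataclass(frozen=True)
class SigmoidModel:
    """Four-parameter logistic: y = lower + (upper-lower)/(1+exp(-slope*(x-mid)))."""

    lower: float
    upper: float
    midpoint: float
    slope: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValidationError("sigmoid lower asymptote must be < upper")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.lower + (self.upper - self.lower) / (
            1.0 + np.exp(-self.slope * (x - self.midpoint))
        )

    def derived_threshold(self) -> float:
        """Operating similarity cutoff: midpoint - 0.01, rounded to 2 decimals."""
        return round(self.midpoint - 0.01, 2)


def _logistic4(x, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (x - midpoint)))


def fit_sigmoid(pairs) -> SigmoidModel:
    """Nonlinear least-squares 4PL fit of (weighted cosine, percent identity).

    *pairs* is an iterable of ``(x, y)`` tuples or a 2-column array.
    Initialization comes from data quantiles; a constant response or a
    non-converging optimizer raises :class:`FitError`.
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 10:
        raise ParameterError("fit_sigmoid needs >= 10 (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(y) == 0:
        raise FitError("constant response; sigmoid fit is degenerate")
    lo0, hi0 = np.quantile(y, 0.05), np.quantile(y, 0.95)
    if hi0 <= lo0:
        lo0, hi0 = y.min(), y.max()
    mid0 = float(np.median(x))
    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    sign = np.sign(np.corrcoef(x, y)[0, 1]) or 1.0
    slope0 = sign * 4.0 / span
    try:
        popt, _ = curve_fit(
            _logistic4, x, y, p0=[lo0, hi0, mid0, slope0], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    lower, upper, midpoint, slope = (float(v) for v in popt)
    if lower > upper:  # canonical orientation (the 4PL is symmetric under swap)
        lower, upper, slope = upper, lower, -slope
    resid = y - _logistic4(x, lower, upper, midpoint, slope)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return SigmoidModel(lower, upper, midpoint, slope, r2)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _linkage_from_similarity(W: np.ndarray, method: str) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-8):
        raise ValidationError("similarity matrix must be square and symmetric")
    D = 1.0 - (W + W.T) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    return hierarchy.linkage(squareform(D, checks=False), method=method)


def cluster_mtus(
    W: np.ndarray,
    spectrum_ids: list[str],
    threshold: float = 0.65,
    linkage: str = "average",
) -> tuple[MTUTable, np.ndarray]:
    """Cut the average-linkage dendrogram of ``1 - W`` at ``1 - threshold``.

    MTU ids are assigned in order of first-occurring spectrum.  Returns the
    MTU table and the scipy linkage matrix.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must lie in (0, 1)")
    if linkage not in ("average", "complete", "single"):
        raise ParameterError(f"unsupported linkage {linkage!r}")
    Z = _linkage_from_similarity(W, linkage)
    raw = hierarchy.fcluster(Z, t=1.0 - threshold, criterion="distance")
    relabel: dict[int, int] = {}
    mtu_ids = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        mtu_ids[i] = relabel[r]
    return MTUTable(list(spectrum_ids), mtu_ids, threshold), Z


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------


@dataclass
class ClusterSupport:
    """Bootstrap proportions (and optional AU values) per internal node."""

    leaf_sets: list[frozenset[str]]  # one per internal node, linkage order
    bp: np.ndarray
    au: np.ndarray | None
    n_boot: int

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "node": np.arange(len(self.leaf_sets)),
                "size": [len(s) for s in self.leaf_sets],
                "bp": self.bp,
            }
        )
        if self.au is not None:
            frame["au"] = self.au
        return frame


def _clades(Z: np.ndarray, ids: list[str]) -> list[frozenset[str]]:
    n = len(ids)
    sets: list[frozenset[str]] = [frozenset([i]) for i in ids]
    for a, b, *_ in Z:
        sets.append(sets[int(a)] | sets[int(b)])
    return sets[n:]


def bootstrap_support(
    fm: FeatureMatrix,
    similarity_fn=None,
    n_boot: int = 100,
    seed: int = 0,
    linkage: str = "average",
    au: bool = False,
) -> ClusterSupport:
    """Column-resampling bootstrap of the dendrogram topology.

    Feature bins (columns) are resampled with replacement *n_boot* times;
    the similarity matrix and dendrogram are recomputed each time, and each
    observed internal node scores the fraction of replicates containing the
    same leaf set.  With ``au=True``, an approximately unbiased value is
    added per node by multiscale bootstrap (10 scales, 0.5-1.4 x n_bins,
    probit regression).
    """
    if fm.n_spectra < 3:
        raise ParameterError("bootstrap_support needs >= 3 spectra")
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    if similarity_fn is None:
        from maldimtu.similarity import similarity_bundle

        def similarity_fn(m):  # noqa: F811 - default pipeline
            return similarity_bundle(m)[0].weighted

    rng = np.random.default_rng(seed)
    W0 = similarity_fn(fm)
    Z0 = _linkage_from_similarity(W0, linkage)
    nodes = _clades(Z0, fm.spectrum_ids)

    def bp_at_scale(size: int, reps: int) -> np.ndarray:
        hits = np.zeros(len(nodes))
        for _ in range(reps):
            cols = rng.integers(0, fm.n_bins, size=size)
            sub = fm.subset_cols(cols)
            Zb = _linkage_from_similarity(similarity_fn(sub), linkage)
            observed = set(_clades(Zb, fm.spectrum_ids))
            for k, s in enumerate(nodes):
                if s in observed:
                    hits[k] += 1
        return hits / reps

    bp = bp_at_scale(fm.n_bins, n_boot)
    au_values = None
    if au:
        scales = np.linspace(0.5, 1.4, 10)
        sizes = np.maximum(1, np.round(scales * fm.n_bins).astype(int))
        r = sizes / fm.n_bins
        bp_scaled = np.vstack([bp_at_scale(int(s), n_boot) for s in sizes])
        eps = 1.0 / (n_boot + 1)
        z = norm.ppf(1.0 - np.clip(bp_scaled, eps, 1.0 - eps))
        au_values = np.empty(len(nodes))
        design = np.vstack([np.sqrt(r), 1.0 / np.sqrt(r)]).T
        for k in range(len(nodes)):
            # degenerate nodes (all scales at 0 or 1) bypass the regression
            if np.all(bp_scaled[:, k] >= 1.0 - eps):
                au_values[k] = 1.0
                continue
            if np.all(bp_scaled[:, k] <= eps):
                au_values[k] = 0.0
                continue
            (v, c), *_ = np.linalg.lstsq(design, z[:, k], rcond=None)
            au_values[k] = 1.0 - norm.cdf(v - c)
    return ClusterSupport(nodes, bp, au_values, n_boot)


# ---------------------------------------------------------------------------
# newick export
# ---------------------------------------------------------------------------


def dendrogram_to_newick(
    Z: np.ndarray,
    leaf_names: list[str],
    support: ClusterSupport | None = None,
) -> str:
    """Serialize a scipy linkage matrix as newick with support node labels."""
    tree = hierarchy.to_tree(Z)
    n = len(leaf_names)

    def label(node_id: int) -> str:
        if support is None:
            return ""
        k = node_id - n
        if k < 0 or k >= len(support.leaf_sets):
            return ""
        bp = support.bp[k]
        if support.au is not None:
            return f"{support.au[k]:.2f}/{bp:.2f}"
        return f"{bp:.2f}"

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6f}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}){label(node.id)}:{length:.6f}"

    body = walk(tree, tree.dist)
    return body + ";"
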