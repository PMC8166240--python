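"""Rarefaction, Chao1 extrapolation and sample-coverage estimation of MTU
richness (Hill number of order 0 only).

Interpolation uses the exact hypergeometric formula
``E[S(m)] = S_obs - sum_i C(n - x_i, m) / C(n, m)``; extrapolation uses the
Chao1-style unseen-richness estimate; coverage is the Good-Turing estimator
with the singleton/doubleton correction.  Confidence intervals come from a
seeded multinomial bootstrap of the abundance vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from maldimtu.errors import ParameterError
from maldimtu.cluster import MTUTable


@dataclass
class AbundanceVector:
    """Isolate counts per MTU with the derived Chao-type statistics."""

    counts: np.ndarray  # one entry per MTU, all >= 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size == 0 or np.any(self.counts < 1):
            raise ParameterError("abundance counts must all be >= 1")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int(self.counts.size)

    @property
    def f1(self) -> int:
        return int(np.sum(self.counts == 1))

    @property
    def f2(self) -> int:
        return int(np.sum(self.counts == 2))

    @property
    def f0_hat(self) -> float:
        """Chao1 estimate of the number of unseen MTUs."""
        n, f1, f2 = self.n, self.f1, self.f2
        if f2 > 0:
            return (n - 1) / n * f1**2 / (2 * f2)
        return (n - 1) / n * f1 * (f1 - 1) / 2

    @property
    def chao1(self) -> float:
        return self.s_obs + self.f0_hat


@dataclass
class DiversityEstimate:
    """Richness and coverage along a grid of hypothetical sample sizes."""

    m: np.ndarray
    method: list[str]  # "interpolated" | "observed" | "extrapolated"
    richness: np.ndarray
    coverage: np.ndarray
    richness_ci: np.ndarray  # (len(m), 2) low/high
    coverage_ci: np.ndarray
    chao1: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m": self.m,
                "method": self.method,
                "richness": self.richness,
                "richness_ci_lo": self.richness_ci[:, 0],
                "richness_ci_hi": self.richness_ci[:, 1],
                "coverage": self.coverage,
                "coverage_ci_lo": self.coverage_ci[:, 0],
                "coverage_ci_hi": self.coverage_ci[:, 1],
            }
        )


def abundance_from_mtus(mtus: MTUTable) -> AbundanceVector:
    """Count isolates per MTU from a cluster-assignment table."""
    return AbundanceVector(np.array(sorted(mtus.sizes.values(), reverse=True)))


def _log_comb(a: np.ndarray, b: float) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def rarefied_richness(av: AbundanceVector, m: int) -> float:
    """Exact expected richness in a subsample of size *m* (m <= n)."""
    n, x = av.n, av.counts
    if m < 1 or m > n:
        raise ParameterError(f"rarefaction size m={m} must lie in [1, {n}]")
    keep = (n - x) >= m
    absent = np.zeros(x.size)
    if np.any(keep):
        absent[keep] = np.exp(_log_comb(n - x[keep].astype(float), m) - _log_comb(float(n), m))
    return float(av.s_obs - absent.sum())


def extrapolated_richness(av: AbundanceVector, m_star: int) -> float:
    """Chao1-based expected richness at sample size ``n + m_star``."""
    if m_star < 0:
        raise ParameterError("extrapolation increment must be >= 0")
    f0, f1, n = av.f0_hat, av.f1, av.n
    if f0 == 0 or f1 == 0:
        return float(av.s_obs)
    return float(av.s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star))


def _expected_coverage(av: AbundanceVector, m: int) -> float:
    """Expected sample coverage at size *m* (iNEXT-style, order 0 input)."""
    n, x = av.n, av.counts
    f1, f2 = av.f1, av.f2
    if m < n:
        # C(m) = 1 - sum_i (x_i/n) * C(n-x_i, m) / C(n-1, m)
        keep = (n - x) >= m
        term = np.zeros(x.size)
        if np.any(keep):
            term[keep] = (
                x[keep] / n
                * np.exp(_log_comb(n - x[keep].astype(float), m) - _log_comb(float(n - 1), m))
            )
        return float(1.0 - term.sum())
    if m == n:
        return coverage(av)
    # extrapolated coverage
    a = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2) if f1 > 0 else 0.0
    return float(1.0 - f1 / n * a ** (m - n + 1))


def coverage(av: AbundanceVector) -> float:
    """Estimated sample coverage of the observed library.

    ``C = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2)``; 1 when there are no
    singletons.
    """
    if av.n < 2:
        raise ParameterError("coverage needs n >= 2")
    f1, f2, n = av.f1, av.f2, av.n
    if f1 == 0:
        return 1.0
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2)))


def rarefy_extrapolate(
    av: AbundanceVector,
    m_grid=None,
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DiversityEstimate:
    """Richness/coverage curve over *m_grid* with bootstrap confidence bands.

    Default grid: 20 evenly spaced sizes from 1 to ``2n``.  CIs are normal
    intervals from a seeded multinomial bootstrap of the abundance vector.
    """
    n = av.n
    if n < 2:
        raise ParameterError("rarefy_extrapolate needs n >= 2")
    if m_grid is None:
        m_grid = np.unique(np.concatenate(
            [np.round(np.linspace(1, 2 * n, 20)).astype(int), [n]]))
    m_grid = np.asarray(m_grid, dtype=int)
    if np.any(m_grid < 1):
        raise ParameterError("all m_grid values must be >= 1")

    def curve(vector: AbundanceVector) -> tuple[np.ndarray, np.ndarray]:
        rich = np.empty(m_grid.size)
        cov = np.empty(m_grid.size)
        for k, m in enumerate(m_grid):
            if m <= vector.n:
                rich[k] = rarefied_richness(vector, int(m))
            else:
                rich[k] = extrapolated_richness(vector, int(m) - vector.n)
            cov[k] = _expected_coverage(vector, int(m))
        return rich, cov

    richness, cov = curve(av)
    rng = np.random.default_rng(seed)
    probs = av.counts / n
    boots_r = np.empty((n_boot, m_grid.size))
    boots_c = np.empty((n_boot, m_grid.size))
    for b in range(n_boot):
        draw = rng.multinomial(n, probs)
        draw = draw[draw > 0]
        if draw.size == 0:  # pragma: no cover - cannot happen with n >= 1
            draw = np.array([n])
        boots_r[b], boots_c[b] = curve(AbundanceVector(draw))
    zcrit = float(np.abs(np.round(_z_for(ci_level), 6)))
    sd_r = boots_r.std(axis=0, ddof=1)
    sd_c = boots_c.std(axis=0, ddof=1)
    r_ci = np.stack([richness - zcrit * sd_r, richness + zcrit * sd_r], axis=1)
    c_ci = np.stack(
        [np.clip(cov - zcrit * sd_c, 0, 1), np.clip(cov + zcrit * sd_c, 0, 1)],
        axis=1,
    )
    method = [
        "interpolated" if m < n else ("observed" if m == n else "extrapolated")
        for m in m_grid
    ]
    return DiversityEstimate(
        m=m_grid,
        method=method,
        richness=richness,
        coverage=cov,
        richness_ci=r_ci,
        coverage_ci=c_ci,
        chao1=av.chao1,
    )


def _z_for(level: float) -> float:
    from scipy.stats import norm

    return norm.ppf(0.5 + level / 2.0)
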