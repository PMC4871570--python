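"""Individual- and coverage-based rarefaction and extrapolation.

Sampling-sufficiency assessment for abundance samples: hypergeometric
interpolation of expected richness, Chao1-based extrapolation, and the
singleton/doubleton sample-coverage estimator, combined into curves that
by default extend to twice the observed number of individuals.

All binomial-coefficient ratios are evaluated in log space so that
samples with thousands of individuals do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .errors import ConfigurationError

__all__ = [
    "AbundanceVector",
    "coverage_estimate",
    "interpolate_richness",
    "extrapolate_richness",
    "rarefaction_curve",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Species abundance counts pooled into a single sample."""

    counts: np.ndarray

    def __init__(self, counts):
        c = np.asarray(counts)
        if c.size and (np.any(c < 0) or np.any(c != np.round(c))):
            raise ConfigurationError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n(self) -> int:
        """Total number of individuals."""
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        """Observed species richness."""
        return int((self.counts > 0).sum())

    @property
    def f1(self) -> int:
        """Number of singletons."""
        return int((self.counts == 1).sum())

    @property
    def f2(self) -> int:
        """Number of doubletons."""
        return int((self.counts == 2).sum())

    @property
    def f0_hat(self) -> float:
        """Chao1 estimate of the number of undetected species.

        Bias-corrected form ``(n-1)/n * f1(f1-1) / (2(f2+1))`` when there
        are no doubletons, the classic ``(n-1)/n * f1^2 / (2 f2)``
        otherwise.
        """
        n, f1, f2 = self.n, self.f1, self.f2
        if n == 0 or f1 == 0:
            return 0.0
        if f2 > 0:
            return (n - 1.0) / n * f1 * f1 / (2.0 * f2)
        return (n - 1.0) / n * f1 * (f1 - 1.0) / 2.0


def coverage_estimate(v: AbundanceVector) -> float:
    """Estimated sample coverage: the proportion of individuals in the
    community belonging to species already represented in the sample.

    ``C = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2)``; equal to 1 exactly
    when there are no singletons.
    """
    n, f1, f2 = v.n, v.f1, v.f2
    if n < 1:
        raise ConfigurationError("coverage undefined for an empty sample")
    if f1 == 0:
        return 1.0
    return 1.0 - (f1 / n) * ((n - 1.0) * f1 / ((n - 1.0) * f1 + 2.0 * f2))


def _log_binom(a, b):
    """log C(a, b) elementwise; -inf where b > a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (
            special.gammaln(a + 1.0)
            - special.gammaln(b + 1.0)
            - special.gammaln(a - b + 1.0)
        )
    return np.where(b > a, -np.inf, out)


def interpolate_richness(v: AbundanceVector, m: int) -> float:
    """Expected richness of a random subsample of ``m`` individuals drawn
    without replacement: ``S(m) = sum_i [1 - C(n - X_i, m)/C(n, m)]``.
    """
    n = v.n
    if not 0 <= m <= n:
        raise ConfigurationError(
            f"interpolation needs 0 <= m <= n={n}; got m={m} "
            "(use extrapolate_richness beyond the observed sample)"
        )
    if m == 0:
        return 0.0
    x = v.counts[v.counts > 0]
    log_ratio = _log_binom(n - x, m) - _log_binom(n, m)
    return float(np.sum(1.0 - np.exp(log_ratio)))


def extrapolate_richness(v: AbundanceVector, m_extra: int) -> float:
    """Estimated richness after ``m_extra`` additional individuals.

    ``S(n + m*) = S_obs + f0 * [1 - (1 - f1/(n f0 + f1))^{m*}]`` with the
    Chao1 ``f0``; the asymptote as ``m* -> inf`` is ``S_obs + f0``.
    """
    if m_extra < 0:
        raise ConfigurationError("m_extra must be >= 0")
    f0 = v.f0_hat
    if m_extra == 0 or f0 == 0.0 or v.f1 == 0:
        return float(v.s_obs)
    n, f1 = v.n, v.f1
    rate = f1 / (n * f0 + f1)
    return float(v.s_obs + f0 * (1.0 - (1.0 - rate) ** m_extra))


def _coverage_interpolated(v: AbundanceVector, m: int) -> float:
    """Expected coverage of a subsample of m < n individuals."""
    n = v.n
    if m >= n:
        return coverage_estimate(v)
    x = v.counts[v.counts > 0]
    log_ratio = _log_binom(n - x, m) - _log_binom(n - 1, m)
    return float(1.0 - np.sum((x / n) * np.exp(log_ratio)))


def _coverage_extrapolated(v: AbundanceVector, m_extra: int) -> float:
    """Analytic extension of the coverage estimator beyond the sample:
    ``C(n + m*) = 1 - (f1/n) * A^{m*+1}`` with
    ``A = (n-1) f1 / ((n-1) f1 + 2 f2)``.
    """
    n, f1, f2 = v.n, v.f1, v.f2
    if f1 == 0:
        return 1.0
    A = (n - 1.0) * f1 / ((n - 1.0) * f1 + 2.0 * f2)
    return float(1.0 - (f1 / n) * A ** (m_extra + 1))


def rarefaction_curve(
    v: AbundanceVector,
    mode: str = "individual",
    factor: float = 2.0,
    n_points: int = 40,
) -> pd.DataFrame:
    """Rarefaction/extrapolation curve out to ``factor * n`` individuals.

    Returns a frame with columns ``m`` (individuals), ``S`` (expected or
    estimated richness), ``C`` (estimated coverage) and ``phase``
    (interpolated / observed / extrapolated).  ``mode`` is a labelling
    convenience only ("individual" or "coverage"); both columns are
    always computed.
    """
    if mode not in ("individual", "coverage"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if factor < 1:
        raise ConfigurationError("extrapolation factor must be >= 1")
    n = v.n
    if n < 1:
        raise ConfigurationError("cannot rarefy an empty sample")

    m_max = int(round(factor * n))
    grid = np.unique(
        np.concatenate(
            [
                np.linspace(1, n, num=min(n_points // 2 + 1, n), dtype=int),
                [n],
                np.linspace(n, m_max, num=n_points // 2 + 1, dtype=int),
            ]
        )
    )
    rows = []
    for m in grid:
        if m < n:
            rows.append(
                (m, interpolate_richness(v, int(m)),
                 _coverage_interpolated(v, int(m)), "interpolated")
            )
        elif m == n:
            rows.append((m, float(v.s_obs), coverage_estimate(v), "observed"))
        else:
            rows.append(
                (m, extrapolate_richness(v, int(m - n)),
                 _coverage_extrapolated(v, int(m - n)), "extrapolated")
            )
    return pd.DataFrame(rows, columns=["m", "S", "C", "phase"])


def pool_abundances(counts: pd.DataFrame, groups=None) -> dict:
    """Pool a plot x species count matrix into per-group abundance vectors.

    ``groups`` maps each plot (row label) to a group label; plots map to
    one pooled :class:`AbundanceVector` per group.  With ``groups=None``
    everything pools into a single ``"all"`` vector.
    """
    if groups is None:
        return {"all": AbundanceVector(counts.to_numpy().sum(axis=0))}
    g = pd.Series(groups)
    out = {}
    for label, idx in counts.groupby(g.reindex(counts.index)).groups.items():
        out[label] = AbundanceVector(counts.loc[idx].to_numpy().sum(axis=0))
    return out
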