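"""Bray-Curtis dissimilarity, NMDS ordination and environmental vectors.

The dissimilarity convention follows common practice for depauperate
trap samples: abundances are square-root transformed and a tiny dummy
"pseudo-species" (1e-7 by default) is appended to every plot so that a
pair of empty plots has a defined dissimilarity of 0 rather than 0/0.

NMDS minimises Kruskal stress-1 by SMACOF with isotonic regression
(scikit-learn's non-metric solver) over several restarts: one start from
the classical metric-MDS (eigendecomposition) configuration, the rest
random.  The returned configuration is centred and rotated to its
principal axes so a fixed seed gives a reproducible layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .errors import ConfigurationError

__all__ = [
    "bray_curtis_matrix",
    "nmds",
    "fit_env_vectors",
    "Ordination",
    "nonempty_plots",
]

DEFAULT_DUMMY = 1e-7


@dataclass
class Ordination:
    """An NMDS configuration with its Kruskal stress-1 value."""

    coords: pd.DataFrame  # plots x axes, centred, principal-axis rotated
    stress: float
    n_restarts: int
    converged: bool


def bray_curtis_matrix(
    counts: pd.DataFrame,
    transform: str = "sqrt",
    dummy: float = DEFAULT_DUMMY,
) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between plot rows.

    ``BC(i,j) = sum|x_i - x_j| / sum(x_i + x_j)`` computed after the
    abundance transform and after appending the dummy pseudo-species, so
    two all-zero plots compare as identical (0) rather than undefined.
    """
    X = np.asarray(counts, dtype=float)
    if np.any(X < 0):
        raise ConfigurationError("abundances must be non-negative")
    if transform == "sqrt":
        X = np.sqrt(X)
    elif transform != "none":
        raise ConfigurationError(f"unknown transform {transform!r}")
    if dummy:
        X = np.column_stack([X, np.full(X.shape[0], dummy)])
    D = squareform(pdist(X, metric="braycurtis"))
    idx = counts.index if isinstance(counts, pd.DataFrame) else None
    return pd.DataFrame(D, index=idx, columns=idx)


def nonempty_plots(counts: pd.DataFrame) -> pd.Index:
    """Plots with at least one individual (ordination keeps only these)."""
    return counts.index[counts.sum(axis=1) > 0]


def _stress1(D: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against target dissimilarities.

    Disparities are the isotonic regression of configuration distances on
    the rank order of the dissimilarities.
    """
    d_target = squareform(D, checks=False)
    d_conf = pdist(coords)
    disp = IsotonicRegression().fit_transform(d_target, d_conf)
    denom = np.sum(d_conf**2)
    if denom == 0:
        return np.inf
    return float(np.sqrt(np.sum((d_conf - disp) ** 2) / denom))


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(G)
    w, V = w[::-1][:k], V[:, ::-1][:, :k]
    return V * np.sqrt(np.maximum(w, 0.0))


def _principal_orientation(coords: np.ndarray) -> np.ndarray:
    """Centre and rotate to principal axes with a fixed sign convention."""
    coords = coords - coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(coords, full_matrices=False)
    out = coords @ Vt.T
    for j in range(out.shape[1]):
        if out[np.abs(out[:, j]).argmax(), j] < 0:
            out[:, j] = -out[:, j]
    return out


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
) -> Ordination:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Best (lowest stress-1) configuration over ``restarts`` starts; the
    first start is the classical-MDS configuration, the rest random.
    """
    D = np.asarray(d, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ConfigurationError("dissimilarity matrix must be square")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    n = D.shape[0]
    rng = np.random.default_rng(seed)

    best = None
    any_converged = False
    for r in range(max(restarts, 1)):
        init = (
            _classical_mds(D, k)
            if r == 0
            else rng.normal(size=(n, k))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, _, n_iter = smacof(
                D,
                metric=False,
                n_components=k,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=1e-9,
                normalized_stress=True,
                return_n_iter=True,
            )
        s = _stress1(D, coords)
        any_converged = any_converged or (n_iter < max_iter)
        if best is None or s < best[0]:
            best = (s, coords)

    if not any_converged:
        warnings.warn(
            "NMDS did not converge in any restart; returning best-so-far",
            RuntimeWarning,
        )
    coords = _principal_orientation(best[1])
    idx = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(
        coords, index=idx, columns=[f"axis{j + 1}" for j in range(k)]
    )
    return Ordination(
        coords=frame,
        stress=best[0],
        n_restarts=max(restarts, 1),
        converged=any_converged,
    )


def fit_env_vectors(
    ordination: Ordination,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit environmental variables as directions on an ordination.

    Each variable is regressed on the ordination coordinates; the unit
    vector of the regression coefficients gives its direction, the
    coefficient of determination its fit quality, and a permutation test
    (shuffling the variable across plots) its P value.
    """
    coords = ordination.coords.to_numpy()
    env = env.loc[ordination.coords.index]
    n, k = coords.shape
    Xc = coords - coords.mean(axis=0)
    rng = np.random.default_rng(seed)

    # hat-matrix-free R^2 via least squares on centred data
    Q, _ = np.linalg.qr(Xc)

    def r2_of(vals: np.ndarray) -> tuple[float, np.ndarray]:
        v = vals - vals.mean()
        tot = v @ v
        if tot == 0:
            return 0.0, np.zeros(k)
        coef, *_ = np.linalg.lstsq(Xc, v, rcond=None)
        fitted = Xc @ coef
        return float(fitted @ fitted / tot), coef

    rows = []
    for name in env.columns:
        vals = env[name].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            warnings.warn(
                f"variable {name!r} is constant; r2 set to 0", RuntimeWarning
            )
            rows.append((name, *np.zeros(k), 0.0, 1.0))
            continue
        r2, coef = r2_of(vals)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else np.zeros(k)
        # permutation null for r2
        v = vals - vals.mean()
        exceed = 0
        for _ in range(n_perm):
            vp = v[rng.permutation(n)]
            f = Q @ (Q.T @ vp)
            if f @ f / (v @ v) >= r2:
                exceed += 1
        p = (1.0 + exceed) / (n_perm + 1.0)
        rows.append((name, *direction, r2, p))

    cols = ["variable"] + [f"cos{j + 1}" for j in range(k)] + ["r2", "P"]
    return pd.DataFrame(rows, columns=cols)
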