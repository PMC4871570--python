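"""Distance-based permutational multivariate ANOVA (sequential fit).

Partitions the total sum of squared dissimilarities over an ordered list
of model terms (Type I / sequential sums of squares) via projections on
the Gower-centred inner-product matrix, and tests each term by permuting
residuals under the reduced model containing only the preceding terms
(the Freedman-Lane scheme used by distance-based PERMANOVA software).

A categorical term entered first with a numeric covariate second mirrors
the common "random factor + covariate" design for elevational community
data; the random-factor logic is carried by the permutation scheme, not
by an expected-mean-squares denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["Term", "PermanovaResult", "gower_centered", "permanova_sequential"]


@dataclass(frozen=True)
class Term:
    """One model term: a factor (categorical) or covariate (numeric)."""

    name: str
    values: np.ndarray
    kind: str = "factor"  # "factor" | "covariate"

    def design(self) -> np.ndarray:
        v = np.asarray(self.values)
        if self.kind == "factor":
            levels = np.unique(v)
            return (v[:, None] == levels[None, :]).astype(float)
        if self.kind == "covariate":
            return np.asarray(v, dtype=float).reshape(len(v), -1)
        raise ConfigurationError(f"unknown term kind {self.kind!r}")


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table."""

    table: pd.DataFrame  # term, df, SS, pseudo_F, P
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int


def gower_centered(d) -> np.ndarray:
    """Gower-centred inner-product matrix ``G = -1/2 J D^2 J``.

    Rows and columns of G sum to zero; for Euclidean distances of
    column-centred data X, ``G = X X^T``.
    """
    D = np.asarray(d, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space of X, and its rank.

    SVD-based so that redundant factor dummy columns are harmless.
    """
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    U = U[:, :rank]
    return U @ U.T, rank


def permanova_sequential(
    d,
    terms: list[Term],
    n_perm: int = 4999,
    seed: int | None = None,
) -> PermanovaResult:
    """Sequential (Type I) PERMANOVA on a dissimilarity matrix.

    Each term's sum of squares is the trace of G projected onto the part
    of its design space orthogonal to all preceding terms; pseudo-F uses
    the full-model residual mean square.  P values come from permuting
    the reduced-model residual matrix: for the j-th term the reduced
    model holds the intercept and terms 1..j-1.
    """
    D = np.asarray(d, dtype=float)
    n = D.shape[0]
    G = gower_centered(D)
    total_ss = float(np.trace(G))

    X = np.ones((n, 1))
    hats = [(_hat(X)[0], 1)]  # cumulative projector, cumulative rank
    for t in terms:
        td = t.design()
        if td.shape[0] != n:
            raise ConfigurationError(
                f"term {t.name!r} is misaligned with the dissimilarity matrix"
            )
        X = np.column_stack([X, td])
        H, r = _hat(X)
        prev_r = hats[-1][1]
        if r == prev_r:
            raise ConfigurationError(
                f"term {t.name!r} is aliased with preceding terms "
                "(rank-deficient design)"
            )
        hats.append((H, r))

    H_full, rank_full = hats[-1]
    df_res = n - rank_full
    if df_res < 1:
        raise ConfigurationError("saturated design: no residual df")
    R_full = np.eye(n) - H_full
    ss_res = float(np.sum(R_full * G.T))
    ms_res = ss_res / df_res

    rng = np.random.default_rng(seed)
    rows = []
    for j, t in enumerate(terms):
        H_prev, r_prev = hats[j]
        H_cur, r_cur = hats[j + 1]
        A = H_cur - H_prev
        df_t = r_cur - r_prev
        ss_t = float(np.sum(A * G.T))
        f_obs = (ss_t / df_t) / ms_res

        # permutation of residuals under the reduced (preceding-terms) model
        R_prev = np.eye(n) - H_prev
        G_red = R_prev @ G @ R_prev
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G_red[np.ix_(perm, perm)]
            num = np.sum(A * Gp.T) / df_t
            den = np.sum(R_full * Gp.T) / df_res
            if den <= 0:
                continue
            if num / den >= f_obs:
                exceed += 1
        p = (1.0 + exceed) / (n_perm + 1.0)
        rows.append((t.name, df_t, ss_t, f_obs, p))

    table = pd.DataFrame(rows, columns=["term", "df", "SS", "pseudo_F", "P"])
    return PermanovaResult(
        table=table,
        residual_df=df_res,
        residual_ss=ss_res,
        total_ss=total_ss,
        n_permutations=n_perm,
    )
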