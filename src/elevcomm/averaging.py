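"""Exhaustive AICc model averaging with a permutation null.

The variable-importance engine: fit every subset of a screened predictor
pool (2^p candidate models, negative-binomial GLMs), convert AICc values
to Akaike weights, and score each predictor by the summed weight of all
models containing it.  Because summed weights have no reference
distribution, significance is calibrated against null datasets obtained
by permuting response rows against the fixed predictor table: the
standardised effect size of predictor j is

    SES_j = (observed SW_j - mean null SW_j) / SD(null SW_j)

and the one-sided permutation P value is
``(1 + #{null SW_j >= observed SW_j}) / (n_null + 1)``.

Two response modes are supported: ``univariate`` (a single count vector,
e.g. plot species richness) and ``multivariate`` (a plot x species count
matrix, fitted species-by-species on the shared predictor subset with
the per-species AICc values summed per model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FitError
from .glm import fit_nb_glm_batch, aicc

__all__ = [
    "ModelSpec",
    "AveragingResult",
    "enumerate_models",
    "fit_all_models",
    "akaike_weights",
    "summed_weights",
    "null_distribution",
    "averaging_table",
    "model_averaging",
]

MAX_PREDICTORS = 20


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a subset of the predictor pool."""

    mask: int
    predictors: tuple[str, ...]

    def __contains__(self, name: str) -> bool:
        return name in self.predictors


@dataclass
class AveragingResult:
    """Per-predictor importance table plus the run conditions."""

    table: pd.DataFrame  # variable, summed_weight_obs, null_mean, null_sd, SES, P
    mode: str
    n_null: int
    seed: int | None
    predictors: list[str]


def enumerate_models(predictors: list[str]) -> list[ModelSpec]:
    """All 2^p predictor subsets, intercept-only model first.

    Deterministic order: subsets are bitmasks counted from 0, bit j
    flagging the j-th predictor.
    """
    names = list(predictors)
    if len(set(names)) != len(names):
        raise ConfigurationError("predictor names must be unique")
    p = len(names)
    if p > MAX_PREDICTORS:
        raise ConfigurationError(
            f"{p} predictors would give 2^{p} models; screen the pool "
            f"down to at most {MAX_PREDICTORS} first"
        )
    return [
        ModelSpec(
            mask=m,
            predictors=tuple(names[j] for j in range(p) if m >> j & 1),
        )
        for m in range(2**p)
    ]


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights ``w_m = exp(-(AICc_m - min AICc)/2)``, normalised.

    Non-finite entries (models excluded because AICc was undefined) get
    weight 0 and are dropped from the normalisation.
    """
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ConfigurationError("no model has a finite AICc")
    delta = a - a[finite].min()
    w = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    return w / w.sum()


def summed_weights(weights, specs: list[ModelSpec], predictors: list[str]) -> pd.Series:
    """Per-predictor summed Akaike weight ``SW_j = sum_{m: j in m} w_m``."""
    w = np.asarray(weights, dtype=float)
    if len(w) != len(specs):
        raise ConfigurationError("weights and model specs are misaligned")
    masks = np.array([s.mask for s in specs])
    sw = {
        name: float(w[(masks >> j & 1).astype(bool)].sum())
        for j, name in enumerate(predictors)
    }
    return pd.Series(sw, name="summed_weight")


def _response_matrix(response, mode: str) -> np.ndarray:
    y = np.asarray(response, dtype=float)
    if mode == "univariate":
        if y.ndim != 1 and not (y.ndim == 2 and y.shape[1] == 1):
            raise ConfigurationError("univariate mode expects a vector response")
        return y.reshape(-1, 1)
    if mode == "multivariate":
        if y.ndim != 2:
            raise ConfigurationError(
                "multivariate mode expects a plot x species matrix"
            )
        return y
    raise ConfigurationError(f"unknown mode {mode!r}")


def _aicc_all_specs(Y: np.ndarray, env: pd.DataFrame, specs: list[ModelSpec]):
    """AICc per spec, summed over response columns.

    ``Y`` may stack several replicates of the response side by side
    (species, permuted copies, or both); columns are grouped back into
    replicates by ``n_series = Y.shape[1] // n_rep`` in the caller.
    Models with undefined AICc (n <= k+1) come back +inf.
    """
    n = Y.shape[0]
    X_full = env.to_numpy(dtype=float)
    names = list(env.columns)
    ones = np.ones((n, 1))
    full = np.column_stack([ones, X_full])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise FitError(
            "predictor table is rank deficient (duplicated or collinear "
            "columns); screen the pool first"
        )
    out = np.empty((len(specs), Y.shape[1]))
    for i, spec in enumerate(specs):
        cols = [names.index(nm) for nm in spec.predictors]
        X = np.column_stack([ones, X_full[:, cols]]) if cols else ones
        k = X.shape[1] + 1  # + theta
        if n <= k + 1:
            out[i] = np.inf
            continue
        # likelihood tolerance of 1e-6 is far below the resolution at
        # which AICc differences move Akaike weights
        _, _, ll, _ = fit_nb_glm_batch(Y, X, tol=1e-6)
        out[i] = -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    return out


def fit_all_models(
    response, env: pd.DataFrame, mode: str = "univariate"
) -> tuple[list[ModelSpec], np.ndarray]:
    """AICc of every predictor subset.

    Univariate: AICc of the NB GLM of the response on each subset.
    Multivariate: the sum over species of per-species NB GLM AICc values
    on the shared subset (per-species k, shared n).
    """
    Y = _response_matrix(response, mode)
    specs = enumerate_models(list(env.columns))
    per_col = _aicc_all_specs(Y, env, specs)
    a = per_col.sum(axis=1)
    if np.any(~np.isfinite(a)):
        warnings.warn(
            f"{int(np.sum(~np.isfinite(a)))} models excluded "
            "(AICc undefined for n <= k+1)",
            RuntimeWarning,
        )
    return specs, a


def null_distribution(
    response,
    env: pd.DataFrame,
    mode: str = "univariate",
    n_null: int = 999,
    seed: int | None = None,
) -> np.ndarray:
    """Summed-weight matrix (n_null x p) from permuted-response nulls.

    Each null dataset permutes the response rows jointly (whole rows of
    the community matrix in multivariate mode, preserving species
    co-occurrence) against the fixed predictor table, then recomputes
    every model's AICc and each predictor's summed weight.  All nulls
    are fitted in one batched sweep per candidate model.
    """
    if n_null < 1:
        raise ConfigurationError("n_null must be >= 1")
    Y = _response_matrix(response, mode)
    n, n_series = Y.shape
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_null)])

    # stack the permuted copies side by side: columns r*n_series..(r+1)*n_series
    Y_big = np.concatenate([Y[perms[r]] for r in range(n_null)], axis=1)
    specs = enumerate_models(list(env.columns))
    per_col = _aicc_all_specs(Y_big, env, specs)
    # AICc per (model, null replicate): sum each replicate's species block
    a = per_col.reshape(len(specs), n_null, n_series).sum(axis=2)

    predictors = list(env.columns)
    out = np.empty((n_null, len(predictors)))
    for r in range(n_null):
        w = akaike_weights(a[:, r])
        out[r] = summed_weights(w, specs, predictors).to_numpy()
    return out


def averaging_table(observed_sw: pd.Series, null_matrix: np.ndarray) -> pd.DataFrame:
    """Combine observed summed weights with their permutation null.

    Columns: variable, summed_weight_obs, null_mean, null_sd, SES, P;
    rows sorted by SES descending.  A predictor whose null SD is zero
    gets SES = NaN (reported, not dropped).
    """
    null_matrix = np.asarray(null_matrix, dtype=float)
    if null_matrix.shape[1] != len(observed_sw):
        raise ConfigurationError("null matrix misaligned with observed weights")
    n_null = null_matrix.shape[0]
    b = null_matrix.mean(axis=0)
    c = null_matrix.std(axis=0, ddof=1)
    a = observed_sw.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(c > 0, (a - b) / c, np.nan)
    p = (1.0 + (null_matrix >= a[None, :]).sum(axis=0)) / (n_null + 1.0)
    out = pd.DataFrame(
        {
            "variable": observed_sw.index,
            "summed_weight_obs": a,
            "null_mean": b,
            "null_sd": c,
            "SES": ses,
            "P": p,
        }
    )
    return out.sort_values("SES", ascending=False, ignore_index=True)


def model_averaging(
    response,
    env: pd.DataFrame,
    mode: str = "univariate",
    n_null: int = 999,
    seed: int | None = None,
) -> AveragingResult:
    """Full variable-importance analysis: observed summed weights, the
    permutation null, standardised effect sizes and P values."""
    specs, a_obs = fit_all_models(response, env, mode)
    w = akaike_weights(a_obs)
    sw = summed_weights(w, specs, list(env.columns))
    null = null_distribution(response, env, mode, n_null=n_null, seed=seed)
    table = averaging_table(sw, null)
    return AveragingResult(
        table=table,
        mode=mode,
        n_null=n_null,
        seed=seed,
        predictors=list(env.columns),
    )
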