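"""Count-model fitting machinery.

Negative-binomial (NB2) GLMs with a log link, fitted by IRLS alternating
with Newton updates of the dispersion parameter theta in log space; a
random-intercept NB mixed model via the Laplace approximation; AICc; and
simple linear regression with adjusted R^2.

The batched fitter (:func:`fit_nb_glm_batch`) fits many response columns
against one shared design matrix in a single vectorised sweep.  The
all-subsets model-averaging engine depends on it: a permutation null at
999 null datasets times 2^p candidate models is only tractable when the
per-model fits across permuted responses are batched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import ConfigurationError, FitError

THETA_CAP = 1e8
THETA_FLOOR = 1e-4
ETA_MIN, ETA_MAX = -30.0, 30.0

__all__ = [
    "FitResult",
    "MixedFitResult",
    "nb_loglik",
    "fit_nb_glm",
    "fit_nb_glm_batch",
    "fit_nb_glmm",
    "fit_ols",
    "aicc",
]


@dataclass
class FitResult:
    """Maximum-likelihood fit of a negative-binomial GLM."""

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    k: int  # parameter count: len(coef) + 1 for theta
    n: int
    aicc: float
    theta: float
    converged: bool
    boundary: bool = False  # all-zero response, intercept at the floor


@dataclass
class MixedFitResult:
    """Random-intercept NB mixed model fit (Laplace approximation)."""

    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    random_variance: float
    theta: float
    loglik: float
    n: int
    n_groups: int
    converged: bool
    names: list[str] = field(default_factory=list)


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta) -> np.ndarray:
    """NB2 log-likelihood, summed over axis 0.

    Parameterisation: Var(y) = mu + mu^2/theta; theta -> inf is Poisson.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    t = np.asarray(theta, dtype=float)
    ll = (
        special.gammaln(y + t)
        - special.gammaln(t)
        - special.gammaln(y + 1.0)
        + t * np.log(t / (t + mu))
        + special.xlogy(y, mu / (t + mu))
    )
    return ll.sum(axis=0)


def _theta_score(theta, y, mu):
    """d loglik / d theta, summed over axis 0 (vectorised over columns)."""
    return (
        special.digamma(y + theta)
        - special.digamma(theta)
        + np.log(theta / (theta + mu))
        + 1.0
        - (y + theta) / (theta + mu)
    ).sum(axis=0)


def _theta_curvature(theta, y, mu):
    """d^2 loglik / d theta^2, summed over axis 0."""
    return (
        special.polygamma(1, y + theta)
        - special.polygamma(1, theta)
        + 1.0 / theta
        - 2.0 / (theta + mu)
        + (y + theta) / (theta + mu) ** 2
    ).sum(axis=0)


class _TailCounts:
    """Exceedance counts of an integer response matrix.

    For integer counts, ``digamma(y+t) - digamma(t) = sum_{j<y} 1/(t+j)``
    (and analogous identities for gammaln and trigamma), so the
    per-observation special-function sums collapse to sums over
    ``T[j] = #{i : y_i > j}`` weighted by elementary functions of
    ``t + j``.  This is both faster and numerically stable at large t.
    """

    def __init__(self, Y: np.ndarray):
        n, m = Y.shape
        Yi = Y.astype(np.int64)
        J = int(Yi.max()) if Yi.size else 0
        C = np.zeros((J + 1, m))
        np.add.at(C, (Yi.ravel(), np.tile(np.arange(m), n)), 1.0)
        # T[j, col] = #{y > j}, j = 0..J-1
        self.T = n - np.cumsum(C, axis=0)[:-1]
        self.j = np.arange(J, dtype=float)[:, None]
        self.gammaln_y1 = special.gammaln(Yi + 1.0).sum(axis=0)

    def gammaln_term(self, t):
        """sum_i [gammaln(y_i + t) - gammaln(t)] per column."""
        return (self.T * np.log(t + self.j)).sum(axis=0)

    def digamma_term(self, t):
        return (self.T / (t + self.j)).sum(axis=0)

    def trigamma_term(self, t):
        return -(self.T / (t + self.j) ** 2).sum(axis=0)

    def subset(self, idx) -> "_TailCounts":
        out = object.__new__(_TailCounts)
        out.T = self.T[:, idx]
        out.j = self.j
        out.gammaln_y1 = self.gammaln_y1[idx]
        return out


def _theta_newton(theta, y, mu, n_steps=3, tails: _TailCounts | None = None):
    """A few Newton steps maximising the profile likelihood in log(theta)."""
    u = np.log(theta)
    n = y.shape[0]
    for _ in range(n_steps):
        t = np.exp(u)
        if tails is not None:
            r = t + mu
            s = (
                tails.digamma_term(t)
                + n * np.log(t)
                - (np.log(r) + (y + t) / r).sum(axis=0)
                + n
            )
            h = (
                tails.trigamma_term(t)
                + n / t
                + (-2.0 / r + (y + t) / r**2).sum(axis=0)
            )
        else:
            s = _theta_score(t, y, mu)
            h = _theta_curvature(t, y, mu)
        # chain rule to u = log(theta)
        gu = t * s
        hu = t * t * h + t * s
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(hu < 0, -gu / hu, np.sign(gu) * 0.5)
        step = np.nan_to_num(step, nan=0.0, posinf=0.5, neginf=-0.5)
        step = np.clip(step, -2.0, 2.0)
        u = np.clip(u + step, np.log(THETA_FLOOR), np.log(THETA_CAP))
    return np.exp(u)


def fit_nb_glm_batch(
    Y: np.ndarray,
    X: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    theta: float | None = None,
):
    """Fit NB GLMs of every column of ``Y`` (n x m) on one design ``X`` (n x p).

    Returns ``(beta (p, m), theta (m,), loglik (m,), converged (m,))``.
    If ``theta`` is given it is held fixed (no dispersion update).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(X, dtype=float)
    n, m = Y.shape
    p = X.shape[1]

    zero_cols = Y.sum(axis=0) == 0

    # initialisation
    mu = (Y + Y.mean(axis=0, keepdims=True)) / 2.0 + 0.1
    eta = np.log(mu)
    if theta is None:
        ybar = Y.mean(axis=0)
        yvar = Y.var(axis=0)
        th = np.clip(
            ybar**2 / np.maximum(yvar - ybar, 1e-8), THETA_FLOOR, THETA_CAP
        )
        th = np.where(yvar <= ybar, THETA_CAP, th)
    else:
        th = np.full(m, float(theta))

    beta = np.zeros((p, m))
    ll_old = np.full(m, -np.inf)
    converged = np.zeros(m, dtype=bool)
    ridge_eye = np.eye(p)

    integral = bool(np.all(Y == np.round(Y)))
    tails = _TailCounts(Y) if integral and Y.max() <= 4096 else None

    def _irls(Ya, th_cur, bt, eta_cur, mu_cur, n_inner=10):
        for _ in range(n_inner):
            W = mu_cur / (1.0 + mu_cur / th_cur)
            z = eta_cur + (Ya - mu_cur) / mu_cur
            A = np.einsum("np,nm,nq->mpq", X, W, X)
            # relative ridge: keeps quasi-separated columns (rank-deficient
            # weighted Gram matrices) solvable at any weight scale
            scale = A.diagonal(axis1=1, axis2=2).max(axis=1)
            A = A + (1e-10 + 1e-10 * scale)[:, None, None] * ridge_eye
            rhs = np.einsum("np,nm->mp", X, W * z)
            bt_new = np.linalg.solve(A, rhs[..., None])[..., 0].T  # (p, m)
            eta_cur = np.clip(X @ bt_new, ETA_MIN, ETA_MAX)
            mu_cur = np.exp(eta_cur)
            done = np.abs(bt_new - bt).max(axis=0) < 1e-10 * (
                1.0 + np.abs(bt_new).max(axis=0)
            )
            bt = bt_new
            if np.all(done):
                break
        return bt, eta_cur, mu_cur

    def _ll(Ya, mu_cur, th_cur, t_sub):
        if t_sub is not None:
            return (
                t_sub.gammaln_term(th_cur)
                - t_sub.gammaln_y1
                + n * th_cur * np.log(th_cur)
                - ((Ya + th_cur) * np.log(th_cur + mu_cur)).sum(axis=0)
                + special.xlogy(Ya, mu_cur).sum(axis=0)
            )
        return nb_loglik(Ya, mu_cur, th_cur)

    # active-set sweep: converged columns drop out of further iterations.
    # A step-halving guard keeps the beta/theta alternation monotone in
    # the likelihood (plain IRLS can oscillate at small theta).
    active = np.flatnonzero(~zero_cols)
    for sweep in range(max_iter):
        if active.size == 0:
            break
        idx = active
        Ya = Y[:, idx]
        t_sub = tails.subset(idx) if tails is not None else None
        b_prev, th_prev = beta[:, idx].copy(), th[idx].copy()
        ll_prev = ll_old[idx]

        bt, eta_a, mu_a = _irls(Ya, th_prev, b_prev, eta[:, idx], mu[:, idx])
        th_a = (
            _theta_newton(th_prev, Ya, mu_a, n_steps=4, tails=t_sub)
            if theta is None
            else th_prev
        )
        ll_a = _ll(Ya, mu_a, th_a, t_sub)

        lam = np.ones(idx.size)
        stuck = np.zeros(idx.size, dtype=bool)
        for _ in range(8):
            worse = np.isfinite(ll_prev) & (ll_a < ll_prev - 1e-12) & ~stuck
            if not worse.any():
                break
            lam[worse] *= 0.5
            bt[:, worse] = b_prev[:, worse] + lam[worse] * (
                bt[:, worse] - b_prev[:, worse]
            )
            th_a[worse] = np.exp(
                np.log(th_prev[worse])
                + lam[worse] * (np.log(th_a[worse]) - np.log(th_prev[worse]))
            )
            eta_w = np.clip(X @ bt[:, worse], ETA_MIN, ETA_MAX)
            mu_a[:, worse] = np.exp(eta_w)
            eta_a[:, worse] = eta_w
            sub = t_sub.subset(worse) if t_sub is not None else None
            ll_a[worse] = _ll(Ya[:, worse], mu_a[:, worse], th_a[worse], sub)
            stuck = stuck | (lam < 1e-2) & (ll_a < ll_prev - 1e-12)
        if stuck.any():
            # no uphill step found: keep the previous (better) iterate
            bt[:, stuck] = b_prev[:, stuck]
            th_a[stuck] = th_prev[stuck]
            eta_w = np.clip(X @ bt[:, stuck], ETA_MIN, ETA_MAX)
            eta_a[:, stuck] = eta_w
            mu_a[:, stuck] = np.exp(eta_w)
            ll_a[stuck] = ll_prev[stuck]

        beta[:, idx], eta[:, idx], mu[:, idx], th[idx] = bt, eta_a, mu_a, th_a
        done = (np.abs(ll_a - ll_prev) < tol * (np.abs(ll_a) + 1.0)) | stuck
        ll_old[idx] = ll_a
        converged[idx] = done
        active = idx[~done]

    if theta is None:
        # columns whose profile likelihood still increases at large theta
        # are (near-)equidispersed: the MLE sits at the Poisson-limit cap
        probe = 1e6
        r = probe + mu
        if tails is not None:
            s_probe = (
                tails.digamma_term(probe)
                + n * np.log(probe)
                - (np.log(r) + (Y + probe) / r).sum(axis=0)
                + n
            )
        else:
            s_probe = _theta_score(probe, Y, mu)
        push = (~zero_cols) & (th > 100.0) & (s_probe > 0)
        if np.any(push):
            idxp = np.flatnonzero(push)
            th[idxp] = THETA_CAP
            t_sub = tails.subset(idxp) if tails is not None else None
            bt, eta_p, mu_p = _irls(
                Y[:, idxp], th[idxp], beta[:, idxp], eta[:, idxp], mu[:, idxp]
            )
            beta[:, idxp], eta[:, idxp], mu[:, idxp] = bt, eta_p, mu_p
            ll_old[idxp] = _ll(Y[:, idxp], mu_p, th[idxp], t_sub)

    if np.any(zero_cols):
        # all-zero response: intercept at the boundary, mu -> 0, loglik -> 0
        th = np.where(zero_cols, THETA_CAP, th)
        ll_old = np.where(zero_cols, nb_loglik(Y, np.exp(ETA_MIN), th), ll_old)
        converged = converged | zero_cols

    return beta, th, ll_old, converged


def fit_nb_glm(y, X, *, tol: float = 1e-8, max_iter: int = 200) -> FitResult:
    """Negative-binomial GLM (log link) of counts ``y`` on design ``X``.

    ``X`` must include its own intercept column and be of full column
    rank.  The parameter count ``k`` used for AICc includes theta.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ConfigurationError("response must be non-negative integers")
    if y.shape[0] != X.shape[0]:
        raise ConfigurationError("response and design rows are misaligned")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient (aliased columns)")

    n, p = y.shape[0], X.shape[1]
    boundary = bool(y.sum() == 0)
    if boundary:
        warnings.warn(
            "all-zero response: intercept at the boundary", RuntimeWarning
        )
    beta, th, ll, conv = fit_nb_glm_batch(
        y[:, None], X, tol=tol, max_iter=max_iter
    )
    beta, th, ll, conv = beta[:, 0], float(th[0]), float(ll[0]), bool(conv[0])

    mu = np.exp(np.clip(X @ beta, ETA_MIN, ETA_MAX))
    W = mu / (1.0 + mu / th)
    info = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover - boundary designs
        se = np.full(p, np.nan)

    k = p + 1
    a = aicc(ll, k, n) if n > k + 1 else np.inf
    return FitResult(
        coef=beta, se=se, loglik=ll, k=k, n=n, aicc=a, theta=th,
        converged=conv, boundary=boundary,
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); undefined for n <= k+1.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if n <= k + 1:
        raise ConfigurationError(
            f"AICc undefined for n={n} <= k+1={k + 1} (over-parameterised model)"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# ---------------------------------------------------------------------------
# Random-intercept NB mixed model (Laplace approximation)
# ---------------------------------------------------------------------------


def _laplace_loglik(params, y, X, gidx, n_groups):
    """Marginal log-likelihood of the NB random-intercept model.

    ``params`` = (beta..., log_sigma, log_theta).  The random-effect
    integral is approximated per group by Laplace: an inner 1-D Newton
    solve for the conditional mode of each group intercept.
    """
    p = X.shape[1]
    beta = params[:p]
    sigma2 = np.exp(2.0 * np.clip(params[p], -8.0, 5.0))
    theta = np.exp(np.clip(params[p + 1], np.log(THETA_FLOOR), np.log(THETA_CAP)))

    eta0 = np.clip(X @ beta, ETA_MIN, ETA_MAX)
    b = np.zeros(n_groups)
    for _ in range(50):
        eta = np.clip(eta0 + b[gidx], ETA_MIN, ETA_MAX)
        mu = np.exp(eta)
        g1 = theta * (y - mu) / (theta + mu)  # d ll / d eta
        g2 = -theta * mu * (y + theta) / (theta + mu) ** 2
        grad = np.bincount(gidx, weights=g1, minlength=n_groups) - b / sigma2
        hess = np.bincount(gidx, weights=g2, minlength=n_groups) - 1.0 / sigma2
        step = np.clip(-grad / hess, -4.0, 4.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break

    eta = np.clip(eta0 + b[gidx], ETA_MIN, ETA_MAX)
    mu = np.exp(eta)
    ll_cond = nb_loglik(y[:, None], mu[:, None], theta)[0]
    g2 = -theta * mu * (y + theta) / (theta + mu) ** 2
    hess = np.bincount(gidx, weights=g2, minlength=n_groups)
    # log det of the Laplace correction: -0.5 log(1 - sigma2 * hess)
    return (
        ll_cond
        - np.sum(b**2) / (2.0 * sigma2)
        - 0.5 * np.sum(np.log1p(-sigma2 * hess))
    )


def fit_nb_glmm(y, X, group, *, names: list[str] | None = None) -> MixedFitResult:
    """NB GLMM with a random intercept per level of ``group``.

    The marginal likelihood is maximised under the Laplace approximation.
    Wald t (= z) statistics and normal two-sided P values are reported
    for the fixed effects.  With a single group the model degenerates to
    :func:`fit_nb_glm` (a warning is emitted).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    levels, gidx = np.unique(np.asarray(group), return_inverse=True)
    n, p = y.shape[0], X.shape[1]
    names = names or [f"x{j}" for j in range(p)]

    if len(levels) < 2:
        warnings.warn(
            "single group: random variance unidentifiable, "
            "falling back to the fixed-effects GLM",
            RuntimeWarning,
        )
        glm = fit_nb_glm(y, X)
        t = glm.coef / glm.se
        return MixedFitResult(
            coef=glm.coef, se=glm.se, tvalues=t,
            pvalues=2.0 * stats.norm.sf(np.abs(t)),
            random_variance=0.0, theta=glm.theta, loglik=glm.loglik,
            n=n, n_groups=1, converged=glm.converged, names=names,
        )

    start_glm = fit_nb_glm(y, X)
    x0 = np.concatenate(
        [start_glm.coef, [np.log(0.5)], [np.log(start_glm.theta)]]
    )

    def nll(params):
        return -_laplace_loglik(params, y, X, gidx, len(levels))

    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    res = optimize.minimize(
        nll, res.x, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-11},
    )

    est = res.x
    beta = est[:p]
    sigma2 = float(np.exp(2.0 * np.clip(est[p], -8.0, 5.0)))
    theta = float(np.exp(np.clip(est[p + 1], np.log(THETA_FLOOR), np.log(THETA_CAP))))

    # observed-information SEs for the fixed effects from a numerical
    # Hessian of the Laplace marginal likelihood
    h = 1e-4 * (1.0 + np.abs(est))
    k = len(est)
    H = np.zeros((k, k))
    f0 = nll(est)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll(est + ei + ej) - nll(est + ei) - nll(est + ej) + f0
            ) / (h[i] * h[j])
    def _se_from(Hm, idx):
        try:
            cov = np.linalg.inv(Hm)
            d = np.diag(cov)[: len(idx)]
            if np.all(np.isfinite(d)) and np.all(d > 0):
                return np.sqrt(d)
        except np.linalg.LinAlgError:
            pass
        return None

    # flat directions (variance at its boundary, theta at the Poisson
    # limit) make the full Hessian singular; fall back to sub-blocks
    se = None
    for idx in (
        list(range(k)),
        list(range(p)) + [p + 1],  # drop sigma
        list(range(p)) + [p],      # drop theta
        list(range(p)),            # beta block only
    ):
        se = _se_from(H[np.ix_(idx, idx)], idx)
        if se is not None:
            break
    se = se[:p] if se is not None else np.full(p, np.nan)

    t = beta / se
    if not res.success:
        warnings.warn("mixed-model optimiser did not converge", RuntimeWarning)
    return MixedFitResult(
        coef=beta, se=se, tvalues=t,
        pvalues=2.0 * stats.norm.sf(np.abs(t)),
        random_variance=sigma2, theta=theta, loglik=float(-res.fun),
        n=n, n_groups=len(levels), converged=bool(res.success), names=names,
    )


def fit_ols(y, x):
    """Simple linear regression; returns ``(slope, adjusted R^2, P)``.

    Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2).
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    n = y.shape[0]
    if n < 3:
        raise ConfigurationError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ConfigurationError("predictor has zero variance")
    if np.ptp(y) == 0:
        # no variance to explain: R^2 = 0 and the penalty drives adj below 0
        return 0.0, float(1.0 - (n - 1.0) / (n - 2.0)), 1.0
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1.0) / (n - 2.0)
    return float(fit.slope), float(adj), float(fit.pvalue)
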