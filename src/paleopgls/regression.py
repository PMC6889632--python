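"""Phylogenetic generalized least squares for the allometric regression.

The model is log10(HL) = a + b * log10(FL) + e, with residuals e correlated
according to shared ancestry: Cov(e) = sigma^2 * V, where V comes from a
Brownian-motion covariance downweighted by Pagel's lambda, from an
Ornstein-Uhlenbeck process with attraction strength alpha, or from the
identity (ordinary least squares). b is the allometric coefficient: b < 1
is negative allometry, b = 1 isometry, b > 1 positive allometry.

lambda and alpha are estimated by maximizing the restricted likelihood
(REML, the default) or the full likelihood (ML) with the regression
coefficients and sigma^2 profiled out. When lambda estimation fails, the
conventional fallback is a pair of fits bracketing the possible signal:
fixed lambda = 1 (pure BM) and OLS (lambda = 0).

:class:`PGLSRegressor` is the scikit-learn estimator around this machinery;
the module-level functions (`gls_fit`, `fit_pgls_bm_lambda`, `fit_pgls_ou`,
`fit_ols`) are thin wrappers kept for pipeline use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .covariance import PhyloCovariance, bm_covariance, lambda_transform, ou_covariance

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "PGLSRegressor",
    "gls_fit",
    "fit_pgls_bm_lambda",
    "fit_pgls_ou",
    "fit_ols",
    "WithinTaxonResult",
    "within_taxon_regression",
]

_ALPHA_BOUNDS = (1e-6, 1e2)  # per My
_GRID_POINTS = 21


@dataclass(frozen=True)
class ModelFit:
    """One regression's estimates, uncertainties and diagnostics."""

    model: str  # "BM+lambda", "OU", "OLS", "GLS"
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    ci_slope: tuple[float, float]  # 95% Student-t, n-2 df
    sigma2: float
    loglik: float
    n: int
    signal: float | None = None  # lambda or alpha
    signal_name: str | None = None
    signal_fixed: bool = True
    converged: bool = True
    caution: bool = False  # OU low-alpha / low-n reliability caveat
    note: str = ""

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "intercept": self.intercept,
            "slope": self.slope,
            "se_slope": self.se_slope,
            "ci_low": self.ci_slope[0],
            "ci_high": self.ci_slope[1],
            "signal": self.signal,
            "signal_name": self.signal_name,
            "signal_fixed": self.signal_fixed,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n": self.n,
            "converged": self.converged,
            "caution": self.caution,
            "note": self.note,
        }


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x])


def _gls_core(y, X, V, method: str):
    """Whitened least squares under covariance V with sigma^2 profiled out.

    Returns (beta, cov_beta_unit, rss, logdet_v, logdet_xtx) where
    cov_beta_unit is (X' V^-1 X)^-1 (multiply by sigma^2 for the
    coefficient covariance).
    """
    n, p = X.shape
    L = linalg.cholesky(V, lower=True)  # raises LinAlgError if singular
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    xtx = Xw.T @ Xw
    if np.linalg.matrix_rank(xtx) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    xtx_inv = linalg.inv(xtx)
    beta = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    # a numerically perfect fit has no estimable scale: treat as zero
    if rss <= 1e-12 * max(float(yw @ yw), np.finfo(float).tiny):
        rss = 0.0
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' V^-1 X not positive definite")
    return beta, xtx_inv, rss, logdet_v, float(logdet_xtx)


def _loglik(rss, n, p, logdet_v, logdet_xtx, method: str) -> float:
    if rss <= 0:
        return np.inf  # exact fit
    if method == "ml":
        s2 = rss / n
        return -0.5 * (n * np.log(2 * np.pi * s2) + logdet_v + n)
    s2 = rss / (n - p)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi * s2) + logdet_v + logdet_xtx + (n - p)
    )


def gls_fit(
    y,
    x,
    V: PhyloCovariance | np.ndarray | None,
    model: str = "GLS",
    signal: float | None = None,
    signal_name: str | None = None,
    signal_fixed: bool = True,
    method: str = "reml",
    conf_level: float = 0.95,
) -> ModelFit:
    """Generalized least squares of y on [1, x] under a fixed covariance.

    ``V = None`` (or the identity) gives ordinary least squares. Standard
    errors use sigma^2 = RSS / (n - 2); the slope CI uses Student-t with
    n - 2 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if len(x) != n:
        raise ValueError("y and x have different lengths")
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if V is None:
        Vm = np.eye(n)
    elif isinstance(V, PhyloCovariance):
        Vm = V.matrix
    else:
        Vm = np.asarray(V, dtype=float)
    if Vm.shape != (n, n):
        raise ValueError(f"V has shape {Vm.shape}, expected ({n}, {n})")

    X = _design(x)
    p = X.shape[1]
    beta, xtx_inv, rss, ldv, ldx = _gls_core(y, X, Vm, method)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    tq = stats.t.ppf(0.5 + conf_level / 2.0, df=n - 2)
    ll = _loglik(rss, n, p, ldv, ldx, method)
    return ModelFit(
        model=model,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        ci_slope=(float(beta[1] - tq * se[1]), float(beta[1] + tq * se[1])),
        sigma2=float(sigma2),
        loglik=float(ll),
        n=n,
        signal=signal,
        signal_name=signal_name,
        signal_fixed=signal_fixed,
    )


def fit_ols(y, x, method: str = "reml", conf_level: float = 0.95) -> ModelFit:
    """Ordinary least squares — PGLS with a star phylogeny (lambda = 0)."""
    return gls_fit(
        y, x, None, model="OLS", signal=0.0, signal_name="lambda",
        signal_fixed=True, method=method, conf_level=conf_level,
    )


def _profile_optimize(objective, grid):
    """Coarse grid scan followed by a bounded local refinement.

    Guards against local optima that a single Brent search from one bracket
    could fall into. Returns (best_param, converged) or (None, False) when
    the objective is non-finite everywhere.
    """
    values = np.array([objective(g) for g in grid])
    finite = np.isfinite(values)
    if not finite.any():
        return None, False
    k = int(np.nanargmin(np.where(finite, values, np.inf)))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    best, best_val = grid[k], values[k]
    if hi > lo:
        res = optimize.minimize_scalar(
            objective, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        if np.isfinite(res.fun) and res.fun <= best_val:
            best, best_val = float(res.x), float(res.fun)
    return best, True


def fit_pgls_bm_lambda(
    y,
    x,
    tree=None,
    bm_cov: PhyloCovariance | None = None,
    method: str = "reml",
    conf_level: float = 0.95,
) -> list[ModelFit]:
    """PGLS under BM with simultaneous Pagel's-lambda estimation.

    Returns a one-element list holding the fit at the (restricted) maximum
    likelihood lambda. If estimation is impossible (likelihood non-finite
    over the whole lambda range, e.g. singular covariance), returns the
    fallback pair: a fixed lambda = 1 fit and an OLS fit, bracketing the
    possible phylogenetic signal.
    """
    if bm_cov is None:
        if tree is None:
            raise ValueError("provide a tree or a precomputed BM covariance")
        bm_cov = bm_covariance(tree)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = _design(x)
    n, p = X.shape

    def objective(lam: float) -> float:
        try:
            Vm = lambda_transform(bm_cov, lam).matrix
            _, _, rss, ldv, ldx = _gls_core(y, X, Vm, method)
        except np.linalg.LinAlgError:
            return np.inf
        return -_loglik(rss, n, p, ldv, ldx, method)

    lam_hat, ok = _profile_optimize(objective, np.linspace(0.0, 1.0, _GRID_POINTS))
    if not ok or not np.isfinite(objective(lam_hat)):
        logger.info("lambda estimation failed; falling back to lambda=1 + OLS")
        fits = []
        try:
            f1 = gls_fit(
                y, x, lambda_transform(bm_cov, 1.0), model="BM+lambda",
                signal=1.0, signal_name="lambda", signal_fixed=True,
                method=method, conf_level=conf_level,
            )
            fits.append(_mark(f1, converged=False, note="lambda fixed at 1 (fallback)"))
        except np.linalg.LinAlgError:
            logger.warning("fixed lambda=1 fit singular; reporting OLS only")
        f0 = fit_ols(y, x, method=method, conf_level=conf_level)
        fits.append(_mark(f0, converged=False, note="OLS fallback (lambda=0)"))
        return fits

    fit = gls_fit(
        y, x, lambda_transform(bm_cov, lam_hat), model="BM+lambda",
        signal=float(lam_hat), signal_name="lambda", signal_fixed=False,
        method=method, conf_level=conf_level,
    )
    return [fit]


def fit_pgls_ou(
    y,
    x,
    tree,
    method: str = "reml",
    conf_level: float = 0.95,
    alpha_bounds: tuple[float, float] = _ALPHA_BOUNDS,
) -> list[ModelFit]:
    """PGLS under an Ornstein-Uhlenbeck model with alpha estimated.

    alpha is profiled over a log-spaced bounded interval. The returned fit
    carries ``caution=True`` when alpha < 0.05 or n < 50, the regime where
    OU-based inference is known to be unreliable (inflated type I error).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = _design(x)
    n, p = X.shape

    def objective(log_alpha: float) -> float:
        try:
            Vm = ou_covariance(tree, 10.0 ** log_alpha).matrix
            _, _, rss, ldv, ldx = _gls_core(y, X, Vm, method)
        except np.linalg.LinAlgError:
            return np.inf
        return -_loglik(rss, n, p, ldv, ldx, method)

    grid = np.linspace(np.log10(alpha_bounds[0]), np.log10(alpha_bounds[1]),
                       _GRID_POINTS)
    la_hat, ok = _profile_optimize(objective, grid)
    if not ok:
        logger.info("alpha estimation failed; falling back to OLS")
        f0 = fit_ols(y, x, method=method, conf_level=conf_level)
        return [_mark(f0, converged=False, note="OLS fallback (alpha inestimable)")]
    alpha_hat = 10.0 ** la_hat
    fit = gls_fit(
        y, x, ou_covariance(tree, alpha_hat), model="OU",
        signal=float(alpha_hat), signal_name="alpha", signal_fixed=False,
        method=method, conf_level=conf_level,
    )
    lo, hi = alpha_bounds
    if alpha_hat >= hi * 0.99 or alpha_hat <= lo * 1.01:
        fit = _mark(fit, caution=True,
                    note="alpha at search boundary; no interior optimum")
    elif alpha_hat < 0.05 or n < 50:
        fit = _mark(fit, caution=True,
                    note="low attraction strength or sample size; OU inference unreliable")
    return [fit]


def _mark(fit: ModelFit, **changes) -> ModelFit:
    from dataclasses import replace

    return replace(fit, **changes)


@dataclass(frozen=True)
class WithinTaxonResult:
    """OLS fit within one genus or species (no phylogeny), or the reason
    no fit was possible."""

    taxon: str
    n: int
    fit: ModelFit | None = None
    reason: str = ""


def within_taxon_regression(records, taxon: str | None = None) -> WithinTaxonResult:
    """Ordinary regression of log HL on log FL within one taxon.

    A preliminary probe of ontogenetic allometry from conspecific or
    congeneric size series; taxa with fewer than 3 specimens are reported
    as insufficient data, not raised.
    """
    records = list(records)
    if taxon is None:
        taxon = records[0].genus if records else "?"
    n = len(records)
    if n < 3:
        return WithinTaxonResult(taxon=taxon, n=n, reason="fewer than 3 specimens")
    y = [r.log_hl for r in records]
    x = [r.log_fl for r in records]
    if np.ptp(x) == 0:
        return WithinTaxonResult(taxon=taxon, n=n, reason="no FL variation")
    return WithinTaxonResult(taxon=taxon, n=n, fit=fit_ols(y, x))


class PGLSRegressor(RegressorMixin, BaseEstimator):
    """Phylogenetic least-squares allometric regression, scikit-learn style.

    Parameters
    ----------
    model : {"bm_lambda", "ou", "ols"}
        Residual covariance family: BM with Pagel's lambda estimated, OU
        with alpha estimated, or ordinary least squares.
    method : {"reml", "ml"}
        Criterion maximized over the signal parameter.
    conf_level : float
        Confidence level of the slope interval (Student-t, n - 2 df).

    Attributes (after fit)
    ----------------------
    coef_ : ndarray of shape (1,) — allometric slope.
    intercept_ : float
    signal_ : float or None — estimated lambda or alpha.
    sigma2_ : float — profiled residual scale.
    loglik_ : float
    result_ : ModelFit — the primary fit.
    results_ : list[ModelFit] — primary plus any fallback fits.

    Examples
    --------
    >>> reg = PGLSRegressor(model="ols").fit([[1.0], [2.0], [3.0]],
    ...                                      [1.0, 2.0, 3.0])
    >>> float(reg.coef_[0])
    1.0
    """

    def __init__(self, model: str = "bm_lambda", method: str = "reml",
                 conf_level: float = 0.95):
        self.model = model
        self.method = method
        self.conf_level = conf_level

    def fit(self, X, y, tree=None, covariance=None, labels=None):
        """Fit the regression.

        X is (n, 1) with the log10 body-size proxy; y the log10 trait.
        For phylogenetic models pass ``tree`` (and optionally ``labels``,
        the tip label of each row, used to align rows with tree tip order;
        a label mismatch is an error — rows are never matched by guesswork).
        ``covariance`` may supply a precomputed :class:`PhyloCovariance`
        to be used as-is with the signal treated as fixed.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("exactly one predictor (log FL) is expected")
        y = np.asarray(y, dtype=float)
        x = X[:, 0]

        if self.model not in ("bm_lambda", "ou", "ols"):
            raise ValueError(f"unknown model {self.model!r}")

        if tree is not None:
            order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
            if labels is not None:
                if sorted(labels) != sorted(order):
                    raise ValueError(
                        "observation labels do not match tree tip labels"
                    )
                pos = {lab: i for i, lab in enumerate(labels)}
                idx = np.array([pos[lab] for lab in order])
                x, y = x[idx], y[idx]
            elif len(x) != len(order):
                raise ValueError("observation count differs from tip count")

        if self.model == "ols":
            fits = [fit_ols(y, x, method=self.method, conf_level=self.conf_level)]
        elif covariance is not None:
            fits = [gls_fit(
                y, x, covariance, model=self.model,
                signal=covariance.parameter,
                signal_name={"bm_lambda": "lambda", "ou": "alpha"}[self.model],
                method=self.method, conf_level=self.conf_level,
            )]
        elif tree is None:
            raise ValueError(f"model {self.model!r} requires a tree or covariance")
        elif self.model == "bm_lambda":
            fits = fit_pgls_bm_lambda(y, x, tree=tree, method=self.method,
                                      conf_level=self.conf_level)
        else:
            fits = fit_pgls_ou(y, x, tree, method=self.method,
                               conf_level=self.conf_level)

        self.results_ = fits
        self.result_ = fits[0]
        self.intercept_ = self.result_.intercept
        self.coef_ = np.array([self.result_.slope])
        self.signal_ = self.result_.signal
        self.sigma2_ = self.result_.sigma2
        self.loglik_ = self.result_.loglik
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X[:, 0] * self.coef_[0]
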