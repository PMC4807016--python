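"""Generalized least squares regression under four trait-evolution models.

The regression of a feature on a lifespan measure is an ordinary GLS problem
whose error covariance (up to a rate factor sigma^2, profiled out
analytically) is one of:

* ``Null``   — identity: no phylogenetic structure.
* ``BM``     — Brownian motion: V = C, the MRCA-depth matrix.
* ``Lambda`` — Pagel's lambda: off-diagonal entries of C scaled by
  lambda in [0, 1], diagonal kept.
* ``OU``     — fixed-root Ornstein-Uhlenbeck with reversion strength alpha:
  ``V[i,j] = exp(-alpha * D[i,j]) * (1 - exp(-2 alpha * C[i,j])) / (2 alpha)``,
  which tends to C entrywise as alpha -> 0 and is valid for non-ultrametric
  trees.

``Lambda``'s lambda and ``OU``'s alpha are estimated by maximizing the
profile log-likelihood (ML, not REML) via bounded scalar search; the best
model is the converged fit with the highest log-likelihood, ties broken
toward the simpler model.  Slope inference is a two-sided t test with
n - 2 degrees of freedom.  Leave-one-out p-values rerun the whole fit with
each taxon removed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, optimize
from scipy import stats

from .phylo import TreeGeometry

__all__ = [
    "MODEL_KINDS",
    "EvolutionModel",
    "GLSFit",
    "PGLSFit",
    "LOOResult",
    "CovarianceError",
    "FitError",
    "covariance_matrix",
    "gls_fit",
    "fit_pgls",
    "select_best_model",
    "loo_pvalues",
]

MODEL_KINDS = ("Null", "BM", "Lambda", "OU")

# Complexity order used to break exact log-likelihood ties.
_COMPLEXITY = {"Null": 0, "BM": 1, "Lambda": 2, "OU": 3}

# OU reversion-strength search window, in units of 1 / max tip depth.
ALPHA_LO = 1e-4
ALPHA_HI = 1e2

_DEGENERATE_RTOL = 1e-12


class CovarianceError(ValueError):
    """Covariance matrix could not be formed or is not positive definite."""


class FitError(ValueError):
    """GLS system is singular (bad V or collinear design)."""


@dataclass(frozen=True)
class EvolutionModel:
    """One of the four trait-evolution covariance models.

    ``lambda_`` applies to the Lambda kind, ``alpha`` to OU; both are
    ignored elsewhere.  ``sigma2`` is a rate multiplier used only when
    simulating; in fitting it is profiled out.
    """

    kind: str
    sigma2: float = 1.0
    lambda_: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.kind == "Lambda":
            if self.lambda_ is None or not (0.0 <= self.lambda_ <= 1.0):
                raise ValueError("Lambda model requires lambda_ in [0, 1]")
        if self.kind == "OU":
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("OU model requires alpha > 0")

    @property
    def parameter(self) -> float | None:
        """The single free parameter (lambda or alpha), if any."""
        if self.kind == "Lambda":
            return self.lambda_
        if self.kind == "OU":
            return self.alpha
        return None


@dataclass(frozen=True)
class GLSFit:
    """Result of one GLS fit at a fixed covariance matrix."""

    beta: np.ndarray  # (intercept, slope)
    sigma2_ml: float
    loglik: float
    t_slope: float
    p_slope: float
    df: int
    n: int
    degenerate: bool = False

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def slope(self) -> float:
        return float(self.beta[1])


@dataclass(frozen=True)
class PGLSFit:
    """A GLS fit plus the evolution model whose parameter was ML-estimated."""

    fit: GLSFit
    model: EvolutionModel
    converged: bool

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def p_slope(self) -> float:
        return self.fit.p_slope


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out slope p-values, one per dropped taxon."""

    labels: tuple[str, ...]
    pvalues: np.ndarray  # NaN where the subfit was degenerate
    max_p: float

    def __len__(self) -> int:
        return len(self.labels)


def covariance_matrix(geom: TreeGeometry, model: EvolutionModel) -> np.ndarray:
    """Model covariance among tips, up to the rate factor sigma^2.

    Raises :class:`CovarianceError` if the result is not positive definite
    even after a single trace-scaled jitter.
    """
    C = geom.mrca_depth
    if model.kind == "Null":
        return np.eye(geom.n)
    if model.kind == "BM":
        V = C.copy()
    elif model.kind == "Lambda":
        lam = model.lambda_
        V = lam * C
        np.fill_diagonal(V, np.diag(C))
    else:  # OU, fixed root
        a = model.alpha
        D = geom.patristic
        with np.errstate(over="ignore"):
            V = np.exp(-a * D) * (-np.expm1(-2.0 * a * C)) / (2.0 * a)
    _assert_pd(V, model)
    return V


def _assert_pd(V: np.ndarray, model: EvolutionModel) -> None:
    try:
        linalg.cholesky(V, lower=True)
        return
    except linalg.LinAlgError:
        pass
    jitter = 1e-10 * np.trace(V) / V.shape[0]
    V += jitter * np.eye(V.shape[0])
    try:
        linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        raise CovarianceError(
            f"covariance for model {model.kind} (parameter={model.parameter}) "
            "is not positive definite"
        ) from None


def gls_fit(
    y: Sequence[float],
    x: Sequence[float],
    V: np.ndarray,
) -> GLSFit:
    """Fit ``y = b0 + b1 x + e`` with ``e ~ N(0, sigma^2 V)`` by GLS/ML.

    sigma^2 is profiled: its ML estimate is the V-weighted residual sum of
    squares over n.  The slope standard error uses the unbiased (n - 2)
    variance estimate, giving the usual t test.

    A perfect fit (zero weighted residual variance) sets the degenerate
    flag, ``p_slope = 0`` by convention and a non-finite log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    if x.shape[0] != n or V.shape != (n, n):
        raise ValueError(f"shape mismatch: y {y.shape}, x {x.shape}, V {V.shape}")
    if n < 3:
        raise ValueError("need at least 3 observations for a slope test")

    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        raise FitError("V is singular or not positive definite") from None
    X = np.column_stack([np.ones(n), x])
    # Whiten: solve L z = v  =>  z = L^{-1} v
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)

    XtX = Xw.T @ Xw
    try:
        XtX_inv = linalg.inv(XtX)
    except linalg.LinAlgError:
        raise FitError("design matrix is collinear (constant predictor?)") from None
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise FitError("design matrix is collinear (constant predictor?)")

    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    df = n - 2

    scale = float(yw @ yw)
    if rss <= _DEGENERATE_RTOL * max(scale, 1.0):
        return GLSFit(
            beta=beta,
            sigma2_ml=0.0,
            loglik=math.inf,
            t_slope=math.inf if beta[1] != 0 else 0.0,
            p_slope=0.0,
            df=df,
            n=n,
            degenerate=True,
        )

    sigma2_ml = rss / n
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * n * math.log(2.0 * math.pi * sigma2_ml) - 0.5 * logdet_V - 0.5 * n

    sigma2_unbiased = rss / df
    se_slope = math.sqrt(sigma2_unbiased * XtX_inv[1, 1])
    t_slope = float(beta[1]) / se_slope
    p_slope = 2.0 * float(stats.t.sf(abs(t_slope), df))
    return GLSFit(
        beta=beta,
        sigma2_ml=sigma2_ml,
        loglik=loglik,
        t_slope=t_slope,
        p_slope=p_slope,
        df=df,
        n=n,
    )


def _profile_loglik(param: float, kind: str, y, x, geom) -> float:
    if kind == "Lambda":
        model = EvolutionModel(kind="Lambda", lambda_=param)
    else:
        model = EvolutionModel(kind="OU", alpha=param)
    V = covariance_matrix(geom, model)
    return gls_fit(y, x, V).loglik


def fit_pgls(
    y: Sequence[float],
    x: Sequence[float],
    geom: TreeGeometry,
    kind: str,
) -> PGLSFit:
    """Fit one evolution model, ML-estimating its free parameter if any.

    Lambda is searched on [0, 1]; OU on a log-alpha grid spanning
    ``[1e-4 / h, 1e2 / h]`` with h the maximum tip depth.  Both searches
    compare the interior optimum against the interval endpoints so the
    returned parameter never scores below either end.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)

    if kind in ("Null", "BM"):
        model = EvolutionModel(kind=kind)
        V = covariance_matrix(geom, model)
        return PGLSFit(fit=gls_fit(y, x, V), model=model, converged=True)

    if kind == "Lambda":
        lo, hi = 0.0, 1.0
        to_param = lambda s: s  # noqa: E731
        from_param = lambda p: p  # noqa: E731
    else:  # OU: optimize on log scale
        h = float(np.max(np.diag(geom.mrca_depth)))
        if h <= 0:
            raise ValueError("tree has zero depth; OU model undefined")
        lo, hi = math.log(ALPHA_LO / h), math.log(ALPHA_HI / h)
        to_param = math.exp
        from_param = math.log

    def neg_ll(s: float) -> float:
        try:
            ll = _profile_loglik(to_param(s), kind, y, x, geom)
        except (CovarianceError, FitError):
            return math.inf
        if ll == math.inf:  # degenerate perfect fit dominates everywhere
            return -math.inf
        return -ll

    converged = True
    try:
        res = optimize.minimize_scalar(
            neg_ll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
        )
        candidates = [(res.x, -res.fun)] if np.isfinite(res.x) else []
        converged = bool(res.success)
    except Exception:
        candidates = []
        converged = False

    for s in (lo, hi):
        candidates.append((s, -neg_ll(s)))
    candidates = [(s, ll) for s, ll in candidates if not math.isnan(ll)]
    if not candidates:
        converged = False
        best_s, best_ll = lo, -math.inf
    else:
        best_s, best_ll = max(candidates, key=lambda t: t[1])

    param = to_param(best_s)
    if kind == "Lambda":
        param = min(1.0, max(0.0, param))
        model = EvolutionModel(kind="Lambda", lambda_=param)
    else:
        model = EvolutionModel(kind="OU", alpha=param)
    V = covariance_matrix(geom, model)
    fit = gls_fit(y, x, V)
    if not np.isfinite(fit.loglik) and not fit.degenerate:
        converged = False
    return PGLSFit(fit=fit, model=model, converged=converged)


def fit_all_models(y, x, geom) -> dict[str, PGLSFit]:
    """Convenience: one :func:`fit_pgls` per model kind."""
    return {kind: fit_pgls(y, x, geom, kind) for kind in MODEL_KINDS}


def select_best_model(fits: dict[str, PGLSFit] | Sequence[PGLSFit]) -> PGLSFit:
    """Pick the converged fit with the highest log-likelihood.

    Exact ties go to the simpler model in the order Null < BM < Lambda < OU.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    usable = [f for f in fits if f.converged]
    if not usable:
        raise FitError("no converged fit to select from")
    return max(usable, key=lambda f: (f.loglik, -_COMPLEXITY[f.model.kind]))


def loo_pvalues(
    y: Sequence[float],
    x: Sequence[float],
    geom: TreeGeometry,
    kind: str,
) -> LOOResult:
    """Slope p-value with each taxon left out in turn.

    The tree geometry restricted to the remaining taxa equals that of the
    pruned tree, so each subfit re-estimates the model parameter on the
    reduced data.  Degenerate subfits are recorded as NaN and excluded from
    ``max_p``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = geom.n
    if y.shape[0] != n or x.shape[0] != n:
        raise ValueError("y, x must match the geometry dimension")
    if n < 4:
        raise ValueError("need at least 4 taxa for leave-one-out (df >= 1 after removal)")

    pvals = np.full(n, np.nan)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = geom.subset([geom.tip_order[j] for j in keep])
        try:
            f = fit_pgls(y[keep], x[keep], sub, kind)
        except (FitError, CovarianceError):
            warnings.warn(f"leave-one-out subfit failed dropping {geom.tip_order[i]!r}")
            continue
        if not f.fit.degenerate:
            pvals[i] = f.p_slope
    finite = pvals[~np.isnan(pvals)]
    max_p = float(np.max(finite)) if finite.size else math.nan
    return LOOResult(labels=geom.tip_order, pvalues=pvals, max_p=max_p)
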