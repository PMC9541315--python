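"""Scalar and multivariate probit machinery.

The model thresholds latent multivariate-normal variables to produce the
observed categorical responses, so its likelihood is built from *rectangle
probabilities* P(L < Z < U) for Z ~ MVN(nu, Psi) with Psi a correlation
matrix.  This module provides:

* the 1.702-scaled logistic approximation to the standard normal CDF
  (``approx_probit_cdf``), used throughout the model's accuracy links and
  cutpoint transforms for numerical robustness;
* the response -> latent-rectangle mapping;
* rectangle probabilities via a GHK-style sequential-conditioning scheme
  (deterministic Gauss-Legendre nodes in the uniform space of each
  truncated conditional, or explicit uniform draws for the Monte Carlo
  variant) and, independently, a brute-force nested-quadrature oracle used
  for testing at small dimension;
* the bijection between strictly increasing cutpoints and the simplex of
  ordinal category probabilities (the parameterisation behind the induced
  Dirichlet pooling model).

``rectangle_prob`` defaults to the exact normal CDF in its conditionals so
that it is a general-purpose numerical routine comparable to independent
integration; the model passes ``link="probit_approx"`` to use the logistic
approximation consistently in its likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit
from scipy.stats import norm

from .data_io import TestDefinition

__all__ = [
    "PROBIT_SCALE",
    "approx_probit_cdf",
    "approx_probit_ppf",
    "probit_max_abs_deviation",
    "Rectangle",
    "response_to_rectangle",
    "rectangle_prob",
    "cutpoints_to_simplex",
    "simplex_to_cutpoints",
    "validate_simplex",
]

PROBIT_SCALE = 1.702


# -- approximate probit link ----------------------------------------------

def approx_probit_cdf(x):
    """Logistic approximation to the standard normal CDF: 1/(1+e^{-1.702 x})."""
    return expit(PROBIT_SCALE * np.asarray(x, dtype=float))


def approx_probit_ppf(q):
    """Inverse of :func:`approx_probit_cdf`: logit(q)/1.702."""
    return logit(np.asarray(q, dtype=float)) / PROBIT_SCALE


def probit_max_abs_deviation():
    """max_x |Phi(x) - Phi'(x)|, located numerically.

    The deviation is symmetric in x but has more than one interior bump, so
    a coarse grid scan locates the global maximum before a bounded scalar
    minimisation polishes it.
    """
    f = lambda x: -(abs(norm.cdf(x) - approx_probit_cdf(x)))
    grid = np.linspace(1e-3, 4.0, 2001)
    x0 = grid[np.argmin([f(x) for x in grid])]
    res = minimize_scalar(f, bounds=(max(x0 - 0.01, 1e-4), x0 + 0.01),
                          method="bounded", options={"xatol": 1e-12})
    return float(-res.fun)


# -- links, pluggable ------------------------------------------------------

_LINKS = {
    "probit": (norm.cdf, norm.ppf),
    "probit_approx": (approx_probit_cdf, approx_probit_ppf),
}


def _get_link(link):
    try:
        return _LINKS[link]
    except KeyError:
        raise ValueError(f"unknown link {link!r}; choose from {list(_LINKS)}")


# -- response -> rectangle -------------------------------------------------

@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned latent rectangle: per-test lower/upper bounds (+-inf ok)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape:
            raise ValueError("lower/upper shape mismatch")
        if np.any(lo >= hi):
            raise ValueError("empty rectangle: lower >= upper")

    @property
    def dim(self):
        return self.lower.shape[0]


def response_to_rectangle(y, test: TestDefinition, cutpoints=None) -> Rectangle:
    """Latent interval implied by one coded response on one test.

    Dichotomous: y=0 -> (-inf, 0), y=1 -> (0, inf).  Ordinal: y=k ->
    (C_{k-1}, C_k) with C_0 = -inf and C_K = +inf.
    """
    if not test.is_ordinal:
        if y not in (0, 1):
            raise ValueError(f"dichotomous response must be 0/1, got {y}")
        return Rectangle([-np.inf, 0.0][y], [0.0, np.inf][y])
    if cutpoints is None:
        raise ValueError(f"ordinal test {test.name!r} needs cutpoints")
    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.shape != (test.n_cutpoints,):
        raise ValueError(
            f"expected {test.n_cutpoints} cutpoints, got shape {cuts.shape}"
        )
    if np.any(np.diff(cuts) <= 0) or not np.all(np.isfinite(cuts)):
        raise ValueError("cutpoints must be finite and strictly increasing")
    if not 1 <= y <= test.n_categories:
        raise ValueError(
            f"ordinal response must be 1..{test.n_categories}, got {y}"
        )
    padded = np.concatenate([[-np.inf], cuts, [np.inf]])
    return Rectangle(padded[y - 1], padded[y])


# -- rectangle probabilities ----------------------------------------------

def _check_corr(corr, dim):
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (dim, dim):
        raise ValueError(f"correlation matrix must be {dim}x{dim}")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric")
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("correlation matrix is not positive definite")
    return corr, L


def _unit_nodes(n):
    """Gauss-Legendre nodes/weights transplanted to (0, 1)."""
    x, w = leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def ghk_rectangle_prob(lower, upper, mean, chol, cdf, ppf, nodes=16, u=None):
    """Sequential-conditioning (GHK) rectangle probability.

    With ``u`` omitted the truncated conditionals are integrated on a
    deterministic tensor grid of Gauss-Legendre nodes; with ``u`` given
    (shape (n_draws, T)) the classic Monte Carlo GHK estimator over those
    uniforms is returned.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    mean = np.asarray(mean, float)
    T = lower.shape[0]
    if u is not None:
        u = np.atleast_2d(np.asarray(u, float))
        z = np.zeros((u.shape[0], T))
        w = np.ones(u.shape[0])
        for t in range(T):
            cond = z[:, :t] @ chol[t, :t]
            a = (lower[t] - mean[t] - cond) / chol[t, t]
            b = (upper[t] - mean[t] - cond) / chol[t, t]
            Fa, Fb = cdf(a), cdf(b)
            w *= Fb - Fa
            q = np.clip(Fa + u[:, t] * (Fb - Fa), 1e-14, 1 - 1e-14)
            z[:, t] = ppf(q)
        return float(np.mean(w))

    xg, wg = _unit_nodes(nodes)
    # running tensor grid over the first t dimensions
    z = np.zeros((1, 0))  # (n_grid, t)
    w = np.ones(1)
    prob = 1.0
    for t in range(T):
        cond = z @ chol[t, :t] if t else np.zeros(1)
        a = (lower[t] - mean[t] - cond) / chol[t, t]
        b = (upper[t] - mean[t] - cond) / chol[t, t]
        Fa, Fb = cdf(a), cdf(b)
        p_t = Fb - Fa  # (n_grid,)
        if t == T - 1:
            prob = float(np.sum(w * p_t))
            break
        # refine grid: for every current node, spawn quadrature nodes of z_t
        q = np.clip(Fa[:, None] + xg[None, :] * p_t[:, None], 1e-14, 1 - 1e-14)
        z_t = ppf(q)  # (n_grid, nodes)
        z = np.concatenate(
            [np.repeat(z, nodes, axis=0), z_t.reshape(-1, 1)], axis=1
        )
        w = (w[:, None] * wg[None, :] * p_t[:, None]).ravel()
    return prob


def oracle_rectangle_prob(lower, upper, mean, corr, nodes=48):
    """Brute-force oracle: nested Gauss-Legendre integration of the MVN
    density over the rectangle (exact normal CDF in the innermost dimension).

    Independent of the GHK construction; intended for T <= 3.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    mean = np.asarray(mean, float)
    T = lower.shape[0]
    if T > 3:
        raise ValueError("oracle supports T <= 3")
    lo = np.maximum(lower - mean, -8.5)
    hi = np.minimum(upper - mean, 8.5)
    if T == 1:
        return float(norm.cdf(hi[0]) - norm.cdf(lo[0]))
    x, w = leggauss(nodes)
    corr = np.asarray(corr, float)
    if T == 2:
        r = corr[0, 1]
        t = 0.5 * (hi[0] - lo[0]) * x + 0.5 * (hi[0] + lo[0])
        wt = 0.5 * (hi[0] - lo[0]) * w
        s = np.sqrt(max(1.0 - r * r, 1e-300))
        inner = norm.cdf((hi[1] - r * t) / s) - norm.cdf((lo[1] - r * t) / s)
        return float(np.sum(wt * norm.pdf(t) * inner))
    # T == 3: integrate density over dims 0,1; exact conditional CDF in dim 2
    t0 = 0.5 * (hi[0] - lo[0]) * x + 0.5 * (hi[0] + lo[0])
    w0 = 0.5 * (hi[0] - lo[0]) * w
    t1 = 0.5 * (hi[1] - lo[1]) * x + 0.5 * (hi[1] + lo[1])
    w1 = 0.5 * (hi[1] - lo[1]) * w
    g0, g1 = np.meshgrid(t0, t1, indexing="ij")
    S11 = corr[:2, :2]
    s12 = corr[:2, 2]
    coef = np.linalg.solve(S11, s12)
    cvar = 1.0 - s12 @ coef
    cvar = max(cvar, 1e-300)
    mu2 = coef[0] * g0 + coef[1] * g1
    inner = (
        norm.cdf((hi[2] - mu2) / np.sqrt(cvar))
        - norm.cdf((lo[2] - mu2) / np.sqrt(cvar))
    )
    det = np.linalg.det(S11)
    inv = np.linalg.inv(S11)
    quad = inv[0, 0] * g0**2 + 2 * inv[0, 1] * g0 * g1 + inv[1, 1] * g1**2
    dens = np.exp(-0.5 * quad) / (2 * np.pi * np.sqrt(det))
    return float(np.einsum("i,j,ij->", w0, w1, dens * inner))


def rectangle_prob(rect, mean, corr, method="ghk", link="probit",
                   nodes=16, u=None):
    """P(Z in rect) for Z ~ MVN(mean, corr) with corr a correlation matrix.

    method="ghk": sequential conditioning through the Cholesky factor, smooth
    in all parameters (deterministic quadrature, or Monte Carlo over ``u``).
    method="oracle": independent nested quadrature (testing; T <= 3, exact
    normal link only).
    """
    if isinstance(rect, Rectangle):
        lower, upper = rect.lower, rect.upper
    else:
        lower, upper = rect
        rect = Rectangle(lower, upper)
    mean = np.atleast_1d(np.asarray(mean, float))
    if mean.shape[0] != rect.dim:
        raise ValueError("mean dimension does not match rectangle")
    corr, L = _check_corr(corr, rect.dim)
    if method == "oracle":
        if link != "probit":
            raise ValueError("oracle uses the exact normal link")
        return oracle_rectangle_prob(rect.lower, rect.upper, mean, corr)
    if method != "ghk":
        raise ValueError(f"unknown method {method!r}")
    cdf, ppf = _get_link(link)
    return ghk_rectangle_prob(rect.lower, rect.upper, mean, L, cdf, ppf,
                              nodes=nodes, u=u)


# -- cutpoints <-> simplex -------------------------------------------------

def validate_simplex(p, tol=1e-12):
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("simplex entries must lie in (0, 1)")
    if abs(p.sum() - 1.0) > max(tol, 1e-12 * p.size):
        raise ValueError(f"simplex does not sum to 1 (sum={p.sum()!r})")
    return p


def cutpoints_to_simplex(cuts, anchor_mean=0.0, link="probit_approx"):
    """Ordinal category probabilities induced by cutpoints around an anchor.

    P_k = F(C_k - anchor) - F(C_{k-1} - anchor), with C_0 = -inf, C_K = +inf.
    """
    cuts = np.atleast_1d(np.asarray(cuts, dtype=float))
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    cdf, _ = _get_link(link)
    F = np.concatenate([[0.0], cdf(cuts - anchor_mean), [1.0]])
    return np.diff(F)


def simplex_to_cutpoints(p, anchor_mean=0.0, link="probit_approx"):
    """Inverse of :func:`cutpoints_to_simplex` (same anchor and link)."""
    p = validate_simplex(p)
    _, ppf = _get_link(link)
    return ppf(np.cumsum(p)[:-1]) + anchor_mean
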