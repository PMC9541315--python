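"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The posterior of the latent-class multivariate-probit model is a smooth
function of a few hundred unconstrained parameters, built from elementary
array operations (arithmetic, logistic links, gathers, small reductions).
This module provides exactly the primitives that model needs, as a
define-by-run tape: every operation records its parents together with a
vector-Jacobian-product closure, and :func:`grad` replays the tape
backwards.  Operations act on float64 ``ndarray`` values and support NumPy
broadcasting; gradients are reduced back to the parent's shape.

Only the gradient (not higher derivatives) is supported — that is all a
Hamiltonian Monte Carlo sampler needs.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import digamma as _digamma
from scipy.special import expit as _expit
from scipy.special import gammaln as _gammaln

_counter = itertools.count()


class Var:
    """A node in the computation graph: a value plus parent/vjp records."""

    __slots__ = ("v", "parents", "id", "g")

    def __init__(self, value, parents=()):
        self.v = np.asarray(value, dtype=np.float64)
        self.parents = parents  # tuple of (Var, vjp callable)
        self.id = next(_counter)
        self.g = None

    @property
    def shape(self):
        return self.v.shape

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __getitem__(self, idx):
        return take(self, idx)


def _val(x):
    return x.v if isinstance(x, Var) else np.asarray(x, dtype=np.float64)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (undo NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(x, y, out, dx, dy):
    parents = []
    if isinstance(x, Var):
        xs = x.v.shape
        parents.append((x, lambda g: _unbroadcast(dx(g), xs)))
    if isinstance(y, Var):
        ys = y.v.shape
        parents.append((y, lambda g: _unbroadcast(dy(g), ys)))
    return Var(out, tuple(parents))


# -- arithmetic ------------------------------------------------------------

def add(x, y):
    return _binary(x, y, _val(x) + _val(y), lambda g: g, lambda g: g)


def sub(x, y):
    return _binary(x, y, _val(x) - _val(y), lambda g: g, lambda g: -g)


def mul(x, y):
    xv, yv = _val(x), _val(y)
    return _binary(x, y, xv * yv, lambda g: g * yv, lambda g: g * xv)


def div(x, y):
    xv, yv = _val(x), _val(y)
    out = xv / yv
    # guard 0 * inf in the denominator vjp (infinite bounds carry zero grad)
    def dy(g):
        with np.errstate(invalid="ignore"):
            r = -g * out / yv
        return np.where(g == 0.0, 0.0, r)

    return _binary(x, y, out, lambda g: g / yv, dy)


def square(x):
    xv = _val(x)
    if not isinstance(x, Var):
        return Var(xv * xv)
    return Var(xv * xv, ((x, lambda g: 2.0 * g * xv),))


# -- elementary functions --------------------------------------------------

def exp(x):
    out = np.exp(_val(x))
    if not isinstance(x, Var):
        return Var(out)
    return Var(out, ((x, lambda g: g * out),))


def log(x):
    xv = _val(x)
    if not isinstance(x, Var):
        return Var(np.log(xv))
    return Var(np.log(xv), ((x, lambda g: g / xv),))


def log1p(x):
    xv = _val(x)
    if not isinstance(x, Var):
        return Var(np.log1p(xv))
    return Var(np.log1p(xv), ((x, lambda g: g / (1.0 + xv)),))


def sqrt(x):
    out = np.sqrt(_val(x))
    if not isinstance(x, Var):
        return Var(out)
    return Var(out, ((x, lambda g: 0.5 * g / out),))


def tanh(x):
    out = np.tanh(_val(x))
    if not isinstance(x, Var):
        return Var(out)
    return Var(out, ((x, lambda g: g * (1.0 - out * out)),))


def sigmoid(x):
    out = _expit(_val(x))
    if not isinstance(x, Var):
        return Var(out)
    return Var(out, ((x, lambda g: g * out * (1.0 - out)),))


def log_sigmoid(x):
    xv = _val(x)
    out = -np.logaddexp(0.0, -xv)
    if not isinstance(x, Var):
        return Var(out)
    s = _expit(-xv)
    return Var(out, ((x, lambda g: g * s),))


def gammaln(x):
    xv = _val(x)
    if not isinstance(x, Var):
        return Var(_gammaln(xv))
    d = _digamma(xv)
    return Var(_gammaln(xv), ((x, lambda g: g * d),))


def clip(x, lo, hi):
    """Clip with pass-through gradient strictly inside the bounds."""
    xv = _val(x)
    out = np.clip(xv, lo, hi)
    if not isinstance(x, Var):
        return Var(out)
    mask = ((xv > lo) & (xv < hi)).astype(np.float64)
    return Var(out, ((x, lambda g: g * mask),))


# -- shape / reduction -----------------------------------------------------

def vsum(x, axis=None, keepdims=False):
    xv = _val(x)
    out = xv.sum(axis=axis, keepdims=keepdims)
    if not isinstance(x, Var):
        return Var(out)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, xv.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, xv.shape).copy()

    return Var(out, ((x, vjp),))


def _is_basic_index(idx):
    if isinstance(idx, tuple):
        return all(isinstance(i, (int, np.integer, slice, type(Ellipsis)))
                   for i in idx)
    return isinstance(idx, (int, np.integer, slice))


def take(x, idx):
    """Basic or integer-array indexing with scatter(-add) backward."""
    xv = _val(x)
    out = xv[idx]
    if not isinstance(x, Var):
        return Var(out)

    if _is_basic_index(idx):
        # basic indexing hits unique positions: plain assignment suffices
        def vjp(g):
            acc = np.zeros_like(xv)
            acc[idx] = g
            return acc
    else:
        def vjp(g):
            acc = np.zeros_like(xv)
            np.add.at(acc, idx, g)
            return acc

    return Var(out, ((x, vjp),))


def reshape(x, shape):
    xv = _val(x)
    if not isinstance(x, Var):
        return Var(xv.reshape(shape))
    orig = xv.shape
    return Var(xv.reshape(shape), ((x, lambda g: g.reshape(orig)),))


def concat(parts, axis=0):
    vals = [_val(p) for p in parts]
    out = np.concatenate(vals, axis=axis)
    sizes = [v.shape[axis] for v in vals]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for i, p in enumerate(parts):
        if isinstance(p, Var):
            lo, hi = offsets[i], offsets[i + 1]

            def vjp(g, lo=lo, hi=hi):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                return g[tuple(sl)]

            parents.append((p, vjp))
    return Var(out, tuple(parents))


def stack(parts, axis=0):
    vals = [_val(p) for p in parts]
    out = np.stack(vals, axis=axis)
    parents = []
    for i, p in enumerate(parts):
        if isinstance(p, Var):
            parents.append((p, lambda g, i=i: np.take(g, i, axis=axis)))
    return Var(out, tuple(parents))


def cumsum(x, axis=-1):
    xv = _val(x)
    out = np.cumsum(xv, axis=axis)
    if not isinstance(x, Var):
        return Var(out)

    def vjp(g):
        return np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)

    return Var(out, ((x, vjp),))


# -- fused link primitives (hot path of the likelihood) --------------------

_PROBIT_SCALE = 1.702


def probit_approx(x):
    """Logistic approximation to the standard-normal CDF, 1/(1+e^{-1.702 x})."""
    out = _expit(_PROBIT_SCALE * _val(x))
    if not isinstance(x, Var):
        return Var(out)
    return Var(out, ((x, lambda g: g * _PROBIT_SCALE * out * (1.0 - out)),))


def probit_approx_inv(q, eps=1e-12):
    """Inverse of :func:`probit_approx`: logit(q)/1.702, with clipped input."""
    qv = np.clip(_val(q), eps, 1.0 - eps)
    out = (np.log(qv) - np.log1p(-qv)) / _PROBIT_SCALE
    if not isinstance(q, Var):
        return Var(out)
    d = 1.0 / (_PROBIT_SCALE * qv * (1.0 - qv))
    inside = ((_val(q) > eps) & (_val(q) < 1.0 - eps)).astype(np.float64)
    return Var(out, ((q, lambda g: g * d * inside),))


def probit_interval(lo, hi):
    """P(lo < X < hi) for X with CDF probit_approx; bounds may be ±inf."""
    lov, hiv = _val(lo), _val(hi)
    plo = _expit(_PROBIT_SCALE * lov)
    phi = _expit(_PROBIT_SCALE * hiv)
    out = phi - plo
    parents = []
    if isinstance(lo, Var):
        dlo = np.where(np.isfinite(lov), -_PROBIT_SCALE * plo * (1.0 - plo), 0.0)
        parents.append((lo, lambda g: _unbroadcast(g * dlo, lov.shape)))
    if isinstance(hi, Var):
        dhi = np.where(np.isfinite(hiv), _PROBIT_SCALE * phi * (1.0 - phi), 0.0)
        parents.append((hi, lambda g: _unbroadcast(g * dhi, hiv.shape)))
    return Var(out, tuple(parents))


def stick_simplex(y):
    """Stick-breaking transform of unconstrained (..., K-1) to a simplex
    (..., K), with the centring shift log(K-k-1) so y = 0 maps to the
    uniform simplex.  Fused forward/backward (hot path: cutpoint pooling).
    """
    yv = _val(y)
    K = yv.shape[-1] + 1
    adj = np.log(K - 1 - np.arange(K - 1, dtype=np.float64))
    z = _expit(yv - adj)
    rem = np.cumprod(1.0 - z, axis=-1)
    parts = np.empty(yv.shape[:-1] + (K,))
    parts[..., 0] = z[..., 0]
    if K > 2:
        parts[..., 1:K - 1] = z[..., 1:] * rem[..., :-1]
    parts[..., K - 1] = rem[..., -1]
    if not isinstance(y, Var):
        return Var(parts)

    def vjp(g):
        gp = g * parts  # (..., K)
        # suffix_j = sum_{k > j} gp_k
        total = gp.sum(axis=-1, keepdims=True)
        suffix = total - np.cumsum(gp, axis=-1)
        return gp[..., :K - 1] * (1.0 - z) - z * suffix[..., :K - 1]

    return Var(parts, ((y, vjp),))


# -- log densities ---------------------------------------------------------

def normal_lpdf(x, mu, sigma):
    """Sum of independent normal log densities (scalar result)."""
    z = div(sub(x, mu), sigma)
    elem = sub(mul(-0.5, square(z)), log(sigma))
    n = np.size(_val(z))
    return sub(vsum(elem), 0.5 * np.log(2.0 * np.pi) * n)


def dirichlet_lpdf(p, alpha):
    """Sum over rows of Dirichlet log density; p, alpha broadcastable 2-D."""
    t1 = vsum(gammaln(vsum(alpha, axis=-1)))
    t2 = vsum(gammaln(alpha))
    t3 = vsum(mul(sub(alpha, 1.0), log(p)))
    return add(sub(t1, t2), t3)


# -- driver ----------------------------------------------------------------

def grad(out: Var, wrt: Var) -> np.ndarray:
    """Gradient of scalar ``out`` with respect to ``wrt`` (reverse sweep)."""
    # collect reachable subgraph
    nodes = {}
    stack_ = [out]
    while stack_:
        n = stack_.pop()
        if n.id in nodes:
            continue
        nodes[n.id] = n
        for p, _ in n.parents:
            stack_.append(p)
    order = sorted(nodes.values(), key=lambda n: n.id, reverse=True)
    for n in order:
        n.g = None
    out.g = np.ones_like(out.v)
    for n in order:
        if n.g is None:
            continue
        for p, vjp in n.parents:
            contrib = vjp(n.g)
            if p.g is None:
                # safe without a copy: accumulation below reallocates
                p.g = contrib
            else:
                p.g = p.g + contrib
    g = wrt.g if wrt.g is not None else np.zeros_like(wrt.v)
    for n in order:
        n.g = None
    return g
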