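"""Posterior summaries: single-test, study-specific, predictive and joint
test accuracy, plus sROC region export.

Summary accuracy evaluates the links at the between-study means and global
cutpoints: Se = F'(mu1) and Sp = 1 - F'(mu0) for dichotomous tests, and at
cutpoint k of an ordinal test Se_k = 1 - F'(C_k^1 - mu1),
Sp_k = F'(C_k^0 - mu0), where F' is the approximate probit.  Predictive
("new study") accuracy re-draws study parameters from the fitted
between-study laws at every posterior draw.  Joint accuracy for a pair of
tests under believe-the-negatives (BTN) / believe-the-positives (BTP)
strategies combines the component accuracies with the global conditional
covariance on the observed scale, which is obtained from the polychoric
correlation by the bivariate-normal rectangle identity.

All tabular outputs are tidy DataFrames with posterior medians and
equal-tailed 95% intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .probit_core import approx_probit_cdf as _F
from .probit_core import approx_probit_ppf as _Finv

__all__ = [
    "summary_accuracy",
    "study_accuracy",
    "predictive_accuracy",
    "predictive_draws",
    "polychoric_to_observed_corr",
    "btn_btp_algebra",
    "joint_accuracy",
    "joint_accuracy_draws",
    "sroc_export",
]

_Q = (2.5, 50.0, 97.5)


def _summarise(rows, samples_by_key):
    out = []
    for key, meta in rows:
        x = samples_by_key[key]
        lo, med, hi = np.percentile(x, _Q)
        out.append({**meta, "estimate": med, "lower": lo, "upper": hi})
    return pd.DataFrame(out)


def _accuracy_per_draw(model, c, nu, cuts_getter):
    """Per-test (and per-cutpoint) Se/Sp for one draw given latent means
    ``nu`` (T, 2) and a cutpoint getter (t, d) -> (K-1,)."""
    vals = {}
    for t, td in enumerate(model.tests):
        if not td.is_ordinal:
            vals[(t, None, "Se")] = _F(nu[t, 1])
            vals[(t, None, "Sp")] = 1.0 - _F(nu[t, 0])
        else:
            c1 = cuts_getter(t, 1)
            c0 = cuts_getter(t, 0)
            for k in range(1, td.n_categories):
                vals[(t, k, "Se")] = 1.0 - _F(c1[k - 1] - nu[t, 1])
                vals[(t, k, "Sp")] = _F(c0[k - 1] - nu[t, 0])
    return vals


def _collect(model, fit, nu_of, cuts_of):
    keys = None
    acc = {}
    for c in fit.constrained_draws():
        vals = _accuracy_per_draw(model, c, nu_of(c), cuts_of(c))
        if keys is None:
            keys = list(vals)
            acc = {k: [] for k in keys}
        for k in keys:
            acc[k].append(vals[k])
    return {k: np.asarray(v) for k, v in acc.items()}


def _rows_from_keys(model, keys, extra=None):
    rows = []
    for (t, k, meas) in keys:
        meta = {"test": model.tests[t].name, "cutpoint": k, "measure": meas}
        if extra:
            meta.update(extra)
        rows.append(((t, k, meas), meta))
    return rows


def summary_accuracy(fit) -> pd.DataFrame:
    """Summary (population-level) Se/Sp per test and cutpoint."""
    model = fit.model
    samples = _collect(
        model, fit,
        nu_of=lambda c: c["mu"],
        cuts_of=lambda c: (lambda t, d:
                           c["global_cutpoints"][model.cutpoint_key(t, d)]),
    )
    df = _summarise(_rows_from_keys(model, samples, {"kind": "summary"}),
                    samples)
    return df


def study_accuracy(fit) -> pd.DataFrame:
    """Study-specific Se/Sp (per study, test, cutpoint)."""
    model = fit.model
    frames = []
    for s in range(model.S):
        samples = _collect(
            model, fit,
            nu_of=lambda c, s=s: c["nu"][s],
            cuts_of=lambda c, s=s: (
                lambda t, d:
                c["study_cutpoints"][model.cutpoint_key(t, d)][s]),
        )
        df = _summarise(
            _rows_from_keys(model, samples,
                            {"kind": "study", "study": model.data.study_ids[s]}),
            samples)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def predictive_draws(fit, seed):
    """Per-posterior-draw simulation of a new (S+1)-th study's Se/Sp.

    At each draw, a new study mean is taken from the bivariate-normal
    between-study law and new cutpoints from the Dirichlet pooling model;
    the returned dict maps (test, cutpoint, measure) to an array over draws.
    """
    model = fit.model
    rng = np.random.default_rng(seed)
    keys = None
    acc = {}
    for c in fit.constrained_draws():
        T = model.T
        nu_new = np.zeros((T, 2))
        for t in range(T):
            if model.perfect[t]:
                nu_new[t] = [-5.0, 5.0]
                continue
            mu, sig, rho = c["mu"][t], c["sigma"][t], c["rho"][t]
            e = rng.standard_normal(2)
            nu_new[t, 0] = mu[0] + sig[0] * e[0]
            nu_new[t, 1] = mu[1] + sig[1] * (rho * e[0]
                                             + np.sqrt(1 - rho**2) * e[1])
        cuts_new = {}
        for t in model.ordinal_idx:
            for d in (0, 1):
                key = model.cutpoint_key(t, d)
                if key in cuts_new:
                    continue
                alpha = c["kappa"][key] * c["pi"][key]
                simplex = np.clip(rng.dirichlet(alpha), 1e-12, None)
                simplex /= simplex.sum()
                cuts_new[key] = _Finv(np.cumsum(simplex)[:-1])
        vals = _accuracy_per_draw(
            model, c, nu_new,
            lambda t, d: cuts_new[model.cutpoint_key(t, d)],
        )
        if keys is None:
            keys = list(vals)
            acc = {k: [] for k in keys}
        for k in keys:
            acc[k].append(vals[k])
    return {k: np.asarray(v) for k, v in acc.items()}


def predictive_accuracy(fit, seed) -> pd.DataFrame:
    """Prediction intervals for the accuracy in a new study."""
    model = fit.model
    samples = predictive_draws(fit, seed)
    return _summarise(
        _rows_from_keys(model, samples, {"kind": "predictive"}), samples)


# =========================================================================
# Joint accuracy
# =========================================================================

def _bvn_upper_prob(a, b, eps, nodes=24):
    """P(Z1 > a, Z2 > b) for a latent pair with polychoric correlation eps
    and approximate-probit margins.

    Uses a Gaussian copula: thresholds are mapped to the exact-normal
    scale through Phi^-1(F'(.)), so both margins equal the approximate
    probit exactly and the dependence is bivariate-normal with
    correlation eps.  Vectorised over broadcastable arrays.
    """
    from numpy.polynomial.legendre import leggauss
    from scipy.stats import norm

    a, b, eps = np.broadcast_arrays(*(np.asarray(x, float)
                                      for x in (a, b, eps)))
    at = norm.ppf(np.clip(_F(a), 1e-15, 1 - 1e-15))
    bt = norm.ppf(np.clip(_F(b), 1e-15, 1 - 1e-15))
    xg_, wg_ = leggauss(nodes)
    xg, wg = 0.5 * (xg_ + 1.0), 0.5 * wg_
    Fa = norm.cdf(at)
    p1 = 1.0 - Fa
    q = Fa[..., None] + xg * p1[..., None]
    z1 = norm.ppf(np.clip(q, 1e-15, 1 - 1e-15))
    s = np.sqrt(np.clip(1.0 - eps**2, 1e-30, None))[..., None]
    arg = (bt[..., None] - eps[..., None] * z1) / s
    inner = 1.0 - norm.cdf(arg)
    return p1 * np.sum(wg * inner, axis=-1)


def polychoric_to_observed_corr(eps, a, b, nodes=24):
    """Convert a polychoric correlation to the observed-scale correlation
    and covariance of the dichotomised indicators.

    ``a`` and ``b`` are the effective thresholds (cutpoint minus latent
    mean) of the two tests.  Returns (rho, cov): the Pearson correlation
    and covariance of the two binary "positive" indicators.  Degenerate
    marginals give cov = 0 and rho = NaN (undefined).
    """
    eps = np.asarray(eps, float)
    if np.any(np.abs(eps) > 1):
        raise ValueError("|eps| must be <= 1")
    p11 = _bvn_upper_prob(a, b, np.clip(eps, -1 + 1e-12, 1 - 1e-12),
                          nodes=nodes)
    p1 = 1.0 - _F(np.asarray(a, float))
    p2 = 1.0 - _F(np.asarray(b, float))
    cov = p11 - p1 * p2
    var = p1 * (1 - p1) * p2 * (1 - p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(var > 0, cov / np.sqrt(np.where(var > 0, var, 1.0)),
                       np.nan)
    cov = np.where(var > 0, cov, 0.0)
    return rho, cov


def btn_btp_algebra(se1, se2, sp1, sp2, cov1, cov0):
    """Joint accuracy of two tests used in combination.

    BTN (believe the negatives): overall positive requires both tests
    positive, so joint Se = P(both + | diseased) = Se1*Se2 + cov1 and
    joint Sp = 1 - P(both + | healthy).  BTP (believe the positives):
    overall negative requires both negative.  cov1/cov0 are the
    conditional covariances of the positive indicators in the diseased /
    non-diseased class (zero under conditional independence).
    """
    return {
        "btn_se": se1 * se2 + cov1,
        "btn_sp": 1.0 - ((1 - sp1) * (1 - sp2) + cov0),
        "btp_se": 1.0 - ((1 - se1) * (1 - se2) + cov1),
        "btp_sp": sp1 * sp2 + cov0,
    }


def _threshold(model, c, t, k, d):
    """Effective global threshold (C_k - mu) for test t; 0 - mu if dichotomous."""
    if model.tests[t].is_ordinal:
        C = c["global_cutpoints"][model.cutpoint_key(t, d)]
        return C[k - 1] - c["mu"][t, d]
    return -c["mu"][t, d]


def joint_accuracy_draws(fit, pair, cutpoints=(None, None), zero_cov=False):
    """Per-draw joint-accuracy quantities for a pair of tests.

    Returns dict of arrays over draws: component accuracies, polychoric
    correlations, observed-scale correlations/covariances per class, and
    the BTN/BTP joint Se/Sp.
    """
    model = fit.model
    names = [td.name for td in model.tests]
    t1, t2 = (names.index(p) if isinstance(p, str) else int(p) for p in pair)
    k1, k2 = cutpoints
    out = {k: [] for k in
           ("se1", "se2", "sp1", "sp2", "eps0", "eps1", "rho0", "rho1",
            "cov0", "cov1", "btn_se", "btn_sp", "btp_se", "btp_sp")}
    for c in fit.constrained_draws():
        a1 = _threshold(model, c, t1, k1, 1)
        b1 = _threshold(model, c, t2, k2, 1)
        a0 = _threshold(model, c, t1, k1, 0)
        b0 = _threshold(model, c, t2, k2, 0)
        se1, se2 = 1.0 - _F(a1), 1.0 - _F(b1)
        sp1, sp2 = _F(a0), _F(b0)
        eps = c["psi_global"][:, max(t1, t2), min(t1, t2)]
        if zero_cov:
            cov1 = cov0 = 0.0
            rho1 = rho0 = 0.0
        else:
            rho1, cov1 = polychoric_to_observed_corr(eps[1], a1, b1)
            rho0, cov0 = polychoric_to_observed_corr(eps[0], a0, b0)
        joint = btn_btp_algebra(se1, se2, sp1, sp2, cov1, cov0)
        for k, v in (("se1", se1), ("se2", se2), ("sp1", sp1), ("sp2", sp2),
                     ("eps0", eps[0]), ("eps1", eps[1]),
                     ("rho0", rho0), ("rho1", rho1),
                     ("cov0", cov0), ("cov1", cov1), *joint.items()):
            out[k].append(float(v))
    return {k: np.asarray(v) for k, v in out.items()}


def joint_accuracy(fit, pair, cutpoints=(None, None), strategy="BTN",
                   zero_cov=False) -> pd.DataFrame:
    """Summary joint Se/Sp for a test pair under a BTN or BTP strategy."""
    strategy = strategy.upper()
    if strategy not in ("BTN", "BTP"):
        raise ValueError(f"unknown strategy {strategy!r}")
    d = joint_accuracy_draws(fit, pair, cutpoints, zero_cov=zero_cov)
    rows = []
    pref = strategy.lower()
    for meas, key in (("Se", f"{pref}_se"), ("Sp", f"{pref}_sp")):
        lo, med, hi = np.percentile(d[key], _Q)
        rows.append({
            "pair": "&".join(str(p) for p in pair),
            "cutpoints": str(cutpoints), "strategy": strategy,
            "measure": meas, "estimate": med, "lower": lo, "upper": hi,
            "median_cov0": float(np.median(d["cov0"])),
            "median_cov1": float(np.median(d["cov1"])),
            "median_rho0": float(np.median(d["rho0"])),
            "median_rho1": float(np.median(d["rho1"])),
        })
    return pd.DataFrame(rows)


# =========================================================================
# sROC export
# =========================================================================

def _ellipse(points, prob=0.95, n=100):
    """Contour of the normal-approximation ``prob`` region of a 2-D cloud."""
    from scipy.stats import chi2

    mean = points.mean(axis=0)
    cov = np.cov(points.T)
    r = np.sqrt(chi2.ppf(prob, 2))
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0, None)
    th = np.linspace(0, 2 * np.pi, n)
    circ = np.stack([np.cos(th), np.sin(th)])
    return mean + (vecs @ (r * np.sqrt(vals)[:, None] * circ)).T


def sroc_export(fit, seed=0, prob=0.95) -> pd.DataFrame:
    """Points plus posterior and prediction regions in (1-Sp, Se) space.

    Regions are normal-approximation ellipses of the draw cloud on the
    latent (probit-approx) scale, mapped back to the unit square; exported
    as plain tables for plotting.
    """
    model = fit.model
    post = _collect(
        model, fit, nu_of=lambda c: c["mu"],
        cuts_of=lambda c: (lambda t, d:
                           c["global_cutpoints"][model.cutpoint_key(t, d)]),
    )
    pred = predictive_draws(fit, seed)
    rows = []
    strata = sorted({(t, k) for (t, k, _) in post}, key=str)
    for (t, k) in strata:
        if model.perfect[t]:
            continue
        name = model.tests[t].name
        se = post[(t, k, "Se")]
        sp = post[(t, k, "Sp")]
        rows.append({"test": name, "cutpoint": k, "kind": "point", "order": 0,
                     "fpr": 1 - np.median(sp), "se": np.median(se)})
        for kind, (se_x, sp_x) in (("posterior_region", (se, sp)),
                                   ("prediction_region",
                                    (pred[(t, k, "Se")], pred[(t, k, "Sp")]))):
            z = np.stack([_Finv(np.clip(1 - sp_x, 1e-9, 1 - 1e-9)),
                          _Finv(np.clip(se_x, 1e-9, 1 - 1e-9))], axis=1)
            contour = _ellipse(z, prob)
            for i, (x, y) in enumerate(contour):
                rows.append({"test": name, "cutpoint": k, "kind": kind,
                             "order": i, "fpr": _F(x), "se": _F(y)})
    return pd.DataFrame(rows)
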