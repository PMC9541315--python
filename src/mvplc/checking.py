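"""Posterior predictive checking and LOO-based model comparison.

Posterior predictive checks replicate the observed meta-analysis from
posterior draws (latent class, then latent continuous vector, then
thresholding — the model's own generative process) and compare observed
statistics with their replicated distributions: pairwise within-study
correlations of the coded responses, and 2x2 cross-tabulations of
dichotomised test pairs.

Model comparison uses Pareto-smoothed importance-sampling leave-one-out
cross-validation (PSIS-LOO) on the per-individual pointwise
log-likelihood; LOO-IC = -2 * ELPD (deviance scale), and ELPD differences
between models carry standard errors from the pointwise differences.
"""

from __future__ import annotations

import warnings

import arviz as az
import numpy as np
import pandas as pd

from .data_io import (MetaDataset, dataset_from_patterns, dichotomize,
                      observed_pairwise_correlations)
from .model import _chol_np
from .probit_core import approx_probit_ppf

__all__ = [
    "ppc_replicate",
    "ppc_correlation_residuals",
    "ppc_table_residuals",
    "loo_compare",
    "loo_pointwise",
    "exact_refit_elpd",
]


# =========================================================================
# Posterior predictive replication
# =========================================================================

def _simulate_from_draw(model, c, rng) -> MetaDataset:
    """One replicated dataset from a single constrained posterior draw."""
    data = model.data
    S, T = model.S, model.T
    sizes = data.study_sizes
    all_codes, all_study = [], []
    for s in range(S):
        n_s = int(sizes[s])
        p = c["prevalence"][s]
        d_ind = (rng.uniform(size=n_s) < p).astype(int)
        chols = np.stack([_chol_np(c["psi_study"][s, 0]),
                          _chol_np(c["psi_study"][s, 1])])
        e = approx_probit_ppf(rng.uniform(size=(n_s, T)))
        nu = c["nu"][s]  # (T, 2)
        z = nu[np.arange(T)[None, :], d_ind[:, None]] + np.einsum(
            "ntj,nj->nt", chols[d_ind], e)
        codes = np.zeros((n_s, T), dtype=int)
        for t, td in enumerate(model.tests):
            if td.is_ordinal:
                C1 = c["study_cutpoints"][model.cutpoint_key(t, 1)][s]
                C0 = c["study_cutpoints"][model.cutpoint_key(t, 0)][s]
                C = np.where(d_ind[:, None] == 1, C1[None, :], C0[None, :])
                codes[:, t] = 1 + (z[:, t][:, None] > C).sum(axis=1)
            else:
                codes[:, t] = (z[:, t] > 0).astype(int)
        all_codes.append(codes)
        all_study.append(np.full(n_s, s))
    codes = np.concatenate(all_codes)
    study = np.concatenate(all_study)
    key = np.column_stack([study, codes])
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    return dataset_from_patterns(
        data.tests, data.study_ids, uniq[:, 0], uniq[:, 1:], counts)


def ppc_replicate(fit, data: MetaDataset, n_reps: int, seed: int):
    """``n_reps`` datasets from the posterior predictive distribution.

    Draws are taken evenly spaced through the (chain-stacked) posterior;
    each replicate has the same study sizes as the observed data.
    """
    model = fit.model
    if data is not model.data and data.n_individuals != model.data.n_individuals:
        raise ValueError("data does not match the fitted dataset")
    rng = np.random.default_rng(seed)
    cons = fit.constrained_draws()
    idx = np.linspace(0, len(cons) - 1, n_reps).astype(int)
    return [_simulate_from_draw(model, cons[i], rng) for i in idx]


def ppc_correlation_residuals(observed: MetaDataset, reps) -> pd.DataFrame:
    """Observed minus replicated within-study pairwise correlations.

    One row per (study, test pair) with the residual median, 95%
    predictive interval, a flag when the interval excludes zero, and an
    ``undefined`` flag when a test had no within-study variance.
    """
    obs_corr, obs_def = observed_pairwise_correlations(observed)
    rep_corrs = []
    rep_defs = []
    for rep in reps:
        c, dn = observed_pairwise_correlations(rep)
        rep_corrs.append(c)
        rep_defs.append(dn)
    rep_corrs = np.array(rep_corrs)  # (n_reps, S, T, T)
    rep_defs = np.array(rep_defs)
    rows = []
    T = observed.n_tests
    for s in range(observed.n_studies):
        for i in range(1, T):
            for j in range(i):
                ok = rep_defs[:, s, i, j]
                res = obs_corr[s, i, j] - rep_corrs[:, s, i, j]
                undefined = (not obs_def[s, i, j]) or ok.mean() < 0.5
                if undefined:
                    med = lo = hi = np.nan
                    flag = False
                else:
                    med, lo, hi = (np.nanmedian(res[ok]),
                                   *np.nanpercentile(res[ok], [2.5, 97.5]))
                    flag = bool(lo > 0 or hi < 0)
                rows.append({
                    "study": observed.study_ids[s],
                    "test1": observed.tests[i].name,
                    "test2": observed.tests[j].name,
                    "residual": med, "lower": lo, "upper": hi,
                    "excludes_zero": flag, "undefined": undefined,
                })
    return pd.DataFrame(rows)


def _pair_table(data: MetaDataset, t1, t2, k1, k2):
    """Per-study 2x2 counts after dichotomising the pair (cells ++, +-, -+, --)."""
    d = data
    for t, k in ((t1, k1), (t2, k2)):
        if d.tests[t].is_ordinal:
            d = dichotomize(d, t, k)
    tables = np.zeros((d.n_studies, 2, 2), dtype=int)
    y1 = d.patterns[:, t1]
    y2 = d.patterns[:, t2]
    np.add.at(tables, (d.pattern_study, 1 - y1, 1 - y2), d.pattern_counts)
    return tables  # [s, 0, 0] = both positive


def ppc_table_residuals(observed: MetaDataset, reps, pair, cutpoints=(1, 1)
                        ) -> pd.DataFrame:
    """Observed minus posterior-predictive 2x2 cell counts per study."""
    names = [t.name for t in observed.tests]
    t1, t2 = (names.index(p) if isinstance(p, str) else int(p) for p in pair)
    k1, k2 = cutpoints
    obs = _pair_table(observed, t1, t2, k1, k2)
    rep = np.array([_pair_table(r, t1, t2, k1, k2) for r in reps])
    labels = [("+", "+"), ("+", "-"), ("-", "+"), ("-", "-")]
    rows = []
    for s in range(observed.n_studies):
        for (ci, cj), lab in zip([(0, 0), (0, 1), (1, 0), (1, 1)], labels):
            res = obs[s, ci, cj] - rep[:, s, ci, cj]
            lo, med, hi = np.percentile(res, [2.5, 50, 97.5])
            rows.append({
                "study": observed.study_ids[s],
                "cell": f"{names[t1]}{lab[0]}/{names[t2]}{lab[1]}",
                "observed": int(obs[s, ci, cj]),
                "predicted_median": float(np.median(rep[:, s, ci, cj])),
                "residual": med, "lower": lo, "upper": hi,
                "excludes_zero": bool(lo > 0 or hi < 0),
            })
    return pd.DataFrame(rows)


# =========================================================================
# LOO
# =========================================================================

def loo_pointwise(fit):
    """PSIS-LOO per individual: (elpd_i array, pareto_k array)."""
    ll = fit.pointwise_loglik()  # (chains*draws, N)
    C = fit.n_chains
    ll3 = ll.reshape(C, -1, ll.shape[-1])
    idata = az.from_dict(posterior={"theta": fit.draws},
                         log_likelihood={"obs": ll3})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    return np.asarray(res.loo_i), np.asarray(res.pareto_k)


def loo_compare(fits, names=None, high_k=0.7) -> pd.DataFrame:
    """Compare fits of the same individuals by PSIS-LOO.

    Returns a table ordered best to worst with ELPD, LOO-IC (= -2 ELPD),
    the ELPD difference to the best model and its standard error computed
    from the pointwise differences.  A warning is issued if a model has a
    non-trivial fraction of Pareto-k diagnostics above ``high_k``.
    """
    if names is None:
        names = [f"model_{i+1}" for i in range(len(fits))]
    ptw, kdiag = [], []
    n_ref = None
    for fit, name in zip(fits, names):
        e_i, k = loo_pointwise(fit)
        if n_ref is None:
            n_ref = len(e_i)
        elif len(e_i) != n_ref:
            raise ValueError("fits must share the same individuals")
        frac = float(np.mean(k > high_k))
        if frac > 0.05:
            warnings.warn(
                f"{name}: {frac:.1%} of Pareto-k diagnostics exceed {high_k}; "
                "PSIS-LOO may be unreliable"
            )
        ptw.append(e_i)
        kdiag.append(k)
    elpd = np.array([e.sum() for e in ptw])
    best = int(np.argmax(elpd))
    rows = []
    for i, name in enumerate(names):
        diff_i = ptw[i] - ptw[best]
        se = float(np.sqrt(len(diff_i) * np.var(diff_i)))
        rows.append({
            "model": name,
            "elpd": float(elpd[i]),
            "loo_ic": float(-2.0 * elpd[i]),
            "elpd_diff": float(elpd[i] - elpd[best]),
            "se_diff": se,
            "n_pareto_k_high": int(np.sum(kdiag[i] > high_k)),
        })
    df = pd.DataFrame(rows).sort_values("elpd", ascending=False)
    return df.reset_index(drop=True)


def exact_refit_elpd(data: MetaDataset, spec, index: int, sampler_kwargs=None):
    """Exact leave-one-out ELPD for one individual by refitting without it.

    The fallback for observations flagged by the Pareto-k diagnostic;
    intended for small datasets (it runs a full MCMC fit).
    """
    from .inference import sample_posterior
    from .model import build_model

    study = data.response_study[index]
    pattern = data.responses[index]
    mask = ((data.pattern_study == study)
            & np.all(data.patterns == pattern, axis=1))
    (row,) = np.where(mask)[:1]
    counts = data.pattern_counts.copy()
    counts[row] -= 1
    keep = counts > 0
    reduced = dataset_from_patterns(
        data.tests, data.study_ids, data.pattern_study[keep],
        data.patterns[keep], counts[keep])
    model = build_model(reduced, spec)
    fit = sample_posterior(model, **(sampler_kwargs or {}))
    # log predictive density of the held-out individual
    from .model import individual_loglik

    vals = []
    for c in fit.constrained_draws():
        sp = model.study_params(c, int(study))
        vals.append(individual_loglik(pattern, data.tests, sp))
    m = np.max(vals)
    return float(m + np.log(np.mean(np.exp(np.array(vals) - m))))
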