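"""Synthetic meta-analysis datasets with the model's exact generative structure.

The generator draws, for each study: a prevalence from a uniform range
(prevalences are unpooled in the model), study accuracy means from the
bivariate-normal between-study law, a study correlation matrix as the
convex combination of a global matrix and a study deviation matrix, and
study ordinal cutpoints from the induced-Dirichlet pooling model.  Each
individual then gets a latent disease class and a latent continuous vector
that is thresholded to the observed categories.

Latent residuals use the same logistic-approximated-normal conditionals
as the model's likelihood, so data simulated here follow the fitted model
exactly — which is what parameter-recovery and calibration experiments
require.

Default configuration: 15 studies of 400 individuals, three tests (two
dichotomous, one 3-category ordinal), moderate between-study heterogeneity
(sigma = 0.35 on the latent scale), within-class polychoric correlations
of 0.3 between all pairs, and prevalences between 0.1 and 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_io import MetaDataset, TestDefinition, dataset_from_patterns
from .model import _chol_np, _cpc_to_chol_np
from .probit_core import approx_probit_cdf, approx_probit_ppf, simplex_to_cutpoints

__all__ = ["GeneratorConfig", "simulate_dataset", "recovery_score",
           "default_tests", "write_dataset"]


def default_tests():
    return [
        TestDefinition("ref", 2),
        TestDefinition("assay", 2),
        TestDefinition("score", 3),
    ]


def _default_mu():
    # reference-like test: Se 0.85 / Sp 0.95; assay: Se 0.80 / Sp 0.70;
    # ordinal score means chosen to give informative 3-category spread
    return np.array([
        [approx_probit_ppf(0.05), approx_probit_ppf(0.85)],
        [approx_probit_ppf(0.30), approx_probit_ppf(0.80)],
        [-0.3, 0.9],
    ])


@dataclass
class GeneratorConfig:
    """True-parameter configuration for one simulated meta-analysis."""

    S: int = 15
    N: object = 400  # individuals per study; int or (lo, hi) range
    tests: list = field(default_factory=default_tests)
    mu: np.ndarray = field(default_factory=_default_mu)  # (T, 2), d in {0,1}
    sigma: object = 0.35  # scalar or (T, 2)
    rho: object = -0.4  # scalar or (T,)
    prevalence_range: tuple = (0.1, 0.5)
    eps_within: float = 0.3  # global polychoric correlation, all pairs
    beta: object = 0.25  # scalar or (2,): study-deviation weight
    corr_deviation_z_sd: float = 0.25  # spread of study deviation matrices
    pi: dict = None  # test index -> (2, K) class simplices
    kappa: float = 50.0
    seed: int = 0

    def __post_init__(self):
        T = len(self.tests)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (T, 2):
            raise ValueError(f"mu must be (T, 2) = ({T}, 2)")
        self.sigma = np.broadcast_to(np.asarray(self.sigma, float), (T, 2)).copy()
        self.rho = np.broadcast_to(np.asarray(self.rho, float), (T,)).copy()
        if np.any(self.sigma < 0) or np.any(np.abs(self.rho) >= 1):
            raise ValueError("sigma must be >= 0 and |rho| < 1")
        self.beta = np.broadcast_to(np.asarray(self.beta, float), (2,)).copy()
        if np.any((self.beta < 0) | (self.beta > 1)):
            raise ValueError("beta must lie in [0, 1]")
        lo, hi = self.prevalence_range
        if not 0 < lo <= hi < 1:
            raise ValueError("prevalence_range must be inside (0, 1)")
        if abs(self.eps_within) >= 1:
            raise ValueError("|eps_within| must be < 1")
        if self.pi is None:
            self.pi = {}
            for t, td in enumerate(self.tests):
                if td.is_ordinal:
                    K = td.n_categories
                    lo_ = np.linspace(2.0, 1.0, K)
                    hi_ = np.linspace(1.0, 2.0, K)
                    self.pi[t] = np.stack([lo_ / lo_.sum(), hi_ / hi_.sum()])
        for t, p in self.pi.items():
            p = np.asarray(p, float)
            if p.shape != (2, self.tests[t].n_categories):
                raise ValueError(f"pi[{t}] must be (2, K_t)")
            if np.any(p <= 0) or not np.allclose(p.sum(axis=1), 1.0):
                raise ValueError(f"pi[{t}] rows must be positive simplices")
            self.pi[t] = p
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def psi_global(self):
        T = len(self.tests)
        G = np.full((T, T), self.eps_within)
        np.fill_diagonal(G, 1.0)
        np.linalg.cholesky(G)  # validity check
        return np.stack([G, G])


def _pairs_of(T):
    return [(i, j) for i in range(1, T) for j in range(i)]


def simulate_dataset(cfg: GeneratorConfig):
    """Simulate one dataset; returns (MetaDataset, truth record dict).

    One master seed expands deterministically into per-study substreams,
    so regenerating any single study reproduces the same records.
    """
    T = len(cfg.tests)
    S = cfg.S
    master = np.random.SeedSequence(cfg.seed)
    study_seeds = master.spawn(S)
    psi_G = cfg.psi_global
    npairs = len(_pairs_of(T))

    truth = {
        "mu": cfg.mu.copy(), "sigma": cfg.sigma.copy(), "rho": cfg.rho.copy(),
        "psi_global": psi_G.copy(), "beta": cfg.beta.copy(),
        "kappa": cfg.kappa, "pi": {t: p.copy() for t, p in cfg.pi.items()},
        "prevalence": np.zeros(S), "nu": np.zeros((S, T, 2)),
        "psi_study": np.zeros((S, 2, T, T)),
        "study_cutpoints": {t: np.zeros((S, 2, cfg.tests[t].n_categories - 1))
                            for t in cfg.pi},
        "global_cutpoints": {
            t: np.stack([simplex_to_cutpoints(cfg.pi[t][d]) for d in (0, 1)])
            for t in cfg.pi
        },
    }

    all_codes, all_study = [], []
    for s in range(S):
        rng = np.random.default_rng(study_seeds[s])
        p_s = rng.uniform(*cfg.prevalence_range)
        eta = rng.standard_normal((T, 2))
        nu = np.zeros((T, 2))
        nu[:, 0] = cfg.mu[:, 0] + cfg.sigma[:, 0] * eta[:, 0]
        nu[:, 1] = cfg.mu[:, 1] + cfg.sigma[:, 1] * (
            cfg.rho * eta[:, 0] + np.sqrt(1 - cfg.rho**2) * eta[:, 1]
        )
        psi_s = np.zeros((2, T, T))
        for d in (0, 1):
            zd = rng.normal(0.0, cfg.corr_deviation_z_sd, size=npairs)
            Ld = _cpc_to_chol_np(zd)
            psi_delta = Ld @ Ld.T
            psi_s[d] = (1 - cfg.beta[d]) * psi_G[d] + cfg.beta[d] * psi_delta
        cuts = {}
        for t, pi_t in cfg.pi.items():
            cs = np.zeros((2, cfg.tests[t].n_categories - 1))
            for d in (0, 1):
                simplex = rng.dirichlet(cfg.kappa * pi_t[d])
                simplex = np.clip(simplex, 1e-6, None)
                simplex /= simplex.sum()
                cs[d] = simplex_to_cutpoints(simplex)
            cuts[t] = cs
            truth["study_cutpoints"][t][s] = cs
        truth["prevalence"][s] = p_s
        truth["nu"][s] = nu
        truth["psi_study"][s] = psi_s

        if np.isscalar(cfg.N):
            n_s = int(cfg.N)
        else:
            n_s = int(rng.integers(cfg.N[0], cfg.N[1] + 1))
        d_ind = (rng.uniform(size=n_s) < p_s).astype(int)
        chols = np.stack([_chol_np(psi_s[0]), _chol_np(psi_s[1])])
        # latent residuals: iid with CDF = approximate probit, combined
        # through the Cholesky factor (the model's exact generative law)
        e = approx_probit_ppf(rng.uniform(size=(n_s, T)))
        z = nu[np.arange(T)[None, :], d_ind[:, None]] + np.einsum(
            "ntj,nj->nt", chols[d_ind], e
        )
        codes = np.zeros((n_s, T), dtype=int)
        for t, td in enumerate(cfg.tests):
            if td.is_ordinal:
                C = cuts[t][d_ind]  # (n, K-1)
                codes[:, t] = 1 + (z[:, t][:, None] > C).sum(axis=1)
            else:
                codes[:, t] = (z[:, t] > 0).astype(int)
        all_codes.append(codes)
        all_study.append(np.full(n_s, s))

    codes = np.concatenate(all_codes)
    study = np.concatenate(all_study)
    key = np.column_stack([study, codes])
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    data = dataset_from_patterns(
        cfg.tests, list(range(1, S + 1)), uniq[:, 0], uniq[:, 1:], counts
    )
    truth["summary_se"], truth["summary_sp"] = _implied_summary(cfg)
    return data, truth


def _implied_summary(cfg):
    """Summary Se/Sp (per test; first-cutpoint stratum for ordinal tests)
    implied by the true between-study means and population cutpoints."""
    T = len(cfg.tests)
    se = np.zeros(T)
    sp = np.zeros(T)
    for t, td in enumerate(cfg.tests):
        if td.is_ordinal:
            c1 = simplex_to_cutpoints(cfg.pi[t][1])
            c0 = simplex_to_cutpoints(cfg.pi[t][0])
            se[t] = 1 - approx_probit_cdf(c1[0] - cfg.mu[t, 1])
            sp[t] = approx_probit_cdf(c0[0] - cfg.mu[t, 0])
        else:
            se[t] = approx_probit_cdf(cfg.mu[t, 1])
            sp[t] = 1 - approx_probit_cdf(cfg.mu[t, 0])
    return se, sp


def write_dataset(data: MetaDataset, truth, csv_path, truth_path=None):
    """Write the long-format counts CSV (loader-compatible) and truth JSON."""
    data.to_long_counts().to_csv(csv_path, index=False)
    if truth_path is not None:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return {str(k): conv(v) for k, v in o.items()}
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            return o
        with open(truth_path, "w") as fh:
            json.dump({k: conv(v) for k, v in truth.items()}, fh, indent=1)


# =========================================================================
# Recovery scoring
# =========================================================================

def recovery_score(truth, fit, first_cut_only=True):
    """Coverage / error table: posterior medians and 95% intervals of the
    shared parameters against the generator's truth record.

    Scores mu, sigma, prevalence, the global within-class (polychoric)
    correlations, and the summary Se/Sp per test.  Returns a pandas
    DataFrame with columns (block, parameter, truth, median, lo, hi, bias,
    covered); scoring is invariant to row order.
    """
    import pandas as pd

    from .summaries import summary_accuracy

    model = fit.model
    rows = []

    def score(block, name, samples, true_val):
        med = float(np.median(samples))
        lo, hi = np.percentile(samples, [2.5, 97.5])
        rows.append({
            "block": block, "parameter": name, "truth": float(true_val),
            "median": med, "lo": float(lo), "hi": float(hi),
            "bias": med - float(true_val),
            "covered": bool(lo <= true_val <= hi),
        })

    for i, t in enumerate(model.imperfect_idx):
        for d in (0, 1):
            score("mu", f"mu[{t},{d}]",
                  fit.stacked(lambda c, t=t, d=d: c["mu"][t, d]),
                  truth["mu"][t, d])
            score("sigma", f"sigma[{t},{d}]",
                  fit.stacked(lambda c, t=t, d=d: c["sigma"][t, d]),
                  truth["sigma"][t, d])
    for s in range(model.S):
        score("prevalence", f"p[{s}]",
              fit.stacked(lambda c, s=s: c["prevalence"][s]),
              truth["prevalence"][s])
    for (i, j) in model.free_pairs:
        for d in (0, 1):
            score("eps_global", f"epsG[{i},{j},{d}]",
                  fit.stacked(lambda c, i=i, j=j, d=d: c["psi_global"][d, i, j]),
                  truth["psi_global"][d, i, j])
    acc = summary_accuracy(fit)
    for t, td in enumerate(model.tests):
        if model.perfect[t]:
            continue
        sub = acc[(acc.test == td.name)
                  & ((acc.cutpoint == 1) | acc.cutpoint.isna())]
        for _, r in sub.iterrows():
            key = "summary_se" if r.measure == "Se" else "summary_sp"
            rows.append({
                "block": "summary_" + r.measure.lower(),
                "parameter": f"{r.measure}[{td.name}]",
                "truth": float(truth[key][t]),
                "median": r.estimate, "lo": r.lower, "hi": r.upper,
                "bias": r.estimate - float(truth[key][t]),
                "covered": bool(r.lower <= truth[key][t] <= r.upper),
            })
    return pd.DataFrame(rows)
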