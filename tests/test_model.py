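"""Prior reconstruction, model restrictions, and likelihood consistency."""

import numpy as np
import pytest

from mvplc.data_io import TestDefinition, dataset_from_patterns
from mvplc.model import (Model, ModelSpec, accuracy_interval_to_normal,
                         build_model, default_priors, individual_loglik,
                         sd_interval_to_truncnormal)
from mvplc.probit_core import approx_probit_cdf
from mvplc.synthetic_data import GeneratorConfig, simulate_dataset
from mvplc import autodiff as ad

from conftest import dvt_tests


class TestPriorReconstruction:
    @pytest.mark.parametrize("interval", [(0.49, 0.94), (0.82, 0.99),
                                          (0.04, 0.96)])
    def test_accuracy_interval_round_trip(self, interval):
        # the normal prior on the latent scale must push forward to the
        # printed 95% accuracy interval (well within 0.01)
        m, s = accuracy_interval_to_normal(*interval)
        lo = approx_probit_cdf(m - 1.959964 * s)
        hi = approx_probit_cdf(m + 1.959964 * s)
        assert lo == pytest.approx(interval[0], abs=0.01)
        assert hi == pytest.approx(interval[1], abs=0.01)

    def test_sd_interval_round_trip(self):
        from scipy.stats import truncnorm

        m, s = sd_interval_to_truncnormal(0.02, 1.09)
        a = -m / s
        q = truncnorm.ppf([0.025, 0.975], a, np.inf, loc=m, scale=s)
        assert q[0] == pytest.approx(0.02, abs=1e-4)
        assert q[1] == pytest.approx(1.09, abs=1e-4)

    def test_default_priors_apply_overrides(self):
        spec = ModelSpec(priors={"tests": {
            "ultrasound": {"se_interval": [0.49, 0.94],
                           "sp_interval": [0.82, 0.99]},
            "wells": {"mu_mean": 0.0, "mu_sd": 1.0},
        }})
        pr = default_priors(spec, dvt_tests())
        # informative ultrasound Se prior: latent interval mid above zero
        se = approx_probit_cdf(pr.mu_mean[0, 1]
                               + np.array([-1.96, 1.96]) * pr.mu_sd[0, 1])
        assert se == pytest.approx([0.49, 0.94], abs=0.01)
        sp = 1 - approx_probit_cdf(pr.mu_mean[0, 0]
                                   + np.array([1.96, -1.96]) * pr.mu_sd[0, 0])
        assert sp == pytest.approx([0.82, 0.99], abs=0.01)
        assert pr.mu_sd[2, 0] == pytest.approx(1.0)
        # correlation priors from the printed intervals
        assert np.tanh(1.959964 * pr.rho_z_sd) == pytest.approx(0.82, abs=1e-6)
        assert np.tanh(1.959964 * pr.corr_z_sd) == pytest.approx(0.65, abs=1e-6)

    def test_infeasible_interval_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            accuracy_interval_to_normal(0.9, 0.4)

    def test_kappa_prior_allows_asymmetric_dirichlet(self):
        # under kappa ~ half-N(0, 50) with a uniform population simplex,
        # the implied Dirichlet parameter vector is frequently far from
        # symmetric (small concentrations allowed)
        rng = np.random.default_rng(0)
        kappa = np.abs(rng.normal(0, 50, size=4000))
        pi = rng.dirichlet(np.ones(3), size=4000)
        alpha = kappa[:, None] * pi
        frac_sparse = np.mean(np.any(alpha < 1.0, axis=1))
        assert frac_sparse > 0.25


def _small_data(seed=3, dep_eps=0.0):
    cfg = GeneratorConfig(S=4, N=60, eps_within=dep_eps, seed=seed)
    return simulate_dataset(cfg)[0]


class TestModelStructure:
    def test_ci_has_no_correlation_parameters(self):
        m = build_model(_small_data(), ModelSpec(dependence="none"))
        assert "zG" not in m.blocks

    def test_full_dependence_parameter_counts(self):
        m = build_model(_small_data(), ModelSpec(dependence="all"))
        # two global matrices with T(T-1)/2 = 3 free entries each,
        # plus per-study deviations and a mixing weight per class
        assert m.blocks["zG"][1] == (2, 3)
        assert m.blocks["zD"][1] == (2, m.S, 3)
        assert m.blocks["logit_beta"][1] == (2,)

    def test_single_pair_dependence(self):
        m = build_model(_small_data(),
                        ModelSpec(dependence=[["assay", "score"]]))
        assert m.free_pairs == [(2, 1)]
        assert m.blocks["zG"][1] == (2, 1)

    def test_overlapping_pairs_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            build_model(_small_data(), ModelSpec(
                dependence=[["ref", "assay"], ["assay", "score"]]))

    def test_meta_regression_hook_rejected(self):
        with pytest.raises(NotImplementedError, match="meta-regression"):
            build_model(_small_data(), ModelSpec(meta_regression={"x": [1]}))

    def test_perfect_gs_must_be_dichotomous(self):
        with pytest.raises(ValueError, match="dichotomous"):
            build_model(_small_data(), ModelSpec(perfect_gs=["score"]))

    def test_spec_from_yaml(self):
        spec = ModelSpec.from_yaml(
            "dependence: all\nperfect_gs: [ref]\nghk_nodes: 4\n")
        assert spec.dependence == "all"
        assert spec.perfect_gs == ["ref"]
        assert spec.ghk_nodes == 4

    def test_shared_cutpoints_switch(self):
        # class-specific cutpoints by default; one shared block when the
        # switch is on, with correct gradients either way
        m = build_model(_small_data(), ModelSpec(dependence="none",
                                                 share_cutpoints=True))
        assert m.cutpoint_key(2, 0) == m.cutpoint_key(2, 1) == (2, "shared")
        assert "P_stick_2_shared" in m.blocks
        assert "P_stick_2_0" not in m.blocks
        rng = np.random.default_rng(1)
        th = m.init_theta(rng)
        lp, g = m.logp_and_grad(th)
        assert np.isfinite(lp) and np.all(np.isfinite(g))
        i = m.blocks["P_stick_2_shared"][0].start
        e = 1e-5
        tp, tm = th.copy(), th.copy()
        tp[i] += e
        tm[i] -= e
        assert g[i] == pytest.approx((m.logp(tp) - m.logp(tm)) / (2 * e),
                                     abs=1e-5)
        md = build_model(_small_data(), ModelSpec(dependence="none"))
        assert md.cutpoint_key(2, 0) != md.cutpoint_key(2, 1)

    def test_anchor_initialised_with_se_plus_sp_above_one(self):
        m = build_model(_small_data(), ModelSpec(dependence="none"))
        rng = np.random.default_rng(0)
        for _ in range(10):
            c = m.constrain(m.init_theta(rng))
            t = m.anchor
            se = approx_probit_cdf(c["mu"][t, 1])
            sp = 1 - approx_probit_cdf(c["mu"][t, 0])
            assert se + sp > 1.0


class TestIndividualLoglik:
    def test_indistinguishable_classes_give_log_half(self):
        from mvplc.model import StudyParams

        tests = [TestDefinition("a", 2)]
        params = StudyParams(prevalence=0.5, nu=np.zeros((1, 2)),
                             psi=np.tile(np.eye(1), (2, 1, 1)), cutpoints={})
        for y in ([0], [1]):
            assert individual_loglik(y, tests, params) == pytest.approx(
                np.log(0.5), abs=1e-10)

    def test_perfect_gs_probabilities(self):
        from mvplc.model import StudyParams

        tests = [TestDefinition("gs", 2)]
        nu = np.array([[-5.0, 5.0]])
        params = StudyParams(prevalence=0.3, nu=nu,
                             psi=np.tile(np.eye(1), (2, 1, 1)), cutpoints={})
        # P(positive | diseased) ~ 1, P(positive | healthy) ~ 0
        ll_pos = individual_loglik([1], tests, params)
        assert np.exp(ll_pos) == pytest.approx(0.3, abs=1e-3)
        ll_neg = individual_loglik([0], tests, params)
        assert np.exp(ll_neg) == pytest.approx(0.7, abs=1e-3)

    def test_ci_mixture_matches_brute_force(self):
        from mvplc.model import StudyParams

        tests = [TestDefinition("a", 2), TestDefinition("b", 2)]
        rng = np.random.default_rng(1)
        nu = rng.normal(size=(2, 2))
        p = 0.35
        params = StudyParams(prevalence=p, nu=nu,
                             psi=np.tile(np.eye(2), (2, 1, 1)), cutpoints={})
        F = approx_probit_cdf
        total = 0.0
        for ya in (0, 1):
            for yb in (0, 1):
                brute = 0.0
                for d, w in ((1, p), (0, 1 - p)):
                    pa = F(nu[0, d]) if ya else 1 - F(nu[0, d])
                    pb = F(nu[1, d]) if yb else 1 - F(nu[1, d])
                    brute += w * pa * pb
                got = np.exp(individual_loglik([ya, yb], tests, params))
                assert got == pytest.approx(brute, abs=1e-9)
                total += got
        assert total == pytest.approx(1.0, abs=1e-9)


class TestLikelihoodConsistency:
    @pytest.mark.parametrize("dep", ["none", "pairs", "all"])
    def test_gradient_matches_finite_differences(self, dep):
        data = _small_data(dep_eps=0.3)
        dd = [["assay", "score"]] if dep == "pairs" else dep
        m = build_model(data, ModelSpec(dependence=dd, ghk_nodes=6))
        rng = np.random.default_rng(0)
        th = m.init_theta(rng)
        lp, g = m.logp_and_grad(th)
        assert np.isfinite(lp) and np.all(np.isfinite(g))
        for i in rng.choice(m.dim, size=10, replace=False):
            e = 1e-5
            tp, tm = th.copy(), th.copy()
            tp[i] += e
            tm[i] -= e
            num = (m.logp(tp) - m.logp(tm)) / (2 * e)
            assert g[i] == pytest.approx(num, abs=1e-4, rel=1e-4)

    def test_pattern_probabilities_sum_to_one(self):
        # the class-conditional pattern probabilities over the complete
        # response space must conserve total probability
        cfg = GeneratorConfig(S=2, N=4000, eps_within=0.4, seed=9)
        data, _ = simulate_dataset(cfg)
        m = build_model(data, ModelSpec(dependence="all", ghk_nodes=8))
        c = m.constrain(m.init_theta(np.random.default_rng(4)))
        probs = m.pattern_probs(c)
        for s in range(m.S):
            mask = m.rows_study == s
            if np.sum(m.data.pattern_counts[mask]) < 3000:
                continue  # not every pattern realised in this study
            for d in (0, 1):
                assert probs[mask, d].sum() == pytest.approx(1.0, abs=2e-3)

    def test_fused_ghk_matches_tape_ghk(self):
        # the hand-derived reverse sweep against the elementary tape
        data = _small_data(dep_eps=0.4)
        m = build_model(data, ModelSpec(dependence="all", ghk_nodes=6))
        rng = np.random.default_rng(8)
        R = 30
        lows, highs, means, L = [], [], [], {}
        for t in range(m.T):
            lo = rng.normal(size=R) - 1.5
            hi = lo + rng.uniform(0.5, 3, R)
            lo[rng.uniform(size=R) < 0.3] = -np.inf
            hi[rng.uniform(size=R) < 0.3] = np.inf
            lows.append(ad.Var(lo))
            highs.append(ad.Var(hi))
            means.append(ad.Var(rng.normal(size=R)))
        z = np.tanh(rng.normal(size=(R, 3)) * 0.5)
        L[(0, 0)] = np.ones(R)
        L[(1, 0)] = ad.Var(z[:, 0])
        L[(1, 1)] = ad.Var(np.sqrt(1 - z[:, 0] ** 2))
        L[(2, 0)] = ad.Var(z[:, 1])
        L[(2, 1)] = ad.Var(z[:, 2] * 0.5)
        L[(2, 2)] = ad.Var(np.sqrt(1 - z[:, 1] ** 2 - (z[:, 2] * 0.5) ** 2))
        w = rng.normal(size=R)

        def run(method):
            lows2 = [ad.Var(x.v) for x in lows]
            highs2 = [ad.Var(x.v) for x in highs]
            means2 = [ad.Var(x.v) for x in means]
            L2 = {k: (ad.Var(v.v) if isinstance(v, ad.Var) else v)
                  for k, v in L.items()}
            P = method(lows2, highs2, means2, L2, R)
            out = ad.vsum(ad.mul(P, w))
            grads = [ad.grad(out, v) for v in means2]
            return P.v, np.array([g for g in grads])

        p1, g1 = run(lambda *a: m._ghk_fused(*a))
        p2, g2 = run(lambda lo, hi, mn, LL, R: m._ghk_rows(lo, hi, mn, LL,
                                                           n_rows=R))
        assert np.allclose(p1, p2, atol=1e-12)
        assert np.allclose(g1, g2, atol=1e-9)

    def test_correlation_pooling_stays_valid(self):
        # convex combination of correlation matrices with beta in [0,1]
        # must remain a valid correlation matrix on every draw
        data = _small_data(dep_eps=0.3)
        m = build_model(data, ModelSpec(dependence="all"))
        rng = np.random.default_rng(12)
        for _ in range(50):
            c = m.constrain(rng.normal(size=m.dim))
            psi = c["psi_study"]
            assert np.allclose(np.diagonal(psi, axis1=-2, axis2=-1), 1.0)
            assert np.all(np.linalg.eigvalsh(psi) > -1e-10)
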