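"""Accuracy summaries, joint-testing algebra, polychoric conversion and
sROC export, checked against closed forms on crafted posterior draws."""

import numpy as np
import pytest

from mvplc.model import ModelSpec, build_model
from mvplc.probit_core import (approx_probit_cdf, approx_probit_ppf,
                               simplex_to_cutpoints)
from mvplc.summaries import (btn_btp_algebra, joint_accuracy,
                             joint_accuracy_draws,
                             polychoric_to_observed_corr, predictive_accuracy,
                             sroc_export, study_accuracy, summary_accuracy)
from mvplc.synthetic_data import GeneratorConfig, simulate_dataset

from conftest import make_fit


def _model(eps=0.3, seed=21, dep="all"):
    cfg = GeneratorConfig(S=3, N=50, eps_within=eps, seed=seed)
    data, _ = simulate_dataset(cfg)
    return build_model(data, ModelSpec(dependence=dep, ghk_nodes=6))


def _crafted_draw(model, rng, sigma=0.3, eps=0.25, kappa=60.0):
    """A valid constrained-parameter dict with known values."""
    S, T = model.S, model.T
    mu = np.array([[-1.2, 1.0], [-0.6, 0.8], [-0.3, 0.9]])
    mu += 0.05 * rng.standard_normal((T, 2))
    c = {
        "mu": mu,
        "sigma": np.full((T, 2), sigma),
        "rho": np.full(T, -0.3),
        "nu": mu[None, :, :] + sigma * rng.standard_normal((S, T, 2)),
        "beta": np.array([0.2, 0.2]),
        "prevalence": rng.uniform(0.2, 0.4, S),
    }
    G = np.full((T, T), eps)
    np.fill_diagonal(G, 1.0)
    c["psi_global"] = np.stack([G, G])
    c["psi_study"] = np.tile(G, (S, 2, 1, 1))
    c["pi"], c["kappa"] = {}, {}
    c["study_simplex"], c["study_cutpoints"], c["global_cutpoints"] = {}, {}, {}
    for t in model.ordinal_idx:
        K = model.tests[t].n_categories
        for d in (0, 1):
            key = model.cutpoint_key(t, d)
            pi = rng.dirichlet(np.full(K, 8.0))
            Ps = rng.dirichlet(kappa * pi, size=S)
            Ps = np.clip(Ps, 1e-6, None)
            Ps /= Ps.sum(axis=1, keepdims=True)
            c["pi"][key] = pi
            c["kappa"][key] = kappa
            c["study_simplex"][key] = Ps
            c["study_cutpoints"][key] = approx_probit_ppf(
                np.cumsum(Ps, axis=1)[:, :-1])
            c["global_cutpoints"][key] = simplex_to_cutpoints(pi)
    return c


@pytest.fixture(scope="module")
def crafted_fit():
    model = _model()
    rng = np.random.default_rng(99)
    return make_fit(model, [_crafted_draw(model, rng) for _ in range(80)])


class TestSummaryAccuracy:
    def test_matches_link_closed_form(self, crafted_fit):
        model = crafted_fit.model
        df = summary_accuracy(crafted_fit)
        mus = np.array([c["mu"] for c in crafted_fit.constrained_draws()])
        se_expect = np.median(approx_probit_cdf(mus[:, 0, 1]))
        row = df[(df.test == "ref") & (df.measure == "Se")]
        assert row.estimate.iloc[0] == pytest.approx(se_expect, abs=1e-12)
        sp_expect = np.median(1 - approx_probit_cdf(mus[:, 0, 0]))
        row = df[(df.test == "ref") & (df.measure == "Sp")]
        assert row.estimate.iloc[0] == pytest.approx(sp_expect, abs=1e-12)

    def test_threshold_at_mean_gives_half(self):
        # mu1 = 0 with a global cutpoint at 0 pins summary Se at 0.5
        model = _model()
        rng = np.random.default_rng(3)
        c = _crafted_draw(model, rng)
        c["mu"][2, 1] = 0.0
        key = model.cutpoint_key(2, 1)
        c["global_cutpoints"][key] = np.array([0.0, 0.8])
        fit = make_fit(model, [c] * 4)
        df = summary_accuracy(fit)
        row = df[(df.test == "score") & (df.cutpoint == 1)
                 & (df.measure == "Se")]
        assert row.estimate.iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_ordinal_se_monotone_in_cutpoint(self, crafted_fit):
        df = summary_accuracy(crafted_fit)
        sub = df[(df.test == "score") & (df.measure == "Se")]
        se = sub.sort_values("cutpoint").estimate.to_numpy()
        assert np.all(np.diff(se) <= 0)
        sub = df[(df.test == "score") & (df.measure == "Sp")]
        sp = sub.sort_values("cutpoint").estimate.to_numpy()
        assert np.all(np.diff(sp) >= 0)

    def test_perfect_gs_summary_near_one(self):
        cfg = GeneratorConfig(S=3, N=60, seed=4)
        data, _ = simulate_dataset(cfg)
        model = build_model(data, ModelSpec(perfect_gs=["ref"]))
        rng = np.random.default_rng(1)
        c = _crafted_draw(model, rng)
        c["mu"][0] = [-5.0, 5.0]
        fit = make_fit(model, [c] * 4)
        df = summary_accuracy(fit)
        assert df[(df.test == "ref") & (df.measure == "Se")
                  ].estimate.iloc[0] > 0.999

    def test_study_accuracy_covers_all_studies(self, crafted_fit):
        df = study_accuracy(crafted_fit)
        assert set(df.study) == set(crafted_fit.model.data.study_ids)


class TestPredictiveAccuracy:
    def test_no_heterogeneity_limit_collapses_to_summary(self):
        # sigma -> 0 and kappa -> inf: the predictive distribution is the
        # summary distribution
        model = _model()
        rng = np.random.default_rng(11)
        draws = [_crafted_draw(model, rng, sigma=0.0, kappa=1e7)
                 for _ in range(60)]
        fit = make_fit(model, draws)
        summ = summary_accuracy(fit).set_index(["test", "cutpoint", "measure"])
        pred = predictive_accuracy(fit, seed=1).set_index(
            ["test", "cutpoint", "measure"])
        for idx in summ.index:
            assert pred.loc[idx, "estimate"] == pytest.approx(
                summ.loc[idx, "estimate"], abs=2e-3)
            width_s = summ.loc[idx, "upper"] - summ.loc[idx, "lower"]
            width_p = pred.loc[idx, "upper"] - pred.loc[idx, "lower"]
            assert width_p == pytest.approx(width_s, abs=5e-3)

    def test_heterogeneity_widens_prediction_interval(self):
        model = _model()
        rng = np.random.default_rng(12)
        base = _crafted_draw(model, rng, sigma=0.8)
        fit = make_fit(model, [base] * 200)  # zero posterior uncertainty
        summ = summary_accuracy(fit)
        pred = predictive_accuracy(fit, seed=2)
        for (_, s), (_, p) in zip(summ.iterrows(), pred.iterrows()):
            assert (p.upper - p.lower) > (s.upper - s.lower) + 0.01


class TestPolychoricConversion:
    def test_independence(self):
        rho, cov = polychoric_to_observed_corr(0.0, 0.3, -0.5)
        assert rho == pytest.approx(0.0, abs=1e-12)
        assert cov == pytest.approx(0.0, abs=1e-12)

    def test_comonotone_equal_thresholds(self):
        rho, cov = polychoric_to_observed_corr(1.0, 0.4, 0.4)
        assert rho == pytest.approx(1.0, abs=1e-6)

    def test_orthant_closed_form(self):
        # eps = 0.5 at zero thresholds: P11 = 1/4 + arcsin(0.5)/(2 pi) = 1/3
        # (exact for the normal; the logistic link deviates by < 5e-3)
        rho, cov = polychoric_to_observed_corr(0.5, 0.0, 0.0)
        assert cov + 0.25 == pytest.approx(1 / 3, abs=5e-3)
        assert rho == pytest.approx(cov / 0.25, abs=1e-12)

    def test_degenerate_marginal(self):
        rho, cov = polychoric_to_observed_corr(0.5, 50.0, 0.0)
        assert np.isnan(rho)
        assert cov == 0.0

    def test_cov_respects_frechet_bounds(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            eps = rng.uniform(-0.95, 0.95)
            a, b = rng.uniform(-2, 2, 2)
            _, cov = polychoric_to_observed_corr(eps, a, b)
            p1 = 1 - approx_probit_cdf(a)
            p2 = 1 - approx_probit_cdf(b)
            lo = max(-p1 * p2, -(1 - p1) * (1 - p2)) - 1e-5
            hi = min(p1 * (1 - p2), p2 * (1 - p1)) + 1e-5
            assert lo <= cov <= hi


class TestJointAccuracy:
    @pytest.mark.parametrize("se,sp,expect", [
        (0.9, None, {"btn_se": 0.81, "btp_se": 0.99}),
        (None, 0.8, {"btn_sp": 0.96, "btp_sp": 0.64}),
    ])
    def test_independence_algebra(self, se, sp, expect):
        se = se or 0.5
        sp = sp or 0.5
        out = btn_btp_algebra(se, se, sp, sp, 0.0, 0.0)
        for k, v in expect.items():
            assert out[k] == pytest.approx(v, abs=1e-12)

    def test_zero_cov_equals_ci_algebra_exactly(self, crafted_fit):
        d = joint_accuracy_draws(crafted_fit, ("ref", "assay"),
                                 zero_cov=True)
        np.testing.assert_allclose(d["btn_se"], d["se1"] * d["se2"],
                                   atol=1e-15)
        np.testing.assert_allclose(
            d["btn_sp"], 1 - (1 - d["sp1"]) * (1 - d["sp2"]), atol=1e-15)
        np.testing.assert_allclose(
            d["btp_se"], 1 - (1 - d["se1"]) * (1 - d["se2"]), atol=1e-15)
        np.testing.assert_allclose(d["btp_sp"], d["sp1"] * d["sp2"],
                                   atol=1e-15)

    def test_symmetric_in_test_order_for_dichotomous_pair(self, crafted_fit):
        d1 = joint_accuracy_draws(crafted_fit, ("ref", "assay"))
        d2 = joint_accuracy_draws(crafted_fit, ("assay", "ref"))
        np.testing.assert_allclose(d1["btn_se"], d2["btn_se"], atol=1e-4)
        np.testing.assert_allclose(d1["btp_sp"], d2["btp_sp"], atol=1e-4)

    def test_positive_dependence_raises_btn_se(self, crafted_fit):
        # with positive conditional dependence, requiring both tests
        # positive loses less sensitivity than independence predicts
        d = joint_accuracy_draws(crafted_fit, ("ref", "assay"))
        assert np.median(d["cov1"]) > 0
        assert np.median(d["btn_se"]) > np.median(d["se1"] * d["se2"])

    def test_table_output(self, crafted_fit):
        df = joint_accuracy(crafted_fit, ("assay", "score"),
                            cutpoints=(None, 1), strategy="BTP")
        assert set(df.measure) == {"Se", "Sp"}
        assert ((df.lower <= df.estimate) & (df.estimate <= df.upper)).all()
        with pytest.raises(ValueError, match="unknown strategy"):
            joint_accuracy(crafted_fit, ("ref", "assay"), strategy="BOTH")


class TestSrocExport:
    def test_regions_contain_median_point(self, crafted_fit):
        df = sroc_export(crafted_fit, seed=0)
        for (test, k), grp in df.groupby(["test", "cutpoint"], dropna=False):
            pt = grp[grp.kind == "point"]
            for kind in ("posterior_region", "prediction_region"):
                reg = grp[grp.kind == kind]
                assert reg.fpr.min() <= pt.fpr.iloc[0] <= reg.fpr.max()
                assert reg.se.min() <= pt.se.iloc[0] <= reg.se.max()

    def test_prediction_region_mass_calibration(self):
        # with the posterior concentrated at the truth, the 95% prediction
        # region is the between-study law's own 95% ellipse: at least 94%
        # of freshly simulated study accuracies must fall inside it
        from scipy.stats import chi2

        from mvplc.summaries import predictive_draws

        model = _model()
        rng = np.random.default_rng(44)
        base = _crafted_draw(model, rng, sigma=0.4)
        fit = make_fit(model, [base] * 1500)
        pred = predictive_draws(fit, seed=9)
        t = 0  # dichotomous reference-like test: probit coords are nu
        cloud = np.stack([approx_probit_ppf(1 - pred[(t, None, "Sp")]),
                          approx_probit_ppf(pred[(t, None, "Se")])], axis=1)
        mean = cloud.mean(axis=0)
        cov = np.cov(cloud.T)
        r2 = chi2.ppf(0.95, 2)
        # held-out new-study draws from the generating law itself
        mu, sig, rho = base["mu"][t], base["sigma"][t], base["rho"][t]
        e = rng.standard_normal((4000, 2))
        nu0 = mu[0] + sig[0] * e[:, 0]
        nu1 = mu[1] + sig[1] * (rho * e[:, 0]
                                + np.sqrt(1 - rho**2) * e[:, 1])
        pts = np.stack([nu0, nu1], axis=1)
        d = pts - mean
        m2 = np.einsum("ni,ij,nj->n", d, np.linalg.inv(cov), d)
        assert (m2 <= r2).mean() >= 0.94

    def test_zero_heterogeneity_regions_coincide(self):
        model = _model()
        rng = np.random.default_rng(15)
        draws = [_crafted_draw(model, rng, sigma=0.0, kappa=1e7)
                 for _ in range(60)]
        fit = make_fit(model, draws)
        df = sroc_export(fit, seed=3)
        for (test, k), grp in df.groupby(["test", "cutpoint"], dropna=False):
            post = grp[grp.kind == "posterior_region"]
            pred = grp[grp.kind == "prediction_region"]
            assert abs(post.se.max() - pred.se.max()) < 0.03
            assert abs(post.fpr.max() - pred.fpr.max()) < 0.03
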