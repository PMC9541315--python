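"""Posterior predictive replication and PSIS-LOO comparison."""

import numpy as np
import pytest

from mvplc.checking import (loo_compare, loo_pointwise,
                            ppc_correlation_residuals, ppc_replicate,
                            ppc_table_residuals)
from mvplc.data_io import observed_pairwise_correlations


class TestPpcReplicate:
    def test_replicates_have_observed_dimensions(self, small_ci_fit):
        fit, _ = small_ci_fit
        data = fit.model.data
        reps = ppc_replicate(fit, data, n_reps=7, seed=1)
        assert len(reps) == 7
        for r in reps:
            assert r.n_studies == data.n_studies
            assert np.array_equal(r.study_sizes, data.study_sizes)

    def test_fixed_seed_reproduces(self, small_ci_fit):
        fit, _ = small_ci_fit
        data = fit.model.data
        a = ppc_replicate(fit, data, n_reps=3, seed=9)
        b = ppc_replicate(fit, data, n_reps=3, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.patterns, y.patterns)
            assert np.array_equal(x.pattern_counts, y.pattern_counts)

    def test_marginal_positivity_within_binomial_error(self, toy_perfect_fit):
        # perfect-GS toy: replicated positivity rate per study should sit
        # near the observed rate (binomial oracle)
        fit = toy_perfect_fit
        data = fit.model.data
        reps = ppc_replicate(fit, data, n_reps=200, seed=3)
        for s, obs_rate in [(0, 0.30), (1, 0.60)]:
            rates = [r.study_responses(s).mean() for r in reps]
            n = data.study_sizes[s]
            # posterior predictive spread ~ sqrt(2 p q / n)
            assert np.mean(rates) == pytest.approx(obs_rate, abs=0.03)
            assert np.std(rates) < 3 * np.sqrt(2 * obs_rate
                                               * (1 - obs_rate) / n)


class TestCorrelationResiduals:
    def test_self_fit_calibration(self, small_ci_fit):
        # data generated from (nearly) the fitted model: ~5% of intervals
        # should exclude zero; allow generous MC slack at this size
        fit, _ = small_ci_fit
        data = fit.model.data
        reps = ppc_replicate(fit, data, n_reps=150, seed=2)
        df = ppc_correlation_residuals(data, reps)
        ok = df[~df.undefined]
        assert len(ok) > 0
        assert ok.excludes_zero.mean() <= 0.25

    def test_ci_fit_to_dependent_data_flags_pair(self, dependent_misfit):
        df = dependent_misfit["corr_residuals"]
        pair = df[(df.test1 == "a") & (df.test2 == "b")
                  | (df.test1 == "b") & (df.test2 == "a")]
        # the conditional dependence the CI model ignores shows up as
        # systematically positive observed-minus-replicated correlation
        assert pair.residual.median() > 0
        assert pair.excludes_zero.mean() > 0.5

    def test_constant_test_study_marked_undefined(self, small_ci_fit):
        from mvplc.data_io import dataset_from_patterns

        fit, _ = small_ci_fit
        data = fit.model.data
        # replace one study's records with a constant first test
        pats = data.patterns.copy()
        pats[data.pattern_study == 0, 0] = 1
        key = np.column_stack([data.pattern_study, pats])
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        counts = np.zeros(len(uniq), dtype=int)
        np.add.at(counts, inv, data.pattern_counts)
        const_data = dataset_from_patterns(
            data.tests, data.study_ids, uniq[:, 0], uniq[:, 1:], counts)
        reps = ppc_replicate(fit, data, n_reps=20, seed=5)
        df = ppc_correlation_residuals(const_data, reps)
        assert df[(df.study == 1) & (df.test1 == "assay")
                  & (df.test2 == "ref")].undefined.iloc[0]


class TestTableResiduals:
    def test_self_fit_residual_intervals_cover_zero(self, small_ci_fit):
        fit, _ = small_ci_fit
        data = fit.model.data
        reps = ppc_replicate(fit, data, n_reps=150, seed=4)
        df = ppc_table_residuals(data, reps, ("ref", "score"), (None, 1))
        assert df.excludes_zero.mean() <= 0.25
        # zero-count cells are handled, residual intervals stay finite
        assert np.isfinite(df[["residual", "lower", "upper"]]).all().all()

    def test_counts_sum_to_study_size(self, small_ci_fit):
        fit, _ = small_ci_fit
        data = fit.model.data
        reps = ppc_replicate(fit, data, n_reps=5, seed=6)
        df = ppc_table_residuals(data, reps, ("ref", "assay"))
        totals = df.groupby("study")["observed"].sum()
        for s, n in zip(data.study_ids, data.study_sizes):
            assert totals[s] == n


class TestLooCompare:
    def test_identical_fits_have_zero_difference(self, small_ci_fit):
        fit, _ = small_ci_fit
        df = loo_compare([fit, fit], names=["a", "b"])
        assert df.elpd_diff.abs().max() == 0.0
        assert df.se_diff.max() == 0.0

    def test_looic_is_minus_two_elpd(self, small_ci_fit):
        fit, _ = small_ci_fit
        df = loo_compare([fit], names=["m"])
        assert df.loo_ic.iloc[0] == pytest.approx(-2 * df.elpd.iloc[0])

    def test_pointwise_sums_to_total(self, small_ci_fit):
        fit, _ = small_ci_fit
        e_i, k = loo_pointwise(fit)
        df = loo_compare([fit], names=["m"])
        assert e_i.sum() == pytest.approx(df.elpd.iloc[0])
        assert len(e_i) == fit.model.data.n_individuals

    def test_cd_model_beats_ci_on_dependent_data(self, dependent_misfit):
        # nested comparison: the model matching the generator (conditional
        # dependence) outranks the restricted CI model
        df = dependent_misfit["loo"]
        assert df.model.iloc[0] == "cd"
        ci_row = df[df.model == "ci"].iloc[0]
        assert ci_row.elpd_diff < 0

    def test_mismatched_individuals_rejected(self, small_ci_fit,
                                             toy_perfect_fit):
        with pytest.raises(ValueError, match="same individuals"):
            loo_compare([small_ci_fit[0], toy_perfect_fit])

    def test_exact_refit_fallback_agrees_with_psis(self, toy_perfect_fit):
        # the refit route (drop one individual, refit, score it) should
        # land close to the PSIS estimate on a well-behaved toy
        from mvplc.checking import exact_refit_elpd
        from mvplc.model import ModelSpec

        fit = toy_perfect_fit
        e_i, _ = loo_pointwise(fit)
        idx = 0
        exact = exact_refit_elpd(
            fit.model.data, ModelSpec(perfect_gs=["gs"]), idx,
            sampler_kwargs={"chains": 2, "iterations": 300, "seed": 3})
        assert exact == pytest.approx(e_i[idx], abs=0.05)
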