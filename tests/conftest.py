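"""Shared fixtures: printed case-study rows, small synthetic datasets, and
session-scoped MCMC fits reused across test modules (sampling is the
expensive step, so fits are shared)."""

import numpy as np
import pytest

from mvplc.data_io import TestDefinition, dataset_from_patterns
from mvplc.inference import sample_posterior
from mvplc.model import ModelSpec, build_model
from mvplc.synthetic_data import GeneratorConfig, simulate_dataset

# The printed cross-classification rows of the DVT case study (studies 1
# and 11): pattern order is ultrasound-negative first, then D-Dimer
# negative/positive, then Wells L/M/H within each.
TABLE1_ROWS = {
    1: [32, 20, 5, 8, 18, 2, 0, 0, 2, 1, 6, 8],
    11: [243, 16, 3, 233, 104, 29, 1, 0, 0, 28, 117, 109],
}


def dvt_tests():
    return [
        TestDefinition("ultrasound", 2),
        TestDefinition("ddimer", 2),
        TestDefinition("wells", 3),
    ]


@pytest.fixture(scope="session")
def table1_dataset():
    tests = dvt_tests()
    patterns, counts, study = [], [], []
    for sid, row in TABLE1_ROWS.items():
        i = 0
        for us in (0, 1):
            for dd in (0, 1):
                for w in (1, 2, 3):
                    patterns.append([us, dd, w])
                    counts.append(row[i])
                    study.append(0 if sid == 1 else 1)
                    i += 1
    return dataset_from_patterns(
        tests, [1, 11], np.array(study), np.array(patterns), np.array(counts)
    )


@pytest.fixture(scope="session")
def small_ci_data():
    """Conditionally independent synthetic data (5 studies of 150)."""
    cfg = GeneratorConfig(S=5, N=150, eps_within=0.0, beta=0.0, seed=11)
    data, truth = simulate_dataset(cfg)
    return data, truth, cfg


@pytest.fixture(scope="session")
def small_ci_fit(small_ci_data):
    data, truth, cfg = small_ci_data
    model = build_model(data, ModelSpec(dependence="none", ghk_nodes=6))
    fit = sample_posterior(model, chains=2, iterations=250, warmup=300, seed=5)
    return fit, truth


@pytest.fixture(scope="session")
def dependent_misfit():
    """A perfect reference test plus two strongly conditionally dependent
    index tests, fitted with both the (misspecified) CI model and the
    matching pairwise-dependence model; used by the correlation-residual
    and LOO tests.  The reference is held perfect so the within-class
    dependence is actually testable (with all tests imperfect a 2-class
    model saturates small panels)."""
    from mvplc.checking import (loo_compare, ppc_correlation_residuals,
                                ppc_replicate)
    from mvplc.probit_core import approx_probit_ppf

    cfg = GeneratorConfig(
        S=6, N=250,
        tests=[TestDefinition("ref", 2), TestDefinition("a", 2),
               TestDefinition("b", 2)],
        mu=np.array([[-5.0, 5.0],
                     [approx_probit_ppf(0.25), approx_probit_ppf(0.78)],
                     [approx_probit_ppf(0.20), approx_probit_ppf(0.72)]]),
        sigma=np.array([[0.0, 0.0], [0.3, 0.3], [0.3, 0.3]]),
        rho=-0.3, eps_within=0.6, beta=0.15, seed=77)
    data, truth = simulate_dataset(cfg)
    ci = build_model(data, ModelSpec(perfect_gs=["ref"], dependence="none"))
    cd = build_model(data, ModelSpec(perfect_gs=["ref"],
                                     dependence=[["a", "b"]], ghk_nodes=6))
    fit_ci = sample_posterior(ci, chains=2, iterations=200, warmup=250,
                              seed=31, max_depth=6)
    fit_cd = sample_posterior(cd, chains=2, iterations=200, warmup=250,
                              seed=32, max_depth=6)
    reps = ppc_replicate(fit_ci, data, n_reps=120, seed=8)
    return {
        "data": data, "truth": truth,
        "fit_ci": fit_ci, "fit_cd": fit_cd,
        "corr_residuals": ppc_correlation_residuals(data, reps),
        "loo": loo_compare([fit_cd, fit_ci], names=["cd", "ci"]),
    }


def make_fit(model, constrained_list, seed=0):
    """A FitResult carrying hand-crafted constrained draws (no MCMC); used
    to test summary algebra against known parameter values."""
    from mvplc.inference import FitResult

    n = len(constrained_list)
    return FitResult(
        model=model,
        draws=np.zeros((2, (n + 1) // 2, model.dim)),
        energies=np.zeros((2, (n + 1) // 2)),
        divergent=np.zeros((2, (n + 1) // 2), dtype=bool),
        accept_stat=np.ones((2, (n + 1) // 2)),
        step_sizes=np.ones(2),
        seed=seed,
        _constrained=list(constrained_list),
    )


@pytest.fixture(scope="session")
def toy_perfect_fit():
    """Two studies, one perfect gold standard: prevalence has a closed form."""
    tests = [TestDefinition("gs", 2)]
    study = np.array([0, 0, 1, 1])
    pats = np.array([[0], [1], [0], [1]])
    counts = np.array([70, 30, 40, 60])
    data = dataset_from_patterns(tests, [1, 2], study, pats, counts)
    model = build_model(data, ModelSpec(perfect_gs=["gs"]))
    fit = sample_posterior(model, chains=4, iterations=400, seed=17)
    return fit
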