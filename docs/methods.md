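# Methods

`mvplc` fits a Bayesian multivariate-probit latent-class (MVP-LC) model to
meta-analysis data from studies that evaluate several diagnostic tests —
dichotomous and ordinal — on the same individuals, without assuming that
any test is a perfect gold standard. This note describes the model, the
numerical choices behind the implementation, and what the validation
experiments do and do not show.

## The model

**Within-study model.** Each individual *n* in study *s* carries a latent
binary disease status `d ~ Bernoulli(p_s)`. Given the class, the T
observed test responses arise by thresholding a latent continuous vector

    Z_{s,n} ~ MVN(nu_s^d, Psi_s^d),

where `nu_s^d` is the study's class-conditional accuracy vector on the
probit scale and `Psi_s^d` a correlation matrix (all latent scales are
fixed at 1 — the standard identifiability restriction for probit latent
class models). A dichotomous test is positive when its latent coordinate
exceeds 0; an ordinal test with K categories responds `k` when its
coordinate falls between strictly increasing cutpoints
`C_{k-1,s,t}^d < C_{k,s,t}^d` (with ±infinity at the ends). Off-diagonal
entries of `Psi_s^d` are *polychoric* correlations and model conditional
dependence between tests within a disease class; setting them to zero
gives the conditional-independence (CI) model.

**Between-study model.** Study accuracy means are partially pooled: for
each test, `(nu_{s,t}^1, nu_{s,t}^0)` follows a bivariate normal with
means `(mu_t^1, mu_t^0)`, SDs `(sigma_t^1, sigma_t^0)` and correlation
`rho_t` (the Se/Sp between-study correlation). Prevalences are unpooled
(an independent uniform per study). Within-study correlation matrices are
partially pooled as the convex combination

    Psi_s^d = (1 - beta^d) * Psi_G^d + beta^d * Psi_s^{d,Delta},

with a global matrix, study-level deviation matrices, and a mixing weight
`beta^d in [0,1]` per class — a convex combination of correlation
matrices is again a correlation matrix, so validity is structural.
Ordinal cutpoints are pooled through an *induced Dirichlet* model: the
cutpoints of test t in study s, anchored at zero through the link,
correspond one-to-one to a simplex of category probabilities
`P_{s,t}^d`; these study simplices are drawn from
`Dirichlet(kappa^d * pi_t^d)` around a population simplex `pi_t^d`
(uniform hyperprior) with concentration `kappa^d >= 0`. Global cutpoints
are the cutpoints induced by `pi_t^d`. Cutpoints are class-specific by
default; a config switch shares them across classes.

A test can be declared a **perfect gold standard**, which pins
`mu = (+5, -5)` on the probit scale (approximately 100% sensitive and
specific) with zero between-study variation.

**Accuracy summaries.** All links use the logistic approximation to the
standard normal CDF, `F'(x) = 1 / (1 + exp(-1.702 x))`, whose maximum
absolute deviation from the normal CDF is 0.0095; the same link is used
in the likelihood, the cutpoint transforms and the summaries, so the
model is internally consistent. Summary accuracy evaluates the links at
the between-study means and global cutpoints (`Se = F'(mu^1)`,
`Sp = 1 - F'(mu^0)`; at cutpoint k of an ordinal test
`Se_k = 1 - F'(C_k^1 - mu^1)`, `Sp_k = F'(C_k^0 - mu^0)`). Predictive
("new study") accuracy re-draws study parameters from the between-study
laws at every posterior draw. Joint accuracy of a test pair under
believe-the-negatives (BTN: positive only if both positive) and
believe-the-positives (BTP: negative only if both negative) combines the
component accuracies with the class-conditional covariance of the
positive indicators:

    Se_BTN = Se1*Se2 + cov^1          Sp_BTN = 1 - [(1-Sp1)(1-Sp2) + cov^0]
    Se_BTP = 1 - [(1-Se1)(1-Se2) + cov^1]    Sp_BTP = Sp1*Sp2 + cov^0.

The covariance on the observed scale is obtained from the polychoric
correlation by the bivariate rectangle identity
`cov = P11 - P1*P1'`, with `P11` evaluated under a Gaussian copula with
approximate-probit margins (thresholds mapped through `Phi^-1(F'(.))`).
This construction makes the margins exactly equal to the summary links,
so the covariance always respects its Fréchet bounds; it reconstructs
the polychoric-to-observed conversion from first principles.

## Priors

Hyperparameters are reconstructed numerically so that each prior's
induced 95% interval matches its target on the natural scale:

| Parameter | Prior | Default 95% interval (natural scale) |
|---|---|---|
| `mu_t^d` (imperfect test) | normal on the probit scale | accuracy 0.04–0.96 (vague), overridable per test (e.g. an informative reference test 0.49–0.94 Se, 0.82–0.99 Sp) |
| `sigma_t^d` | zero-lower-truncated normal | 0.02–1.09 |
| `rho_t` | `tanh` of a centred normal | −0.82 to 0.82 |
| within-study correlation entries | `tanh` of centred normals (canonical partial correlations in the full-dependence model) | −0.65 to 0.65 |
| `kappa^d` | half-normal(0, 50) | allows highly asymmetric Dirichlet vectors |
| `p_s`, `beta^d` | uniform(0, 1) | — |

For the full-dependence model the correlation interval is matched on the
canonical-partial-correlation scale, which is approximate for the
marginal entries; for single-pair dependence it is exact. The
anchored test (by default the first imperfect test; the reference test
in applications) has its class means declared ordered, `mu^1 > mu^0`
(sensitivity + specificity > 1), as a label-switching safeguard on top
of the informative priors.

## Computation

The posterior is sampled by a multinomial no-U-turn HMC kernel written
for this package, running on gradients from a small in-package
reverse-mode tape. Design choices that matter:

- **Marginalised likelihood.** Individuals collapse to at most
  `prod(K_t)` distinct response patterns per study, and each pattern's
  class-conditional probability is a T-dimensional rectangle probability
  under the latent law. Rectangles are integrated by deterministic GHK:
  sequential conditioning through the Cholesky factor with
  Gauss–Legendre nodes in the uniform space of each truncated
  conditional (8 nodes per dimension by default; experiments use 4–6,
  where the quadrature error is ~1e-4 to 1e-5 — far below Monte Carlo
  error).
  The classic Monte Carlo GHK over explicit uniforms is available in
  `rectangle_prob`; the sampler never needs per-individual nuisance
  variables because the quadrature integrates them out.
- **Hot-path fusion.** Three blocks are fused into single tape nodes
  with hand-derived reverse sweeps, each validated against the
  elementary tape construction and finite differences: the batched GHK
  recursion, the correlation pipeline (partial correlations → Cholesky →
  convex pooling → per-study Cholesky → row gather), and the induced
  Dirichlet cutpoint block.
- **Dense mass matrix.** The posterior has a structural ridge: shifting
  an ordinal test's mean and all of its cutpoints together changes the
  likelihood only through the priors, so those coordinates are strongly
  correlated a posteriori (the model keeps both pooling routes, as
  specified; with diffuse priors this is the near-non-identifiability
  the approach is known for). Warmup adapts a dense metric (sample
  covariance shrunk toward its diagonal by n/(n+dim)) so trajectories
  can move along the ridge; this roughly triples effective sample sizes
  per unit time over a diagonal metric on conditional-dependence fits.
- **Divergences and E-FMI** follow Stan's conventions (energy error >
  1000; BFMI < 0.2 flags a chain); split R-hat and bulk ESS come from
  arviz. A fit is PASS only with R-hat < 1.05 everywhere, zero
  divergences and no E-FMI warning. A crude histogram-valley screen
  flags possibly bimodal marginals, advisory only.
- **Initialisation** draws from a shrunk prior with the anchored test
  started at `Se + Sp > 1`; non-finite starts are retried.

Model comparison uses PSIS-LOO (via arviz) on the per-individual
pointwise log-likelihood; LOO-IC = −2·ELPD, and ELPD-difference standard
errors use the pointwise-difference estimator. The pointwise unit is the
individual record, matching the individual-level model specification.
An exact-refit fallback for Pareto-k-flagged observations is provided
for small datasets.

## Synthetic data

The generator (`synthetic_data`) draws data with exactly the model's
generative structure: per study a prevalence from a uniform range, study
means from the bivariate-normal law, a study correlation matrix from the
convex pooling model (deviation matrices via random partial
correlations), study cutpoints from `Dirichlet(kappa*pi)`, then per
individual a class and a latent vector thresholded to categories.
Latent residuals use the same `F'` conditionals as the likelihood, so
the fitted model is exactly the data-generating process — which is what
parameter-recovery and calibration experiments require.

Defaults emulate a DVT-like panel: 15 studies of 400 individuals; three
tests (a reference-like dichotomous test with Se 0.85/Sp 0.95, a
dichotomous assay with Se 0.80/Sp 0.70, and a 3-category score with
means (0.9, −0.3) and class simplices (0.2, 0.3, 0.5) / (0.6, 0.3, 0.1));
between-study SDs 0.35 and Se/Sp correlation −0.4 (moderate
heterogeneity); within-class polychoric correlations 0.3 between all
pairs with mixing weight 0.25 and deviation spread 0.25; prevalences
uniform on (0.1, 0.5); cutpoint concentration kappa = 50. One master
seed expands into per-study substreams, so datasets are reproducible
under partial regeneration.

What passing on such data shows: the estimation machinery is correct and
calibrated *under the model's own assumptions*. What it does not show:
robustness to real-data features the generator omits — covariate-driven
heterogeneity, more than two latent classes, missing cross-classification
cells, or reporting artefacts.

## Validation experiments and problem sizes

The acceptance script and the corresponding tests run four experiments
end to end (sizes chosen so the whole battery completes in minutes on
one CPU; the scientific structure is unchanged):

1. **Oracle agreement.** GHK rectangle probabilities vs an independent
   nested-quadrature oracle and the closed-form bivariate orthant
   identity, over 200 randomised T ≤ 3 instances.
2. **Parameter recovery.** Full conditional-dependence fits to datasets
   from the generator (10 studies of 400 at default effect sizes; two
   replicate datasets; 2 chains of 300 warmup + 150 draws, tree depth
   capped at 6): 95%-interval coverage of accuracy means, SDs,
   prevalences and global polychoric correlations, and posterior-median
   bias of summary Se/Sp. The fitted model uses the application's prior
   structure — an informative accuracy prior on the reference-like test
   — because a latent-class posterior with no gold standard and all
   priors vague is only weakly identified, and its posterior medians
   shrink far from the truth regardless of chain length.
3. **Dichotomisation sensitivity.** A 3-category test under an imperfect
   reference: collapsing the score at cutpoint 1 versus cutpoint 2 and
   fitting the dichotomised models moves the reference test's
   sensitivity posterior by more than Monte Carlo error, while the full
   ordinal model covers the generating truth — the reason a-priori
   dichotomisation is hazardous without a gold standard.
4. **CI vs CD ranking.** Ten replicate datasets of a near-perfect
   reference test plus two index tests with strong conditional
   dependence (polychoric 0.6), each fitted with the reference held
   perfect under CI and under pairwise dependence, and compared by
   PSIS-LOO. The perfect reference matters: with every test imperfect
   and unrestricted study effects, a 2-class latent-class model is
   essentially saturated on 2–3 test panels, so the CI restriction is
   not testable there — pinning the reference is what makes conditional
   dependence a falsifiable assumption in this scaled experiment.

## Known limitations

- Arbitrary zero patterns in the dependence structure are not
  supported: "none", "all", or disjoint test pairs (positive
  definiteness is structural in each case). The case-study model
  variants need nothing more.
- Meta-regression covariates are accepted in the configuration schema
  but not implemented (the hook exists so configs validate).
- The dense-metric NUTS implementation is adequate for the posterior
  sizes here (a few hundred parameters); very large meta-analyses would
  profit from a compiled gradient backend.
- The ordinal-mean/cutpoint ridge is inherent to keeping both pooling
  routes for ordinal tests; with vague priors and few studies it slows
  mixing and inflates posterior-median variability. Convergence reports
  should be taken seriously, and the informative-prior route (as in the
  case-study presets) is recommended for reference tests.
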