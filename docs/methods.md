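# Methods

`celltwas` implements a cell-type-aware transcriptome-wide association
study (TWAS) for bulk tissue composed of two cell-type compartments: a
cell type of interest (e.g. mammary epithelium) and everything else (e.g.
stroma).  This note records the models, the estimation choices, and what
the synthetic experiments do and do not establish.

## Mixture model for bulk expression

Observed bulk expression of a gene in sample *i* is a proportion-weighted
mixture of unobserved cell-type-level expression,

    y_i = pi_i * u_i + (1 - pi_i) * v_i,

with linear-additive genetic models in each compartment:

    u_i = a_u + x_i' b_u + z_i' c + e_ui,    e_ui ~ N(0, su^2)
    v_i = a_v + x_i' b_v + z_i' c + e_vi,    e_vi ~ N(0, sv^2).

Here `x` are cis-SNP dosages (0–2), `z` non-genetic covariates (shared
coefficient vector `c` across compartments), and `pi_i` the proportion of
the cell type of interest.  The genetically regulated expression (GReX)
in each compartment is the genetic term `x' b_u` and `x' b_v` alone.

## Proportion estimation (`proportions`)

`pi` is estimated from signature genes of the cell type of interest
jointly with a prior score.  For signature gene *g* the compartment
levels are modeled as `s ~ N(mu_S^g, sigma_S^g)` and
`t ~ N(mu_T^g, sigma_T^g)` with parameters shared across samples, so the
mixture `w_i^g = pi_i s + (1 - pi_i) t` has closed-form marginal

    w_i^g ~ N(pi_i mu_S + (1-pi_i) mu_T,
              pi_i^2 sigma_S^2 + (1-pi_i)^2 sigma_T^2).

The variance form follows from independent compartment-level noise; the
model ignores gene–gene correlation, trading efficiency for a small loss
of information.  A prior proportion `h_i` in (0,1) — in practice a
min–max-rescaled xCell-style enrichment score, clipped to
[0.01, 0.99] — enters through `h_i ~ Beta(pi_i delta, (1-pi_i) delta)`,
which makes `h_i` conditionally unbiased for `pi_i` with noise controlled
by the concentration `delta` (estimated; bounded to [0.1, 1e4],
initialized at 10).

The joint log likelihood is maximized by block coordinate ascent:
per-gene L-BFGS-B over `(mu_S, mu_T, log sigma_S, log sigma_T)`,
per-sample bounded 1-D maximization of `pi_i` on [0.01, 0.99], and a
bounded 1-D update of `log delta`.  Because the marginal likelihood is
available in closed form there is no latent E-step; each block update is
accepted only when it does not decrease the objective, so the trace is
provably non-decreasing (asserted at run time).  Convergence is declared
at relative objective change below 1e-6 (cap 500 iterations).  Label
switching — the likelihood is invariant under swapping compartments and
`pi -> 1 - pi` — is resolved by initializing `pi` at the prior, which
anchors the "S" component to the cell type the prior describes; no
ordering constraint on the means is imposed.

Robustness comes from bagging: 100 bootstrap fits on 80% draws with
replacement, each scoring all samples under its fitted parameters; the
final estimate is a per-sample mean after trimming 5% of bootstrap
estimates in each tail.  Trimming is per sample, not per replicate.

## Prediction models (`grex`)

Substituting the compartment models into the mixture and writing
`c_i = pi_i - 0.5` gives the symmetric training design

    y_i = (a_u+a_v)/2 + c_i (a_u-a_v) + x_i'(b_u+b_v)/2
          + c_i x_i'(b_u-b_v) + z_i'c + eps_i,

fit by elastic net (mixing 0.5) with the penalty on
`((b_u+b_v)/2, b_u-b_v, c)` and none on the two intercept terms.  Both
compartments are regularized identically, so relabeling them merely swaps
`(a_u, b_u)` with `(a_v, b_v)` — verified to 1e-8 in tests.  The
asymmetric variant (penalty on `(b_v, b_u-b_v, c)` with `pi` rather than
`pi - 0.5` interactions) is provided for benchmarking; it is order
dependent by construction.  A tissue-level elastic net of `y` on `[x, z]`
is the PrediXcan-style baseline.  Residual variance is treated as
constant although the mixture makes it depend on `pi`; the variance
structure has negligible influence on regularized coefficient estimates.

Implementation notes.  scikit-learn's solvers penalize every column, so
the unpenalized block (intercept and `c_i`) is handled by exact
Frisch–Waugh–Lovell residualization, which leaves the penalized problem
unchanged.  Penalized columns are standardized to unit variance inside
the solver and back-scaled; without this, the interaction columns
(`|c_i| < 0.5`) would be implicitly over-penalized.  The penalty strength
is chosen on a 10-fold cross-validated path (folds seeded).  The default
rule is the largest penalty within one standard error of the CV-error
minimum ("1se").  The CV-minimum rule is available
(`ElasticNetSpec.lambda_rule="min"`) but retains spurious SNPs and
interaction terms in roughly half of pure-noise fits, which cascades into
cell-type-specific calls for genes whose genetic regulation is actually
shared; the 1-SE rule restores the intended behavior (noise genes yield
empty models; homogeneous genes yield nonspecific models in a large
majority of replicates) and is therefore the default throughout,
including the tissue-level baseline.

Whether a gene is genuinely cell-type specific is decided by bootstrap
stability selection on `b_u - b_v`: when the elastic net selects any
interaction term, 200 bootstrap resamples refit ordinary least squares on
the pre-selected columns (intercept and `c_i` always included; selected
SNP, interaction and covariate columns) and per-SNP 95% percentile
confidence intervals of `b_u - b_v` are formed.  The model is
cell-type specific iff any selected SNP's interval excludes zero — a
per-SNP resolution of the interval rule; a joint-vector alternative was
considered and found unnecessary once penalty selection was fixed.
Otherwise the gene collapses to the tissue-level (nonspecific) weights.
Rank-deficient bootstrap systems are solved with a 1e-8 ridge jitter.
Genes whose fit selects no SNPs are flagged untrainable and excluded from
association testing and from multiple-testing denominators.

GReX prediction for new subjects is the genetic term only,
`y_u = X b_u`, `y_v = X b_v` — no intercepts or covariates — so weights
transfer to GWAS cohorts without covariate harmonization.  Held-out
*accuracy evaluation* against observed bulk expression is the one place
the per-cell-type means matter: the tissue-level prediction used there is
`pi (a_u + X b_u) + (1-pi) (a_v + X b_v)`, since the proportion-weighted
mean difference is genuinely predictive of bulk expression while a
constant intercept cannot change a Pearson correlation.

## Association testing (`association`)

Because both GReX vectors are predicted from the same genotypes with
jointly learned weights, each can carry leaked signal from the other;
per-compartment inference is therefore anti-conservative.  The test
targets the composite null of no association in *any* compartment.  For
cell-type-specific genes, effects are estimated in one joint generalized
linear model `g(d) = eta_0 + eta_u y_u + eta_v y_v + covariates` unless
`|cor(y_u, y_v)| >= 0.99` or one vector is degenerate, in which case two
separate single-GReX models are fit.  The two Wald p-values are combined
with the Cauchy combination (ACAT):

    T = w_u tan(pi (1/2 - p_u)) + w_v tan(pi (1/2 - p_v)),
    p_tissue = 1/2 - arctan(T) / pi,

with equal weights `w_u = w_v = 1/2`.  Equal weights summing to one give
`combine(p, p) = p` and keep the combined p-value between its inputs; the
unweighted two-term sum evaluated against the standard Cauchy tail is
anti-conservative under dependence and is available only for comparison
(`weights=(1, 1)`).  P-values are clipped to [1e-15, 1-1e-15] before the
tangent transform.  Nonspecific genes reduce exactly to a single
tissue-level GLM.  Transcriptome-wide annotation applies Bonferroni
(`fwer / n_testable`) and Benjamini–Hochberg step-up at the requested
FDR, with untestable genes excluded from the denominators.

## Simulation engine (`simulation`)

Each replicate mimics the two-stage design: a training set of 300 bulk
samples and an independent case-control GWAS of 3000 subjects.  Defaults:
50 SNPs with MAF uniform on [0.05, 0.50], independent Hardy–Weinberg
binomial dosages; `pi ~ Beta(2, 3)` (mean 40%); compartment expression
`u = b0 + x'b1 + e`, `v = x'b2 + e` with unit noise and `b0 = 1`; one
causal SNP per compartment with |effect| 1 and random sign (the same SNP
and sign under the homogeneous setting), giving cell-level
cis-heritability `2p(1-p)/(2p(1-p)+1)`, median about 0.27 over the MAF
range.  Disease follows `logit P(d=1) = eta0 + eta1 u + eta2 v`, with
`eta0` calibrated by bracketed root-finding on the realized sample to a
1:1 case-control ratio.  Five expression-disease patterns are preset:
null (0, 0), homogeneous (0.2, 0.2), major-cell (0, 0.2), minor-cell
(0.2, 0), opposite (-0.2, 0.2).

Training proportions default to the truth, isolating model and test
behavior; noisy estimation is injected through explicit misspecification
transforms — `0.8 pi`, `0.7 pi + 0.2`, and conditionally unbiased
`Beta(c pi, c (1-pi))` noise with concentration 50 or 5.5.  Under the
Beta(2,3) truth the exact correlation of the Beta-noise estimates with
the truth is `sd(pi) / sqrt(var(pi) + E[pi(1-pi)]/(c+1))`, i.e. 0.954 and
0.752 for c = 50 and 5.5 (tests assert these closed-form values).  A
latent-third-cell option mixes three compartments with mean proportions
(0.4, 0.5, 0.1) and mild Dirichlet variation, decomposed in analysis as
compartment 1 versus the rest.

What the generator does not emulate: linkage disequilibrium (SNPs are
independent, so the realized heritability spectrum only approximates a
reference-panel simulator), covariates (none, taken literally from the
study design), library-size or count-level noise (expression is already
on a normalized continuous scale), and more than three cell types.
Passing tests therefore establish the statistical properties of the
estimator and tests under the stated generative model, not performance on
real tissue with LD structure and measurement artifacts.

## Problem sizes and runtime choices

Monte-Carlo studies use 500 replicates at the spec'd defaults when run
via `run_study`; the shipped test suite and the acceptance script run
200-replicate type-I-error checks (95% binomial band widened to
[0.02, 0.09] accordingly) and 150–200-replicate power comparisons, sizes
chosen so the full pipeline re-runs in minutes on one core while leaving
each assertion at least two Monte-Carlo standard errors of headroom.
Bagged proportion estimation defaults to 100 bootstraps; unit tests use
4–5 bootstraps on 40-sample fixtures, which exercises every code path at
a fraction of the cost.

## Known limitations

* Two-compartment decomposition only; a latent third cell type is
  simulated but not modeled.
* The stability-selection CI is conditional on the one-time variable
  selection, so the specific/nonspecific call is a heuristic, not an
  inference with guaranteed error control.
* Summary-statistics (S-PrediXcan-style) testing, inflation-factor
  estimation and fine-mapping are out of scope.
* The proportion model assumes signature genes are informative primarily
  through mean differences; genes whose contrast is in variance only
  contribute little.
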