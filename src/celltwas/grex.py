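"""Genetically regulated expression (GReX) prediction models.

Three model families are trained per gene from bulk expression, SNP dosages
and covariates:

* a tissue-level elastic-net baseline (PrediXcan-style):
  ``y = a + x'b + z'c + e`` with the elastic-net penalty on (b, c);
* an asymmetric interaction model that regresses bulk expression on SNPs
  and proportion x SNP interactions, penalizing (b_v, b_u - b_v, c).  The
  penalty treats the two cell types unequally, so swapping the component
  labels changes the fit — kept for benchmarking;
* the symmetric cell-type model: with centered proportions
  ``c_i = pi_i - 0.5`` the mixture of two per-cell-type linear models

      y_i = (a_u + a_v)/2 + c_i (a_u - a_v)
            + x_i' (b_u + b_v)/2 + c_i x_i' (b_u - b_v) + z_i' c + eps_i

  is penalized on ((b_u + b_v)/2, b_u - b_v, c) and left unpenalized on the
  two intercept terms, so both cell types are regularized identically and
  relabeling the cell types merely swaps (b_u, a_u) with (b_v, a_v).

Whether a gene genuinely has cell-type-specific genetic regulation is
decided by bootstrap stability selection on b_u - b_v: if the elastic net
selects any interaction term, ordinary least squares is refit on the
pre-selected columns over B bootstrap resamples and the percentile
confidence interval of b_u - b_v is computed per SNP; only when some CI
excludes zero is the cell-type-specific model kept, otherwise the gene
falls back to the tissue-level (nonspecific) weights.

Residual variance is treated as constant even though the mixture makes it
depend on pi; the variance structure has little influence on regularized
coefficient estimates and a homoscedastic solver is much faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._penalized import fit_partially_penalized

__all__ = [
    "TrainingGeneData",
    "ElasticNetSpec",
    "TissueModel",
    "CellTypePredictionModel",
    "GrexPrediction",
    "build_celltype_design",
    "train_tissue_model",
    "train_celltype_model",
    "train_celltype_model_asymmetric",
    "predict_grex",
    "evaluate_prediction",
]


@dataclass
class TrainingGeneData:
    """Per-gene training inputs: expression y, dosages X, covariates Z, proportions."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray | None = None
    pi_hat: np.ndarray | None = None
    gene_id: str = "gene"
    snp_ids: list | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("X and y sample counts differ")
        if np.any(self.X < 0) or np.any(self.X > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.Z is not None:
            self.Z = np.asarray(self.Z, dtype=float)
            if self.Z.shape[0] != n:
                raise ValueError("Z and y sample counts differ")
        if self.pi_hat is not None:
            self.pi_hat = np.asarray(self.pi_hat, dtype=float)
            if np.any((self.pi_hat <= 0) | (self.pi_hat >= 1)):
                raise ValueError("pi_hat must lie strictly in (0, 1)")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j}" for j in range(self.X.shape[1])]


@dataclass
class ElasticNetSpec:
    """Elastic-net hyperparameters: mixing alpha, CV folds, lambda rule, seed.

    ``lambda_rule`` picks the penalty from the cross-validated path:
    ``"1se"`` (default) is the largest penalty within one standard error of
    the CV-error minimum — the standard guard against retaining noise
    predictors — and ``"min"`` is the CV-error minimizer.
    """

    alpha: float = 0.5
    n_folds: int = 10
    seed: int = 0
    lambda_: float | None = None  # overrides cross-validation when set
    lambda_rule: str = "1se"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_rule not in ("1se", "min"):
            raise ValueError("lambda_rule must be '1se' or 'min'")


@dataclass
class TissueModel:
    gene_id: str
    snp_ids: list
    b: np.ndarray
    a: float
    c: np.ndarray
    cv_performance: float
    lambda_: float
    untrainable: bool = False


@dataclass
class CellTypePredictionModel:
    gene_id: str
    snp_ids: list
    b_u: np.ndarray
    b_v: np.ndarray
    a_u: float
    a_v: float
    c: np.ndarray
    model_type: str  # "cell_type_specific" | "nonspecific"
    diff_ci: np.ndarray | None = None  # (n_snps, 2) lo/hi for b_u - b_v
    n_boot: int = 0
    cv_performance: float = float("nan")
    lambda_: float = float("nan")
    untrainable: bool = False


@dataclass
class GrexPrediction:
    """Predicted genetic component of expression per subject and cell type."""

    y_u: np.ndarray
    y_v: np.ndarray
    tissue: np.ndarray | None = None
    subject_ids: np.ndarray | None = None


def train_tissue_model(data: TrainingGeneData, spec: ElasticNetSpec) -> TissueModel:
    """Elastic-net fit of bulk expression on dosages and covariates.

    The mixing parameter defaults to 0.5 and the penalty strength is chosen
    on a cross-validated path by ``spec.lambda_rule``; the intercept is
    unpenalized.  Genes for which no SNP survives the penalty are returned
    flagged untrainable (no predictive genetic component).
    """
    if np.std(data.y) == 0:
        raise ValueError(f"{data.gene_id}: constant expression")
    p = data.X.shape[1]
    P = data.X if data.Z is None else np.hstack([data.X, data.Z])
    fit = fit_partially_penalized(
        data.y, P, None, l1_ratio=spec.alpha, n_folds=spec.n_folds,
        seed=spec.seed, lambda_=spec.lambda_, lambda_rule=spec.lambda_rule,
    )
    b = fit.coef_pen[:p]
    c = fit.coef_pen[p:]
    untrainable = not np.any(b != 0)
    if untrainable:
        warnings.warn(f"{data.gene_id}: untrainable GReX (no predictive SNPs)")
    return TissueModel(
        gene_id=data.gene_id, snp_ids=list(data.snp_ids), b=b,
        a=float(fit.coef_unpen[0]), c=c, cv_performance=fit.cv_r,
        lambda_=fit.lambda_, untrainable=untrainable,
    )


def build_celltype_design(X: np.ndarray, Z: np.ndarray | None, pi_hat: np.ndarray):
    """Augmented design for the symmetric cell-type model.

    Returns ``(U, P, blocks)``: the unpenalized block ``U = [c]`` with
    ``c_i = pi_i - 0.5`` (the intercept is implicit in the solver), the
    penalized block ``P = [X, c*X, Z]``, and slice metadata for each block.
    """
    pi_hat = np.asarray(pi_hat, dtype=float)
    if np.any((pi_hat <= 0) | (pi_hat >= 1)):
        raise ValueError("pi_hat must lie strictly in (0, 1)")
    X = np.asarray(X, dtype=float)
    if X.shape[0] != pi_hat.shape[0]:
        raise ValueError("X and pi_hat sample counts differ")
    c = pi_hat - 0.5
    inter = c[:, None] * X
    parts = [X, inter]
    p = X.shape[1]
    blocks = {"snp": slice(0, p), "interaction": slice(p, 2 * p)}
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        parts.append(Z)
        blocks["covariate"] = slice(2 * p, 2 * p + Z.shape[1])
    return c[:, None], np.hstack(parts), blocks


def _bootstrap_diff_ci(y, cols, n_unpen, snp_pos, B, ci_level, rng):
    """Percentile CIs of b_u - b_v from bootstrap OLS on pre-selected columns.

    ``cols`` is [1, c, selected penalized columns]; ``snp_pos`` maps each
    SNP with a selected interaction to its column index in ``cols``.
    Rank-deficient resamples are solved with a 1e-8 ridge jitter.
    """
    n, k = cols.shape
    diffs = np.empty((B, len(snp_pos)))
    n_jitter = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        A = cols[idx]
        yb = y[idx]
        AtA = A.T @ A
        Aty = A.T @ yb
        try:
            beta = np.linalg.solve(AtA, Aty)
            if not np.all(np.isfinite(beta)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            n_jitter += 1
            beta = np.linalg.solve(AtA + 1e-8 * np.eye(k), Aty)
        diffs[b] = beta[snp_pos]
    if n_jitter:
        warnings.warn(f"{n_jitter}/{B} bootstrap OLS fits required ridge jitter")
    lo = np.percentile(diffs, 100 * (1 - ci_level) / 2, axis=0)
    hi = np.percentile(diffs, 100 * (1 + ci_level) / 2, axis=0)
    return lo, hi


def train_celltype_model(
    data: TrainingGeneData,
    spec: ElasticNetSpec,
    B: int = 200,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> CellTypePredictionModel:
    """Train the symmetric cell-type model with stability selection.

    Fits the elastic net on the augmented design (intercept and centered
    proportion unpenalized), back-transforms the mean/difference
    parameterization to per-cell-type weights ``b_u = beta_x + beta_cx / 2``
    and ``b_v = beta_x - beta_cx / 2``, then decides specific vs.
    nonspecific by bootstrap percentile CIs of ``b_u - b_v``.  Nonspecific
    genes collapse to the tissue-level fit on the same data.
    """
    if np.std(data.y) == 0:
        raise ValueError(f"{data.gene_id}: constant expression")
    if data.pi_hat is None:
        raise ValueError("pi_hat required for cell-type model training")
    c_col, P, blocks = build_celltype_design(data.X, data.Z, data.pi_hat)
    fit = fit_partially_penalized(
        data.y, P, c_col, l1_ratio=spec.alpha, n_folds=spec.n_folds,
        seed=spec.seed, lambda_=spec.lambda_, lambda_rule=spec.lambda_rule,
    )
    p = data.X.shape[1]
    beta_x = fit.coef_pen[blocks["snp"]]
    beta_cx = fit.coef_pen[blocks["interaction"]]
    c_cov = fit.coef_pen[blocks["covariate"]] if "covariate" in blocks else np.zeros(0)
    beta0, beta_c = float(fit.coef_unpen[0]), float(fit.coef_unpen[1])
    b_u = beta_x + beta_cx / 2
    b_v = beta_x - beta_cx / 2
    a_u = beta0 + beta_c / 2
    a_v = beta0 - beta_c / 2

    diff_ci = None
    specific = False
    inter_sel = np.flatnonzero(beta_cx != 0)
    if inter_sel.size > 0:
        # pre-selected columns: intercept + c always; penalized columns with
        # nonzero weight (SNP main effects, interactions, selected covariates)
        sel_pen = np.flatnonzero(fit.coef_pen != 0)
        cols = np.hstack([np.ones((len(data.y), 1)), c_col, P[:, sel_pen]])
        # interaction column j of P sits at position 2 + rank within sel_pen
        pos_in_cols = {j: 2 + r for r, j in enumerate(sel_pen)}
        snp_pos = np.array([pos_in_cols[p + j] for j in inter_sel])
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        lo, hi = _bootstrap_diff_ci(data.y, cols, 2, snp_pos, B, ci_level, rng)
        diff_ci = np.full((p, 2), np.nan)
        diff_ci[inter_sel, 0] = lo
        diff_ci[inter_sel, 1] = hi
        specific = bool(np.any((lo > 0) | (hi < 0)))

    if specific:
        return CellTypePredictionModel(
            gene_id=data.gene_id, snp_ids=list(data.snp_ids),
            b_u=b_u, b_v=b_v, a_u=a_u, a_v=a_v, c=c_cov,
            model_type="cell_type_specific", diff_ci=diff_ci, n_boot=B,
            cv_performance=fit.cv_r, lambda_=fit.lambda_,
            untrainable=not (np.any(b_u != 0) or np.any(b_v != 0)),
        )
    tissue = train_tissue_model(data, spec)
    return CellTypePredictionModel(
        gene_id=data.gene_id, snp_ids=list(data.snp_ids),
        b_u=tissue.b.copy(), b_v=tissue.b.copy(), a_u=tissue.a, a_v=tissue.a,
        c=tissue.c, model_type="nonspecific", diff_ci=diff_ci, n_boot=B,
        cv_performance=tissue.cv_performance, lambda_=tissue.lambda_,
        untrainable=tissue.untrainable,
    )


def train_celltype_model_asymmetric(data: TrainingGeneData, spec: ElasticNetSpec) -> CellTypePredictionModel:
    """Asymmetric interaction model (benchmarking only, no stability selection).

    Regresses bulk expression on ``[pi (unpenalized), X, pi*X, Z]`` with the
    penalty on (b_v, b_u - b_v, c); the two cell types are not penalized
    symmetrically, so swapping component labels changes the fit.
    """
    if np.std(data.y) == 0:
        raise ValueError(f"{data.gene_id}: constant expression")
    if data.pi_hat is None:
        raise ValueError("pi_hat required for cell-type model training")
    X = data.X
    p = X.shape[1]
    inter = data.pi_hat[:, None] * X
    parts = [X, inter] if data.Z is None else [X, inter, data.Z]
    P = np.hstack(parts)
    fit = fit_partially_penalized(
        data.y, P, data.pi_hat[:, None], l1_ratio=spec.alpha,
        n_folds=spec.n_folds, seed=spec.seed, lambda_=spec.lambda_,
        lambda_rule=spec.lambda_rule,
    )
    b_v = fit.coef_pen[:p]
    b_u = b_v + fit.coef_pen[p:2 * p]
    c_cov = fit.coef_pen[2 * p:] if data.Z is not None else np.zeros(0)
    a_v = float(fit.coef_unpen[0])
    a_u = a_v + float(fit.coef_unpen[1])
    specific = bool(np.any(b_u != b_v))
    return CellTypePredictionModel(
        gene_id=data.gene_id, snp_ids=list(data.snp_ids),
        b_u=b_u, b_v=b_v, a_u=a_u, a_v=a_v, c=c_cov,
        model_type="cell_type_specific" if specific else "nonspecific",
        cv_performance=fit.cv_r, lambda_=fit.lambda_,
        untrainable=not (np.any(b_u != 0) or np.any(b_v != 0)),
    )


def predict_grex(
    model: CellTypePredictionModel | TissueModel,
    X_new: np.ndarray,
    pi_new: np.ndarray | None = None,
    subject_ids: np.ndarray | None = None,
) -> GrexPrediction:
    """Predict the genetic component of expression for new subjects.

    GReX is the genotype term only — no intercepts or covariates — so
    predictions are comparable across datasets that lack covariate
    harmonization.  When proportions are supplied the tissue-level GReX is
    the proportion-weighted mixture of the two cell-type predictions.
    """
    X_new = np.asarray(X_new, dtype=float)
    if isinstance(model, TissueModel):
        b_u = b_v = model.b
    else:
        b_u, b_v = model.b_u, model.b_v
    if X_new.shape[1] != len(b_u):
        raise ValueError(
            f"{model.gene_id}: expected {len(b_u)} model SNPs, got {X_new.shape[1]}")
    y_u = X_new @ b_u
    y_v = X_new @ b_v
    tissue = None
    if pi_new is not None:
        pi_new = np.asarray(pi_new, dtype=float)
        tissue = pi_new * y_u + (1 - pi_new) * y_v
    return GrexPrediction(y_u=y_u, y_v=y_v, tissue=tissue, subject_ids=subject_ids)


def evaluate_prediction(models_by_method: dict, y_true: np.ndarray,
                        X: np.ndarray, pi: np.ndarray,
                        include_means: bool = True):
    """Held-out prediction accuracy per gene and paired method comparison.

    ``models_by_method`` maps method name -> list of per-gene models (same
    gene order as the columns of ``y_true``).  Accuracy is the Pearson r
    between the predicted tissue-level expression — the proportion-weighted
    mixture of the per-cell-type predictions, including the per-cell-type
    means when ``include_means`` (a Pearson r is unaffected by the constant
    intercept of a tissue-level model, but the proportion-weighted mean
    difference of a cell-type model is genuinely predictive) — and observed
    expression.  Genes with zero-variance predictions get r = 0 and a flag.
    Methods are compared pairwise by the two-sided Wilcoxon signed-rank
    test on their r vectors.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    pi = np.asarray(pi, dtype=float)
    rows = {}
    flags = {}
    for method, models in models_by_method.items():
        rs, fl = [], []
        for g, model in enumerate(models):
            pred = predict_grex(model, X, pi_new=pi).tissue
            if include_means and not isinstance(model, TissueModel):
                pred = pred + pi * model.a_u + (1 - pi) * model.a_v
            if np.std(pred) < 1e-12 or np.std(y_true[:, g]) < 1e-12:
                rs.append(0.0)
                fl.append(True)
            else:
                rs.append(float(stats.pearsonr(pred, y_true[:, g])[0]))
                fl.append(False)
        rows[method] = np.asarray(rs)
        flags[method] = np.asarray(fl)
    comparisons = {}
    names = list(rows)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = rows[names[i]] - rows[names[j]]
            if np.allclose(d, 0):
                pval = 1.0
            else:
                pval = float(stats.wilcoxon(rows[names[i]], rows[names[j]],
                                            zero_method="wilcox").pvalue)
            comparisons[(names[i], names[j])] = pval
    return rows, flags, comparisons
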