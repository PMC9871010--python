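"""Association testing of predicted cell-type GReX with a phenotype.

Because the two cell-type GReX vectors are predicted from the same
genotypes with jointly learned weights, each may carry leaked signal from
the other; naive per-cell-type inference therefore inflates type I error.
The test performed here targets the composite null

    H0: the GReX is not associated with the phenotype in any cell type,

which is robust to such leakage.  Per-cell-type effects are estimated in a
joint generalized linear model when the two GReX vectors are
distinguishable, or in separate models when they are (near-)collinear, and
the two Wald p-values are aggregated with the Cauchy combination (ACAT),
which remains valid for dependent p-values.  Genes whose training selected
the nonspecific model have identical weights in both cell types; for them
the pipeline reduces exactly to a single tissue-level test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grex import CellTypePredictionModel, GrexPrediction, TissueModel, predict_grex

__all__ = [
    "AssociationResult",
    "cell_level_test",
    "cauchy_combine",
    "associate_gene",
    "transcriptome_wide",
]

P_CLIP = 1e-15
COLLINEARITY_R = 0.99


@dataclass
class AssociationResult:
    gene_id: str
    mode: str  # "separate" | "joint" | "single"
    effect_u: float
    se_u: float
    p_u: float
    effect_v: float
    se_v: float
    p_v: float
    t_cauchy: float
    p_tissue: float
    testable: bool = True


def _glm_family(family: str):
    if family == "binomial":
        return sm.families.Binomial()
    if family == "gaussian":
        return sm.families.Gaussian()
    raise ValueError(f"unknown family {family!r}")


def _glm_fit(d, cols, family):
    model = sm.GLM(d, cols, family=_glm_family(family))
    res = model.fit()
    if family == "binomial":
        mu = res.fittedvalues
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
            raise RuntimeError("perfect separation in logistic fit")
    return res


def cell_level_test(
    grex: GrexPrediction,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "binomial",
):
    """Wald tests of per-cell-type GReX effects on the phenotype.

    Fits a joint GLM ``g(d) = eta0 + eta_u y_u + eta_v y_v + covariates``
    unless the two GReX vectors are nearly collinear (|r| >= 0.99) or one
    is degenerate, in which case two separate single-GReX models are fit.
    Returns effects, standard errors, two-sided p-values and the mode used.
    """
    d = np.asarray(phenotype, dtype=float)
    y_u, y_v = grex.y_u, grex.y_v
    su, sv = float(np.std(y_u)), float(np.std(y_v))
    if su == 0 and sv == 0:
        return None  # untestable: no genetic variation in either prediction
    base = [np.ones_like(d)]
    if covariates is not None:
        base.append(np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(len(d), -1))
    base = np.column_stack(base)

    if su > 0 and sv > 0:
        r = float(np.corrcoef(y_u, y_v)[0, 1])
        joint = abs(r) < COLLINEARITY_R
    else:
        joint = False  # one degenerate prediction: test each on its own

    def single(y):
        if np.std(y) == 0:
            return 0.0, np.inf, 1.0
        res = _glm_fit(d, np.column_stack([base, y]), family)
        return float(res.params[-1]), float(res.bse[-1]), float(res.pvalues[-1])

    if joint:
        res = _glm_fit(d, np.column_stack([base, y_u, y_v]), family)
        eff_u, se_u, p_u = float(res.params[-2]), float(res.bse[-2]), float(res.pvalues[-2])
        eff_v, se_v, p_v = float(res.params[-1]), float(res.bse[-1]), float(res.pvalues[-1])
        mode = "joint"
    else:
        eff_u, se_u, p_u = single(y_u)
        eff_v, se_v, p_v = single(y_v)
        mode = "separate"
    return eff_u, se_u, p_u, eff_v, se_v, p_v, mode


def cauchy_combine(p_u: float, p_v: float, weights=(0.5, 0.5)) -> tuple[float, float]:
    """Cauchy combination (ACAT) of two possibly dependent p-values.

    ``T = w_u tan(pi (0.5 - p_u)) + w_v tan(pi (0.5 - p_v))`` and the
    combined p-value is ``0.5 - arctan(T) / pi``.  With the default equal
    weights (summing to 1) the combination satisfies the identity
    ``combine(p, p) = p`` and always lies between the two inputs; passing
    ``weights=(1, 1)`` gives the unweighted two-term sum evaluated against
    the standard Cauchy tail, which is anti-conservative under dependence
    and provided only for comparison.
    """
    pu = float(np.clip(p_u, P_CLIP, 1 - P_CLIP))
    pv = float(np.clip(p_v, P_CLIP, 1 - P_CLIP))
    t = weights[0] * np.tan(np.pi * (0.5 - pu)) + weights[1] * np.tan(np.pi * (0.5 - pv))
    if not np.isfinite(t):
        raise FloatingPointError("non-finite Cauchy statistic")
    p_tissue = 0.5 - np.arctan(t) / np.pi
    return float(t), float(min(max(p_tissue, P_CLIP), 1.0))


def associate_gene(
    model: CellTypePredictionModel | TissueModel,
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "binomial",
    weights=(0.5, 0.5),
) -> AssociationResult:
    """Test one gene's predicted GReX against the phenotype.

    Cell-type-specific models run the two-cell-type test and Cauchy
    combination; nonspecific (or tissue-level) models reduce to a single
    tissue-level GLM whose p-value is reported for all slots.
    """
    gene_id = model.gene_id
    if getattr(model, "untrainable", False):
        return AssociationResult(gene_id, "single", *[np.nan] * 6,
                                 t_cauchy=np.nan, p_tissue=np.nan, testable=False)
    grex = predict_grex(model, genotypes)
    nonspecific = isinstance(model, TissueModel) or model.model_type == "nonspecific"
    try:
        if nonspecific:
            if np.std(grex.y_u) == 0:
                return AssociationResult(gene_id, "single", *[np.nan] * 6,
                                         t_cauchy=np.nan, p_tissue=np.nan,
                                         testable=False)
            base = [np.ones_like(np.asarray(phenotype, dtype=float))]
            if covariates is not None:
                base.append(np.atleast_2d(np.asarray(covariates, dtype=float))
                            .reshape(len(phenotype), -1))
            cols = np.column_stack(base + [grex.y_u])
            res = _glm_fit(np.asarray(phenotype, dtype=float), cols, family)
            eff, se, p = float(res.params[-1]), float(res.bse[-1]), float(res.pvalues[-1])
            return AssociationResult(gene_id, "single", eff, se, p, eff, se, p,
                                     t_cauchy=np.nan, p_tissue=p)
        out = cell_level_test(grex, phenotype, covariates, family)
        if out is None:
            return AssociationResult(gene_id, "separate", *[np.nan] * 6,
                                     t_cauchy=np.nan, p_tissue=np.nan,
                                     testable=False)
        eff_u, se_u, p_u, eff_v, se_v, p_v, mode = out
        t, p_tissue = cauchy_combine(p_u, p_v, weights)
        return AssociationResult(gene_id, mode, eff_u, se_u, p_u,
                                 eff_v, se_v, p_v, t_cauchy=t, p_tissue=p_tissue)
    except RuntimeError as exc:
        raise RuntimeError(f"{gene_id}: {exc}") from exc


def transcriptome_wide(results, fwer: float = 0.05, fdr: float = 0.10) -> pd.DataFrame:
    """Multiple-testing annotation across the tested transcriptome.

    The Bonferroni threshold is ``fwer / n_testable``; Benjamini-Hochberg
    step-up runs at the requested FDR.  Untestable genes (no predictive
    SNPs) are excluded from both denominators and flagged.
    """
    rows = []
    for r in results:
        rows.append({
            "gene_id": r.gene_id, "mode": r.mode, "effect_u": r.effect_u,
            "se_u": r.se_u, "p_u": r.p_u, "effect_v": r.effect_v,
            "se_v": r.se_v, "p_v": r.p_v, "t_cauchy": r.t_cauchy,
            "p_tissue": r.p_tissue, "testable": r.testable,
        })
    table = pd.DataFrame(rows)
    testable = table["testable"].to_numpy(dtype=bool)
    n_testable = int(testable.sum())
    if n_testable < 1:
        raise ValueError("no testable genes")
    threshold = fwer / n_testable
    table["bonferroni_threshold"] = threshold
    table["bonferroni_significant"] = testable & (table["p_tissue"] < threshold)
    from statsmodels.stats.multitest import multipletests

    bh = np.zeros(len(table), dtype=bool)
    if n_testable:
        rej, *_ = multipletests(table.loc[testable, "p_tissue"], alpha=fdr,
                                method="fdr_bh")
        bh[np.flatnonzero(testable)] = rej
    table["bh_significant"] = bh
    return table.sort_values("p_tissue", na_position="last").reset_index(drop=True)
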