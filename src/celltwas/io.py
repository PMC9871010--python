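"""File formats, genotype-model harmonization and model stores.

Genotype input is either VCF (dosage ``DS`` preferred over hard ``GT``
calls when both are present; sporadic missing genotypes are mean-imputed
per SNP) or a TSV dosage matrix with one row per SNP.  Trained prediction
models are stored as TSV or SQLite with one row per (gene, SNP) carrying
the two cell-type weights; nonspecific models can be exported to a
PredictDB-style single-weight schema.

Harmonization aligns GWAS genotypes to the alleles a model was trained on:
exact ref/effect matches pass through, allele-reversed SNPs have their
dosage flipped ``d -> 2 - d``, and strand-ambiguous pairs (A/T, C/G) are
dropped by default because their orientation cannot be resolved without
frequency information.  SNPs are keyed by chrom:pos:sorted-alleles with an
rsid fallback, which is robust to identifier drift across genome builds.
"""

from __future__ import annotations

import sqlite3
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grex import CellTypePredictionModel, TissueModel

__all__ = [
    "HarmonizedGenotypes",
    "read_genotypes",
    "write_genotypes_tsv",
    "harmonize",
    "write_models_tsv",
    "read_models_tsv",
    "write_models_sqlite",
    "export_predictdb",
    "read_expression_tsv",
    "read_prior_tsv",
    "read_phenotype_tsv",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}
META_COLS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class HarmonizedGenotypes:
    """Dosages aligned to model SNPs, with per-SNP provenance flags."""

    subject_ids: np.ndarray
    dosages: np.ndarray          # subjects x retained model SNPs
    snp_ids: list
    provenance: dict             # snp_id -> {"matched", "swapped", "dropped"}


def _impute_missing(dos: np.ndarray) -> tuple[np.ndarray, int]:
    miss = ~np.isfinite(dos)
    n_miss = int(miss.sum())
    if n_miss:
        means = np.nanmean(np.where(miss, np.nan, dos), axis=0)
        means = np.where(np.isfinite(means), means, 0.0)
        dos = np.where(miss, means[None, :], dos)
    return dos, n_miss


def read_genotypes(path, fmt: str | None = None):
    """Read genotype dosages into (meta DataFrame, subjects x SNPs array, ids).

    ``fmt`` is inferred from the extension when omitted.  VCF coordinates
    are 1-based per the standard; ``DS`` is used when present, otherwise
    dosage is the count of alt alleles in ``GT``.  Missing entries are
    mean-imputed per SNP with a warning reporting the count.
    """
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(path)
    subject_ids = np.asarray(vcf.samples)
    meta, rows = [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValueError(f"record {i + 1}: only biallelic sites supported")
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where(dos < 0, np.nan, dos)
        else:
            gt = np.asarray(var.genotypes, dtype=float)
            alleles = gt[:, :2]
            dos = np.where((alleles < 0).any(axis=1), np.nan,
                           alleles.clip(0).sum(axis=1))
        meta.append({"snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                     "chrom": str(var.CHROM), "pos": int(var.POS),
                     "ref": var.REF, "alt": var.ALT[0]})
        rows.append(dos)
    dosages = np.asarray(rows, dtype=float).T  # subjects x snps
    dosages, n_miss = _impute_missing(dosages)
    if n_miss:
        warnings.warn(f"mean-imputed {n_miss} missing genotype entries")
    if np.any(dosages < 0) or np.any(dosages > 2):
        raise ValueError("dosages outside [0, 2]")
    return pd.DataFrame(meta), dosages, subject_ids


def _read_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV lacks columns {missing}")
    meta = df[META_COLS].copy()
    meta["pos"] = meta["pos"].astype(int)
    sample_cols = [c for c in df.columns if c not in META_COLS]
    dosages = df[sample_cols].to_numpy(dtype=float).T
    dosages, n_miss = _impute_missing(dosages)
    if n_miss:
        warnings.warn(f"mean-imputed {n_miss} missing genotype entries")
    if np.any(dosages < 0) or np.any(dosages > 2):
        raise ValueError("dosages outside [0, 2]")
    return meta, dosages, np.asarray(sample_cols)


def write_genotypes_tsv(path, meta: pd.DataFrame, dosages: np.ndarray,
                        subject_ids) -> None:
    out = meta.copy()
    for j, sid in enumerate(subject_ids):
        out[str(sid)] = dosages[:, j]
    out.to_csv(path, sep="\t", index=False)


def _key(chrom, pos, a1, a2):
    return f"{chrom}:{pos}:{':'.join(sorted((str(a1), str(a2))))}"


def harmonize(model_snps: pd.DataFrame, geno_meta: pd.DataFrame,
              dosages: np.ndarray, subject_ids,
              drop_ambiguous: bool = True) -> HarmonizedGenotypes:
    """Align genotype dosages to model SNPs and alleles.

    ``model_snps`` needs columns snp_id, chrom, pos, ref, eff.  A SNP whose
    genotype ref/alt equal the model ref/eff is ``matched``; reversed
    alleles are ``swapped`` and the dosage transformed ``d -> 2 - d`` (the
    algebraic equivalent of flipping the weight sign, applied exactly
    once); ambiguous or unmatched SNPs are ``dropped``.  Harmonizing
    already-aligned data is a no-op, so the operation is an involution.
    """
    if geno_meta["snp_id"].duplicated().any():
        dups = geno_meta.loc[geno_meta["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate SNP ids in genotypes: {dups}")
    if model_snps["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP ids in model")

    by_key, by_rsid = {}, {}
    for j, row in geno_meta.reset_index(drop=True).iterrows():
        by_key[_key(row["chrom"], row["pos"], row["ref"], row["alt"])] = j
        by_rsid[str(row["snp_id"])] = j

    provenance, keep_cols, keep_ids, flip = {}, [], [], []
    for _, m in model_snps.iterrows():
        sid = str(m["snp_id"])
        alleles = frozenset((str(m["ref"]), str(m["eff"])))
        if drop_ambiguous and alleles in _AMBIGUOUS:
            provenance[sid] = "dropped"
            continue
        j = by_key.get(_key(m["chrom"], m["pos"], m["ref"], m["eff"]))
        if j is None:
            j = by_rsid.get(sid)
        if j is None:
            provenance[sid] = "dropped"
            continue
        g = geno_meta.iloc[j]
        if g["ref"] == m["ref"] and g["alt"] == m["eff"]:
            provenance[sid] = "matched"
            flip.append(False)
        elif g["ref"] == m["eff"] and g["alt"] == m["ref"]:
            provenance[sid] = "swapped"
            flip.append(True)
        else:
            provenance[sid] = "dropped"
            continue
        keep_cols.append(j)
        keep_ids.append(sid)
    out = dosages[:, keep_cols].copy() if keep_cols else np.zeros((dosages.shape[0], 0))
    for k, do_flip in enumerate(flip):
        if do_flip:
            out[:, k] = 2.0 - out[:, k]
    return HarmonizedGenotypes(subject_ids=np.asarray(subject_ids),
                               dosages=out, snp_ids=keep_ids,
                               provenance=provenance)


def _model_rows(model) -> list[dict]:
    rows = []
    if isinstance(model, TissueModel):
        w1 = w2 = model.b
        mtype = "nonspecific"
    else:
        w1, w2 = model.b_u, model.b_v
        mtype = model.model_type
    for j, sid in enumerate(model.snp_ids):
        if w1[j] == 0 and w2[j] == 0:
            continue  # zero-weight SNPs are omitted from storage
        rows.append({"gene_id": model.gene_id, "snp_id": sid,
                     "weight_cell1": w1[j], "weight_cell2": w2[j],
                     "model_type": mtype})
    return rows


def _extra_rows(models) -> list[dict]:
    out = []
    for m in models:
        b = m.b if isinstance(m, TissueModel) else m.b_u
        ci = getattr(m, "diff_ci", None)
        n_excl = 0
        if ci is not None:
            fin = np.isfinite(ci).all(axis=1)
            n_excl = int(np.sum((ci[fin, 0] > 0) | (ci[fin, 1] < 0)))
        out.append({"gene_id": m.gene_id,
                    "n_snps": int(np.sum(b != 0)),
                    "cv_performance": float(m.cv_performance),
                    "model_type": ("nonspecific" if isinstance(m, TissueModel)
                                   else m.model_type),
                    "n_ci_excluding_zero": n_excl,
                    "untrainable": bool(getattr(m, "untrainable", False))})
    return out


def write_models_tsv(path_prefix, models, snp_meta: pd.DataFrame | None = None) -> None:
    """Write weights and per-gene summary tables as <prefix>.weights.tsv / .extra.tsv."""
    weights = pd.DataFrame([r for m in models for r in _model_rows(m)],
                           columns=["gene_id", "snp_id", "weight_cell1",
                                    "weight_cell2", "model_type"])
    if snp_meta is not None:
        weights = weights.merge(
            snp_meta.rename(columns={"alt": "eff_allele", "ref": "ref_allele"}),
            on="snp_id", how="left")
    weights.to_csv(f"{path_prefix}.weights.tsv", sep="\t", index=False)
    pd.DataFrame(_extra_rows(models)).to_csv(f"{path_prefix}.extra.tsv",
                                             sep="\t", index=False)


def read_models_tsv(path_prefix) -> list[CellTypePredictionModel]:
    weights = pd.read_csv(f"{path_prefix}.weights.tsv", sep="\t")
    models = []
    for gene_id, grp in weights.groupby("gene_id", sort=False):
        snp_ids = grp["snp_id"].tolist()
        models.append(CellTypePredictionModel(
            gene_id=str(gene_id), snp_ids=snp_ids,
            b_u=grp["weight_cell1"].to_numpy(float),
            b_v=grp["weight_cell2"].to_numpy(float),
            a_u=0.0, a_v=0.0, c=np.zeros(0),
            model_type=str(grp["model_type"].iloc[0]),
        ))
    return models


def write_models_sqlite(path, models) -> None:
    con = sqlite3.connect(path)
    try:
        pd.DataFrame([r for m in models for r in _model_rows(m)]).to_sql(
            "weights", con, index=False, if_exists="replace")
        pd.DataFrame(_extra_rows(models)).to_sql(
            "extra", con, index=False, if_exists="replace")
    finally:
        con.close()


def export_predictdb(path, models) -> int:
    """Export nonspecific models to a single-weight PredictDB-style SQLite.

    Cell-type-specific models have two weight vectors and are skipped (the
    single-weight schema cannot represent them); returns the number of
    genes exported.
    """
    rows = []
    for m in models:
        mtype = "nonspecific" if isinstance(m, TissueModel) else m.model_type
        if mtype != "nonspecific":
            continue
        for r in _model_rows(m):
            rows.append({"gene": r["gene_id"], "rsid": r["snp_id"],
                         "weight": r["weight_cell1"]})
    con = sqlite3.connect(path)
    try:
        pd.DataFrame(rows, columns=["gene", "rsid", "weight"]).to_sql(
            "weights", con, index=False, if_exists="replace")
    finally:
        con.close()
    return len({r["gene"] for r in rows})


def read_expression_tsv(path):
    """Signature/bulk expression TSV: first column sample id, gene columns."""
    df = pd.read_csv(path, sep="\t")
    sample_ids = df.iloc[:, 0].to_numpy()
    genes = df.columns[1:].to_numpy()
    return df.iloc[:, 1:].to_numpy(dtype=float), genes, sample_ids


def read_prior_tsv(path):
    """Two-column TSV (sample_id, score) of raw prior enrichment scores."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("prior TSV needs (sample_id, score) columns")
    return df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(dtype=float)


def read_phenotype_tsv(path, phenotype_col: str = "phenotype"):
    """Phenotype/covariate TSV with subject_id, phenotype and covariate columns."""
    df = pd.read_csv(path, sep="\t")
    if phenotype_col not in df.columns:
        raise KeyError(f"phenotype column {phenotype_col!r} not found in {path}")
    subject_ids = df.iloc[:, 0].to_numpy()
    d = df[phenotype_col].to_numpy(dtype=float)
    cov_cols = [c for c in df.columns[1:] if c != phenotype_col]
    Z = df[cov_cols].to_numpy(dtype=float) if cov_cols else None
    return subject_ids, d, Z, cov_cols
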