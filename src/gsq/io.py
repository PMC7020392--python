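"""Genotype/phenotype containers, file formats, SNP QC and phenotype pre-correction.

Genotypes are held as an individuals x markers matrix of additive allele
codes (AA=0, AB=1, BB=2), with missing calls stored as -1 internally and
exposed through a boolean mask. Phenotypes live in a plain pandas DataFrame
with one row per individual, a block column and one column per trait.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x markers additive codes in {0,1,2}, missing = -1.

    Parameters
    ----------
    codes
        Integer matrix, shape (n_individuals, n_markers).
    individual_ids
        Unique labels, length n_individuals.
    marker_meta
        DataFrame with columns ``marker``, ``chrom``, ``pos`` (and optionally
        ``ref``/``alt``), one row per marker, in column order of ``codes``.
    """

    codes: np.ndarray
    individual_ids: list[str]
    marker_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x markers)")
        self.individual_ids = [str(i) for i in self.individual_ids]
        if len(self.individual_ids) != self.codes.shape[0]:
            raise ValueError("individual_ids length does not match codes rows")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        if self.marker_meta is None:
            n = self.codes.shape[1]
            self.marker_meta = pd.DataFrame(
                {"marker": [f"M{j}" for j in range(n)],
                 "chrom": ["1"] * n,
                 "pos": np.arange(1, n + 1)}
            )
        self.marker_meta = self.marker_meta.reset_index(drop=True)
        if len(self.marker_meta) != self.codes.shape[1]:
            raise ValueError("marker_meta length does not match codes columns")
        bad = (self.codes < MISSING) | (self.codes > 2)
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2} or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker over non-missing calls."""
        c = self.codes.astype(float)
        c[c == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(c, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.codes[:, idx],
            list(self.individual_ids),
            self.marker_meta.iloc[idx].reset_index(drop=True),
        )

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.codes[idx, :],
            [self.individual_ids[i] for i in idx],
            self.marker_meta,
        )


@dataclass
class AdjustedPhenotype:
    """Pre-corrected phenotype vector y* (block and structure effects removed)."""

    y_star: np.ndarray
    trait: str
    individual_ids: list[str]
    correction_terms: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "csv012") -> GenotypeMatrix:
    """Read genotypes from VCF (biallelic GT) or 0/1/2 CSV.

    CSV layout: index column of individual ids, one column per marker id;
    cells are 0/1/2 or NA. VCF: biallelic records only; multi-allelic
    records are skipped with a warning.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "csv012":
        return _read_csv012(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    cols, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%s", var.CHROM, var.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.copy()
        col = np.full(gt.shape, MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        cols.append(col)
        meta.append((var.ID or f"{var.CHROM}_{var.POS}", str(var.CHROM), int(var.POS),
                     var.REF, var.ALT[0]))
    if not cols:
        raise ValueError(f"no usable biallelic records in {path}")
    codes = np.column_stack(cols)
    mm = pd.DataFrame(meta, columns=["marker", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(codes, ids, mm)


def _read_csv012(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    codes = df.to_numpy(dtype=float)
    out = np.full(codes.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(codes)
    out[ok] = codes[ok].astype(np.int8)
    mm = pd.DataFrame({"marker": df.columns.astype(str),
                       "chrom": ["1"] * df.shape[1],
                       "pos": np.arange(1, df.shape[1] + 1)})
    return GenotypeMatrix(out, list(df.index.astype(str)), mm)


def write_csv012(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.codes.astype(float), index=geno.individual_ids,
                      columns=geno.marker_meta["marker"])
    df[geno.codes == MISSING] = np.nan
    df.to_csv(path, na_rep="NA")


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT fields (unphased)."""
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    mm = geno.marker_meta
    ref = mm["ref"] if "ref" in mm else pd.Series(["A"] * geno.n_markers)
    alt = mm["alt"] if "alt" in mm else pd.Series(["G"] * geno.n_markers)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = mm["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individual_ids) + "\n")
        for j in range(geno.n_markers):
            row = [str(mm["chrom"].iloc[j]), str(int(mm["pos"].iloc[j])),
                   str(mm["marker"].iloc[j]), str(ref.iloc[j]), str(alt.iloc[j]),
                   ".", "PASS", ".", "GT"]
            row += [gtmap[int(v)] for v in geno.codes[:, j]]
            fh.write("\t".join(row) + "\n")


def read_pedigree(path) -> pd.DataFrame:
    """Read 3-column pedigree CSV (id, dam, sire; '0' = unknown)."""
    ped = pd.read_csv(path, dtype=str).fillna("0")
    ped.columns = ["id", "dam", "sire"]
    return ped


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_markers(geno: GenotypeMatrix, call_rate_min: float = 0.7,
                   maf_min: float = 0.05) -> GenotypeMatrix:
    """Retain markers with call rate strictly above ``call_rate_min`` and MAF
    strictly above ``maf_min`` (MAF on non-missing calls only).

    Returns the filtered panel; removal counts per criterion are logged and
    attached as ``.filter_report`` on the result.
    """
    cr = geno.call_rate()
    maf = geno.maf()
    keep_cr = cr > call_rate_min
    keep_maf = np.nan_to_num(maf, nan=0.0) > maf_min
    keep = keep_cr & keep_maf
    report = {
        "n_input": geno.n_markers,
        "removed_call_rate": int((~keep_cr).sum()),
        "removed_maf": int((keep_cr & ~keep_maf).sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        warnings.warn("all markers removed by QC filters; panel is empty")
    logger.info("marker QC: %s", report)
    out = geno.subset_markers(np.where(keep)[0])
    out.filter_report = report  # type: ignore[attr-defined]
    return out


def impute_knn(geno: GenotypeMatrix, k_neighbors: int = 5,
               l_sites: int = 30) -> GenotypeMatrix:
    """LD-kNN imputation of missing calls.

    For each marker with missing calls, the ``l_sites`` markers most
    correlated with it (|Pearson r| of codes) define the distance space;
    each missing call is filled by a 1/distance-weighted vote of the
    ``k_neighbors`` nearest individuals with an observed call, distance
    being the mean absolute code difference over sites non-missing in both.
    Ties vote for the lower code. Observed calls are never altered.
    """
    if geno.n_individuals < k_neighbors + 1:
        raise ValueError("need at least k_neighbors+1 individuals")
    codes = geno.codes.astype(float)
    codes[codes == MISSING] = np.nan
    if not np.isnan(codes).any():
        return geno

    # marker-marker |r| on mean-filled codes (missingness is sparse post-QC)
    filled = codes.copy()
    col_mean = np.nanmean(filled, axis=0)
    nan_cols = np.isnan(col_mean)
    col_mean[nan_cols] = 0.0
    inds = np.where(np.isnan(filled))
    filled[inds] = np.take(col_mean, inds[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = filled.std(axis=0)
        z = (filled - filled.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        corr = np.abs(z.T @ z) / filled.shape[0]

    out = geno.codes.copy()
    n, p = codes.shape
    for j in np.unique(np.where(np.isnan(codes))[1]):
        col = codes[:, j]
        miss_rows = np.where(np.isnan(col))[0]
        obs_rows = np.where(~np.isnan(col))[0]
        if obs_rows.size == 0:
            fill = int(round(float(col_mean[j]))) if not nan_cols[j] else 0
            logger.warning("marker %d missing in all individuals; filled with %d",
                           j, fill)
            out[miss_rows, j] = fill
            continue
        r = corr[:, j].copy()
        r[j] = -np.inf  # exclude self
        l_eff = min(l_sites, p - 1)
        sites = np.argpartition(r, -l_eff)[-l_eff:]
        sub = codes[:, sites]
        for i in miss_rows:
            diff = np.abs(sub[obs_rows] - sub[i])
            shared = ~np.isnan(diff)
            with np.errstate(invalid="ignore"):
                dist = np.where(shared.sum(axis=1) > 0,
                                np.nansum(np.where(shared, diff, 0.0), axis=1)
                                / np.maximum(shared.sum(axis=1), 1),
                                np.inf)
            k_eff = min(k_neighbors, obs_rows.size)
            nearest = np.argpartition(dist, k_eff - 1)[:k_eff]
            w = 1.0 / (dist[nearest] + 1e-6)
            votes = np.zeros(3)
            for wt, row in zip(w, obs_rows[nearest]):
                votes[int(col[row])] += wt
            out[i, j] = int(np.argmax(votes))  # argmax takes lower code on ties
    return GenotypeMatrix(out, list(geno.individual_ids), geno.marker_meta)


# ---------------------------------------------------------------------------
# Phenotype pre-correction
# ---------------------------------------------------------------------------

def adjust_phenotypes(pheno: pd.DataFrame, trait: str, use_structure: bool = False,
                      structure_covariates: np.ndarray | None = None,
                      block_col: str = "block", id_col: str = "id") -> AdjustedPhenotype:
    """Pre-correct a trait for block (and optionally structure) effects.

    Fits an ordinary linear model of the trait on block indicators (plus the
    supplied structure covariate columns when ``use_structure``) and returns
    the residuals as y*. Ordinal traits are treated on their numeric scale.
    Rank-deficient designs are handled by least-squares pseudo-inverse with a
    warning.
    """
    if trait not in pheno.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    y = pheno[trait].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    blocks = pd.get_dummies(pheno[block_col].astype(str), drop_first=True)
    X = np.column_stack([np.ones(len(y)), blocks.to_numpy(dtype=float)])
    if use_structure:
        if structure_covariates is None:
            raise ValueError("use_structure=True requires structure_covariates")
        S = np.asarray(structure_covariates, dtype=float)
        if S.ndim == 1:
            S = S[:, None]
        X = np.column_stack([X, S])
    rank = np.linalg.matrix_rank(X[ok])
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design in phenotype adjustment; "
                      "using pseudo-inverse fit")
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    resid = np.full(len(y), np.nan)
    resid[ok] = y[ok] - X[ok] @ beta
    terms = pd.DataFrame({"term": [f"b{i}" for i in range(len(beta))], "coef": beta})
    ids = list(pheno[id_col].astype(str)) if id_col in pheno else [str(i) for i in range(len(y))]
    return AdjustedPhenotype(resid, trait, ids, terms)
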