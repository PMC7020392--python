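"""Descriptive population-genetic statistics: heterozygosity, F_ST, LD.

F_ST uses the Weir & Cockerham (1984) theta estimator (ratio of sums over
markers), computed from unphased genotype codes. LD is the composite
genotypic r-squared (squared Pearson correlation of allele counts), the
appropriate measure for unphased SNP data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass
class DiversitySummary:
    he_per_marker: np.ndarray
    ho_per_marker: np.ndarray

    @property
    def he(self) -> float:
        return float(np.nanmean(self.he_per_marker))

    @property
    def ho(self) -> float:
        return float(np.nanmean(self.ho_per_marker))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"he": self.he_per_marker, "ho": self.ho_per_marker})


def heterozygosity(geno: GenotypeMatrix) -> DiversitySummary:
    """Observed (fraction of hets) and expected (2p(1-p)) heterozygosity.

    Missing calls are excluded per marker; panel values are unweighted means
    over markers.
    """
    if geno.n_markers == 0 or geno.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    c = geno.codes.astype(float)
    c[c == MISSING] = np.nan
    ho = np.nanmean(c == 1, axis=0)
    p = np.nanmean(c, axis=0) / 2.0
    he = 2.0 * p * (1.0 - p)
    return DiversitySummary(he, ho)


def _wc_components(codes: np.ndarray, groups: np.ndarray):
    """Per-marker a, b, c variance components of Weir & Cockerham (1984)."""
    labels = np.unique(groups)
    r = len(labels)
    n_i = np.zeros((r, codes.shape[1]))
    p_i = np.zeros((r, codes.shape[1]))
    h_i = np.zeros((r, codes.shape[1]))
    c = codes.astype(float)
    c[c == MISSING] = np.nan
    for k, g in enumerate(labels):
        sub = c[groups == g]
        n_i[k] = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.nansum(sub, axis=0) / (2 * n_i[k])
            h_i[k] = np.nansum(sub == 1, axis=0) / n_i[k]
    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_i ** 2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        cc = hbar / 2
    return a, b, cc


def weir_cockerham_fst(geno: GenotypeMatrix, group_labels) -> float:
    """Multi-population theta, ratio of sums over markers."""
    groups = np.asarray(group_labels)
    a, b, c = _wc_components(geno.codes, groups)
    denom = np.nansum(a + b + c)
    if denom == 0:
        return np.nan
    return float(np.nansum(a) / denom)


def pairwise_fst(geno: GenotypeMatrix, group_labels) -> pd.DataFrame:
    """Symmetric matrix of pairwise Weir–Cockerham F_ST between groups."""
    groups = np.asarray(group_labels)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    out = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            sel = (groups == labels[i]) | (groups == labels[j])
            sub = geno.subset_individuals(np.where(sel)[0])
            out[i, j] = out[j, i] = weir_cockerham_fst(sub, groups[sel])
    return pd.DataFrame(out, index=labels, columns=labels)


def ld_r2(geno: GenotypeMatrix, marker_pairs) -> pd.DataFrame:
    """Composite LD r^2 (squared Pearson correlation of codes) per pair.

    Pairs must lie on a single chromosome each; monomorphic markers yield a
    missing value.
    """
    chrom = geno.marker_meta["chrom"].astype(str).to_numpy()
    rows = []
    c = geno.codes.astype(float)
    c[c == MISSING] = np.nan
    for a, b in marker_pairs:
        if chrom[a] != chrom[b]:
            raise ValueError(f"markers {a},{b} are on different chromosomes")
        x, y = c[:, a], c[:, b]
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.std() == 0 or y.std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append({"marker_a": a, "marker_b": b, "chrom": chrom[a], "r2": r2})
    return pd.DataFrame(rows)
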