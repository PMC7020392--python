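"""Relationship matrices: pedigree numerator A, realized marker kinship, and
the QTL-genotype covariance built from GWAS-significant SNPs.

All three are returned as :class:`RelationshipMatrix`, a labeled symmetric
PSD matrix. A small ridge (``epsilon * I``) is available to keep
near-singular matrices (for example a Q built from a handful of markers)
usable inside the Gibbs sampler.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

DEFAULT_EPSILON = 1e-6


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    ids: list[str]
    kind: str  # pedigreeA | kinshipK | qtlQ | markerG
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids length does not match matrix")
        asym = np.abs(self.values - self.values.T).max() if self.values.size else 0.0
        if asym > 1e-10:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.2e})")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def regularized(self, epsilon: float = DEFAULT_EPSILON) -> "RelationshipMatrix":
        return RelationshipMatrix(self.values + epsilon * np.eye(self.n),
                                  list(self.ids), self.kind,
                                  self.epsilon + epsilon)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def submatrix(self, ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]

    def cross_block(self, row_ids, col_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.ids)}
        r = np.array([pos[i] for i in row_ids])
        c = np.array([pos[i] for i in col_ids])
        return self.values[np.ix_(r, c)]

    def to_csv(self, path, sidecar: bool = True) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)
        if sidecar:
            meta = {"kind": self.kind, "epsilon": self.epsilon}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh)


def pedigree_A(ped: pd.DataFrame, op_sib_coefficient: float = 0.25) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``ped`` has columns id, dam, sire with "0" meaning unknown. Parents must
    appear before their offspring. Open-pollinated families (shared dam,
    sires unknown) get an additive relationship among maternal sibs of
    ``op_sib_coefficient`` — 0.25 for pure half-sibs, larger to reflect a
    selfing or full-sib admixture in the pollen cloud.
    """
    ids = list(ped["id"].astype(str))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    pos = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    dam = np.full(n, -1, dtype=int)
    sire = np.full(n, -1, dtype=int)
    for i, (d, s) in enumerate(zip(ped["dam"].astype(str), ped["sire"].astype(str))):
        for parent, arr in ((d, dam), (s, sire)):
            if parent not in ("0", "nan", ""):
                if parent not in pos:
                    raise ValueError(f"parent {parent!r} not in pedigree")
                j = pos[parent]
                if j >= i:
                    raise ValueError("parents must precede offspring "
                                     f"(individual {ids[i]!r})")
                arr[i] = j
    A = np.zeros((n, n))
    for i in range(n):
        d, s = dam[i], sire[i]
        a_ds = A[d, s] if (d >= 0 and s >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_ds
        for j in range(i):
            val = 0.0
            if d >= 0:
                val += 0.5 * A[j, d]
            if s >= 0:
                val += 0.5 * A[j, s]
            A[i, j] = A[j, i] = val
    if op_sib_coefficient != 0.25:
        # rescale sib-sib entries of open-pollinated families (shared dam,
        # both sires unknown): tabular gives 0.25 there
        for i in range(n):
            if dam[i] < 0 or sire[i] >= 0:
                continue
            for j in range(i):
                if dam[j] == dam[i] and sire[j] < 0:
                    A[i, j] = A[j, i] = op_sib_coefficient
    return RelationshipMatrix(A, ids, "pedigreeA")


def marker_kinship(geno: GenotypeMatrix, marker_subset=None,
                   kind: str | None = None) -> RelationshipMatrix:
    """VanRaden realized relationship G = W W' / (2 sum p(1-p)).

    ``W`` is the column-centered code matrix (x - 2p). Monomorphic markers
    in the subset are dropped with a warning. ``kind`` defaults to
    ``kinshipK`` for the full panel and ``qtlQ`` for a subset.
    """
    if geno.missing_mask.any():
        raise ValueError("marker_kinship requires a fully imputed panel")
    if marker_subset is not None:
        sub = geno.subset_markers(np.asarray(marker_subset))
    else:
        sub = geno
    p = sub.allele_freq()
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic marker(s) "
                      "from kinship computation")
        sub = sub.subset_markers(np.where(poly)[0])
        p = p[poly]
    if sub.n_markers == 0:
        raise ValueError("no polymorphic markers available for kinship")
    W = sub.codes.astype(float) - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (W @ W.T) / denom
    if kind is None:
        kind = "kinshipK" if marker_subset is None else "qtlQ"
    return RelationshipMatrix(G, list(geno.individual_ids), kind)


def qtl_Q(geno: GenotypeMatrix, significant_markers,
          epsilon: float = DEFAULT_EPSILON) -> RelationshipMatrix:
    """QTL-genotype covariance: realized relationship over significant SNPs.

    Raises if the significant set is empty (use the GS model in that case).
    The result is ridge-regularized so that a Q built from few markers stays
    positive definite.
    """
    idx = np.asarray(significant_markers)
    if idx.size == 0:
        raise ValueError("no significant markers: Q undefined, use the GS model")
    Q = marker_kinship(geno, idx, kind="qtlQ")
    return Q.regularized(epsilon)
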