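"""Stage 1: single-marker mixed-model association scan.

The model per marker is y* = S a + Q v + Z u + e with a fixed marker
effect a, fixed population-structure covariates v, a random polygenic
effect u with Var(u) = 2 K sigma_g^2 and homoscedastic residuals.
Variance components are estimated once by REML on the null model (no
marker) via the eigendecomposition of 2K, then held fixed for every
marker (the P3D / EMMAX scheme); each marker gets a GLS Wald test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import AdjustedPhenotype, GenotypeMatrix
from .kinship import RelationshipMatrix

logger = logging.getLogger(__name__)


@dataclass
class MTAResult:
    marker_id: str
    chromosome: str
    position: int
    marker_index: int
    effect_estimate: float
    standard_error: float
    p_value: float
    q_value: float = np.nan
    significant: bool = False
    variance_explained: float = np.nan


def _reml_null(y: np.ndarray, W: np.ndarray, K2: np.ndarray):
    """REML variance components for y = W b + u + e, Var(u) = K2*sg2.

    Profiles the ratio delta = se2/sg2 on the spectrum of K2. Returns
    (sg2, se2). Falls back to a pure-residual model when the polygenic
    component hits the boundary.
    """
    n, c = W.shape
    s, U = np.linalg.eigh(K2)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Wt = U.T @ W

    def neg_reml(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        w = s + delta
        WdW = (Wt / w[:, None]).T @ Wt
        Wdy = (Wt / w[:, None]).T @ yt
        try:
            beta = np.linalg.solve(WdW, Wdy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Wt @ beta
        rss = float(r @ (r / w))
        sg2 = rss / (n - c)
        sign, logdet_WdW = np.linalg.slogdet(WdW)
        if sign <= 0 or sg2 <= 0:
            return np.inf
        ll = -0.5 * ((n - c) * np.log(2 * np.pi * sg2) + np.sum(np.log(w))
                     + logdet_WdW + (n - c))
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-6.0, 6.0), method="bounded")
    delta = 10.0 ** res.x
    w = s + delta
    WdW = (Wt / w[:, None]).T @ Wt
    beta = np.linalg.solve(WdW, (Wt / w[:, None]).T @ yt)
    r = yt - Wt @ beta
    sg2 = float(r @ (r / w)) / (n - c)
    se2 = sg2 * delta
    return sg2, se2


def scan_markers(y_star: AdjustedPhenotype, geno: GenotypeMatrix,
                 K: RelationshipMatrix,
                 structure_covariates: np.ndarray | None = None) -> list[MTAResult]:
    """Mixed-model scan of every marker against an adjusted phenotype."""
    y = np.asarray(y_star.y_star, dtype=float)
    n = len(y)
    if geno.n_individuals != n:
        raise ValueError("genotype and phenotype dimensions differ")
    if geno.missing_mask.any():
        raise ValueError("scan requires an imputed panel")
    K2 = 2.0 * K.submatrix(geno.individual_ids) if K.ids != geno.individual_ids \
        else 2.0 * K.values
    W = np.ones((n, 1))
    if structure_covariates is not None:
        S = np.asarray(structure_covariates, dtype=float)
        if S.ndim == 1:
            S = S[:, None]
        W = np.column_stack([W, S])

    sg2, se2 = _reml_null(y, W, K2)
    logger.info("null REML: sigma_g^2=%.4g sigma_e^2=%.4g", sg2, se2)

    # whiten by V^{-1/2}, V = sg2*K2 + se2*I
    s, U = np.linalg.eigh(K2)
    v = sg2 * np.clip(s, 0, None) + se2
    Vinv_sqrt = (U / np.sqrt(v)) @ U.T
    yw = Vinv_sqrt @ y
    Ww = Vinv_sqrt @ W
    Xw = Vinv_sqrt @ geno.codes.astype(float)

    # project covariates out of y and all markers at once
    Qc, _ = np.linalg.qr(Ww)
    yr = yw - Qc @ (Qc.T @ yw)
    Xr = Xw - Qc @ (Qc.T @ Xw)

    xx = np.einsum("ij,ij->j", Xr, Xr)
    xy = Xr.T @ yr
    results: list[MTAResult] = []
    meta = geno.marker_meta
    for j in range(geno.n_markers):
        if xx[j] < 1e-12:
            logger.warning("marker %s has zero design variance after projection; "
                           "skipped", meta["marker"].iloc[j])
            continue
        b = xy[j] / xx[j]
        se = 1.0 / np.sqrt(xx[j])  # unit residual variance after whitening
        z = b / se
        pval = 2.0 * stats.norm.sf(abs(z))
        results.append(MTAResult(
            marker_id=str(meta["marker"].iloc[j]),
            chromosome=str(meta["chrom"].iloc[j]),
            position=int(meta["pos"].iloc[j]),
            marker_index=j,
            effect_estimate=float(b),
            standard_error=float(se),
            p_value=float(pval),
        ))
    return results


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone in rank)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_mtas(results: list[MTAResult], alpha: float = 0.001,
                fdr_max: float = 0.10) -> list[MTAResult]:
    """Significant MTAs: p < alpha AND BH q < fdr_max (both strict).

    q-values are computed over all scanned markers and written back onto
    every result; the returned list holds the significant subset.
    """
    if not results:
        raise ValueError("no scan results to select from")
    p = np.array([r.p_value for r in results])
    q = benjamini_hochberg(p)
    selected = []
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = (r.p_value < alpha) and (qv < fdr_max)
        if r.significant:
            selected.append(r)
    return selected


def variance_explained(y_star: AdjustedPhenotype, geno: GenotypeMatrix,
                       marker_index: int) -> float:
    """R^2 of the single-marker ordinary regression of y* on allele count."""
    x = geno.codes[:, marker_index].astype(float)
    y = np.asarray(y_star.y_star, dtype=float)
    if x.std() == 0:
        raise ValueError("marker is monomorphic")
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2)


def annotate_variance_explained(results: list[MTAResult],
                                y_star: AdjustedPhenotype,
                                geno: GenotypeMatrix) -> None:
    for r in results:
        r.variance_explained = variance_explained(y_star, geno, r.marker_index)


def results_to_frame(results: list[MTAResult]) -> pd.DataFrame:
    rows = [{
        "marker": r.marker_id, "chrom": r.chromosome, "pos": r.position,
        "effect": r.effect_estimate, "se": r.standard_error,
        "p": r.p_value, "q": r.q_value, "significant": r.significant,
        "r2": r.variance_explained, "neg_log10_p": -np.log10(max(r.p_value, 1e-300)),
    } for r in results]
    return pd.DataFrame(rows)
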