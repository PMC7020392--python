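"""Model comparison: partitioned heritabilities, DIC and cross-validated
predictive ability.

Heritabilities are per-draw variance ratios (then averaged), with one
common denominator sigma_a^2 + sigma_m^2 + sigma_q^2 + sigma_e^2; the
GS model simply has sigma_q^2 = 0. DIC = D-bar + pD with
pD = D-bar - D(theta-bar). Predictive ability is the Pearson correlation
between pre-corrected phenotypes and predicted breeding values in the
validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import AdjustedPhenotype, GenotypeMatrix
from .wgr import ModelSpec, PosteriorFit, fit as wgr_fit, marker_variance, predict_ebv


@dataclass
class HeritabilityEstimates:
    h2_a: float
    h2_m: float
    h2_q: float
    per_draw: dict


@dataclass
class DicResult:
    dic: float
    d_bar: float
    p_d: float
    d_at_mean: float


@dataclass
class CVResult:
    n_folds: int
    fold_assignment: np.ndarray
    per_fold_pa: np.ndarray

    @property
    def mean_pa(self) -> float:
        return float(np.nanmean(self.per_fold_pa))


def heritabilities(sigma_a2, sigma_m2, sigma_q2, sigma_e2) -> HeritabilityEstimates:
    """Per-draw heritability ratios, averaged over retained draws.

    All four arguments are aligned draw vectors; pass zeros for sigma_q2
    under the GS model.
    """
    arrs = [np.atleast_1d(np.asarray(v, dtype=float))
            for v in (sigma_a2, sigma_m2, sigma_q2, sigma_e2)]
    if len({a.size for a in arrs}) != 1:
        raise ValueError("draw vectors must have equal length")
    sa, sm, sq, se = arrs
    denom = sa + sm + sq + se
    if np.any(denom == 0):
        raise ValueError("all-zero variance draw encountered")
    per = {"h2_a": sa / denom, "h2_m": sm / denom, "h2_q": sq / denom}
    return HeritabilityEstimates(
        float(per["h2_a"].mean()), float(per["h2_m"].mean()),
        float(per["h2_q"].mean()), per)


def fit_heritabilities(posterior: PosteriorFit) -> HeritabilityEstimates:
    """Heritability partition of a PosteriorFit using the genomic-variance
    formula matched to its marker prior."""
    vd = posterior.variance_draws
    sm2 = marker_variance(posterior)
    return heritabilities(vd["sigma_a2"], sm2, vd["sigma_q2"], vd["sigma_e2"])


def dic(deviance_draws, d_at_mean: float) -> DicResult:
    draws = np.asarray(deviance_draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 deviance draws")
    if not (np.isfinite(draws).all() and np.isfinite(d_at_mean)):
        raise ValueError("non-finite deviance values")
    d_bar = float(draws.mean())
    p_d = d_bar - float(d_at_mean)
    return DicResult(d_bar + p_d, d_bar, p_d, float(d_at_mean))


def fit_dic(posterior: PosteriorFit) -> DicResult:
    return dic(posterior.deviance_draws, posterior.d_at_mean)


def delta_dic(dic_gs: float, dic_gsq: float):
    """Signed DIC difference GS - GSq (positive favors GSq) plus verdict.

    |delta| > 10: strong support for the lower-DIC model; 5 <= |delta| <= 10:
    substantial; |delta| < 5: not significant.
    """
    if not (np.isfinite(dic_gs) and np.isfinite(dic_gsq)):
        raise ValueError("DIC values must be finite")
    delta = float(dic_gs) - float(dic_gsq)
    mag = abs(delta)
    if mag > 10:
        verdict = "strong"
    elif mag >= 5:
        verdict = "substantial"
    else:
        verdict = "not significant"
    return delta, verdict


def predictive_ability(y_star_validation, y_hat_validation) -> float:
    """Pearson correlation between held-out y* and predicted breeding values."""
    y = np.asarray(y_star_validation, dtype=float)
    yh = np.asarray(y_hat_validation, dtype=float)
    if y.size != yh.size or y.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if y.std() == 0 or yh.std() == 0:
        return np.nan
    return float(np.corrcoef(y, yh)[0, 1])


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Random near-equal partition; fold label per individual."""
    if n_folds > n:
        raise ValueError("more folds than individuals")
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(labels)
    return labels


def cross_validate(y_star: AdjustedPhenotype, geno: GenotypeMatrix,
                   spec: ModelSpec, n_folds: int = 20, seed: int = 0) -> CVResult:
    """k-fold cross-validated predictive ability of one model spec.

    The GWAS-selected marker partition inside ``spec`` is held fixed from
    the full-data scan; only the regression is refit per fold. Validation
    predictions come from the posterior-mean marker effects plus the
    joint-normal kernel conditionals.
    """
    y = np.asarray(y_star.y_star, dtype=float)
    n = len(y)
    folds = make_folds(n, n_folds, seed)
    counts = np.bincount(folds, minlength=n_folds)
    if counts.min() < 3:
        raise ValueError("a fold has fewer than 3 individuals; reduce n_folds")
    kernels = {name: K for name, K in spec.random_kernels}
    pa = np.empty(n_folds)
    for f in range(n_folds):
        val = np.where(folds == f)[0]
        train = np.where(folds != f)[0]
        g_train = geno.subset_individuals(train)
        g_val = geno.subset_individuals(val)
        y_train = AdjustedPhenotype(y[train], y_star.trait,
                                    list(g_train.individual_ids))
        fold_spec = replace(spec)
        posterior = wgr_fit(y_train, g_train, fold_spec)
        y_hat = predict_ebv(posterior, g_val, kernels)
        pa[f] = predictive_ability(y[val], y_hat)
    return CVResult(n_folds, folds, pa)
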