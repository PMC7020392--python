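"""Bayesian whole-genome regression with correlated random kernels.

Implements single-site Gibbs samplers for four marker-effect priors --
Bayes A (per-marker scaled-inverse-chi^2 variances), Bayes B (spike at
zero with probability pi plus a Bayes A slab, pi fixed), Bayes Cpi
(spike plus common slab variance, pi sampled from its Beta posterior)
and Bayesian ridge regression (common variance, no spike) -- extended
with Gaussian random effects whose covariance is an arbitrary PSD kernel
(pedigree A for the polygenic term, QTL-genotype Q for the GSq model).

The GS model is  y* = 1 mu + X m + Z a + e,  a ~ N(0, sigma_a^2 A);
the GSq model adds  Z q,  q ~ N(0, sigma_q^2 Q), with X restricted to
the markers not significantly associated with the trait.

Kernel effects are sampled blockwise in the eigenbasis of their
covariance (the data rotation makes the conditional posteriors
independent scalars), which is what makes ~500x500 kernels cheap. The
marker loop is compiled with numba. Variance components use
scaled-inverse-chi^2 full conditionals. A Gaussian residual likelihood
supplies the deviance draw per retained sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io import AdjustedPhenotype, GenotypeMatrix
from .kinship import RelationshipMatrix

_BRR, _BA, _BB, _BC = 0, 1, 2, 3
_METHOD_CODES = {"BRR": _BRR, "BayesA": _BA, "BayesB": _BB, "BayesCpi": _BC}
_EIG_FLOOR = 1e-8


@dataclass
class MCMCSettings:
    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ModelSpec:
    """Specification of one whole-genome-regression fit."""

    method: str = "BRR"                 # BayesA | BayesB | BayesCpi | BRR
    approach: str = "GS"                # GS | GSq
    marker_set: np.ndarray | None = None  # None = all markers
    random_kernels: list = field(default_factory=list)  # [(name, RelationshipMatrix)]
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    df_prior: float = 4.2
    r2_heuristic: float = 0.5           # prior share of variance given to the model
    pi_bayesb: float = 0.95             # exclusion probability, fixed (Bayes B)
    pi_cpi_fixed: float | None = None   # fix Bayes Cpi's pi instead of sampling
    # degenerate hyperpriors for oracle checks: fix variances instead of sampling
    fixed_snp_variance: float | None = None
    fixed_residual_variance: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHOD_CODES:
            raise ValueError(f"unknown method {self.method!r}")
        if self.approach not in ("GS", "GSq"):
            raise ValueError(f"unknown approach {self.approach!r}")


@dataclass
class PosteriorFit:
    """Posterior summaries and retained draws of one Gibbs run."""

    spec: ModelSpec
    individual_ids: list[str]
    marker_set: np.ndarray
    marker_col_means: np.ndarray
    allele_freq: np.ndarray            # per fitted marker
    mu_mean: float
    m_mean: np.ndarray
    m_sd: np.ndarray
    kernel_effect_means: dict          # name -> posterior-mean effect vector
    variance_draws: dict               # sigma_a2 / sigma_q2 / sigma_e2 / pi
    snp_variance_draws: np.ndarray     # (nd,) common or (nd,p) per-marker
    deviance_draws: np.ndarray
    d_at_mean: float

    @property
    def n_retained(self) -> int:
        return len(self.deviance_draws)

    def effective_sample_sizes(self) -> dict:
        """ESS of the retained variance-component (and deviance) chains."""
        out = {}
        for name, draws in {**self.variance_draws,
                            "deviance": self.deviance_draws}.items():
            out[name] = effective_sample_size(np.asarray(draws))
        return out

    def genetic_values(self) -> np.ndarray:
        """Fitted genetic value of every training individual."""
        g = self._X_centered @ self.m_mean
        for v in self.kernel_effect_means.values():
            g = g + v
        return g

    # set by fit(); kept out of the dataclass signature
    _X_centered: np.ndarray = field(default=None, repr=False)  # type: ignore


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (xc @ xc)
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


@njit(cache=True)
def _gibbs_core(y, X, xx, method, pi_init, pi_fixed,
                U_a, d_a, has_a, U_q, d_q, has_q,
                df_m, S_m, df_k, S_a, S_q, df_e, S_e,
                fix_m, sig_m_fix, fix_e, sig_e_fix,
                n_iter, burn_in, thin, seed):
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    nd = (n_iter - burn_in) // thin

    mu = y.mean()
    m = np.zeros(p)
    incl = np.ones(p, dtype=np.bool_)
    sig2m = np.empty(p)
    common = S_m if not fix_m else sig_m_fix
    for j in range(p):
        sig2m[j] = common
    pi = pi_init
    sigma_e2 = S_e if not fix_e else sig_e_fix
    sigma_a2 = S_a
    sigma_q2 = S_q
    na = d_a.shape[0]
    nq = d_q.shape[0]
    alpha_a = np.zeros(na)
    alpha_q = np.zeros(nq)
    a_vec = np.zeros(n)
    q_vec = np.zeros(n)
    e = y - mu

    per_marker_var = (method == _BA) or (method == _BB)
    mu_sum = 0.0
    m_sum = np.zeros(p)
    m_sq = np.zeros(p)
    a_sum = np.zeros(n)
    q_sum = np.zeros(n)
    dev = np.empty(nd)
    sa2_d = np.empty(nd)
    sq2_d = np.empty(nd)
    se2_d = np.empty(nd)
    pi_d = np.empty(nd)
    if per_marker_var:
        snp_d = np.empty((nd, p))
    else:
        snp_d = np.empty((nd, 1))

    kept = 0
    for it in range(n_iter):
        # --- intercept ---
        rhs = e.sum() + n * mu
        mu_new = rhs / n + np.sqrt(sigma_e2 / n) * np.random.standard_normal()
        e += mu - mu_new
        mu = mu_new

        # --- marker effects ---
        spike = (method == _BB) or (method == _BC)
        for j in range(p):
            if xx[j] <= 0.0:
                continue
            xj = X[:, j]
            old = m[j]
            r = 0.0
            for i in range(n):
                r += xj[i] * e[i]
            r += xx[j] * old
            vj = sig2m[j]
            take = True
            if spike:
                t = xx[j] * vj + sigma_e2
                log_bf = 0.5 * np.log(sigma_e2 / t) + 0.5 * r * r * vj / (sigma_e2 * t)
                if log_bf > 35.0:
                    p_in = 1.0
                else:
                    odds = (1.0 - pi) / pi * np.exp(log_bf)
                    p_in = odds / (1.0 + odds)
                take = np.random.random() < p_in
            if take:
                c = xx[j] + sigma_e2 / vj
                mean = r / c
                m_new = mean + np.sqrt(sigma_e2 / c) * np.random.standard_normal()
                incl[j] = True
            else:
                m_new = 0.0
                incl[j] = False
            if m_new != old:
                diff = old - m_new
                for i in range(n):
                    e[i] += xj[i] * diff
                m[j] = m_new

        # --- marker variances ---
        if not fix_m:
            if method == _BA:
                for j in range(p):
                    sig2m[j] = (m[j] * m[j] + df_m * S_m) / \
                        np.random.chisquare(df_m + 1.0)
            elif method == _BB:
                for j in range(p):
                    if incl[j]:
                        sig2m[j] = (m[j] * m[j] + df_m * S_m) / \
                            np.random.chisquare(df_m + 1.0)
                    else:
                        sig2m[j] = df_m * S_m / np.random.chisquare(df_m)
            else:  # BRR / BC share one slab variance
                ss = 0.0
                k_in = 0
                for j in range(p):
                    if incl[j]:
                        ss += m[j] * m[j]
                        k_in += 1
                newv = (ss + df_m * S_m) / np.random.chisquare(df_m + k_in)
                for j in range(p):
                    sig2m[j] = newv

        # --- pi (Bayes Cpi) ---
        if (method == _BC) and (not pi_fixed):
            k_in = 0
            for j in range(p):
                if incl[j]:
                    k_in += 1
            pi = np.random.beta(1.0 + (p - k_in), 1.0 + k_in)
            if pi < 1e-6:
                pi = 1e-6
            if pi > 1.0 - 1e-6:
                pi = 1.0 - 1e-6

        # --- kernel effects, blockwise in the eigenbasis ---
        if has_a:
            r_vec = e + a_vec
            rt = U_a.T @ r_vec
            for i in range(na):
                di = d_a[i]
                if di < _EIG_FLOOR:
                    alpha_a[i] = 0.0
                    continue
                denom = di * sigma_a2 + sigma_e2
                mean = di * sigma_a2 * rt[i] / denom
                var = di * sigma_a2 * sigma_e2 / denom
                alpha_a[i] = mean + np.sqrt(var) * np.random.standard_normal()
            a_new = U_a @ alpha_a
            e += a_vec - a_new
            a_vec = a_new
            ss = 0.0
            cnt = 0
            for i in range(na):
                if d_a[i] >= _EIG_FLOOR:
                    ss += alpha_a[i] * alpha_a[i] / d_a[i]
                    cnt += 1
            sigma_a2 = (ss + df_k * S_a) / np.random.chisquare(df_k + cnt)

        if has_q:
            r_vec = e + q_vec
            rt = U_q.T @ r_vec
            for i in range(nq):
                di = d_q[i]
                if di < _EIG_FLOOR:
                    alpha_q[i] = 0.0
                    continue
                denom = di * sigma_q2 + sigma_e2
                mean = di * sigma_q2 * rt[i] / denom
                var = di * sigma_q2 * sigma_e2 / denom
                alpha_q[i] = mean + np.sqrt(var) * np.random.standard_normal()
            q_new = U_q @ alpha_q
            e += q_vec - q_new
            q_vec = q_new
            ss = 0.0
            cnt = 0
            for i in range(nq):
                if d_q[i] >= _EIG_FLOOR:
                    ss += alpha_q[i] * alpha_q[i] / d_q[i]
                    cnt += 1
            sigma_q2 = (ss + df_k * S_q) / np.random.chisquare(df_k + cnt)

        # --- residual variance ---
        if not fix_e:
            ee = 0.0
            for i in range(n):
                ee += e[i] * e[i]
            sigma_e2 = (ee + df_e * S_e) / np.random.chisquare(df_e + n)
            if sigma_e2 < 1e-12:
                sigma_e2 = 1e-12

        # --- retain ---
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < nd:
            mu_sum += mu
            for j in range(p):
                m_sum[j] += m[j]
                m_sq[j] += m[j] * m[j]
            a_sum += a_vec
            q_sum += q_vec
            ee = 0.0
            for i in range(n):
                ee += e[i] * e[i]
            dev[kept] = n * np.log(2.0 * np.pi * sigma_e2) + ee / sigma_e2
            sa2_d[kept] = sigma_a2
            sq2_d[kept] = sigma_q2
            se2_d[kept] = sigma_e2
            pi_d[kept] = pi
            if per_marker_var:
                for j in range(p):
                    snp_d[kept, j] = sig2m[j] if incl[j] else 0.0
            else:
                snp_d[kept, 0] = sig2m[0]
            kept += 1

    return (mu_sum, m_sum, m_sq, a_sum, q_sum, dev,
            sa2_d, sq2_d, se2_d, pi_d, snp_d, kept)


def _hyper_scales(y: np.ndarray, X: np.ndarray, spec: ModelSpec,
                  n_kernels: int):
    """Scaled-inverse-chi^2 scales so each prior mode splits var(y) evenly
    among model terms (markers + kernels) at the chosen R^2 heuristic."""
    vy = float(np.var(y))
    if vy <= 0:
        vy = 1.0
    df = spec.df_prior
    n_terms = (1 if X.shape[1] > 0 else 0) + n_kernels
    r2_term = spec.r2_heuristic / max(n_terms, 1)
    mode_to_scale = (df + 2.0) / df
    msx = float(np.sum(np.var(X, axis=0))) if X.shape[1] > 0 else 1.0
    if msx <= 0:
        msx = 1.0
    frac_in = 1.0
    if spec.method == "BayesB":
        frac_in = max(1.0 - spec.pi_bayesb, 0.01)
    elif spec.method == "BayesCpi":
        frac_in = 0.5  # prior guess; pi is sampled
    S_m = r2_term * vy / (msx * frac_in) * mode_to_scale
    S_kernel = r2_term * vy * mode_to_scale
    S_e = (1.0 - spec.r2_heuristic) * vy * mode_to_scale
    return S_m, S_kernel, S_e


def fit(y_star: AdjustedPhenotype, geno: GenotypeMatrix,
        spec: ModelSpec) -> PosteriorFit:
    """Run the Gibbs sampler for one model specification.

    ``spec.random_kernels`` lists (name, RelationshipMatrix) pairs; the GS
    model uses [("A", A)], the GSq model [("A", A), ("Q", Q)]. Kernel
    matrices may cover more individuals than the training set; the
    submatrix over ``geno.individual_ids`` is used.
    """
    y = np.asarray(y_star.y_star, dtype=float)
    n = len(y)
    if geno.n_individuals != n:
        raise ValueError("genotype and phenotype dimensions differ")
    if geno.missing_mask.any():
        raise ValueError("impute the panel before fitting")
    if not np.isfinite(y).all():
        raise ValueError("y* contains non-finite values")

    marker_set = (np.arange(geno.n_markers) if spec.marker_set is None
                  else np.asarray(spec.marker_set))
    X_raw = geno.codes[:, marker_set].astype(float)
    col_means = X_raw.mean(axis=0)
    X = X_raw - col_means
    xx = np.einsum("ij,ij->j", X, X)
    p_freq = X_raw.mean(axis=0) / 2.0

    if len(spec.random_kernels) > 2:
        raise ValueError("at most two random kernels (A and Q) are supported")
    eigs = []
    for name, K in spec.random_kernels:
        sub = (K.values if K.ids == geno.individual_ids
               else K.submatrix(geno.individual_ids))
        d, U = np.linalg.eigh(sub)
        if d[0] < -1e-8:
            raise ValueError(f"kernel {name!r} is not PSD (min eig {d[0]:.2e}); "
                             "regularize it first")
        eigs.append((name, U, np.clip(d, 0.0, None)))

    S_m, S_kern, S_e = _hyper_scales(y, X, spec, len(eigs))
    has_a = len(eigs) >= 1
    has_q = len(eigs) >= 2
    U_a, d_a = (eigs[0][1], eigs[0][2]) if has_a else (np.zeros((1, 1)), np.zeros(1))
    U_q, d_q = (eigs[1][1], eigs[1][2]) if has_q else (np.zeros((1, 1)), np.zeros(1))

    method = _METHOD_CODES[spec.method]
    pi_init = spec.pi_bayesb if spec.method == "BayesB" else 0.5
    pi_fixed = spec.method != "BayesCpi"
    if spec.method == "BayesCpi" and spec.pi_cpi_fixed is not None:
        pi_init = spec.pi_cpi_fixed
        pi_fixed = True
    pi_init = float(np.clip(pi_init, 1e-9, 1 - 1e-9))
    fix_m = spec.fixed_snp_variance is not None
    fix_e = spec.fixed_residual_variance is not None

    mc = spec.mcmc
    out = _gibbs_core(
        y, X, xx, method, pi_init, pi_fixed,
        np.ascontiguousarray(U_a), d_a, has_a,
        np.ascontiguousarray(U_q), d_q, has_q,
        spec.df_prior, S_m, spec.df_prior, S_kern, S_kern,
        spec.df_prior, S_e,
        fix_m, spec.fixed_snp_variance or 0.0,
        fix_e, spec.fixed_residual_variance or 0.0,
        mc.n_iter, mc.burn_in, mc.thin, mc.seed,
    )
    (mu_sum, m_sum, m_sq, a_sum, q_sum, dev,
     sa2_d, sq2_d, se2_d, pi_d, snp_d, kept) = out
    if kept == 0:
        raise RuntimeError("no retained draws; check MCMC settings")
    if not np.isfinite(dev[:kept]).all():
        raise RuntimeError("divergent deviance draws; the sampler overflowed")

    mu_mean = mu_sum / kept
    m_mean = m_sum / kept
    m_var = np.maximum(m_sq / kept - m_mean ** 2, 0.0)
    kernel_means = {}
    if has_a:
        kernel_means[eigs[0][0]] = a_sum / kept
    if has_q:
        kernel_means[eigs[1][0]] = q_sum / kept

    variance_draws = {
        "sigma_a2": sa2_d[:kept] if has_a else np.zeros(kept),
        "sigma_q2": sq2_d[:kept] if has_q else np.zeros(kept),
        "sigma_e2": se2_d[:kept],
        "pi": pi_d[:kept],
    }

    # deviance at the posterior means of all effects (plug-in for pD)
    e_hat = y - mu_mean - X @ m_mean
    for v in kernel_means.values():
        e_hat = e_hat - v
    se2_hat = float(np.mean(se2_d[:kept]))
    d_at_mean = n * np.log(2.0 * np.pi * se2_hat) + float(e_hat @ e_hat) / se2_hat

    per_marker = spec.method in ("BayesA", "BayesB")
    snp_draws = snp_d[:kept] if per_marker else snp_d[:kept, 0]

    fit_obj = PosteriorFit(
        spec=spec, individual_ids=list(geno.individual_ids),
        marker_set=marker_set, marker_col_means=col_means,
        allele_freq=p_freq, mu_mean=float(mu_mean),
        m_mean=m_mean, m_sd=np.sqrt(m_var),
        kernel_effect_means=kernel_means,
        variance_draws=variance_draws,
        snp_variance_draws=snp_draws,
        deviance_draws=dev[:kept], d_at_mean=float(d_at_mean),
    )
    fit_obj._X_centered = X
    return fit_obj


def marker_variance(fit: PosteriorFit, maf: np.ndarray | None = None,
                    method: str | None = None) -> np.ndarray:
    """Genomic variance draws sigma_m^2 from the SNP-variance draws.

    BRR / Bayes Cpi (common variance): sigma_m^2 = 2 sigma_SNP^2 sum p(1-p).
    Bayes A / B (per-marker):          sigma_m^2 = 2 sum p_i(1-p_i) sigma_SNPi^2,
    with Bayes B markers currently in the spike contributing 0.
    """
    method = method or fit.spec.method
    if maf is None:
        # monomorphic markers (possible on an unfiltered panel) contribute 0
        p = np.minimum(fit.allele_freq, 1 - fit.allele_freq)
    else:
        p = np.asarray(maf, dtype=float)
        if p.size and (np.any(p <= 0) or np.any(p > 0.5)):
            raise ValueError("MAF values must lie in (0, 0.5]")
    het = 2.0 * p * (1.0 - p)
    if p.size == 0:
        return np.zeros(np.asarray(fit.snp_variance_draws).shape[0])
    if method in ("BRR", "BayesCpi"):
        return np.asarray(fit.snp_variance_draws) * het.sum()
    if fit.snp_variance_draws.ndim != 2:
        raise ValueError("per-marker variance draws missing for this fit")
    return fit.snp_variance_draws @ het


def predict_ebv(fit: PosteriorFit, geno_new: GenotypeMatrix,
                kernels: dict | None = None) -> np.ndarray:
    """Predicted breeding values for new individuals.

    y-hat* = sum_i x_i m-hat_i plus, for each kernel, the joint-normal
    conditional prediction K[new, train] K[train, train]^{-1} u-hat[train].
    Training individuals get their fitted genetic values back. ``kernels``
    maps kernel name to the full RelationshipMatrix covering training and
    new individuals.
    """
    X_new = geno_new.codes[:, fit.marker_set].astype(float) - fit.marker_col_means
    yhat = X_new @ fit.m_mean
    kernels = kernels or {}
    for name, u_hat in fit.kernel_effect_means.items():
        if name not in kernels:
            raise KeyError(f"kernel {name!r} required for prediction")
        K = kernels[name]
        for ind in geno_new.individual_ids:
            if ind not in K.ids:
                raise KeyError(f"individual {ind!r} absent from kernel {name!r}")
        K_tt = K.submatrix(fit.individual_ids)
        K_nt = K.cross_block(geno_new.individual_ids, fit.individual_ids)
        sol = np.linalg.solve(K_tt + 1e-8 * np.eye(K_tt.shape[0]), u_hat)
        yhat = yhat + K_nt @ sol
    return yhat
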