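# Methods

## Models

Both prediction models operate on pre-corrected phenotypes y\*: the raw
trait (ordinal traits on their numeric scale) is regressed by ordinary
least squares on block indicators and, when available, population-structure
covariates; y\* is the residual vector. This mirrors the common practice of
fitting the design effects once and analyzing adjusted records.

**GS**: y\* = 1μ + Σᵢ xᵢmᵢ + Za + ε with xᵢ the allele count (0/1/2) of
marker i, a ~ N(0, σ²ₐA) the pedigree polygenic effect and
ε ~ N(0, σ²ₑI). **GSq** adds q ~ N(0, σ²_qQ) and restricts the marker sum
to non-significant SNPs. Q is the realized (VanRaden) relationship over
the GWAS-significant SNPs: the conceptual quantity — IBD probabilities at
significant markers — is estimated from unphased SNPs by the standard
realized-relationship estimator; a ridge of 1e-6·I keeps few-marker Q
matrices positive definite.

Stage 1 (GWAS) is the mixed model y\* = Sa + Qv + Zu + ε with
Var(u) = 2Kσ²_g, K the VanRaden kinship of the full panel. Variance
components are estimated once by REML on the null model — profiled over
δ = σ²ₑ/σ²_g on the spectrum of 2K — and held fixed for every marker
(P3D/EMMAX); each marker then gets a GLS Wald test after whitening by
V^(−1/2). Significance requires p < 0.001 **and** Benjamini–Hochberg
q < 0.10, both strict, with q-values computed per trait over all scanned
markers. BH was chosen because the FDR procedure is otherwise
unspecified; it is the field default.

## Gibbs sampler

A single-site Gibbs sampler (numba-compiled inner loop) updates:

- μ (flat prior) and each mᵢ from Gaussian full conditionals, with the
  residual vector maintained incrementally;
- marker-inclusion indicators for the spike–slab priors via the
  marginal Bayes factor with mᵢ integrated out; Bayes B fixes the
  exclusion probability π = 0.95, Bayes Cπ samples π ~ Beta(1+#excluded,
  1+#included) (π may also be fixed, which at π = 0 reduces Bayes Cπ to
  BRR — a tested identity);
- per-marker variances (Bayes A/B) or the common slab variance (BRR/
  Bayes Cπ) from scaled-inverse-χ² full conditionals;
- kernel effects a and q **blockwise in the eigenbasis** of their
  covariance: with K = UDUᵀ and orthonormal U, rotating the partial
  residual makes the conditional posterior of the eigen-coordinates a
  product of independent scalars, so a 490×490 kernel costs two
  matrix–vector products per sweep (the eigendecomposition is done
  once). Eigenvalues below 1e-8 are excluded;
- variance components σ²ₐ, σ²_q, σ²ₑ from scaled-inverse-χ² full
  conditionals.

The deviance draw per retained sample is the Gaussian residual
−2 log f(y\*|θ) conditional on all sampled effects; D(θ̄) plugs in the
posterior means of μ, m, a, q and σ²ₑ. This matches how DIC is computed
by standard Bayesian whole-genome-regression software and guarantees
pD = D̄ − D(θ̄) ≥ 0 for the Gaussian likelihood.

**Hyperpriors.** All variance components get scaled-inverse-χ² priors
with df 4.2. Scales are solved so each component's prior mode splits the
phenotypic variance evenly among model terms at an R² heuristic of 0.5
(markers divided by Σvar(xᵢ), and by the expected inclusion fraction for
spike–slab priors). These follow common whole-genome-regression
defaults; with ~500 observations they are weakly informative, but for
variance *ratios* under weak designs (half-sib families) the posterior
mean is pulled toward the prior's even split — a known behavior noted
below.

**Settings.** Desk-scale defaults are 30,000 iterations, 5,000 burn-in,
thinning 10; production-scale chains (10⁶ iterations, 10⁵ burn-in) are a
configuration change. The analysis scripts and acceptance run use 1,500–
22,000 iterations depending on the role of the fit (cross-validation
folds use the shortest chains); these sizes were chosen as the package's
desk-scale operating point and are stated with each script.

## Prediction and evaluation

Predicted breeding values for held-out individuals are
ŷ\* = Σᵢxᵢm̂ᵢ + Ẑa + Ẑq, where kernel effects for new individuals come
from the joint-normal conditional K_new,train K_train,train⁻¹ û.
Cross-validation partitions individuals into random near-equal folds
(20 by default; the scripts use 5 for speed); MTA selection is performed
once on the full data, not re-selected per fold, matching a protocol
that cross-validates the prediction models only (nested re-selection
would alter optimism and is deliberately not the default). Predictive
ability is the Pearson correlation between y\* and ŷ\* in the validation
fold, averaged over folds.

ΔDIC = DIC_GS − DIC_GSq, positive favoring GSq; |Δ| > 10 is "strong",
5–10 "substantial", < 5 "not significant". Heritabilities are per-draw
ratios averaged over draws (the proper posterior of a ratio), with σ²ₘ
from the MAF-weighted SNP-variance formulas; Bayes B markers currently
in the spike contribute zero.

## Synthetic data

The generator emulates an open-pollinated progeny trial:

- **Founders.** Ancestral allele frequencies uniform on the configured
  MAF band (default 0.10–0.50, keeping simulated panels above the QC
  threshold); subpopulation frequencies are Balding–Nichols beta draws.
  A scalar F_ST target applies one divergence parameter to every
  subpopulation; a pairwise target vector (default 0.086/0.25/0.28 for
  three subpopulations) is converted to per-subpopulation divergences by
  solving F_ST(i,j) ≈ (Fᵢ+Fⱼ)/2.
- **Families.** One dam per family; each offspring's pollen parent is a
  fresh random genotype from the dam's subpopulation (the unknown pollen
  cloud) or the dam itself with the configured selfing rate (default 0 —
  the relationship adjustment for selfing is exposed through the
  pedigree-A sib coefficient instead). Offspring are Mendelian gametes
  of their two parents. 49 families × 10 offspring and a 30-block design
  are the defaults.
- **Traits.** phenotype = block effect + Σ QTL + polygenic + diffuse
  marker background + residual, non-block variance normalized to 1 so
  architecture fractions are direct variance shares; genetic components
  are rescaled to their realized variance, so each QTL's realized share
  matches its target up to covariance between terms. Ordinal traits
  threshold the latent value at equiprobable quantiles (the field scales
  give levels but not category frequencies). Default trait set: seven
  architectures with 5–26 QTLs each explaining 1.5–4% of variance and
  pedigree heritabilities 0.08–0.30.

Not emulated: linkage-disequilibrium decay along chromosomes (an
optional copy-previous block mode provides within-block LD for the LD
statistics only), recombination maps, mutation, genotyping error, and
coalescent-realistic haplotype structure. Passing tests therefore show
that the estimators recover the generating model's structure, not that
real eucalypt data would behave identically — in particular real panels
have LD between QTLs and markers that the independent-locus default does
not create, which makes the simulated GS-vs-GSq contrast conservative
(GS cannot tag QTLs through LD here).

## Numerical choices and edge cases

- QC filters use strict inequalities (call rate > 0.7, MAF > 0.05);
  imputation is an LD-kNN vote (top-30 most-correlated sites, 5 nearest
  individuals, 1/distance weights, ties to the lower code) and never
  alters observed calls; a marker missing everywhere falls back to the
  rounded panel mean.
- Pedigree A uses the tabular method; maternal sibs with unknown sires
  get 0.25 by construction, and the open-pollinated sib coefficient is a
  parameter for selfing/full-sib admixture corrections (the specific
  literature adjustment for this population is not reproduced here).
- Rank-deficient adjustment designs fall back to pseudo-inverse with a
  warning; monomorphic markers are skipped in the scan and dropped from
  kinship subsets with a warning; an empty significant set raises and
  directs the caller to the GS model.
- Per-stage seeds are derived from one global seed by hashing the stage
  name (kept below 2³¹), so every stage is independently reproducible
  and a rerun with the same configuration is byte-identical.

## Known limitations

- Under weakly identified variance partitions (half-sib pedigree only,
  or markers-versus-pedigree confounding within families) the posterior
  mean of a heritability ratio is biased toward the prior's even split;
  REML point estimates and the Bayesian posterior means can differ by
  ~0.1 in such designs.
- The σ²ₘ = 2Σp(1−p)σ²_SNP formula ignores LD/relatedness covariance
  between markers and slightly understates realized genomic variance in
  structured samples.
- DIC uses the conditional (residual-level) likelihood; marginal-
  likelihood DIC variants would give different pD magnitudes.
- Ordinal traits are analyzed on the numeric scale throughout (no
  threshold model), consistent with the linear Gaussian treatment the
  comparison targets.
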