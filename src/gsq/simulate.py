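"""Synthetic open-pollinated progeny-trial data.

Emulates the statistical structure of a eucalypt breeding trial: founder
dams drawn from differentiated subpopulations (Balding–Nichols allele
frequencies), open-pollinated families whose pollen parents are unknown
random draws from the dam's subpopulation (or the dam itself when selfing),
Mendelian offspring genotypes, and phenotypes built from a randomized
complete block design plus a handful of moderate-effect QTLs, an
A-structured polygenic value, a diffuse marker background and Gaussian
noise. A truth record stores everything needed for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .kinship import pedigree_A


@dataclass
class TraitArchitecture:
    """Genetic architecture of one simulated trait.

    Variance fractions are shares of the total non-block phenotypic
    variance (normalized to 1): each QTL's share, the pedigree polygenic
    share and the diffuse marker-background share; the residual is the
    remainder. ``scale`` is "continuous" or "ordinal"; ordinal traits are
    produced by thresholding the latent value at equiprobable quantiles
    into ``ordinal_levels`` categories starting at ``ordinal_start``.
    """

    name: str
    n_qtl: int = 0
    qtl_variance_fractions: tuple = ()
    polygenic_h2: float = 0.2
    marker_h2: float = 0.1
    scale: str = "continuous"
    ordinal_levels: int = 4
    ordinal_start: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl != len(self.qtl_variance_fractions):
            if not self.qtl_variance_fractions and self.n_qtl > 0:
                # equal split of nothing specified is an error; require explicit
                raise ValueError("qtl_variance_fractions must have n_qtl entries")
            raise ValueError("qtl_variance_fractions length must equal n_qtl")
        total = sum(self.qtl_variance_fractions) + self.polygenic_h2 + self.marker_h2
        if total > 1.0 + 1e-9:
            raise ValueError(f"variance fractions sum to {total:.3f} > 1")
        if not (0 <= self.polygenic_h2 <= 1 and 0 <= self.marker_h2 <= 1):
            raise ValueError("heritability fractions must be in [0,1]")

    @property
    def qtl_h2(self) -> float:
        return float(sum(self.qtl_variance_fractions))


@dataclass
class SimConfig:
    """Study-design parameters of the simulated progeny trial.

    Defaults mirror a 49-family open-pollinated trial genotyped at ~10
    offspring per family on a low-density panel spread over 11 chromosomes,
    with three subpopulations whose pairwise F_ST is near 0.086/0.25/0.28
    and a 30-block randomized complete block design.
    """

    n_families: int = 49
    offspring_per_family: int = 10
    n_markers: int = 3879
    n_chromosomes: int = 11
    chromosome_length_bp: int = 60_000_000
    n_subpops: int = 3
    target_fst: object = (0.086, 0.25, 0.28)  # scalar or pairwise upper triangle
    maf_range: tuple = (0.10, 0.50)
    selfing_rate: float = 0.0
    n_blocks: int = 30
    block_variance: float = 0.1
    ld_block_size: int = 0   # >1 enables block-correlated founder haplotypes
    ld_rho: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "offspring_per_family", "n_markers",
                     "n_chromosomes", "n_subpops", "n_blocks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_markers < self.n_chromosomes:
            raise ValueError("n_markers must be >= n_chromosomes")
        if not (0 <= self.selfing_rate <= 1):
            raise ValueError("selfing_rate must be in [0,1]")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")


@dataclass
class TruthRecord:
    qtl_marker_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    realized_h2_components: dict
    subpop_assignment: list


@dataclass
class GenotypeSim:
    """Everything simulate_genotypes produces."""
    geno: GenotypeMatrix           # genotyped offspring
    pedigree: pd.DataFrame         # id, dam, sire ("0" = unknown)
    subpop_labels: np.ndarray      # per offspring (= dam's subpopulation)
    founders: GenotypeMatrix       # the dams
    founder_subpops: np.ndarray


def _per_subpop_F(config: SimConfig) -> np.ndarray:
    """Per-subpopulation divergence F_k from the pairwise targets.

    Under independent Balding–Nichols divergence the expected pairwise
    F_ST(i,j) is close to (F_i + F_j)/2, so a pairwise target triple is
    solved by a small linear system; a scalar target uses a common F.
    """
    k = config.n_subpops
    t = config.target_fst
    if np.isscalar(t):
        return np.full(k, float(t))
    t = np.asarray(t, dtype=float)
    n_pairs = k * (k - 1) // 2
    if t.size != n_pairs:
        raise ValueError(f"target_fst needs a scalar or {n_pairs} pairwise values")
    if k == 1:
        return np.zeros(1)
    A = np.zeros((n_pairs, k))
    row = 0
    for i in range(k):
        for j in range(i + 1, k):
            A[row, i] = A[row, j] = 0.5
            row += 1
    F, *_ = np.linalg.lstsq(A, t, rcond=None)
    return np.clip(F, 0.0, 0.95)


def _draw_subpop_freqs(p_anc: np.ndarray, F: float, rng) -> np.ndarray:
    if F <= 0:
        return p_anc.copy()
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    p = rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))
    return np.clip(p, 1e-4, 1 - 1e-4)


def _draw_haplotype(p: np.ndarray, rng, block: int, rho: float) -> np.ndarray:
    """One haplotype; optional copy-previous LD within blocks of ``block`` markers."""
    h = (rng.random(p.size) < p).astype(np.int8)
    if block > 1:
        for j in range(1, p.size):
            if j % block != 0 and rng.random() < rho:
                h[j] = h[j - 1]
    return h


def _genotype_from_freqs(p: np.ndarray, rng, block: int, rho: float) -> np.ndarray:
    return _draw_haplotype(p, rng, block, rho) + _draw_haplotype(p, rng, block, rho)


def _mendelian_gamete(genotype: np.ndarray, rng) -> np.ndarray:
    """One gamete from an unphased genotype: hets transmit a fair coin."""
    g = np.where(genotype == 2, 1, 0).astype(np.int8)
    het = genotype == 1
    g[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    return g


def simulate_genotypes(config: SimConfig) -> GenotypeSim:
    """Simulate founder dams, open-pollinated families and offspring genotypes."""
    rng = np.random.default_rng(config.seed)
    m = config.n_markers

    # marker map: markers spread evenly over chromosomes, sorted positions
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c, n_c in enumerate(per_chrom, start=1):
        pos = np.sort(rng.integers(1, config.chromosome_length_bp, size=n_c))
        chroms += [str(c)] * n_c
        positions.append(pos)
    marker_meta = pd.DataFrame({
        "marker": [f"SNP{j:05d}" for j in range(m)],
        "chrom": chroms,
        "pos": np.concatenate(positions),
    })

    p_anc = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    flip = rng.random(m) < 0.5          # random reference allele
    p_anc = np.where(flip, 1 - p_anc, p_anc)
    F = _per_subpop_F(config)
    subpop_freqs = [_draw_subpop_freqs(p_anc, F[k], rng)
                    for k in range(config.n_subpops)]

    fam_subpop = np.arange(config.n_families) % config.n_subpops
    dam_ids = [f"DAM{f:03d}" for f in range(config.n_families)]
    dams = np.stack([
        _genotype_from_freqs(subpop_freqs[fam_subpop[f]], rng,
                             config.ld_block_size, config.ld_rho)
        for f in range(config.n_families)
    ])

    off_codes, off_ids, ped_rows, off_subpop = [], [], [], []
    for f in range(config.n_families):
        ped_rows.append((dam_ids[f], "0", "0"))
        for o in range(config.offspring_per_family):
            if rng.random() < config.selfing_rate:
                pollen = dams[f]
            else:
                pollen = _genotype_from_freqs(subpop_freqs[fam_subpop[f]], rng,
                                              config.ld_block_size, config.ld_rho)
            child = _mendelian_gamete(dams[f], rng) + _mendelian_gamete(pollen, rng)
            oid = f"F{f:03d}_O{o:02d}"
            off_codes.append(child)
            off_ids.append(oid)
            ped_rows.append((oid, dam_ids[f], "0"))
            off_subpop.append(fam_subpop[f])

    geno = GenotypeMatrix(np.stack(off_codes), off_ids, marker_meta)
    founders = GenotypeMatrix(dams, dam_ids, marker_meta)
    pedigree = pd.DataFrame(ped_rows, columns=["id", "dam", "sire"])
    return GenotypeSim(geno, pedigree, np.array(off_subpop), founders, fam_subpop)


def simulate_phenotypes(geno: GenotypeMatrix, ped: pd.DataFrame,
                        arch: TraitArchitecture, n_blocks: int = 30,
                        block_variance: float = 0.1, seed: int = 0,
                        qtl_marker_indices=None):
    """Simulate one trait on the genotyped individuals.

    phenotype = block effect + sum_j x_j beta_j + polygenic + marker
    background + residual, with the non-block variance normalized to 1 so
    architecture fractions are direct variance shares. Genetic components
    are rescaled to their realized (empirical) variance, so each QTL's
    realized share matches its target up to sampling covariance between
    terms. Returns (PhenotypeTable, TruthRecord).
    """
    rng = np.random.default_rng(seed)
    n = geno.n_individuals
    if arch.n_qtl > geno.n_markers:
        raise ValueError("QTL count exceeds marker count")

    codes = geno.codes.astype(float)
    var_x = codes.var(axis=0)
    p = geno.allele_freq()

    # QTLs: sample among reasonably informative markers unless fixed by caller
    if arch.n_qtl > 0:
        if qtl_marker_indices is not None:
            qtl_idx = np.asarray(qtl_marker_indices)
            if qtl_idx.size != arch.n_qtl:
                raise ValueError("qtl_marker_indices length must equal n_qtl")
        else:
            eligible = np.where((np.minimum(p, 1 - p) >= 0.1) & (var_x > 0))[0]
            if eligible.size < arch.n_qtl:
                eligible = np.where(var_x > 0)[0]
            qtl_idx = rng.choice(eligible, size=arch.n_qtl, replace=False)
        fracs = np.asarray(arch.qtl_variance_fractions, dtype=float)
        signs = rng.choice([-1.0, 1.0], size=arch.n_qtl)
        beta = signs * np.sqrt(fracs / var_x[qtl_idx])
        qtl_value = codes[:, qtl_idx] @ beta
        qtl_value -= qtl_value.mean()
    else:
        qtl_idx = np.array([], dtype=int)
        beta = np.array([])
        qtl_value = np.zeros(n)

    # pedigree polygenic value
    if arch.polygenic_h2 > 0:
        A = pedigree_A(ped)
        Ao = A.submatrix(geno.individual_ids)
        L = np.linalg.cholesky(Ao + 1e-8 * np.eye(n))
        a = L @ rng.standard_normal(n)
        a = a - a.mean()
        a *= np.sqrt(arch.polygenic_h2) / a.std()
    else:
        a = np.zeros(n)

    # diffuse marker background over non-QTL markers
    if arch.marker_h2 > 0:
        bg_idx = np.setdiff1d(np.where(var_x > 0)[0], qtl_idx)
        gamma = rng.standard_normal(bg_idx.size)
        u = (codes[:, bg_idx] - codes[:, bg_idx].mean(axis=0)) @ gamma
        u -= u.mean()
        sd = u.std()
        u *= np.sqrt(arch.marker_h2) / (sd if sd > 0 else 1.0)
    else:
        u = np.zeros(n)

    resid_var = 1.0 - arch.qtl_h2 - arch.polygenic_h2 - arch.marker_h2
    e = rng.standard_normal(n) * np.sqrt(max(resid_var, 0.0))

    blocks = np.tile(np.arange(1, n_blocks + 1), n // n_blocks + 1)[:n]
    rng.shuffle(blocks)
    b_eff = rng.standard_normal(n_blocks) * np.sqrt(block_variance)
    latent = b_eff[blocks - 1] + qtl_value + a + u + e

    if arch.scale == "ordinal":
        qs = np.quantile(latent, np.linspace(0, 1, arch.ordinal_levels + 1)[1:-1])
        values = np.digitize(latent, qs) + arch.ordinal_start
        values = values.astype(float)
    else:
        values = latent

    tbv = qtl_value + a + u
    total_var = latent.var()
    realized = {
        "qtl": float(qtl_value.var() / total_var),
        "per_qtl": [float((codes[:, j] * b).var() / total_var)
                    for j, b in zip(qtl_idx, beta)],
        "polygenic": float(a.var() / total_var),
        "marker_background": float(u.var() / total_var),
        "residual": float(e.var() / total_var),
    }
    pheno = pd.DataFrame({"id": geno.individual_ids, "block": blocks,
                          arch.name: values})
    truth = TruthRecord(qtl_idx, beta, tbv, realized,
                        list(np.asarray(ped.loc[ped["sire"] == "0", "id"])))
    return pheno, truth


def default_traits() -> list[TraitArchitecture]:
    """Seven trait architectures echoing a eucalypt progeny trial: growth
    traits with ~10-26 moderate QTLs, ordinal stem-quality and flowering
    scores, pedigree heritabilities in the 0.08-0.34 band."""
    return [
        TraitArchitecture("HT", 11, tuple([0.03] * 11), 0.20, 0.10),
        TraitArchitecture("DBH", 16, tuple([0.025] * 16), 0.15, 0.10),
        TraitArchitecture("STR", 5, tuple([0.03] * 5), 0.20, 0.15,
                          scale="ordinal", ordinal_levels=4, ordinal_start=0),
        TraitArchitecture("SLD", 26, tuple([0.015] * 26), 0.10, 0.05),
        TraitArchitecture("WD", 10, tuple([0.03] * 10), 0.17, 0.12),
        TraitArchitecture("FI", 5, tuple([0.04] * 5), 0.30, 0.10,
                          scale="ordinal", ordinal_levels=4, ordinal_start=0),
        TraitArchitecture("BHT", 17, tuple([0.025] * 17), 0.08, 0.08,
                          scale="ordinal", ordinal_levels=5, ordinal_start=1),
    ]


def truth_to_json(truth: TruthRecord) -> dict:
    d = asdict(truth)
    d["qtl_marker_indices"] = [int(v) for v in truth.qtl_marker_indices]
    d["qtl_effects"] = [float(v) for v in truth.qtl_effects]
    d["true_breeding_values"] = [float(v) for v in truth.true_breeding_values]
    return d
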