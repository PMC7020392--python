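"""End-to-end comparison: QC -> phenotype pre-correction -> GWAS -> kernels
-> GS/GSq fits under four marker priors -> DIC / predictive-ability /
heritability tables.

One global seed derives per-stage seeds deterministically by hashing the
stage name, so stages are reproducible independently of each other.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas, popgen
from .evaluate import cross_validate, delta_dic, fit_dic, fit_heritabilities
from .io import (AdjustedPhenotype, GenotypeMatrix, adjust_phenotypes,
                 filter_markers, impute_knn, read_genotypes, read_pedigree,
                 read_phenotypes)
from .kinship import marker_kinship, pedigree_A, qtl_Q
from .simulate import SimConfig, TraitArchitecture, default_traits, \
    simulate_genotypes, simulate_phenotypes
from .wgr import MCMCSettings, ModelSpec, fit as wgr_fit

logger = logging.getLogger(__name__)

METHODS = ("BayesA", "BayesB", "BayesCpi", "BRR")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    # simulate-mode inputs
    sim: SimConfig | None = None
    sim_traits: list = field(default_factory=default_traits)
    # file-mode inputs
    genotype_path: str | None = None
    genotype_format: str = "csv012"
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    traits: list | None = None          # trait names when loading from files
    structure_covariates_path: str | None = None
    # stages
    call_rate_min: float = 0.7
    maf_min: float = 0.05
    knn_k: int = 5
    knn_l: int = 30
    gwas_alpha: float = 0.001
    gwas_fdr_max: float = 0.10
    methods: tuple = METHODS
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    cv_folds: int = 20
    run_cv: bool = True
    op_sib_coefficient: float = 0.25
    outdir: str = "gsq_run"
    seed: int = 1


def summarize_mtas(per_trait_results: dict) -> dict:
    """Per-trait significant-MTA counts, total, per-chromosome distribution
    and variance-explained ranges."""
    counts = {t: len(res) for t, res in per_trait_results.items()}
    per_chrom: dict = {}
    r2_range = {}
    for t, res in per_trait_results.items():
        for r in res:
            per_chrom[r.chromosome] = per_chrom.get(r.chromosome, 0) + 1
        r2s = [r.variance_explained for r in res
               if np.isfinite(r.variance_explained)]
        r2_range[t] = [float(min(r2s)), float(max(r2s))] if r2s else None
    return {"per_trait": counts, "total": int(sum(counts.values())),
            "per_chromosome": dict(sorted(per_chrom.items())),
            "variance_explained_range": r2_range}


def _load_or_simulate(config: RunConfig):
    """Returns (geno_raw, pedigree, phenotype table, structure covariates,
    subpop labels or None, truths dict or None)."""
    if config.sim is not None:
        sim = config.sim
        gs = simulate_genotypes(sim)
        pheno = None
        truths = {}
        for i, arch in enumerate(config.sim_traits):
            tseed = stage_seed(config.seed, f"pheno:{arch.name}:{i}")
            tab, truth = simulate_phenotypes(gs.geno, gs.pedigree, arch,
                                             n_blocks=sim.n_blocks,
                                             block_variance=sim.block_variance,
                                             seed=tseed)
            pheno = tab if pheno is None else pheno.merge(
                tab[["id", arch.name]], on="id")
            truths[arch.name] = truth
        # subpopulation indicator covariates (drop first to avoid confounding
        # with the intercept)
        S = pd.get_dummies(gs.subpop_labels, drop_first=True).to_numpy(float)
        return gs.geno, gs.pedigree, pheno, S, gs.subpop_labels, truths
    geno = read_genotypes(config.genotype_path, config.genotype_format)
    ped = read_pedigree(config.pedigree_path)
    pheno = read_phenotypes(config.phenotype_path)
    if "SLD" in (config.traits or []) and "SLD" not in pheno.columns \
            and {"HT", "DBH"} <= set(pheno.columns):
        # slenderness = height (m) / diameter (m); DBH recorded in cm
        pheno["SLD"] = pheno["HT"] / (pheno["DBH"] / 100.0)
    S = None
    if config.structure_covariates_path:
        S = pd.read_csv(config.structure_covariates_path, index_col=0) \
            .to_numpy(float)
    return geno, ped, pheno, S, None, None


def run_comparison(config: RunConfig) -> dict:
    """Execute the full GS-versus-GSq comparison; returns the report dict
    and writes tables plus a machine-readable JSON under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    stage = "inputs"
    try:
        geno_raw, ped, pheno, S, subpops, truths = _load_or_simulate(config)
        trait_names = ([a.name for a in config.sim_traits] if config.sim is not None
                       else list(config.traits or []))
        for t in trait_names:
            if t not in pheno.columns:
                raise KeyError(f"trait {t!r} missing from phenotype table")

        stage = "qc"
        geno_f = filter_markers(geno_raw, config.call_rate_min, config.maf_min)
        geno = impute_knn(geno_f, config.knn_k, config.knn_l)
        report["stages"]["qc"] = dict(geno_f.filter_report)

        stage = "diversity"
        div = popgen.heterozygosity(geno)
        report["stages"]["diversity"] = {"he": div.he, "ho": div.ho}
        per_chrom = geno.marker_meta.groupby("chrom").size()
        report["stages"]["panel"] = {
            "n_markers": geno.n_markers,
            "n_chromosomes": int(per_chrom.size),
            "mean_snps_per_chromosome": float(per_chrom.mean()),
        }
        if subpops is not None and len(np.unique(subpops)) > 1:
            fst = popgen.pairwise_fst(geno, subpops)
            fst.to_csv(out / "fst_pairwise.csv")
            report["stages"]["fst_pairwise"] = {
                f"{a}-{b}": float(fst.loc[a, b])
                for i, a in enumerate(fst.index) for b in fst.index[i + 1:]}

        stage = "kernels"
        A = pedigree_A(ped, config.op_sib_coefficient)
        K = marker_kinship(geno)

        per_trait_mtas: dict = {}
        tables: dict = {"dic": [], "pa": [], "h2": []}
        for trait in trait_names:
            stage = f"gwas:{trait}"
            aligned = pheno.set_index("id").loc[geno.individual_ids].reset_index()
            S_aligned = S  # simulate mode already aligned; file mode caller's duty
            y_star = adjust_phenotypes(aligned, trait, use_structure=S is not None,
                                       structure_covariates=S_aligned)
            scan = gwas.scan_markers(y_star, geno, K, S_aligned)
            sig = gwas.select_mtas(scan, config.gwas_alpha, config.gwas_fdr_max)
            gwas.annotate_variance_explained(scan, y_star, geno)
            gwas.results_to_frame(scan).to_csv(out / f"mta_{trait}.tsv",
                                               sep="\t", index=False)
            per_trait_mtas[trait] = sig
            sig_idx = np.array([r.marker_index for r in sig], dtype=int)

            stage = f"fit:{trait}"
            trait_report = {"n_mta": len(sig)}
            gs_kernels = [("A", A)]
            gsq_possible = len(sig) > 0
            if gsq_possible:
                Q = qtl_Q(geno, sig_idx)
                gsq_kernels = [("A", A), ("Q", Q)]
                nonsig = np.setdiff1d(np.arange(geno.n_markers), sig_idx)
            else:
                trait_report["gsq_note"] = ("no significant MTAs; GSq undefined, "
                                            "GS only")
            for method in config.methods:
                fits = {}
                mc = MCMCSettings(config.mcmc.n_iter, config.mcmc.burn_in,
                                  config.mcmc.thin,
                                  stage_seed(config.seed, f"{trait}:{method}"))
                specs = {"GS": ModelSpec(method, "GS", None, gs_kernels, mc)}
                if gsq_possible:
                    specs["GSq"] = ModelSpec(method, "GSq", nonsig, gsq_kernels, mc)
                for approach, spec in specs.items():
                    posterior = wgr_fit(y_star, geno, spec)
                    d = fit_dic(posterior)
                    h2 = fit_heritabilities(posterior)
                    fits[approach] = (posterior, d, h2)
                    tables["dic"].append({"trait": trait, "approach": approach,
                                          "method": method, "dic": d.dic,
                                          "d_bar": d.d_bar, "p_d": d.p_d})
                    tables["h2"].append({"trait": trait, "approach": approach,
                                         "method": method, "h2_a": h2.h2_a,
                                         "h2_m": h2.h2_m, "h2_q": h2.h2_q})
                    if config.run_cv:
                        cv = cross_validate(y_star, geno, spec, config.cv_folds,
                                            stage_seed(config.seed, f"cv:{trait}"))
                        tables["pa"].append({"trait": trait, "approach": approach,
                                             "method": method,
                                             "mean_pa": cv.mean_pa})
                if gsq_possible:
                    delta, verdict = delta_dic(fits["GS"][1].dic,
                                               fits["GSq"][1].dic)
                    tables["dic"].append({"trait": trait, "approach": "delta",
                                          "method": method, "dic": delta,
                                          "d_bar": np.nan, "p_d": np.nan,
                                          "verdict": verdict})
            report["stages"][f"trait:{trait}"] = trait_report

        stage = "summary"
        report["mta_summary"] = summarize_mtas(per_trait_mtas)
        for name, rows in tables.items():
            df = pd.DataFrame(rows)
            df.to_csv(out / f"table_{name}.tsv", sep="\t", index=False)
            report[f"table_{name}"] = rows
        if truths:
            report["truth_recovery"] = _recovery_report(tables, truths)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=_jsonify)
        return report
    except Exception as exc:
        with open(out / "FAILED.json", "w") as fh:
            json.dump({"stage": stage, "error": str(exc)}, fh, default=_jsonify)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _recovery_report(tables: dict, truths: dict) -> dict:
    out = {}
    h2 = pd.DataFrame(tables["h2"])
    for trait, truth in truths.items():
        sub = h2[(h2["trait"] == trait)]
        if sub.empty:
            continue
        out[trait] = {
            "true_polygenic_h2": truth.realized_h2_components["polygenic"],
            "true_marker_h2": truth.realized_h2_components["marker_background"],
            "true_qtl_h2": truth.realized_h2_components["qtl"],
            "estimated_h2_a_mean": float(sub["h2_a"].mean()),
            "estimated_h2_m_mean": float(sub["h2_m"].mean()),
            "estimated_h2_q_mean": float(sub[sub["approach"] == "GSq"]["h2_q"].mean())
            if (sub["approach"] == "GSq").any() else None,
            "n_true_qtl": int(len(truth.qtl_marker_indices)),
        }
    return out


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
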