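"""Stage 2: GS and GSq whole-genome regression fits.

For each trait, fits the GS model (all markers + pedigree polygenic kernel)
and, where the scan found MTAs, the GSq model (non-significant markers +
pedigree kernel + QTL-genotype kernel) under each requested marker prior.
Writes DIC and heritability partitions per fit under results/fits/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gsq.evaluate import fit_dic, fit_heritabilities
from gsq.io import adjust_phenotypes, read_genotypes, read_pedigree, \
    read_phenotypes
from gsq.kinship import pedigree_A, qtl_Q
from gsq.wgr import MCMCSettings, ModelSpec, fit

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--methods", nargs="+", default=["BRR", "BayesCpi"],
                    choices=["BayesA", "BayesB", "BayesCpi", "BRR"])
    ap.add_argument("--n-iter", type=int, default=6000)
    ap.add_argument("--burn-in", type=int, default=1500)
    ap.add_argument("--traits", nargs="+", default=None,
                    help="subset of traits (default: all)")
    args = ap.parse_args()

    data = ROOT / "results" / "data"
    gwas_dir = ROOT / "results" / "gwas"
    out = ROOT / "results" / "fits"
    out.mkdir(parents=True, exist_ok=True)
    geno = read_genotypes(data / "genotypes_clean.csv", "csv012")
    pheno = read_phenotypes(data / "phenotypes.csv")
    ped = read_pedigree(data / "pedigree.csv")
    S = pd.read_csv(data / "structure.csv", index_col=0).to_numpy(float)
    A = pedigree_A(ped)

    traits = args.traits or [c for c in pheno.columns
                             if c not in ("id", "block")]
    rows = []
    for trait in traits:
        aligned = pheno.set_index("id").loc[geno.individual_ids].reset_index()
        ys = adjust_phenotypes(aligned, trait, use_structure=True,
                               structure_covariates=S)
        mta = pd.read_csv(gwas_dir / f"mta_{trait}.tsv", sep="\t")
        sig_idx = mta.index[mta["significant"]].to_numpy()
        specs = {"GS": (None, [("A", A)])}
        if sig_idx.size:
            specs["GSq"] = (np.setdiff1d(np.arange(geno.n_markers), sig_idx),
                            [("A", A), ("Q", qtl_Q(geno, sig_idx))])
        else:
            print(f"{trait}: no MTAs, GSq skipped")
        for method in args.methods:
            for approach, (marker_set, kernels) in specs.items():
                mc = MCMCSettings(args.n_iter, args.burn_in, 3,
                                  seed=args.seed)
                post = fit(ys, geno, ModelSpec(method, approach, marker_set,
                                               kernels, mc))
                d = fit_dic(post)
                h2 = fit_heritabilities(post)
                rows.append({"trait": trait, "method": method,
                             "approach": approach, "dic": round(d.dic, 1),
                             "p_d": round(d.p_d, 1),
                             "h2_a": round(h2.h2_a, 3),
                             "h2_m": round(h2.h2_m, 3),
                             "h2_q": round(h2.h2_q, 3),
                             "n_mta": int(sig_idx.size)})
                print(rows[-1])
    table = pd.DataFrame(rows)
    table.to_csv(out / "fit_summary.tsv", sep="\t", index=False)
    with open(out / "fit_summary.json", "w") as fh:
        json.dump(rows, fh, indent=1)


if __name__ == "__main__":
    main()
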