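"""Simulate the open-pollinated progeny trial used by the downstream steps.

Generates 49 maternal families of 10 genotyped offspring on a low-density
SNP panel spread over 11 chromosomes, with founder dams drawn from three
subpopulations (pairwise F_ST targets 0.086 / 0.25 / 0.28), a 30-block
field design, and seven traits mixing moderate-effect QTLs with a pedigree
polygenic background. Writes genotypes, pedigree, phenotypes, structure
covariates and the truth record under results/data/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gsq.io import write_csv012, write_vcf
from gsq.simulate import SimConfig, default_traits, simulate_genotypes, \
    simulate_phenotypes, truth_to_json

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-markers", type=int, default=800,
                    help="panel size (desk-scale default keeps later MCMC fast)")
    args = ap.parse_args()

    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_markers=args.n_markers, seed=args.seed)
    sim = simulate_genotypes(cfg)
    write_vcf(sim.geno, out / "genotypes.vcf")
    write_csv012(sim.geno, out / "genotypes.csv")
    sim.pedigree.to_csv(out / "pedigree.csv", index=False)
    pd.get_dummies(sim.subpop_labels, drop_first=True).astype(float) \
        .to_csv(out / "structure.csv")

    pheno, truths = None, {}
    for i, arch in enumerate(default_traits()):
        tab, truth = simulate_phenotypes(sim.geno, sim.pedigree, arch,
                                         n_blocks=cfg.n_blocks,
                                         block_variance=cfg.block_variance,
                                         seed=args.seed * 131 + i)
        pheno = tab if pheno is None else pheno.merge(tab[["id", arch.name]],
                                                      on="id")
        truths[arch.name] = truth_to_json(truth)
    pheno.to_csv(out / "phenotypes.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=1)

    print(f"simulated {sim.geno.n_individuals} offspring x "
          f"{sim.geno.n_markers} markers; traits: "
          f"{[a.name for a in default_traits()]}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
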