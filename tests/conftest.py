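import numpy as np
import pandas as pd
import pytest

from gsq.io import GenotypeMatrix
from gsq.simulate import SimConfig, simulate_genotypes


def make_geno(codes, chrom=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, p = codes.shape
    meta = pd.DataFrame({
        "marker": [f"M{j}" for j in range(p)],
        "chrom": chrom if chrom is not None else ["1"] * p,
        "pos": np.arange(1, p + 1) * 100,
    })
    return GenotypeMatrix(codes, [f"ind{i}" for i in range(n)], meta)


@pytest.fixture(scope="session")
def small_sim():
    """One panmictic simulated trial reused across read-only tests."""
    cfg = SimConfig(n_families=20, offspring_per_family=8, n_markers=400,
                    n_chromosomes=4, n_subpops=1, target_fst=0.0, seed=42)
    return simulate_genotypes(cfg)
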