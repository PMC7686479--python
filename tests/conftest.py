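import numpy as np
import pandas as pd
import pytest

from tprsmap.genotypes import VARIANT_COLUMNS, GenotypeMatrix
from tprsmap.simulate import SimulationConfig, simulate_study


def make_genotypes(dosages, chrom=None, pos=None, ref=None, alt=None,
                   maf=None, info=None, ids=None):
    """Build a GenotypeMatrix from a raw dosage array with simple metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    emp_maf = np.minimum(p, 1 - p)
    variants = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, int),
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["G"] * m,
            "maf": maf if maf is not None else emp_maf,
            "info": info if info is not None else np.full(m, 0.99),
            "missing_rate": np.isnan(dosages).mean(axis=0),
        },
        columns=VARIANT_COLUMNS,
    )
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(n)], variants)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_subjects=120, n_variants=300, n_genes=10, snps_per_gene=2,
        n_voxels=100, grid_dims=(5, 5, 4), seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, n_causal=10)
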