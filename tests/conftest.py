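import numpy as np
import pandas as pd
import pytest

from teqtl.geno import GenotypeMatrix
from teqtl.simulate import SimConfig, simulate_cohort


def make_genotypes(dosage, chrom=None, pos=None, ids=None) -> GenotypeMatrix:
    """Small GenotypeMatrix from a raw sample x variant dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["chr1"] * m,
            "pos": pos if pos is not None else list(range(1000, 1000 + 1000 * m, 1000)),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "maf": np.nan,
            "hwe_p": np.nan,
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)], variants=variants, dosage=dosage
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One compact cohort with the three default planted trios."""
    cfg = SimConfig(
        n_samples=120, n_snvs=400, n_genes=60, n_te_loci_per_region=40, seed=7
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects at all."""
    cfg = SimConfig(
        n_samples=120, n_snvs=400, n_genes=60, n_te_loci_per_region=40, seed=11
    )
    return simulate_cohort(cfg, plant_defaults=False)
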