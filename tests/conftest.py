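import numpy as np
import pytest

from hwukit.containers import CohortTable, GenotypeMatrix, VariantRecord
from hwukit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-sample cohort with one male-only causal gene and light
    missingness; shared across read-only tests."""
    config = SimulationConfig(
        n_samples=300,
        n_genes=3,
        snps_per_gene=10,
        causal={"GENE01": (0.5, 0.0)},
        missing_rate=0.02,
    )
    return simulate_cohort(config, seed=11)


@pytest.fixture()
def tiny_genotypes():
    """Hand-built 4x3 dosage matrix with one missing cell."""
    variants = [
        VariantRecord(chrom="1", pos=100, id="rs1", ref_allele="A", alt_allele="G", maf=0.25),
        VariantRecord(chrom="1", pos=200, id="rs2", ref_allele="C", alt_allele="T", maf=0.375),
        VariantRecord(chrom="2", pos=300, id="rs3", ref_allele="G", alt_allele="A", maf=0.5),
    ]
    dosage = np.array([
        [0.0, 1.0, 2.0],
        [1.0, 0.0, 1.0],
        [0.0, 2.0, 0.0],
        [1.0, 0.0, 1.0],
    ])
    mask = np.zeros((4, 3), dtype=bool)
    mask[2, 1] = True
    return GenotypeMatrix(["S1", "S2", "S3", "S4"], variants, dosage, mask)


@pytest.fixture()
def tiny_cohort():
    import pandas as pd

    return CohortTable(pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4"],
        "cpd": [0, 1, 3, 2],
        "gender": [0, 1, 0, 1],
        "race": ["Caucasian"] * 4,
        "site": ["COGA", "COGA", "COGEND", "COGEND"],
        "age": [40.0, 35.0, 50.0, 45.0],
    }))
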