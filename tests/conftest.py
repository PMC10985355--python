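import numpy as np
import pandas as pd
import pytest

import droughtomics as dm


@pytest.fixture(scope="session")
def small_geno() -> dm.GenotypeMatrix:
    """119 samples × 500 SNPs on two chromosomes, mild structure, no missing."""
    cfg = dm.SimConfig(
        n_samples=119,
        n_snps=500,
        chrom_lengths={"A01": 20_000_000, "C01": 20_000_000},
        fst=0.1,
        n_subpops=3,
        missing_rate=0.0,
        seed=42,
    )
    return dm.simulate_genotypes(cfg)


@pytest.fixture()
def toy_geno() -> dm.GenotypeMatrix:
    """Hand-built 6-sample × 4-SNP matrix with one missing call."""
    dosage = np.array(
        [
            [0, 2, 1, 0],
            [1, 1, 0, 0],
            [2, 0, 1, 1],
            [0, 2, 2, dm.MISSING],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    snps = pd.DataFrame(
        {
            "id": ["A01_100", "A01_900", "A01_5000", "C01_100"],
            "chrom": ["A01", "A01", "A01", "C01"],
            "pos": [100, 900, 5000, 100],
            "ref": ["A", "C", "G", "T"],
            "alt": ["G", "T", "A", "C"],
        }
    )
    return dm.GenotypeMatrix(
        samples=[f"S{i}" for i in range(6)], snps=snps, dosage=dosage
    )


def make_pheno(values: dict[str, list[float]], trait="T", year=2017, regime="WW"):
    """Long phenotype frame from {variety: [rep1, rep2, ...]}."""
    rows = []
    for v, reps in values.items():
        for r, val in enumerate(reps, start=1):
            rows.append((v, trait, year, regime, r, val))
    return pd.DataFrame(
        rows, columns=["variety", "trait", "year", "regime", "rep", "value"]
    )
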