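import numpy as np
import pandas as pd
import pytest

from treeblup.data_io import GenotypeMatrix, PhenotypeTable, SnpRecord
from treeblup.simulate import SimConfig, simulate_cohort


def make_matrix(dosage, chroms=None, positions=None) -> GenotypeMatrix:
    """Small GenotypeMatrix from a literal dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    snps = [
        SnpRecord(f"s{k + 1}",
                  str(chroms[k]) if chroms is not None else "1",
                  int(positions[k]) if positions is not None else (k + 1) * 1000)
        for k in range(m)
    ]
    return GenotypeMatrix([f"a{i + 1}" for i in range(n)], snps, dosage)


def make_pheno(y, groups=None, ages=None, ids=None) -> PhenotypeTable:
    y = np.asarray(y, dtype=float)
    n = len(y)
    return PhenotypeTable(pd.DataFrame({
        "animal_id": ids if ids is not None else [f"a{i + 1}" for i in range(n)],
        "y_raw": y,
        "contemporary_group": groups if groups is not None else ["G1"] * n,
        "age_days": ages if ages is not None else [400] * n,
    }))


@pytest.fixture(scope="session")
def small_cohort():
    """Shared mid-size simulated cohort with real signal (n=300, m=600)."""
    cfg = SimConfig(n_animals=300, m_snps=600, n_qtl=30, h2_true=0.4,
                    n_groups=6, seed=314)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
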