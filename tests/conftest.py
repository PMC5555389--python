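import numpy as np
import pandas as pd
import pytest

from twinherit.grm import GenotypeMatrix
from twinherit.synthetic import CohortSpec, simulate_twin_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Complete-pair cohort at study architecture, reduced group sizes."""
    return simulate_twin_cohort(CohortSpec(
        n_pairs_by_group={"MZ-f": 150, "DZ-f": 200, "MZ-m": 150,
                          "DZ-m": 150, "OS": 300},
        singleton_fraction=0.0, seed=42))


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """Full-size cohort (3612 complete pairs) at the study architecture."""
    return simulate_twin_cohort(CohortSpec(singleton_fraction=0.0, seed=7))


@pytest.fixture()
def tiny_genotypes() -> GenotypeMatrix:
    """3 individuals x 2 SNPs with clean arithmetic for hand checks."""
    snps = pd.DataFrame({"id": ["s1", "s2"], "chrom": "1", "pos": [100, 200],
                         "a1": "A", "a2": "G"})
    dos = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
    return GenotypeMatrix(["i1", "i2", "i3"], snps, dos)
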