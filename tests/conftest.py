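"""Shared fixtures: a simulated four-population study panel and small
hand-built genotype matrices."""

import numpy as np
import pandas as pd
import pytest

from introsel.genotype_io import MISSING, GenotypeMatrix
from introsel.simulate import DemographyParams, simulate_panel


@pytest.fixture(scope="session")
def sim_default():
    """One full-size simulated study: (panel, gm, truth), alpha = 0.25."""
    return simulate_panel(DemographyParams(seed=11))


@pytest.fixture(scope="session")
def sim_small():
    """A faster, smaller replicate for tests that only need structure."""
    dp = DemographyParams(
        n_snps=1200,
        split_gens={"O": 120, "P3": 80, "P12": 40},
        admix_gen=10,
        seed=7,
    )
    return simulate_panel(dp)


def make_gm(dosages, bp=None, chrom=None, pops=None, sex=None, cm=None):
    """Build a GenotypeMatrix from a dosage array with minimal metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    bp = np.arange(1, m + 1) * 1000 if bp is None else np.asarray(bp)
    chrom = ["1"] * m if chrom is None else list(chrom)
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "snp_id": [f"s{j}" for j in range(m)],
            "cm": bp / 1e6 if cm is None else cm,
            "bp": bp.astype(np.int64),
            "allele1": "A",
            "allele2": "B",
        }
    )
    pops = ["POP"] * n if pops is None else list(pops)
    sex = ["unknown"] * n if sex is None else list(sex)
    individuals = pd.DataFrame(
        {"id": [f"i{k}" for k in range(n)], "population": pops, "sex": sex}
    )
    return GenotypeMatrix(dosages=dosages, snps=snps, individuals=individuals)


@pytest.fixture
def toy_gm():
    """4 diploids x 5 SNPs with one missing call."""
    d = np.array(
        [
            [0, 1, 2, 1, 0],
            [1, 1, 2, 0, 0],
            [2, 0, 2, 1, MISSING],
            [1, 2, 2, 2, 0],
        ],
        dtype=np.int8,
    )
    return make_gm(d)
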