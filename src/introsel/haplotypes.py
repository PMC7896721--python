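"""Phased haplotype container shared by the simulator and the selection scans."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes, two consecutive rows per individual.

    ``haplotypes`` is a (2*n_ind, n_snp) array in {0, 1}; a value of 1
    means the haplotype carries allele1 of the SNP map.  The per-SNP
    ``ancestral`` column of ``snps`` records orientation: 1 if allele1
    is ancestral, 0 if allele2 is, -1 if unknown.
    """

    haplotypes: np.ndarray
    snps: pd.DataFrame
    individuals: pd.DataFrame
    phased: bool = True

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.individuals), len(self.snps)):
            raise ValueError("haplotype shape inconsistent with metadata")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("haplotypes must be binary")

    @property
    def n_ind(self) -> int:
        return len(self.individuals)

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    def hap_index(self, population: str) -> np.ndarray:
        """Row indices of the haplotypes belonging to one population."""
        ind = np.flatnonzero(self.individuals["population"].to_numpy() == population)
        if ind.size == 0:
            raise KeyError(f"population {population!r} not present")
        return np.sort(np.concatenate([2 * ind, 2 * ind + 1]))

    def to_genotypes(self) -> GenotypeMatrix:
        dosages = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        return GenotypeMatrix(
            dosages=dosages, snps=self.snps.copy(), individuals=self.individuals.copy()
        )
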