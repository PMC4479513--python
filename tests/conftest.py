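"""Shared fixtures: small hand-built genotype tables and synthetic datasets."""

import numpy as np
import pytest

from msatpop.genotype_io import GenotypeTable, PopulationGroup


@pytest.fixture
def toy_table() -> GenotypeTable:
    """Two populations, two loci, one missing pair; states in repeat units."""
    alleles = np.array(
        [
            [[10, 12], [20, 20]],
            [[10, 10], [20, 21]],
            [[12, 12], [0, 0]],
            [[11, 12], [21, 21]],
            [[10, 11], [20, 21]],
        ]
    )
    return GenotypeTable(
        individuals=["a1", "a2", "a3", "b1", "b2"],
        loci=["L1", "L2"],
        alleles=alleles,
        populations=["A", "A", "A", "B", "B"],
    )


@pytest.fixture
def rarefaction_table() -> GenotypeTable:
    """One population, one locus: 5 diploids with allele copy counts {6, 3, 1}."""
    alleles = np.array(
        [[[10, 10]], [[10, 10]], [[10, 11]], [[11, 11]], [[10, 12]]]
    )
    return GenotypeTable(
        individuals=[f"i{k}" for k in range(5)],
        loci=["L1"],
        alleles=alleles,
        populations=["P"] * 5,
    )


@pytest.fixture
def groups_ab() -> tuple[PopulationGroup, PopulationGroup]:
    return PopulationGroup("ga", ["A"]), PopulationGroup("gb", ["B"])
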