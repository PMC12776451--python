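import numpy as np
import pytest

from foundercnv.formats import CNVCall, GeneticMap, HaplotypePanel, uniform_map
from foundercnv.sharing import Region


@pytest.fixture
def two_anchor_map() -> GeneticMap:
    """Anchors (1 Mb -> 0 cM) and (2 Mb -> 1 cM), terminal rate 1 cM/Mb."""
    gmap = GeneticMap()
    gmap.add_chromosome("chr1", [1_000_000, 2_000_000], [1.0, 1.0], [0.0, 1.0])
    return gmap


@pytest.fixture
def small_region() -> Region:
    return Region("chr1", 5_000_000, 5_100_000)


@pytest.fixture
def flat_map(small_region) -> GeneticMap:
    return uniform_map("chr1", 1_000_000, 9_000_000, 1.0)


def make_call(sample="S1", chrom="chr1", start=100_000, end=200_000, state="DEL",
              n_probes=20, caller="A", cn=None) -> CNVCall:
    return CNVCall(sample, chrom, start, end, state, n_probes, caller, cn)


@pytest.fixture
def toy_panel(small_region) -> HaplotypePanel:
    """Deterministic panel: 10 SNPs each side of the region, 4 haplotypes.

    Haplotypes H1/H2 are identical (the ancestral background); H3 differs
    at the 3rd SNP out on each side; H4 is the complement everywhere.
    """
    left = np.arange(4_990_000, 5_000_000, 1_000)
    right = np.arange(5_101_000, 5_111_000, 1_000)
    positions = np.concatenate([left, right])
    ancestral = np.tile([0, 1], 10)
    h3 = ancestral.copy()
    h3[7] = 1 - h3[7]    # 3rd SNP walking left from the boundary (index 9,8,7)
    h3[12] = 1 - h3[12]  # 3rd SNP walking right (index 10,11,12)
    alleles = np.stack([ancestral, ancestral, h3, 1 - ancestral])
    return HaplotypePanel("chr1", positions, alleles,
                          ["A_h1", "B_h1", "C_h1", "D_h1"])
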