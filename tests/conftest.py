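import numpy as np
import pytest

from splicelocus.panel import PhasedPanel, VariantDef
from splicelocus.sim import locus


@pytest.fixture(scope="session")
def gene():
    return locus.gene_model()


@pytest.fixture(scope="session")
def genome():
    return locus.genome()


@pytest.fixture
def tiny_panel():
    """Hand-built 2-individual (4-chromosome) panel over two variants.

    Chromosomes: (1,0), (0,1), (0,0), (1,0) -> haplotype counts are known
    by inspection.
    """
    variants = [
        VariantDef("vA", "chr1", 100, "A", "G", 0.4),
        VariantDef("vB", "chr1", 200, "C", "T", 0.2),
    ]
    chroms = np.array([[1, 0], [0, 1], [0, 0], [1, 0]], dtype=np.int8)
    alleles = chroms.reshape(2, 2, 2).transpose(0, 2, 1)
    return PhasedPanel(["i1", "i2"], variants, alleles)


def panel_from_counts(n11: int, n10: int, n01: int, n00: int) -> PhasedPanel:
    """Panel whose chromosomes realize exact 2x2 haplotype counts
    (alt/alt, alt/ref, ref/alt, ref/ref); counts are doubled if the total
    is odd so chromosomes pair into individuals."""
    rows = (
        [[1, 1]] * n11 + [[1, 0]] * n10 + [[0, 1]] * n01 + [[0, 0]] * n00
    )
    if len(rows) % 2:
        rows = rows * 2
    chroms = np.array(rows, dtype=np.int8)
    n = len(rows) // 2
    variants = [
        VariantDef("va", "chr1", 10, "A", "G", 0.5),
        VariantDef("vb", "chr1", 20, "C", "T", 0.5),
    ]
    alleles = chroms.reshape(n, 2, 2).transpose(0, 2, 1)
    return PhasedPanel([f"s{i}" for i in range(n)], variants, alleles)
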