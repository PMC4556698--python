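"""The default simulated study locus.

Four biallelic variants at an LDL-receptor-like locus whose minor alleles
are mutually exclusive on haplotypes, with their population frequencies and
additive non-HDL-cholesterol effects (mmol/l per allele):

==============  ========  =====  ============================
variant         MAF (%)   beta   role
==============  ========  =====  ============================
rs17248720-T    8.8       -0.24  common upstream variant
rs17248748-T    3.4       -0.13  intron-1 variant
rs200238879-C   0.06      +1.33  rare splice-donor variant
rs72658867-A    2.2       -0.44  splice-region index variant
==============  ========  =====  ============================

Plus a synthetic 18-exon gene on its own contig used by the RNA-seq
simulator and the consequence predictor.  The gene's intron 14 is the
retention target; its sequence is constructed so that a retained-intron
transcript translates through exactly 33 novel residues before a premature
stop, and the coding sequence elsewhere is free of in-frame stops.  The
contig sequence is deterministic (fixed internal seed): it is a coordinate
system and translation fixture, not a source of randomness.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from splicelocus.genes import TranscriptModel
from splicelocus.panel import VariantDef
from splicelocus.sim.rnaseq import MarkerDef, RnaSimConfig

INDEX_VARIANT = "rs72658867"

#: adjusted per-allele effects on non-HDL-C, mmol/l
NONHDL_EFFECTS = {
    "rs17248720": -0.24,
    "rs17248748": -0.13,
    "rs200238879": 1.33,
    "rs72658867": -0.44,
}

TRAIT_MEAN = 4.00  # mmol/l
TRAIT_SD = 1.18  # mmol/l

_EXON_LEN = 120
_INTRON_LEN = 250
_N_EXONS = 18
_FLANK = 1000
RETAINED_INTRON = 14
CDS_OFFSET = 60  # 0-based transcript coordinate of the CDS start
GENE_CHROM = "geneX"

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def locus_variants() -> list[VariantDef]:
    return [
        VariantDef("rs17248720", "chr19", 11_059_187, "C", "T", 0.088),
        VariantDef("rs17248748", "chr19", 11_067_040, "C", "T", 0.034),
        VariantDef("rs200238879", "chr19", 11_077_278, "T", "C", 0.0006),
        VariantDef("rs72658867", "chr19", 11_092_203, "G", "A", 0.022),
    ]


def exclusivity_groups() -> list[list[str]]:
    """All four minor alleles are mutually exclusive on haplotypes."""
    return [[v.id for v in locus_variants()]]


def gene_model() -> TranscriptModel:
    exons = []
    pos = _FLANK + 1
    for _ in range(_N_EXONS):
        exons.append((pos, pos + _EXON_LEN - 1))
        pos += _EXON_LEN + _INTRON_LEN
    return TranscriptModel("geneX", GENE_CHROM, "+", tuple(exons))


@lru_cache(maxsize=1)
def genome() -> dict[str, str]:
    """Deterministic contig for the synthetic gene."""
    rng = np.random.default_rng(20150901)
    model = gene_model()
    length = model.exons[-1][1] + _FLANK
    seq = rng.choice(list("ACGT"), size=length)

    # lay down a stop-free CDS over the exons, terminated by TAA
    spliced_pos = np.concatenate(
        [np.arange(s - 1, e) for s, e in model.exons]
    )  # 0-based genomic positions of spliced transcript bases
    n_cds = model.spliced_length - CDS_OFFSET - 66  # leave a 3' UTR
    n_cds -= n_cds % 3
    codons = rng.choice(_NONSTOP, size=n_cds // 3 - 1)
    cds = "".join(codons) + "TAA"
    for tpos, base in zip(range(CDS_OFFSET, CDS_OFFSET + n_cds), cds):
        seq[spliced_pos[tpos]] = base

    # intron 14: GT..., 33 non-stop codons in the shifted frame, then TAA
    s14, e14 = model.intron(RETAINED_INTRON)
    intron = list(rng.choice(list("ACGT"), size=_INTRON_LEN))
    novel = "GT" + str(rng.choice(list("ACGT")))
    novel += "".join(rng.choice(_NONSTOP, size=32)) + "TAA"
    intron[: len(novel)] = list(novel)
    intron[-2:] = ["A", "G"]
    seq[s14 - 1 : e14] = intron
    return {GENE_CHROM: "".join(seq)}


def domain_table() -> pd.DataFrame:
    """Synthetic protein domain annotation for the demo gene (residue
    coordinates of the 677-aa translation product)."""
    return pd.DataFrame(
        [
            ("ligand-binding", 1, 300),
            ("EGF-like", 301, 500),
            ("O-linked glycan", 541, 580),
            ("transmembrane", 581, 610),
            ("cytoplasmic", 611, 677),
        ],
        columns=["domain", "start", "end"],
    )


def ase_markers() -> tuple[MarkerDef, ...]:
    """Five phased exonic markers, index alt allele linked to the reference
    base at each (sign = -1)."""
    model = gene_model()
    exon_idx = (2, 5, 8, 12, 16)
    return tuple(
        MarkerDef(f"mk{e}", model.exons[e - 1][0] + _EXON_LEN // 2, sign=-1)
        for e in exon_idx
    )


def rna_config(**overrides) -> RnaSimConfig:
    """Default RNA-seq simulation: intron-14 retention at 0.5 on the mutant
    haplotype, 1.44x mutant-haplotype expression, 7.7% reference-mapping
    bias, five planted markers."""
    kwargs = dict(
        retained_intron_index=RETAINED_INTRON,
        retention_fraction_mut=0.5,
        retention_fraction_background=0.0,
        mut_expr_ratio=1.44,
        map_bias_discard=0.077,
        depth=100.0,
        read_length=76,
        markers=ase_markers(),
    )
    kwargs.update(overrides)
    return RnaSimConfig(**kwargs)
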