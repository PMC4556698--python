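"""Readers and writers for the standard interchange formats.

VCF v4.2 with phased ``|``-separated genotypes, SAM v1.6, GFF3, FASTA and
TSV tables.  Writers emit plain text; readers go through pysam (VCF, SAM),
gffutils (GFF3) and Biopython (FASTA).
"""

from __future__ import annotations

import datetime as _dt

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from splicelocus.genes import TranscriptModel
from splicelocus.panel import PhasedPanel, VariantDef


class VcfFormatError(ValueError):
    pass


def write_phased_vcf(panel: PhasedPanel, path: str) -> None:
    """VCF v4.2 with phased GT for every individual."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##fileDate={_dt.date.today():%Y%m%d}\n")
        fh.write("##source=splicelocus\n")
        for chrom in dict.fromkeys(v.chrom for v in panel.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individuals)
            + "\n"
        )
        for j, v in enumerate(panel.variants):
            gts = "\t".join(
                f"{a}|{b}" for a, b in panel.alleles[:, j, :]
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path: str, maf_from_data: bool = True) -> PhasedPanel:
    """Read a phased VCF into a panel.

    ``/``-separated (unphased) genotypes and multi-allelic sites are
    rejected with errors naming the offending site/sample.  Variant MAFs
    are taken from the observed data (capped into (0, 0.5]).
    """
    with pysam.VariantFile(path) as vcf:
        individuals = list(vcf.header.samples)
        variants: list[VariantDef] = []
        rows = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfFormatError(
                    f"{rec.id or rec.pos}: multi-allelic or ALT-less site"
                )
            alleles = np.zeros((len(individuals), 2), dtype=np.int8)
            for i, name in enumerate(individuals):
                sample = rec.samples[name]
                gt = sample["GT"]
                if gt is None or None in gt or len(gt) != 2:
                    raise VcfFormatError(
                        f"{rec.id or rec.pos}: missing GT for sample {name}"
                    )
                if not sample.phased:
                    raise VcfFormatError(
                        f"site {rec.id or rec.pos}, sample {name}: "
                        "unphased genotype; haplotype analyses need '|'"
                    )
                alleles[i] = gt
            rows.append(alleles)
            freq = float(np.mean(rows[-1])) if individuals else 0.25
            maf = min(max(freq, 1e-6), 0.5) if maf_from_data else 0.25
            variants.append(
                VariantDef(
                    id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    maf=maf,
                )
            )
    alleles = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(individuals), 0, 2), dtype=np.int8)
    )
    return PhasedPanel(individuals=individuals, variants=variants, alleles=alleles)


def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_gff3(model: TranscriptModel, path: str) -> None:
    """Single-transcript gene model as GFF3 (gene/mRNA/exon features)."""
    gmin = min(s for s, _ in model.exons)
    gmax = max(e for _, e in model.exons)
    gid, mid = model.gene_id, f"{model.gene_id}.t1"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"{model.chrom}\tsplicelocus\tgene\t{gmin}\t{gmax}\t.\t{model.strand}\t.\t"
            f"ID={gid}\n"
        )
        fh.write(
            f"{model.chrom}\tsplicelocus\tmRNA\t{gmin}\t{gmax}\t.\t{model.strand}\t.\t"
            f"ID={mid};Parent={gid}\n"
        )
        for i, (s, e) in enumerate(sorted(model.exons), start=1):
            fh.write(
                f"{model.chrom}\tsplicelocus\texon\t{s}\t{e}\t.\t{model.strand}\t.\t"
                f"ID={mid}.exon{i};Parent={mid}\n"
            )


def read_gff3(path: str) -> TranscriptModel:
    """Read a single-transcript gene model from GFF3."""
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = list(db.features_of_type("gene"))
    if len(genes) != 1:
        raise ValueError(f"expected exactly one gene, found {len(genes)}")
    gene = genes[0]
    exons = sorted(
        (f.start, f.end) for f in db.features_of_type("exon")
    )
    if gene.strand == "-":
        exons = exons[::-1]
    return TranscriptModel(
        gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, exons=tuple(exons)
    )


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
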