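"""Protein consequence of intron retention: frameshift, novel peptide and
lost domains.

Retaining an intron inserts its sequence into the mature mRNA.  Translation
stays intact through the last complete codon encoded 5' of the insertion
point; beyond it the ribosome reads into the intron (generally out of
frame) until the first stop codon.  The HGVS-style annotation
``p.<Aa><Pos>fsTer<N>`` reports the first altered residue and the stop's
position in the new reading frame; because conventions differ on whether
the added-residue count or the stop index is printed, the report exposes
both (``novel_residues`` added residues correspond to ``Ter`` index
``novel_residues + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from splicelocus.genes import TranscriptModel

_STOPS = set(standard_dna_table.stop_codons)

#: premature stop more than this many nt upstream of the last exon-exon
#: junction is flagged as a nonsense-mediated-decay candidate
NMD_JUNCTION_RULE_NT = 50


@dataclass
class ConsequenceReport:
    transcript_id: str
    retained_intron: int
    last_intact_residue: int  # protein position of the last unchanged residue
    last_intact_aa: str  # one-letter code
    first_novel_aa: str | None
    novel_residues: int  # residues added before the stop
    stop_found: bool
    novel_peptide: str
    annotation: str | None  # p.<Aa><Pos>fsTer<N+1>, None when no stop found
    nmd_predicted: bool | None
    lost_domains: list[tuple[str, int, int]] = field(default_factory=list)
    partial_domains: list[tuple[str, int, int]] = field(default_factory=list)
    retained_domains: list[tuple[str, int, int]] = field(default_factory=list)


def build_retained_transcript(
    model: TranscriptModel, genome: dict[str, str], intron_index: int
) -> str:
    """mRNA with the designated intron retained in place (5'->3',
    reverse-complemented for minus-strand models)."""
    return model.sequence(genome, retained_intron=intron_index)


def _translate(seq: str) -> str:
    aas = []
    table = standard_dna_table.forward_table
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            aas.append("*")
            break
        aas.append(table.get(codon, "X"))
    return "".join(aas)


def translate_to_stop(
    mrna: str,
    cds_offset: int,
    frameshift_offset: int,
) -> tuple[int, str, int, bool, str]:
    """Walk the shifted reading frame from the last intact codon boundary.

    ``cds_offset`` is the 0-based position of the CDS start in ``mrna``;
    ``frameshift_offset`` is the 0-based position where the retained intron
    begins (the first base that differs from the spliced transcript).  The
    last intact codon is the last complete codon lying entirely 5' of the
    frameshift; translation then proceeds until the first stop codon.

    Returns (last_intact_residue, last_intact_aa, novel_residues,
    stop_found, novel_peptide).
    """
    if not 0 <= cds_offset < len(mrna):
        raise ValueError("CDS start outside the transcript")
    if frameshift_offset < cds_offset:
        raise ValueError("frameshift upstream of the CDS start")
    intact_bases = frameshift_offset - cds_offset
    n_intact = intact_bases // 3
    last_intact_aa = "M"
    if n_intact >= 1:
        codon = mrna[cds_offset + 3 * (n_intact - 1) : cds_offset + 3 * n_intact]
        last_intact_aa = _translate(codon) or "X"
    novel = _translate(mrna[cds_offset + 3 * n_intact :])
    stop_found = novel.endswith("*")
    peptide = novel[:-1] if stop_found else novel
    return n_intact, last_intact_aa, len(peptide), stop_found, peptide


def domain_overlap_report(
    truncation_residue: int, domains: pd.DataFrame
) -> tuple[list, list, list]:
    """Classify protein domains relative to a truncation position.

    Domains entirely 3' of the truncation are lost, those spanning it are
    partial, those entirely 5' are retained.  Overlapping definitions are
    allowed and classified independently.
    """
    lost, partial, retained = [], [], []
    for _, row in domains.iterrows():
        item = (str(row["domain"]), int(row["start"]), int(row["end"]))
        if row["start"] > truncation_residue:
            lost.append(item)
        elif row["end"] <= truncation_residue:
            retained.append(item)
        else:
            partial.append(item)
    return lost, partial, retained


def predict_consequence(
    model: TranscriptModel,
    genome: dict[str, str],
    intron_index: int,
    cds_offset: int,
    domains: pd.DataFrame | None = None,
) -> ConsequenceReport:
    """Full consequence report for retaining ``intron_index``."""
    mrna = build_retained_transcript(model, genome, intron_index)
    # transcript offset where the retained intron begins: end of exon k + 1
    upstream_exonic = sum(model.exon_lengths()[:intron_index])
    n_intact, last_aa, n_novel, stop_found, peptide = translate_to_stop(
        mrna, cds_offset, upstream_exonic
    )
    first_novel = peptide[0] if peptide else ("*" if stop_found else None)

    annotation = None
    nmd = None
    if stop_found:
        # annotated at the last intact residue, stop indexed in the new frame
        annotation = f"p.{seq3(last_aa)}{n_intact}fsTer{n_novel + 1}"
        stop_tpos = cds_offset + 3 * n_intact + 3 * n_novel  # stop codon start
        last_junction = _last_junction_offset(model, intron_index)
        nmd = stop_tpos < last_junction - NMD_JUNCTION_RULE_NT

    lost, partial, kept = ([], [], [])
    if domains is not None:
        lost, partial, kept = domain_overlap_report(n_intact, domains)
    return ConsequenceReport(
        transcript_id=model.gene_id,
        retained_intron=intron_index,
        last_intact_residue=n_intact,
        last_intact_aa=last_aa,
        first_novel_aa=first_novel,
        novel_residues=n_novel,
        stop_found=stop_found,
        novel_peptide=peptide,
        annotation=annotation,
        nmd_predicted=nmd,
        lost_domains=lost,
        partial_domains=partial,
        retained_domains=kept,
    )


def _last_junction_offset(model: TranscriptModel, retained_intron: int) -> int:
    """Transcript offset of the most 3' exon-exon junction in the
    retained-intron transcript."""
    lengths = model.exon_lengths()
    total = sum(lengths) + model.intron_length(retained_intron)
    return total - lengths[-1]
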