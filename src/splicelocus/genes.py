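"""Transcript models and transcript/genome coordinate arithmetic.

Genomic coordinates are 1-based inclusive throughout the public surface
(matching GFF3 and SAM); transcript coordinates are 0-based half-open
internally.  Intron ``k`` (1-based) lies between exons ``k`` and ``k + 1``
in transcript order.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq


@dataclass(frozen=True)
class TranscriptModel:
    """A single-transcript gene model.

    ``exons`` are (start, end) 1-based inclusive genomic intervals, ordered
    5'->3' in transcript orientation: ascending genomic coordinates on the
    plus strand, descending on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 >= s2:
                raise ValueError("exons overlap or abut")
        ordered = genomic if self.strand == "+" else genomic[::-1]
        if tuple(ordered) != tuple(self.exons):
            raise ValueError("exons not ordered 5'->3' in transcript orientation")
        if any(s > e for s, e in self.exons):
            raise ValueError("exon start > end")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths())

    def intron(self, k: int) -> tuple[int, int]:
        """Genomic interval (1-based inclusive) of intron ``k`` (1-based)."""
        if not 1 <= k <= self.n_introns:
            raise IndexError(f"intron index {k} outside 1..{self.n_introns}")
        up, down = self.exons[k - 1], self.exons[k]
        if self.strand == "+":
            return (up[1] + 1, down[0] - 1)
        return (down[1] + 1, up[0] - 1)

    def intron_length(self, k: int) -> int:
        s, e = self.intron(k)
        return e - s + 1

    def blocks(self, retained_intron: int | None = None) -> list[tuple[int, int]]:
        """Genomic intervals of the mature transcript in transcript order.

        With ``retained_intron`` set, the intron is kept in place and its
        flanking exons merge with it into one contiguous block.
        """
        blocks = list(self.exons)
        if retained_intron is not None:
            k = retained_intron
            intron = self.intron(k)
            merged_lo = min(blocks[k - 1][0], blocks[k][0], intron[0])
            merged_hi = max(blocks[k - 1][1], blocks[k][1], intron[1])
            blocks[k - 1 : k + 1] = [(merged_lo, merged_hi)]
        return blocks

    def transcript_length(self, retained_intron: int | None = None) -> int:
        return sum(e - s + 1 for s, e in self.blocks(retained_intron))

    def sequence(self, genome: dict[str, str], retained_intron: int | None = None) -> str:
        """Mature mRNA sequence (5'->3'), optionally with one intron retained."""
        chrom_seq = genome[self.chrom]
        parts = []
        for s, e in self.blocks(retained_intron):
            piece = chrom_seq[s - 1 : e]
            if self.strand == "-":
                piece = str(Seq(piece).reverse_complement())
            parts.append(piece)
        return "".join(parts)

    def genome_to_transcript(self, gpos: int, retained_intron: int | None = None) -> int | None:
        """0-based transcript coordinate of genomic position, or None if intronic."""
        offset = 0
        for s, e in self.blocks(retained_intron):
            if s <= gpos <= e:
                within = gpos - s if self.strand == "+" else e - gpos
                return offset + within
            offset += e - s + 1
        return None

    def read_segments(
        self, tstart: int, length: int, retained_intron: int | None = None
    ) -> list[tuple[int, int]]:
        """Genomic intervals covered by a read of ``length`` starting at
        0-based transcript coordinate ``tstart``, ordered by genomic position.

        Only meaningful for plus-strand models (reads are emitted on the
        reference forward strand); minus-strand callers should convert.
        """
        if self.strand != "+":
            raise ValueError("read placement requires a plus-strand model")
        segs: list[tuple[int, int]] = []
        remaining = length
        offset = 0
        for s, e in self.blocks(retained_intron):
            blen = e - s + 1
            if remaining <= 0:
                break
            if tstart < offset + blen:
                lo = max(tstart - offset, 0)
                take = min(blen - lo, remaining)
                segs.append((s + lo, s + lo + take - 1))
                remaining -= take
            offset += blen
        if remaining > 0:
            raise ValueError("read extends past transcript end")
        return segs
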