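"""Simulation of spliced RNA-seq alignments for a multi-exon gene.

The model: each individual expresses the gene from both haplotypes; a
haplotype carrying the index (splice-region) alternative allele is
up-weighted by ``mut_expr_ratio`` and its transcripts retain the designated
intron with probability ``retention_fraction_mut`` (others with the
background rate).  Transcript copy numbers are Poisson; single-end reads are
placed uniformly along each transcript so that per-base read counts are
proportional to transcript copy number, and emitted as SAM records with
``N`` CIGAR operations across spliced-out introns.  Reads overlapping a
planted heterozygous exonic marker carry the haplotype's marker allele and,
when that allele differs from the reference base, are discarded with
probability ``map_bias_discard`` — a reference-mapping-bias model.

Read names encode individual, haplotype and splicing category
(``ind|h0|S|123``) so that truth-table read counts can be reconciled
against SAM-derived counts.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np
import pandas as pd

from splicelocus.genes import TranscriptModel
from splicelocus.panel import ConfigError

# default alternative allele planted at a marker: any base != the reference base
_ALT_OF = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass(frozen=True)
class MarkerDef:
    """A phased exonic marker used for allele-specific expression.

    ``sign`` is +1 when the marker's alternative allele rides on the same
    haplotype as the index alternative allele, -1 when the reference allele
    does.  ``alt_base`` defaults to a fixed substitution of the genome base.
    """

    id: str
    position: int  # 1-based genomic, must fall in an exon
    sign: int = -1
    alt_base: str | None = None

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ConfigError(f"marker {self.id}: sign must be +1 or -1")


@dataclass
class RnaSimConfig:
    """Tunable parameters of the RNA-seq simulator.

    ``depth`` is the expected number of junction-covering reads per
    individual at baseline (two expression units); ``transcripts_per_unit``
    sets the Poisson mean of transcript copies per expression unit, the
    dominant source of between-individual expression noise.
    """

    retained_intron_index: int
    retention_fraction_mut: float = 0.5
    retention_fraction_background: float = 0.0
    mut_expr_ratio: float = 1.44
    map_bias_discard: float = 0.077
    depth: float = 100.0
    read_length: int = 76
    markers: tuple[MarkerDef, ...] = ()
    transcripts_per_unit: int = 200
    total_aligned: float = 2.0e8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "retention_fraction_mut",
            "retention_fraction_background",
            "map_bias_discard",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.mut_expr_ratio <= 0:
            raise ConfigError("mut_expr_ratio must be positive")


class _Template:
    """One haplotype x splicing-category transcript template."""

    __slots__ = ("seq", "boff", "bstart", "blen", "alt_tpos", "retained")

    def __init__(
        self,
        seq: str,
        blocks: list[tuple[int, int]],
        alt_tpos: list[int],
        retained: bool,
    ):
        self.seq = seq
        self.bstart = [s for s, _ in blocks]
        self.blen = [e - s + 1 for s, e in blocks]
        self.boff = list(np.cumsum([0] + self.blen[:-1]))
        self.alt_tpos = alt_tpos
        self.retained = retained

    def cigar_and_pos(self, s: int, r: int) -> tuple[int, str]:
        i = bisect.bisect_right(self.boff, s) - 1
        within = s - self.boff[i]
        pos = self.bstart[i] + within
        if within + r <= self.blen[i]:
            return pos, f"{r}M"
        parts = []
        remaining = r
        while remaining > 0:
            take = min(self.blen[i] - within, remaining)
            parts.append(f"{take}M")
            remaining -= take
            if remaining > 0:
                gap = self.bstart[i + 1] - (self.bstart[i] + self.blen[i])
                parts.append(f"{gap}N")
                i += 1
                within = 0
        return pos, "".join(parts)


def _substitute(seq: str, positions: list[int], bases: list[str]) -> str:
    if not positions:
        return seq
    chars = list(seq)
    for p, b in zip(positions, bases):
        chars[p] = b
    return "".join(chars)


def sam_header(gene: TranscriptModel, genome: Mapping[str, str]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, seq in genome.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(seq)}")
    return "\n".join(lines) + "\n"


def simulate_rnaseq(
    genotypes: Mapping[str, int],
    gene: TranscriptModel,
    genome: Mapping[str, str],
    config: RnaSimConfig,
    sam_path: str,
) -> pd.DataFrame:
    """Simulate alignments for individuals with the given index-variant
    genotypes (alt-allele counts 0/1/2), writing SAM to ``sam_path``.

    Returns the truth table with one row per individual x haplotype x
    splicing category: transcript counts, emitted reads and bias-discarded
    reads.  Every simulated individual is heterozygous at each planted
    marker unless homozygous for the index allele (then markers are
    homozygous for the linked allele) — mirroring a study design in which
    only marker-heterozygous individuals are measured.
    """
    rng = np.random.default_rng(config.seed)
    if gene.strand != "+":
        raise ConfigError("the read simulator requires a plus-strand gene model")
    k = config.retained_intron_index
    if not 1 <= k <= gene.n_introns:
        raise ConfigError(f"retained_intron_index {k} is not an internal intron")
    r = config.read_length
    if r > gene.spliced_length:
        raise ConfigError("read_length exceeds the spliced transcript length")
    min_pair = min(
        gene.exon_lengths()[i] + gene.exon_lengths()[i + 1]
        for i in range(gene.n_exons - 1)
    )
    if r > min_pair:
        raise ConfigError("read_length exceeds the shortest adjacent exon-pair span")

    chrom_seq = genome[gene.chrom]
    markers = list(config.markers)
    for mk in markers:
        if gene.genome_to_transcript(mk.position) is None:
            raise ConfigError(f"marker {mk.id} at {mk.position} is not exonic")
    ref_bases = [chrom_seq[mk.position - 1] for mk in markers]
    alt_bases = [
        mk.alt_base if mk.alt_base is not None else _ALT_OF[ref]
        for mk, ref in zip(markers, ref_bases)
    ]
    tpos = {
        False: [gene.genome_to_transcript(mk.position) for mk in markers],
        True: [gene.genome_to_transcript(mk.position, k) for mk in markers],
    }
    base_seq = {False: gene.sequence(genome), True: gene.sequence(genome, k)}
    blocks = {False: gene.blocks(), True: gene.blocks(k)}

    c = config.depth / (2.0 * config.transcripts_per_unit * r)
    retention = {True: config.retention_fraction_mut, False: config.retention_fraction_background}

    truth_rows = []
    with open(sam_path, "w") as sam:
        sam.write(sam_header(gene, genome))
        for ind, g in genotypes.items():
            if g not in (0, 1, 2):
                raise ConfigError(f"{ind}: genotype {g} not in 0/1/2")
            hap_mut = (g >= 1, g == 2)
            # marker alleles per haplotype: True = alternative base
            if g == 1:
                hap_alt = [
                    [mk.sign == 1 for mk in markers],
                    [mk.sign != 1 for mk in markers],
                ]
            elif g == 2:
                hap_alt = [[mk.sign == 1 for mk in markers]] * 2
            else:
                first = [bool(b) for b in rng.integers(0, 2, size=len(markers))]
                hap_alt = [first, [not b for b in first]]

            for h in (0, 1):
                weight = config.mut_expr_ratio if hap_mut[h] else 1.0
                n_hap = rng.poisson(config.transcripts_per_unit * weight)
                n_ret = rng.binomial(n_hap, retention[hap_mut[h]]) if n_hap else 0
                for retained, n_t in ((False, n_hap - n_ret), (True, n_ret)):
                    sub_pos = [
                        p for p, a in zip(tpos[retained], hap_alt[h]) if a
                    ]
                    sub_base = [
                        b for b, a in zip(alt_bases, hap_alt[h]) if a
                    ]
                    tpl = _Template(
                        _substitute(base_seq[retained], sub_pos, sub_base),
                        blocks[retained],
                        sub_pos,
                        retained,
                    )
                    le = len(tpl.seq) - r + 1
                    n_reads = rng.poisson(n_t * c * le) if n_t else 0
                    starts = rng.integers(0, le, size=n_reads)
                    biased = np.zeros(n_reads, dtype=bool)
                    for p in tpl.alt_tpos:
                        biased |= (starts <= p) & (p < starts + r)
                    discard = biased & (rng.random(n_reads) < config.map_bias_discard)
                    cat = "R" if retained else "S"
                    n_emitted = 0
                    for serial, (s, drop) in enumerate(zip(starts, discard)):
                        if drop:
                            continue
                        pos, cigar = tpl.cigar_and_pos(int(s), r)
                        seq = tpl.seq[s : s + r]
                        sam.write(
                            f"{ind}|h{h}|{cat}|{serial}\t0\t{gene.chrom}\t{pos}"
                            f"\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n"
                        )
                        n_emitted += 1
                    truth_rows.append(
                        {
                            "individual": ind,
                            "haplotype": h,
                            "mutant": hap_mut[h],
                            "retained": retained,
                            "n_transcripts": int(n_t),
                            "n_reads": n_emitted,
                            "n_discarded": int(discard.sum()),
                        }
                    )
    return pd.DataFrame(truth_rows)
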