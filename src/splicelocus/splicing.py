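"""Intron-retention and expression quantification from RNA-seq alignments.

The central statistic: among reads that cover the last base of the exon
upstream of a junction, the proportion whose alignment gap spans the full
intron to the downstream exon start ("correctly spliced").  Reads that run
into the intron cover the base but are not spliced, so the proportion falls
with intron retention.  Coverage is normalized per individual as reads
covering a base divided by the individual's total aligned reads in
billions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from collections.abc import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from splicelocus.genes import TranscriptModel
from splicelocus.ranktests import mann_whitney

logger = logging.getLogger(__name__)

_SKIP_FLAGS = 0x4 | 0x100 | 0x400 | 0x800  # unmapped, secondary, dup, supplementary


@dataclass
class AlignedRead:
    """One parsed alignment: covered genomic segments, gap segments from
    ``N`` operations, and enough bookkeeping to look up read bases at
    marker positions.  All coordinates 1-based inclusive."""

    individual: str
    chrom: str
    pos: int
    segments: tuple[tuple[int, int], ...]
    gaps: tuple[tuple[int, int], ...]
    matches: tuple[tuple[int, int, int], ...]  # (gstart, gend, read_offset)
    seq: str | None

    def covers(self, gpos: int) -> bool:
        return any(s <= gpos <= e for s, e in self.segments)

    def base_at(self, gpos: int) -> str | None:
        """Read base aligned to a genomic position (M/=/X only)."""
        if self.seq is None:
            return None
        for gs, ge, off in self.matches:
            if gs <= gpos <= ge:
                return self.seq[off + (gpos - gs)]
        return None


def _segments_from_cigar(
    pos: int, cigartuples: list[tuple[int, int]]
) -> tuple[tuple, tuple, tuple]:
    """Covered segments, gaps and match blocks from a CIGAR.

    M/=/X consume read and reference (covered); D consumes reference and
    extends the covered span; N consumes reference as a gap; I/S consume
    read only; H/P consume neither.
    """
    segments: list[list[int]] = []
    gaps: list[tuple[int, int]] = []
    matches: list[tuple[int, int, int]] = []
    g = pos
    read_off = 0
    for op, length in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if segments and segments[-1][1] == g - 1:
                segments[-1][1] = g + length - 1
            else:
                segments.append([g, g + length - 1])
            matches.append((g, g + length - 1, read_off))
            g += length
            read_off += length
        elif op == 2:  # D: covered reference span, no read bases
            if segments and segments[-1][1] == g - 1:
                segments[-1][1] = g + length - 1
            else:
                segments.append([g, g + length - 1])
            g += length
        elif op == 3:  # N
            gaps.append((g, g + length - 1))
            g += length
        elif op in (1, 4):  # I, S: read only
            read_off += length
        elif op in (5, 6):  # H, P
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    return (
        tuple((s, e) for s, e in segments),
        tuple(gaps),
        tuple(matches),
    )


def parse_alignments(
    sam_path: str,
    region: tuple[str, int, int] | None = None,
    keep_seq: bool = True,
) -> Iterator[AlignedRead]:
    """Stream alignments from a SAM file as :class:`AlignedRead`.

    The individual id is taken as the read-name prefix before the first
    ``|`` (the simulator's convention) or the full read name.  Unmapped,
    secondary, duplicate and supplementary records are skipped; a record
    that fails to parse is reported with its ordinal and skipped.
    """
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        it = iter(sam)
        i = -1
        while True:
            i += 1
            try:
                rec = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                logger.warning("skipping malformed record %d: %s", i, exc)
                continue
            try:
                if rec.flag & _SKIP_FLAGS or rec.cigartuples is None:
                    continue
                chrom = rec.reference_name
                pos = rec.reference_start + 1
                if region is not None and chrom != region[0]:
                    continue
                segments, gaps, matches = _segments_from_cigar(
                    pos, rec.cigartuples
                )
                if region is not None and (
                    segments[-1][1] < region[1] or segments[0][0] > region[2]
                ):
                    continue
                name = rec.query_name or f"read{i}"
                yield AlignedRead(
                    individual=name.split("|", 1)[0],
                    chrom=chrom,
                    pos=pos,
                    segments=segments,
                    gaps=gaps,
                    matches=matches,
                    seq=rec.query_sequence if keep_seq else None,
                )
            except (ValueError, IndexError) as exc:
                logger.warning("skipping malformed record %d: %s", i, exc)


@dataclass
class CoverageProfile:
    individual: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    normalized: np.ndarray  # per-base normalized read count
    total_aligned: int


def coverage_profile(
    reads: Iterable[AlignedRead],
    region: tuple[str, int, int],
    total_aligned: float,
    individual: str = "",
) -> CoverageProfile:
    """Per-base normalized read count over a region for one individual:
    reads covering the base / (total aligned reads / 1e9)."""
    chrom, start, end = region
    if end < start:
        raise ValueError("zero-length region")
    if total_aligned <= 0:
        raise ValueError("total_aligned must be positive")
    diff = np.zeros(end - start + 2)
    for read in reads:
        for s, e in read.segments:
            lo, hi = max(s, start), min(e, end)
            if lo <= hi:
                diff[lo - start] += 1
                diff[hi - start + 1] -= 1
    counts = np.cumsum(diff[:-1])
    return CoverageProfile(
        individual=individual,
        chrom=chrom,
        start=start,
        end=end,
        normalized=counts / (total_aligned / 1e9),
        total_aligned=int(total_aligned),
    )


def coverage_profiles(
    reads: Iterable[AlignedRead],
    region: tuple[str, int, int],
    total_aligned: float,
) -> dict[str, CoverageProfile]:
    """Streaming per-individual coverage profiles over a region.

    Accumulates per-base counts in one pass without materializing the
    reads, so arbitrarily deep SAM streams can be profiled.
    """
    chrom, start, end = region
    if end < start:
        raise ValueError("zero-length region")
    if total_aligned <= 0:
        raise ValueError("total_aligned must be positive")
    diffs: dict[str, np.ndarray] = {}
    for read in reads:
        diff = diffs.get(read.individual)
        if diff is None:
            diff = diffs[read.individual] = np.zeros(end - start + 2)
        for s, e in read.segments:
            lo, hi = max(s, start), min(e, end)
            if lo <= hi:
                diff[lo - start] += 1
                diff[hi - start + 1] -= 1
    return {
        ind: CoverageProfile(
            individual=ind,
            chrom=chrom,
            start=start,
            end=end,
            normalized=np.cumsum(diff[:-1]) / (total_aligned / 1e9),
            total_aligned=int(total_aligned),
        )
        for ind, diff in diffs.items()
    }


def exon_medians(profile: CoverageProfile, model: TranscriptModel) -> np.ndarray:
    """Median normalized coverage per exon (transcript order) for one
    individual."""
    out = []
    for s, e in model.exons:
        lo, hi = s - profile.start, e - profile.start + 1
        out.append(float(np.median(profile.normalized[lo:hi])))
    return np.asarray(out)


def exon_group_summary(
    profiles_by_group: dict[str, list[CoverageProfile]],
    model: TranscriptModel,
) -> pd.DataFrame:
    """Per-exon, per-group median of individual exon medians, with MAD.

    For each individual the summary of an exon is the median of its
    per-base normalized counts; groups are then summarized by the median
    and median absolute deviation across individuals.  Empty groups are
    omitted with a warning.
    """
    rows = []
    for group, profiles in profiles_by_group.items():
        if not profiles:
            warnings.warn(f"group {group!r} is empty; omitted")
            continue
        for k, (s, e) in enumerate(model.exons, start=1):
            per_ind = []
            for prof in profiles:
                lo, hi = s - prof.start, e - prof.start + 1
                per_ind.append(float(np.median(prof.normalized[lo:hi])))
            per_ind = np.asarray(per_ind)
            med = float(np.median(per_ind))
            rows.append(
                {
                    "group": group,
                    "exon": k,
                    "median": med,
                    "mad": float(np.median(np.abs(per_ind - med))),
                    "n": len(per_ind),
                }
            )
    return pd.DataFrame(rows)


def expression_shift_test(
    medians_by_group: dict[str, Iterable[float]]
) -> tuple[float, pd.Series]:
    """Two-group comparison of per-individual region medians.

    Medians are log-transformed (with a pseudo-count if non-positive values
    occur), pooled-standardized to mean 0 / SD 1, and compared with a
    two-sample t test (equivalently, regression on the group indicator).
    Returns (P, standardized group means).
    """
    if len(medians_by_group) != 2:
        raise ValueError("exactly two groups required")
    (ga, va), (gb, vb) = [(g, np.asarray(list(v), float)) for g, v in medians_by_group.items()]
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("need at least 2 individuals per group")
    pooled = np.concatenate([va, vb])
    if (pooled <= 0).any():
        pseudo = np.abs(pooled[pooled > 0]).min() / 2 if (pooled > 0).any() else 1.0
        logger.warning("non-positive medians; adding pseudo-count %g", pseudo)
        va, vb = va + pseudo, vb + pseudo
        pooled = pooled + pseudo
    la, lb = np.log(va), np.log(vb)
    pooled = np.concatenate([la, lb])
    mu, sd = pooled.mean(), pooled.std(ddof=1)
    za, zb = (la - mu) / sd, (lb - mu) / sd
    t, p = stats.ttest_ind(za, zb, equal_var=True)
    return float(p), pd.Series({ga: za.mean(), gb: zb.mean()})


@dataclass
class SpliceStat:
    individual: str
    n_covering: int
    n_spliced: int

    @property
    def proportion(self) -> float:
        return self.n_spliced / self.n_covering


def splice_proportion(
    reads: Iterable[AlignedRead],
    model: TranscriptModel,
    intron_index: int,
) -> pd.DataFrame:
    """Per-individual spliced proportion at the designated junction.

    ``n_covering`` counts reads covering the last base (in transcript
    orientation) of the upstream exon; ``n_spliced`` counts the subset whose
    alignment gap spans exactly the full intron.  Individuals with no
    covering reads are omitted.
    """
    k = intron_index
    up_exon = model.exons[k - 1]
    junction_base = up_exon[1] if model.strand == "+" else up_exon[0]
    intron = model.intron(k)
    counts: dict[str, list[int]] = {}
    for read in reads:
        if not read.covers(junction_base):
            continue
        c = counts.setdefault(read.individual, [0, 0])
        c[0] += 1
        if intron in read.gaps:
            c[1] += 1
    rows = [
        {
            "individual": ind,
            "n_covering": c[0],
            "n_spliced": c[1],
            "proportion": c[1] / c[0],
        }
        for ind, c in counts.items()
    ]
    return pd.DataFrame(rows, columns=["individual", "n_covering", "n_spliced", "proportion"])


def intron_exon_ratio(
    profile: CoverageProfile, model: TranscriptModel, intron_index: int
) -> float:
    """Ratio of median intron coverage to median upstream-exon coverage.

    Returns NaN (individual to be omitted) when the exon has no coverage.
    """
    s_i, e_i = model.intron(intron_index)
    s_e, e_e = model.exons[intron_index - 1]
    off = profile.start
    intron_med = float(np.median(profile.normalized[s_i - off : e_i - off + 1]))
    exon_med = float(np.median(profile.normalized[s_e - off : e_e - off + 1]))
    if exon_med == 0:
        return float("nan")
    return intron_med / exon_med


def location_shift_test(proportions_a, proportions_b):
    """Mann-Whitney location-shift test between two groups of proportions
    (exact for small groups, tie-corrected normal approximation otherwise).
    """
    return mann_whitney(proportions_a, proportions_b)
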