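"""Phase-oriented allele-specific expression (ASE) at exonic markers.

A heterozygous exonic marker phased to an index variant lets read base
counts separate the two haplotypes' transcript output.  The oriented
proportion puts the index-linked allele in the numerator: #ALT bases /
#total when the marker's alternative allele rides with the index
alternative allele (sign +1), #REF bases / #total otherwise (sign -1).
Under no allelic imbalance and no mapping bias the proportion centres on
0.5; reference-mapping bias shifts the non-carrier baseline above 0.5
whenever the index-linked allele is the reference base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import pandas as pd

from splicelocus.haplo import ld_stats
from splicelocus.ranktests import mann_whitney
from splicelocus.splicing import AlignedRead

D_PRIME_MIN = 0.99


@dataclass(frozen=True)
class ASEMarker:
    """An exonic marker usable for phase-oriented ASE."""

    id: str
    position: int  # 1-based genomic
    ref_base: str
    alt_base: str
    sign: int  # +1: index alt linked to marker ALT; -1: linked to marker REF
    d_prime: float | None = None
    r2: float | None = None


def select_ase_markers(
    panel,
    index_variant: str,
    candidate_ids: Iterable[str],
    d_prime_min: float = D_PRIME_MIN,
) -> list[ASEMarker]:
    """Retain candidate markers in near-complete LD (D' >= threshold) with
    the index variant; the orientation sign is the sign of D."""
    markers = []
    for cid in candidate_ids:
        ld = ld_stats(panel, index_variant, cid)
        if ld.d_prime < d_prime_min:
            continue
        v = panel.variants[panel.variant_index(cid)]
        markers.append(
            ASEMarker(
                id=cid,
                position=v.pos,
                ref_base=v.ref_allele,
                alt_base=v.alt_allele,
                sign=ld.sign,
                d_prime=ld.d_prime,
                r2=ld.r2,
            )
        )
    if not markers:
        warnings.warn("no candidate markers pass the D' threshold")
    return markers


def ase_proportions(
    reads: Iterable[AlignedRead],
    markers: list[ASEMarker],
    het_individuals: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Oriented base-count proportions per marker x individual.

    Only individuals heterozygous at a marker are informative; restrict
    with ``het_individuals`` (None = all).  Bases other than the marker's
    ref/alt alleles are ignored; observations with zero informative
    coverage are omitted.
    """
    keep = set(het_individuals) if het_individuals is not None else None
    counts: dict[tuple[str, str], list[int]] = {}
    for read in reads:
        if keep is not None and read.individual not in keep:
            continue
        for mk in markers:
            base = read.base_at(mk.position)
            if base is None:
                continue
            c = counts.setdefault((read.individual, mk.id), [0, 0])
            if base == mk.ref_base:
                c[0] += 1
            elif base == mk.alt_base:
                c[1] += 1
    signs = {mk.id: mk.sign for mk in markers}
    rows = []
    for (ind, mid), (ref, alt) in sorted(counts.items()):
        total = ref + alt
        if total == 0:
            continue
        oriented = alt / total if signs[mid] == 1 else ref / total
        rows.append(
            {
                "individual": ind,
                "marker": mid,
                "ref_count": ref,
                "alt_count": alt,
                "proportion": oriented,
            }
        )
    return pd.DataFrame(
        rows, columns=["individual", "marker", "ref_count", "alt_count", "proportion"]
    )


def ase_group_compare(
    observations_by_group: Mapping[str, pd.DataFrame],
    per_individual: bool = False,
) -> dict:
    """Group medians of oriented proportions and a Mann-Whitney P.

    By default marker x individual observations are pooled within each
    group; ``per_individual=True`` first takes each individual's median
    across markers.  The P value rests on a simplifying assumption of
    independence of the pooled proportions, which is recorded in the
    output metadata.
    """
    medians = {}
    samples = {}
    for group, obs in observations_by_group.items():
        props = (
            obs.groupby("individual")["proportion"].median()
            if per_individual
            else obs["proportion"]
        )
        samples[group] = props.to_numpy()
        medians[group] = float(props.median())
    out = {
        "medians": medians,
        "p": None,
        "note": "P assumes independence of pooled proportions",
    }
    if len(samples) == 2:
        a, b = samples.values()
        if len(a) and len(b):
            out["p"] = mann_whitney(a, b).p
    return out
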