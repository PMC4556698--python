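"""Haplotype enumeration, diplotype phenotype summaries, additivity checks
and pairwise LD from phased genotype panels.

Haplotypes over a chosen variant set are labelled ``H0`` for the all-major
haplotype and ``H1, H2, ...`` for the rest in order of descending frequency
(ties broken by the position of the first carried minor allele).  A
diplotype ``Hn|Hm`` is the unordered pair of labels an individual carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UnphasedGenotypeError(ValueError):
    pass


@dataclass
class HaplotypeSet:
    """Enumerated haplotypes plus the per-chromosome label assignment."""

    table: pd.DataFrame  # label, pattern, count, frequency
    assignment: np.ndarray  # (n_individuals, 2) of label strings
    variant_ids: list[str]


@dataclass
class LDResult:
    variant_a: str
    variant_b: str
    r2: float
    d_prime: float
    sign: int


def enumerate_haplotypes(panel, variant_ids: list[str]) -> HaplotypeSet:
    """Enumerate distinct haplotypes over ``variant_ids``.

    Labels: H0 = all-major; remaining by descending frequency, ties by the
    genomic position of the first minor allele carried.
    """
    hap = panel.haplotypes(variant_ids)  # (2n, k)
    n_chrom = hap.shape[0]
    patterns, inverse, counts = np.unique(
        hap, axis=0, return_inverse=True, return_counts=True
    )
    pos = {v: panel.variants[panel.variant_index(v)].pos for v in variant_ids}

    def first_minor_pos(pattern: np.ndarray) -> int:
        carried = [pos[v] for v, a in zip(variant_ids, pattern) if a == 1]
        return min(carried) if carried else -1

    order = sorted(
        range(len(patterns)),
        key=lambda i: (
            0 if patterns[i].sum() == 0 else 1,  # H0 first
            -counts[i],
            first_minor_pos(patterns[i]),
        ),
    )
    labels = {}
    rows = []
    next_label = 0
    for i in order:
        if patterns[i].sum() == 0:
            label = "H0"
        else:
            next_label += 1
            label = f"H{next_label}"
        labels[i] = label
        rows.append(
            {
                "label": label,
                "pattern": "".join(map(str, patterns[i])),
                "count": int(counts[i]),
                "frequency": counts[i] / n_chrom if n_chrom else np.nan,
            }
        )
    assignment = np.array([labels[i] for i in inverse], dtype=object).reshape(-1, 2)
    return HaplotypeSet(
        table=pd.DataFrame(rows), assignment=assignment, variant_ids=list(variant_ids)
    )


def diplotype_label(a: str, b: str) -> str:
    lo, hi = sorted([a, b], key=lambda s: int(s[1:]))
    return f"{lo}|{hi}"


def diplotype_summary(
    panel, variant_ids: list[str], trait: pd.Series
) -> pd.DataFrame:
    """Trait mean/SD per unordered haplotype pair.

    ``trait`` is indexed by individual id; classes with a single member get
    a missing SD, empty classes are omitted.
    """
    haps = enumerate_haplotypes(panel, variant_ids)
    values = trait.reindex(panel.individuals).to_numpy(dtype=float)
    labels = [diplotype_label(a, b) for a, b in haps.assignment]
    df = pd.DataFrame({"diplotype": labels, "trait": values})
    out = (
        df.groupby("diplotype")["trait"]
        .agg(count="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return out.sort_values("count", ascending=False, ignore_index=True)


def additivity_check(
    summaries: pd.DataFrame,
    effects: dict[str, float],
    baseline: float | None = None,
) -> pd.DataFrame:
    """Compare observed diplotype means with additive predictions.

    The additive prediction for ``Hn|Hm`` is ``baseline + effect(Hn) +
    effect(Hm)`` with ``effect(H0) = 0``; ``baseline`` defaults to the
    observed H0|H0 mean.  Deviations are z-scored against the class
    standard error; classes with unknown effects are skipped.
    """
    if baseline is None:
        ref = summaries.loc[summaries["diplotype"] == "H0|H0"]
        if ref.empty:
            raise ValueError("no H0|H0 class; supply baseline explicitly")
        baseline = float(ref["mean"].iloc[0])
    eff = dict(effects)
    eff.setdefault("H0", 0.0)
    rows = []
    for _, row in summaries.iterrows():
        a, b = row["diplotype"].split("|")
        if a not in eff or b not in eff:
            continue
        predicted = baseline + eff[a] + eff[b]
        se = (
            row["sd"] / np.sqrt(row["count"])
            if row["count"] > 1 and np.isfinite(row["sd"])
            else np.nan
        )
        deviation = row["mean"] - predicted
        rows.append(
            {
                "diplotype": row["diplotype"],
                "count": row["count"],
                "observed_mean": row["mean"],
                "predicted_mean": predicted,
                "deviation": deviation,
                "se": se,
                "z": deviation / se if se and np.isfinite(se) and se > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ld_stats(panel, variant_a: str, variant_b: str) -> LDResult:
    """Pairwise LD (D', r^2 and correlation sign) from phased haplotypes.

    Computed with respect to the alternative alleles of the two variants.
    D' uses the standard normalization ``|D| / D_max`` with ``D_max`` the
    min() bound appropriate to the sign of D.
    """
    hap = panel.haplotypes([variant_a, variant_b])
    pa = hap[:, 0].mean()
    pb = hap[:, 1].mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("LD undefined for a monomorphic variant")
    pab = float((hap[:, 0] * hap[:, 1]).mean())
    d = pab - pa * pb
    if d >= 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(d) / d_max if d_max > 0 else 1.0
    r2 = d**2 / (pa * (1 - pa) * pb * (1 - pb))
    return LDResult(
        variant_a=variant_a,
        variant_b=variant_b,
        r2=float(r2),
        d_prime=float(min(d_prime, 1.0)),
        sign=1 if d >= 0 else -1,
    )
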