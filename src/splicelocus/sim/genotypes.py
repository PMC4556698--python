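"""Simulation of phased haplotypes and imputed dosages.

Haplotypes are sampled i.i.d. per chromosome: no LD beyond the optional
mutual-exclusivity constraint and no relatedness.  An exclusivity group is a
set of variants whose minor alleles never co-occur on one haplotype, so each
chromosome carries at most one of the group's minor alleles and the
haplotype distribution over the group is categorical with the minor-allele
frequencies as class probabilities.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from splicelocus.panel import ConfigError, PhasedPanel, VariantDef


def simulate_haplotypes(
    variant_defs: Sequence[VariantDef],
    n_individuals: int,
    exclusivity_groups: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
) -> PhasedPanel:
    """Draw a phased panel of ``n_individuals`` diploid individuals.

    Variants inside an ``exclusivity_group`` are drawn jointly so that no
    haplotype carries two of the group's minor alleles; all other variants
    are independent Bernoulli(maf) per chromosome.
    """
    rng = np.random.default_rng(seed)
    variant_defs = list(variant_defs)
    m = len(variant_defs)
    by_id = {v.id: i for i, v in enumerate(variant_defs)}
    if len(by_id) != m:
        raise ConfigError("duplicate variant ids")

    n_chrom = 2 * n_individuals
    alleles = np.zeros((n_chrom, m), dtype=np.int8)

    grouped: set[int] = set()
    for group in exclusivity_groups or []:
        idx = [by_id[v] for v in group]
        grouped.update(idx)
        freqs = np.array([variant_defs[i].maf for i in idx])
        if freqs.sum() > 1.0:
            raise ConfigError(
                f"minor-allele frequencies in exclusivity group {list(group)} "
                f"sum to {freqs.sum():.3f} > 1"
            )
        # outcome 0 = all-major haplotype, outcome j >= 1 = minor allele of idx[j-1]
        probs = np.concatenate([[1.0 - freqs.sum()], freqs])
        draws = rng.choice(len(probs), size=n_chrom, p=probs)
        for j, i in enumerate(idx, start=1):
            alleles[draws == j, i] = 1

    for i, v in enumerate(variant_defs):
        if i not in grouped:
            alleles[:, i] = rng.random(n_chrom) < v.maf

    individuals = [f"ind{i:06d}" for i in range(n_individuals)]
    return PhasedPanel(
        individuals=individuals,
        variants=variant_defs,
        alleles=alleles.reshape(n_individuals, 2, m).transpose(0, 2, 1),
    )


def simulate_dosages(
    panel: PhasedPanel, target_info: float, seed: int = 0
) -> pd.DataFrame:
    """Imputed expected allele counts at a target imputation information.

    Per haploid allele theta the dosage is ``alpha * theta + (1 - alpha) * p``
    with ``alpha = sqrt(target_info)`` and ``p`` the variant's population
    frequency; the diploid dosage is the sum over the two haplotypes.  Since
    Var(alpha * theta) = alpha^2 p(1-p), the measured information score of
    the output equals ``target_info`` up to sampling error.
    """
    if not 0.0 <= target_info <= 1.0:
        raise ConfigError(f"target_info {target_info} outside [0, 1]")
    alpha = float(np.sqrt(target_info))
    cols = {}
    for j, v in enumerate(panel.variants):
        hap = panel.alleles[:, j, :].astype(float)  # (n, 2)
        dose = alpha * hap + (1.0 - alpha) * v.maf
        cols[v.id] = dose.sum(axis=1)
    return pd.DataFrame(cols, index=pd.Index(panel.individuals, name="individual"))
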