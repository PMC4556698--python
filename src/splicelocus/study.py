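"""Reference experiments at the study's printed conditions.

Each function reproduces one headline quantity of the splice-region-variant
analysis from scratch under the default simulation conditions (group sizes,
frequencies, effect sizes and rates the study reports), returning the
measured statistic.  They are the single source for both the acceptance
checks and the worked examples in the documentation.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np
import pandas as pd

from splicelocus import ase as ase_mod
from splicelocus import assoc
from splicelocus import splicing as sp
from splicelocus.meta import CohortSummary, fixed_effect_meta
from splicelocus.panel import VariantDef
from splicelocus.sim import locus
from splicelocus.sim.genotypes import simulate_haplotypes
from splicelocus.sim.phenotypes import (
    SimPhenoConfig,
    simulate_case_control,
    simulate_phenotypes,
)
from splicelocus.sim.rnaseq import simulate_rnaseq

#: printed replication-cohort summaries (effect in mmol/l, two-sided P)
REPLICATION_COHORTS = {
    "rs72658867": [
        ("Denmark", -0.36, 1.0e-4),
        ("Netherlands", -0.60, 8.1e-7),
        ("Iran", -0.33, 1.4e-3),
    ],
    "rs17248748": [
        ("Denmark", -0.16, 0.039),
        ("Netherlands", -0.20, 0.042),
        ("Iran", -0.04, 0.71),
    ],
}

#: RNA-seq group sizes of the expression dataset
N_NONCARRIERS = 238
N_HETEROZYGOTES = 15
N_HOMOZYGOTES = 3


def _sub_seed(seed: int, k: int) -> int:
    return int((1_000_003 * seed + 7919 * k + 1) % (2**31 - 1))


def combined_replication_effect(variant: str) -> float:
    """Inverse-variance fixed-effect combined beta over the printed
    replication cohorts, with SEs back-derived from beta and P."""
    cohorts = [
        CohortSummary(label, beta=b, p=p)
        for label, b, p in REPLICATION_COHORTS[variant]
    ]
    return fixed_effect_meta(cohorts).beta


def splice_proportion_het_median(seed: int, depth: float = 2000.0) -> float:
    """Median per-individual spliced proportion among simulated
    heterozygotes (retention 0.5 on the mutant haplotype, expression
    ratio 1.44)."""
    cfg = locus.rna_config(depth=depth, markers=(), seed=_sub_seed(seed, 3))
    genotypes = {f"HET{i:03d}": 1 for i in range(N_HETEROZYGOTES)}
    stats = _splice_stats(genotypes, cfg)
    return float(stats["proportion"].median())


def splice_proportion_hom_mean(seed: int, depth: float = 2000.0) -> float:
    """Mean spliced proportion among simulated homozygous carriers."""
    cfg = locus.rna_config(depth=depth, markers=(), seed=_sub_seed(seed, 4))
    genotypes = {f"HOM{i}": 2 for i in range(N_HOMOZYGOTES)}
    stats = _splice_stats(genotypes, cfg)
    return float(stats["proportion"].mean())


def splice_proportion_noncarrier_mean(seed: int, depth: float = 50.0) -> float:
    """Mean spliced proportion among simulated non-carriers with a 5%
    background mis-splicing rate."""
    cfg = locus.rna_config(
        depth=depth,
        retention_fraction_background=0.05,
        markers=(),
        seed=_sub_seed(seed, 5),
    )
    genotypes = {f"NC{i:03d}": 0 for i in range(N_NONCARRIERS)}
    stats = _splice_stats(genotypes, cfg)
    return float(stats["proportion"].mean())


def _splice_stats(genotypes, cfg) -> pd.DataFrame:
    with tempfile.TemporaryDirectory() as d:
        sam = os.path.join(d, "reads.sam")
        simulate_rnaseq(genotypes, locus.gene_model(), locus.genome(), cfg, sam)
        return sp.splice_proportion(
            sp.parse_alignments(sam), locus.gene_model(), locus.RETAINED_INTRON
        )


def ase_group_medians(seed: int, depth: float = 100.0) -> dict[str, float]:
    """Oriented ASE medians for simulated non-carriers and heterozygotes
    under the default reference-mapping-bias model (markers' index-linked
    alleles are the reference bases)."""
    cfg = locus.rna_config(depth=depth, seed=_sub_seed(seed, 6))
    genotypes = {f"NC{i:03d}": 0 for i in range(N_NONCARRIERS)}
    genotypes.update({f"HET{i:03d}": 1 for i in range(N_HETEROZYGOTES)})
    chrom_seq = locus.genome()[locus.GENE_CHROM]
    markers = [
        ase_mod.ASEMarker(
            id=mk.id,
            position=mk.position,
            ref_base=chrom_seq[mk.position - 1],
            alt_base={"A": "C", "C": "A", "G": "T", "T": "G"}[
                chrom_seq[mk.position - 1]
            ],
            sign=mk.sign,
        )
        for mk in cfg.markers
    ]
    with tempfile.TemporaryDirectory() as d:
        sam = os.path.join(d, "reads.sam")
        simulate_rnaseq(genotypes, locus.gene_model(), locus.genome(), cfg, sam)
        obs = ase_mod.ase_proportions(sp.parse_alignments(sam), markers)
    groups = {
        "GG": obs[obs["individual"].str.startswith("NC")],
        "GA": obs[obs["individual"].str.startswith("HET")],
    }
    out = ase_mod.ase_group_compare(groups)
    return out["medians"]


def expression_increase_percent(seed: int, depth: float = 150.0) -> float:
    """Percent increase in exon-median normalized coverage of heterozygotes
    over non-carriers at the printed group sizes, averaged over exons."""
    cfg = locus.rna_config(depth=depth, markers=(), seed=_sub_seed(seed, 8))
    genotypes = {f"NC{i:03d}": 0 for i in range(N_NONCARRIERS)}
    genotypes.update({f"HET{i:03d}": 1 for i in range(N_HETEROZYGOTES)})
    gene = locus.gene_model()
    region = (locus.GENE_CHROM, gene.exons[0][0], gene.exons[-1][1])
    with tempfile.TemporaryDirectory() as d:
        sam = os.path.join(d, "reads.sam")
        simulate_rnaseq(genotypes, gene, locus.genome(), cfg, sam)
        profiles = sp.coverage_profiles(
            sp.parse_alignments(sam), region, cfg.total_aligned
        )
    groups = {"noncarrier": [], "het": []}
    for ind, prof in profiles.items():
        groups["het" if ind.startswith("HET") else "noncarrier"].append(prof)
    summary = sp.exon_group_summary(groups, gene)
    piv = summary.pivot(index="exon", columns="group", values="median")
    ratio = float((piv["het"] / piv["noncarrier"]).mean())
    return 100.0 * (ratio - 1.0)


def lipid_effect_recovery(
    seed: int, n: int = 50_000, beta: float = -0.44, maf: float = 0.022
) -> float:
    """Per-allele effect (mmol/l) recovered by the full pipeline: simulate,
    inverse-normal transform, regress on allele count, rescale by the
    trait SD."""
    v = VariantDef("index", "chr19", 11_092_203, "G", "A", maf)
    panel = simulate_haplotypes([v], n, seed=_sub_seed(seed, 9))
    cfg = SimPhenoConfig(effects={"index": beta}, seed=_sub_seed(seed, 10))
    pheno = simulate_phenotypes(panel, cfg)
    adjusted = assoc.adjust_phenotype(pheno)
    res = assoc.linear_assoc(
        panel.genotype("index"),
        adjusted.reindex(panel.individuals).to_numpy(),
        trait_sd=cfg.trait_sd,
    )
    return res.beta_units


def odds_ratio_recovery(
    seed: int,
    n: int = 230_000,
    odds_ratio: float = 0.76,
    baseline_odds: float = 0.15,
    maf: float = 0.022,
) -> float:
    """Per-allele odds ratio recovered by logistic regression of simulated
    disease status on allele count (~30,000 cases / 200,000 controls)."""
    v = VariantDef("index", "chr19", 11_092_203, "G", "A", maf)
    panel = simulate_haplotypes([v], n, seed=_sub_seed(seed, 11))
    status = simulate_case_control(
        panel, odds_ratio, baseline_odds, seed=_sub_seed(seed, 12)
    )
    res = assoc.logistic_assoc(panel.genotype("index"), status["status"])
    return res.beta_units


def stepwise_recovery_rate(
    seed: int, n_replicates: int = 20, n: int = 50_000, n_null: int = 200,
    threshold: float = 5e-8,
) -> float:
    """Fraction of replicates in which stepwise forward selection recovers
    exactly the four planted locus signals among null variants."""
    rng = np.random.default_rng(_sub_seed(seed, 13))
    hits = 0
    for rep in range(n_replicates):
        defs = list(locus.locus_variants())
        for i in range(n_null):
            defs.append(
                VariantDef(
                    f"null{i:03d}", "chr19", 11_000_000 + i * 100, "A", "G",
                    float(rng.uniform(0.01, 0.5)),
                )
            )
        panel = simulate_haplotypes(
            defs, n, locus.exclusivity_groups(), seed=_sub_seed(seed, 100 + rep)
        )
        pheno = simulate_phenotypes(
            panel,
            SimPhenoConfig(
                effects=locus.NONHDL_EFFECTS, seed=_sub_seed(seed, 200 + rep)
            ),
        )
        adjusted = assoc.inverse_normal_transform(pheno["trait"].to_numpy())
        dosages = pd.DataFrame(
            panel.alleles.sum(axis=2),
            index=panel.individuals,
            columns=[v.id for v in defs],
        ).astype(float)
        selected = {
            r.variant
            for r in assoc.stepwise_select(
                dosages, adjusted, threshold=threshold,
                positions={v.id: v.pos for v in defs},
            )
        }
        if selected == set(locus.NONHDL_EFFECTS):
            hits += 1
    return hits / n_replicates
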