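"""Top-level pipeline: simulate -> associate -> meta -> splice -> ASE ->
consequence, with a JSON run report.

The pipeline is driven by a YAML configuration with one block per stage;
unknown stages or keys are rejected.  Each stage derives its own seed from
the global seed, records its outputs (with content hashes) and key
statistics in the report, and re-running with the same configuration and
seed reproduces the report exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from splicelocus import assoc as assoc_mod
from splicelocus import io as slio
from splicelocus import meta as meta_mod
from splicelocus import splicing as splicing_mod
from splicelocus import ase as ase_mod
from splicelocus import consequence as cons_mod
from splicelocus.panel import ConfigError
from splicelocus.sim import locus
from splicelocus.sim.genotypes import simulate_haplotypes, simulate_dosages
from splicelocus.sim.phenotypes import SimPhenoConfig, simulate_phenotypes
from splicelocus.sim.rnaseq import simulate_rnaseq

logger = logging.getLogger(__name__)

STAGES = (
    "genotypes",
    "phenotypes",
    "dosages",
    "association",
    "meta",
    "rnaseq",
    "splicing",
    "ase",
    "consequence",
)

_STAGE_KEYS = {
    "genotypes": {"n_individuals"},
    "phenotypes": {"effects", "sex_effect", "med_prob", "med_effect"},
    "dosages": {"target_info"},
    "association": {"threshold", "covariates"},
    "meta": {"cohorts"},
    "rnaseq": {"n_noncarriers", "n_het", "n_hom", "depth", "read_length"},
    "splicing": set(),
    "ase": set(),
    "consequence": set(),
}

_SEED_OFFSET = {name: 1000 + 17 * i for i, name in enumerate(STAGES)}


def load_config(path: str) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    validate_config(config)
    return config


def save_config(config: dict, path: str) -> None:
    validate_config(config)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def validate_config(config: dict) -> None:
    known_top = {"stages", "seed"}
    unknown = set(config) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for stage, block in (config.get("stages") or {}).items():
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        extra = set(block or {}) - _STAGE_KEYS[stage]
        if extra:
            raise ConfigError(f"stage {stage!r}: unknown keys {sorted(extra)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str, seed: int = 1) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run report (also written to ``<out_dir>/report.json``).  A
    stage failure halts its dependents and is recorded as partial
    completion.
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages") or {}
    report: dict = {"seed": seed, "stages": {}, "status": "ok"}
    state: dict = {}

    for stage in STAGES:
        if stage not in stages:
            continue
        block = dict(stages[stage] or {})
        stage_seed = seed + _SEED_OFFSET[stage]
        entry: dict = {"seed": stage_seed, "params": block, "outputs": {}, "stats": {}}
        try:
            runner = globals()[f"_stage_{stage}"]
            runner(block, stage_seed, out, state, entry)
            entry["status"] = "ok"
        except Exception as exc:
            logger.exception("stage %s failed", stage)
            entry["status"] = f"failed: {exc}"
            report["stages"][stage] = entry
            report["status"] = f"partial: failed at {stage}"
            break
        for f in entry["outputs"]:
            entry["outputs"][f] = _sha256(out / f)
        report["stages"][stage] = entry

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_genotypes(block, seed, out, state, entry):
    n = int(block.get("n_individuals", 2000))
    panel = simulate_haplotypes(
        locus.locus_variants(), n, locus.exclusivity_groups(), seed=seed
    )
    state["panel"] = panel
    slio.write_phased_vcf(panel, out / "genotypes.vcf")
    entry["outputs"]["genotypes.vcf"] = None
    entry["stats"]["n_individuals"] = n
    entry["stats"]["allele_freqs"] = {
        v.id: round(panel.allele_freq(v.id), 5) for v in panel.variants
    }


def _stage_phenotypes(block, seed, out, state, entry):
    effects = block.get("effects") or locus.NONHDL_EFFECTS
    cfg = SimPhenoConfig(
        effects=effects,
        sex_effect=float(block.get("sex_effect", 0.1)),
        med_prob=float(block.get("med_prob", 0.1)),
        med_effect=float(block.get("med_effect", -0.5)),
        seed=seed,
    )
    pheno = simulate_phenotypes(state["panel"], cfg)
    state["pheno"] = pheno
    state["trait_sd"] = cfg.trait_sd
    slio.write_tsv(pheno, out / "phenotypes.tsv")
    entry["outputs"]["phenotypes.tsv"] = None
    entry["stats"]["trait_mean"] = round(float(pheno["trait"].mean()), 4)
    entry["stats"]["trait_sd"] = round(float(pheno["trait"].std(ddof=1)), 4)


def _stage_dosages(block, seed, out, state, entry):
    info = float(block.get("target_info", 0.98))
    dosages = simulate_dosages(state["panel"], info, seed=seed)
    state["dosages"] = dosages
    slio.write_tsv(dosages.reset_index(), out / "dosages.tsv")
    entry["outputs"]["dosages.tsv"] = None
    entry["stats"]["target_info"] = info


def _stage_association(block, seed, out, state, entry):
    panel = state["panel"]
    pheno = state["pheno"]
    covariates = block.get("covariates") or ["sex", "age", "site", "med"]
    covariates = [c for c in covariates if pheno[c].nunique() > 1]
    adjusted = assoc_mod.adjust_phenotype(pheno, covariates)
    dosages = state.get("dosages")
    if dosages is None:
        dosages = pd.DataFrame(
            {v.id: panel.genotype(v.id) for v in panel.variants},
            index=panel.individuals,
        )
    y = adjusted.reindex(dosages.index).to_numpy()
    rows = []
    for vid in dosages.columns:
        info = assoc_mod.imputation_info(
            dosages[vid].to_numpy(), panel.allele_freq(vid)
        )
        if info < assoc_mod.INFO_MIN:
            continue
        res = assoc_mod.linear_assoc(
            dosages[vid], y, trait_sd=state.get("trait_sd", 1.0), variant=vid
        )
        d = res.to_dict()
        d["info"] = info
        rows.append(d)
    table = pd.DataFrame(rows)
    slio.write_tsv(table, out / "association.tsv")
    entry["outputs"]["association.tsv"] = None
    selected = assoc_mod.stepwise_select(
        dosages, y, threshold=float(block.get("threshold", 5e-8)),
        positions={v.id: v.pos for v in panel.variants},
    )
    entry["stats"]["stepwise_selected"] = [r.variant for r in selected]
    entry["stats"]["betas_mmol"] = {
        r["variant"]: round(r["beta_units"], 4) for r in rows
    }


def _stage_meta(block, seed, out, state, entry):
    cohorts = [
        meta_mod.CohortSummary(**c) for c in (block.get("cohorts") or [])
    ]
    if not cohorts:
        raise ConfigError("meta stage needs cohorts")
    combined = meta_mod.fixed_effect_meta(cohorts)
    het = (
        meta_mod.heterogeneity_test(cohorts, combined.beta)
        if len(cohorts) > 1
        else None
    )
    table = pd.DataFrame(
        [{"label": c.label, "beta": c.beta, "p": c.p, "se": c.resolved_se()} for c in cohorts]
        + [{"label": "combined", "beta": combined.beta, "p": combined.p, "se": combined.se}]
    )
    slio.write_tsv(table, out / "meta.tsv")
    entry["outputs"]["meta.tsv"] = None
    entry["stats"]["combined_beta"] = round(combined.beta, 4)
    if het:
        entry["stats"]["q"] = round(het.q, 4)
        entry["stats"]["p_het"] = round(het.p, 4)


def _stage_rnaseq(block, seed, out, state, entry):
    cfg = locus.rna_config(
        depth=float(block.get("depth", 200.0)),
        read_length=int(block.get("read_length", 76)),
        seed=seed,
    )
    n0 = int(block.get("n_noncarriers", 20))
    n1 = int(block.get("n_het", 8))
    n2 = int(block.get("n_hom", 2))
    genotypes = {f"NC{i:03d}": 0 for i in range(n0)}
    genotypes.update({f"HET{i:03d}": 1 for i in range(n1)})
    genotypes.update({f"HOM{i:03d}": 2 for i in range(n2)})
    gene = locus.gene_model()
    genome = locus.genome()
    truth = simulate_rnaseq(genotypes, gene, genome, cfg, str(out / "rnaseq.sam"))
    slio.write_tsv(truth, out / "rnaseq_truth.tsv")
    slio.write_gff3(gene, out / "gene.gff3")
    slio.write_fasta(genome, out / "genome.fasta")
    state["rna"] = {"genotypes": genotypes, "cfg": cfg}
    for f in ("rnaseq.sam", "rnaseq_truth.tsv", "gene.gff3", "genome.fasta"):
        entry["outputs"][f] = None
    entry["stats"]["n_reads"] = int(truth["n_reads"].sum())


_PREFIX_GENOTYPE = {"NC": 0, "HET": 1, "HOM": 2}


def _stage_splicing(block, seed, out, state, entry):
    gene = locus.gene_model()
    sam = out / "rnaseq.sam"
    if not sam.exists():
        raise FileNotFoundError(f"{sam} missing: run the rnaseq stage first")
    reads = splicing_mod.parse_alignments(str(sam))
    stats_df = splicing_mod.splice_proportion(reads, gene, locus.RETAINED_INTRON)
    if stats_df.empty:
        raise ValueError(f"{sam}: no junction-covering alignments parsed")
    slio.write_tsv(stats_df, out / "splice_stats.tsv")
    entry["outputs"]["splice_stats.tsv"] = None
    rna = state.get("rna")
    geno = (
        rna["genotypes"]
        if rna
        else {
            ind: next(
                (g for p, g in _PREFIX_GENOTYPE.items() if ind.startswith(p)), 0
            )
            for ind in stats_df["individual"]
        }
    )
    stats_df["genotype"] = stats_df["individual"].map(geno)
    med = stats_df.groupby("genotype")["proportion"].median()
    entry["stats"]["median_splice_proportion"] = {
        str(g): round(float(v), 4) for g, v in med.items()
    }
    groups = {
        g: stats_df.loc[stats_df["genotype"] == g, "proportion"].to_numpy()
        for g in sorted(stats_df["genotype"].unique())
    }
    if 0 in groups and 1 in groups and len(groups[0]) and len(groups[1]):
        res = splicing_mod.location_shift_test(groups[0], groups[1])
        entry["stats"]["mann_whitney_p"] = float(res.p)


def _stage_ase(block, seed, out, state, entry):
    rna = state["rna"]
    cfg = rna["cfg"]
    genome = locus.genome()
    chrom_seq = genome[locus.GENE_CHROM]
    markers = [
        ase_mod.ASEMarker(
            id=mk.id,
            position=mk.position,
            ref_base=chrom_seq[mk.position - 1],
            alt_base=mk.alt_base or {"A": "C", "C": "A", "G": "T", "T": "G"}[
                chrom_seq[mk.position - 1]
            ],
            sign=mk.sign,
        )
        for mk in cfg.markers
    ]
    geno = rna["genotypes"]
    obs_by_group = {}
    for g, label in ((0, "noncarrier"), (1, "heterozygote")):
        inds = [i for i, v in geno.items() if v == g]
        reads = splicing_mod.parse_alignments(str(out / "rnaseq.sam"))
        obs = ase_mod.ase_proportions(reads, markers, het_individuals=inds)
        obs_by_group[label] = obs
    all_obs = pd.concat(
        [df.assign(group=g) for g, df in obs_by_group.items()], ignore_index=True
    )
    slio.write_tsv(all_obs, out / "ase_observations.tsv")
    entry["outputs"]["ase_observations.tsv"] = None
    cmp = ase_mod.ase_group_compare(obs_by_group)
    entry["stats"]["ase_medians"] = {
        g: round(v, 4) for g, v in cmp["medians"].items()
    }
    if cmp["p"] is not None:
        entry["stats"]["ase_p"] = float(cmp["p"])
    entry["stats"]["note"] = cmp["note"]


def _stage_consequence(block, seed, out, state, entry):
    report = cons_mod.predict_consequence(
        locus.gene_model(),
        locus.genome(),
        locus.RETAINED_INTRON,
        locus.CDS_OFFSET,
        locus.domain_table(),
    )
    payload = {
        "transcript": report.transcript_id,
        "retained_intron": report.retained_intron,
        "last_intact_residue": report.last_intact_residue,
        "novel_residues": report.novel_residues,
        "stop_found": report.stop_found,
        "annotation": report.annotation,
        "nmd_predicted": report.nmd_predicted,
        "lost_domains": report.lost_domains,
        "partial_domains": report.partial_domains,
        "retained_domains": report.retained_domains,
        "novel_peptide": report.novel_peptide,
    }
    (out / "consequence.json").write_text(json.dumps(payload, indent=2))
    entry["outputs"]["consequence.json"] = None
    entry["stats"]["annotation"] = report.annotation
    entry["stats"]["novel_residues"] = report.novel_residues
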