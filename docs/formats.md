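# File formats

All tabular interchange is tab-separated with a header row; reports are
JSON; run configuration is YAML.

## Inputs

- **Phased genotypes** — VCF v4.2, single-sample-column-per-individual,
  biallelic sites, `GT` with `|` separator. `/`-separated genotypes are
  rejected for haplotype analyses with an error naming site and sample.
- **Dosages** — TSV: `individual` + one column per variant id, diploid
  expected allele counts in [0, 2].
- **Phenotypes/covariates** — TSV: `individual`, `trait`, plus covariate
  columns (`sex`, `age`, `site`, `med`, …); repeated measurement rows per
  individual are averaged.
- **Cohort summaries** — TSV: `label`, `beta`, `p` (and optionally `se`,
  `n`); `se` is back-derived from `beta`/`p` when absent.
- **Alignments** — SAM v1.6 with `@SQ` header lines; the individual id is
  the read-name prefix before the first `|`.
- **Gene models** — GFF3, one gene/mRNA with exon features.
- **Genome** — FASTA.
- **Domain table** — TSV: `domain`, `start`, `end` (protein residues).

## Outputs

- `association.tsv` — `variant, beta_sd, beta_units, se, chi2, p,
  log10_p, adjusted_for, n[, info]`.
- `meta.tsv` — cohort rows plus a `combined` row: `label, beta, se, p[,
  p_het]`.
- haplotype table — `label, pattern, count, frequency`; diplotype table —
  `diplotype, count, mean, sd`.
- `splice_stats.tsv` — `individual, n_covering, n_spliced, proportion`.
- `ase_observations.tsv` — `individual, marker, ref_count, alt_count,
  proportion[, group]`.
- `rnaseq_truth.tsv` — `individual, haplotype, mutant, retained,
  n_transcripts, n_reads, n_discarded`.
- `consequence.json` — annotation, truncation position, novel peptide,
  domain classification.
- `report.json` — per-stage seed, parameters, output hashes and key
  statistics.
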