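seed: 1
stages:
  genotypes:
    n_individuals: 2000
  phenotypes: {}
  dosages:
    target_info: 0.98
  association:
    threshold: 1.0e-3
  meta:
    cohorts:
      - {label: Denmark, beta: -0.36, p: 1.0e-4}
      - {label: Netherlands, beta: -0.60, p: 8.1e-7}
      - {label: Iran, beta: -0.33, p: 1.4e-3}
  rnaseq:
    n_noncarriers: 20
    n_het: 8
    n_hom: 2
    depth: 200
  splicing: {}
  ase: {}
  consequence: {}
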