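# Default synthetic study for `introsel run --config examples/study.yaml`.
# Omit `simulate` and set `bfile: <prefix>` to run on real PLINK data
# instead (roles then name the actual population labels in the .fam).
simulate:
  n_snps: 1200
  split_gens: {O: 120, P3: 80, P12: 40}
  admix_gen: 10
  admix_frac: 0.25
roles: {P1: P1, P2: P2, P3: P3, O: O}
lineage_refs: [P1, P3]
phenotype:
  h2: 0.4
  causal_beta: 0.5
seed: 7
outdir: scratch/study_out
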