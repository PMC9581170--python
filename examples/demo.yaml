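# Three-chromosome demo study: 300 simulated F8 lines, two environments,
# four planted QTL, a restorer locus gating yield-trait scans.
seed: 101
orientation: {GL: 1, GYP: 1}
yield_traits: [GYP]
scan:
  pin: 0.001
  step_cm: 2.0
  lod_threshold: 3.0
  permutations: 0        # >0 replaces the fixed threshold with a permutation one
simulation:
  n_lines: 300
  replicates: 2
  environments: {HF: 0.0, NN: 0.4}
  chromosomes:
    - {id: c1, length_cm: 100, n_markers: 26}
    - {id: c2, length_cm: 100, n_markers: 26}
    - {id: c3, length_cm: 100, n_markers: 26}
  traits:
    GL:  {mean: 6.4, residual_sd: 0.25}
    GYP: {mean: 25.0, residual_sd: 1.0}
  qtl:
    - {chrom: c1, pos_cm: 30, trait: GL, a: 0.4, d: 0.1}
    - {chrom: c2, pos_cm: 60, trait: GL, a: 0.3, d: 0.5}
    - {chrom: c2, pos_cm: 20, trait: GYP, a: 0.5, d: 0.0}
    - {chrom: c3, pos_cm: 50, trait: GYP, a: 0.4, d: -0.6}
  restorer: {chrom: c3, pos_cm: 10}
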