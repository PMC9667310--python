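# Demo study: 200-residue toy serpin, error-prone-PCR library of 1e5 clones
# (mean 4.2 missense substitutions per clone), 48 h latency/selection time
# course with 3 replicates at 1e6 reads per sample.
seed: 1
reference:
  n_residues: 200
panel:
  n_amplicons: 4
  length: 150
library:
  n_clones: 100000
  mutation_mean: 4.2
design:
  replicates: 3
  depth_per_sample: 1000000
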