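# Bundled end-to-end demo: small enough to finish in well under five
# minutes on one CPU, large enough that every stage recovers its planted
# ground truth.
seed: 42
k: 31
d_min: 3
d_max: 250
size_cutoff: auto
tau: 0.05
r_min: 0.9
transform: none
out_dir: polyorigin_demo
simulate:
  ancestral_length: 40000
  divergence_per_branch: 0.02
  downsizing_fraction: 0.05
  coverage: 20.0
  read_length: 100
  error_rate: 0.002
  n_ortholog_groups: 150
  peptide_length: 300
  ortholog_divergence: 0.03
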