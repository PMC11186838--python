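# Full synthetic benchmark: CtNTH/dGMP emulation through every stage.
# Run with:  halomode all --config examples/synthetic_ctnth_dgmp.yaml
seed: 1
output_dir: halomode_out/ctnth_dgmp
synthetic:
  preset: ctnth_dgmp
  n_frames: 5000
# criteria / active_site / substrate / occupancy default to the synthetic
# template wiring; DCCA tracks the backbone-like atoms plus the nucleotide.
dcca:
  residues:
    - {res_id: 178, names: [CA]}
    - {res_id: 238, names: [CA]}
    - {res_id: 108, names: [CA]}
    - {res_id: 401, names: ["C1'", N9]}
dpc:
  n_centers: 1
max_cluster_frames: 300
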