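# Alternative d_O-H reading: ferryl oxo to the 3'-OH hydroxyl hydrogen
# (the "hydrogen bond between 3'-OH and the oxo group" reading).  Identical
# to ctnth_criteria_c2h.yaml except for reactive_pair_OH.
trajectory: path/to/your_trajectory.pdb
output_dir: halomode_out/ctnth_3oh
criteria:
  mode1_anchor:
    residues: [{res_id: 178, names: [NE, NH1, NH2]}]
  mode2_anchor:
    residues: [{res_id: 238, names: [NE, NH1, NH2]}]
  phosphate_acceptors:
    residues: [{res_id: 503, names: [O1P, O2P, O3P]}]
  reactive_pair_OH:
    - {residues: [{res_id: 501, names: [O1]}]}     # ferryl oxo O
    - {residues: [{res_id: 503, names: ["HO3'"]}]}  # 3'-OH hydrogen
  reactive_pair_CCl:
    - {residues: [{res_id: 503, names: ["C2'"]}]}
    - {residues: [{res_id: 502, names: [CL]}]}
substrate:
  residues: [{res_id: 503}]
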