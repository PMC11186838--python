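# Classification criteria for a CtNTH/dGMP trajectory (real-system
# numbering), with d_O-H measured from the ferryl oxo to the abstractable
# C2' hydrogen (the "reacting atoms" reading).
#
# Residue/atom names assume an AMBER-style topology: ferryl oxygen O1 on the
# iron residue (here res_id 501), chloride CL (res_id 502), nucleotide
# res_id 503.  Adjust res_ids to your system before use.
trajectory: path/to/your_trajectory.pdb
output_dir: halomode_out/ctnth_c2h
criteria:
  mode1_anchor:
    residues: [{res_id: 178, names: [NE, NH1, NH2]}]
  mode2_anchor:
    residues: [{res_id: 238, names: [NE, NH1, NH2]}]
  phosphate_acceptors:
    residues: [{res_id: 503, names: [O1P, O2P, O3P]}]
  reactive_pair_OH:
    - {residues: [{res_id: 501, names: [O1]}]}     # ferryl oxo O
    - {residues: [{res_id: 503, names: ["H2'", "H2''"]}]}  # C2' hydrogens
  reactive_pair_CCl:
    - {residues: [{res_id: 503, names: ["C2'"]}]}
    - {residues: [{res_id: 502, names: [CL]}]}
  hbond_cutoff: 3.2
  d_OH_max: 3.2
  d_CCl_max: 4.5
  tie_break: shorter_distance
active_site:
  residues:
    - {res_id: 106}   # Asp
    - {res_id: 108}   # Lys
    - {res_id: 178}   # Arg, mode-1 anchor
    - {res_id: 193}   # His
    - {res_id: 195}   # His
    - {res_id: 238}   # Arg, mode-2 anchor
    - {res_id: 253}   # His
    - {res_id: 272}   # Phe
    - {res_id: 274}   # His (second sphere)
    - {res_id: 306}   # Arg
    - {res_id: 501}
    - {res_id: 502}
    - {res_id: 503}
substrate:
  residues: [{res_id: 503}]
occupancy_residues:
  - {residues: [{res_id: 99}]}
  - {residues: [{res_id: 108}]}
  - {residues: [{res_id: 178}]}
  - {residues: [{res_id: 306}]}
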