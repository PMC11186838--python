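# halomode

Binding-mode and catalytic-competence analysis for MD trajectories of
Fe(II)/α-ketoglutarate-dependent nucleotide halogenases (αKGHs), plus a
sequence-triage layer for finding halogenase candidates.

These enzymes chlorinate the C2′ position of nucleotide 5′-monophosphates
(dGMP, dAMP) through a ferryl Fe(IV)=O intermediate that abstracts the C2′
hydrogen before chloride transfer.  Which way the substrate's 5′-phosphate
points — hydrogen-bonded to one active-site arginine anchor (*mode 1*,
e.g. Arg178) or the other (*mode 2*, e.g. Arg238) — controls whether the
deoxyribose sits close enough to the Fe-oxo/Cl centre to react.  Given a
multi-model PDB trajectory and a criteria config, `halomode` computes:

* **per-frame binding modes** from phosphate–arginine hydrogen bonds
  (heavy-atom distance ≤ 3.2 Å, inclusive), and a **productive** flag for
  frames satisfying the catalytic-competence geometry
  d(O⋯H) ≤ 3.2 Å and d(C2′⋯Cl) ≤ 4.5 Å;
* **P1/P2 statistics** — the percentage of total frames in each mode, and
  the percentage of total frames in each mode that are productive — with
  per-mode distance means ± sd and per-residue H-bond occupancies;
* **representative structures** per mode, via density-peak clustering of
  the pairwise active-site RMSD matrix (Kabsch superposition, proper
  rotations only);
* **dynamic cross-correlation maps** (DCCA) of atomic displacements after
  superposition on an iterated mean structure;
* **sequence triage**: global pairwise alignment and percent identity
  (Gotoh affine gaps, BLOSUM62), and facial-triad classification —
  hydroxylase-like HXD/E vs halogenase-like HXG/A — anchored by alignment
  to a curated reference.

A synthetic active-site generator with known ground-truth labels stands in
for cluster-scale MD, so the whole pipeline is testable and benchmarkable
on a laptop.  See `docs/methods.md` for the underlying definitions,
numerical choices and limitations.

## Worked example

Run the full synthetic benchmark — a 5,000-frame emulation of the
CtNTH/dGMP condition, in which mode 1 is generated at 65.1 % occupancy
with 43.5 % of all frames productive — and print the recovered statistics:

```sh
halomode all --config examples/synthetic_ctnth_dgmp.yaml
halomode report --out-dir halomode_out/ctnth_dgmp
```

```
 mode1: P1 = 65.4%  P2 = 44.4%
 mode2: P1 = 8.6%  P2 = 3.0%
 other: P1 = 26.0%  P2 = 0.0%
```

The classifier recovers the generated occupancies within binomial
sampling error (3 SE ≈ ±2.0 points at n = 5,000): mode 1 dominates and
carries essentially all productive frames, mode 2 is minor and rarely
productive — the signature that distinguishes a dGMP-preferring enzyme
from a dAMP-preferring one, where the same analysis puts mode 2 on top.
The output directory also contains `frame_labels.tsv` (per-frame mode,
productive flag, reacting-atom distances), `occupancy.tsv`,
`mode1_rep.pdb` / `mode2_rep.pdb` (representative structures),
`dcca.tsv`, full-precision JSON mirrors, and a run manifest.

The library surface mirrors the CLI:

```python
from halomode import (get_condition, sample_trajectory, build_template_topology,
                      default_criteria, classify_frames, mode_statistics)

traj, truth = sample_trajectory(get_condition("ctnth_dgmp", n_frames=5000, seed=1))
labels = classify_frames(traj, build_template_topology(), default_criteria())
stats = mode_statistics(labels)
```

On the sequence side:

```python
from halomode import make_sequence_fixtures, global_align, call_facial_triad
from halomode.synthdata import triad_positions_of_reference

ref, hxa, hxd, deleted, a, b = make_sequence_fixtures(0)
print(global_align(a, b).identity_percent)      # 75.0  (10 of 40 positions mutated)
call = call_facial_triad(hxd, ref, triad_positions_of_reference())
print(call.call)                                # HXD_E_hydroxylase_like
```

For real trajectories, copy `examples/ctnth_criteria_c2h.yaml` (d_O-H
measured to the C2′ hydrogen) or `examples/ctnth_criteria_3oh.yaml`
(measured to the 3′-OH hydrogen) and adjust residue ids to your topology.

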