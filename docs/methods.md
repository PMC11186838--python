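# Methods

## The analysis

`halomode` analyses MD trajectories of Fe(II)/α-ketoglutarate-dependent
nucleotide halogenases (αKGHs) in complex with a nucleotide
5′-monophosphate substrate.  These enzymes abstract the substrate's C2′
hydrogen with a high-valent ferryl (Fe(IV)=O) intermediate and transfer a
chloride to the resulting radical.  Whether a trajectory frame can react
depends on two things the package quantifies:

1. **Binding mode.**  The substrate's 5′-phosphate can hydrogen-bond one of
   two active-site arginine anchors.  A frame is *mode 1* when at least one
   phosphate oxygen is within the hydrogen-bond cutoff of the mode-1
   arginine (Arg178 in CtNTH numbering, Arg177 in AdaV), *mode 2* for the
   second arginine (Arg238 / Arg237), and *other* when neither anchor is
   contacted.  Hydrogen bonds are detected on heavy-atom distance alone,
   donor N/O to acceptor O ≤ 3.2 Å, boundary inclusive.  An optional
   donor–H–acceptor angle gate exists but is off by default, since the
   distance criterion is the one the classification is defined by.
2. **Catalytic competence.**  A frame is *productive* when the reacting
   atoms are positioned for both chemical steps:
   d(O⋯H) ≤ 3.2 Å (ferryl oxo to the abstractable substrate hydrogen) and
   d(C2′⋯Cl) ≤ 4.5 Å, both boundaries inclusive.

From per-frame labels the package reports, per mode *m*:
P1(*m*) = 100·(frames in *m*)/T and P2(*m*) = 100·(frames in *m* that are
productive)/T — both over the **total** frame count T, so ΣP1 = 100 % and
P2(*m*) ≤ P1(*m*).  The conditional fraction P2/P1 is exposed separately
and never substituted for P2.  Per-mode distance statistics are sample
mean ± sample sd (n − 1 denominator) over the frames of that mode.
Per-residue hydrogen-bond occupancy is the percentage of frames in a
subset (default: the frames of the mode under study) in which the residue
forms ≥ 1 hydrogen bond with the substrate; simultaneous bonds count the
frame once.

Frames hydrogen-bonded to **both** anchors are resolved by the
`tie_break` policy: the default assigns the closer anchor
(`shorter_distance`); `ambiguous_bucket` sends the frame to *other*.
Either way the count is reported as `ambiguous_count`.  The criteria read
as a partition and real both-anchor frames are geometrically implausible
(the anchors sit on opposite sides of the phosphate pocket), but the
policy is explicit because the case is not impossible in distorted
structures.

## Representative structures

A representative structure per mode is the centre of the most populated
cluster of that mode's frames, clustered by density peaks on the pairwise
active-site RMSD matrix (selected atoms, per-pair Kabsch superposition,
proper rotations only).  Density-peak clustering follows the standard
ρ/δ construction: Gaussian-kernel density ρ_i = Σ_{j≠i} exp(−(d_ij/d_c)²),
separation δ_i = distance to the nearest point of strictly higher density
(ties broken by index; the global maximum takes δ = max_j d_ij), centres
ranked by γ = ρ·δ, remaining points assigned to their nearest
higher-density neighbour in descending-ρ order.

Numerical choices, made here because the method leaves them open:

* `d_c = "auto"` uses the 2nd percentile of the off-diagonal distances,
  clamped to the `max(2, 200/n)`-th percentile so each point keeps on the
  order of two neighbours within d_c on small matrices.
* `n_centers = "auto"` picks the largest ratio gap in the descending
  γ/γ_max sequence, searched only while the leading value is ≥ 0.1 of the
  maximum and with a 0.01 damping floor, so near-zero tails cannot spawn
  centres.  The pipeline itself uses `n_centers = 1` per mode: one
  representative per binding mode.
* Halo/outlier detection from the original density-peak algorithm is not
  implemented.
* Pipelines cap the per-mode frame count entering the O(n²) RMSD matrix at
  `max_cluster_frames` (default 300) by even striding.

## Dynamic cross-correlation

Every frame is Kabsch-superposed onto an iterated mean structure (re-fit
and re-average until the mean moves < 1e-6 Å RMSD, at most 10 iterations).
With displacements Δr_i(t) = r_i(t) − ⟨r_i⟩,
C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) ∈ [−1, 1].  Correlation with a
multi-atom group (a ligand, a phosphate group) is computed on the group's
geometric-centre displacement, superposed in the same shared frame as the
atom selection.  Atoms whose displacement variance is ≤ 1e-20 Å² (static
to superposition round-off) get NaN-marked rows, listed in `undefined`,
rather than propagating NaN.  A PCA of the displacement covariance is
exposed as a secondary diagnostic.  Note that rigid-body removal itself
induces O(1/N) correlations between otherwise independent atoms; with few
tracked atoms, small |C| values are not evidence of independent motion.

## Sequence triage

Candidate sequences are triaged by the iron-binding facial triad:
hydroxylase-like HXD/E (2-His-1-carboxylate) versus halogenase-like HXG/A,
where the missing carboxylate opens the halide coordination site.  The
triad is located by global alignment against a curated reference with
known triad positions, not by motif regex (a bare HX[GA] scan is shipped
only as a labelled heuristic).  Alignment is Needleman–Wunsch/Gotoh with
affine gaps via Biopython's `PairwiseAligner` (BLOSUM62, gap open −10,
gap extend −0.5 — standard protein defaults; the tools behind published
identity figures are rarely stated, so the identity denominator is an
explicit enum recorded in every output: gap-free columns by default,
shorter-sequence or full-alignment length as alternatives).

## The synthetic generator

Cluster-scale MD cannot be regenerated at desk scale, so every stage is
exercised against a generator that emulates the *statistical* structure of
the analysis problem with known ground truth:

* A ~30-atom template active site: two arginine guanidinium anchors 18 Å
  apart (> 2·(cutoff + 3·jitter), so both-anchor frames have probability
  ≈ 0), an Fe/oxo/Cl centre, a lysine, and a phosphorylated nucleotide
  fragment.
* Per frame, a binding mode is drawn from a Markov chain whose stationary
  distribution equals the target occupancies π; the persistence knob ρ
  (default 0 = i.i.d., keeping binomial error formulas exact) controls
  interconversion kinetics without changing π.
* The phosphate's nearest oxygen is placed at a truncated-normal distance
  ~ N(2.9, 0.1) Å clipped to [2.4, 3.2] from the drawn anchor (or parked
  ≥ 8 Å from both for "other").  A productive flag ~ Bernoulli(q_m) selects
  between in-cutoff distance distributions (d_O-H ~ N(2.8, 0.2) on
  [2.2, 3.2]; d_C2′-Cl ~ N(4.2, 0.2) on [3.5, 4.5] Å) and out-of-cutoff
  ones (shifted ≈ +1.5 Å, bounded away from the cutoffs); the reacting
  atoms are placed along fixed directions at exactly the drawn distances.
  Alternatively a mode can specify *marginal* distance distributions, from
  which distances are drawn unconditionally and the productive flag is
  derived from the cutoffs — used for distance-statistics recovery.
* Isotropic Gaussian jitter (default sd 0.05 Å) is added to all atoms not
  carrying a drawn distance.

This is construction, not physics: distances are realized directly, bonded
geometry is not enforced (the generated C2′–H2′ separation is not a
covalent bond length), there is no solvent, no force field, no kinetics
beyond the persistence knob, and no conformational coupling between the
phosphate pose and the reacting-atom distances other than what the
per-mode distributions encode.  Passing recovery tests therefore shows
that the detection → classification → statistics chain is correct and
unbiased at realistic geometry scales — not that the package would extract
the same numbers from real MD ensembles, which depend on force field,
sampling and criteria choices upstream of this package.

### Study-condition presets

Named presets parameterize the generator with published per-condition
values: occupancies π set so E[P1] matches the reported mode percentages,
q_m = P2(m)/P1(m) so E[P2] matches the reported productive percentages,
and in-cutoff distance means following the reported per-mode distances.
Values the reports leave unstated were fixed once at plausible magnitudes
and do not affect the recovered statistics of interest: the minor-mode
occupancies of the AdaV/dAMP (18 %), AdaV/dGMP (15 %), CtNTH-H274Y/dAMP
(22 %) and CtNTH-H274Y/dGMP (40 % mode 2) conditions, and the mutant
productive probabilities (q₁ = 0.02, q₂ = 0.25 for H274Y/dAMP; 0.05 for
H274Y/dGMP).

## Problem sizes and reproducibility

Recovery runs use 20,000 frames (binomial 3-SE bands of ±1.0 percentage
points at P1 ≈ 65 %) and 10,000 frames for distance recovery (3-SE band
±0.012 Å at sd 0.4 Å); property suites use 400–10,000 frames depending on
the bound being tested.  All sampling flows through
`numpy.random.default_rng(seed)`; a spec, config or CLI seed reproduces
trajectories bit-for-bit, and re-running a pipeline config reproduces its
TSV outputs byte-for-byte.  `scripts/acceptance.py` derives one sub-seed
per study condition from its `--seed` argument.

## Known limitations

* PDB I/O covers the plain ATOM/HETATM/MODEL subset only: no altlocs,
  insertion codes, unit cells or binary trajectory formats; inputs are
  assumed imaged/whole (no periodic-boundary handling).
* All frames given are analysed; there is no stride/equilibration logic.
* The two readings of d_O-H (oxo → C2′ hydrogen vs oxo → 3′-OH hydrogen)
  are both chemically motivated; the reactive pair is fully configurable
  and both example configs are shipped (`examples/ctnth_criteria_*.yaml`).
* DCCA is computed on whatever trajectory it is given; replicate
  concatenation order is the caller's responsibility and is recorded only
  by the input itself.
* Identity percentages depend on the alignment parameters and denominator
  convention; comparisons across tools are meaningful only with the
  convention stated (it is recorded in every alignment result).
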