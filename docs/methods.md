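# Methods

## Profile HMMs from per-residue predictions

A profile HMM normally models a multiple-sequence alignment; here its
parameters are instead taken directly from per-residue predictions. For a
chain of L residues the profile has L match states. Match emissions are the
predicted identity-probability vectors; insert emissions equal the
background distribution (uniform, 1/20 or 1/4, by default — this makes the
zero-information case score exactly 0 and keeps the construction free of
composition assumptions; HMMER's standard amino background can be passed
instead). Transitions at position *i* come from that residue's confidence
c⁽ⁱ⁾:

    P(M→M) = max(c − d, 0.5)     P(D→M) = P(I→M) = 1 − d
    P(M→D) = P(M→I) = (1 − P(M→M)) / 2
    P(D→D) = P(I→I) = d          P(I→D) = P(D→I) = 0

with the constant d = 0.5 by default (configurable). Note that with
c ∈ [0, 1] and d = 0.5 the max() clamp is always active, so P(M→M) = 0.5
for every residue; the formula is implemented as stated rather than
"fixed", because c may arrive on a different scale from other producers
and d is a configuration key. The final node's delete branch is folded
into the exit (P(M→D) mass added to P(M→M), final delete exits with
certainty) so that serialized profiles are structurally valid.

### HMMER3 serialization

Profiles are written in the HMMER3/f ASCII dialect: probabilities as
negative natural logs, impossible transitions as `*`, the standard
7-column transition order, node 0 carrying the background as insert-0
emissions. Files include STATS lines with placeholder Gumbel parameters
(λ = ln 2): HMMER refuses to report hits from profiles without them, but
bit scores are unaffected. E-values derived from these placeholders are
**not calibrated** — E-value calibration is deliberately left to HMMER
itself, and the internal engine ranks by bit score only.

### Viterbi search

The built-in engine computes the best profile-local, sequence-local
alignment under log-odds scoring: match states score
log₂(emission/background), transitions log₂ P, entry into any of the L
match states costs log₂(1/L) (uniform entry), and exit from any match
state is free. Alignments start and end in match states. Ambiguity codes
score at background (log-odds 0). Database search uses a vectorized
batch recurrence (the silent-delete chain along the profile is folded
into a prefix-maximum, so each sequence position costs one pass of
(n_sequences × L) vector work); alignments with tracebacks are then
recomputed for reported hits only. Forbidden transitions are clamped to a
−10⁶-bit penalty inside the batch scorer to keep the prefix sums finite.
The engine is verified against exhaustive path enumeration for all
profiles of length ≤ 4 against every nucleotide sequence of length ≤ 5.

Internal bit scores differ from external HMMER's by a few bits (entry/exit
and null-model conventions differ); rankings agree on every fixture
tested, and a cross-check test drives a real HMMER search through pyhmmer
over a written profile.

### Identification and assignment

With known sequences, each chain's best hit (if ≥ 25 bits, configurable)
renumbers the chain by sequence coordinates and mutates every match-state
residue to the matched sequence identity; unaligned residues keep their
argmax identity. With unknown chains, every chain of ≥ 10 residues is
searched against the proteome; chains whose top-5 candidates share a
proteome entry are grouped and the group is scored by the sum of its
chains' bit scores for that entry — a concrete form of bootstrapping weak
hits across pseudosymmetric copies, which the qualitative description
leaves open. Multiple chains may map to overlapping ranges of one
sequence (no cross-chain uniqueness). All orderings are fully tie-broken
(score, then id), so reports are deterministic. An optional
reversed-orientation search covers fragments traced with unknown chain
direction.

## Post-processing

Predicted residues form a k-nearest-neighbour graph (k = 20, clamped to
n − 1, distance ties broken by lower index). Chains are traced by
accepting candidate links shortest-first under a bond cutoff (4.2 Å Cα–Cα
for protein, 7.5 Å P–P for nucleic acids) provided neither endpoint
already has two links and no cycle forms; this greedy rule matches the
exhaustive most-links/shortest-total optimum on all small fixtures
tested. Fragments assigned to the same sequence with order-compatible,
non-overlapping ranges merge when the gap between their facing ends is at
most (missing residues + 1) × 3.8 Å — i.e. a fully extended linker could
span it; the numeric rule is this package's concretization of
"sequence and proximity". Chain direction comes from sequence
coordinates, never geometry. Chains shorter than 4 residues are pruned
(idempotent). Connection never moves atoms — only topology and numbering
change.

## Idealized geometry

`data/ideal_geometry.json` stores, for all 20 amino acids and 4
ribonucleotides, an internal-coordinate atom tree derived from the
Chemical Component Dictionary's ideal coordinates
(`scripts/make_geometry_table.py` regenerates it): every heavy atom
beyond the three frame atoms has a parent bond length, bond angle, and a
torsion that is either fixed or expressed as χₖ + offset about a
rotatable axis. Reconstruction is NeRF placement; branches attached to a
rotated bond follow it rigidly because their references move with it.

Conventions: amino-acid frames are anchored at Cα with x toward C and N
in the xy-plane; nucleotide frames at P with x toward O5′ and C5′ in the
xy-plane. The backbone O uses its tabulated default torsion (the builder
is stateless per residue; refinement downstream repositions O against the
next residue anyway). Proline's ring makes its χ angles non-free, so its
torsions are fixed at ring-consistent values. Missing torsions fall back
to the tabulated canonical rotamer with a warning. Occupancy is 1.0, no
altlocs, no hydrogens. The build→measure round trip reproduces every
tabulated value within 10⁻³ Å and 0.1° for all 24 types, and all built
Cα centres are L-configured.

The per-residue confidence written to the B-factor column is
clamp((1.2 − r.m.s.d.)/0.7, 0, 1): 1 at a predicted backbone r.m.s.d. of
0.5 Å or better, 0 at 1.2 Å or worse, linear between.

## Maps

MRC/CCP4 I/O goes through gemmi; axis permutations (MAPC/MAPR/MAPS) are
normalized to X,Y,Z on read, and the origin is taken from the ORIGIN
record when nonzero, else NXSTART·voxel (the two conventions coexist in
deposited maps; ORIGIN wins). Resampling to a common voxel size (1 Å in
the modelling pipeline) defaults to real-space trilinear interpolation —
convex, so output extrema never exceed input extrema — with Fourier
cropping/padding available for band-limited maps (exact for them, but it
can overshoot). Out-of-bounds interpolation returns a fill value
(default 0) rather than raising, so radial sampling near the box edge
degrades gracefully.

## Metrics

**Q-score.** Around each atom the map is sampled on radial shells (0.1 Å
steps to 2.0 Å, 24 fixed Fibonacci-sphere directions per shell plus the
centre); sample points nearer to a different atom are excluded via a
k-d tree. Q is the Pearson correlation between sampled values and the
reference Gaussian exp(−½(r/σ)²) with σ = 0.6 Å — correlation is
affine-invariant, so the reference's height and offset are irrelevant and
Q ∈ [−1, 1]. Flat density (zero variance) yields Q = 0 with a flag;
atoms outside the map are flagged and excluded. For a model on its own
noiseless simulated map, Q equals 1 up to interpolation error only when
atoms do not overlap: bonded neighbours' Gaussian tails distort the
radial profile and cap full-atom models near Q ≈ 0.96 regardless of
voxel size. The Q ≥ 0.99 self-consistency checks therefore use
Cα-trace models (atoms 3.8 Å apart) on 0.5 Å-voxel maps, where the
exactness argument genuinely applies.

**Matching, r.m.s.d., completeness.** Models are compared in the shared
map frame with no superposition. Reference residues match predicted ones
greedily, nearest pair first, one-to-one, within 3 Å (ties by residue
index); the greedy matching equals the optimal-assignment oracle on all
tested perturbed instances up to n = 20. Backbone r.m.s.d. runs over
(N, CA, C, O) or (P, O5′, C5′, C4′, C3′, O3′) atoms present in both
partners; the global value is the root of the mean square over all
matched atoms. Completeness counts a reference residue as built when its
matched Cα/P lies within 3 Å and (for sequence completeness) the identity
agrees; without the identity clause it is backbone completeness, and the
strict version can never exceed the loose one.

**FSC.** Model density is simulated on the experimental map's exact grid
(never resampling the experimental map) as atomic-number-weighted
Gaussians with σ² = B/(8π²); both volumes are padded to cubic, Fourier
transformed, and correlated per integer-|k| shell. Only the curve's
shape is meaningful — scattering factors are reduced to atomic-number
proportionality, which preserves shell correlation but not absolute
scale.

## Synthetic emulator

`emulate_predictions` draws identity probabilities from a Dirichlet with
concentration 50 centred on (a, (1−a)/(K−1), …) — accuracy a is the
expected mass on the truth; a = 1 short-circuits to exact one-hot.
Positions get isotropic Gaussian noise; frames are random rotations.
Confidence is 0.9 when the sampled argmax is correct and 0.4 otherwise,
±0.05 uniform jitter, clamped to [0, 1] — tying confidence to
correctness the way the upstream network's training objective implies,
without claiming its actual law; predicted r.m.s.d. is the inverse linear
map of the confidence. Decoy databases are i.i.d. from the background
composition. All generators are bit-reproducible under their seed.

What the emulator does *not* model: correlated errors along the chain,
register shifts, map-quality-dependent confidence, realistic amino-acid
composition (background is uniform), or broken/partial traces. Passing
identification tests therefore demonstrate the correctness and
discrimination of the profile/search machinery under controlled noise,
not end-to-end performance on experimental maps.

## Problem sizes and tolerances

The test and acceptance workloads are sized for interactive runs: 10–80
residue chains, 200–1,000-entry decoy databases, 20 seeded replicates for
the identification recovery rate (accuracy 0.5, ≥ 95% top-1 required),
exhaustive Viterbi verification at L ≤ 4 × n ≤ 5 over the nucleotide
alphabet, and 0.5 Å-voxel maps of ≤ 10⁶ voxels. Serialization round
trips are required to 10⁻⁴ in probability (5-decimal −ln format),
geometry round trips to 10⁻³ Å / 0.1°, and the completeness/confidence
scans use 0.01 Å / 0.001 Å grids.

## Known limitations

- E-values are never computed internally; thresholds are bit scores.
- The chain-connection distance rule and the cross-referencing statistic
  are this package's concrete choices for qualitatively described steps.
- Nucleotide support covers RNA (A, C, G, U); DNA would need its own
  geometry entries and alphabet naming.
- Q-scores of tightly packed full-atom models saturate below 1 by
  construction (overlapping Gaussians), matching the behaviour of the
  published reference implementation on real maps only qualitatively.
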