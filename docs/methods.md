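# Methods

This note documents the models, conventions, and numerical choices behind
the toolkit, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting

Given a multiple sequence alignment (MSA) for a query protein of length L,
the toolkit predicts a *distogram*: for every residue pair (i, j), a
categorical distribution over 10 binned Cβ–Cβ distances (Cα for glycine).
The bins are < 4 Å, then 2 Å bins up to 20 Å, and a final ≥ 20 Å bin.
Contact probability is the summed mass of the first three bins (< 8 Å),
matching the CASP contact definition. Auxiliary per-residue tasks —
secondary structure (9 classes), φ/ψ torsions (36 ten-degree bins plus an
error/gap class), and relative accessible surface area (10 bins plus N/A) —
are trained jointly to regularize the main task.

## Input featurization (L × L × 547)

The published totals for the input tensor are 547 channels overall, of
which 442 come from direct-coupling analysis, with a 21-letter sequence
alphabet. The exact per-channel layout is this package's documented
convention (the totals alone do not determine it; a plain
42 + 2 + 60 + 442 sum leaves one channel unaccounted for):

| channels | content |
|---------:|---------|
| 21 + 21  | one-hot of residues i and j (20 amino acids + shared unknown/gap) |
| 1 + 1    | raw integer residue indices i and j (0-based; unnormalized — the network's initial BatchNorm absorbs scale) |
| 30 + 30  | profile rows for i and j: 20 match emissions, 7 transitions, 3 diversity values, matching the hhm file layout so external profiles and the internal MSA-derived fallback are interchangeable |
| 441 + 1  | DCA: the flattened 21×21 coupling block of the ordered pair, plus the APC-corrected coupling norm |
| 1        | validity mask: 1 on real residues, 0 on crop padding |

**Sequence reweighting.** Row r is weighted 1/(number of rows with ≥ 80%
identity to r, itself included); Neff is the weight sum. The 80% threshold
is the common choice in the coevolution literature.

**DCA.** Couplings come from inverting the shrinkage-regularized covariance
of the one-hot MSA columns, the approach of the inverse-covariance lineage
of coevolution methods (not pseudo-likelihood, which is stronger but far
more expensive). The gap state is excluded from the inverted system —
gap-driven covariance otherwise dominates — and zero-filled back into the
21×21 blocks so the channel count stays 441. The default diagonal shrinkage
is 4.5/√(Neff·L): enough to keep the 20L×20L system well-conditioned at
desk-scale alignment depths while vanishing for deep alignments. Per-pair
coupling strength is the Frobenius norm of the gap-excluded block with the
average-product correction (APC) applied, off-diagonal means only, zero
diagonal.

**Profile fallback.** When no hhm file is supplied, emissions are weighted
per-site residue frequencies (gap mass excluded, so the 20 values sum to
≤ 1), transitions come from weighted gap-open/extend counts between
adjacent columns (insertion transitions are zero because aligned rows carry
no insertion states), and the diversity columns carry the per-site
effective non-gap sequence count.

## Labels

* **Distances**: binned Cβ map as above; symmetric with a zero-distance
  diagonal (class 0). Pairs where either residue lacks Cα carry a reserved
  ignore value (−1) that every loss component excludes — silently dropping
  residues would misalign the label arrays.
* **Torsions**: IUPAC sign convention; the first residue's φ and last
  residue's ψ are undefined (class 36), as is any angle at a chain gap.
* **Secondary structure**: parsing classic DSSP text output is preferred.
  The internal fallback implements the Kabsch–Sander rules — amide H placed
  opposite the previous carbonyl O, electrostatic H-bond energy below
  −0.5 kcal/mol, helices from consecutive n-turns (precedence I < G < H as
  in DSSP), strands from bridge patterns. Bends (S) are not assigned by
  the fallback. The fixed letter→class table is
  H=0, G=1, I=2, E=3, B=4, T=5, S=6, coil/blank=7, gap/error=8; whether the
  original 9-class grouping used blank or gap as its ninth class is not
  documented, so this table is a convention of this package.
* **Relative ASA**: Shrake–Rupley with a 1.4 Å probe and a fixed
  960-point golden-spiral sphere lattice (doubling the lattice moves values
  by < 0.02 on the test fixtures), per-element radii, normalized by the
  Tien et al. theoretical maximum per residue type and clamped to [0, 1].
  Which max-ASA normalization the original pipeline used is unstated; the
  theoretical table is the most permissive standard choice.

## Network

An initial BatchNorm + 1×1 convolution is followed by 220 pre-activation
residual blocks (BN–ELU–1×1, BN–ELU–3×3 dilated, dropout, BN–ELU–1×1,
identity addition). The 3×3 dilations cycle 1, 2, 4, 8; the first 28 blocks
are 256 channels wide and the remaining 192 are 128 wide, with a learned
1×1 projection on the skip path at the width change (the only unstated
transition detail; a projection is the standard ResNet treatment). The
bottleneck width inside each block is half the block width, following the
architecture family this design descends from. Spatial (channel-wise)
dropout at rate 0.15 sits after the 3×3 convolution, active only in
training. Heads: a 1×1 convolution to 10 distance classes, and full-row /
full-column convolutions (kernel 1×c and c×1) collapsing one spatial axis
for the i- and j-axis auxiliary predictions, one convolution per task,
concatenated to 94 channels per axis.

The engine is a compact self-contained NumPy layer library
(`prospr.nn`): im2col + BLAS convolutions, explicit backward passes
verified against central-difference gradients, and Adam. With dilation
cycling, the default network's analytic receptive field (1651 cells) far
exceeds the 64-cell crop.

Softmax is applied per crop *before* aggregation (probability averaging,
not logit averaging): averages of normalized distributions stay normalized,
which keeps aggregation closed on the simplex.

## Training

Each epoch lays a freshly random-offset non-overlapping c×c grid over every
domain (full coverage of the L×L map; edge crops zero-padded with mask 0
and ignore labels) and re-derives features from a fresh 50% MSA subsample
(query always kept, remainder sampled without replacement). The loss is
15·CE(dist) + 0.5·CE(SS) + 0.25·CE(φ) + 0.25·CE(ψ) + 0.5·CE(ASA), each
term a mean over non-ignored positions; the i-axis and j-axis views of a
per-residue task each carry half that task's weight. Optimizer: Adam at
initial LR 0.001 with the three published piecewise-constant schedules
(A: 0.0005 @ 5, 0.0001 @ 15; B: @ 10/25; C: @ 8/20) and otherwise common
defaults (β₁ 0.9, β₂ 0.999, no weight decay). Validation uses static
offset-(0,0) grids, and the three lowest-validation-loss checkpoints are
retained.

Features can be recomputed online from each epoch's subsample (the default,
exact) or taken from a precomputed tensor (`recompute_features=False`) when
throughput matters more than augmentation.

## Inference

A base (0,0) grid plus `n_offsets − 1` shifted grids cover crop boundaries;
shifts are deterministic stride fractions by default (reproducible without
a seed) or random when a generator is passed. Each cell's distribution is
the arithmetic mean over all covering crops — cells covered by more crops
simply average more terms — then the distogram is symmetrized by averaging
(i,j) with (j,i), since the network itself is not architecturally
symmetric. Ensembling averages the distograms of several models and
renormalizes each cell (a no-op up to rounding, kept for safety).

## Evaluation

Top-L normalized precision per separation range (short 6–11, mid 12–23,
long ≥ 24; separations < 6 excluded): rank in-range pairs by probability,
select the top min(L, #in-range pairs) with deterministic lexicographic
tie-breaking, and score TP/min(L, T) where T is the number of true in-range
contacts. min(L, T) is the minimal denominator that makes 100% attainable
when fewer than L true contacts exist; a range with T = 0 is undefined and
excluded from averages rather than scored 0. Scores are invariant to any
monotone transform of the probability map. The depth/length correlation
report splits targets at MSA depth 400 and computes Pearson r of average
accuracy against depth within each stratum and against length overall.

## Synthetic data

* `ideal_helix`: poly-alanine backbone from fixed internal coordinates
  (φ = −57°, ψ = −47°, ω = 180°, standard bond lengths/angles; Cβ by ideal
  tetrahedral geometry). Recomputing its torsions and Cβ distances is the
  oracle for the labeling code.
* `potts_sample`: Gibbs sampling from a 20-state pairwise Potts model whose
  only couplings are planted same-state interactions of strength β = 1.5 on
  pairs separated by ≥ 5 positions, with per-site fields of scale 0.3.
  Each alignment row is an independent chain run for a fixed burn-in of 50
  full sweeps (exact sampling is infeasible at L = 40; the β = 0 column
  independence test is the convergence spot-check). Recovering the planted
  pairs among the top APC scores is the ground-truth check for DCA.
* `random_msa`: i.i.d. mutated copies of a random query with occasional
  gaps — shape and plumbing tests only.
* `compact_chain`: a fixed-bond random walk with an origin-restoring bias,
  giving contacts in all three separation ranges; a truth structure for the
  evaluation oracles, not a physical decoy.

None of these reproduce real evolutionary correlation structure,
phylogeny, or realistic protein geometry. Passing tests demonstrate that
each algorithmic stage is implemented correctly (recovery of planted
signal, exact agreement with brute-force oracles, optimization sanity),
*not* that the network reaches published accuracy on real targets — that
requires the original training corpus and multi-week GPU training, which
is out of scope.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: alignments of
20–2000 rows, L of 12–100, a tiny 8-block/16-channel network for training
loops, and a single 64×64 crop through the full-size 220-block network to
audit the architecture. The 200-step overfit check trains on one fixed
synthetic domain with precomputed features and a constant learning rate —
it is an optimization sanity check, so the per-epoch augmentation and LR
decay that help generalization would only confound it. All stochastic
steps take explicit seeds; evaluation-mode forward passes are exactly
deterministic, and HDF5 outputs are written without timestamps so repeated
runs are byte-identical.

## Known limitations

* Pseudo-likelihood DCA (stronger on deep alignments) is not implemented.
* The internal DSSP fallback omits bends and some π-helix edge cases.
* ASA uses backbone + Cβ atoms only on synthetic fixtures without side
  chains, so absolute rASA values there are coarse; binning is robust to
  this.
* Insertion-state statistics in the internal profile fallback are zero by
  construction (a3m insertions are removed on read).
* PDB insertion codes are ordered as encountered; whether upstream domain
  structure files contain them is unverified.
* mmCIF, multi-model NMR (beyond the first model), and hetero-atom
  accessibility are out of scope.
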