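# Methods

## Problem and representation

`pocketseg` detects ligand-binding pockets on prepared protein structures by
semantic segmentation of a voxelized representation.  A protein is mapped to
a cubic lattice of 36 nodes per axis at 2 Å spacing — a 70 Å node-to-node
span — centered on the unweighted mean of the heavy-atom coordinates.  Each
heavy atom contributes an 18-channel feature vector at its nearest lattice
node (half-up rounding per axis; feature vectors of atoms sharing a node are
summed, so channel totals are conserved).  Reference pockets are point
clouds filling the cavity; a mask voxel is set when at least one pocket
point falls inside the spacing-sized cube centered on the node — the same
nearest-node rule, so grid and mask stay co-registered.  Pockets that
voxelize to an empty mask are retained for training as negative examples
and skipped in validation.

The 18 channels are: 9 one-hot element classes (B, C, N, O, P, S, Se,
halogen = F/Cl/Br/I, metal), hybridization (1–3), heavy-atom bond count,
heteroatom bond count, five binary flags (hydrophobic, aromatic, H-bond
acceptor, H-bond donor, ring) and the partial charge read from mol2 input
(0 when absent).  Input files carry no bond orders (mol2 point clouds and
prepared PDB/mol2 proteins), so perception is rule-based and geometric:
bonds from a covalent-radius distance criterion (1.3 × Σ r_cov), rings from
graph cycles, aromaticity assigned to planar 5/6-membered C/N/O/S rings
(RMS out-of-plane < 0.15 Å), donors are N/O/S with an explicit hydrogen
neighbor, acceptors are N/O, hydrophobic carbons have no heteroatom
neighbor, and hybridization follows neighbor count and local planarity.
These rules are deliberately simple and deterministic; they are not a
substitute for full cheminformatics perception and are documented here so
the feature semantics are reproducible.

## Network and objective

The model is a 3D U-Net: nine blocks of two same-padded 3³ convolutions
with ReLU — four encoder blocks (32, 64, 128, 256 filters), a 512-filter
bottleneck, four decoder blocks mirroring the encoder (256, 128, 64, 32).
Max-pooling patch sizes down the encoder are (2, 2, 3, 3) and nearest-
neighbor up-sampling sizes up the decoder are (3, 3, 2, 2), so a 36³ input
reaches a 1×1×1 bottleneck (36 → 18 → 9 → 3 → 1) and is restored
symmetrically.  The final feature map of each encoder block is concatenated
(after the up-sampled decoder channels) with the first feature map of the
mirrored decoder block.  A 1×1×1 convolution with a sigmoid yields the
single-channel per-voxel pocket probability.  Same padding is required by
the symmetric size arithmetic; up-sampling is parameter-free repetition;
the default architecture has 23 546 977 trainable parameters (verified
against a closed-form per-layer count).

The objective is the negative smoothed Dice coefficient

    C(y, t) = -(2 Σ y·t + ε) / (Σ (y + t) + ε),   ε = 0.01,

bounded in [-1, 0), equal to -1 at perfect overlap and in the both-empty
limit (so correctly silent predictions on empty-mask negatives are not
penalized), plus an L2 penalty λ Σ w² (λ = 1e-5) over convolution kernels
(biases excluded).  Optimization is Adam; the full-scale reference regime
is 1.5·10⁶ steps with batches of 10 at learning rate 1e-6, which needs
accelerator-class throughput and is retained only as configuration.

The network, its backpropagation and Adam are implemented directly on
numpy (float32, channels-last; convolutions as one GEMM per kernel offset).
Parameter gradients of the full network are verified against central
finite differences in the test suite.  Two numerical choices depart from
framework defaults and are deliberate: max-pool ties share the incoming
gradient equally (the conservative subgradient, so pooled gradients match
finite differences even on the exact ties that ReLU produces), and the
output convolution's bias is initialized to -4 so the initial predicted
probability (≈ 0.018) matches the sparsity of pocket targets — the
standard prior-probability initialization for heavily imbalanced
segmentation, without which early optimization is dominated by driving
down the background.

## Training protocol

Structures of one protein (one group id) must never straddle a
train/validation boundary.  Folds are assigned to whole groups greedily:
groups sorted by size descending (ties shuffled by seed), each assigned to
the currently smallest fold — fold sizes balance to within the largest
group size and no group ever spans folds (property-tested over random
manifests).  Batches are drawn uniformly with replacement; augmentation
resamples, per draw, one of the 24 proper axis-aligned cube rotations
(exact on-lattice, no interpolation) and an integer translation of at most
3 voxels (6 Å) per axis, applied identically to grid and mask with
zero-fill.

## Inference and evaluation

Prediction re-centers the lattice on the query protein, featurizes,
and runs one forward pass.  The density is binarized at 0.5 (results are
stable for thresholds 0.3–0.8; the threshold is a parameter), split into
6-connected (face-adjacent) components, and components below `min_voxels`
(default 50 voxels = 400 ų) are discarded.  A segment's score is its
summed probability — a volume-weighted confidence used only for ranking —
and its center is the unweighted centroid of member voxel centers (a
probability-weighted centroid is available).  Pocket-forming residues are
those with any heavy atom within 4.5 Å of a member voxel center.  Closely
spaced pockets can merge into one component; splitting merged components at
local probability maxima is out of scope.

Evaluation follows the top-n protocol: per structure, only the n
highest-scoring segments are kept (n = number of reference pockets); each
is matched to the reference pocket with the smallest center distance (DCC).
Matching is non-exclusive by default — two predictions may chase one
reference — because the protocol does not define an assignment problem; an
exclusive Hungarian assignment is available for sensitivity analysis.  A
reference pocket with no prediction receives the worst possible values:
DVO = 0 and DCC = span·√3, the lattice space diagonal (121.24 Å for the
default grid).  Success at threshold T is the fraction of matches with
DCC strictly below T ("below 4 Å" counts 4.0 as a failure); DVO is
voxel-lattice intersection-over-union (defined 0 when both masks are
empty); detection F1 is the harmonic mean of precision (true positives
over retained predictions) and recall (over reference pockets) with
DCC < 4 Å defining a true positive.  The precision denominator counts the
retained top-n predictions; counting all raw components instead would only
lower precision and is the documented alternative.

## Synthetic fixtures

Desk-scale fixtures emulate the geometry of the real data only: a
"protein" of 400 atoms rejection-sampled uniformly in an 18 Å ball, with a
spherical cavity of radius 5 Å whose center sits 13 Å from the origin
(surface-adjacent), atoms excluded from the cavity; the reference pocket is
the 2 Å-lattice point cloud filling the cavity sphere — the same point-
cloud representation real cavity references use.  Elements are drawn from a
C-dominated palette that exercises every element class across seeds;
charges are N(0, 0.2).  Everything is deterministic given the seed.  These
fixtures have no secondary structure, no chemistry beyond the feature
rules, and cavities are ideal spheres — passing the learning probe shows
the pipeline (featurization → optimization → extraction) can recover a
geometrically encoded cavity signal, not that the model attains
literature-level accuracy on real proteins, which requires the full
training corpus and full-scale optimization.

## Desk-scale problem sizes

The shipped tests use reduced problem sizes chosen once as the package's
desk-scale conditions: the learning probe trains a narrow variant of the
architecture (encoder 4–8–16–32, bottleneck 64 — same depth, schedules and
objective) on five fixtures for 500 steps at learning rate 1e-4, batch 5,
without augmentation.  An overfit probe measures memorization capacity, so
augmentation is disabled there; with the 24-rotation augmentation enabled
the same configuration learns the task but needs several-fold more steps.
Under these conditions training Dice exceeds 0.95 and all five planted
cavities are relocated to within 4 Å (typically < 0.2 Å).  Full-scale
defaults remain available via configuration.

## Known limitations

- Geometric feature perception approximates chemistry; aromaticity and
  hybridization on unusual chemotypes will differ from toolkit perception.
- Training at the full published scale is impractical on CPU; the package
  trains desk-scale models and loads checkpoints for inference.
- Pockets merged by connected-component extraction are reported as one.
- cmap output is a minimal HDF5 layout (dataset plus origin/step
  attributes), not a byte-compatible Chimera map.
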