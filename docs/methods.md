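# Methods

`cryoss` annotates protein secondary structure — α-helix, β-sheet, coil
("Others") — for every voxel of a cryo-EM density map, using a 3D nested
U-Net voxel classifier. This note documents the model, the data pipeline,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## The classification task

A cryo-EM map is a scalar density field on a regular voxel grid. At
intermediate resolution (5–10 Å) individual atoms are invisible, but
secondary-structure elements have characteristic density shapes: helices
appear as solid rods ~5 Å across, sheets as thin slabs, coil as irregular
tubes. The classifier maps a density chunk to per-voxel class probabilities
(helix, sheet, other), from which whole-map annotations are stitched.

Ground truth comes from an atomic model aligned to the map. Each voxel
takes the secondary-structure class of the residue owning the nearest
backbone atom (N, Cα, C) within 3.0 Å (inclusive); voxels with no backbone
atom in range are *Unassigned* and are excluded from the training loss.
Per-residue classes come either from external STRIDE/DSSP-style code files
(H/G/I → helix; B/b/E → sheet; everything else → other) or from the
built-in dihedral-window assigner (below).

## Network

The model is a nested U-Net (UNet++-style): a grid of convolution-block
nodes X(i, j) with pyramid level i (0 = full resolution) and skip-pathway
position j, for 0 ≤ i + j ≤ L. Encoder nodes X(i, 0) follow 2× max pooling
of X(i−1, 0); every nested node X(i, j) consumes the channel concatenation
of all shallower same-level nodes X(i, 0..j−1) with the 2× trilinearly
upsampled X(i+1, j−1). These dense skip pathways are what distinguish the
nested variant from a plain U-Net. Each block is (3×3×3 convolution →
batch normalization → ReLU) applied twice, with mid-channels equal to
out-channels; convolutions use same-padding so spatial size is preserved.
The decoder outputs X(0, 1..L) are concatenated and a 1×1×1 convolution
produces three logits per voxel; softmax yields the class distribution.
Optional deep-supervision heads (one 1×1×1 convolution per X(0, j), losses
averaged with the main head) exist but are off by default — the
concatenated single head is the reference configuration.

Defaults: depth L = 4 with channels (16, 32, 64, 128, 256), a conventional
doubling schedule; the desk-scale benchmark uses depth 2 with channels
(8, 16, 32). The network is fully convolutional: any input with spatial
dims divisible by 2^L produces an equally-sized output. Upsampling is
non-learned trilinear interpolation (half-pixel-center convention),
implemented as per-axis interpolation matrices so the backward pass is the
exact transpose.

### The numpy engine

The layers (dense 3D convolution, batch norm, ReLU, 2× max pool, 2×
trilinear upsampling) and Adam are implemented directly in numpy with
hand-derived backward passes (`cryoss.nn`). Convolution is decomposed over
the k³ kernel offsets into stacked BLAS matmuls against shifted input
slices, processed one sample at a time so the working set stays
cache-resident; the gradient-input path is computed as a full convolution
of the output gradient with the flipped kernel rather than a scatter-add.
The whole engine is validated against finite differences (exact to ~1e-9
in float64) in the test suite. It is a compact CPU engine for desk-scale
models, not a general autograd.

## Data pipeline

**Grid unification.** Maps are resampled to 1.0 Å isotropic spacing by
trilinear interpolation; the deposited world frame (origin) is preserved,
and points outside the input support interpolate to 0 (background treated
as empty). On read, MRC axis permutations (MAPC/MAPR/MAPS) are normalized
to x-fastest order; the ORIGIN header record is preferred, with
nstart × spacing as the fallback when ORIGIN is zero.

**Boxing.** Maps (and their label maps) are tiled into 60³ boxes at stride
30. Axes not congruent to the stride get a final flush start at dim − 60 so
the far face is always covered; maps smaller than a box are padded (density
with zeros, labels with Unassigned, which carries no loss). Density in each
box is clipped at 0 and divided by the box maximum, mapping to [0, 1]; an
all-nonpositive box becomes all zeros. Boxes that are ≥ 95 % Unassigned are
excluded from training (a box at exactly 95 % is excluded).

**Augmentation.** One training chunk per box per epoch: one of the 24
proper rotations of the cube (the full orientation-preserving octahedral
group, read broadly from "random 90° rotations"), applied identically to
density and labels, followed by a uniformly random 40³ crop (corner offsets
in {0..20}³).

## Training protocol

Weighted cross-entropy with class weights (0.25, 0.5, 0.25) for (helix,
sheet, other) — approximately inverse class abundance — normalized as a
weighted mean over contributing (non-Unassigned) voxels, so the loss scale
is independent of chunk occupancy and invariant to rescaling the weights.
Adam, initial learning rate 1e-3, no weight decay. Training maps (not
boxes) are split 90/10 into train/validation; validation uses center crops
without augmentation. The learning rate halves when the mean training loss
has not strictly improved for 4 consecutive epochs (the first epoch, which
has no predecessor, counts toward patience; the counter resets on halving),
and training stops once a halving takes the rate below 1e-5 — with the 0.5
factor the rate never equals 1e-5 exactly, so the threshold reading is the
only executable one. The parameters of the minimum-validation-loss epoch
are returned. Full-scale batch size is 180 boxes; desk-scale runs use 8.

**Batch-norm recalibration.** With very few optimizer steps per epoch, the
exponential running averages that batch norm uses at eval time lag the
rapidly-changing weights so far that eval-mode losses become meaningless
(we observed eval-mode loss 3.9 versus 0.5 train-mode on the *same* data).
After each epoch the running statistics are therefore recomputed as the
exact average of batch statistics over a fixed sample of up to 16 training
chunks ("precise BN"). This affects only the statistics buffers, never the
learned parameters, and is a no-op in the large-batch regime where the
running averages are already converged.

## Inference

The map (already at 1.0 Å) is zero-padded by 15 voxels on every face,
tiled into 60³ boxes at stride 30 (flush rule), and each box is normalized,
center-cropped to the 40³ network input, and classified. Only the central
30³ cube of each output is kept. The padding exists because the crop
geometry otherwise leaves a 15-voxel border uncovered: with it, the center
cubes tile the original extent starting at voxel 0. Where flush boxes
overlap previously covered territory, they write only the not-yet-covered
remainder, so every voxel is written exactly once (audited in tests).
Class per voxel is the argmax over the three channels; ties break to the
lowest channel index (helix over sheet over other). Background can be
masked by a density threshold; the mask keeps voxels *strictly above* the
threshold.

## Evaluation

**Voxel level.** Ground truth for scoring uses the nearest *Cα* within
3.0 Å (not the full backbone). Truth-Unassigned voxels and voxels at or
below the density threshold are excluded from all counts. Per-class
precision, recall and F1 are computed from the confusion matrix; an empty
denominator scores 0 and sets an `undefined` flag. The headline "overall"
voxel F1 is the macro (unweighted) mean of the three class F1 scores;
since aggregates can be defined either way, the micro score (plain
accuracy over evaluated voxels) is reported alongside.

**Residue level (Q3).** A residue is excluded when it lacks a Cα or when
any voxel center within 1.0 Å of its Cα has density below the threshold.
An evaluated residue is correct when a strict majority (> half; ties
incorrect) of the voxel centers within 3.0 Å of its Cα carry its true
class in the prediction; a residue with no voxels in range counts as
incorrect. Q3 is correct/evaluated, overall and per class.

## Dataset curation

Two computations support training-set curation of deposited maps:
map–model agreement as the Pearson correlation between a deposited map and
the map simulated from its model on the same grid (0.65 is the customary
acceptance threshold; the correlation is an error on constant grids), and
redundancy removal by greedy clustering of a boolean similarity matrix:
repeatedly take the item similar to the most remaining items (ties to the
lowest identifier), cluster it with everything still similar to it, and
remove the cluster. Computing sequence identities is delegated to external
alignment tools; the similarity matrix is an input (CSV edge list).

## Density simulation

Simulated maps place an isotropic Gaussian on every atom with
FWHM = nominal resolution R, i.e. σ = R / (2√(2 ln 2)), amplitude equal to
the atomic number (or 1 in uniform mode), truncated at 5σ. This is a
standard convention chosen for its qualitative fidelity — helices and
sheets are resolvable at 6 Å and progressively merge toward 10 Å — and no
equivalence with any specific simulation program is claimed. No B-factors,
solvent, or noise.

## Synthetic structures

The generators build poly-alanine backbones (N, CA, C, O, CB) from ideal
internal coordinates by natural-extension-of-reference-frame chaining, so
helix parameters (≈1.56 Å rise, ≈100° twist, ≈2.25 Å Cα radius from
φ, ψ = −57°, −47°) and strand geometry (≈3.3–3.5 Å rise from −139°, 135°)
emerge from the dihedrals. Sheets are antiparallel with 4.8 Å inter-strand
spacing; coils use jittered polyproline-II-like dihedrals. The toy-domain
generator packs a random mix (first three elements always helix, sheet,
coil, so all classes are present) into a bounded cube with ≥ 3.0 Å between
elements, by rejection sampling of random rigid poses.

The built-in dihedral-window assigner (helix: φ ∈ [−100°, −30°],
ψ ∈ [−80°, −5°] for a residue and both neighbours; sheet: φ ∈ [−180°, −90°],
ψ ∈ [90°, 180°] in a run of ≥ 2; otherwise Others; termini Others) is a
deliberately simple, deterministic stand-in for hydrogen-bond-based
assignment programs. It is exact on the ideal geometry the generators
produce; on real structures it is cruder than STRIDE/DSSP, which is why an
ingestion path for external code files exists.

## The desk-scale benchmark

`cryoss.benchmark.run_benchmark` exercises the pipeline end to end at a
size one CPU finishes in minutes: 16 training and 4 held-out toy domains
of 20 elements in a 50 Å cube (chosen to mimic the packing density of a
globular domain — sparser layouts leave every box above the 95 %-Unassigned
exclusion and nothing to train on), simulated at 6.0 Å; a depth-2
(8, 16, 32) model trained for 12 epochs with batches of 8 boxes; held-out
structures scored at 6 Å and again at 10 Å. Problem sizes were fixed once,
from packing-density and runtime considerations.

What passing shows: every stage is wired correctly, the network learns
genuine shape features (residue Q3 ≈ 0.9+ on held-out structures with
per-class voxel F1 well above chance), and accuracy degrades when the same
structures are simulated at 10 Å — the qualitative resolution trend.
What it does not show: performance on experimental maps. Toy maps are
noiseless, have no B-factor variation, no partial occupancy, no
misfit between model and map, no solvent, and idealized geometry; absolute
scores here are far above what any method achieves on real data and are
not comparable to published benchmarks.

## Numerical choices and edge cases

- Distances to voxel *centers*; the labeling cutoff is inclusive (≤ 3.0 Å).
- Nearest-atom ties resolve to the lowest (chain, residue, file-order)
  atom, exactly as a brute-force scan with `argmin` would.
- Threshold masks are strict (> threshold survives); residue exclusion is
  strict below (< threshold excludes).
- Argmax ties at inference break to the lowest channel index.
- An all-Unassigned chunk contributes zero loss and zero gradient.
- Zero-variance grids make cross-correlation an error, not a NaN.
- `split_train_val` rounds half-up and keeps at least one validation map.
- Checkpoints embed the architecture config and a format-version string;
  batch-norm statistics buffers are saved alongside parameters.

## Known limitations

- The per-level channel counts of the reference architecture are not
  recoverable from text, so the doubling schedule is a configurable
  convention, not a claim of equivalence.
- The numpy engine is single-threaded and CPU-bound; full-scale training
  (hundreds of maps, batch 180) is out of reach here by design.
- The dihedral-window assigner ignores hydrogen bonds; isolated β-bridges
  and π-helices are classified by their dihedrals only.
- mmCIF models, nucleic acids, half-maps, and map sharpening are out of
  scope.
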