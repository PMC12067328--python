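# Methods

## Scope and model

The package implements an end-to-end workflow for suppressing air-bubble
phase-contrast artifacts in 3D micro-CT volumes of FFPE lung tissue:
synthetic training-pair construction by artifact transplantation, a 3D
pix2pix conditional GAN, checkpoint selection by RE/PSNR/SSIM, tiled
whole-volume inference, and watershed pore morphometrics. All data carriers
are 8-bit volumes in `(z, y, x)` axis order (z = slice axis) with an
isotropic voxel size in µm; floating-point inputs are windowed to 8-bit
once, at ingest (`to_uint8`, rounding half away from zero, constant volumes
mapping to 0).

The GAN is the standard conditional image-to-image objective

    G* = arg min_G max_D L_cGAN(G, D) + λ E‖y − G(x)‖₁

with λ = 100. The discriminator loss is halved (½[BCE(real→1) +
BCE(fake→0)]), following the original pix2pix convention; the combined
generator loss is BCE(fake→1) + λ·mean|G(x) − y|. Optimisation is
alternating single-sample updates with Adam(lr 2·10⁻⁴, β₁ = 0, β₂ = 0.999).
β₁ = 0 is deliberate and exposed in `TrainConfig`; the upstream pix2pix
implementation uses β₁ = 0.5, and users who want that behaviour can set it.

## Architecture conventions

* **Depth rule.** `len(encoder_filters) == log2(cube_edge)` so the encoder
  bottleneck is exactly 1 voxel; the decoder mirrors the encoder minus the
  bottleneck. At edge 256 with default filters this reproduces
  C64–C128–C256–C512×5 / T512×4–T256–T128–T64.
* **Padding.** TensorFlow-style "same" padding everywhere: stride-2 layers
  map extent n → ⌈n/2⌉, stride-1 layers preserve the extent. This is what
  makes the printed shape bookkeeping work (256 → 1 through 8 stride-2
  blocks; a 70³ input maps 70 → 35 → 18 → 9 through three stride-2 layers).
* **Receptive field.** Computed by the recurrence rf += (k−1)·jump,
  jump ×= stride over the layer stack including the 1-filter scoring
  convolution. The default PatchGAN (k = 4; strides 2,2,2,1 plus the
  stride-1 scoring conv) gives 70 voxels per axis and a score map of
  edge/8. A quoted "final receptive field of 16³" for this stack is not
  reproducible from the layer arithmetic; the package reports the computed
  sizes.
* **Normalisation.** Intensities enter the network as (I/127.5 − 1) ∈
  [−1, 1] to match the tanh head and are mapped back by the exact inverse
  (round half away from zero, clip); the round trip is the identity on
  8-bit data.
* **Batch normalisation with batch 1** normalises each channel over the
  spatial axes and keeps running averages (momentum 0.1) for inference.
  Note two consequences: (a) at a 1³ spatial map, training-mode batchnorm
  is degenerate (zero variance kills signal and gradient) — the
  architecture avoids norm layers at the bottleneck for exactly this
  reason, and discriminator inputs should be ≥ 16 voxels per axis;
  (b) training-mode statistics couple all voxels, so receptive-field
  probes must run in eval mode.
* **Inference is deterministic**: dropout off, batchnorm on running stats.
  The upstream pix2pix keeps dropout on at test time as a noise source; the
  evaluation protocol here compares fixed generated/ground-truth pairs,
  which presumes deterministic outputs. The choice is switchable
  (`training=True` on the network's forward).
* **Initialisation**: weights ~ N(0, 0.02), batchnorm gain ~ N(1, 0.02)
  (pix2pix convention).

## NumPy backend

No deep-learning framework is used: the networks run on a small explicit
forward/backward module system (`airgap3d.nn`) with im2col-based 3D
convolution and transposed convolution (the exact linear adjoint of the
equivalent strided convolution, sharing one code path), batchnorm, inverted
dropout, the usual activations and Adam. Every backward pass is verified
against central finite differences in the test suite (float64, tolerance
1e-6). Compute is BLAS matmuls, so desk-scale cubes (edge 16–32) train in
seconds to minutes on one CPU; full 256³ training is the same code but is a
GPU-scale workload and out of the desk-test envelope.

## Training-pair factory

The air-artifact mask recipe is: two-sided threshold (I ≤ `low_thr` = 10 or
I ≥ `high_thr` = 245, bracketing the saturated bins with noise tolerance) →
opening with a discrete ball (radius 1) → removal of connected components
below `min_component_vox` = 50 (replacing the human judgement of a manual
artifact/no-artifact sort) → dilation with a ball of radius 2 to capture the
bright rims. The cube-level artifact classifier reuses the same thresholds:
a cube is flagged when the cleaned saturated-voxel fraction reaches
`min_extreme_fraction` = 0.001. Whether void and rim should be thresholded
jointly or separately is ambiguous at the source; the package merges the two
threshold passes into one binary image before morphology.

Donor/recipient pairing samples the (artifact × clean) product in a seeded
shuffled order, so provenance stays distinct up to the product size. The
transplant inherits a known limitation: the anatomical region being replaced
is not the one that originally contained the air, which bounds how well the
generator can learn true tissue continuation.

## Checkpoint metrics

* RE = Σ|I_gen − I_real| / Σ I_real per pair, averaged over pairs. The sum
  is taken over all voxels before normalising (the alternative — voxel-wise
  normalisation then averaging — diverges at dark voxels and is not used).
* PSNR = 10·log₁₀(255²/MSE); identical pairs report the +∞ sentinel
  (serialised as "inf").
* SSIM is the global single-window form over the whole pair
  [(2μ_gμ_r + c₁)(2σ_gr + c₂)] / [(μ_g² + μ_r² + c₁)(σ_g² + σ_r² + c₂)]
  with c₁ = (0.01·255)², c₂ = (0.03·255)²; a sliding-window mean is
  deliberately not the default because the selection formula is defined per
  volume pair.
* Selection: best average rank across (RE ↑, PSNR ↓, SSIM ↓), ties broken
  toward the later epoch; an RE-only rule is selectable.

## Phantoms

Clean phantoms: seeded white noise smoothed with a Gaussian kernel of width
`pore_correlation_length_vox` (default 3), thresholded at the empirical
quantile giving `target_porosity` (default 0.45), pore phase set to the
paraffin gray level (90), tissue to 180, plus N(0, 6²) noise and a 0.8-voxel
blur, clipped to [5, 250] so clean volumes never touch the saturated bins.
Artifacts: spheres (radius 3–6 voxels by default) with a smooth random
quadratic radial perturbation (`shape_irregularity`, 0 = exact sphere, so
geometry stays analytically checkable), interior forced to 0 and an
isotropic Euclidean-distance rim band (2 voxels) forced to 255. Phantom and
artifact seeds are independent so one tissue realisation can carry different
artifact realisations.

What the phantom does *not* emulate: Fresnel/TIE edge physics (the rim is a
uniform band, not a fringe profile), beam hardening, detector noise,
anisotropic alveolar anatomy, and the long-range airway tree. Passing tests
therefore demonstrate that the pipeline machinery is correct and that the
GAN can learn this class of inpainting task at desk scale — not that the
learned generator transfers to real scans.

## Desk-scale training configuration

The smoke-scale study conditions used by the test suite: 16 training pairs
and 4 held-out pairs of edge-16 phantom cubes (one bubble of radius 2–3,
rim 2 per cube), 30 epochs, batch 1, λ = 100, Adam(2·10⁻⁴, 0, 0.999),
checkpoints every 10 epochs plus the untrained epoch-0 model, fixed seed.
Filter widths at this scale are 32-64-64-64 for both networks — wide enough
to learn the task, small enough that the full run takes about half a minute
on one CPU. Under these conditions the held-out RE of the final checkpoint
drops below the RE of the artifact-bearing source, and the rank-sum
selection prefers the final checkpoint over epoch 0.

## Pore analysis

Pore phase: I ≤ `pore_threshold` (paraffin-filled airways are darker than
tissue; default 128, and the paraffin mode of the histogram is a better
choice when known) → closing (ball, radius 1; the volume is edge-padded
first so the closing is border-neutral) → fill-holes. Markers: local maxima
of the Euclidean distance transform separated by ≥ `min_distance_vox`
(default 3; set it to the expected pore radius) → watershed of the negated
distance transform restricted to the mask, face (6-neighbour) connectivity
by default. Labels partition the mask exactly; when `min_pore_vox` > 0 the
voxels of removed small pores are removed from the stored mask as well, so
the partition identity survives.

Per-pore extent = volume / bounding-box volume; solidity = volume /
convex-hull volume, with the hull computed on voxel coordinates and
re-voxelised so the ratio is a voxel count over a voxel count. Regions too
thin for a 3D hull are dilated by one voxel for the hull computation and
flagged in the record. Discretisation note: a voxelised ball of integer
radius r has bounding box (2r+1)³ and extent ≈ 0.45, not π/6; the continuum
ratios apply to odd-diameter balls (radius r + ½), which the tests use.

The fixed-value masking baseline replaces artifact voxels with a constant
(defaulting to the estimated paraffin mode); the three-way comparison
reports porosity, mean pore volume, mean extent and mean solidity per ROI
for original / masked / generator-suppressed variants, with the suppressed
variant as reference since no physical ground truth exists.

## Whole-volume inference

Non-overlapping tiles at the generator's cube edge; per-tile artifact
detection reuses the pair-factory classifier with the same parameters, so
training-time and inference-time detection agree. Artifact-free tiles are
copied bit-exactly (clean volumes are fixed points of the whole operation).
Remainders: `crop` (default) processes only full tiles and records the
untouched margins; `pad_reflect` mirror-pads to the next multiple and trims
afterwards. Tiles are not blended — seam artifacts at tile faces are
accepted and documented rather than averaged away.

## Known limitations

* Training at the full 256³ scale on CPU is impractical; the package keeps
  the architecture generic and the tests desk-scale.
* The GAN objective with batch-1 batchnorm is noisy; convergence is not
  guaranteed and checkpoint selection, not loss convergence, picks the
  model.
* Transplanted training pairs mismatch the underlying anatomy (above).
* The phantom omits phase-contrast physics; quantitative transfer to real
  scans is untested by design.
* Streaming/out-of-core volumes, anisotropic voxels, DICOM and 16-bit
  processing paths are out of scope.
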