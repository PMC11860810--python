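# Methods

## Model and procedure

`thinslice` studies how CT slice thickness distorts automated pulmonary
nodule categorization, and whether a learned slice-generation network
repairs it. The pipeline has four stages.

**Degradation.** Thick-slice CT is simulated from thin-slice CT by
averaging every `r` consecutive slices (default `r = 4`; 1.0 mm → 4.0 mm,
300 slices → 75). Trailing `z mod r` slices are dropped so every thick
slice is an equal-weight mean of exactly `r` thin slices. This fixes the
geometric alignment used everywhere: thick slice `k` sits at thin
coordinate `k·r + (r−1)/2`. Averaging runs in floating-point HU with no
re-quantization so training pairs carry no double rounding.

**Generator.** A 3D residual-in-residual dense network in the ESRGAN
lineage: a first convolution lifts the single HU channel to 64 features;
23 ResBlocks follow, each containing two small blocks of five kernel-3,
stride-1, padding-1 convolutions with dense connections (the input of
convolution *i* is the block input concatenated with the outputs of
convolutions 1..*i−1*, each 32 growth channels wide) and leaky-ReLU
(slope 0.2) after the first four. Local (small-block) and block-level
residuals are scaled by β = 0.2; a global residual links the first
ResBlock's input to the last one's output. A convolution expands channels
by `r`, VoxelShuffle-SG permutes channels into depth — channel-major, so
`out[b,c,h,w,d·r+k] = in[b,c·r+k,h,w,d]` — and two convolutions emit the
output. An optional trilinear depth-upsampling skip from input to output
(default on) makes the network a residual corrector on top of linear
interpolation; at initialization (Kaiming weights scaled by 0.1) the
output is then already a sensible interpolant, which is what makes very
short training runs meaningful.

Volumes are processed as 16-slice z-segments (the deepest chunk the
network consumes), overlapping by 2 thick slices; segment outputs are
blended with a linear cross-fade over the overlap and edge-replication
padding of the last segment is cropped after stitching. Reformatting to
coronal/sagittal planes is available as an explicit axis permutation, but
super-resolution always acts on the stored slice axis: relabeling the
viewing plane must not change the math.

**Discriminator and losses.** The discriminator stacks eight conv/LReLU
pairs (channels 64,64,128,128,256,256,512,512; stride alternating 1,2),
a dense layer of width 1024, LReLU and a final dense + sigmoid; real thin
slices score 1, generated ones 0. The generator trains against a weighted
sum of (i) voxel MSE over the super-resolved grid, (ii) a slice-wise
perceptual loss — volumes are split into 2D slices along the depth axis,
each slice's feature distance under a VGG16-topology extractor φ_{i,j}
(features after conv *j* of stage *i*, default (3,3)) is normalized by the
feature-map size, and the result is averaged over slices — and (iii) the
adversarial loss `Σ −log D(G(I^LR))`. The bundled extractor carries
fixed-seed random weights so no pretrained download is needed; random
convolutional features still embed local image structure, but their scale
is not comparable to a pretrained classifier's, which matters for the
loss weighting below.

**Nodule evaluation.** Volumetry is voxel counting on masks times voxel
volume. Type is called from the HU histogram inside the nodule: with
`s` = fraction of voxels ≥ −300 HU, a nodule is ground-glass if
`s < 0.1`, solid if `s ≥ 0.9`, part-solid between. Categories come from a
versioned Lung-RADS v2022 volume-threshold table shipped as YAML
(solid: 113/268/1767 mm³ on total volume; part-solid: category 2 below a
113 mm³ total-volume gate, then 113/268 mm³ on the solid component;
non-solid: 3351 mm³), with closed-open intervals so a volume equal to a
cutpoint takes the higher category. The 80–350 mm³ size filter is closed
on both ends. Since nodule detection/segmentation networks are out of
scope, condition-specific masks come from a fixed-threshold connected-
component segmentation (nodule tissue ≥ −750 HU, solid core ≥ −300 HU)
inside a spherical search region around the known nodule centre.

## Synthetic phantoms

Each phantom is a soft-tissue block (40 HU) with two ellipsoidal lung
fields (−850 HU), a few vessel-like tubes (40 HU) drifting roughly along
z, and spherical nodules: solid (−50 HU), ground-glass (−650 HU), or
part-solid (ground-glass shell, solid core with 30–70% core volume
fraction). Sphere radii give exact analytic volumes, the ground truth for
volumetry. Additive Gaussian noise (sd 20 HU) is the only corruption.
HU levels are placed so the −300 HU type threshold and −750 HU
segmentation threshold sit far from every tissue mode relative to the
noise; results are insensitive to threshold shifts of ±100 HU.

Nodules are rasterized with **partial-volume coverage**: each voxel's HU
is the volume-weighted average of the tissues inside it (supersampled
3× per axis at the boundary), because a CT voxel is a volume average —
the very physics the slice-thickness problem comes from. This matters
downstream: with binary edges the thin-slice reference would carry step
profiles that no continuous reconstruction can match, and histogram
typing would behave differently on the reference than on any generated
volume. Under partial volume, a small pure-solid nodule's threshold mask
contains a faint boundary shell, so the −750/−300 histogram rule types it
sub-solid consistently in *every* condition — the agreement study
measures condition-relative consistency against the thin reference, not
agreement with the analytic label.

What the phantoms emulate: the partial-volume mechanics of slice
averaging on small spherical targets, the HU contrast structure that
drives histogram typing, and cohort composition (stratified solid /
part-solid / ground-glass mixes, volumes uniform in 80–350 mm³; a
40-series/55-nodule-shaped cohort is one call). What they do not emulate:
real lung anatomy (airways, fissures, pleural attachment), scanner noise
spectra and reconstruction kernels, irregular nodule shapes, or detection
errors — the study consumes known nodule locations. Passing tests
therefore demonstrate the pipeline's internal correctness and the
direction of the slice-thickness effect, not clinical performance.

## Desk-scale training

The package trains end to end on one CPU using a numpy autodiff engine
(`thinslice.nn`): 3D convolution as one GEMM per kernel tap, reverse-mode
graphs, Adam, global-norm gradient clipping. Default desk problem sizes,
chosen so a full run finishes in minutes: a generator with 2 ResBlocks,
16 base channels, 8 growth channels (identical topology to the full
23-block network, which is also constructed and exercised in the tests);
LR patches 16×16×8 with batch 4; 200 iterations; four 32×32×64-voxel
training phantoms.

Training hyperparameters at this scale: Adam, learning rate 3·10⁻³ for
the generator; the first half of the run is an MSE-only warm-up, after
which the discriminator (8 base channels, dense width 128, learning rate
3·10⁻⁴) and the perceptual/adversarial terms switch on with weights
(λ_mse, λ_perc, λ_adv) = (1.0, 0.1, 10⁻⁵). Two of these choices deserve
explanation. First, the MSE-dominant weighting inverts the perceptual-
dominated weighting customary with pretrained VGG features because the
bundled random-weight extractor produces feature distances on an
arbitrary scale; the voxel term must anchor optimization or fidelity is
lost. Second, the adversarial weight is small and the discriminator slow
because at desk scale the discriminator separates real from generated
patches almost immediately; with a larger weight its unbounded logits
dominate the clipped generator gradient and fidelity collapses (observed
as a runaway MSE within ~50 adversarial iterations). Gradients of both
networks are clipped to global norm 1.0, and the loop raises on any
non-finite loss.

Stopping: the qualitative criterion "train until the loss saturates" is
approximated by the fixed iteration budget plus a validation-plateau flag
(no auto-stop) when a validation fraction is held out. ``train`` accepts
``resume_from`` for staged runs (a fresh optimizer continues from earlier
weights); a staged MSE-only refinement pushes held-out generation error
well below the 200-iteration level when more compute is available.

Inference offers an optional degradation-consistency projection (each
group of r output slices shifted by a constant so its mean reproduces the
thick input slice). The true thin volume satisfies this constraint, and
the projection lowers voxel error — but the constant-per-group shift
re-smears restored edges inside a group, which measurably worsens
threshold volumetry downstream; it is therefore off by default and useful
mainly when voxel fidelity, not volumetry, is the target.

## Numerical choices

- HU clip range [−1024, 3071]; network inputs scaled linearly to [0, 1]
  and outputs inverse-scaled and re-clipped.
- float32 throughout the networks; losses and metrics accumulate in
  float64.
- Spline depth-upsampling baselines (trilinear/tricubic) use the same
  slice-mean alignment as the network skip, with clamped edges.
- Cross-fade weights over a stitch overlap of n slices are
  (i+1)/(n+1) against (n−i)/(n+1), which sum to one, then normalized —
  constant inputs stitch to constants exactly.
- NIfTI spacing is rounded to 10⁻⁶ mm on read to absorb float32 header
  quantization; DICOM series must have uniform inter-slice spacing within
  10⁻³ mm, and rescale slope/intercept are applied per slice.
- Ties in the 2×2 max-pool backward go to the first maximal element.

## Design choices on genuinely open points

- **ResBlock "central" residual**: interpreted as one β-scaled residual
  around the two-small-block pair (the ESRGAN convention `x + β·f(x)`);
  alternatives (around each small block only, or between them) are less
  literal readings.
- **Channel→depth interleave order**: channel-major, mirroring the 2D
  pixel-shuffle convention; the brute-force index oracle in the tests is
  the normative definition.
- **Perceptual slice axis**: slices are taken along the tensor depth
  axis (the super-resolved axis), configurable in the numpy-facing loss.
- **Interpolation skip**: an addition to the bare layer stack (see
  above); disable with `GeneratorConfig(interp_skip=False)`.
- **Lung-RADS cutpoints** ship as data, not code constants, and every
  category test pins the `v2022-simplified` table version.

## Known limitations

- The desk-scale network cannot reach the fidelity of a full-scale run on
  tens of thousands of real CT images; held-out tests therefore check
  direction (trained beats untrained and tricubic interpolation; generated-
  thin categorization ≥ thick) rather than clinical accuracy figures.
- The GAN phase is kept deliberately weak; at larger scales the
  adversarial balance would need retuning (or an adaptive weighting).
- Only integer depth-axis scale factors; no 2D fallback; no DICOM
  writing; gantry-tilted or rotated geometries are rejected rather than
  resampled.
- Phantom realism limits are listed above; in particular, threshold
  segmentation would fail on juxta-vascular nodules in real data, which
  is why vessels are kept clear of nodules in the phantoms.
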