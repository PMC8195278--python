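# Methods

`neoharm` implements an unsupervised domain-adaptation pipeline for
harmonizing brain tissue segmentations across two MRI acquisition domains,
together with the synthetic two-cohort phantom and the regression-based
validation used to demonstrate that the harmonization works. This note
documents the models, the generator's assumptions, the numerical choices,
and what the desk-scale results do and do not show.

## The segmentation and adaptation models

Three models are trained, all operating on single-channel 3D volumes scaled
to [-1, 1]:

* **Baseline.** A 3D U-Net trained supervised on the labeled *source*
  domain only, minimizing the generalized Dice loss

  L_seg = 1 − 2 · (Σ_l w_l Σ_n p_ln t_ln) / (Σ_l w_l Σ_n (p_ln + t_ln)),
  w_l = 1 / (Σ_n t_ln)²,

  over the 7 tissue classes (background, CSF, cortical GM, WM, deep GM,
  cerebellum, brainstem). Classes absent from a target map are excluded
  from both sums; their 1/0² weight is undefined, and exclusion keeps the
  loss in [0, 1]. Optimizer: Adam with default moments and a decaying
  cyclical learning rate (triangular wave between 2·10⁻⁶ and 2·10⁻³, the
  ceiling halving each cycle — "triangular2"; cycle length 10 epochs by
  default).

* **Latent-space adaptation.** The same segmenter plus a PatchGAN domain
  classifier. Both domains' volumes pass through the segmenter; each
  decoder level's feature map (bottleneck included) is trilinearly
  resampled to the second-deepest level's grid and channel-concatenated
  into the classifier input. Alternating updates: the classifier minimizes
  binary cross-entropy against domain labels (Adam β₁=0.5, β₂=0.999,
  linearly decaying LR from 2·10⁻³); the segmenter minimizes
  L_seg − α·L_adv, where α ramps linearly from 0 at epoch 20 to 0.05 at
  epoch 50 and stays there. Realizing the minimax via alternating updates
  rather than a gradient-reversal layer is an implementation choice with
  the same objective. Whether L_adv should read the classifier's loss on
  target batches only or on the mixed batch is ambiguous; the mixed batch
  is used. Target-domain labels are never read — the data loader wraps
  target subjects in a guard object whose label accessors raise.

* **Image-space adaptation.** A generator U-Net (Tanh head, single
  channel) translates source volumes into target-like volumes; an LSGAN
  PatchGAN discriminator judges real target vs synthesized volumes
  (L_D = E[(D(x)−b)²] + E[(D(G(x))−a)²], a=0 synthesized, b=1 real — the
  labels are conventions, configurable); the segmenter trains on both real
  source and synthesized volumes against the source labels. Generator and
  segmenter share one combined update of
  L_seg + E[(D(G(x))−b)²] + λ·(1 − NCC(x, G(x))), with λ=1 by default.
  The global normalized cross-correlation term anchors each synthesized
  volume to its source anatomy; its direction (minimize 1 − NCC) and
  weight are implementation choices.

Architecture (shared by segmenter, generator and the cortical parcellation
network): five encoder-decoder levels with 16/32/64/128/256 channels, 3³
stride-1 convolutions with instance normalization (no learned affine by
default) and LeakyReLU (slope 0.01), a 2³ *average* pool after the first
encoder block and 2³ max pools below, 3³ transposed convolutions upward,
and a 3³ output convolution with a softmax (segmentation) or Tanh
(translation) head. The discriminator uses five 4³ stride-2 blocks with
64/128/256/512/1 channels; on grids too small for five halvings the block
count reduces to the largest B with 2^B ≤ min dimension, truncating the
channel progression. A `width_multiplier` shrinks channel counts for CPU
work. Weight init is Kaiming-style and seedable; identical specs and seeds
give identical networks.

All of this runs on a small reverse-mode autograd backend written on numpy
(`neoharm.nn`): im2col/GEMM and per-pair-correlation convolutions, scatter
adjoints for strided and transposed convolutions, and the usual pointwise
ops. Every operator's gradient is verified against central finite
differences in the test suite, and the convolution fast paths are checked
against the generic route. Backward passes release graph closures as nodes
retire so 3D activation graphs do not outlive their step.

## The phantom

Real neonatal cohorts of the kind this pipeline targets are
access-controlled, so validation runs on a synthetic phantom that encodes
the *statistical* structure the analyses assume — not realistic cortical
geometry (no folding; thickness validity matters here, gyrification does
not).

**Anatomy.** Nested shells around an outer brain ellipsoid: a CSF rim
(2.5 mm), a cortical ribbon whose metric width realizes the thickness law

T = T₀ + β_pma·(PMA − 41.3) + β_ga·(GA − 30.5) + β_int·(PMA−41.3)(GA−30.5) + ε,

with T₀ = 1.73 mm, β_pma = 0.04 mm/week, β_ga = 0.06 mm/week,
β_int = −0.001, ε ~ N(0, σ_T²), and a WM core containing a deep-GM
ellipsoid, a cerebellum sphere and a brainstem cylinder. The ribbon is
bounded by two inward *offset surfaces* of the outer ellipsoid, computed
from the exact point-to-ellipsoid distance (Newton iteration on the
foot-point multiplier near the surface), so the realized ribbon width
equals the drawn T everywhere up to voxelization. σ_T is set to 0.087 mm:
together with the matched-cohort age spreads (GA SD 1.2 w, PMA SD 1.0 w)
acting through the β's, the *total* matched-subset thickness SD comes out
at the 0.12 mm the calibration targets; treating 0.12 as purely irreducible
noise would double-count the age-driven variance. Brain semi-axes grow
0.3 mm per PMA week and carry 0.5 mm per-subject jitter; together with a
sub-voxel center jitter this dithers voxel quantization so cohort-mean
measurements stay unbiased on coarse grids.

**Cohorts.** The *source* cohort's gestational ages follow a
term-dominated mixture (80% N(39.6, 1.4), 20% U(28, 37) weeks); the
*target* cohort is preterm-only (U(24, 33)); both scan near
term-equivalent age. Matched subsets draw GA ~ N(30.5, 1.2) and
PMA ~ N(41.3, 1.0) in *both* cohorts, so matched anatomy differs only by
sampling noise. Outcome scores (a language-composite analogue) are drawn
N(96.4, 14.9) in the source and N(91.3, 17.4) in the target cohort, with
**no dependence on thickness** — the cohort-level offset is the ingredient
that lets un-harmonized pooling manufacture a spurious association.

**Rendering.** Per-class mean intensities, a smooth multiplicative bias
field, Gaussian smoothing, additive noise, and a fixed affine map to
[-1, 1] (no per-image rescaling, so intensity windows are stable).
Boundaries are rendered with sub-voxel partial volume via logistic
transitions in the signed-distance field. The intensity ordering is
monotone along the spatial nesting (WM > cGM > CSF > background, a
T1-like ordering): blurred transitions between spatially adjacent classes
then cross only those two classes' intensity windows, which makes the
window-based reference segmenter well-posed and puts detected interfaces
at blurred-profile midpoints, i.e. at the rendered geometry. With the
anatomically realistic T2-like ordering (cGM darker than WM) the CSF→cGM
transition sweeps through the WM window and produces spurious shells —
an instructive failure, but not the mechanism under study.

**The domain gap.** The target domain differs by per-class contrast shifts
(±0.02–0.05 on the [0, 1] scale, chosen symmetric about the source-window
boundaries so window-based detection is not shifted by contrast alone),
stronger smoothing (1.6 vs 1.1 mm FWHM), a stronger bias field, more
noise — and the key confound: the *rendered* cGM/CSF interface is pushed
outward by `domain_boundary_offset_mm` = 0.2 mm. Ground-truth labels are
never modified by rendering. Intensity-based segmentation of target
renderings therefore overestimates mean cortical thickness by ≈0.2 mm,
which is the pre-harmonization cohort effect the pipeline must remove.

**Grids.** Default calibration: 64³ voxels at 0.75 mm. At 1.0 mm the
1.73 mm ribbon is under two voxels wide and the thickness estimate biases
upward by ~9%; at 0.75 mm per-subject recovery is within ~5%. Network
experiments run at 48³ / 0.9 mm with proportionally smaller anatomy
(problem sizes chosen as the package's own desk scale). An analytic fast
path (`sample_truth_table`) draws per-subject true thickness and ellipsoid
volumes from the same generative law without rasterizing, for simulations
where only the measurement table matters (type-I calibration, the outcome
demonstration).

## Measurements

**Reference segmentation** (`naive_segment`): hierarchical intensity
windows. Stage 1 assigns each voxel the nearest of the four shell-class
references (background, CSF, cGM, WM, taken from the *source* rendering
means regardless of the image's domain); each shell class keeps its
largest 26-connected component and orphans take the nearest surviving
label. Stage 2 classifies deep structures within the WM region eroded by
~1.5 mm (interface partial-volume voxels sweep through the deep windows
and must not vote), again keeping one component per structure. The
classifier is deliberately domain-agnostic so it *inherits* the rendered
acquisition bias — that is what makes it the pre-harmonization reference.

**Cortical thickness**: a voxel-based Laplace-equation method. The
potential is solved by Jacobi iteration on the cGM ribbon with Dirichlet
values imposed at the voxel *faces* (ghost values 2·bc − φ), 0 on the
WM/deep side and 1 on the CSF/background side; per-voxel thickness is the
length of the field line through the voxel, integrated both ways with RK
steps of 0.2 mm and the final partial step resolved by bisection on the
ribbon indicator. Face-based conditions remove the half-voxel bias of
center-based ones: a w-voxel slab measures exactly w·spacing. On analytic
spherical shells the error is ~1% at 4 voxels per ribbon and ~5–9% below
2 voxels (curvature plus voxel-mean weighting, biased upward). This is an
explicit stand-in for registration-based thickness (DiReCT), which is out
of scope; it preserves the analysis structure — one thickness scalar per
subject plus parcel means. Global means average over ribbon voxels (a
surface-weighted mean is the main alternative; the voxel mean slightly
overweights thick regions).

**Segmentation quality**: per-class Dice, precision, recall, and the
average symmetric surface distance (mean of the two directed mean
nearest-neighbour distances between 6-connectivity surface voxels,
center-to-center in mm). The maximum Hausdorff distance is computed too
but plays no role in acceptance. All four metrics are validated against a
brute-force all-pairs implementation on small masks.

## Statistical validation

All models are ordinary least squares (statsmodels) with cohort and sex as
0/1 indicators (source/F reference, so a positive cohort coefficient means
"larger in the target cohort"); significance is two-sided at 0.05 with no
multiple-testing correction (per-measure flags are reported side by side
instead). The harmonization criterion for a measurement condition is the
*non*-significance of the cohort term in
`measure ~ cohort + PMA + GA + sex` on matched cohorts. The headline group
comparison is a pooled-variance t-test (df = n_A + n_B − 2). Matched
subsets are built by greedy nearest-neighbour matching on standardized
(GA, PMA) with standardized-mean-difference diagnostics. The
outcome-association analysis regresses the outcome score on a thickness
measure controlling PMA, GA, sex and intracranial volume (sum of
non-background tissue volumes), separately per cohort and pooled.

Under the default calibration the full chain — matched cohorts of 30,
rendering, window segmentation, Laplace thickness, regression — recovers
the encoded structure: source-cohort mean thickness ≈ 1.78 mm (true
1.73 mm plus the ~+0.05–0.09 mm discretization bias shared by both
cohorts), a cohort coefficient ≈ 0.2 mm with p ≪ 0.001, and a positive
PMA slope whose single-run estimate scatters around 0.04 mm/week with
SE ≈ 0.015 at n = 60 over a 1-week PMA spread.

The spurious-outcome demonstration needs large pooled cohorts
(3000/cohort in the analytic fast path): because GA itself nearly
separates the cohorts and is controlled for, only the part of the cohort
offset not explained by the covariates can leak into the thickness
coefficient, and with a 0.2 mm bias against ~0.09 mm irreducible
thickness SD that leakage is small. The mechanism is reproduced in kind —
pooled un-harmonized fits significant, per-cohort and harmonized fits
null — not at the original effect magnitudes.

## Desk-scale end-to-end experiment

The domain-adaptation property is exercised at 48³ / 0.9 mm with
three-level 8/16/32-channel U-Nets (half-width of the first three default
levels) and a width-shrunken discriminator. The shallow-wide variant is
used because the phantom's shell anatomy is locally decodable and it
converges in several times fewer optimizer steps than the narrow
five-level network at equal per-step cost; the five-level architecture
remains the package default. One baseline and one image-space DA model
are trained (independently seeded, 5 source + 5 target training subjects,
24 epochs), then seeded *validation replicates* — fresh matched cohorts
of 10+10, rendered and measured — are pushed through the trained models.
This mirrors the underlying study design (one trained model, repeated
statistical validation); training ten independent adversarial models per
suite run is not a sensible use of a CPU test budget. Each replicate
checks that (a) the DA segmenter beats the baseline on held-out
target-domain Dice, and (b) the cohort effect on measured thickness is
significant under the reference segmentation and non-significant under DA
segmentation. At this scale the generalized-Dice training is only
partially converged (mean non-background Dice ≈ 0.3–0.4, dominated by the
loss's 1/n² preference for small structures); the property holds anyway
because harmonization concerns the *bias* of the cGM boundary, not
absolute overlap. Passing at desk scale shows the mechanics and the
statistical logic work end to end; it does not certify performance on
real, folded, artifact-laden MRI.

## Known limitations

* Ellipsoidal-shell anatomy: no cortical folding, so thickness algorithms
  face none of the deep-sulcus partial-volume ambiguity of real cortex.
* The Laplace thickness stand-in carries a small upward bias on curved,
  coarsely sampled ribbons; it is shared across cohorts and cancels in
  cohort contrasts but is visible in absolute means.
* The naive reference segmenter is only well-posed because the phantom's
  contrast ordering was chosen to make it so; it is a measurement
  instrument for this phantom, not a general segmentation method.
* Desk-scale networks are far from convergence; Dice numbers are not
  comparable to full-scale training.
* Outcome scores are Gaussian with a cohort offset only; no real
  behavioural structure is modelled.
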