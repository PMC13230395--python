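# Methods

`fastpetdn` studies whether whole-body FDG-PET acquisitions that are 2-3x
faster than a 70 s/AFOV clinical reference can be restored by denoising, and
how a learned denoiser compares with optimized classical filters — entirely
on synthetic digital phantoms, so the pipeline can be exercised end to end
without patient data. This note records the models, the defaults and why
they were chosen, and what the synthetic setting can and cannot show.

## Digital phantoms

A phantom is a piecewise-constant SUV map on a regular grid (default
64 x 64 x 96 voxels at 4 mm isotropic — whole-body aspect ratio at clinical
PET resolution, small enough to train on a single CPU; full clinical
matrices are supported through the config). It contains:

* an ellipsoidal **body** at SUV 1.0 (soft-tissue background),
* an ellipsoidal **liver** at SUV 2.2 and two ellipsoidal **lungs** at
  SUV 0.5 — a plausible FDG biodistribution, chosen as synthetic
  conventions, not measurements,
* spherical hot **lesions** drawn from a two-stratum population:
  a conspicuous stratum (SUV 4.96 +- 0.5, MTV 9.3 +- 1.5 cm^3) and a faint
  stratum (SUV 2.75 +- 0.15, MTV 2.3 +- 0.5 cm^3), i.e. the kinds of lesions
  that are respectively kept and lost when acquisitions get fast.

Voxel membership is by the voxel-center-in-geometry test with no
partial-volume antialiasing, and no scanner physics (attenuation, scatter,
PSF, reconstruction) is modelled. Lesion masks, organ masks and the body are
exported as integer label volumes (0 air, 1 body, 2 liver, 3/4 lungs,
100+id lesions) in NIfTI-1.

## Acquisition noise model

PET count noise follows a mixed Gaussian-Poisson model. A simulated
acquisition of duration fraction `f` (relative to the 70 s/AFOV reference)
draws, per voxel,

    counts ~ Poisson(SUV * count_scale * f)
    image   = counts / (count_scale * f) + N(0, gaussian_sigma^2),

clipped at zero (the clipped fraction is logged in the volume metadata).
The Poisson step is mean-preserving with SUV-scale variance
`SUV / (count_scale * f)`: halving the acquisition time doubles the
variance, which is the premise of the whole study. Fast scans are simulated
by this count thinning on the activity map rather than by rebinning raw
listmode data (which a synthetic study does not have); the two differ mainly
in reconstruction-induced noise correlations, which are outside this model.

Defaults: `count_scale = 70` pseudo-counts per SUV unit at reference
duration and `gaussian_sigma = 0.05` SUV. These are tunables, not
measurements; they were fixed once so that the reference-duration liver SNR
(mean/SD) lands near 12, inside the 10-15 range typical of digital PET.
A consequence worth noting: at these settings the raw 20/70 and 30/70
acquisitions lose about 45% and 33% of liver SNR relative to the reference,
which is the regime the study design targets.

## Denoisers

### Classical benchmarks

* **Gaussian filter**, parameterised by FWHM in mm
  (`sigma = FWHM / (2 sqrt(2 ln 2))`, converted to voxels per axis), applied
  with reflective boundaries and a wide (6 sigma) kernel truncation so it is
  mass-preserving to 1e-6 on air-bordered volumes.
* **Non-local means** with patch radius r (comparison kernel `(2r+1)^3`),
  search radius d (window `(2d+1)^3`) and decay constant h. The weight of a
  patch at distance D (mean squared difference over the patch) is
  `exp(-max(D - 2 sigma^2, 0) / (h sigma)^2)`, where sigma is a robust noise
  estimate (MAD of the Laplacian residual over the body support — air is
  excluded because it is nearly noiseless and would collapse the estimate).
  Subtracting the expected noise contribution `2 sigma^2` means
  statistically identical patches receive full weight, so small h (~0.3)
  already denoises; without the offset the filter is inert at such h.
  With `sigma = 0` the weights reduce to plain `exp(-D/h^2)`, which gives
  the exact identity limit as `h -> 0` on noiseless data. An absolute-h mode
  bypasses the noise scaling. Boundaries are edge-including reflection,
  identical between the vectorised implementation and the triple-loop
  reference used in the tests.

Both filters are tuned by **MSE-minimising grid search** against reference
volumes over training phantoms, with the objective restricted to the body
support (air would dilute it; a whole-grid mode exists for parity checks)
and ties broken toward the weaker smoother. Default grids: FWHM in
{3..7} mm; h in {0.1..1.0}, d in {1,2,3}, r in {1,2}. The experiment
pipeline uses a reduced NLM grid (h in {0.2..1.0}, d=3, r=1) to keep the
optimization affordable at desk scale.

### Learned denoiser

Three U-Net variants are implemented on a small self-contained NumPy network
engine (im2col convolutions, hand-written backward passes, Adam):

* `axial_3ch_2p5d` — 2-D U-Net over axial slices with the two neighbouring
  slices as extra input channels (edge slices replicated, which avoids the
  dark-rim artifact zero padding would produce);
* `triplanar_1ch_2p5d` — one 2-D U-Net fed single slices of *any*
  anatomical plane; at inference the volume is denoised three times (all
  axial, all coronal, all sagittal slices) and the three reconstructions are
  fused voxel-wise — mean by default, median via config. Under squared loss
  the mean fusion can never be worse than the worst single plane;
* `patch_3d` — 3-D U-Net over overlapping cubic patches, overlap-averaged
  with uniform weights.

Architecture: two 3^n convolutions + ReLU per resolution level, **average
pooling** between levels (a denoiser should smooth, not pick extremes),
nearest-neighbour upsampling with skip concatenation, **no batch
normalisation**, **He-normal** initialisation, a linear 1x1 output
convolution, and an identity shortcut adding the (central) input channel to
the output so the network learns a correction to the noisy image — this
residual form converges much faster in the small-epoch regime used here.
Depth 3 with 8 base channels (~30k parameters) is the desk-scale default;
depth/width are config-driven.

Training: voxel-wise MSE, Adam at `lr0 = 1e-3` halved after a validation
plateau (patience in epochs is config-driven), inputs divided by a fixed SUV
scale of 10 — per-volume normalisation is deliberately rejected because it
distorts SUV recovery after inversion. Training pairs mix all five fast
durations (10-30 s/AFOV) so the network sees a range of noise levels; the
split is at phantom level, never slice level. On-the-fly paired
augmentation: rotation +-10 deg, anisotropic scaling 0.9-1.1, translation
+-5 voxels, applied with probability 0.5 to input and target alike. The
deployed checkpoint is the absolute validation-loss minimum. Each epoch
draws a fixed number of random slices (with replacement) rather than a full
pass over every slice of every pair; epoch counts quoted below refer to
these subsampled epochs. All randomness flows through one seeded generator
and training is deterministic on a single device.

## Quantitative assessment

* **MSE** over the body support (g^2/mL^2).
* **SSIM** with a uniform 7^3 window, standard constants (k1=0.01, k2=0.03)
  and a *fixed* dynamic range of 20 SUV, so scores are comparable across
  volumes (per-pair ranges are not); with a mask, the local SSIM map is
  averaged over the masked voxels.
* **ICC(A,1)** — two-way, single-measure, absolute-agreement intraclass
  correlation with voxels as subjects and the two volumes as measurements;
  computed from ANOVA mean squares, with deterministic voxel striding
  available for large grids. Degenerate zero-variance input yields NaN with
  a warning.
* **Regional SNR** = ROI mean / ROI sample SD (ddof 1) in manually
  delineated uniform-uptake regions; here the liver and lung label masks
  eroded by one voxel. This mean/SD definition is the standard
  uniform-region PET convention. Relative deltas are
  `100 * (test - ref) / ref` percent.

## Lesion quantification and detectability

Lesion segmentation is a deterministic adaptive-threshold region grower
(stand-in for a semi-automatic statistical segmenter, and pluggable): local
maximum within 12 mm of the seed, background = median in a 15-25 mm shell,
threshold = `bg + 0.41 (max - bg)`, connected component containing the peak,
capped at a 40 mm radius so a noisy grow cannot leak into a whole organ.
Features: SUV_max, SUV_mean, SUV_peak (maximum over in-lesion voxel centers
of the mean within a 1 cm^3 sphere, radius 6.2 mm, voxel-center-in-sphere
membership — the sphere convention had to be fixed here as the standard
one), MTV = voxel count x voxel volume, TLG = SUV_mean x MTV (an exact
identity by construction). Lesions below **4 voxels (0.256 cm^3 at 4 mm
isotropic)** are excluded from quantification.

Detectability uses an algorithmic reader emulation: the volume is smoothed
(5 mm FWHM), local maxima are scored by peak-minus-local-background contrast
(background = median in a shell around the peak — a global background fails
badly on multi-organ anatomy), and kept when the contrast exceeds both a
z-score threshold on the residual noise scale and an absolute SUV floor.
Three simulated readers are three threshold settings; a candidate survives
when >= 2 of 3 readers report it (majority consensus). This is an emulation
of a reading panel, not a claim of equivalence to physicians. Matching to
ground truth is greedy nearest-first one-to-one on centroids with a 10 mm
tolerance (2.5 voxels; unspecified upstream, exposed as a flag).
Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP).

## Statistics

Friedman's rank test (average ranks, tie-corrected chi-square) for the
omnibus repeated-measures comparison across image sets, Wilcoxon signed-rank
(zero differences dropped; exact null for n <= 25 untied pairs, tie-corrected
normal approximation otherwise) post hoc. Significance is strictly
`p < 0.05` and **no multiple-comparison correction is applied by default**
(a Holm step-down mode exists behind a flag).

## Desk-scale experiment sizes

The bundled experiment runner and the reproduction script use: 11 phantoms
(5 train / 1 validation / 5 held-out test) on the 64 x 64 x 96 grid, all five
fast durations for training, 20 and 30 s/AFOV for testing, and a depth-3 /
8-channel triplanar U-Net trained 50 epochs x 256 slices. These sizes were
chosen as the package's desk-scale operating point: large enough that the
learned denoiser cleanly leads the optimized Gaussian and NLM benchmarks on
MSE, SSIM and ICC, small enough to run on one CPU core in minutes. The
faint-lesion detectability study uses 20 lesions over 5 phantoms with a
stricter reader panel (z in {5,6,7}), since the faint stratum is the regime
where durations differ.

## What passing tests do and do not show

The phantoms are piecewise-constant with uncorrelated voxel noise. Real PET
has textured uptake, reconstruction-induced spatial noise correlation,
partial-volume blur and anatomical variability; a denoiser trained here will
not transfer to patients, and absolute metric values (MSE in 1e-3 g^2/mL^2,
SSIM, ICC, deltas) are not comparable to clinical numbers. What the
synthetic setting does establish is the machinery and the orderings: the
noise model's variance scaling with duration, the correctness of every
metric and statistic against independent oracles, and the relative ranking
of the denoising approaches under a controlled ground truth. Feature
deviations (especially MTV) come out smaller than on clinical data because
threshold segmentation is nearly deterministic on piecewise-constant
lesions.

## Numerical conventions

* Intensities are float32 SUV end to end; no integer quantisation.
* Geometry checks (`check_aligned`) guard every paired operation; spacing
  tolerance 1e-6 mm.
* Boundary handling is edge-including reflection for all filters; U-Net
  convolutions use zero padding, with volumes reflectively padded to the
  pooling divisibility and cropped back.
* Grid-search ties go to the weaker smoother; greedy lesion matching breaks
  distance ties by enumeration order.
* Report CSVs are written with 6 significant digits; reruns with the same
  config and seed are byte-identical.
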