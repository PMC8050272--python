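# Methods

This note documents the models, conventions and numerical choices behind
`microqc`, and what the synthetic test data does and does not establish.

## Coordinate and intensity conventions

Pixel indices are 0-based; tiles and bounding boxes are half-open intervals.
The physical position of pixel `(row, col)` is its centre:
`x_nm = (col + 0.5) · pixel_size_nm`. This single convention is shared by the
SMLM simulator, the histogram renderer, the localisation extractor and the
centroid exporter, which keeps simulate → render → extract round trips free
of half-pixel bias. Pascal VOC XML stores 1-based inclusive pixel
coordinates; the reader/writer converts to and from the internal half-open
form, so a box covering pixels 0–9 is serialised as `xmin=1, xmax=10`.

Frame binning (grouped sum projection) accumulates in 32-bit float regardless
of input dtype and drops an incomplete trailing group, mirroring the grouped
z-projection behaviour of common image-processing tools; binning a
59,900-frame acquisition by 4 or 10 therefore yields 14,975 or 5,990 frames.

## Restoration metrics

Model outputs and ground truth generally live on unrelated intensity scales,
so all comparisons are made scale-free first: the target is
percentile-normalised (defaults pmin = 1, pmax = 99.9, robust against hot
pixels; not clipped) and the source and prediction are mapped onto it by the
closed-form least-squares affine fit `α·image + β`. As a consequence every
reported metric is invariant to affine rescaling of the compared image, the
convention of the content-aware restoration ecosystem. A zero-variance input
degenerates to `α = 0, β = mean(target)` and is flagged.

SSIM uses the standard Wang et al. constants (K₁ = 0.01, K₂ = 0.03, Gaussian
window σ = 1.5 over an 11-px support, data range L = 1 on normalised data)
with population (Gaussian-weighted) variances. The per-pixel map is returned
for artefact localisation; mSSIM averages windows that fit fully inside the
image. NRMSE divides the RMSE by the target standard deviation by default;
`range` and `mean` denominators are selectable and the choice is recorded in
the report, since "normalised" is ambiguous across tools. PSNR of identical
images is reported as the explicit sentinel +inf rather than an error. 3D
inputs are scored slice-wise and averaged, with per-slice maps.

## Segmentation scoring

The binarisation-threshold sweep rescales float probability maps min–max to
8 bits and evaluates IoU at integer levels 1–254, returning the lowest
maximising threshold (deterministic tie-break). A constant map is flagged and
returns the midpoint 127.

Instance matching computes the pairwise IoU matrix from one joint-histogram
pass, then solves the one-to-one assignment maximising total IoU restricted
to pairs with IoU ≥ τ (Hungarian algorithm; a greedy-by-IoU strategy is
available behind a flag and differences are test-covered). τ defaults to 0.5
and is always recorded, as scores are meaningless without it. F1, SQ, RQ and
PQ follow the usual panoptic-quality definitions; a result with no true
positives scores 0 everywhere and is flagged rather than NaN. IoU of two
empty masks is defined as 1 (flagged) to avoid NaN propagation in batch QC.
Both whole-image semantic IoU and the mean matched (per-object) IoU are
reported side by side, since both aggregations are in common use.

## Detection scoring

Evaluation is the standard ranked protocol at a single IoU threshold
(mAP@0.5 by default): per class, predictions sorted by descending confidence
are matched greedily (best-IoU first) to unused same-class ground-truth boxes
in the same image. Ties in confidence are broken by (image name, box
coordinates) so results are reproducible across runs. AP integrates the
right-to-left monotone precision envelope over recall (all-point
interpolation); the older 11-point VOC sampling is available and the choice
is recorded. The F1 operating confidence (default 0.3) is likewise a
required, recorded parameter. mAP averages AP over classes present in the
ground truth, unweighted.

## SMLM simulator

Per frame, the emitter count is `round(max(0, N(density_mean, density_std)) ·
area_µm²)` — a per-frame Normal draw on density, with a Poisson alternative
behind a flag since the sampling law is a modelling choice, not an
observable. Emitter positions are uniform over the field of view; each
emitter draws photons ~ N(photons_mean, photons_std) and PSF width
σ ~ N(psf_sigma_nm, psf_sigma_std_nm), both truncated positive by resampling
(≤ 100 rounds, then clamped). The expected photon image integrates the 2D
Gaussian over each pixel via differences of the Gaussian CDF — correct in the
σ ≈ 1 px regime of the shipped presets, where centre-sampling would bias
spot mass. The camera applies
`ADU = offset + Poisson(photons)/conversion + N(0, read_noise)`, clipped at
zero. The conversion factor is photoelectrons per A/D count (ThunderSTORM
camera convention); the reciprocal convention is available behind
`adu_per_photon=True`. With zero spreads the ground-truth photon mean is
exact, and the second moment of a rendered spot recovers σ after Sheppard's
binning correction (−px²/12).

Three parameter presets (`BIN4`, `BIN10`, `TUB`) reproduce the published
acquisition conditions for 20-frame, 64×64 px training sets, e.g. BIN4:
10,240 nm FOV, 160 nm pixels, 2.8 emitters/µm² (std 0), σ = 153 ± 29 nm,
3500 ± 850 photons, conversion 16, read noise 1040 ADU, offset 10,550 ADU —
giving round(2.8 · 10.24²) = 294 emitters per frame.

EM-gain excess noise, astigmatic/3D PSFs and partial spots wrapped across the
field border are not modelled.

## Localisation post-processing

*Extraction* finds local maxima in the (2r+1)² neighbourhood at or above a
fraction of the image maximum; exact-tie plateaus (an emitter centred on a
pixel boundary) are collapsed to one candidate via connected-component
labelling. Positions are intensity-weighted centroids over the window;
intensities are window sums.

*Event merging* links localisations frame to frame (nearest neighbour,
one-to-one, ties to the lowest track index) when the distance is within
`radius_nm` and the gap within `max_dark_frames`; each track emits one record
with photon-weighted mean position, summed photons and first frame. Defaults
are 40 nm and no dark frame, the published post-processing rule.

*Drift estimation* splits localisations into equal-count temporal bins
(robust to blinking non-stationarity), renders each at `render_pixel_nm`
(default 20 nm, light Gaussian blur), and reads the shift of each bin
against the first from the circular FFT cross-correlation peak with 3×3
centroid sub-pixel refinement. The per-frame trace linearly interpolates
between bin-centre frames and linearly extrapolates to the stack ends —
without extrapolation a linear drift would be systematically underestimated
by roughly one half-bin at each end — then is re-anchored so frame 1 is
exactly (0, 0). Bins with fewer than 10 localisations are flagged low
confidence. On the synthetic 100 nm linear-drift scene the endpoint is
recovered to a few nm, well within half a rendering pixel.

## Augmentation

The eight D4 symmetries are applied with the same element to both members of
a pair, identity included, so the dataset grows exactly ×8 (×4
rotation-only, ×3 flip-only with identity). Duplicates arising from symmetric
images are not deduplicated. Bounding boxes are mapped by the exact
continuous coordinate transform on the half-open grid; a property test
verifies, for every element, that the transformed box rasterises to exactly
the transformed raster of the original box, including on non-square images
where dimensions swap.

## Overfitting verdict and report

"Increasing divergence between validation and training loss" is
operationalised as: final validation loss > (1 + δ)·minimum validation loss
while the final training loss is at or below its value at the
validation-minimum epoch (δ = 0.05 by default, recorded). The verdict is
invariant to positive rescaling of both curves, and the validation-minimum
epoch is recommended as the checkpoint. The report serialises every supplied
parameter and QC scalar (with its configuration: τ, confidence,
normalisation mode, seeds) into a markdown + JSON twin; the timestamp is the
only non-deterministic field and is isolated on one line for diffability.

## Synthetic data: what it shows and what it does not

The fixture generators are pure functions of their spec (seed included).
They emulate the *geometry and statistics* the metrics consume —
non-overlapping elliptical nuclei with exact labels, Poisson + Gaussian
noise with known moments, detection scenes whose drop/false-positive
corruption makes expected recall countable (recall = 1 − drop fraction at
the full ranking), blinking binding sites under linear drift. They do not
reproduce the texture, anisotropy, label noise or optical aberrations of
real microscopy data; a passing suite therefore certifies the *correctness
of the measurements*, not the performance of any particular trained model on
real data. Scene sizes in the tests (≤ 128² images, ≤ 20 objects, 64×64×20
simulations, 200-frame drift scenes) were chosen as the smallest scales at
which every statistical check has comfortable power.

## Known limitations

- Instance matching is 2D; for 3D data only slice-wise semantic IoU applies.
- No frequency-domain resolution estimates (FRC) or learned perceptual
  metrics.
- Drift correction assumes a rigid lateral drift common to the whole field;
  fiducial-based and non-rigid correction are out of scope.
- Order-based (rather than name-based) dataset pairing is supported but
  fragile, and off by default.
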