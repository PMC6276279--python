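# Methods

`credkit` implements the offline computational core of a semi-automated
continuous-rotation electron diffraction (cRED) acquisition system with
SerialED crystal screening.  This note documents the models, the numerical
choices, and what the bundled simulator does and does not emulate.

## Electron optics

The wavelength is the relativistic de Broglie wavelength

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2)))

with CODATA-2018 constants, voltage accepted in kV.  At 200 kV this gives
0.02508 Å.  Resolution at a detector radius uses the exact Bragg relation
`d = lambda / (2 sin(atan(r/L)/2))`; at electron wavelengths the small-angle
form `d ~ lambda L / r` is accurate to well below 0.1% over the whole
detector.  The *effective* camera length depends on a magnification
calibration that is instrument-specific; the nominal 250 mm default is
carried as metadata and every geometric computation takes the camera length
as an explicit input.

## Timepix geometry

The detector is a 2x2 tile of 256x256 modules whose facing edge pixels are
physically 165 µm instead of 55 µm.  A raw 512x512 frame is expanded to the
516x516 logical grid: raw indices 255 and 256 per dimension each become three
logical pixels, and the recorded counts of a big pixel are split equally
(÷3) among its three logical pixels.  Equal splitting conserves integrated
intensity exactly — important because the tracking-QC statistic sums frame
counts — and costs nothing for integration because the resulting 6-pixel
cross (logical indices 255–260) is always masked.  The mask is emitted in the
XDS open-interval convention: a pixel at 1-based coordinate x is inside
(x1, x2) iff x1 < x < x2, so the two strips are `255 262 0 517` and
`0 517 255 262`.  Whether real hardware applies an additional per-pixel gain
to the big pixels beyond the flatfield is not modelled; the flatfield is a
separate mean-normalized response map (dead pixels: response <= 0, output 0).

## Acquisition schedule and defocus tracking

During continuous rotation the goniometer never stops, so time maps linearly
to angle.  The schedule is a sequence of equal-duration slots
(`frame_time`, e.g. 0.512 s = 0.5 s exposure + readout/overhead).  Crystal
tracking defocuses the diffraction pattern once per cycle: **n_interval data
frames, then one defocus-tracking slot** (default 10:1, i.e. 430 data frames
contain 43 tracking slots; trailing partial cycles get none).  The phrase
"every nth pattern" could also be read as 9:1; the 10:1 convention is the one
consistent with run tables pairing 430 with 43 and 554 with 55.  A defocus
slot occupies a full frame time even though its exposure is ~0.01 s — the
remaining time models lens settling — so every gap covers exactly one frame's
oscillation, which is what XDS/DIALS require of excluded images.  A 0.2 s
start delay shifts the time origin only.  Frame numbering is 1-based
everywhere the XDS/DIALS conventions apply.

The per-frame oscillation angle for integration is computed as
`tilt_range / total_time * frame_time`.  Published run tables can be
internally inconsistent at the printed precision (slot count x slot time need
not equal the printed total time, and a printed oscillation may be a
truncation rather than a rounding); the formula is authoritative here and
values are printed with four decimals.

## Beam center

Processing uses the arg-max of the frame after Gaussian smoothing
(default sigma 10 px, the sharp end of the useful 10–30 px range; reflect
padding; ties break to the lowest row then column).  Screening uses the
centroid of the brightest ~5% of pixels: the cutoff is the ceil(0.05 N)-th
brightest value and *all* pixels at or above it are included, so the result
never depends on storage order (a constant frame gives the geometric
center).  Per-run aggregation is the component-wise median over frames,
robust to a minority of obscured frames.  The median is taken on corrected
(516x516) frames.

## Elliptical distortion

Post-specimen lens distortion maps a circle of spots into an ellipse with
eccentricity e = sqrt(1 - (b/a)^2).  The model is the affine stretch about
the distortion center: coordinates along the major axis unchanged, minor-axis
coordinates multiplied by b/a (distort) or a/b (correct).  Fitting delegates
to scikit-image's total-least-squares `EllipseModel`; axes are reordered so
`a` is the major axis and the azimuth is reported modulo 180 deg.  The
azimuth is a free parameter (default 0 deg) — only the eccentricity of the
instrument distortion is typically known a priori.  XDS consumes the
correction as X-/Y-GEO_CORR tables: per-pixel (corrected - observed)
displacements in integer hundredths of a pixel, written as SMV images with a
+32768 bias so negative offsets fit the unsigned format.

## Screening pipeline

Preprocessing (in order): locate the beam (top-percentile centroid), crop
400x400 about it with zero padding outside the detector, cap intensities at
mu + 4 sigma of the crop (the direct beam otherwise dwarfs the spots),
feature-scale to [0, 1] — a constant crop maps to all zeros — and shrink to
150x150 by local-mean resampling, which preserves integrated spot intensity
better than subsampling.  Capping is deliberately not idempotent: re-running
the cap on a sparse, already-capped image can clip again because the moments
change; the pipeline applies it exactly once.

The classifier is a small convolutional network implemented directly on
numpy (im2col convolutions executed as BLAS matrix products), trained with
the protocol: batches of 75, 20 epochs, dropout 0.15 on the dense hidden
layer, binary cross-entropy, RMSprop (lr 1e-3, rho 0.9), ReLU activations
and a single logistic output; score > 0.5 (strictly) classifies a pattern
good.  The default architecture is compact — a fixed 2x2 average-pool input
stage, two 3x3 conv blocks of 8 and 16 filters with 4x4 max-pooling, and a
48-unit dense layer — because the synthetic training classes (sharp spot
patterns vs powder rings / blanks) are far simpler than a real labelled
corpus of tens of thousands of instrument images; this net trains on CPU in
minutes and scores held-out synthetic patterns above 0.95.  Deeper stacks
(e.g. 32-64-128-128 with a 128 dense layer) are a `CnnConfig` away and the
training loop is unchanged.  All randomness (weight init, shuffling,
dropout) flows from explicit seeds and training is bit-reproducible on CPU.
Accuracy measured on these synthetic classes says nothing quantitative about
real diffraction corpora, where labels are subjective and classes overlap.

Candidate selection keeps crystals whose nearest neighbour is >= 1.5 µm away
(both members of a closer pair are dropped — neither can be hit cleanly by
the beam) and that lie >= 0.5 µm from every image edge.  The candidates CSV
columns are (image_path, image_seq, crystal_seq, score, object_size,
stage_x, stage_y); scores print with 4 decimals; sizes are in µm.

## Tracking QC

The per-frame scale is the summed counts outside a beam-exclusion disc
(default radius 30 px) and outside the module-cross mask, normalized to a
series median of 1.  This emulates — not replicates — the per-image scale
that integration programs report from their initial background job, whose
exact estimator is internal to them; both the Bragg spots and the diffuse
(inelastic) background scale with how much of the crystal the aperture
admits, so dips in this statistic flag the crystal leaving the selected-area
aperture.  Frames with scale < 0.5 are flagged; a run is "poorly tracked" iff
it has >= 5 consecutive flagged frames or a coefficient of variation > 0.5,
so a single-frame dip (e.g. a grid bar at high tilt) is flagged but does not
fail the run.  The statistic is invariant under global intensity scaling and
equivariant under frame permutation.

## Simulator

The simulator is kinematic: reciprocal-lattice points (crystallographic
convention, no 2*pi) within an excitation tolerance epsilon (default
0.002 1/Å) of the Ewald sphere at each slot's angular midpoint are projected
with r = L·lambda/d, rendered as Gaussian spots (sigma 1.5 px, peak 400
counts) with a triangular partiality factor in |s|/epsilon and a simple
falling form factor, plus a bright direct-beam blob, detector floor
(0.5 counts/px) and crystal diffuse scatter (3 counts/px at full aperture
overlap), all Poisson-sampled.  The default orientation is a fixed generic
rotation — a real crystal almost never lands zone-axis-aligned, and an
axis-aligned default would make per-frame excited-spot counts spike through
dense zones.  Crystal drift attenuates per-frame intensities by the exact
circle-circle overlap fraction of the crystal disc (default radius 0.35 µm)
with the selected-area aperture (default radius 0.75 µm); defocus slots
render the drifted crystal silhouette instead of a pattern.  Everything is
reproducible from a single seed, and a truth sidecar records the beam
center, per-frame spot lists (hkl, position, intensity, d) and the
attenuation profile.

Not emulated: dynamical scattering (kinematic intensities only), inelastic
background shape, physical defocus optics, goniometer backlash, and
space-group-aware structure factors.  Tests passing on simulator output
therefore validate the *bookkeeping and estimation machinery* (geometry,
scheduling, centering, distortion, QC statistics), not data quality on a
real instrument.

## Problem sizes used in the test suite

The bundled checks run the bulk properties at sizes a workstation handles
comfortably: 1000 random frames for geometry conservation, 1000 random
images for the preprocessing contract, 1000 random crystal fields against
the O(n^2) isolation oracle, exhaustive schedule-partition enumeration for
n_data <= 200 and n_interval <= 12, a 30-frame drifting rotation series for
parameter recovery, and classifier training at 2000 images per class with
1000 held out.  These sizes are the package's own choice of a thorough but
quick regression suite.

## Known limitations

* The CNN is a binary good/bad scorer; no multi-class or calibration layer.
* GEO_CORR tables assume the affine elliptical model; higher-order (radial,
  spiral) distortion fields are out of scope.
* The SMV dialect is the ADSC-style subset XDS/DIALS read; HDF5/NeXus export
  is not implemented.
* The per-frame scale statistic is a stand-in with the same sensitivity as
  integration-program scale factors, not a numerical reproduction of them.
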