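# Methods

This note documents the models behind `shadowimg`, the parameter choices
that matter, what the synthetic phantoms do and do not emulate, and the
numerical decisions a user should know before trusting a number.

## Image model and conventions

All rasters are carried as five-axis arrays `(t, c, z, y, x)` with
singleton axes materialized, following the ImageJ hyperstack convention;
pixel geometry (`dx`, `dy` in µm, optional `dz`, `dt`) travels with the
data and round-trips through TIFF. Coordinates are 0-based and
pixel-centered: the physical position of index `i` is `i · dx` µm, and
sub-pixel values come from bilinear interpolation (exact on affine
intensity fields, which the test suite checks).

Contrast normalization is per-frame and robust: the 0.1 and 99.9
percentiles map to 0 and 1, then values clip. Fractional thresholds
(e.g. the >70% / <2% tissue-state cutoffs) are defined on this range.
Robust percentiles rather than min/max make those thresholds insensitive
to isolated hot or dead pixels; both percentiles are parameters. A frame
whose two percentiles coincide has no contrast; it is zeroed and flagged
rather than propagating NaNs. Inversion (`v → 1 − v`) is only defined on
normalized stacks and is an involution.

Saturated pixels (at the container dtype's maximum on read) are flagged,
and the pure-ECS reference refuses regions containing them: the
volume-fraction normalization is only meaningful with the detector in
its linear range.

## ECS volume fraction

The estimator is the normalized-intensity formula
`VF = (⟨I_ROI⟩ − bg)/(I_ECS − bg)`. Design points:

- **Background defaults to 0**, mirroring the plain normalization; an
  optional offset (fixed value or dark-ROI mean) exists because real
  detectors have offsets, and it is off by default.
- **The pure-ECS reference** is either a designated ROI (preferred — a
  perivascular pool large enough to contain the excitation volume) or
  the mean of the brightest 0.1% of pixels as a fallback. The
  top-fraction mode is biased high under shot noise (it selects positive
  noise excursions), which biases VF low by a few percent relative; the
  ROI mode does not suffer from this and is what the acceptance checks
  use.
- Estimates outside [0, 1] (possible under noise) are clipped and
  flagged, not rejected.
- **Resolution independence** holds because convolution with a unit-sum
  kernel preserves regional means; the test suite verifies < 1 point of
  spread across PSF FWHMs of 0.2–0.8 µm on a fixed geometry.

## Vessel and PVS widths

Cross-section profiles are sampled perpendicular to a user-supplied (or
phantom-supplied) centerline polyline, at pixel pitch, averaging 5
parallel lines by default. The model fitted is

`I(x) = b + A_L G(x; µ_L, σ_L) + A_R G(x; µ_R, σ_R) − A_0 G(x; µ_0, σ_0)`

with all amplitudes constrained non-negative and `µ_L < µ_0 < µ_R`
enforced post-fit. A simultaneous fit (rather than three windowed fits)
is required because flanks and trough overlap at capillary scale.
Reported widths are FWHMs (`2.3548σ`). Two significance guards prevent
fitting noise as anatomy: a flank is reported missing when its amplitude
is below 3× the residual sd *or* below 5% of the trough depth (the
absolute floor covers the noiseless limit where the residual sd
vanishes); a profile whose trough fails the same 3× test is flagged
`no_vessel`.

For the lumen–PVS coupling, the default pairing averages the two sides
of each vessel into one PVS width (selectable to per-side pairs). In the
phantom, each vessel draws one PVS width shared by both sides
(`w = w₀ + b·(D − D₀) + ε`), so the population correlation has the
closed form `r = b·σ_D / √(b²σ_D² + σ_ε²)` under the mean pairing; the
default noise sd (0.0781 µm at b = 0.12, σ_D = 1.0 µm) sets r ≈ 0.838.

## Phagocytic triage

Pipeline: median filter (disk radius 4 px — the convention of the
GUI tool the procedure derives from) → robust normalize → invert →
threshold: intact = pixels > 0.70, lysed = pixels < 0.02 (strict
inequalities; the masks are disjoint by construction).

Cup detection binarizes the EGFP channel with a **stack-level** Otsu
threshold (one threshold for the whole series; a per-frame threshold
invents foreground in cup-free baseline frames, where only noise is
present), fills holes per frame, and subtracts: the remainder is exactly
the enclosed background — candidate cup interiors, which a
border-flood-fill oracle confirms on random images. Candidates are
linked over (x, y, t) with 26-connectivity and gated on median
equivalent diameter (3–12 µm window centred on the typical ~6 µm cup)
and mean circularity (4πA/P² ≥ 0.6), then ranked most-circular first.
All three gates are parameters: the size and circularity cutoffs are
this package's operationalization of a qualitative description, not
published values.

Content classification redirects each cup interior onto the thresholded
masks: a cup is positive for a state in a frame when **more than half**
of its interior pixels carry it (the median of the binary content is
non-zero). The interior is first eroded by 2 px: hole-boundary pixels
are partial-volume mixtures of wall and cargo that threshold to neither
state, and for the smallest cups they would otherwise dilute the
median below 50% for genuinely full cups. `rim_erosion_px=0` restores
the literal rule. Lifetime classes: lysed / intact / both (positive for
both states in the same or different frames) / empty.

The automatic lesion ROI is the per-frame closing (disk, 1 µm) of
lysed ∪ newly-appearing intact pixels, followed by a small dilation
(0.8 µm) that compensates the rim each structure loses where its blurred
edge crosses back over a threshold — the ROI outlines an *area*
containing damaged material, so it should reach structures' true
boundaries. An expert-drawn ROI overrides the automatic one.

Enrichment: "In ROI" = percent of lesion-ROI area carrying each state,
averaged over frames with a nonempty ROI; "In PC" = percent of cups
positive for each state, averaged over frames with at least one cup.

## Motility

`track_metrics` sums frame-to-frame displacements up to arrival (first
frame within 2 µm of the lesion point; the lesion spot has finite size,
which is also why the trajectory phantom ends paths at that boundary
rather than the lesion centre). The mean velocity averages the
inter-frame speeds between 1-based listed frames 3–7 (transitions 3→4 …
6→7) — the early, linear portion of an approach — counted from the first
tracked frame, and is undefined below 8 frames. Path classification
samples the straight baseline→lesion segment at half-pixel pitch against
a cell-body mask (dark connected components ≥ 5 µm equivalent diameter
in the baseline shadow frame).

## Phantoms: what they emulate, and what they do not

All generators are deterministic functions of a single integer seed
(independent named substreams per generator), and every painted
structure has exactly one ground-truth record.

**Image formation** is a 2-D Gaussian PSF (σ = FWHM/2.3548) applied per
plane with reflective boundaries (mean conservation depends on this),
followed by Poisson shot noise at a configurable photons-per-unit-
intensity scaling plus Gaussian read noise, rescaled back to intensity
units. No scattering, aberrations, axial blur or motion artifacts are
simulated; passing tests demonstrate correctness of the estimators under
this idealized optics, not robustness to every in-vivo nuisance.

**Neuropil**: elliptical neurite-scale cross-sections (semi-axes
0.15–0.6 µm, matching sub-µm process calibers and keeping the ECS
fraction spatially homogeneous at the 10 µm ROI scale) are packed until
the ECS fraction off the reference plateau hits the target within
±0.002, with a final single-pixel adjustment that vanishes under the
PSF. A pure-ECS plateau (side ≥ max(3×PSF, 2 µm)) is reserved for the
reference ROI, which is eroded at measurement time so blur from abutting
structures stays out. Defaults: 0.1 µm pixels, 0.32 µm PSF, photon peak
200, VF 0.23 — a cortical value.

**Vessels**: one straight horizontal vessel per frame (the t axis
indexes vessels), built *directly in the image domain*: cross-sections
are baseline + two Gaussian peaks − one trough at the specified apparent
FWHMs, because published PVS/lumen widths are measured on blurred images
without deconvolution — this makes the configured widths exactly what an
ideal measurement recovers. A pre-blur mode constructs the same geometry
at physical widths and then blurs, for testing the √(a² + b²) quadrature
broadening law. Defaults: lumen 3.7 ± 1.0 µm, PVS 0.58 µm, coupling as
above. Profile discretization (bilinear sampling at 0.1 µm pitch) widens
the narrow PVS peaks by ~1–2%, visible as a small positive bias in
recovered PVS means.

**Lesion series**: cups are laid out on a jittered 10 µm grid (their
interiors can never merge), appear from frame 2 (frames 0–1 are a clean
baseline), and persist to the end; interior diameters are 6 ± 0.8 µm
clipped to [4.5, 7.5]. Interiors are painted dye-bright (lysed class),
dye-dark (intact), or lysed-then-intact switching mid-lifetime ("both" —
contents are engulfed sequentially; a spatial half/half interior would
defeat the median rule by construction). Non-cup distractors (open arcs,
line segments) occupy spare slots; micron-scale lysed pools and intact
blebs grow around the field centre as the lesion. The shadow channel
uses photon peak 1000: the 2%-from-the-end threshold needs the
percentile normalization anchor within ~2σ of the dye-positive bulk,
which corresponds to the well-exposed acquisitions this analysis is run
on in practice. Class counts are multinomial by default; an
`exact_counts` switch forces the largest-remainder integer split for
deterministic recovery checks.

**Trajectories**: straight constant-speed approach toward the lesion
with isotropic Gaussian positional jitter per frame (tracking error),
ending at the lesion-core boundary, then dwelling. Defaults: 29 neuropil
tips at 0.07 µm/s over 17.1 µm, 14 cell-body tips at 0.12 µm/s over
28.1 µm, 20 s frames, 0.1 µm jitter. Jitter inflates measured path
lengths by ~σ²/step per step (≈1% here); no meandering is simulated.

**Beads**: analytic 2-D Gaussian spots at sub-pixel positions with a
minimum separation (default 3 µm) and a border margin for fitting;
default FWHM 212 nm at 40 nm pixels — a confocal-class lateral
resolution. **Clearance**: `I(t) = I₀e^{−λt}`; a target drop d over
[t₁, t₂] sets λ = ln(1/(1−d))/(t₂−t₁), so the generated series
reproduces that drop identically.

## Numerical choices

- Gaussian fits initialize from moments (median baseline, extremum
  amplitude/position, damped second-moment width) — deterministic and
  derivative-free; trough fitting reuses the peak path on the negated
  profile (one code path, signed amplitude). `auto` polarity fits both
  and keeps the lower RMSE.
- The SNR of a frame is (max − min of the line profile)/sd of a
  background ROI — one reasonable definition among several; it is
  documented here precisely because the quantity has no universal
  definition.
- Bead fields exclude beads closer than 3× the median FWHM to a
  neighbour from the field mean (crowded PSFs bias widths upward).
- Percentile interpolation follows the linear (numpy default)
  convention; the normalization oracle in the tests recomputes it by
  sorting.
- Problem sizes in the recovery checks (800² neuropil field, 300–500
  vessels, 130 cups over 8 frames, 1000² bead field) were chosen so each
  stage's sampling error is several times smaller than its acceptance
  band.

## Known limitations

- The Gaussian PSF under-represents the Airy side-lobes of high-NA
  systems; FWHM-level conclusions are unaffected, but faint halo
  structure is not reproduced.
- Tissue-state thresholds are fractions of a per-frame normalized range;
  on data with frame-to-frame content shifts (e.g. a lesion filling the
  field) the effective absolute thresholds drift with the percentiles.
- The vessel fitter assumes one vessel per profile; crossing vessels or
  branch points need manual station placement.
- Cup detection requires the cup to be optically closed in 2-D; cups
  opening toward the camera (3-D geometry) produce no hole and are
  missed, as in the original procedure.
- Trajectories are inputs (or phantom outputs); there is no automated
  tip tracker.
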