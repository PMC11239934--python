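# Methods

## Coordinate and timing conventions

Pixel coordinates are 0-based with row 0 at the image top; spatial
intervals are half-open `[start, end)` except the ventricular-most
laminar bin, which is closed so a cell exactly on the ventricular
boundary is counted. The radial (pial–ventricular) axis is the image
row axis; slices are assumed mounted with the cortical surface
horizontal, and the annotation flag `radial_up` records whether
decreasing row index points toward the pia. Arbitrary-angle radial axes
are out of scope. Frame `i` is stamped with its start time
`t0 + i·Δt`; the acquisition interval `Δt` is required metadata and is
never guessed from files. "Exclude the first 4.5 h" removes frames
whose start time is strictly before 4.5 h, so the frame starting
exactly at the cutoff is retained and the retained frame count is
reproducible for any interval.

## Reporter quantification

The movie is reduced to a `grid_rows × grid_cols` (default 14 × 16)
array of per-square mean-intensity time series. Grid boundaries are
`round(i·H/grid_rows)` (half-open), so any image size is accepted and
every pixel belongs to exactly one square; no divisibility is required.

Each retained series is Fourier-transformed and summed over an
inclusive low band (default bins 2–30) and high band (default bins
30–75). The band limits are DFT bin indices, not physical hertz: at
time-lapse cadences of minutes per frame the Nyquist frequency is far
below 1 Hz, so only the bin-index reading makes such bands meaningful.
The two printed bands overlap at bin 30 and are kept as printed by
default; a config switch (`high_band=(31, 75)`) makes them disjoint.
Bands are clipped to the available bins with a warning; a correction
band entirely above Nyquist disables the correction with a warning
rather than failing the run.

**Power vs magnitude.** By default the band sums are of spectral power
`|X[k]|²`; summing magnitudes `|X[k]|` is available via
`use_power_spectrum=False`. Both are defensible readings of "summing
the frequency domain", and which one the original analysis used cannot
be determined, so both ship. Power is the default because the
cosmic-ray correction below relies on additivity: powers of independent
components add in expectation, so a flat floor estimated from the high
band can be subtracted from the low band without bias. Magnitudes add
in quadrature on structured backgrounds (a spike raises `|X|` by
roughly `h²/2|X|` where signal is strong but by `~h` where the
background is weak), which biases the same subtraction toward
over-correction.

**Cosmic-ray correction.** A cosmic ray on a long-exposure luminescence
camera is a single-pixel, single-frame additive spike — a temporal
impulse whose spectrum is exactly flat. Its per-bin level is therefore
estimated from the high band, where slow biological signal is absent,
and removed from the low band: `B* = max(0, B − n_low·H/n_high)`. For
an isolated impulse on zero background this annihilates the
contribution exactly (an analytic identity used as a test). The
wording "low-pass filter … by adding the high frequencies" is
implemented as this corrective subtraction because literally zeroing
bins 30–75 cannot change a sum over bins 2–30; the literal `mask` mode
ships as well (a no-op for disjoint bands; with the default overlapping
bands it removes only bin 30), as does `none`.

**SP selection.** The grid row containing the annotated SP-band centre
is located; the `sp_half_rows` (default 4) rows immediately above and
below are retained, all columns kept. Whether the centre row itself is
included is not determinable from the published wording; the default
excludes it (`include_sp_center` switches). Selections clipped at the
image edge produce a one-sided selection with a warning.

## Tracking and velocity

Detection thresholds the labelled-cell channel and returns
intensity-weighted centroids of connected components with at least
`min_area_px` (default 4) pixels. The default threshold (70) sits above
the rendered process intensity and below the soma peak, so detections
are somata — the reproducible surrogate for the manual soma tracking
used with such movies, and insensitive to the MP→BP shape change.

Linking is greedy nearest-neighbour: all (track end, detection) pairs
within `linking_max_disp_um` (default 15 µm) are assigned in ascending
distance order, ties broken by (track index, detection index);
unmatched detections start new tracks and a missed detection terminates
a track (no gap closing, no mitosis handling). Optimal assignment was
deliberately not used: at sparse electroporation densities greedy
linking is equally accurate, deterministic and dependency-free.

Radial velocity defaults to endpoint displacement of the radial
coordinate over elapsed time, in µm/h, positive toward the pia under
either slice orientation; whether published per-cell velocities were
net-displacement or path-based is unstated, so a regression-slope
estimator is available (`method="regression"`). Tracks with fewer than
2 points are excluded with a warning.

## Morphology, bins, zones

The classifier skeletonizes the cell mask, locates the soma at the
maximum of the Euclidean distance transform (largest inscribed disk,
radius ≥ `min_soma_px`, default 2 px), removes skeleton pixels within
`soma_radius + 2 px` of the centre, and counts the remaining connected
components that touch the soma neighbourhood and have at least
`min_neurite_px` (default 4) pixels as primary neurites. The longest
neurite is a leading process when its far endpoint lies within a ±45°
cone of the pial direction. ≥ 3 neurites → MP; 1–2 neurites with a
leading process → BP; everything else (including bare somata) is
ambiguous and excluded from compositions (but reported). These
thresholds are explicit, documented surrogates for a by-eye criterion;
the classification is invariant to mask translation and to mirroring
of the lateral axis.

BIN analysis divides the pial→ventricular span into `n_bins`
equal-height half-open intervals, BIN 1 adjacent to the pia, last bin
closed. The published analyses do not state their bin count, so it is a
parameter (default 5) and all outputs are labelled with it. Cells
outside the span are excluded and counted separately. Zone scoring uses
the same half-open convention for the SP band: `above_SP` is the pial
side in the radial sense under either orientation, and the per-cell
signal is the mean of the secondary channel over the cell mask or a
3-px disk at the cell's frame.

## Statistics

Group summaries are mean ± SEM (sample sd with `n−1` denominator over
`√n`). The default test is the pooled-variance unpaired two-tailed
Student's t-test (Welch's optional), with stars at strict thresholds
`* p < 0.05`, `** p < 0.01`, `*** p < 0.001` (p = 0.05 is "ns"). Zero
pooled variance with equal means gives t = 0, p = 1; with unequal means
the infinite-t edge case is reported as p = 0 with a warning. No
multiple-testing correction is applied; the report counts comparisons
so users can correct externally. Observations are pooled across slices
and animals (no nested random effects) — a documented property of the
analysis, not an oversight.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the estimators
consume, not photorealism. Cells are isotropic Gaussian somata
(σ ≈ 2 px, peak 100) with 1-px polyline processes (intensity 60):
3–5 arms of 8–12 px at ≥ 55°-separated angles while multipolar, and a
16–22 px pia-directed leading process (±30°) plus a short trailer after
crossing the transition row. Each cell moves toward the pia at a
velocity drawn once from the condition's Normal(mean, sd) plus
isotropic per-frame jitter; cells that would exit the frame are clamped
at the border and flagged. Morphology switches permanently at the first
crossing of the transition row.

The luminescence channel paints a disk of peak `burst_amplitude` at the
cell centroid during one contiguous burst window — from the cell's
first entry into the burst-permissive band until it first leaves the
band or `burst_duration_h` elapses — over Gaussian background noise,
clamped at zero. Cosmic rays are Poisson-count single-pixel
single-frame additive spikes, matching the impulse model the correction
targets.

Default fixture conditions: 160 frames at 0.5 h/frame, so the 4.5 h
exclusion removes 9 frames and the remaining 151 give one-sided bins
0–75, making the full printed band range well defined. The field of
view is 56 × 64 px at 8 µm/px — a heavily binned luminescence-camera
frame covering ~450 × 510 µm of cortical wall. Aggressive on-chip
binning is standard for photon-starved bioluminescence imaging and is
also why single cosmic-ray events visibly contaminate whole analysis
grid squares at this scale. 40 labelled cells migrate at
Normal(12, 2) µm/h with 2 µm/frame jitter; the burst band spans rows
[10, 42) around the SP centre (row 26), i.e. the SP-adjacent region
where the reporter is described as active; bursts have amplitude 50
over noise sd 5 (10:1), radius 1 px, and last up to 24 h of band
residence. The tracking fixture instead uses a 224 × 256 px field at
2 µm/px, 49 frames (24 h), 10–20 cells at 10 µm/h with 1-px
(2 µm/frame) jitter — cells resolvable and in-frame for the full movie.

What the generator does **not** emulate — and hence what passing tests
do not certify on real data: optics and PSF blur, luciferin/luciferase
kinetics, photobleaching and baseline drift, anisotropic or curved
migration paths, touching/overlapping cells at high labelling density,
z-drift, and non-Gaussian camera noise. The noise statistics of the
real instrument are unknown; the defaults are stated here, not claimed
to match it.

## Numerical choices and degenerate inputs

The DFT uses `numpy.fft.rfft`; an O(N²) direct-sum transform exists
only in the tests as an independent oracle (agreement to 1e−8 for all
N ≤ 256). Grid partitions use rounded integer boundaries. Readers
reject NaN and negative intensities rather than clipping. Fewer than
two frames surviving the initial exclusion, grids larger than the
image, bands entirely above Nyquist (signal band), disconnected
morphology masks, all-ambiguous compositions and out-of-range frame
indices are errors; empty detection lists, one-sided SP selections and
sub-minimum samples for SEM are warnings with defined results. Pipeline
errors are labelled with the stage that raised them. All analysis
stages are deterministic; all generators are bit-reproducible under a
fixed seed. Plots are written as SVG with a fixed hash salt and no
embedded date, so regenerated reports are byte-identical.

## Known limitations

Greedy linking can swap identities when cells pass within the linking
radius of each other; velocities are unaffected in expectation but
per-track assignments may mix. The skeleton classifier assumes masks of
well-separated cells (one connected component); touching cells must be
segmented upstream. The broadband spike correction assumes the high
band is signal-free; genuinely fast biological dynamics (period
< ~2.7 h at the default cadence and movie length) would be partly
subtracted. Velocity is reported per track, not per biological cell, so
a track broken by a missed detection contributes twice.
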