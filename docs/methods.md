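# Methods

## Scope and assumptions

`focicount` analyses 2-D single-plane, 8- or 16-bit fluorescence images
with one nuclear-stain channel (DAPI, blue) and one or two marker channels
(green/red). Z-stacks and time series are rejected rather than silently
projected. The pixel size in µm must come from file metadata or an explicit
override — the nucleus-area filter is physically calibrated, so a silent
1.0 µm default would corrupt it. Channel roles are taken from explicit
configuration, else from embedded LUT colors, else from a documented order
convention (channel 0 = green marker, channel 1 = red marker on 3-channel
files, last channel = nucleus) that is written to the run log; an image
whose nucleus channel cannot be identified is an error, not a guess.

## Nucleus segmentation

1. **Huang threshold.** The global threshold minimises the fuzzy-entropy
   measure: for candidate *t*, the two classes (gray level ≤ *t*, > *t*)
   get mean intensities m_lo/m_hi; level *g* has membership
   µ = 1/(1 + |g − m|/C) to its class with C the intensity span; the
   fuzziness is −Σ h(g)[µ ln µ + (1−µ) ln(1−µ)]. Ties break to the smallest
   candidate, for determinism. 16-bit (or float) data are binned to 256
   equal-width bins over the observed range before the scan and the chosen
   bin's upper edge is mapped back to the intensity scale; ranges of ≤ 256
   integer levels are scanned exactly, so 8-bit behaviour has no binning
   error. The brighter class becomes foreground (nuclei are bright on a
   DAPI image); a constant channel yields "no nuclei" with a warning, since
   an empty field of view is a valid observation.
2. **Denoise and re-threshold.** Holes in the binary mask are filled, the
   grayscale masked to the filled foreground is blurred with a Gaussian
   (σ = 3 px, reflective boundary, clipped to the input range), and the
   Huang threshold is applied once more. Blurring the grayscale rather than
   the binary mask keeps the second thresholding meaningful. The smooth
   intensity ramp at object edges makes the second threshold land below the
   half-maximum, dilating masks by a few pixels (≈ 4 px at the default
   geometry); this is inherent to re-thresholding a blurred image and is
   why the area filter, not the mask boundary, decides which objects count.
3. **Watershed.** Touching nuclei are split by flooding the inverted
   Euclidean distance transform from seed maxima. Seeds are the regional
   maxima of the h-maxima transform of the distance map with tolerance
   h = 2: peaks separated by a saddle shallower than 2 collapse onto one
   plateau and yield one seed, so discretisation ripples along an
   elongated nucleus's medial ridge do not oversplit it, while genuinely
   overlapping nuclei (saddle deeper than 2) are cut by a one-pixel
   watershed line. A component whose maxima were all suppressed keeps one
   seed at its distance maximum. Components are 8-connected.
4. **Particle analysis.** Surviving regions with area ≥ 100 µm²
   (inclusive: a nucleus of exactly 100 µm² counts) are relabelled 1..N in
   raster order of their first pixel. Border-touching nuclei are kept by
   default; `exclude_border_nuclei` drops them before the area filter.

## Focus detection

Bernsen's local threshold runs over a disk neighbourhood (default radius
40 px, clipped at image borders): where the local contrast max − min
reaches the contrast threshold, a pixel is foreground iff it is at least
the local mid-gray (max+min)/2; in low-contrast regions the whole
neighbourhood is classified by mid-gray ≥ half the full intensity range
(128 on 8-bit, 32 768 on 16-bit), which keeps dark background empty and
saturated plateaus filled. The contrast threshold is specified on the
8-bit scale (default 15, the common ImageJ default, since no principled
value exists for this data) and rescaled by 2^(bit_depth−8), i.e. 3840 on
16-bit data. The disk min/max filters are computed exactly by decomposing
the disk into one horizontal run per row offset and cascading 1-D moving
filters — O(radius) passes instead of O(radius²) work per pixel, which
makes the default radius practical on 512×512 fields.

Detection is per nucleus: the marker is cropped to the ROI bounding box
padded by the Bernsen radius (neighbourhoods at the box edge see real
context), binarized, intersected with the nucleus mask, and labeled
8-connected with **no** minimum particle size. Statistics (min/max/mean
intensity, area, centroid) come from the raw marker values. Touching foci
merge into one particle; no declumping is attempted.

A focus qualifies against `mark_brightness` by its **maximum** intensity —
robust to focus size, and a single saturated pixel is exactly what a
brightness criterion means on these images; the statistic is switchable to
mean or min via `FociParams.brightness_statistic` since the convention
varies between labs. Both classification thresholds are inclusive (≥),
matching the "10 or more foci of 10 000 or more" phrasing of the standard
damage rule.

`average_intensity` is the mean marker intensity over the union of all
nucleus pixels (not just focus pixels): it is a per-image normalisation
aid, not a focus statistic.

## Colocalization

With two markers, the pixelwise minimum image is bright only where both
channels are bright; foci detected on it are colocalized foci. The maximum
image is the union signal. Both grids go through the identical detection
and summary path as real channels, tagged `Min`/`Max`; TIF positivity is
the same rule with a per-channel `mark_count` override (typically 3 on the
Min channel versus 10 for single-channel damage). min + max = a + b holds
exactly in integer arithmetic and is asserted in the tests. No
correlation-based metrics (Pearson/Manders) are computed.

## Outputs

One summary CSV per evaluated channel (`out_green.csv`, `out_red.csv`,
`out_Min.csv`, `out_Max.csv`), header
`filename,average_intensity,number_selected_nucleus,number_total_nuclei,ratio_selected_nucleus`,
one row per input image in lexicographic filename order. Per image, a
folder named after the file holds `nucleus_<label>.csv` with one row per
focus (`channel,focus_id,area_px,min_intensity,max_intensity,mean_intensity`).
`number_selected_nucleus` is a count; the [0, 1] quantity is
`ratio_selected_nucleus`. Zero-nuclei images get an empty ratio cell —
distinguishing "no cells" from "no damage" — rather than 0 or NaN. Ratios
and intensities are printed to 6 decimals with Unix newlines and UTF-8, so
identical runs byte-reproduce the tree; there is no randomness anywhere in
the analysis path. Each run echoes its full configuration to
`config.yaml` and its decisions (role fallbacks, skipped files) to
`run.log` in the output folder.

## Synthetic scenes

The generator renders what the pipeline consumes: filled ellipses
(nuclei) on a uniform background, truncated Gaussian spots (foci, support
6σ so ground truth stays local to a nucleus), optional Gaussian and/or
Poisson noise applied last under a fixed seed. Default geometry is a
512×512 field at 0.312 µm/pixel — a 40× confocal scale where the
100 µm² filter separates a 20-px-radius disk (≈122 µm²) from a
12-px-radius one (≈44 µm²). Randomised scenes draw 3–10 elliptical nuclei
(aspect ratio ≤ 1.5, areas 120–400 µm², boundary separation ≥ 8 px so
dilated masks cannot bridge), a sub-100 µm² distractor, and 0–15 foci per
nucleus (peak 30 000 over background 1 000, σ 1.5 px, ≥ 6 px apart, ≥ 6 px
inside the boundary). Colocalization scenes duplicate a chosen fraction of
green spots at identical red positions and place the remainder ≥ 6 px
away.

What passing on these scenes does **not** show: real nuclei have textured
chromatin, intensity gradients, out-of-focus haze and overlapping debris;
real foci vary in size and brightness and form clusters. The fixtures
validate the algorithmic contracts (thresholds, splitting, counting,
classification arithmetic, file formats), not biological accuracy on any
particular microscope's data — parameters should still be sanity-checked
per experiment against a few manually scored fields.

## Numerical and design notes

- Binarisation is strict (`intensity > t`); the Huang bin-edge mapping is
  adjusted for integer data so every value in a background bin tests as
  background.
- Watershed tolerance 2 px (distance-map units) and 8-connected
  components / 4-connected flooding mirror the common ImageJ binary
  watershed behaviour.
- Problem sizes in the test suite (512×512 fields, 25 seeded scenes per
  recovery check, 200 histograms and 20 images against brute-force
  oracles) were chosen to exercise every rule exhaustively while keeping
  the full suite under a minute of compute.
- CZI reading dispatches to `aicsimageio` when installed; without it, CZI
  files raise a clear error suggesting TIFF conversion. All analysis code
  is format-agnostic past `read_image`.

## Known limitations

No z-stacks (single-plane contract), no declumping of merged foci, no
shading/flat-field correction, no GUI, no statistical comparison across
conditions — the tool produces per-image quantifications; downstream
statistics belong to the experiment analysis.
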