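# Methods

## The measurement model

The assay images one larval CNS hemisphere per stack on a spinning-disc
confocal (20×/0.8 NA, 16-bit sCMOS, 0.44 µm optical sections). Two channels
are quantified: GFP, expressed cytoplasmically in every cell that carries
the sensor, and mCherry, targeted to the nucleus and produced only where the
sensor is transcriptionally active. A Hoechst channel may be present as a
QC stain; it is carried through the data model but never thresholded or
quantified.

The pipeline is deliberately simple and deterministic, mirroring a typical
FIJI particle-analysis workflow:

1. **Threshold** each quantified channel. Default: Otsu's method on the
   whole stack's histogram (one level per channel per stack), foreground
   defined by the strict inequality `intensity > level`. A per-slice mode
   and a fixed-level override exist in config.
2. **Segment punctae** per z-slice: 2D connected components
   (8-connectivity by default, 4 available), discarding components smaller
   than `min_area_px` (default 100 px, i.e. 32.5 µm² at the default
   0.325 µm²/px calibration; the rule is inclusive, a 100-px object
   survives). Component ordering is deterministic: by slice, then by
   top-left-most pixel in row-major order. Intensity summaries are always
   taken from the unthresholded image.
3. **Cross-measure**: each puncta's pixel set is evaluated in the *other*
   channel on its own z-slice. A puncta is "positive" when at least
   `tau_overlap` (default 0.1) of its pixels fall inside the other channel's
   thresholded mask. The mean intensity of the other channel over the
   puncta is also recorded, and an alternative `mean_above_threshold`
   positivity rule can be selected; both rules are approximations to an
   unknowable original and the choice is exposed in config.
4. **Summarize per hemisphere**: puncta counts, integrated densities
   (pixel area × Σ intensities over puncta pixels, identical to mean
   intensity × total area in µm² — the identity is asserted in tests), and
   the two object-based proportions. A proportion with zero punctae in its
   denominator is *undefined* and serialized as an empty cell, never as 0,
   because coding 0/0 as 0 would bias group means downward.

Counts are 2D objects summed over slices; no z-linking is performed by
default, since per-slice segmentation is how such stacks are convention-
ally analyzed and keeps one puncta ≈ one cell section. An optional
3D-linked mode (`link_punctae_3d`) merges punctae overlapping by ≥1 pixel
on adjacent slices for users who prefer object counts in 3D.

### Why thresholding has a separability guard

Otsu's method always returns *some* level, even for a channel containing
nothing but background noise — in that case it bisects the noise
distribution and the "foreground" percolates into large spurious
components. The pipeline therefore checks Otsu's effectiveness measure
η = (between-class variance at the chosen level) / (total variance). For a
structureless unimodal histogram η peaks near 2/π ≈ 0.64 (and 0.75 for a
uniform one), while genuinely bimodal reporter channels measure ≳0.8 even
when only a handful of cells are present. Below `min_separability`
(default 0.7) the channel is declared signal-free: the mask is empty, the
level is still reported, and a warning is logged. The guard can be
disabled by setting `min_separability: 0`. Extremely sparse real signal
(roughly a single labelled cell in a full-size stack) can fall under the
guard; inspection of the logged η is advised when zero counts are
unexpected.

## Statistics

- **Two-way ANOVA** (treatment × stage, fixed effects with interaction)
  uses Type II sums of squares, which reduces to the classical balanced
  decomposition when cell sizes are equal; implemented on statsmodels OLS.
- **One-way ANOVA** with all-pairs pooled-variance t post hoc,
  Bonferroni-adjusted `p_adj = min(1, m·p_raw)` over the m pairs — so an
  indistinguishable pair is reported with p capped at exactly 1.0. Post hoc
  runs only when the omnibus p ≤ α.
- **Kruskal–Wallis**: tie-corrected H against χ²(k−1); an all-identical
  response returns H = 0, p = 1 rather than an error. Post hoc is Dunn's
  z on pooled mean ranks (tie-corrected variance) with Bonferroni
  adjustment, implemented in-package.
- **Mann–Whitney**: two-sided; exact by full enumeration of the
  C(n1+n2, n1) rank assignments when n1+n2 ≤ 12 and tie-free, otherwise
  normal approximation with tie and continuity corrections. The reported U
  is the smaller of the two one-sample statistics (U = n1·n2/2 under
  perfect overlap).
- Group summaries are mean ± SEM (sample SD/√n, missing for n = 1).
  Undefined proportions are dropped listwise from the tested response with
  the count logged and reported (`n_dropped`).
- α defaults to 0.05. The statistical unit is one hemisphere stack; the
  `replicate` column is carried for user-side aggregation but no
  mixed-effects modeling of the trial structure is attempted.

## The synthetic generator

`SyntheticSpec` draws `n_cells` cells, placed by rejection sampling with
each cell confined to a single random z-slice and same-slice centers at
least one blurred cell diameter apart, so 2D puncta counts map 1:1 onto
cells. Each cell is GFP-expressing with probability `expressing_fraction`;
expressing cells are mCherry-positive with probability `p_coloc`
(the activation fraction a treatment modulates), non-expressing cells with
probability `p_mcherry_only` (the sub-threshold-sensor population: their
GFP annulus is drawn at `subthreshold_gfp_fraction` of full intensity,
below any sensible threshold, which is what drives the reverse proportion
below 1). GFP is a cytoplasmic annulus (outer soma disk minus nucleus
disk), mCherry a filled nucleus disk. The optics/camera model is
background + structures, per-slice Gaussian PSF blur (`psf_sigma_px`),
Poisson shot noise plus Gaussian read noise, rounded and clipped to the
bit depth. Everything is reproducible from `seed`; cohort generation
derives per-sample seeds from one master seed and embeds a deterministic
UUID in each OME-TIFF so repeated runs are byte-identical.

Default geometry (nucleus radius 6 px → ~113 px nucleus disk, safely above
the 100 px filter; soma radius 10 px; blur σ = 2 px; foreground ≈ 3000
counts over a 100-count background) was chosen to resemble 20× cell bodies
at 0.325 µm²/px with the strongly bimodal histograms this assay produces.
Cross-channel positivity arises naturally from the geometry: blur pushes
the thresholded GFP ring's inner edge over the nucleus boundary, giving
positive cells an overlap fraction ≈ 0.2–0.3 versus exactly 0 for negative
cells, far on either side of the 0.1 default `tau_overlap`.

What the generator does **not** emulate: spatially varying cell density,
depth-dependent attenuation and scattering, autofluorescence, touching or
overlapping somata, multi-slice cell bodies (available as an option via
larger structures but not default), chromatic shift, or a physically
accurate PSF. Passing recovery tests therefore demonstrates that the
measurement chain is correct under its own assumptions, not that real
tissue segments this cleanly; on real stacks, touching cells and
out-of-focus light will make counts threshold-sensitive in ways the
simulation does not probe.

## Numerical conventions and problem sizes

- Foreground is strictly `> level`; connectivity 8; size filter inclusive
  `>= 100 px`; all documented so results are bit-reproducible.
- Quant tables serialize floats at full precision (`repr`) and are read
  back with round-trip float parsing, so write→read is exact.
- Verification sizes: component labeling is checked against a flood-fill
  oracle on all 65 536 binary 4×4 masks and 1000 random 32×32 masks;
  Otsu against exhaustive variance scans on 200 random 8-bit images;
  colocalization recovery on 200-cell, 4×512×512 low-noise stacks across
  activation fractions {0, 0.25, 0.5, 0.75, 1} × 50 seeds; test
  calibration on 2000 null replicates at n = 10/group. These sizes give
  Monte-Carlo standard errors well below the asserted tolerances while
  keeping the default suite fast.

## Known limitations

- Otsu per stack assumes a common background across slices; strong
  bleaching or depth attenuation would argue for `per: slice`.
- The positivity rule (mask overlap ≥ τ) is one of several defensible
  readings of "puncta contains signal"; τ and the alternative mean-based
  rule are exposed precisely because results depend on them.
- Whether two hemispheres of one animal are independent is a study-design
  question; the pipeline treats each stack as one unit and records
  `replicate` for the user's own aggregation.
- No watershed splitting, machine-learned segmentation, registration,
  deconvolution or flat-field correction; inputs are assumed already
  converted to TIFF/OME-TIFF.
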