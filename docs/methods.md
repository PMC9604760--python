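# Methods

## Problem and pipeline

The package quantifies a nuclear immunofluorescence marker (BCL6)
specifically in the glandular epithelium of endometrial sections. The
marker stains both epithelial and stromal cells, so the separation is
morphological, not spectral: stromal cells appear as small isolated
objects, glandular epithelium as connected ring-like structures of much
greater size. The per-section pipeline is

1. extract the grey-level green component of the 8-bit RGB slide
   (marker channel; DAPI counterstain occupies blue);
2. automatic global thresholding — Otsu's criterion, i.e. the integer
   cut `t ∈ [0, 255]` maximising the between-class variance of
   `{levels ≤ t}` vs `{levels > t}`, foreground strictly `> t`, ties to
   the smallest `t`;
3. morphological filtering: erosion (and optionally opening) with a
   structuring element sized between the stromal objects and the gland
   wall thickness, followed by geodesic reconstruction (iterated
   conditional dilation of the filtered image under the thresholded
   mask, 8-connectivity) — opening-by-reconstruction, which deletes
   stroma but restores every surviving gland to its full thresholded
   shape; residual components below a minimum area are dropped;
4. background elimination by multiplying the binary epithelium mask
   with the grey-level channel, and a 256-bin intensity histogram of
   the result.

Sections enter group-level analysis only with ≥ 20 glands (connected
components of the retained mask). Grey level 0 is excluded from the
histograms by default because after multiplication it conflates genuine
zero-intensity epithelium with background; the flag is configurable.

## Group statistics

Per-section histograms are normalized to unit mass (sections differ in
epithelial area) and averaged point by point; the SEM uses the n−1
standard deviation over the n sections of a group. Group curves are
summarised three ways:

- **Percentiles** (p10/p25/p50/p75/p90) of the curve treated as a
  density over grey levels. The CDF is accumulated over mass-carrying
  levels and inverted with linear interpolation between consecutive
  support levels; a point mass therefore returns its own level for
  every percentile. Percentiles are extracted from the smoothed curve
  in the pipeline (smoothing never feeds the tests).
- **Smoothing** by Stineman (1980) rational interpolation on a denser
  grid (default 4× the level grid). The interpolant passes through
  every data point, reproduces straight lines exactly, and suppresses
  the overshoot of cubic splines. Its monotonicity guarantee holds
  when both the ordinates and the chord slopes are monotone; on
  arbitrary monotone data with alternating steep/flat chords small
  bumps are possible — a property of the scheme itself, not of this
  implementation. Slopes are Stineman's circle-based estimates, with
  end slopes extrapolated from the adjacent chord and clamped to zero
  on sign flips.
- **Gaussian fit** `A exp(−(x−μ)²/2σ²)` by least squares
  (`scipy.optimize.curve_fit`), initialised from the curve's moments
  (A = max, μ = mass-weighted mean, σ = mass-weighted sd), at most
  10,000 function evaluations. Non-convergence returns the moment
  estimates flagged `converged=False` with a warning.

Two-group comparisons use the Mann–Whitney U test: exact null
distribution for tie-free samples up to n = 25 per group, otherwise the
tie-corrected normal approximation *without* continuity correction so
that identical samples give p = 1 exactly. The point-by-point variant
compares per-section normalized frequencies at each grey level and
flags p ≤ α (default 0.05). Raw pointwise p-values are reported by
default — the score is descriptive, localising where distributions
differ; a Benjamini–Hochberg option exists but is off by default.
Levels at which every section of both groups has identical frequency
(outside the intensity support) are marked untested with p = 1.

The HSCORE (Σ Pᵢ(i+1)/100 over weak/moderate/intense percentages,
range 0–4) is linked to the pixel measurement two ways: continuous
intensities can be bucketed into the three categories at configurable
grey-level cuts (default 63/127/191, the 8-bit quartiles — observers
judge categories visually, so the cuts are a convention), and each
section's HSCORE is regressed (OLS) on the fitted Gaussian mean of its
own distribution, falling back to the arithmetic mean when the fit
fails. Observer agreement is summarised by mean absolute per-section
difference and Pearson r; the consensus score is the observer mean.

## Synthetic slides and cohorts

The generator renders the features the pipeline's logic depends on and
nothing else. Glands are annuli (outer radius 14–18 px, wall 9–11 px by
default) placed without overlap by rejection sampling (≤ 10,000
attempts); stroma are disks of radius 1–3 px scattered outside the
glands. The separability premise is enforced by construction: stromal
diameter < gland wall thickness, so a disk erosion of radius 4 (default;
stromal radius + 1) deletes all stroma while seeding every gland.
Default slides are 384×384 px with 24 glands, epithelial marker
intensity N(130, 30), stromal N(110, 30), background 8, additive
Gaussian read noise σ = 6, all clipped and rounded to [0, 255]. The
blue channel carries a uniform nuclear speckle in cell regions. Every
slide and cohort is a pure function of its seed; per-section seeds
derive from the cohort seed via `numpy` seed sequences.

Cohorts add two levels of structure: a per-group shift of the
epithelial intensity location, and optional per-section N(0, sd)
location jitter (`between_section_sd`) modelling patient-to-patient
heterogeneity. Simulated observer HSCOREs are the ground-truth
categorised score plus N(0, 0.15) observer noise, clipped to [0, 4].
Distribution-level samplers (`sample_section_distribution`,
`sample_group_distributions`) draw per-section histograms directly —
identical intensity model, no rendering — for simulations where images
add nothing (e.g. the 200-replicate null calibration of the pointwise
test).

For emulating the published group comparisons, the validation suite
uses two regimes, both fixed up front:

- *bright homogeneous cohorts* (the slide defaults above, +40
  grey-level shift, 4–5 sections per group) for segmentation accuracy
  and percentile ordering — the shifted group's p50 exceeds the
  reference group's in ≥ 95% of 50 seeded cohorts;
- *skewed heterogeneous cohorts* (lognormal median 35 grey levels,
  log-σ 0.65 — matching the right-skewed percentile pattern of real
  group curves — +40 median shift, per-section jitter sd 12, n = 5 per
  group) for the spatial pattern of pointwise significance, which then
  concentrates above the reference group's median as reported for
  clinical cohorts. With homogeneous sections the pointwise test flags
  nearly every level in the shifted range instead; both behaviours are
  correct, the difference being between-patient variance.

## What passing tests do and do not show

Synthetic slides have clean annular glands, disjoint compartments,
Gaussian read noise and no illumination gradients, autofluorescence,
out-of-focus blur, tissue folds or touching glands. Passing the
recovery criteria (epithelium IoU ≥ 0.90, ≥ 95% stromal pixel removal
at defaults) therefore validates the algorithmic chain, not performance
on clinical material, where structuring-element sizes and the minimum
gland area must be re-tuned to the acquisition ("appropriate sizes"
are data-dependent by design, exposed in the TOML config).

## Numerical and design choices

- Only 8-bit inputs are accepted; higher depths are rejected rather
  than rescaled since the analysis is defined on 256 grey levels.
  Greyscale inputs are promoted to RGB by replication with a warning.
- Masks: row-major, origin top-left, 0-based; 0 = background,
  255/True = foreground; components and reconstruction use
  8-connectivity so ring walls at arbitrary angles stay connected.
- Erosion and opening are sequential when both radii are positive;
  either may be disabled (radius 0). With both disabled the filter is
  the identity.
- The null calibration of the pointwise test is checked against a
  tolerance of two binomial standard errors with the 200 replicates as
  the unit of information, because grey levels within a replicate are
  strongly correlated through histogram normalization.
- All analysis stages are deterministic; randomness is confined to the
  synthetic module. Pipeline outputs are invariant to input file
  ordering (sections are processed in sorted id order) and the run
  manifest records a configuration hash and library versions.

## Known limitations

- Very dim staining breaks segmentation gracefully but completely:
  when a large fraction of epithelial pixels falls below the automatic
  threshold, ring walls fragment and erosion leaves no seed, so glands
  vanish and sections fall below the inclusion rule. This mirrors the
  documented dependence of the filtering step on image quality.
- No nucleus-level instance segmentation or cell counting: the HSCORE
  bridge treats pixels, not cells, as the counting unit.
- Physical pixel size is not modelled (no scanner calibration); all
  sizes are in pixels.
- Poisson shot noise, pyramidal whole-slide formats and brightfield
  colour deconvolution are out of scope.
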