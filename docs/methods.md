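# Methods

This note records the quantitative model behind `fibrequant`, the defaults
and why they are what they are, and the limits of what the synthetic
validation can show.

## Positive-signal definition and background model

A pixel is *positive* when its intensity strictly exceeds the picture's
background mean + 2 SD. The implicit model is Gaussian background noise, for
which the threshold passes ≈ 2.3% of pure background pixels — the size rule
below, not the threshold, is what rejects that noise floor.

"Background of the picture" is ambiguous when the picture contains bright
structures. Two estimators are provided (`threshold_mode`):

* `naive` — mean/SD over the whole raster. Bright fibres inflate both, so
  the effective threshold drifts up with fibre load.
* `iterative` (default) — one exclusion pass: estimate on the whole raster,
  drop pixels above mean + 2 SD, re-estimate on the remainder. This stays
  close to the whole-picture reading while removing most of the
  signal-driven bias.

SD is the population SD (÷N): the pixels *are* the population of the
picture. Background estimation fails loudly below 100 usable pixels, or when
an exclusion mask leaves under 10% of the raster. Thresholding is
equivariant under positive affine intensity transforms when the background
is re-estimated, so gain/offset changes of the acquisition do not move the
mask.

## Fibre extraction

* **Connectivity** is 8-connected — standard for thin curvilinear
  structures; 4-connectivity fragments diagonal segments.
* **Tissue assignment** is by majority vote of footprint pixels over the
  label map (0 none / 1 myocyte / 2 connective). Unlabelled pixels are
  ignored; exact ties and all-unlabelled footprints go to connective tissue,
  the compartment that carries most innervation.
* **Merging** (the "same fibre" rule): components whose minimum
  pixel-center distance is ≤ 5 µm, in the same tissue, and "sharing the same
  path" belong to one fibre; grouping is the transitive closure. "Same
  path" is operationalised as principal-axis agreement within 30°
  (configurable; `None` disables the gate). Two refinements matter in
  practice:
  * components smaller than 10 px have no stable axis; by default they
    **never** merge (`small_component_policy="exclude"`). The alternative —
    letting tiny components merge on distance alone — is available but
    hazardous: at the designed 2.3% background-pixel rate, an expected ≈ 7
    positive noise pixels fall within any 5 µm radius, so tiny components
    chain transitively into image-spanning false objects.
  * components with axis-length ratio < 1.5 are effectively round, their
    axis direction is noise, and they are treated as orientation-compatible.
    This keeps near-square fragments of a wide fibre mergeable.
* **Size rule**: merged components count as fibres when the maximum Feret
  diameter is ≥ 4 µm *and* the minimum Feret diameter is ≥ 4 µm. Feret
  diameters are measured on the convex hull of the pixel unit squares, so a
  10×10 px block at 0.5 µm/px is 5 µm wide exactly. Feret measures are
  orientation-free, unlike bounding boxes. The rule is applied **after**
  merging (so fragments of one fibre are not discarded piecemeal); applying
  it before merging is available via `size_filter_before_merge`.
* Components touching the image border are retained; no edge-exclusion rule
  is imposed.

## Colocalization

Marker masks use the same per-channel mean + 2 SD threshold. By default each
marker mask is additionally cleaned with the same 4 µm × 4 µm Feret rule
(no merging): a *signal* has a minimum physical size regardless of channel.
This matters quantitatively — against raw thresholded masks, a fibre
footprint of ≥ ~100 px overlaps at least one false-positive noise pixel with
probability ≈ 1, which would saturate every flag; with size-cleaned masks
the false-flag rate is negligible. The raw behaviour is available
(`marker_size_filter=False`), as is the overlap depth (`min_overlap_px`,
default 1 px = any overlap).

Combinations are non-exclusive by default ("SP/NR2B" = expresses both,
NGF unconstrained), which makes triple ≤ pairwise ≤ single a structural
invariant. The exclusive partition reading is a switch
(`exclusive_combinations`).

## Aggregation

Per image and tissue: density = count / tissue area (mm²), frequency =
expressing / total fibres. A tissue absent from an image yields an
*undefined* density, and zero fibres yield *undefined* frequencies —
undefined propagates as missing, never as zero, because conflating "no
fibres seen" with "0% expressing" biases frequencies downward. Participant
summaries are means over the defined images only; participants lacking a
tissue entirely drop out of that tissue's stratum. The combined scope pools
counts and areas (total count / total area); averaging the two per-tissue
densities instead is a switch (`combined_density="mean"`). The
tissue-percentage split divides the cohort-average per-tissue count by the
cohort-average total count. Cohort tables use linear-interpolation
percentiles (the common type-7 rule, the default of mainstream statistics
environments) for median and IQR.

## Statistics

* Mann-Whitney U, two-sided, for tissue (connective vs myocyte) and sex
  comparisons of density and the 7 frequencies — 8 tissue tests and 24 sex
  tests (combined + per-tissue scopes), judged at α = .05. Exact p-values
  by enumeration of rank splits for tie-free samples with n₁+n₂ ≤ 14 (or on
  request); with ties, exact mode enumerates group assignments conditional
  on the observed tie pattern; otherwise the tie-corrected normal
  approximation with continuity correction. Completely tied samples return
  U = n₁n₂/2, p = 1. The tissue comparison is unpaired by design fidelity
  even though both tissues come from the same participants; a paired
  Wilcoxon signed-rank alternative is provided (`tissue_test="wilcoxon"`).
* Spearman rank correlation (tie-aware mid-ranks) of age against each of
  the 7 combined frequencies, per sex — 14 tests. p via the t
  approximation; a permutation option (≥ 10⁴ draws) is available and is
  used for n < 15 when enabled. These form the Bonferroni family of 7
  expression combinations: each is judged at α/7 = .00714 (reported .007).
  Applying the correction to the correlation family only, and the
  Mann-Whitney tests at .05, is the reading under which all the planted
  effects and thresholds are coherent.
* Two-sided p throughout; sidedness is a convention, not an inference.

## The synthetic generator

What it emulates, per image: a label map of blob-shaped myocyte regions
(smoothed white noise, σ = 25 µm, thresholded at the exact myocyte
quantile) in a connective matrix; fibres as straight capsules
(length 10–25 µm, width 6–9 µm) placed entirely within one compartment with
≥ 8 µm clearance between distinct fibres (so truth identity is unambiguous
under the 5 µm merge rule); 20% of fibres split in the middle by a
2.5–4 µm gap to exercise merging; rendering at `signal_offset_sd` (default
5) background-SDs above the background mean, Gaussian PSF blur
(σ = 0.5 µm), additive Gaussian noise N(100, 10) clipped at 0.

Cohort-level defaults are calibrated to healthy adult masseter muscle:
60 participants (30 women, 30 age-matched men), 4 images each, ages
N(28, 10) years truncated to [18, 60]; densities 400 (connective) and 230
(myocyte) fibres/mm²; connective tissue 60% of the frame, which puts ≈ 72%
of fibres in connective tissue. The per-tissue 8-state marker models (the
joint distribution over SP × NR2B × NGF) encode an SP-rich sensory
phenotype in connective tissue and an NR2B/NGF-rich putative motor
phenotype near myocytes; they were derived by inclusion–exclusion from
representative median combination frequencies in men. Women differ by
`sex_effect` (+0.02 on each SP-containing state, ≈ +8 percentage points of
total SP expression) and by `age_slope` (−0.0015/yr on the triple-positive
state, centred at the reference age of 28 — the cohort mean). With ~80
fibres per participant the binomial estimation noise on a participant's
triple-positive frequency is ≈ 0.027, so this slope induces an observable
age correlation of roughly −0.4 to −0.5 in women. Adjusted state vectors
are clipped to [0, 1] (with a warning) and renormalised.

A pixel-free path (`simulate_summary_cohort`) samples the same Poisson
counts and multinomial marker states directly into participant summaries
through the identical aggregation formulas; it is what makes
hundreds-of-cohorts calibration studies affordable (a rendered cohort of
240 sections takes minutes; the pixel-free path takes milliseconds).

What the generator does **not** emulate: curved or branching fibres,
spectral bleed-through, uneven illumination, optical vendor PSFs, 3D
stacks, between-participant random effects in density or expression, or
histology-derived label noise (the pipeline consumes a label map; it never
derives one from haematoxylin images). Passing the validation suite
therefore demonstrates correctness of the *rules* (threshold, merge, size,
overlap, aggregation, tests) under a clean forward model — not robustness
to real-microscopy artefacts.

## Validation sizes and numerical choices

The shipped checks run at: 20 sections (512×512, 0.5 µm/px) for detection
recall/precision; one rendered cohort of 60×4 sections for parameter
recovery (median densities within 15%, frequencies within ±0.05,
expectations set by Poisson/binomial sampling error at these sizes); 300
replicate pixel-free cohorts for null calibration of the sex and age
families (each test's rejection rate within 3 Monte-Carlo SEs of nominal —
the tissue family is excluded because its difference is planted by
design); 100 cohorts for power against a stronger planted age slope
(−0.005/yr), where the women's test must fire in ≥ 80% of cohorts while the
men's stays at its nominal level. Exhaustive oracles back the core
algorithms: flood fill for components, all-pairs distance + union-find for
merging, rank-split enumeration for exact Mann-Whitney, 10⁵ permutations
for Spearman, corner-point sweeps for Feret diameters.

Degenerate inputs are defined, not patched: empty masks give empty fibre
sets; constant rasters give SD 0 and an empty mask (nothing *strictly*
exceeds the threshold); zero-variance samples make Spearman an error;
empty groups make a battery entry an error record while the battery
continues. All coordinates are 0-based (row, col); distances are between
pixel centers; seeds fix every stochastic path bit-identically.

## Known limitations

* The pipeline counts fibre *profiles*; it cannot distinguish nerve endings
  from fibres of passage, and no skeletonization or diameter histogram is
  attempted.
* The unpaired tissue comparison ignores the within-participant pairing and
  is therefore conservative in power; the paired alternative is provided
  but non-default.
* Whether the 4 µm rule precedes or follows merging, and whether background
  is estimated per channel or once per image, are genuinely open
  conventions; the defaults (after merging; per channel) are switches, not
  facts.
* Exclusive-combination reporting changes what the 7 columns mean; both
  readings are supported, and only the non-exclusive one guarantees the
  subset-monotonicity invariant.
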