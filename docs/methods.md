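# Methods

## Scope and model

`iterquant` models an arrayed protoplast base-editing screen as two coupled
measurement processes:

* an **imaging process**: round, wall-less protoplasts in dilute suspension,
  imaged per well as several fields of multi-channel Z-stacks. Transfection
  is a per-cell Bernoulli event at the well's transfection rate; editing is a
  second Bernoulli event, conditional on transfection, at the well's editing
  rate. Transfected cells express nuclear mCherry, edited cells additionally
  nuclear GFP. The per-well editing efficiency is therefore a binomial
  proportion estimated from the GFP⁺/mCherry⁺ ratio.
* a **sequencing process**: each sample is a mixture of amplicon haplotypes
  (reference, substitution alleles, at most one indel per haplotype) observed
  through reads with independent per-base substitution errors and Gaussian
  Phred qualities.

Both processes carry exact ground truth, which is what makes the pipeline
testable: every segmentation, gating or quantification step can be compared
against the generating labels.

## Synthetic plates

The generator reproduces the acquisition geometry of a high-content screen:
96 wells, 9 fields per well, 7 Z-planes, 4 channels. Numbers that the
geometry does not fix were chosen once as follows:

| parameter | default | rationale |
| --- | --- | --- |
| field size | 512 × 512 px | keeps a rendered field ~4 MB while leaving ≥10 cell diameters per side |
| cell radius | 20 ± 2.5 px | protoplasts are 30–40 µm; ~0.8 µm/px at a 20× objective scaled to the field size |
| nucleus radius | 7 ± 1 px | nuclei are roughly a third of the cell diameter |
| cells per well | 150 | a dilute suspension; per-field density is a free parameter of the assay, and statistics needing ~1000 transfected cells/well use the counts-level path (below) |
| background / noise | 200 / 15 (16-bit counts) | dark fluorescence background with mild read noise |
| nuclear reporter foreground | 3000 ± 500 | ~15× over background, typical for strong transient expression |
| chlorophyll foreground | 1500 ± 250 | autofluorescence is dimmer than the reporters |
| vignetting strength | 0.3 | strong enough that uncorrected gating would fail at field corners |
| debris per field | 2 | exercises the roundness filter |

Design choices:

* **Non-overlap.** Cells are placed by rejection sampling with a minimum
  centre distance of 2.2× the mean radius (and a border margin), emulating a
  dilute suspension and making truth matching unambiguous. Debris streaks
  (elongated ellipses with chlorophyll-like intensity, no nuclear signal) are
  kept clear of cells for the same reason; debris may overlap other debris.
* **Z structure.** Object intensity follows a Gaussian profile across planes
  (σ = 1.5 planes) peaking at a random focal plane. This makes
  maximum-intensity projection meaningful without modelling optics.
* **Vignetting** is a radially symmetric multiplicative falloff applied to
  signal and background alike, giving the flat-field correction something
  real to remove.
* **Seeding.** One master seed; each (well, field) gets a counter-derived
  `SeedSequence` substream, so regenerating any single field reproduces it
  exactly regardless of what else is simulated. `simulate_truth` draws from
  the same substreams without rendering pixels — the counts-level and
  image-level simulations agree cell for cell. Statistical properties that
  need ~8000 transfected cells per plate use this path; rendering them as
  images would add nothing but pixels.
* Control wells (`control=True`) force transfection and editing rates to
  zero: no DNA is delivered.

Simulated reads are single, full-amplicon, forward-orientation sequences
(optionally reverse-complemented with a configurable probability to exercise
strand handling); paired-end structure and adapters are out of scope, as real
pairs are assumed pre-merged. `deterministic_counts` allocation gives each
haplotype exactly `round(fraction × n)` reads (any rounding drift goes to the
most abundant haplotype) so tests can assert exact percentages;
`multinomial` allocation gives sampling noise.

## Imaging pipeline

* **Projection**: maximum intensity over Z — robust for sparse bright nuclei
  and insensitive to the focal-plane position.
* **Flat-field correction**: each projected channel is divided by a
  Gaussian-smoothed copy of itself (σ = 32 px, nearest-edge padding),
  repeated twice; the second pass removes most of the curvature bias the
  smoothing itself introduces. The output is rescaled to preserve the mean.
  On a pure synthetic vignette this reduces the coefficient of variation by
  more than 10×.
* **Cell segmentation (wheat mode)**: smoothed chlorophyll (σ = 2 px), Otsu
  threshold, hole filling, distance-transform watershed. Watershed seeds
  require a distance-transform depth of at least half the minimum credible
  cell radius (`0.5·√(min_area/π)`), which stops thin debris from being split
  into round-looking fragments. Regions failing the filters are flagged, not
  deleted.
* **Roundness** is 4π·Area/Perimeter², with the Crofton perimeter estimate
  and a cutoff of 0.8 (a digitized disc measures ≈1.0, a 4:1 ellipse ≈0.55).
  The cutoff, like all parameters here, is configurable.
* **Nucleus segmentation**: connected regions of the thresholded pixelwise
  maximum of mCherry and GFP (union semantics, so a GFP-only nucleus is still
  found), filtered by area (20–2000 px²) and by contrast: a candidate's mean
  intensity must exceed 1.5× the image median, which rejects the spurious
  regions Otsu produces on featureless or halo-contaminated backgrounds.
* **Gating**: each protoplast is assigned at most one nucleus by centroid
  containment, ties broken toward the brighter mean mCherry (deterministic
  and order-independent). `is_transfected ⇔ mean nuclear mCherry ≥ T_mCherry`
  and `is_gfp_positive ⇔ is_transfected ∧ mean nuclear GFP ≥ T_GFP` (nested
  gating; the independent GFP gate is also recorded for co-transfection
  ratios). In maize (etiolated) mode there is no chlorophyll body: the nuclei
  are the analysis units directly.
* **Gate thresholds** default to the 99.9th percentile of reporter-channel
  pixel intensity in the plate's negative-control wells, times a 1.2 margin.
  The pixel quantile is used rather than per-nucleus statistics because
  control wells contain no transfected nuclei to measure; the margin keeps
  background-level nuclear means — which straddle the raw quantile,
  especially in low-noise data — on the negative side, while genuine nuclear
  signal sits an order of magnitude above. Fallbacks: per-image Otsu, or
  fixed values.
* Cells touching the field border are excluded from counting (standard
  high-content practice); pixel coordinates are 0-based with the origin at
  the top-left; percentages are reported to one decimal alongside the raw
  value.

## Plate statistics

Replicate aggregation uses the **mean of per-well efficiencies** as the
primary summary (wells are the biological replicates; published count pairs
such as 57.3% for n = 1908/3316 match per-well averaging, not the pooled
ratio of 57.5%), with the pooled-count ratio emitted alongside.

Group comparisons mirror the tests used for such panels: one-way ANOVA with
Tukey's HSD, Kruskal–Wallis with Dunn's post-hoc test (Holm-adjusted; Dunn's
z uses the tie-corrected rank variance), pairwise Mann–Whitney, and the
two-proportion z test (pairwise Holm-adjusted, chi-square omnibus). All at
α = 0.05, with a compact letter display derived by insert-and-absorb.
Dunn's test is implemented directly from the rank statistics; Tukey and the
adjustment machinery come from statsmodels.

The **detection limit** of a replicate design is estimated by Monte Carlo:
for each candidate editing rate on a log grid (0.05–10%, 20 points), simulate
the treated wells (replicates × cells per well, background + rate) against
re-simulated control wells, apply a one-sided two-proportion z test at
α = 0.05, and report the smallest rate reaching 80% power, with its
simulation standard error (2000 replicates per grid point, seeded). With zero
background and 8 × 1000 transfected cells this lands well below 1%,
consistent with a design able to flag a handful of GFP⁺ cells; the threshold
is non-increasing in the number of replicates.

## Amplicon quantification

* **Demultiplexing** matches the 5′ 6-nt prefix against the sample indices
  (default max mismatch 0; indices must be pairwise separated by more than
  twice the allowance) and trims it. Assigned + unassigned = input, always.
* **Quality filter**: mean Phred ≥ Q30, inclusive at the boundary.
* **Alignment** is semi-global (free end gaps on the amplicon only): match
  +2, mismatch −1, gap open −5, gap extend −1, both orientations scored,
  floor 0.8× the perfect match score of the read. Biopython's
  `PairwiseAligner` does the dynamic programming; tests check its scores
  against an independent hand-written affine DP on small cases.
* **Windows.** With spacer length L, window size w and center offset c, the
  scored positions are `[p_c − ⌈w/2⌉ + 1, p_c + ⌊w/2⌋] ∩ [1, L]` where
  `p_c = L + c`. Defaults (w = 10, c = −12) give positions 4–13 for a 20-nt
  Cas9 spacer — the canonical base-editing window — and 7–16 for a 23-nt
  Cas12a spacer. The indel window uses the same construction centered at the
  cleavage position `L + offset` (offset −4 for Cas12a). The exact center
  convention of upstream tools is not uniquely documented; this formula is
  the package's fixed, documented choice.
* **Classes.** A read with an indel overlapping the indel window is an
  indel-class read (an insertion overlaps if either flank of its junction is
  in the window); otherwise it is substitution-only if it carries any
  non-reference base at a window position, else unmodified. The three classes
  partition the passing reads exactly. Per-position substitution percentages
  are computed over reads that are gap-free at that position and not in the
  indel class.
* **Numbering** is 1-based 5′→3′ along the protospacer for both nuclease
  classes; because Cas9's PAM is 3′ and Cas12a's is 5′, this is "PAM-distal
  position 1" for Cas9 and "PAM-adjacent position 1" for Cas12a. Each table
  carries the applicable label. For minus-strand protospacers, read bases are
  complemented into spacer sense before comparison.
* **Alleles** group reads by their window haplotype string (deletions as
  `-`, uncovered positions as `.`, in-window insertions appended as `+SEQ`),
  sorted by count, ties by sequence.
* **Zygosity**: WT below 25%, heterozygous for rates in [25, 70], homozygous
  above 70. Both boundaries belong to the heterozygous class — "between 25
  and 70" is read inclusively, "higher than 70" exclusively.
* **Spacer mismatch annotation** labels positions 1–8 (PAM-adjacent,
  Cas12a) as seed and the remainder distal, for homeolog off-target
  bookkeeping in polyploid genomes.
* Multiplex panels assign each read to the amplicon with the best alignment
  score, requiring a 10-point margin over the runner-up.

## What the simulations do and do not show

The generator produces well-separated discs with clean nuclear signal and
Gaussian noise. Passing tests therefore demonstrate the correctness of the
bookkeeping — segmentation geometry, gate logic, count nesting, window
arithmetic, statistical calibration — under the stated model. They do not
demonstrate robustness to properties real protoplast images have and the
model lacks: overlapping or lysed cells, chloroplast texture inside the cell
body, cytoplasmic reporter leakage, focus drift, or optical PSF blur.
Likewise the read simulator's i.i.d. substitution errors do not emulate
homopolymer indel errors or quality-correlated error bursts. Parameters are
exposed so harder conditions can be simulated, but the defaults are the
tested conditions.

## Numerical and degenerate-input conventions

* Empty fields segment to zero regions (not an error); wells with no
  detected cells summarize to zero counts with a warning; efficiencies with
  zero denominators are NaN-flagged and excluded from aggregation with a
  warning.
* Constant (featureless) images short-circuit Otsu thresholding to "no
  foreground".
* Flat-field division floors the background estimate at a small epsilon.
* Negative radius/intensity draws in the generator are resampled, never
  rendered.
* Haplotype fractions must sum to 1 within 1e-9; deterministic read counts
  always sum exactly to n.
* Tie-breaks (nucleus assignment, allele ordering) are deterministic so that
  identical inputs yield byte-identical outputs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on simulated data
regenerated at run time: single 512-px fields of 50–60 cells for imaging
checks, counts-level plates of 8 wells × 2000 cells for rate recovery,
2000 Monte-Carlo replicates per grid point for the detection limit, and read
sets of 40–1000 reads for the sequencing checks. These sizes keep any single
check in the seconds range while leaving the binomial error bands (3 SE)
narrow enough to be informative.
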