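# Methods

## Measurement model

Q-FISH on formalin-fixed tissue sections yields, per nucleus, an
integrated telomere probe signal T (Cy3) and an integrated centromere
probe signal C (FITC). Both are proportional to the underlying repeat
content times an unknown slide-wide factor g (hybridization efficiency,
exposure, section thickness), so the per-nucleus ratio

    TCR = T / C

is a relative telomere-length estimate that is robust to nucleus
truncation by sectioning (which removes telomeres and centromeres
proportionally) but still carries any *channel-specific* slide factor.
A cell block of a cultured fibroblast strain, mounted on the same slide
and processed identically, shares those factors; dividing each tissue
TCR by the mean cell-block TCR gives the normalized TCR

    NTCR = TCR / mean(TCR_cellblock),

in which every slide-wide multiplicative gain cancels exactly. The
package verifies this invariance on noise-free phantoms to machine
precision (gains 0.5–5 leave every NTCR unchanged while raw TCRs scale
linearly). The cell-block strain has a Southern-blot-measured telomere
length of 8.64 kbp at the population-doubling level used, so
`estimate_absolute_length_kbp` maps NTCR to kilobase pairs; this is a
calibration-anchored estimate, not an independent measurement.

The relative telomere length (RTL) of one cell type in one patient is
the arithmetic mean NTCR over 110–120 nuclei (`compute_rtl` enforces
the minimum and takes a seeded uniform subsample when more are
available; the original selection protocol is unstated, so the choice
is explicit and logged).

### Image processing

* Segmentation: Gaussian smoothing (σ = 1 px) → Otsu threshold → hole
  filling → distance-transform watershed seeded from local maxima
  (minimum peak separation 5 px) → area filter (30–2000 px) →
  border-touching nuclei removed. Constant planes yield zero labels
  rather than an error.
* Background: per channel, the median intensity outside all nuclei and
  outside lipofuscin-flagged pixels — robust and deterministic.
* Integration: per nucleus, Σ max(I − background, 0) over the mask
  minus lipofuscin pixels. Nuclei with non-positive centromere signal,
  or fully covered by the lipofuscin mask, are dropped and counted in a
  QC log. The positive-part correction is exact on noise-free images;
  on noisy images it adds a small positive bias proportional to mask
  area, which is shared across nuclei and negligible at realistic
  signal-to-background (see *Phantom realism* below).

### Cell-type assignment

ZR cytoplasm is packed with lipofuscin, an autofluorescent pigment
bright in both probe channels ("yellow"). The classifier scores each
nucleus by the fraction of perinuclear-ring pixels (ring width 3 px)
jointly above per-channel thresholds set at background median + 6·MAD,
then applies a deterministic cascade:

1. lipofuscin score ≥ τ_ZR (default 0.15) → ZR;
2. centroid past the cortex/medulla boundary and eccentricity ≤ 0.7
   (chromaffin nuclei are regular) → chromaffin;
3. outer cortex band with local nucleus density ≥ 4·10⁻⁴ px⁻²
   (ZG cells are small and densely packed) → ZG;
4. otherwise ZF.

An undefined score (empty ring at the image border) or missing layout
priors yields `unknown`. The original identification was by eye; this
cascade is a documented stand-in, evaluated only on phantoms, where
per-zone recall exceeds 0.9 at the defaults. Ground-truth labels can be
passed through directly when testing downstream statistics in
isolation.

## IHC quantification

The published analysis used proprietary multispectral unmixing and
trained cell classifiers. The package substitutes deterministic
Beer–Lambert color deconvolution: OD = −log₁₀(I/white) per RGB channel,
projected onto three unit stain vectors — the standard published
hematoxylin (0.650, 0.704, 0.286) and DAB (0.269, 0.568, 0.778)
vectors, and the Fast Red vector (0.214, 0.851, 0.478) for Vector Red.
Cells are segmented on the hematoxylin OD map with a fixed-width (3 px)
cytoplasmic ring grown by label expansion. Positivity applies the
published thresholds to the **compartment mean OD** of each cell, with
the boundary inclusive (mean OD = threshold counts positive; the
original OD scale and compartment convention are unstated, so both
choices are documented here and configurable):

| run | marker → chromogen/compartment | threshold |
|---|---|---|
| CytB5/CgA | CytB5 → DAB cytoplasm | 0.06 |
| Ki-67/CytB5 | Ki-67 → DAB nucleus; CytB5 → Vector Red cytoplasm | 0.2; 0.3 |
| CYP17A1/CgA | CYP17A1 → DAB cytoplasm | 0.09 |

CgA (Vector Red, threshold 0.3 — our default; the source used it only
to mask the medulla) marks chromaffin cells, which are excluded from
cortical totals. Counts pool exactly three images per patient
(configurable). The Ki-67 index is 100 × (CytB5⁺ ∧ nuclear-Ki-67⁺) /
CytB5⁺.

## Statistics

`mann_whitney` mirrors the two-branch behaviour of the legacy software
used for the original analysis (GraphPad Prism 5):

* **exact** (tie-free pooled sample): the permutation distribution of
  U is built by the count recurrence N(n₁,n₂;u) = N(n₁−1,n₂;u−n₂) +
  N(n₁,n₂−1;u); the two-sided p doubles the smaller tail and caps at 1.
  Equivalence with full enumeration over all C(n₁+n₂,n₁) assignments is
  asserted bitwise for all n₁,n₂ ≤ 6 over 200 random datasets.
* **approx_cc** (ties present): z = (|U − n₁n₂/2| − 0.5)/σ with the
  pooled tie-corrected variance σ² = n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))];
  this matches scipy's asymptotic continuity-corrected branch exactly
  and is what reproduces the cohort's tied-data p-values (0.9416,
  0.0007, 0.0094) to four decimals.
* **forced exact with ties**: full enumeration with midrank U. The
  cohort's RTL comparisons are run this way because the printed
  per-patient values are 2-decimal roundings of continuous NTCR means —
  the rounding manufactures ties (e.g. two 0.95 values in one group)
  that the underlying data did not have; enumeration coincides with the
  recurrence when no ties exist. This choice reproduces the printed
  0.0012 for the women's ZR comparison.

Auto mode selects exact iff the pooled sample is tie-free. Under the
null (identical lognormal groups, n = 7 vs 10) the achieved size of the
exact branch at α = 0.05 is 0.0431 (discreteness of the permutation
distribution); simulated rejection rates land within 0.04–0.06, and
power under the male ZR effect (means 1.10 vs 0.61, SDs 0.14/0.10)
exceeds 0.99.

Wilcoxon signed-rank drops zero differences and uses the exact W⁺
distribution for n ≤ 25 without ties (sign-pattern enumeration with
midranks for small tied samples, Gaussian with continuity and tie
correction otherwise). Kruskal–Wallis H and its χ² p come from scipy
(tie-corrected); Dunn's pairwise z uses the pooled-rank variance with
tie term and Bonferroni multiplication. Spearman is the Pearson
correlation of midranks with the t-based p (scipy), with zero-variance
inputs flagged undefined.

Disease durations are parsed from their printed dialects ("15 h",
"12-13 h" → midpoint, "46 days", "3 months", "1 year") with explicit
conventions: 1 day = 24 h, 1 month = 30 days, 1 year = 365 days. The
conventions are configurable because the original conversion is
unstated; the duration–RTL Spearman coefficients therefore reproduce
the published conclusions (non-significance) but not necessarily the
printed p-values to all decimals.

## Synthetic slides

The phantom generator renders what the analysis *assumes* about the
data, not what tissue looks like:

* horizontal bands capsule/ZG/ZF/ZR/medulla (default fractions
  0.05/0.16/0.32/0.27/0.20 of image height), nuclei as non-overlapping
  ellipses placed by rejection sampling (≥ 2 px separation, capped
  attempts; an optional touching-pairs mode renders adjacent circular
  nuclei to stress watershed splitting, default off);
* per-nucleus telomere content drawn lognormally with zone medians
  defaulting to the published control-group zone means expressed
  through the 8.64 kbp anchor (ZG 7.17, ZF 5.88, ZR 9.50, chromaffin
  6.22 kbp) and geometric SD 1.18; the content is distributed over
  8–20 discrete Cy3 spots strictly inside the mask, so the noise-free
  in-mask integral equals truth × gain exactly;
* centromere content lognormal (median 8000 a.u., geometric SD 1.10),
  spread uniformly over the mask;
* lipofuscin as perinuclear granules bright in both channels, confined
  to ZR and strictly extranuclear — the ZR identification cue and a
  controllable contamination stressor;
* Poisson photon noise on expected counts followed by additive Gaussian
  read noise (SD 2 counts), both switchable off;
* a same-slide cell-block field of constant 8.64 kbp content sharing
  the tissue gains.

**Phantom realism.** Intensities are in arbitrary camera counts; the
scale (1000 a.u. per kbp against a background of 20 counts/px) puts
FISH spots far above background, as any usable acquisition would, so
the positive-part background correction contributes ≲ 3% bias. What
the phantoms deliberately omit: overlapping/touching nuclei beyond the
optional pairs mode, autolysis, sectioning artifacts, intra-zone
gradients, and any H&E appearance. Passing phantom tests therefore
demonstrates correctness of the measurement chain under the stated
model, not performance on real tissue.

**Recovery metrics.** NTCR estimates the telomere/centromere *content
ratio* of each nucleus; phantom recovery is scored against that ratio
(per-slide Spearman > 0.9, observed ≈ 0.99, and per-zone RTL rank order
agreeing with the realized truth in ≥ 95% of 40 replicates). Against
telomere content alone the correlation is additionally capped by the
configured independent centromere variability (≈ 0.9 at defaults) —
that ceiling reflects the phantom's biology, not measurement error.
The published absolute RTLs are not reproducible (the specimens are
unavailable); truth recovery on phantoms substitutes for them.

The IHC phantom composes stain concentration maps (nuclear hematoxylin
OD 0.7, ring chromogen OD 0.45/0.6 for positives, 0.01 for negatives)
through the Beer–Lambert model into 8-bit RGB; per zone,
round(fraction × n) cells are positive, so configured proportions are
recovered exactly on noise-free renders. Unmixing round-trip error is
bounded by 8-bit quantization (mean |ΔOD| ≤ 0.02, observed ≈ 10⁻³).

The synthetic cohort generator draws per-patient RTL-like values from
lognormal distributions parameterized by arithmetic mean and SD
(matched by moment inversion), with the published male group means/SDs
as defaults, and emits tables in the fixture CSV schema.

## Numerical and design choices

* Coordinates are 0-based pixel centers, row-major; label maps are the
  single source of nucleus geometry.
* Exact-branch enumeration is refused above 500,000 assignments;
  two-sided p-values are capped at 1; all-identical samples give p = 1
  with a degenerate flag rather than an error.
* Group summaries use the n−1 sample SD, undefined for n = 1. The
  printed group SDs of the source tables derive from unrounded raw
  data and are not reproducible from the 2-decimal printed values
  (recomputation gives e.g. 0.145 where 0.14 is printed), so only the
  means are asserted.
* Missing serum values ("N/A" cells) stay missing and are excluded
  pairwise per test; they are never imputed or zero-filled.
* All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; identical (config, seed) pairs reproduce byte-identical
  images, tables and reports. Run outputs carry a MANIFEST with SHA-256
  content hashes.

## Known limitations

* The segmentation/background stand-in is validated on phantoms, not
  against the original proprietary pipeline; no bit-compatibility is
  claimed.
* The rule-cascade classifier needs layout priors (capsule at the top)
  and breaks on tangentially cut or fragmented cortex.
* Spot-level telomere analysis, 3-D stacks, telomerase activity and
  single-telomere assays are out of scope.
* Dunn's adjusted p-values use Bonferroni multiplication; no reference
  values exist in the source tables to compare against.
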