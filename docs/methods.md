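# Methods

`sipbiofilm` implements the image- and assay-analysis layer of a
stable-isotope-probing (SIP) experiment on a phototrophic biofilm: a
filamentous cyanobacterium (the sole autotroph) plus attached and distal
heterotroph cells, pulse-labeled with H¹³CO₃⁻ and either ¹⁵NO₃⁻ or ¹⁵NH₄⁺,
imaged by NanoSIMS, and characterized in bulk by IRMS, qPCR and
metaproteomics.  This note records the models, defaults and numerical
choices, and what the synthetic validation does and does not demonstrate.

## Delta notation and the count-to-ratio model

All isotope content is expressed in standard delta notation,

    δ = (R_sample / R_standard − 1) × 1000 ‰,

with δ¹³C referenced to VPDB (R = 0.0112372) and δ¹⁵N to atmospheric N₂
(AIR, R = 0.003676).  δ is strictly increasing in the sample ratio,
δ(R_standard) = 0, and doubling both ratios leaves δ unchanged.

NanoSIMS measures carbon through the diatomic C₂⁻ ion.  Under random
(binomial) pairing of carbon atoms, the isotopologue abundances are
(1−x)² : 2x(1−x) : x² for ¹²C¹²C⁻ : ¹²C¹³C⁻ : ¹³C¹³C⁻, where x is the ¹³C
atom fraction.  Neglecting the doubly heavy species (second order in x;
its weight relative to the singly heavy signal is x/(2(1−x)), about 1% at
x = 0.02), the count ratio ¹²C¹³C⁻/¹²C¹²C⁻ equals 2x/(1−x) and **half** of
it is the atomic ratio ¹³C/¹²C = x/(1−x) exactly.  This factor-½
correction is standard SIMS practice and is applied by default; because
published workflows differ on the convention, `c2_correction="none"`
reports the raw count-ratio-based values instead, and every output records
which convention ran.  The CN⁻ pair carries one nitrogen atom, so
¹²C¹⁵N⁻/¹²C¹⁴N⁻ is the atomic ¹⁵N/¹⁴N ratio with no factor.

Per-pixel ratios are always **ratios of plane-summed counts**, never means
of per-plane ratios (the two differ whenever counts vary between planes;
the package asserts this on a two-plane counterexample).  Pixels whose
denominator isotopologue (¹²C¹²C⁻, resp. ¹²C¹⁴N⁻) carries fewer than
`min_counts` summed counts are masked invalid and excluded from every
statistic; the default of 100 keeps the Poisson standard error of δ below
roughly 100‰ at natural abundance.  Deltas are computed in double
precision and ‰ is the only unit exposed.  The inverse map
x = R/(1+R) with R = R_standard(1+δ/1000) round-trips with the forward
map to ≤ 1e−12 relative error for moderate-to-heavy labeling; at extreme
depletion (δ → −1000‰) the delta scale itself loses precision to float
cancellation, a property of the notation rather than of the code.

No instrumental mass-fractionation, dead-time or QSA corrections are
applied; inputs are assumed to be detector counts already suitable for
ratio formation.

## Segmentation

Classes are separated from the ¹⁶O⁻, ¹²C¹⁴N⁻ and ³¹P⁻ channels.  Each
channel is log-transformed (log1p, so zero-count pixels are admitted) and
thresholded.  The default threshold maximizes between-class variance on
the log histogram (Otsu); original workflows of this kind used manual
thresholds with unpublished values, and a manual override is provided, but
automation is required for reproducible tests.  The binary masks combine
through a user-overridable boolean recipe whose default treats elevated
³¹P⁻ as the autotroph marker:

    biomass = cn;  autotroph = biomass & p;  heterotroph = biomass & ~p;
    background = ~(cn | o);  phosphate_high = p & ~biomass

This recipe is a stated assumption, not a claim about any instrument; it
is stored with thresholds in the output provenance.  Cleanup is a binary
opening with a chessboard-ball footprint (a (2r+1)-square, consistent with
the package-wide 8-connectivity convention) followed by removal of
components below `min_object_px` (default 5); cleanup is idempotent.

Heterotroph cells lying **on top** of a filament are not analyzable and
are deleted: any 8-connected heterotroph component overlapping the
autotroph mask by more than `overlap_fraction_cutoff` (default 0.5) of its
own area is removed, while side-attached components are kept with their
overlapping pixels reassigned to the autotroph.  Pixels in the
phosphate-high region are excluded from all cell records and statistics.
Filaments are treated as single cells (per-filament, not per-trichome
records), matching how filamentous cyanobacteria are discussed at the
population level.  Per-cell deltas are ratios of counts summed over the
cell's valid pixels.

A known limitation: the automatic ³¹P⁻ threshold presumes the scene
contains a genuinely ³¹P-high class.  On scenes without filaments the Otsu
split degenerates to the weak heterotroph/background contrast and
misassigns classes; such data need a manual ³¹P threshold (covered by a
regression test).

## Population statistics

Summaries report arithmetic mean and sample SD (n−1) per class on either
a pixel basis (every valid pixel one observation) or a cell basis (each
cell's ratio-of-sums delta one observation), with 50-bin histograms over
the display bounds by default.  The two bases agree exactly for
internally homogeneous, equal-sized cells.

The default two-sample comparison is the **unpaired Wilcoxon rank-sum
(Mann–Whitney) test**: pixel or cell populations from two different images
are unpaired, so a paired signed-rank test cannot apply as such.  The
signed-rank variant remains available behind `variant="signed_rank_paired"`
for genuinely paired designs, and every result records which variant ran.
The null distribution is enumerated exactly for combined n ≤ 25 without
ties; otherwise the tie-corrected normal approximation is used.  P values
below 10⁻³ are formatted as "<0.001", never as a literal zero.  Bivariate
(δ¹³C, δ¹⁵N) populations are summarized by 95% coverage ellipses from the
sample mean and covariance eigendecomposition, semi-axes scaled by
√χ²₀.₉₅(2) = √5.9915 ≈ 2.4477.  Replicate image histograms sharing bin
edges aggregate into a mean signature with per-bin SD.

## Rendering

Delta images are winsorized — "bottom 5% and upper 95%" is read as setting
values beyond the 5th/95th percentiles to those percentile values, the
only self-consistent reading — or clamped to fixed bounds (−200..9000‰ for
δ¹³C, −200..37000‰ for δ¹⁵N by figure convention; count images may use
min..99th percentile), then min-max scaled and colorized with cividis on a
black background.  Percentiles use the linear-interpolation definition.
Foreground pixels within `fade_band_px` (default 2) of the nearest
background pixel — Euclidean distance — fade toward black by scaling their
perceptual lightness L* in CIELAB by d/(band+1), a linear ramp, leaving
the chromatic channels untouched in the uniform space; pixels beyond the
band are bit-identical before and after.  Rendering is pure: identical
inputs and spec yield byte-identical PNGs.  Realized bounds, the
percentile definition and the distance metric are echoed into per-image
provenance.

## Bulk assays

**IRMS.**  Measured bulk deltas are recalibrated by a two-point affine
correction anchored on USGS 40 and USGS 41 (assigned δ¹³C −26.39‰ and
+37.63‰; δ¹⁵N reuses the machinery with AIR-referenced anchors).
Standards run after highly enriched samples are screened for carryover:
a post-labeled standard deviating from the running mean of its previously
accepted replicates (or from its assigned value when it has none) by more
than a tolerance — default 2‰, a conservative choice well above typical
EA-IRMS repeatability, as no tolerance is published — is flagged and
excluded from the fit, and always reported.  The correction is exact at
the anchor means and applying it twice is the identity.  Calibration is
per-run.

**qPCR.**  Genome counts come from a least-squares fit of Cq against
log₁₀(copies) over the decade standard series 3×10¹..3×10⁶, assayed in
triplicate and averaged per level before fitting (the aggregation level is
the package's choice).  The single-copy rpoC marker makes copies a genome
proxy.  Efficiency is 10^(−1/slope) − 1; at 100% efficiency decades are
log₂10 = 3.3219 cycles apart.  Relative abundances normalize per
replicate, and members are compared across the two nitrogen conditions by
Welch's unequal-variance t test (two-sided), skipped with a warning when a
condition has a single replicate.

**Proteomics.**  A protein's peptide count is divided by the total peptide
count of its source organism in that sample, removing organism-abundance
differences; an organism's community share is its total over the sample's
grand total.  Zero-total organisms yield flagged-missing fractions.

## Synthetic scenes: what they emulate and what they do not

The generator reproduces the acquisition geometry (40×40 µm, 256×256
pixels, 2 ms/pixel, 13 planes — within the reported 12–15) and the two
labeling regimes.  Filaments are constant-width tubes along random cubic
splines (geometry is only shown, never described, in this kind of study,
so the shapes are the package's invention); heterotrophs are discs, half
attached to filament flanks and half distal, never touching one another;
small phosphate granules inside filaments locally elevate ³¹P⁻.  A
side-attached disc must keep ≥ 60% of its area beside (not under) the
filament, otherwise it would not be a side-attached cell.

Class atom fractions default to the per-condition heterotroph population
deltas printed for this experimental system (NO₃⁻-only: δ¹³C 1328.39‰,
δ¹⁵N 1814.13‰; NH₄⁺-amended: δ¹³C 121.38‰, δ¹⁵N 6351.97‰) with autotrophs
co-enriched under both conditions and more strongly under NH₄⁺ (4000/9000
and 6000/20000‰, inside the δ display bounds) — generator parameters, not
claims.  Per-class channel count rates are invented (no intensities are
published): background 2/0.5/1/0.05, autotroph 30/45/150/8, heterotroph
25/40/120/0.2 counts·px⁻¹·plane⁻¹ for ¹⁶O⁻/C₂⁻/CN⁻/³¹P⁻, granules +50 on
³¹P⁻.  They satisfy the stated well-posedness requirement (biomass CN⁻
≥ 10× background) with realistic Poisson noise at these dwell times.
Counts are Poisson per pixel-plane; C₂⁻ totals split binomially with
heavy probability 2x/(1+x), CN⁻ with x₁₅; the ¹²C+¹³C pair sums to the
drawn total by construction.  Each operation draws from its own stream
seeded from (seed, operation-tag), so adding objects never perturbs
unrelated draws, and identical seeds are bit-reproducible.

Deliberately **not** emulated: partial-volume mixing at cell boundaries
(classes are hard-edged), cell-to-cell variability within a class (the
printed ±SD of real populations arises here only from counting noise),
instrument effects (dead time, QSA, beam drift, plane misalignment), and
reaction-diffusion labeling gradients.  Passing the recovery and Jaccard
suites therefore shows the pipeline is algebraically and algorithmically
correct under its stated model, not that segmentation quality or delta
accuracy transfer to arbitrary real acquisitions; real drifting data would
additionally need per-plane alignment, which is intentionally not
implemented.

## Problem sizes

The validation suite renders two full-geometry 256×256, 13-plane scenes
(one per condition) for recovery and segmentation checks, uses 1000
simulations for rank-test type-I calibration, 10⁴ bivariate normal points
for ellipse coverage, and 1000 members for Welch calibration — sizes at
which the binomial/Poisson standard errors make the 3-SE recovery bands a
few permil wide while the whole suite stays fast on a laptop.
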