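# Methods

## Scope and units

`mpq` quantifies two endpoint readouts of micropatterned hESC colonies —
nuclear SMAD2/3 localisation after a 1 h activin A pulse, and marker
domain areas of day-7 neuruloids — and compares them across cell lines.
All geometry is in µm (`µm = px × pixel_size`; 0-based pixel indices,
origin top-left, x = column, y = row, shared by every module). Intensities
are arbitrary units throughout; nothing depends on absolute calibration,
and the radial profile is explicitly normalized to its own maximum.

## Synthetic benchmark model

The generator emulates the assay geometry, not the microscope:

* **Colony layout.** Nucleus centers are placed in a disc (default radius
  250 µm) by batched dart-throwing (random sequential adsorption with a
  kd-tree reject step) under a hard minimum separation, default 8 µm.
  Requested counts above the hexagonal-packing bound are rejected with the
  bound in the error message; placements that stall more than 5% short of
  the target set a `shortfall` flag. Nucleus radii are uniform in
  [3.5, 5.5] µm (~9 µm nuclei, typical of confluent hESC). The default
  1800 nuclei per 500 µm pattern gives ~58% areal coverage — confluent but
  below the packing limit, so placement is fast and reproducible. Counts
  at fixation are not well constrained experimentally; this default is a
  plausibility choice, not a fitted one.
* **Activation rule.** A nucleus at distance ≥ radius − edge_band_width
  (default band 75 µm) from the center activates with probability
  `p_edge`, interior nuclei with `p_center`. Presets: WT (1, 0), HET
  (1, 0.4 with 40 µm patches), HD (1, 0.95), KO (1, 1). Patchy interior
  activation thresholds a Gaussian random field smoothed to the patch
  length at the empirical quantile of the interior field values, so the
  realised interior fraction equals `p_center` (up to rounding) while
  neighbouring nuclei are strongly correlated.
* **Rendering.** DAPI draws each nucleus as an antialiased radial dome —
  intensity 1 at the center falling to 0.6 at the rim, scaled to 100 a.u.,
  then blurred at σ = 0.7 µm. The dome matters: real interphase nuclei are
  center-bright, and those per-nucleus maxima are what makes confluent
  colonies segmentable at all (a flat-top rendering leaves the colony
  interior a featureless plateau). The SMAD2/3 channel paints
  `intensity_on` (100) inside activated nuclei and `intensity_off` (20)
  inside inactive ones with *no* blur, so in noiseless renders the
  per-nucleus median equals the set level exactly — this is what lets
  classification tests assert zero error. Overlapping pixels go to the
  nucleus with the smallest d/r, which also yields a ground-truth label
  image. Noise is additive: flat background (5 a.u. = 5% of on-intensity)
  plus Gaussian readout noise (σ = 2 a.u.), optional Poisson shot noise
  (off by default). Same (parameters, seed) reproduces images bit-exactly.
* **Neuruloids.** Concentric antialiased discs (DAPI, PAX6, N-CAD) and a
  SOX10 annulus, radii nested `ncad ≤ pax6 ≤ sox10_outer ≤ dapi`. True
  fractions are analytic: (r/R)² for discs, (r₂²−r₁²)/R² for the annulus.
  Presets encode the phenotype direction (WT → KO: PAX6 140→210 µm,
  N-CAD 90→160 µm, SOX10 annulus 180–240 → 225–240 µm in a 250 µm disc),
  i.e. HD-like lines have an enlarged neuroectodermal core and a
  contracted neural-crest ring.
* **Truth-record shortcut.** `nucleus_records_from_truth` emits the
  measurement table segmentation would produce (per-nucleus intensity =
  level + background + Gaussian noise), bypassing rasterisation. It is
  used where only the downstream statistics are under test; the imaging
  chain itself is always validated through rendered images.

What the generator does **not** model: PSF/optical blur beyond a token
Gaussian, uneven illumination, chromatic shifts, nuclear shape variation,
out-of-focus debris, or neuruloid morphogenesis dynamics. Tests passing on
this benchmark therefore certify the measurement code (geometry handling,
binning, normalization, statistics), not robustness to every real-world
imaging artifact.

## Colony detection

Otsu threshold on DAPI (scale-invariant, so detection is unchanged under
any positive rescaling), morphological closing (5 µm disk), hole filling,
connected components, and an area window `[0.65, 1.35]·π(D/2)²` around the
predicted pattern area; components touching the image border are rejected
with reason `border`, others with `too-small`/`too-large`. The boundary
polygon is the alpha shape (Delaunay triangles with circumradius ≤ α,
default α = D/5) of up to 4000 stride-subsampled foreground pixels, with a
convex-hull fallback — micropatterns are convex discs, so the fallback is
exact in practice. The colony center is the polygon centroid; on noiseless
synthetic colonies it lands within ~0.3 µm of truth, and the area within
a few tenths of a percent of π·250².

Degenerate inputs: an all-zero image returns no regions; a constant
non-zero image raises a threshold-failure error.

## Nuclear segmentation and measurement

Foreground by Otsu (or a supplied absolute threshold), debris below 5 µm²
dropped, then marker-controlled watershed. Markers are local maxima of a
landscape combining the smoothed DAPI image and the distance transform
(each normalized to max 1), with a minimum peak separation of 4 µm.
Distance-transform peaks alone cannot seed a confluent colony interior —
it is one connected blob with no internal distance structure — while
intensity alone fails on flat-textured sparse objects; the sum handles
both. 4 µm (half the default packing separation) keeps neighbouring true
centers from suppressing each other; at 7 µm suppression the recovered
count drops by several percent. Recovered counts are within ~2% of truth
at default density.

Size filter: keep 30–300 µm² (the lower bound removes debris, the upper
mitotic/merged figures); removals are logged with a reason. Nuclei
straddling the colony boundary are kept.

Per nucleus we report median and mean intensity over the label's pixels.
The median uses the **lower-median** convention for even counts so the
reported value is always attained in the image (an averaged median of a
bimodal 20/100 nucleus could report 60, a value present nowhere). Radial
profiling uses the median (robust to bright speckles); binary
classification uses the mean by default; both are always in the table.

## Radial profiles, bands, classification

Profiles bin nuclei by distance in half-open 10 µm bins to 250 µm; nuclei
beyond the last edge are counted in an overflow bucket and excluded from
means; empty bins carry NaN, never 0. Normalization divides by the maximum
bin mean (error if ≤ 0) and is idempotent. Band summaries average raw
per-nucleus intensities within center 10–25 µm and edge 175–225 µm
(half-open; non-overlap enforced). The center band deliberately starts at
10 µm: the innermost disc contains very few nuclei (the 0–10 µm bin holds
~1–2), so including it would add noise without information, and both
bounds are configurable. Across-colony aggregation reports per-bin mean,
sample SD (0 when a single colony contributes) and n.

A nucleus is SMAD2/3⁺ when its intensity is strictly above the threshold
(ties negative, so fraction is monotone non-increasing in the threshold).
Because the underlying assay choice was a manual cutoff, the package
provides two recorded, reproducible estimators — Otsu on the pooled
nucleus intensities, or the midpoint of a deterministic 1-D two-means fit
— flagged as degenerate when the two cluster centers sit within 5% of the
intensity range. One global threshold per batch, estimated on the control
condition, is the default.

## Neuruloid domains

Each channel is smoothed (σ = 2 µm), thresholded (Otsu by default),
opened (3 µm disk) and cleaned of components below 100 µm². (The smoothing
is applied before the threshold; a binary mask cannot meaningfully be
Gaussian-smoothed.) Fractions divide the marker mask area by the DAPI mask
area, after intersecting with DAPI (default `clip` mode, bounding
fractions in [0, 1]); `raw` mode divides unclipped areas and is flagged in
the record. N-CAD is measured as the filled region, not a lumen ring.
Recovered fractions sit within ~0.005 of analytic truth at 1 µm/px.

## Statistics

One-way fixed-effects ANOVA from the classical sum-of-squares
decomposition. Dunnett's two-sided many-to-one adjusted p is

&nbsp;&nbsp;p_adj = P( max_j |T_j| ≥ |t_obs| ),

with pooled-SD statistics and the equicorrelated multivariate-t null whose
correlation comes from the group sizes. It is evaluated by deterministic
2-D quadrature — probabilists' Gauss–Hermite (96 nodes) over the
standardised control mean, Gauss–Legendre (64 nodes) over the probability
transform of the pooled-SD chi distribution — with the inner product over
comparisons accumulated via log1p/expm1 so small tails keep relative
precision. Agreement with a 10⁶-draw Monte Carlo max-|T| oracle is ~10⁻³,
and with `scipy.stats.dunnett` to ~10⁻⁴; the analytic bound
p_adj ≥ p_unadj is enforced exactly so quadrature error can never invert
the dominance relation. Equal variances are assumed (the classical test;
no Welch variant). Tukey's all-pairs p uses the studentized-range
distribution with the Tukey–Kramer standard error for unbalanced groups.

Group summaries report mean, sample (n−1) SD and n; stars follow
\*p<0.05, \*\*p<0.01, \*\*\*p<0.001, \*\*\*\*p<0.0001, else ns. The
statistical unit is the colony — nuclei within a colony are never treated
as independent samples.

## Pipeline and determinism

`RunConfig` is a strict dataclass (unknown keys rejected, channel map
validated before any compute); the effective config, its hash, the seed
and the package version go into `provenance.json`. All randomness derives
from the run seed through `numpy` `SeedSequence` children keyed by stage
and colony index, CSVs are written with a fixed float format, and
iteration orders are sorted, so identical (config, seed) runs are
byte-identical. Ingest mode reads the generator's float64 multi-page
TIFFs and reproduces in-memory results exactly. Plots are views of the
CSVs only.

## Problem sizes in tests and the acceptance script

Unit tests run on 240 µm / ~420-nucleus colonies, which match the default
areal density at a quarter of the pixel count; full 500 µm / 1800-nucleus
colonies are exercised in the acceptance layer. The replicated
phenotype-separation simulations reuse a fixed set of colony layouts
across replicates (the micropattern geometry is the same physical
substrate; per-replicate variation enters through activation and
measurement noise) and compute band means from ground-truth records; the
neuruloid ordering replicates render at 4 µm/px with n = 10 per group,
where the preset effect (PAX6 fraction 0.31 vs 0.58) dwarfs the
coarse-grid quantisation. These sizes are the package's own benchmark
choices and are stated here so they can be scaled up when more precision
is wanted.

## Known limitations

* Classical segmentation assumes center-bright nuclei and roughly circular
  colonies; heavily textured chromatin, elongated nuclei or non-convex
  patterns would need the learned-segmentation route the package
  deliberately avoids.
* Angular structure is ignored (radial symmetry assumed); no
  nuclear/cytoplasmic ratio scoring; no 3-D (inputs are 2-D projections).
* The Dunnett implementation covers the two-sided, equal-variance case
  only.
* Synthetic realism limits are listed above; absolute intensities are
  never meaningful.
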