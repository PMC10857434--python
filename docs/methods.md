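# Methods

`midgutlam` analyzes tables of 3D-segmented nuclei from the adult
*Drosophila* midgut as a linearized, one-dimensional organ: every nucleus is
assigned a normalized anterior→posterior coordinate, features are aggregated
per axis bin, anatomical region borders are called from multivariate change
scores, and dietary cohorts are compared bin by bin. This note documents the
model behind each stage, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## Axis linearization

The organ axis is a piecewise median polyline ("vector") fitted to the 2D
nucleus centroids: the xy point cloud is rotated so its first principal axis
is the abscissa, the abscissa range is cut into `slice_count` equal-width
slices (default 30), and each non-empty slice contributes a control point at
(slice midpoint, median ordinate). Ordinates are smoothed with a 3-point
moving average, and the terminal segments are extended to the abscissa range
of the data — without the extension the axis would stop half a slice short
of each end and fringe objects would pile into the end bins. Arc length is
accumulated along the polyline; a degenerate cloud (no abscissa span, or
fewer than two occupied slices) falls back to a straight axis with a logged
warning.

Every object is projected to its nearest point over *all* polyline segments,
giving an arc position `s`, a normalized position `u = s/L ∈ [0, 1]`
(positions beyond the termini clamp rather than error, since segmentation
routinely includes cardia/hindgut fringe), and an unsigned in-plane radial
offset `d`. `u` is cut into `n_bins` half-open bins (default 100), the last
bin closed at 1.

The axis is fitted in 2D because the organ is imaged lying roughly flat;
z is kept only for 3D nearest-neighbor distances. The slice-median
construction resolves curvature down to roughly one slice width: gently
curved organs (the synthetic default) are fine at 30 slices, while a tightly
curved specimen (e.g. a semicircular arc with near-vertical ends) needs the
slice resolution raised to match — the tests exercise a semicircle at 100
slices. Fitted arc length systematically underestimates the true arc by a
few percent (chord + smoothing shortcuts), and the per-slice median has
sampling wobble of order `r/√n_slice` for a tube of radius `r`; both effects
are condition-independent and cancel in the fed/starved contrasts the
pipeline reports.

## Per-bin profiles

For each sample the pipeline tabulates, per bin: total counts, per-type
counts and mean per-type nucleus area (when type labels exist), polyploid
("large") nucleus area (median and mean), the mean 3D nearest-neighbor
distance among polyploid nuclei, and midgut width.

* **Ploidy gate.** Nucleus areas are bimodal (diploid
  progenitors/enteroendocrine cells vs polyploid enterocytes). The
  threshold sits at the minimum of a smoothed log-area histogram between
  the two largest modes; if the valley is closer than 0.2 log-units to
  either mode the distribution is treated as unimodal and a manual
  threshold is required. At the default synthetic medians (12 vs 55 µm²,
  log-sd 0.25) misclassification is ≪ 1%.
* **Width** = 2 × median radial offset of the bin's records. The
  epithelium is a monolayer tube, so the typical wall offset estimates the
  radius; the median is robust to stray objects (an extreme-value variant,
  2 × P95, can be computed from the same projected table). Bins with fewer
  than 5 records are missing (NaN), never 0.
* **Nearest distances** between polyploid nuclei are computed sample-wide
  in 3D and then averaged per bin, so a bin boundary never splits true
  neighbors.

## Border detection

The border score aggregates localized change in several tracks (defaults:
width 1.0, polyploid area 1.0, nearest distance 1.0, total count 0.5; the
count track is noisier and gets half weight). Each track is
median-normalized per sample, averaged across samples, and its contribution
at bin `b` is `|mean(b−w, b] − mean(b, b+w]|`, z-scored across scorable
bins; the score is the weighted sum. The window half-width `w` defaults to 5
bins of 100. The outermost `edge_exclude` bins per terminus (default 4)
are excluded from every window: at the organ ends, wall objects of the
terminal tube cross-section overhang the centerline by roughly one tube
radius (≈ 3–4 bins at midgut geometry), corrupting the width and count
tracks there, and a window that consumes those bins manufactures spurious
change peaks. Beyond that margin, bins within `w` of either terminus are
likewise unscorable, and the scorable set `[trim+w, n−2−w−trim]` is chosen
invariant under anterior/posterior reversal, which makes the score track
exactly symmetric under reversal (a property test). A constant track has
zero variance and contributes 0 ("degenerate-variance rule") rather than
NaN.

Borders are the `k` highest local maxima (default `k = 4`, giving B1–B4 and
regions R1–R5) after greedy non-maximum suppression within
`min_separation = 5` bins; fewer available peaks is an error reporting how
many were found. A score peak at bin `b` marks change between bins ≤ b and
> b, so the border position is `(b+1)/n_bins`. Region lengths are reported
in bins, normalized units and µm (via the fitted arc length) and sum to L
exactly. For cross-sample comparison, each sample's `u` can be warped by the
monotone piecewise-linear map sending its borders to the cross-sample
median border positions.

## Cell-level classification

* **Marker gates** use the same log-histogram valley as the ploidy gate
  (default), or an explicit quantile (`quantile:q`); positivity is
  `value ≥ threshold` and the threshold/method is recorded.
* **FUCCI phases**: the E2F1-degron reporter is present in G1 and G2-M, the
  CycB-degron reporter in S and G2-M, so (+,−) → G1, (−,+) → S,
  (+,+) → G2-M; (−,−) is *unclassified* and counted, never dropped.
* **Progenitor doublets** are mutual nearest neighbors among esg+ cells
  within a 10 µm pairing radius, rejected when either member has a third
  progenitor within 15 µm (nests/clusters are not doublets). The radii are
  conventions — progenitor nest geometry, not measured values — and are
  configurable and logged. Mutual nearest-neighborhood guarantees each cell
  joins at most one doublet. Doublet symmetry follows the members' Delta
  and Prospero status: Delta+/Delta+ (Pros−) symmetric ISC–ISC,
  Delta+/Delta− asymmetric ISC–EB, any Delta+Pros+ member → ISC–preEE.
  Doublets deliberately include adjacent non-sibling cells; no siblinghood
  inference is attempted.

## Statistics

Bin-wise group comparisons use the two-sided Wilcoxon rank-sum test. With
combined n ≤ 10 the p-value is exact by full enumeration of all
C(n, n_a) labelings of the pooled midranks (ties included; C(10,5) = 252
labelings is trivial); larger problems use the normal approximation with
tie-corrected variance and a ±0.5 continuity correction. Benjamini-Hochberg
step-up FDR is applied across the scorable bins of one feature and one
comparison — per-panel, not pooled across features. A bin missing in more
than half of either group is unscorable: a bin present in only one sample
cannot support a two-group test. Kruskal-Wallis (tie-corrected, χ²
reference with k−1 df) provides the omnibus for ≥ 3 groups with rank-sum +
BH follow-up; the paired t test requires non-degenerate differences; the
two-factor ANOVA uses classical (sequential) sums of squares when balanced
and Type II otherwise, with Tukey HSD over factor-level cells against the
studentized-range reference.

Samples, not cells, are the replication unit in `per_bin_compare`.
Cell-level pooling (e.g. for intensity panels) can be run by passing
cell-value matrices directly, and should be labelled as such.

## The synthetic midgut generator

The generator is the package's ground-truth source. One sample is built as:

* **Geometry** — a planar sinusoidal centerline `y = A sin(2πx/λ)` with
  `L = 3000 µm`, `A = 300 µm`, `λ = 3000 µm`. One full period gives a
  gently S-shaped organ (maximum slope ≈ 0.63, crest bend radius
  ≈ 760 µm), so the axis fit is exercised on genuine curvature while the
  fed-scaled tube walls (up to 160 µm radius) stay clear of the bend
  radius; a tighter wavelength would fold the inner wall at the crests and
  make the tube geometrically inconsistent.
* **Regions** — five regions R1–R5 with arc-length proportions
  (0.20, 0.25, 0.10, 0.30, 0.15); the tiny cardia (R0) is not modeled.
  Region radii (90, 70, 100, 75, 60) µm; the fed condition scales all
  radii by 1.6.
* **Cells** — an inhomogeneous Poisson process along the axis with
  region-specific linear densities per class (per 100 µm: EC 75–90,
  ISC 12–18, EB 10–14, EE 8–12; absolute densities are free parameters —
  no published per-region counts exist — chosen so a sample holds
  ≈ 4500–5000 nuclei). Nuclear areas are lognormal: polyploid EC median
  per region (65, 60, 40, 55, 50) µm², diploid median 12 µm² (EB × 1.6,
  EE × 0.85), log-sd 0.25 — well-separated ploidy modes with realistic
  overlap from growing EBs.
* **Radial placement** — the projected appearance of a dissected monolayer
  tube: 60% of nuclei at the silhouette walls, ±(radius + N(0, 2 µm)),
  40% seen en face uniformly across the lumen; z is N(0, 0.3 × radius).
  The wall majority makes 2 × median offset a consistent width estimator,
  while the filled interior keeps the slice-median axis anchored to the
  centerline (wall-only placement makes the slice median bistable between
  the two walls).
* **Dietary effects** (fed vs starved baseline), directions per the
  biology, magnitudes chosen to be recoverable at cohort size 8: radius
  × 1.6 everywhere; ISC nucleus area × 1.3 in R2/R4/R5 only; EB density
  × 1.8 in R2/R4; EE density × 1.6 in R3 and 10%-of-axis flanks.
* **Markers** — lognormal intensity channels (log-sd 0.3–0.4) with
  positive/negative populations per cell type: Delta (ISC, weakly preEE;
  regionally high in R2/R4 and feeding-activated there), Prospero
  (EE/preEE), escargot and GFP (progenitors), p4E-BP (ubiquitous;
  × (1, 1.6, 2.4) across G1/S/G2-M, × 1.8 fed, region-modulated), and the
  two FUCCI reporters gated by true phase. ISCs cycle with phase
  probabilities (0.5, 0.25, 0.25); other types are non-cycling.
* **Doublets** — 15% of ISCs anchor a doublet with a partner placed
  ≈ 3 µm away: symmetric ISC–ISC with probability 0.6 (starved) / 0.3
  (fed), 5% of the remainder ISC–preEE, the rest asymmetric ISC–EB.

Everything is drawn from one `numpy` Generator per sample, so a fixed
(config, condition, seed) reproduces the table byte for byte. Ground truth
(region, type, phase, doublet identity/partner/class per record; border
positions, scaled radii and arc length per sample) rides along in `true_*`
columns and a `GroundTruth` object.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: segmentation errors (merged/split nuclei),
intensity bleed-through and spatial staining gradients, the R0 cardia and
the named subregions (R2ab, R4a–c), within-region density gradients,
muscle/trachea contaminant objects, lineage structure over time, and any
correlation between neighboring cells beyond the explicit doublets. Border
sharpness in particular is idealized: real regional transitions are
gradual, so real border scores will be broader than the synthetic ones.

## Recovery experiments (tests and acceptance script)

* **Width fold**: 8 starved + 8 fed samples; per-sample width profiles;
  fold = mean over bins of (group-mean fed / group-mean starved). The
  estimator's downward width bias cancels in the ratio; measured folds run
  1.53–1.58 against the injected 1.6.
* **Border recovery**: 20 cohorts of 8 samples; called borders must number
  exactly 4 and sit within ±3 bins of truth in ≥ 95% of cohorts.
* **Type-I error**: 20 null cohorts (two groups of 5 from the identical
  configuration); the mean fraction of bins flagged at FDR 0.05 must not
  exceed 0.05 + 2·SE. With 5-vs-5 samples per bin the exact rank-sum p is
  bounded below by 2/252, so BH across ~90 bins rejects essentially
  nothing under the global null — the check verifies that discreteness and
  adjustment interact safely.
* **Localization**: one 16 + 16 cohort; significant bins for ISC area,
  EE counts and EB counts must fall ≥ 80% inside the regions the
  respective fold was injected into. Sixteen samples per group were chosen
  a priori for the count tracks: per-bin Poisson counts are noisier than
  areas and need more replicates for bin-level significance, while still
  keeping the axis-estimation smearing at the window edges small.
* **Doublet recovery**: a sparse-progenitor configuration (ISC 12/100 µm,
  EB background 0.5/100 µm, doublet fraction 0.95) yields 200+ recoverable
  doublets per sample with negligible spurious mutual-NN background;
  recovered symmetric fractions must be within ±0.07 of the injected 0.6
  (starved) and 0.3 (fed), with ≥ 95% class accuracy on recovered true
  pairs. At the default (dense) progenitor densities most candidate pairs
  are rejected by the cluster-exclusion rule, which is faithful to how
  nests look in real tissue but makes fraction recovery a
  controlled-experiment question, hence the dedicated configuration.

Problem sizes (≈ 5000 nuclei/sample, 8–16 samples/group, 20 replicate
cohorts) are the package's standard experiment sizes; the full suite runs
in well under a minute per experiment on one CPU.

## Known limitations

* The slice-median axis under-measures arc length by 2–4% on curved organs
  and its per-slice wobble biases absolute widths downward by ~10–25%
  depending on curvature and cell density; contrasts and fold changes are
  unaffected, but absolute width/length values should be read with that
  bias in mind.
* Border calling assumes at least `k` genuine change points separated by
  `min_separation`; organs with fewer real transitions will surface noise
  peaks as borders (the error path reports how many peaks exist).
* The exact rank-sum path enumerates up to combined n = 16 but `auto`
  switches at 10; heavily tied data at 11–16 fall to the normal
  approximation.
* `align_samples` requires every sample to carry the same number of
  borders; partial border sets must be resolved upstream.
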