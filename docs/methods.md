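# Methods

This note documents the models implemented in `npq`, the parameter
defaults and why they hold, the synthetic-data generators used for
validation, and the design choices made where the underlying workflow was
genuinely open.

## Stain model and positive-area metric

Brightfield absorbance is modeled by Beer–Lambert on an 8-bit scale:
OD = −log₁₀(max(I, ε)/255) per channel, with incident intensity I₀ = 255,
floor ε = 1 intensity unit, and ceiling OD_max = log₁₀(255) ≈ 2.41. The
floor makes a fully dark pixel well-defined (OD = OD_max) rather than
infinite; both constants are the standard 8-bit scanner convention.

Color deconvolution treats the per-pixel OD vector as a linear mixture of
three unit-normalized stain vectors (hematoxylin, DAB, residual) and
solves the 3×3 system per pixel. Negative unmixed concentrations —
off-model pixels — are clipped to zero, the standard practice. A singular
stain matrix raises an error naming the offending vectors. With an
orthonormal basis the transform reduces to per-channel identity, which the
test suite uses as a sanity limit.

Positive-area analysis operates on the DAB *pseudo-intensity* map,
255·10^(−OD_DAB), the single-stain inverse of the OD transform. A pixel is
positive when its pseudo-intensity is **below** the upper positive
threshold (default 200): the threshold is an upper bound on how pale a
pixel may be and still count as stained. This direction is the only one
under which a threshold of 200 selects DAB-positive (dark) pixels and
under which calibration by lowering the threshold removes background. Both
the segmentation threshold (220) and positivity threshold (200) are
exposed as parameters, since a vendor implementation could apply them to a
differently-scaled intensity.

ROI membership uses the pixel-center convention: a pixel belongs to a
polygon ROI iff its center lies inside (even-odd rule, 0-based
coordinates). Densities use the ROI's pixel-count area, which tiles
exactly — two disjoint halves of an ROI sum to the whole — unlike the
shoelace polygon area (also provided).

## Inclusion detection and declustering

Candidates are pixels of the raw DAB pseudo-intensity map below the
segmentation threshold (220), restricted to the ROI. Thresholding the raw
(not smoothed) map keeps measured object areas faithful to the stained
footprint; the Gaussian-smoothed map (σ = smoothing radius, 2 µm,
converted to pixels) drives only the watershed declustering. The vendor's
declustering algorithm is proprietary; here basins of the smoothed
intensity are pre-merged by an h-minima transform with h = the merging
threshold (2.5), so two touching inclusions separate only when the saddle
between them is at least 2.5 intensity units shallower than their minima.
This reproduces the qualitative split/merge behavior with a single knob;
its numerical agreement with any vendor implementation is not claimed.

Shape features: area = pixel count × pixel size²; perimeter by the Crofton
approximation (a naive pixel-edge perimeter systematically deflates
roundness); roundness = 4πA/P²; elongation = minor/major axis of the
best-fit ellipse. These are the standard definitions consistent with the
stated admissible ranges (roundness ≥ 0.25 excludes fibers; elongation
≥ 0.1 excludes extreme threads). Filters keep objects with
20 µm² ≤ A ≤ 225 µm², both bounds inclusive, and mean raw DAB intensity at
or below the positivity threshold.

Threshold calibration pools the per-slide object-intensity histograms
(the per-slide vs pooled choice is not determinable from the source
workflow; pooled is the default) and returns the smallest cut point
capturing ≥ 99% of positive-slide objects while admitting ≤ 60% of
negative-slide objects; when the two constraints cannot be met jointly the
maximizer of the cumulative-fraction gap is returned flagged
`constrained=False`.

## RIR

RIR = (outer − blank)/(inner − blank) on mean 8-bit intensities,
normalized to a blank region per slide. Region means use the unweighted
grayscale (channel mean); the measurement is configurable to any intensity
map. Because staining darkens pixels, both differences are negative and
the ratio is positive, 1 for symmetric staining. At low OD the intensity
deficit is approximately linear in stain amount, so the RIR tracks the
underlying outer/inner stain-density ratio; the validation fixtures use
ODs ≤ 0.05 where the Beer–Lambert linearization error is under 2%.

## Cohort selection and matching

Selection predicates: resistant = non-demented, last CASI within 2 years
of death (365.25-day years), Braak ≤ III, CERAD none, age ≥ 85; resilient
= non-demented, CASI within 2 years, Braak VI, CERAD frequent. Matching
candidates are demented cases with Braak VI + CERAD frequent. Matching is
greedy and without replacement, processing index cases in ascending
case-id order (the original processing order is unrecorded; a fixed order
makes the output deterministic and auditable), ranking same-sex candidates
lexicographically by |Δ age at death|, |Δ year of death|, |Δ PMI|, with
the final tie broken by smallest case id. Age and year are ranked
hierarchically rather than by a weighted distance because no metric
combining them is specified; the lexicographic rule is deterministic and
reproduces the stated PMI tie-break.

## Scoring

ADNC subscore = Braak/2 + CERAD (0–6, half-integers allowed); µVBI =
microinfarct count capped at 3; LBD and LATE-NC are ordinal 0–3 mappings
of distribution labels; the summary score is their sum (0–15). Binning
scales: pTau 0 / <3 / 3–10 / >10 per 10x field → 0–3; Aβ 0 / <5 / 5–20 /
>20 → 0–3; pTDP-43 0 / 1–2 / 3–5 / 6–10 / 11–15 / 16–20 / >20 → 0–6. The
published pTDP-43 scale lists 15 in both the 11–15 and 15–20 bins; the
lower bin wins at shared edges, applied uniformly to all scales. A count
of 0 tangles always scores 0 even though the "<3" band would nominally
admit it. Fractional counts (e.g. densities) are floored before binning.

## Exact statistics

The Wilcoxon matched-pairs signed-ranks test drops zero differences (the
classical treatment; commercial packages vary here, a known source of
small p-value discrepancies), mid-ranks tied |differences|, and computes
the exact null distribution of the positive-rank sum by dynamic
programming over sign flips on the doubled-rank (integer) grid — exact
even under ties, which off-the-shelf exact modes typically refuse. The
exact path is used up to n = 25 (the DP is O(n·Σranks), trivial at that
size); beyond it the normal approximation with tie correction applies.
Two-sided p-values double the smaller tail and cap at 1, for both Wilcoxon
and the exact-binomial McNemar test. No multiple-testing correction is
applied; per-variable p-values are reported raw. The chi-square goodness
of fit (against expected ratios, df = k−1) delegates to
`scipy.stats.chisquare`.

## Segregation model

A cross of a parent homozygous for one transgene and heterozygous for
another segregates the second at 25/50/25 (+/+, +/−, −/−). Genotype-
specific relative viabilities in [0, 1] multiply the Mendelian ratios and
renormalize to give the expected surviving-progeny proportions; synthetic
lethality is a near-zero viability of the +/+ class (near-zero rather
than zero, since rare double homozygotes are recoverable by scoring large
progeny numbers). The segregation test compares observed counts against
the *pre-selection* Mendelian ratios — the scientific question is
departure from neutral assortment. A two-class presence/absence mode
(¾ : ¼) supports blind scoring that records only transgene carriage.

## Synthetic-data generators

All generators are pure functions of parameters + seed.

*Images.* Per-pixel RGB = 255·10^(−(OD_hem·v_hem + OD_dab·v_dab))
channel-wise with the default stain vectors; planted objects (disks,
ellipses with configurable aspect, 1.5 µm-wide fibers guaranteed to fail
the roundness filter) are rasterized onto the DAB OD canvas over a uniform
hematoxylin background (default OD 0.3). Noise is additive Gaussian on
intensity (default SD 2 units, a scanner shot-noise stand-in; the true
noise process of a slide scanner is not modeled), clipped to [0, 255].
Overlapping objects without a declared bridge are an error, since the
ground-truth table would be ambiguous; bridges are stained strips fusing
two objects for declustering fixtures. The ground-truth table carries each
object's true and rasterized area, shape class, and stain OD, sufficient
to compute every downstream metric's expected value in closed form.

*Cohorts.* Defaults mirror the study structure: 684 cases with 14 planted
resistant, 7 planted resilient, and an 80-case severe-ADNC dementia pool
(large enough for same-sex matching without replacement). Planted cases
satisfy their predicates by construction; eight decoys each violate
exactly one criterion (age, Braak, CERAD, CASI latency, dementia status);
fillers are structurally unable to satisfy either predicate (non-demented
with stale CASI, or demented without severe ADNC, which also keeps the
matching pool exactly the planted one). CASI trajectories are biennial:
stable around 90 for non-demented cases, linearly declining and crossing
the ≤ 85 evaluation threshold at the last recorded visit for demented
cases (testing stops at diagnosis in the source protocol). Group-level
shifts follow the reported directions — the dementia pool carries LATE-NC
at 13/14 prevalence vs 2/14 in resistant cases, lower brain weight
(N(1115, 80) vs N(1228, 80) g), and higher vascular scores. These planted
effects are what the matched-pair power checks detect; passing them shows
the pipeline recovers planted structure under this idealized model, not
that real cohorts behave this way (no missingness, no staging drift over
calendar time, independent cases).

*Progeny.* Multinomial draws from the viability-adjusted genotype
proportions.

## Problem sizes in tests

Validation suites use canvases of 240–600 px (0.12–0.30 mm at
0.5 µm/pixel) with 3–24 planted objects, 5+5 training slides for
calibration, 300–500 Monte-Carlo replicates for the segregation power and
null-calibration checks, 1500–2000 replicates for the Wilcoxon level
check, and 60 replicate cohorts for the matched-pair power check — sizes
at which every planted effect is comfortably resolvable in closed form.

## Known limitations

- The declustering stand-in (watershed + h-minima) is one interpretation
  of an unpublished vendor algorithm; only its qualitative behavior is
  validated.
- Pigment artifacts (lipofuscin, hemosiderin) are not modeled; exclusion
  masks are supported as plumbing.
- Whole-slide pyramidal formats are out of scope; inputs are plain
  TIFF/PNG region images.
- Stain vectors are supplied, not estimated from data.
- The Wilcoxon zero-difference and tie conventions may differ from
  commercial implementations in the last decimal of exact p-values.
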