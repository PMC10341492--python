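# Methods

## Synthetic cohorts

The generator treats a published group summary (mean ± SEM over a group
of `source_n` animals) as the law of an individual animal's endpoint:
values are drawn from N(mean, sd) with sd = SEM·√`source_n`, rejected and
redrawn while outside the endpoint's admissible range (OD% in [0, 100],
densities ≥ 0, myelin scores in [1, 4], weight loss ≤ 100%). Rejection
rather than clipping is used because clipping piles probability mass on
the bound and biases the mean; rejection only biases when the normal law
itself puts appreciable mass outside the bounds, which among the packaged
parameters happens only for near-zero control spheroid densities
(region-215 control APP, mean 1.2 ± 0.8 SEM: the truncated mean is ≈ 2.0
rather than 1.2 — a sub-rank-width shift for groups this far apart).

`source_n` (5, from 35 animals across 7 groups; per-group sizes are a
design default, configurable) converts SEM→SD independently of the
simulated `n_per_group`, so scaled-up cohorts keep the printed per-animal
dispersion.

Determinism: each animal owns an RNG substream seeded by
(root seed, CRC-32 of the animal id). Identical inputs are bit-identical;
enlarging a cohort appends animals without reshuffling existing ones.

### Body weight

The study design feeds 0.3% w/w cuprizone, reduced to 0.275% on day 16
after the expected ~10% weight loss, over 35 days, weighing twice weekly
to day 14 and weekly after. The simulator uses a deterministic
piecewise-linear backbone — linear drop to 90% of start weight at day 14,
plateau through day 18 (reduction day + 2, a lag for intake to respond),
linear recovery to the animal's final weight — plus additive N(0,
noise_sd) jitter on interior weighing days; day 0 and the final day are
anchored exactly. Controls grow linearly. Only the qualitative shape of
these trajectories is published; the backbone is the simplest curve with
the documented features (initial ~10% drop, stabilization after the dose
reduction, mild terminal recovery).

Start weight is not published; the fixture uses 22.0 ± 0.5 g (6-week-old
male C57BL/6 after one week of acclimation). The weight-loss endpoint is
`loss% = 100·(start − final)/start` (positive = loss, so a stronger
cuprizone reaction is a larger value; gains are negative losses). Group
weight-loss parameters are derived from the published end-of-study
weights and this start weight; because the start is shared across groups,
the ranking is insensitive to its exact value. An alternative
`max_drop` definition (trajectory minimum) is available behind a flag;
the default is the end-of-study change.

## Synthetic images

*Optical-density fields*: exactly `round(f·|ROI|)` ROI pixels, chosen
uniformly, get foreground intensities; the rest background. Default laws
are N(200, 12) vs N(40, 10) on the 8-bit scale — 16 background SDs apart,
chosen so the two-class structure is unambiguous ("well separated"); a
warning fires if a caller's laws overlap within 2·(σ_fg+σ_bg). Positive
is rendered bright; real DAB is dark-positive, accommodated by the
`invert` flag at quantification rather than by a second rendering
convention. The recorded ground-truth fraction is the realized one and is
exact by construction.

*Spheroid fields*: object count ~ Poisson(density × ROI area in mm²),
centers uniform on the ROI, each object an additive Gaussian-profile blob
(peak 200, σ = radius/2, default radius 3 µm at 1 µm/px) saturating at
255. Ground truth is the placed count and centroid list. A warning fires
when the expected overlap fraction exceeds 50%, where component counting
becomes ill-posed. Pixel area is pixel_size²; 1 mm² = 10⁶ µm².

What the generator does **not** emulate: spatial autocorrelation of
staining, intensity gradients and vignetting, stain-specific chromogen
color (no deconvolution), section artefacts, and — for cohorts —
within-animal correlation across endpoints. The last point matters for
interpretation: group-mean cumulative ranks depend only on the endpoints'
marginal distributions, so recovery tests validate the ranking machinery
against the published marginals, not the joint behavior of real animals.

## Thresholding

All three algorithms consume a 256-bin histogram; "positive" is intensity
strictly greater than the threshold, everywhere.

* **IsoData (iterative intermeans)**: fixed point of
  t ← round((μ_below + μ_above)/2), μ_below over bins ≤ t, μ_above over
  bins > t. Initialization at the midpoint of the occupied support (the
  fixed point, not the start, is the contract — tests verify the
  fixed-point condition post hoc). Rounding is half-up; iterates are
  clamped so both classes stay non-empty; the rare period-2 cycle
  resolves to the smaller member; ≤ 256 iterations.
* **Default (classic trimmed intermeans)**: bins 0 and 255 are zeroed
  first — the historical guard against erased and saturated areas — then
  the same fixed-point iteration runs on the trimmed histogram. On
  histograms with empty end bins it coincides with IsoData. If trimming
  removes everything, the classic midpoint fallback (128) is returned.
  The exact historical trimming rule has several descriptions; this
  variant (trim-then-intermeans) is the documented, tested choice.
* **MaxEntropy (Kapur)**: maximizes the sum of the two class-conditional
  Shannon entropies, natural log (the argmax is base-invariant),
  zero-probability bins contributing nothing, candidates restricted to
  splits giving both classes positive probability, ties broken toward the
  smallest t. Verified exhaustively against a brute-force scan.

A single-bin histogram is degenerate and raises; quantification maps
this to an error for optical density (a uniform ROI is not a valid OD
field) but to "empty field, density 0" for spheroid counting, where blank
control tissue is an expected input.

## Quantification

Optical density: ROI histogram → protocol algorithm → 100 × positive
pixels / ROI pixels. The per-image threshold mirrors per-image ImageJ
practice. Protocol map: PLP/265 → MaxEntropy, GFAP/265 → Default, and
IsoData for PLP/215, GFAP/215, IBA1/215; IBA1/265 is not pinned by the
protocol and defaults to IsoData.

Spheroid density automates a manual count: threshold (IsoData), label
components with 8-connectivity, drop components < 4 px (noise specks),
count components whose centroid lies in the ROI (a border policy the
protocol leaves open), divide by ROI mm². Two guards return 0 with a
warning instead of counting phantoms on blank fields: a degenerate
histogram, and a **contrast gate** — if the class means at the chosen
threshold are separated by less than 4 background-class SDs, there is no
genuine bright class (splitting a pure normal yields ≈ 1.6 SD; real
spheroids sit > 10 SD above background) and the field is called empty,
as a human counter would.

Myelin scores are integer per rater (1–4) and averaged per animal;
published group means with one decimal imply fractional per-animal means
from two raters, which integer scores produce naturally. Whether raters
could give half-points is unknown; integers are enforced.

## Ranking

Per region, five endpoints enter the composite: PLP OD, IBA1 OD, GFAP
OD, APP density, weight loss (the LFB score is reported but not ranked).
Direction conventions: PLP OD and LFB score are lower-is-stronger, all
others higher-is-stronger; rank 1 = weakest reaction. Ties get midranks,
which preserve Σ ranks = N(N+1)/2 per endpoint exactly and hence
Σ cumulative = E·N(N+1)/2. Any animal missing any endpoint is removed
from the entire region's ranking before ranks are assigned, so ranks run
1..N over complete animals; the two regions are ranked independently
over the same animals.

### A structural note on the published region-215 composite

The packaged published composite values cannot be reproduced exactly by
*any* five-endpoint ranking, independent of simulation choices: their
region-215 group means, weighted by group size, total ≈ 2486, below the
identity minimum of 2805 for E = 5 endpoints and N = 33 ranked animals
(the published exclusion arithmetic is itself inconsistent, naming 33
animals but ranks to 34). The per-group average, 71.0, equals E(N+1)/2
for E ≈ 4 with N = 34 — consistent with a four-analysis sum. The
region-265 composite does satisfy the identity for E = 5, N ≈ 34.
Additionally, under the published per-endpoint summaries, Cuprizone C is
the strongest group on four of the five region-215 endpoints, so any
synthesis faithful to those marginals places C at or near the top
(≈ 128 of a 175 maximum here; an independent brute-force oracle agrees
to < 1), above the published 94.6. The package follows its own
arithmetic — the identity is an enforced invariant — and reports the
discrepancy rather than reproducing it.

## Statistics

Kruskal–Wallis H uses pooled midranks with the tie correction
1 − Σ(t³−t)/(N³−N) and a χ²(k−1) reference; all-identical data define
H = 0, p = 1. Dunn's z uses the pooled-variance form with the matching
tie term and two-sided normal p-values; the family adjustment is
Bonferroni multiplication over all k(k−1)/2 pairs (the commercial
implementation this battery mirrors does not document its adjustment;
Bonferroni is the conservative, reproducible choice). ANOVA + Tukey HSD
and Shapiro–Wilk are delegated to scipy; zero-variance input defines
F = 0, p = 1. The gate routes to the parametric branch only if every
group passes Shapiro–Wilk at α = 0.05; groups with n < 3 or constant
values route nonparametric with a warning. α = 0.05 throughout.

## Problem sizes and tolerances

Recovery checks use sizes at which Monte-Carlo error is comfortably
below the assertion tolerance: 50 seeds × 256² px for optical-density
recovery (±1.0 percentage point), 100 seeds × 0.5 mm² fields at
702 objects/mm² for spheroid recovery (±5%; blob merging at this density
costs ~1–3%), 200 seeds of 7×5 cohorts for composite-rank recovery, and
1,000 random histograms for the threshold oracles. The type-I-error
calibration of Kruskal–Wallis uses 10,000 null simulations of 3×20
normals (band 0.04–0.06 at α = 0.05); group sizes of 20 keep the χ²
approximation itself from confounding the calibration.

## Known limitations

* Endpoint draws are independent within an animal; real lesion severity
  correlates endpoints. Group-level rank means are unaffected (they
  depend on marginals only), but animal-level rank dispersion is not
  calibrated to real data.
* MaxEntropy on heavily imbalanced two-class fields (≳ 95:5) shaves the
  majority mode's near tail, biasing OD by up to ~1 percentage point;
  this is a property of the algorithm, reproduced deliberately.
* The spheroid counter undercounts merged blobs; at the densities
  packaged here the effect is ≲ 3%.
* The weight backbone is piecewise linear; it reproduces anchors and
  cadence, not intra-week dynamics.
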