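# Methods

This note documents the statistical procedures, the synthetic-study
generator, and the numerical and design choices behind `memtopo`.

## Data model

The unit of inference is an experimental **session** ("sample"): one
participant watching ~300 one-second diary videos of their own life in
the scanner. Each video carries behavioral annotations — memory age in
days before the scan, geographic coordinates (optional; locations are
often protected in shared data), 1–5 memory-strength and emotion
ratings, and content booleans (`has_people`, `people_new`,
`contains_self`, `place_new`) — and a per-voxel statistic (the
t-statistic of a first-level GLM beta). Producing those first-level maps
(HRF modelling, motion regression) is upstream of this package; the
`BetaStack` container consumes them. Group inference always treats the
session as the unit: statistics are computed within each session and
compared across sessions.

People-content categories use the precedence **new > self > familiar**:
a video with both unfamiliar people and the participant themself counts
as "new". Selfie-only videos are excluded from both sides of the
new-vs-familiar people contrast. Videos with missing coordinates keep a
missing distance and are dropped listwise from any distance-using
analysis.

Geodesic distance is spherical haversine with R = 6371.0088 km. At the
precision of these analyses (correlations over hundreds of videos, log
scaling) the <0.5 % difference from an ellipsoidal geodesic is
irrelevant.

## Univariate rank regression

The outcome (ROI mean or sphere mean of the per-video statistic) is rank
transformed (average ranks on ties) and fitted by OLS with intercept on
raw-unit predictors: age (days), strength (1–5), emotion (1–5), distance
(km). Predictors are deliberately *not* standardized — group inference
on the slope sign is scale-free, and raw-unit slopes are easier to
read. Ranking makes the per-session slope invariant under any strictly
monotone transform of the raw signal (tested with exp/log/affine
transforms). Collinearity is monitored as the max pairwise |Pearson r|
(warning at the conventional 0.80); the design matrix is rejected as
rank-deficient when, after standardizing columns, its smallest singular
value falls below 1e-8 of the largest, naming the most collinear pair.

Group level: one-sample two-tailed t-test of per-session slopes against
zero; Cohen's d = mean/SD; BH-FDR (`fdr_correct`, backed by
statsmodels) across the four MTL ROIs per predictor for ROI analyses.
Voxelwise maps are thresholded at uncorrected p (0.01 by default for
display), with BH across voxels available.

**Searchlight.** Sphere membership is strict Euclidean distance ≤
(diameter−1)/2 in voxel units, ties at the radius included (33 voxels at
diameter 5); the outcome at a center is the in-mask sphere mean,
computed exactly by 3-D convolution of the masked volumes with the
spherical kernel. Centers whose sphere holds fewer than `min_voxels`
(default 10, capped at the kernel size so diameter 1 degenerates
exactly to voxelwise regression) emit missing values rather than
unstable fits. Per-session maps are fitted in one batched least-squares
solve per session.

**Crossed control.** The own-brain/other-ratings control reuses the
identical machinery with participant B's ratings predicting participant
A's activity while viewing B's videos, after a strict video-order
alignment check.

## RSA

Neural RDM: 1 − Pearson correlation between multivoxel patterns (range
[0, 2]); constant patterns are an error (or a skipped center inside the
searchlight). All vectorizations use the strict upper triangle. The
combined RDM regression is plain OLS with intercept on dissimilarity
vectors (no rank transform); the temporal model *comparison* uses
Spearman correlation, Fisher-z transformed, with one-sample and paired
t-tests — two deliberately different conventions for the two questions
(effect size of a joint model vs. which single code fits best).

Log floors: age is clamped to ≥ 1 day before log₁₀, distance to ≥ 0.1 km.
The exponential code exponentiates u = age/exp_scale with exp_scale
defaulting to the session's maximum age, bounding 10^u in [1, 10]:
exponentiating raw day counts overflows, and the rescaling preserves the
code's ordinal geometry, which is all a rank-based comparison sees.

The spatial RDM models each memory as a planar vector anchored at the
scan site, direction = initial great-circle bearing, length = log₁₀ of
the clamped geodesic distance; dissimilarity is Euclidean distance
between endpoints. For collinear bearings this reduces analytically to
|log₁₀ dA − log₁₀ dB| (tested). Distances below 1 km produce negative
log-lengths, i.e. an endpoint on the opposite bearing — a documented
quirk of the convention; an alternative (`log_latlon`) applies the log
radially in latitude/longitude space.

## Topography and leave-one-out selectivity

Per-session effect maps: recent-minus-remote means for memory age
(cutoff 90 days ≈ three months, configurable), familiar-minus-novel for
people (selfies excluded) and places, own-minus-other for session
identity, and per-level mean maps for the five-level rating factors.
Sessions with fewer than five videos in any cell are excluded with a
logged reason (the study's rule, applied uniformly).

Group maps: per-voxel one-sample t (contrasts) or one-way
repeated-measures ANOVA over the five level means with session as the
repeated unit (level × session interaction as error) — the
repeated-measures variant is a documented choice; the alternative
(pooled one-way) ignores the session pairing.

**Peak regions** are the top-K voxels by |statistic| among those with
p < threshold, optionally within a medial-parietal restrict mask, ties
at the K-th value broken by ascending voxel index. K must stay well
below the significant-voxel supply: when K exceeds the strongly
significant core, the region absorbs every threshold-passing voxel in
the mask, including chance voxels inside *other* factors' territories,
which injects systematic cross-factor leakage. The study regime (K =
1000 out of a far larger significant supply) selects peak cores; at
desk scale the tests therefore set K to the smallest planted-region
size. On synthetic recovery problems the regions are scored against
ground truth by ranking on |mean slope| rather than |t| within the
p-eligible set — searchlight t-values are nearly scale-free along the
smearing halo of a compact region, while the effect magnitude peaks
inside it.

**Leave-one-out selectivity**: for each held-out session, each factor's
region is recomputed from the remaining sessions; the held-out session's
effect map (level maps reduced to a linear trend across levels) is
standardized across all in-mask voxels and averaged within each region;
each (region, factor) cell is then tested against zero with BH-FDR over
all cells. Standardization centres on the across-voxel **median**: a
small strongly-driven region would shift the mean of the reference
distribution and leak an offset of opposite sign into every other
region, whereas the median is insensitive to it. Regions may overlap (no
winner-take-all); folds with an empty region are skipped and logged.

## The synthetic-study generator

The generator's defaults *are* the study conditions: 32 sessions × 300
videos; strength marginals (.180, .174, .209, .202, .235); emotion
marginals (.011, .041, .275, .378, .295); 74.3 % of videos with people,
93.2 % of those familiar, 80 % familiar places; Spearman couplings
(age, strength) = −0.16, (age, emotion) = −0.07,
(distance, strength) = +0.19, (distance, emotion) = +0.19; ages up to
2547 days.

Ratings are coupled to age and distance through a **Gaussian copula**:
latent correlations r = 2·sin(πρ/6) target the configured Spearman
values; uniforms are then pushed through the marginal quantile
functions. Discretizing to five levels attenuates the realized Spearman
by a few percent (measured ≈ −0.14 vs the −0.16 target at n = 300); the
couplings are left as configured rather than inflated, since all
downstream checks tolerate this.

Per-session **time spans** are drawn from the study's composition
(≈ 11/23 sessions spanning 0.5–1 year, 6/23 1–2 years, 6/23 2–7 years),
ages uniform within the span — a homogeneous 7-year span would leave
only a handful of "recent ≤ 90 days" videos per session, contradicting
the recorded protocol's premise that both recency bins are well filled.
**Distances** are a heavy-tailed mixture: 70 % log-uniform on
[0.1, 50] km, 30 % on [50, 15000] km, with the lowest 30 % of draws
pinned to a per-session "home" point (rank-preserving, so the copula
couplings survive); locations are realized by great-circle destination
points at random bearings from the scan site (Bethesda, MD). Novel-place
probability is logistic in log-distance with the intercept solved by
bisection to hit the 20 % marginal; novel places get a mean-centred
latent strength boost (default 0.3 SD) mirroring the observed
better-remembered novel places. The self-given-people proportion (0.20)
is not reported in the source material and is a chosen default.

**Brains**: voxel value = baseline + Σ planted slope × standardized
predictor (inside named ROIs) + contrast shifts (± effect/2 by group)
+ Gaussian noise, on a box atlas (default 24³, 1-voxel border; ten
disjoint cubic ROIs of 27–125 voxels packed on a 3×3×3 cell lattice,
including four medial-parietal factor regions, a pure-noise control
region, and a planted-geometry region). The temporal geometry embeds
each video's coded age f(age) (linear/log₁₀/scaled-exp) on a circular
arc of ≤ π radians spanned by two random orthonormal voxel patterns, so
1 − Pearson dissimilarity increases monotonically with |f(aᵢ) − f(aⱼ)|.
Paired-viewing stacks contain no dependence on the partner's ratings
except an optional "stimulus memorability" leakage term (partner's
strength, small slope, in the strength-planted ROIs). Feature matrices
spread a latent signal s = r·z(target) + √(1−r²)·noise across random
loadings so the best linear readout has population correlation r.

What the generator does **not** emulate: spatial autocorrelation of
fMRI noise (noise is i.i.d. per voxel), hemodynamics and temporal
autocorrelation, inter-session registration error, non-Gaussian voxel
noise, and realistic effect sizes — planted signal-to-noise is chosen
high enough that desk-scale recovery is decisive, so passing tests
demonstrate correctness of the machinery, not expected power on real
data. Run assignment emulates the even-temporal-sampling scheme
(equal-count age strata, jittered within-stratum choice, runs assigned
by permuting consecutive strata blocks).

## Problem sizes and test design

The validation suites run at reduced sizes chosen to keep the full
battery in the minutes range while leaving effects decisive: typically
6–16 sessions of 60–200 videos on 14³–24³ grids (searchlight recovery
and topography at 24³, the spec grid for those analyses; ROI-level
simulations at 14³–16³). The selectivity battery uses a generator
configuration with all cross-feature couplings zeroed, so the planted
ground truth is orthogonal — with the default couplings a strength
region *correctly* responds to the age contrast through the behavioral
correlation, which is a property of the data, not a pipeline error.
Calibration checks (type-I error of each group test) use 200–300 null
simulations against 99 % binomial bands. All simulations are
deterministic given their seeds.

## Known limitations

- The ANOVA variant, the z-scoring reference set, and the exponential
  code's time unit are underdetermined by the source protocol; the
  choices above are documented, not asserted as the original ones.
- `geo_vector_rdm`'s sub-kilometre sign flip (negative log length) is a
  property of the chosen convention.
- The leave-one-out folds share region-defining sessions, so fold values
  are weakly dependent; the per-cell t-test is slightly anticonservative
  in small samples.
- The SVR protocol fixes a linear kernel with default regularization,
  standardizing features on training folds only; kernel and
  hyperparameters were not specified by the source protocol.
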