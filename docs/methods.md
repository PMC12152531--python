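# Methods

## Model and procedure

The pipeline treats an annotated micrograph as a planar geometry problem.
Fibrils are straight segments (their annotated start/end points); gold
particles are points (their annotated centres). The physical contact
criterion — a gold particle conjugated to a secondary antibody whose
primary antibody touches the fibril surface — translates into a
centre-to-axis distance threshold

    t = r + a + d/2

where r is the gold-particle radius, a the primary+secondary antibody
complex span, and d the fibril width (so d/2 is the half-width from axis to
surface). Defaults r = 5 nm and d = 17 nm are values measured directly on
negative-stain micrographs; a = 30 nm is a literature value for an
IgG–IgG complex. The resulting 43.5 nm threshold is reported rounded as
~44 nm. Note one terminology trap: in figure-caption style the 8.5 nm
half-dimension is sometimes called the fibril "diameter"; here d = 17 nm is
the full width and the threshold always uses d/2 = 8.5 nm.

The point-to-segment distance is the standard one: perpendicular distance
when the orthogonal projection falls inside the segment, distance to the
nearer endpoint otherwise. The endpoint case needs no separate code path —
clamping the projection parameter to [0, 1] produces it — and this is
exactly the intended treatment of particles located off a fibril end.

A particle whose minimum distance over all fibrils of its micrograph is
<= t is bound, and is assigned to the closest fibril only, so every bound
particle contributes to exactly one fibril. The comparison is inclusive at
equality (a measure-zero event; the choice is stated once and tested) and
ties between exactly equidistant fibrils go to the first fibril in file
order, a deterministic rule. The per-fibril binding score is
bound_count / length in particles per nm; fibrils with no bound particles
score 0 and stay in the analysis.

### Crowding filter

Fibrils lying closer together than an antibody complex can reach are
sterically shielded, and annotators typically skip them. For exhaustively
annotated or synthetic data, `crowding_filter` reproduces that selection:
greedy retention in file order, dropping any fibril whose minimum
segment-to-segment distance to an already retained fibril is below
`min_separation`. The filter is off by default (curated annotations are
assumed already selected); when enabled its default separation is the
binding threshold, since a particle between two fibrils closer than t is
ambiguous by construction. The value is a documented package choice — no
quantitative "sufficiently separated" rule exists to inherit.

## Statistical comparison

Scores are pooled per sample across micrographs and treated as independent
observations (fibrils are the unit of analysis; no micrograph-level random
effect is modelled). The two-step procedure:

1. **Gate.** Shapiro–Wilk per group at alpha = 0.05 (applied per group, not
   to pooled residuals). All groups pass -> parametric route; any failure,
   any group with n < 3 (the test's minimum), or a constant group ->
   nonparametric route.
2. **Omnibus.** One-way ANOVA (parametric) or tie-corrected Kruskal–Wallis
   H (nonparametric). If every observation in every group is identical the
   statistic is undefined and the pipeline raises instead of guessing.
3. **Post hoc**, only when omnibus p < 0.05 (an explicit override flag
   exists and is recorded in the output). All-pairs mode: Tukey HSD
   (parametric; its p-values are family-wise already, so raw = adjusted) or
   Mann–Whitney U with Bonferroni m = k(k-1)/2 (nonparametric). Reference
   mode: only the k-1 pairs involving the reference, Bonferroni m = k-1,
   with two-sample t-tests on the parametric route. Mann–Whitney is
   two-sided; exact when both groups have n <= 20 and the pooled data has
   no ties, asymptotic with tie correction otherwise.

Labels use strict asterisk boundaries (*** iff p < 0.001, etc.), and the
Bonferroni adjustment is capped at 1. Homogeneity of variances is not
tested before ANOVA; this is a known limitation of the procedure as
specified, mitigated in practice by the gate routing skewed score
distributions (which are also typically heteroscedastic) to the
nonparametric branch.

All statistics are computed on complete data. The violin plots may hide
points beyond 1.5 × IQR from the quartiles for readability; the plotting
layer has no channel back into the statistics, and a dedicated test
asserts report equality with the rule on and off.

## Synthetic data generator

The generator emulates the statistical structure of annotated immunogold
data, not the images: straight fibrils with uniform random centre and
orientation and truncated-normal lengths (mean 400 nm, sd 150 nm, truncated
at 0 — chosen as a realistic span for fibril extents at high-magnification
TEM; no empirical length distribution is available to fit); per fibril a
Poisson(lambda_bound × length) number of planted particles at uniform
positions along the axis with perpendicular offsets uniform on
[0, threshold] (the least-informative distribution consistent with the
binding definition — any such particle is bound by construction); and a
Poisson(background_density × area) uniform background field. Everything is
driven by one `numpy` Generator seeded from the config, so identical seeds
give identical annotation sets.

A synthetic "sample" stands for the pooled annotated area of a labelling
experiment (real studies pool fibrils from ~100 micrographs per sample),
hence the default 10,000 × 10,000 nm field with 150 fibrils — group sizes
of the same order as the real datasets.

Two optional constraints support exact ground truth: `min_separation`
(pairwise fibril spacing, rejection-sampled with an attempt cap that raises
with advice to lower the density) and `edge_margin` (endpoints kept at
least that far from the border). With min_separation >= 2t fibril capture
regions cannot overlap, and with edge_margin >= t each capture region — a
stadium of area 2tL + pi t^2 — lies fully inside the uniformly sampled
field, giving the closed form

    E[mean score] = lambda_bound + 2 rho t + pi rho t^2 / mean_length.

The end-cap term uses the truncated-normal mean length, i.e. approximates
E[1/L] by 1/E[L]; the relative bias is of order CV^2 on a term that is
itself ~100× smaller than typical planted rates, far below the Monte-Carlo
resolution of the recovery tests. What passing recovery tests show is that
assignment and scoring are unbiased under the generative model; they say
nothing about annotation quality, labelling efficiency, steric occlusion or
antibody avidity in real micrographs, none of which are modelled.

## Numerical and design choices

- All internal computation is in nm; pixel inputs are scaled once at load.
  Distances are double precision with no rounding before the threshold
  comparison.
- Segment-segment distances (crowding filter, generator spacing) use
  shapely; point-segment distances are computed vectorized in numpy and are
  cross-checked against shapely and against dense sampling in tests.
- Fibrils extending beyond the image border are kept as annotated; the
  annotations define the analysed extent.
- Violin KDEs use the scipy Gaussian KDE with its rule-of-thumb bandwidth;
  the realised bandwidth factor and the per-sample count of
  display-excluded points are recorded in a JSON sidecar next to every
  figure. Violins are clipped at zero because scores cannot be negative.
- The overlay figure draws fibrils as bands of width d and particles as
  circles of radius r + a, making the threshold rule visually checkable:
  circle-touches-band is algebraically identical to distance <= r + a + d/2
  (tested programmatically with an independent polygon-intersection
  oracle).

## Problem sizes in the test suite

The simulation-backed tests use 8-fibril isolated fields over 200 seeds per
rate setting for score recovery, 100 seeded six-sample experiments at 150
fibrils/sample for the group-comparison check, and 500 replicates per route
for null calibration — sizes chosen to put Monte-Carlo standard errors well
below the effects being checked while keeping the suite quick to run.

## Known limitations

- Fibrils are straight segments; strongly curved fibrils must be annotated
  piecewise, and the pipeline will then treat the pieces as separate
  fibrils.
- Observations are pooled across micrographs within a sample; micrograph-
  or animal-level clustering is not modelled.
- No effect sizes are reported, only p-values with asterisk labels.
- The generator does not render images and does not model stain texture,
  gold clustering, or partial labelling.
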