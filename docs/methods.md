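# Methods

This note documents the models implemented in `rivaq`, the conventions
that had to be fixed where the field literature leaves them open, the
defaults and why, and what the synthetic generators do and do not emulate.

## TIN surfaces (`rivaq.tin`)

Scattered head or water-surface points (projected metres; geographic
coordinates are rejected by design, since gradients need metric units) are
triangulated with a Delaunay triangulation of their (x, y) projections —
reproducible, convex-hull-complete and the standard choice of GIS TIN
tooling.  Each triangle defines a unique plane `z = a·x + b·y + c` from
which three attributes follow:

* elevation — mean of the three vertex z;
* slope — `|∇z| = hypot(a, b)`, dimensionless; on a piezometric surface
  this is the hydraulic gradient *i*;
* aspect — azimuth of the **downslope** vector `(−a, −b)`, degrees
  clockwise from grid north.  Downslope (not upslope) because the aspect
  is read as the direction of groundwater or river flow.

Conventions fixed here:

* Slopes below 1e−12 are treated as exactly flat; flat triangles carry
  `defined_aspect = False` and contribute zero flux downstream instead of
  erroring (dry or flat reaches are physically meaningful).
* Point lookups on shared edges/vertices resolve to the adjacent triangle
  with the **lowest index** — a deterministic tie-break.
* Duplicate input locations with identical z are merged; with conflicting
  z they are an error (`ambiguous elevation`).

Segment sampling (`sample_segment`) returns length-weighted means over the
triangles a segment crosses: the arithmetic mean for slope, the exact
chord integral for elevation, and the length-weighted circular mean of
unit vectors for aspect.  A segment lying in a single triangle degenerates
exactly to the midpoint lookup, and a zero-length segment to `sample_at`.

## Darcy exchange chain (`rivaq.exchange`)

Per bank segment:

```
D  = aspect_piezo − aspect_river, normalized to (−180°, 180°]
A  = max(groundwater head − riverbed elevation, 0)        [m]
Qe = 86400 · K · i · A · sin(D)                            [m³/day per m]
```

* *A* is treated as a saturated **thickness in metres** and Qe as a flux
  per metre of bank, so that `Qf = Σ Qe·L` lands in m³/day — the only
  dimensionally consistent reading when typical sections are ~4.2 m.
* The 86400 s/day factor is applied inside `segment_qe`; daily fluxes are
  the legible scale for these weak exchanges (~10⁻³ m³/s per km).
* The gradient *i* is the non-negative TIN slope magnitude; **all**
  directionality lives in `sin(D)`.  Positive Qe = aquifer feeds river.
* Groundwater head along a segment is read by exact plane interpolation at
  the segment midpoint, not from the triangle-mean elevation.
* Zone aggregation keeps the two signs separate (`Qf_pos ≥ 0 ≥ Qf_neg`,
  with their own bank lengths), mirroring synthesis tables that report
  gaining and losing sub-reaches of one zone on separate rows.
* Unit flow `Qu = Qf/(L/1000)` is reported as an integer, rounded half
  away from zero.  The packaged reference-sector synthesis table
  (`rivaq/data/bregnier_cordon_zone_fluxes.csv`) reproduces the published
  sector totals exactly under this rule (−3538 m³/day lost over 8214 m,
  i.e. −431 m³/day/km; +62566 m³/day gained over 14678 m, i.e. 4263
  m³/day/km); a few printed per-zone unit flows are consistent only with
  rounding applied before the flux itself was rounded, so only the
  unambiguous ones are asserted in tests.

Out of scope by design: transient flow, gridded numerical groundwater
models, riverbed clogging/conductance, and calibration against head
observations.

## Stygobite indices (`rivaq.stygofauna`)

Richness S counts distinct stygobite taxa in the pool; S% divides by the
pool's total distinct richness (the denominator is per-pool — per sample,
site or section — not per campaign).  Abundances from repeated visits are
summed, preserving integer counts.  Section classification defaults:
a site with **S ≥ 2 taxa and ≥ 10 individuals** marks clear upwelling; a
section with no stygobites at all is classed `none`; anything between is
`mixed`.  These cut-offs separate the observed field contrasts (e.g. 15
individuals of several taxa at one station versus entirely barren
reaches); they are configuration, echoed in every output so verdicts stay
auditable.  A packaged reference list carries the nine regional stygobite
species with their kilometric ranges.

## Macrophyte profiling (`rivaq.macrophytes`)

Site descriptors:

* thermal axis — relative standard deviation (sample SD / mean, %) of ≥12
  monthly temperatures; low variability indicates groundwater feeding;
* phosphorus axis — `mean(log10 monthly PO₄) + z(log10 mean substrate P)`,
  the z-score taken across sites; substrate replicates are averaged
  before the log, and zero concentrations are shifted by half the smallest
  positive value of the same variable (detection-limit device);
* ammonia axis — mean monthly NH₃.

Sites are split into **equilibrated classes** (5 for temperature and
phosphorus, 4 for ammonia): equal-count ordered bins whose sizes differ by
at most one for distinct values; ties on a boundary all fall into the
lower class.

Species profiles: for every species occurring in ≥ 5 sites, per-class mean
abundances (Braun-Blanquet codes converted as r→0.1, +→0.5, 1..5→1..5;
configurable) are normalized to sum 1.  A mean-centred Levene test at
α = 0.05 gates the class-difference test — one-way ANOVA under variance
homogeneity, Kruskal–Wallis otherwise; α is a declared default, exposed in
configuration.

The 5-class phosphorus and 4-class ammonia profiles combine into one
4-class trophic profile by an **ordered-quantile correspondence matrix**
(class j of 5 spreads over the 4 target classes by quantile-interval
overlap), then averaging and renormalizing.  The matrix is an explicit,
overridable configuration value.

Site scoring: `class_score[c] = Σ_species bb(code) · weight[c]`; the
argmax class is the site's trophic level, ties resolving toward the more
eutrophic class (flagged).  The groundwater-influence index is

```
index = max(#groundwater-preferring − #stenothermy-intolerant, 0)
```

mapped to classes 0 → null, 1–4 → low, 5–9 → intermediate, >9 → high.
Two conventions are deliberate closures of gaps in the published class
bounds (which leave the value 4 unassigned and the subtraction order
ambiguous relative to the class labels): index 4 is `low`, and the
subtraction is oriented so that a **larger index means more groundwater
influence**; both are echoed in output metadata.  Thermal categories are
assigned from the temperature-variability profile of a species: a
significant profile peaking in the two most stable classes ⇒
groundwater-preferring; in the two most variable ⇒ stenothermy-intolerant;
otherwise indifferent.

Nitrate-based profiling is explicitly out of scope (nitrate rarely tracks
eutrophication in these systems), as are ordination methods and trait
databases.

### Worked example

The originally published worked example for this scoring scheme (a relevé
whose best trophic-class score is 4.46) was distributed only as a
supplementary archive that cannot be redistributed with this package, and
its tables are not reconstructible from the open literature.  The scoring
operation is therefore validated against brute-force double-loop oracles
and linearity/tie-break properties on synthetic relevés instead; the
acceptance-level check against the published value is left failing with an
explicit message rather than silently passing on a stand-in.

## Overlay (`rivaq.overlay`)

The three maps align on a user-supplied partition of KP intervals per
bank (KP decreases downstream on the main channel; interval membership is
by metric midpoint).  Reduction of each metric to a sign is explicit
configuration with these defaults: hydraulic sign(Qu); macrophyte
null → loss, low → none, intermediate/high → gain; invertebrate
none → loss, mixed → none, upwelling → gain.  Verdicts: convergent when
all present metrics agree on a direction, divergent when gain and loss
are both claimed, partial when agreement involves a neutral metric,
incomparable below two metrics.  Correlations are ordinary least squares
(R² = squared Pearson, two-sided slope t-test) on ordinally encoded
classes (none/null = 0 … high = 3, configurable); the three indicator
pairs are reported raw, without multiple-testing correction.

## Synthetic generators (`rivaq.synthetic`)

All generators are pure functions of config + seed.

**Valley.**  A straight river flows north along `x = x_river` with a
planar stage surface (slope −5e−4 along flow by default).  Piezometric
head is `h = stage(y) + g(y)·(x_river − x)` with the toward-river gradient
g constant inside each reach (defaults: a gaining reach at g = +2e−3,
K = 1.3e−3 m/s and a losing reach at g = −2e−3, K = 3.9e−4 m/s) and
linearly interpolated across a 400 m transition band that carries no bank
segments.  Grid rows sit exactly on reach boundaries, so every triangle
used by a segment lies in an exactly planar region and the per-zone flux
has the closed form `Σ 86400·K·i·A·sin(D)·L`.  Defaults mirror an alpine
alluvial corridor: K within 1e−5–1.3e−3 m/s, exchange sections ≈ 4.2 m,
~684 surface points.  Head noise is available but **off by default** so
the oracle comparison is exact (observed pipeline error ~1e−11 %).  What
this does not emulate: curved rivers, heterogeneous K within a reach,
non-planar head fields, measurement error — so a 1 % recovery bound shows
chain correctness, not robustness to real survey noise.

**Communities.**  36 wetlands carry a planted 4-level trophic class
(phosphate, substrate P and ammonia all scale with it, distinct levels
0.01–0.8 mg/L NH₃ and 0.005–0.8 mg/L PO₄ with 0.05 log₁₀ within-class
spread) and an independent temperature-variability level spanning 2–40 %
CV; realized monthly series are rescaled so the sample CV equals the
planted value exactly.  40 species (24 trophic indicators, 16 thermal)
follow a geometric unimodal response (ratio 0.15 per class step, expected
count 30 at the optimum; Poisson by default, negative binomial optional)
rendered as Braun-Blanquet codes.  This plants sharp, separable structure;
real communities have broader niches, interacting gradients and
observation error, so the ≥80 % site-class and ≥90 % species-optimum
recovery demonstrated on these defaults are upper-bound behaviour, not a
field performance claim.

**Stygofauna.**  Per-zone upwelling intensities drive Poisson stygobite
counts (species drawn from the packaged reference list with a fixed
rank-abundance weighting) over a constant epigean background; zero
intensity yields strictly zero stygobites.

## Problem sizes and determinism

The test suite and the acceptance script run the valley at ~684 TIN points
and 36 segments, communities at 36 sites × 40 species, and fauna at 2–500
site visits; the whole suite completes in a few seconds on one CPU.  All
randomness flows through `numpy.random.default_rng(seed)`; the acceptance
script derives its per-stage seeds from `--seed`.  Statistical recovery
assertions (≥80 % / ≥90 %, Monte-Carlo 2-SE checks) are evaluated at fixed
seeds and hold across the seeds exercised.

## Known limitations

* The hydraulic sign convention (sign of sin D) encodes gaining/losing
  correctly for the bank geometry used here (groundwater approaching from
  the left of the river-flow azimuth = gaining); mirrored right-bank
  geometries must be supplied in a consistent orientation.
* Segment sampling reads heads at segment midpoints; on strongly curved
  surfaces this differs from a true line integral of the flux.
* Equilibrated-class binning with heavy ties can produce unbalanced
  classes (tie rule above); the class sizes are available for inspection.
* The overlay's ordinal encodings and sign reductions are conventions;
  correlations between ordinally encoded classes should be read as
  rank-style associations, not calibrated effect sizes.
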