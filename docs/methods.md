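# Methods

This note records the models, the defaults that matter, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Catalogue: groups and social units

Photographs below quality Q = 3 are discarded before any social inference.
Two individuals *associate* on a day when the minimum gap between their
photo times that day is ≤ 2 h; when one of them has no timed photograph
(archival records), same-date co-occurrence is accepted and the association
is flagged. A *group* is a connected component of the association graph
pooled over all days (components sharing a member merge across days); a
*social unit* is a component of the sub-graph restricted to pairs associated
in at least two distinct calendar years. Calendar year, not field season,
defines "different years". Island labels are attached by nearest gazetteer
centroid (great-circle distance).

Open choices resolved here: the 2-h rule is applied to the minimum pairwise
time gap over each individual's photos of the day (rather than first-photo
times), because it is the least restrictive reading consistent with "observed
within 2 h of each other".

## Coda typing

Codas with fewer than 3 or more than 11 clicks are excluded (inconsistent
marking of very short/long codas), and daily repertoires with fewer than
25 codas are dropped; both filters report their exclusions so that
kept + excluded always equals the input.

Within one click-count family (dimension d = clicks − 1) the ICI vectors
are fitted by EM with k Gaussian components plus one fixed contamination
component, uniform over the observed ICI bounding box padded by 5% per
side. The contamination mass is re-estimated by EM but the component's
density is fixed; this is a deliberately minimal robust-mixture variant —
per-component contamination inflation would add parameters the data here
cannot separate, and the choice is config-exposed (`covariance`,
`cont_w0`). Defaults: diagonal covariances (ICI dimensions are weakly
coupled and diagonal fits avoid singularities at small n; full covariance
is available), variance regularization 1e-6 s², EM tolerance 1e-8 relative
log-likelihood, ≤ 500 iterations, k-means initialization seeded per family.
k is chosen by BIC over k = 1..15, stopping after three consecutive BIC
increases past the incumbent. Components are re-ordered lexicographically
by mean vector, so type identifiers "<clicks>-<index>" are deterministic
under a fixed seed.

Rhythm labels: a type is "<n>R" (regular) when max/min mean ICI ≤ 1.15;
otherwise the click train is split where an ICI exceeds 1.8× the minimum
ICI and labelled by "+"-joined sub-group sizes ("1+1+3"). Both thresholds
were set so the canonical regular and one-plus-one-plus-three shapes label
correctly and are config-exposed.

All sources are pooled into a single type space before fitting: repertoires
from different sources must be comparable in the clan step, which requires
one shared set of types.

## Clan delineation

Usage repertoires pool all codas of one day, keyed by the combination of
group labels recorded that day; unclassified (contamination) codas count
toward the 25-coda size filter but never toward usage proportions.

Similarity is the Bhattacharyya coefficient Σ_t √(p_a p_b) (1 iff the
distributions are equal, 0 on disjoint support); clustering is average
linkage on distance 1 − similarity with leaves pre-sorted lexicographically
for deterministic tie-breaking.

Identity codas: type t marks clan c when (i) ≥ 50% of c's repertoires use
t at proportion ≥ 0.05, (ii) t's mean proportion outside c is ≤ 0.05, and
(iii) no other clan also satisfies (i)–(ii) for t. The exclusivity clause
(iii) is essential, not cosmetic: the mean-outside-usage bound dilutes as
partitions get finer (most repertoires outside a small cluster do not use
the type at all), so without exclusivity even singleton clusters "own"
moderately-used types and the cut search below degenerates into all-singleton
partitions. A marker that identifies two different clans identifies
neither; that is the operational content of "used consistently by one set
of repertoires and rarely by others".

The accepted partition is the dendrogram cut with the largest number of
clusters in which every cluster owns at least one identity coda (the cut
search walks the ≤ n − 1 merge heights from finest to coarsest; the first
qualifying cut is the maximal one because cluster counts only shrink).
If no cut qualifies, a single clan is returned with an explanatory note.
The partition is then re-derived by clustering on identity-type usage alone
(renormalized over the identity set) and the adjusted Rand index between
the two partitions is reported as `stability_ari`; `similarity_mode=
"identity-weighted"` makes that second partition the canonical output.

The threshold sweep re-runs the delineation over a 3×3×3 grid around the
defaults and reports each point's partition, the pairwise ARI matrix and
the fraction of points agreeing exactly with the modal partition. On the
default synthetic bundle agreement is ≈ 0.93; the disagreeing points sit at
u_min = 0.10, where a sampling-noise sub-split of one clan can qualify via
a moderately-used type (the resulting partitions still have ARI ≥ 0.96
with the modal one). This sensitivity is a property of the method that the
sweep exists to expose, not a defect to be tuned away.

Heat-map shading of usage proportions: white = 0, light = (0, 0.05],
mid = (0.05, 0.10], dark > 0.10.

## Movement and space

**Projection.** All likelihood math runs in a planar km frame produced by
an azimuthal-equidistant projection about the study centroid (14.5° N,
61.0° W). An equirectangular map with the origin's fixed cosine was
rejected: its east–west scale error reaches ~1.2% at the edges of a 600-km
box, while azimuthal equidistant keeps pairwise distances within 0.05% of
great-circle values there. Geographic I/O stays in lat/lon; great-circle
distances use the haversine form with Earth radius 6371 km.

**Windowed displacement.** Tracks (5-min fixes) are truncated to the
first/last whale-cluster sighting when bounds are supplied, then tiled into
consecutive windows (1/3/6 h); a window's displacement is the great-circle
distance between its first and last fix, with the boundary fix shared by
adjacent windows so displacements tile without gaps. Windows with < 80% of
the expected fixes are dropped and counted, as are windows implying more
than 12 km/h (a 5-min-fix vessel track faster than that indicates a track
error; the guard is a parameter).

**Effort.** The effort field counts, per grid cell (0.05° default), the
number of survey days with identification effort that surveyed the cell. A
cell counts as surveyed when it contains a fix or, with `radius_km > 0`,
when its centre lies within that distance of a fix — the area actually
searched extends to the detection radius around the track, and without the
dilation, photographs taken away from the vessel's own cells would sit in
zero-effort cells and be rejected by the likelihood. Pairs whose end point
nevertheless falls in a zero-effort cell are dropped with a warning.

**RMS displacement likelihood.** Sightings are first reduced to one per
individual per day (earliest), and only lags strictly greater than one day
enter (within-day positions are autocorrelated because whales were actively
followed). For each lag bin (τ_lo, τ_hi] — default geometric edges 1, 2, 5,
10, 30, 90, 180, 365, 500 days, since the appropriate binning is a property
of the data density — all same-individual ordered sighting pairs with lag
in the bin contribute

log L(s) = Σ_p [ log E(cell(y_p)) − |y_p − x_p|²/(2s²) −
           log Σ_z E(z) exp(−|z − x_p|²/(2s²)) ],

an isotropic bivariate Gaussian displacement model conditioned on detection
proportional to cell effort (constant factors cancel). This per-bin
formulation is one concrete operationalization of the effort-corrected
likelihood idea (a continuous-across-lags diffusion fit is a possible
extension) and reduces exactly to the naive sample RMS when effort is flat. s is maximized by bounded scalar
search on log s over (0.1, 5000) km (estimates within 1% of a bound are
flagged); rms = s√2. `max_pairs_per_bin` optionally subsamples pairs with a
seeded RNG (estimates stay unbiased; only the variance grows). Identifiability
caveat: when the true displacement scale is much larger than the surveyed
area, the likelihood flattens and the estimate degrades toward the boundary
flag — effort must cover a non-trivial fraction of the displacement scale.

**Jackknife.** Standard errors leave out one individual at a time:
se = √(((n−1)/n) Σ_i (θ_(i) − θ̄)²) with n the number of individuals
contributing pairs to the bin; bins with fewer than two contributing
individuals report no SE. On replicate pure-diffusion simulations the mean
jackknife SE is within a few percent of the replicate SD of the estimator.

**Kernel density.** Gaussian KDE of encounter fixes on a lat/lon grid
(0.001° default display resolution), evaluated separably in the planar
frame; bandwidth defaults to Silverman's rule per clan (the field's GIS
default is unspecified, so it is config-exposed). The grid extends 5
bandwidths beyond the data so the mass integral equals the fix count to
within 0.1%.

**Same-island fraction.** Among individuals seen in ≥ 2 calendar years, the
fraction whose island-label set is a singleton, per clan with numerator and
denominator reported.

**Scale comparison.** `compare_scales` divides packaged reference constants
(Eastern Tropical Pacific social-unit sizes, 3/6-h displacements, daily and
yearly RMS, range) by the corresponding estimates and flags ratios ≥ 10.

## Synthetic data

The generator emulates a study system of the Eastern Caribbean's shape.

*Codas*: 3 clans × 5 groups × 10 days (150 cells on unique calendar dates
striding both survey years), per-day counts Poisson(120) floored at 25,
with 5% of cells deliberately sub-threshold (5–24 codas) to exercise the
repertoire filter. Each clan's usage mix puts its dominant identity types
at 54%, 61% and 57% of output respectively; three background types
(3R/7R/8R) are used by every clan at rates whose cross-clan means are well
above the identity out-max threshold, so they are unambiguously shared.
ICIs are Gaussian (sd 10 ms) about the type means, floored at 10 ms. A
`leakage` parameter spends usage mass on other clans' identity types to
probe the delineation's breakdown.

*Movement*: units follow a discrete-day mean-reverting walk about a home
island, X_{t+1} = home + (1−a)(X_t − home) + ε, ε ~ N(0, σ_d² I), with
σ_d = 10 km/√day (daily RMS displacement σ_d√2 ≈ 14 km, matching the
10–20 km scale a resident population shows), attraction a = 0.3 (stationary
per-axis spread σ_d/√(1−(1−a)²) ≈ 14 km — island scale), rare home
switching (0.002/day) between the clan's islands, and 1-km member jitter
about the unit track. Setting a = 0 and switching = 0 gives pure Brownian
motion — the calibration preset with closed-form truth.

*Survey*: a vessel runs the leeward island arc (shifted 10 km west) back
and forth at four knots, 12 h and 144 five-minute fixes per day, across
Feb–Apr 2019 and Jan–Mar 2020. Units whose centroid comes within 15 km of
the day's track are encountered (nearest four), members photographed with
probability 0.95, qualities uniform on 1–5 (so Q ≥ 3 keeps ~60%), encounter
time windows spaced 3.5 h so distinct units never fall inside the 2-h
association window by construction. Detection is therefore spatially biased
by design, which is what the effort-corrected likelihood must undo.

What passing the synthetic tests does **not** show about real data: planted
types are well separated (≥ 5 sd), whereas real coda types can grade into
one another; clan usage mixes are stationary in time; detection within the
radius is spatially uniform and photo quality is independent of distance
and behaviour; movement is isotropic with no coastline constraint; and the
vessel never alters whale behaviour. Recovery results are therefore a
correctness floor for the machinery, not a field performance claim.

## Problem sizes

The test suite and `scripts/acceptance.py` run the default 150-cell coda
bundle (~17–18k codas), movement calibrations with 120–200 individuals
yielding 300–800 pairs per lag bin, and 100 replicate datasets of 25
individuals for the jackknife calibration — sizes chosen so each
statistical check has comfortable power while the whole pipeline remains a
few minutes of single-CPU work.

## Known limitations

- The delineation assumes every clan owns at least one identity coda; a
  real clan marked only by usage *gradients* (no exclusive types) collapses
  into its neighbour.
- The movement likelihood treats lag bins independently rather than fitting
  one continuous diffusion across lags, and models displacement as
  isotropic Gaussian; heavy-tailed or coast-following movement will bias s.
- The effort field is binary per day (surveyed / not), ignoring time spent
  per cell.
- Identity-coda thresholds are in proportion units and insensitive to
  repertoire size differences beyond the 25-coda floor.
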