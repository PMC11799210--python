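# Methods

This note documents the models, conventions, and design choices behind
`thermobias`, in the order data flows through the pipeline.

## Time binning and occurrence ingest

Analyses run on an ordered sequence of time bins (default: the six ammonite
(sub)zones Margaritatus, Spinatum, Tenuicostatum, Exaratum, Falciferum,
Bifrons, ~1 Myr each), with the bins immediately before and after the
sequence (Davoei, Variabilis) tracked as *flanking* bins for edge-boundary
classification. Rows binned only to an undivided parent zone that the
analysis resolves into subzones (e.g. an undivided "Serpentinum") cannot be
placed and are dropped by default; a sensitivity switch duplicates them into
both subzones instead. Species names are normalised conservatively
(whitespace collapse, genus capitalised, epithet lowercased, optional
user-supplied synonym table); no fuzzy matching, since taxonomic vetting is
an expert task, not a string-distance one. Every ingest drop is counted by
reason and the report reconciles: kept + dropped = input rows.

Habitat categorisation maps depositional lithology to
carbonate/siliciclastic and depositional environment to shallow/deep by
exact membership in four fixed keyword lists; anything else is `unknown`.
Environmental affinity per species uses an exact binomial test, one-tailed
in the direction of the observed deviation from the dataset-wide background
proportion (computed excluding unknowns), affinity assigned only at
p < alpha (default 0.1); a two-tailed variant is a flag. Where an occurrence
carries conflicting substrate descriptors, the first-listed primary
lithology is decisive.

## Temperature fields

A `TemperatureField` is a regular cell-centred lon-lat grid of summer mean
SST with NaN over land, plausibility-checked to [−5, 60] °C. Sampling at a
paleocoordinate returns the containing cell or, if land-masked, the nearest
unmasked cell within `max_search_cells` (default 2) by great-circle
distance, ties broken by smaller |Δlat| then |Δlon|; coordinates beyond the
search radius yield missing and are counted out of the thermal metrics.
Bilinear downscaling uses the four surrounding coarse cell centres with
mask-renormalised weights, so values never overshoot the coarse field's
range and a target cell is masked only when all four corners are. Field
comparison reports Spearman rho and RMSE over jointly unmasked cells; RMSE
is the plain root-mean-square of differences (the offset-sensitive variant),
with a mean-centred (residual SD) option, because the two diagnose different
disagreements: a constant offset leaves rho at 1 while inflating RMSE.

Each analytical series uses a single paleogeography's maps throughout
(primary 180 Ma rotation/coordinates, secondary 185 Ma as a sensitivity
axis) to avoid artificial coordinate jumps mid-series. The pCO₂ scenario
table (main and secondary ppm per bin) ships as YAML.

## Regions

Discrete regions are agglomerative clusters (default Ward) of the unique
occurrence paleocoordinates pooled over all bins, using Euclidean distance
on raw degrees (great-circle optional). Input order cannot affect the
partition: points are sorted lexicographically before clustering and labels
are canonicalised. The default cluster count is k = 10 for file-based data;
synthetic runs use the generator's region count. An independent ecological
clustering (average linkage on Jaccard distances between localities'
species sets, clusters under 14 species removed as small-sample
dissimilarity artifacts) validates the spatial partition via a pair-counting
(Rand) agreement index — the index is our choice, as is the linkage pair,
since standard practice leaves both open. A region is *analyzable* when it
has more than `min_occ_per_bin` (default 25, strict) occurrences in at
least two consecutive bins; a whitelist can force inclusion of a region
whose gaps are ecological rather than sampling-driven.

## Thermal metrics and sign conventions

STI is the **median** of a species' sampled temperatures pooled over all
regions and all bins of the analysis sequence (flanks excluded); the mean is
a sensitivity flag. Regional ambient per (region, bin) is the median of
temperatures at occurrence points (not polygon grid cells — regions are
occurrence-defined), with a locality-unique variant by flag.

**Sign convention:** thermal bias = preference − ambient, so positive =
prefers warmer than local conditions (immigrant-like), negative = cooler
preference (extirpation-prone under warming). With a common ambient, the
assemblage bias (median STI − T) equals the median of member biases — an
algebraic identity the tests assert numerically. Cool/warm weighting of the
CTI uses a weighted median with weights proportional to each member's
distance from the warm/cool extreme (configurable exponent); on a symmetric
member set the cool and warm weightings displace the CTI symmetrically
around the unweighted median. The exact kernel is a configuration choice,
not an asserted quantity.

Boundary climate phases default to: cold stasis (Margaritatus→Spinatum),
warming 1, warming 2, transitional, warm stasis; warming 1 + warming 2 +
transitional form the *warming-associated* subset the species model fits by
default. Custom bin sequences require an explicit boundary→phase mapping.

## Occupancy classification

Two-timer rules per (species, region, boundary i→i+1): persisting = present
i and i+1; immigrating = absent i, present i+1 and i+2; originating =
immigrating with dataset-wide FAD = i+1; extirpated = present i−1 and i,
absent i+1; extinct = extirpated with dataset-wide LAD = i. At the first and
last boundaries the i−1 / i+2 requirement may be met by a presence anywhere
in the dataset in the flanking bin, but a regional occurrence at the focal
boundary is still required — relaxation lets species pass the sampling
threshold without creating responses. Species matching no rule are
unclassifiable and excluded with counts. Species absent from the range
table classify at the non-extreme level (immigrating/extirpated) with a
warning. The three-timer variant centres on bin i; its required flank-bin
*presences* relax dataset-wide at the edges while required *absences* are
always regional.

The bias attached to a record is evaluated in its context bin: time i for
persisting/extirpated/extinct, time i+1 (the arrival context) for
immigrating/originating; a common-bin variant is a flag. Note this
convention couples levels to ambient whenever ambient changes — see the
null world below. Pooling for regression follows the conservative default
(extinct→extirpated, originating→immigrating), with five-level and
three-level (extremes dropped) variants, the latter guarding against the
circularity that extinct species' niches are estimated from past-only
occurrences.

Assemblage summaries report persisting/extirpated/extinct as percentages of
classified current-assemblage members (these sum to 100), immigrating and
originating as percentages of classified new-assemblage members (persisting
species included in the denominator — they are members of the new
assemblage too), and Jaccard turnover between the regional species sets.

## Inference

The species-level model treats the ordered response as continuous and fits
a linear mixed model by REML. Random structure: time zones (boundaries) as
groups with a random intercept, regions as a variance component within
zones, and optionally species-in-region as a further component. The
pipeline defaults to the region-in-zone structure: each (species, region,
zone) cell contributes exactly one record, so the innermost intercept is
confounded with the residual (unidentifiable) and costly to carry; the full
nesting remains available (`random="species_region_zone"`) and the fitter
reduces the structure automatically on singular/non-converged fits,
flagging the result. Fixed-effect p-values use t statistics with a residual
df approximation (n − p, configurable); clade is treatment-coded against
Bivalvia, with clades under 20 records dropped from clade models. R²:
marginal = var(Xβ) / (var(Xβ) + Σ random variances + residual);
conditional adds the random variances to the numerator. A
`force_zero_variance` fit pins all random variances at zero, in which limit
the mixed GLS solve is exactly OLS (tested to 1e-6).

Per-context slopes regress bias on (3-level pooled) response level per
(region, boundary) by OLS, keeping slope, SE, n, and ΔT; contexts with one
represented level are not estimable and are excluded. The meta-regression
is WLS of slope on ΔT with weights 1/SE², restricted to contexts with at
least 20 species. Because "R" on a weighted fit is ambiguous, both the
weighted correlation and the standardized slope are reported and labelled.

Assemblage models fit one (response, predictor) pair at a time with regions
nested in zones; thermal-bias predictors are weighted by the inverse SD of
member biases via a WLS transform of both sides. Predictions at a stated
warming propagate the fixed-effect covariance into the CI. Responses with
unidirectional hypotheses (origination/immigration and extirpation versus
bias) fit the warming-associated subset by default.

## The synthetic world

The generator emulates the structure the analysis assumes, not any real
dataset: conserved thermal niches, a handful of latitudinally ordered
regions, ordered climate phases, suitability-governed occupancy, imperfect
detection, and optional anoxia.

Default conditions (frozen as the study conditions): 500 species in three
clades (55% bivalve-analogs, 35% brachiopod-analogs with narrower niches,
10% gastropod-analogs); optima ~ N(29, 7) °C; five regions at latitudes
42–18° on an analytic SST surface T = 46 − 0.7·|lat| (regions ~4 °C apart,
initial regional means ~17–33 °C); boundary steps of about +0.2, +3.4,
+3.4, +0.8, −0.4 °C at the reference latitude, amplified poleward; 30
candidate localities per region-bin; detection 0.9 per species-region-bin
(a deliberately well-sampled record — the two-timer design targets exactly
such data, and detection misses masquerade as false immigrations and
extirpations that dilute every class contrast).

Occupancy follows a colonization/persistence Markov chain per (species,
region): colonization at rate 0.6 × suitability for absent species,
persistence at a wider-tolerance suitability for present ones
(persistence breadth = 2 × colonization breadth). The default suitability
kernel is **asymmetric ("warm_edge")**: peak establishment sits 2.5 °C
below the optimum (settlement needs thermal headroom against summer
extremes), the warm side of the niche is sharp, and the cool side 1.5×
wider — the upper-limit sensitivity typical of marine ectotherms. This
asymmetry, together with the establishment/persistence gap, is what makes
simulated assemblages lag the climate: cool-preferring legacy members
persist while only warm-preferring species newly establish. A symmetric
Gaussian kernel is available (`kernel="gaussian"`), but under it — with
biases computed from *realized* STIs and arrival-context ambients — the
persisting class's mean bias structurally exceeds the immigrants' and the
expected response gradient cannot emerge; we consider the asymmetric kernel
the ecologically faithful default, not a tuning device. Random streams are
split per component (niches, presence, detection, localities) so toggling
one never perturbs the others; identical configurations are byte-identical.

Presets: `tracking` (the defaults), `null`, `anoxia` (the two
high-latitude regions lose all habitat during the three early-warm bins,
emulating seafloor anoxia superseding temperature), and `clade-contrast`
(widened breadth gap between clades). The `null` preset makes occupancy
temperature-blind **and holds the trajectory flat**: with ambient change
present, the arrival-context convention alone shifts immigrants' ambients
upward relative to other levels, so a warming null would measure that
mechanical coupling rather than the estimation machinery.

What passing simulation tests does and does not show: the generator has no
spatial autocorrelation within regions, no abundance structure, no
preservation or lithology biases correlated with climate, and detection is
independent across bins; real fossil data violate all of these, so recovery
in the synthetic world is necessary, not sufficient, for inference on real
occurrences.

## Numerical choices and degenerate inputs

Coastal sampling ties break deterministically (distance rounded to 1e-9 km,
then |Δlat|, then |Δlon|). Spearman rho is snapped to exactly 1 when the
two fields' rankings are identical. Perfectly separable per-context
regressions (SE = 0) receive a floor SE of 1e-9 to keep inverse-variance
weights finite. Mixed fits run L-BFGS then Powell (max 500 iterations);
non-positive or non-finite SEs trigger the random-structure reduction.
Degenerate assemblage fits (constant response) report zero-width prediction
intervals. Empty inputs raise or return empty-with-warning as contracts
state, never silently.

## Problem sizes

Default test-suite simulations use 150-species worlds; the directional-
recovery and coverage checks run 100 seeds each at the full 500-species
conditions through the lean analysis path (world → classification → species
model), which keeps the whole suite around five minutes on one CPU. The
acceptance script performs one full 500-species pipeline run.

## Known limitations

Ordered responses are modelled as continuous (an ordinal-logit alternative
is exposed but is not the reference path). The species-level random
structure omits phylogeny and spatial autocorrelation. Temperature is the
only niche axis; substrate and bathymetry enter only as affinity tests and
assemblage-level change covariates. The synthetic world's climate is an
analytic surface, not a circulation model; only sampled values reach the
pipeline, so field-level realism is limited to gradients and offsets.
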