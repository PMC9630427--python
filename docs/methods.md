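# Methods

## Scope and data model

The unit of observation is one identified individual in one *group sighting*
on one date at one planar location. Tables are CSV, one row per
`(group_id, individual_id)`, with sex, age class (`subadult`, `21-30`,
`31-40`, `41-50`, `51-60`), behavioural state (`foraging`/`musth`) and musth
stage (`early`/`peak`/`late`/`none`). Coordinates are projected metres;
the package does no geodetic arithmetic because every downstream use is a
Euclidean distance. A *study year* is a 365-day bin counted from the study
window's first date (year 1 = first 365 days); calendar years are available
as an option. This anchored definition keeps simulated and analysed data
self-consistent regardless of when a study starts.

## Between-sightings interval

Mean BSI is the average of the gaps between consecutive *distinct* sighting
days, equivalently `(last − first)/(n_days − 1)`. Same-day repeats collapse
to one date because the interval is defined in whole days elapsed. The mean
is undefined — represented as missing, never coerced to zero — below two
distinct days. Yearly mean BSI uses within-year gaps only, while the overall
mean spans first-to-last including cross-year gaps; this interpretation is a
package decision where the two are not forced to agree, and both are
reported so either convention can be recovered. Residency is mean BSI
strictly below 90 days (configurable) *and* presence in at least two study
years; a single sighting can never evidence residency.

## Male strategies and male-weeks

Strategy classification is a pure function of the observed state sequence:
no musth sighting → foraging-only; all musth → musth-only; otherwise both.
A musth sighting made while the animal also foraged counts as musth, for
both classification and week scoring. Weeks are 7-day bins anchored at a
configurable origin (default: study start) rather than ISO calendar weeks,
because an anchored bin is reproducible from the data alone. The male-week
score keeps the maximum of the week's evidence (musth > foraging > unseen),
so total male-weeks seen always partitions into musth weeks plus
foraging-only weeks. Musth bouts are maximal runs of musth sightings; a
bout is *complete* only when bracketed by non-musth sightings on both sides,
and its duration is the elapsed days between the run's endpoints (zero for a
single-sighting bout).

## Association and communities

The simple ratio index uses group sightings as the sampling unit by default,
with denominator `x + yA + yB`: with group-level units a pair cannot be
"seen apart in the same unit", so the classic `yAB` term is structurally
zero. A day-level option merges all groups of a date into one unit, in which
case `yAB` (both seen that day in different groups) enters the denominator.

Community detection is weighted-modularity Louvain (networkx
implementation), seeded for reproducibility; individuals without positive
edges become singletons, and labels are renumbered contiguously by size then
smallest member. Matching across consecutive years uses reciprocal majority:
clusters are the same community iff the intersection exceeds half of each
cluster, with "more than half" read strictly (an exactly-half overlap does
not match). Two disjoint strict majorities of one set are impossible, so the
match is one-to-one; unmatched clusters receive fresh persistent IDs. The
two-period consensus assigns each individual her later-year cluster's
persistent ID, falling back to the earlier label for individuals unseen in
the later year. Individuals absent from a period are omitted from that
period's partition rather than forced into a community.

## Pairwise matrices and MRQAP

BSI similarity is the Pearson correlation of two females' yearly mean BSI
vectors over the years where both are defined; pairs sharing fewer than
`min_overlap` years (default 3 — below that the correlation is too unstable
to mean anything) or with a constant vector are masked. Spatial control is
the Euclidean distance between per-individual sighting centroids (arithmetic
mean of coordinates).

MRQAP point estimates are OLS on the vectorised upper-triangle dyads with
masked dyads dropped listwise (imputation would manufacture dyadic data; a
mean-imputation option exists only for sensitivity checks). Significance
uses Dekker-style double semi-partialing by default: each predictor is
residualised on the remaining predictors, the residual matrix's rows and
columns are permuted jointly by a node relabeling, and the two-tailed p is
the share of permuted |t| at or above the observed |t|, observed statistic
included — so p ≥ 1/(n_perm + 1) and is never exactly zero. Plain
dependent-matrix permutation is available as `method="y"`. Adjusted R² and
residual standard error are reported from the dyadic OLS.

The exact binomial test is two-tailed by the minimum-likelihood rule (sum of
all outcome probabilities not exceeding that of the observed count, with a
1 + 1e-7 relative tie tolerance, matching the convention of standard
implementations). Contingency tables use the uncorrected chi-square
statistic; 2×2 tables get the hypergeometric exact p and larger tables a
seeded Monte-Carlo p over fixed-margin tables.

The mixed-model frame for male BSI (one row per interval, with individual,
month and year as grouping columns and age class × strategy as covariates)
is constructed but deliberately not fitted: estimation belongs to an
external mixed-model package and the frame is link-agnostic.

## Synthetic data generator

The simulator emulates the data-generating situation the analysis assumes,
with ground truth retained for recovery tests.

- **Residency**: alternating in/out bouts with exponential lengths
  (means 60 and 120 days by default, putting roughly a third of individuals
  inside the observable area at any time — the turnover regime the method
  targets). Memoryless bouts are the simplest process producing both
  short-BSI and long-BSI phenotypes.
- **Community synchrony** `residency_mixing_rho`: each female's daily
  presence is copied from her community's shared schedule with probability
  rho, else from her own independent schedule. rho = 1 gives identical
  schedules within a community; rho = 0 gives independence. The default 0.9
  links association to PA-use similarity, the relationship the female
  analysis is designed to detect.
- **Grouping**: present community members are partitioned each day by a
  Chinese-restaurant process with concentration `grouping_concentration`
  (default 1.0); concentration → 0 yields no splitting. One knob, direct
  fission–fusion interpretation.
- **Musth**: one window per study year per male (durations gamma with
  shape 4 and age-class means 24.5 / 32.5 / 45 / 45 days). Stage is assigned
  by thirds of the window (early/peak/late) since the physical-appearance
  cues used in the field have no simulated counterpart. Strategy governs
  presence: `f` males leave the area during their windows, `m` males are
  present only during windows, `f+m` males are present for both.
- **Detection**: each present individual is detected independently per day
  with `detection_prob` (default 0.5). Detection is per individual, not per
  group, so co-detection noise does not fabricate association–BSI coupling
  under rho = 0.
- **Space**: community centres are uniform in a 15 km arena; individual
  centroids scatter around them with sd `centroid_sd` (2 km); sighting
  locations add isotropic noise with sd `centroid_sd`/2.
- **Determinism**: every individual, community-day and male-day draws from
  its own `SeedSequence` substream of the single seed, so enlarging the
  roster leaves earlier individuals' schedules and centroids untouched.

What the generator does **not** emulate: spatially explicit movement
(home-range kernels, habitat), demography, observer route geometry, or the
far sparser effort of real field sampling — simulated individuals are
detected much more often than field animals, so absolute BSI magnitudes and
resident fractions in simulations are not comparable to field values, and
passing tests demonstrate correctness of the statistical machinery, not
field realism.

## Problem sizes and numerical conventions

The default simulation uses 130 females in 16 communities of 2–22 members,
216 males and a 6-year window; statistical suites use smaller instances (30
node MRQAP nulls with 499 permutations; 36-female pipelines with 199
permutations over 20 replicates) chosen to keep the whole suite fast while
leaving the binomial acceptance bands meaningful. Table percentages use
nearest rounding by default with a truncation option, since published
tabulations mix both conventions. Permutation p-values include the observed
statistic in numerator and denominator. Louvain ties are resolved by the
seeded node shuffle of the underlying implementation; partitions are
relabelled deterministically afterwards.

## Known limitations

- The BSI confounds absence with non-detection; the simulator separates the
  two, field data cannot.
- Reciprocal-majority matching is greedy across adjacent years only; a
  community that splits evenly loses its persistent identity by design.
- The SRI sampling-unit choice (group vs day) changes denominators; both are
  provided but results are reported for the group-level default.
- MRQAP assumes dyadic exchangeability under node relabeling; structured
  missingness (e.g. whole cohorts lacking yearly BSI) can distort the
  permutation distribution because masked cells move with the relabeling.
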