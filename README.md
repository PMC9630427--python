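# pasight

Protected-area (PA) use analysis from longitudinal individual-ID sighting
data, built for mark–resight studies of free-ranging animals — originally
Asian elephants observed inside a national park — where individuals are
photo-identified in group sightings over many years but cannot be tracked
continuously.

The package answers two questions a sighting record can address that a
telemetry sample cannot (because it covers most of a population over many
years): how continuously does each individual use the observed area, and is
that use structured by life history (male reproductive state and age) or by
social ties (female community membership)?

## What it computes

**Between-sightings interval (BSI).** For an individual sighted on distinct
days $d_1 < d_2 < \dots < d_n$, the BSI values are the consecutive gaps
$d_{i+1} - d_i$ (days) and the mean BSI is their average, which reduces to
$(d_n - d_1)/(n-1)$. It is undefined for a single sighting day. Possible
*residents* are individuals with mean BSI < 90 days seen in two or more
study years.

**Male musth strategies.** Each mature male (age class 21–30 … 51–60) is
labelled *foraging-only* (never seen in musth), *musth-only* (every sighting
in musth) or *foraging-and-musth*. Sightings are also scored per male-week:
0 unseen, 1 seen foraging only, 2 seen in musth at any time that week; the
musth male-week proportion of the resident subset is compared with the
population by a two-tailed exact binomial test (minimum-likelihood method).
Musth bout durations are days elapsed between the first and last musth
sighting of a run observed from beginning to end.

**Female social networks.** From a group-by-individual matrix the simple
ratio index

$$\mathrm{SRI}_{ij} = \frac{x}{x + y_{AB} + y_A + y_B}$$

gives the proportion of sampling units in which the pair was seen together
out of all units in which either was seen. Per-year SRI networks are
clustered by weighted-modularity Louvain, and clusters in consecutive years
are identified as the same social community when they share more than half
of the members of *each* cluster (reciprocal majority).

**MRQAP.** A multiple regression quadratic assignment procedure regresses
pairwise BSI similarity (Pearson correlation of the two females' yearly mean
BSI vectors) on the SRI association matrix, controlling for the Euclidean
distance between sighting centroids. Point estimates are OLS on the
vectorised dyads; p-values come from node-label permutations with Dekker
double semi-partialing.

**Synthetic data.** A fission–fusion sighting simulator generates tables
with the structure the analysis assumes — community-synchronised residency
bouts, daily random-partition grouping, age-dependent annual musth windows,
imperfect detection — with ground truth retained, so every stage of the
pipeline is testable without field data.

## Worked example

```python
from pasight import RunConfig, SimConfig, run_all

cfg = RunConfig(
    sim=SimConfig(study_days=4 * 365, n_communities=4,
                  community_sizes=[8, 6, 5, 3], n_males=40, seed=7),
    n_perm=999, seed=7,
)
report = run_all(cfg)
```

Printed with the snippet in the repository this yields:

```
mature males seen: 40
strategy totals: {'musth_only': 2, 'foraging_only': 16, 'foraging_and_musth': 22}
male-weeks seen: 3137, in musth: 479 (15.3%)
females retained: 22
community sizes: [8, 6, 5, 3]
MRQAP: sri coef = 5.817 (p = 0.001), distance coef = 5.36e-06 (p = 0.614), adj R2 = 0.259
```

The four simulated communities are recovered exactly from the SRI networks;
the MRQAP detects that socially associated females use the area on similar
schedules (the simulator synchronises 90 % of each female's residency
schedule with her community), while centroid distance carries no signal.
The same pipeline runs from the shell:

```sh
pasight simulate --seed 7 --out runs/demo
pasight analyse --sightings runs/demo/sightings.csv --roster runs/demo/roster.csv \
    --seed 7 --out runs/demo/analysis.json
pasight report --seed 7 --out runs/demo
```

## Layout

- `pasight.io` — sighting-table model, CSV round-trip, inclusion filters, GBI
- `pasight.metrics` — BSI, strategies, male-weeks, musth bouts, residency
- `pasight.network` — SRI, Louvain communities, dynamic matching
- `pasight.matrix_stats` — pairwise matrices, MRQAP, binomial/contingency tests
- `pasight.simulate` — synthetic fission–fusion sighting generator
- `pasight.pipeline` / `pasight.cli` — orchestration and command line

See `docs/methods.md` for the model assumptions, parameter meanings and
numerical conventions.
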