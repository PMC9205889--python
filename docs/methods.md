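# Methods

This note documents the models, conventions and parameter choices behind
badgenet: what each stage assumes, where the design was genuinely open and
which option the package takes, and what the synthetic-data generator does
and does not emulate.

## Data model

The raw inputs are three per-minute streams. A *detection record*
(org, person, counterpart, minute) states that one badge saw another during
that minute; recordings are directional, and preprocessing pools the two
directions of a dyad. A *movement sample* (person, minute, zero_cross)
carries the zero-cross count of the chest acceleration norm for that
minute — a frequency-like activity proxy (roughly: 0–60/min quiet desk
work, 60–120 talking/typing, above ~180 animated discussion or walking).
A *CES-D response* is 20 items scored 0–3 over the past week; the four
positively worded items are reverse-keyed, so totals span 0–60.
Timestamps are integer epoch-minutes and all intervals are half-open.

## Episode merging

Badge infrared links drop out briefly even during continuous conversation,
so raw detection runs are fragmented. Two detection minutes m1 < m2 of a
dyad are assigned to the same episode iff the empty interval between them,
m2 − m1 − 1, is *strictly less than* the 5-minute gap limit; an exactly
5-minute-empty interval splits. Merging uses detections from either member.
The resulting episodes satisfy, per dyad: duration ≥ 1, pairwise
non-overlap, and separation by at least `gap_limit` empty minutes. Merging
is idempotent, and the episode count is non-increasing in the gap limit
(both are property-tested).

"Number of interactions" always means number of merged episodes, not
detection minutes; a `weight_by="minutes"` switch exists for sensitivity
analysis.

## Participant filtering and networks

A person is retained iff device wear is at least 300 minutes AND total
interaction time is at least 60 minutes ("less than" is strict, so the
boundary values are kept). Wear time is the count of minutes with any
movement sample — the stream has no explicit on/off log, and movement is
sampled continuously while the badge is worn. Interaction time is the sum
of a person's episode durations (concurrent episodes with different
counterparts count separately; dyads are treated independently
throughout).

Each organization yields one undirected network: nodes are the retained
persons (isolated nodes kept), edge weight w_ij = episodes(i,j) / n_days.
The day denominator is per organization — the number of distinct calendar
days with any detected episode — since the observation window is an
organizational property; a generator-driven run passes the configured
number of days explicitly.

## The 11 network characteristics

Individual scale: Degree k_i (partner count) and Weight s_i = Σ_j w_ij
(episodes/day). Surrounding scale: the unweighted clustering coefficient
and the Barrat, Onnela and Zhang weighted variants. Weights are
deliberately **not** normalized by the maximum weight: the analysis
compares magnitudes across organizations, and a per-organization maximum
would destroy that comparability. Conventions, where the literature
varies:

- All weighted clustering sums run over **ordered** neighbour pairs (j,k),
  consistently in numerator and denominator.
- ⟨w_i⟩ in the Barrat coefficient is the node's mean edge weight s_i/k_i.
- Nodes with k_i < 2 get clustering 0 rather than NaN; the correlation
  layer can instead exclude them (`exclude_low_degree_clustering`), since
  their 0 is a convention, not an observation.

Organizational scale: closeness (n−1)/Σ_j d(j,i) on unweighted shortest
paths; betweenness with the 2/((n−1)(n−2)) normalization, endpoints
excluded; eigenvector centrality as the principal eigenvector of the
(binary or weighted) adjacency. Weighted shortest paths use distance
1/w_ij — a stronger tie is a shorter distance; the transform is
configurable because no single convention is canonical. Disconnected
graphs are handled per connected component with component-local n (this
avoids infinite distances and is standard practice); eigenvector
centrality is normalized to unit Euclidean norm per component, and
edgeless components get 0.

Eigenvector centrality is solved by shifted power iteration (shift =
max strength + 1, guaranteeing convergence on bipartite components) to a
successive-iterate tolerance of 1e-14; the suite checks agreement with a
dense eigensolver to 1e-10.

## Community detection

Weighted modularity is evaluated exactly from its ordered-pair definition,
Q = (1/2W) Σ_ij (w_ij − s_i s_j/2W) δ(c_i, c_j). Louvain proceeds in the
usual two phases — greedy local moves, then aggregation of communities
into nodes with self-loops — iterated until no gain. Open details fixed
here: a node moves to the neighbouring community with maximal positive
ΔQ, ties broken by lowest community id, and no move occurs on ΔQ ≤ 0
(within a 1e-12 numerical guard). The node-visit order is shuffled by the
seed, and detection is run as an ensemble over visit orders (default 5000
runs) because the order can change the result. The Q returned by a run is
always recomputed from scratch on the final partition, which turns any
bookkeeping error into a test failure.

Before detection — and only there — link weights are raised to the power
1/4. Interaction frequencies are heavy-tailed; the sub-linear transform
keeps a handful of very strong dyads from dominating the partition. The
exponent is a configuration knob with no further calibration machinery.
Member-level metrics always use the original weights.

## Inference layer

Individual scale: Pearson and Spearman correlations (average ranks for
ties) of each feature with the CES-D total over the pooled dataset, with
Benjamini–Hochberg adjustment across the 11 features run separately
within the Pearson family and within the Spearman family. Persons are
treated as independent even though neighbouring clustering values are
dependent — the field-standard choice, and a known limitation: the
nominal p values are somewhat anti-conservative for network-derived
features.

Within-organization summaries compute the coefficient inside each
organization and bootstrap the *set of organization-level coefficients*
(1000 draws, percentile 95% CI of the mean). Resampling organizations
rather than persons matches the question "is the relationship consistent
across workplaces"; person-level bootstrap is available by composing the
pieces.

Group-scale nulls: the observed statistic is the Spearman correlation
between group means of Barrat clustering and of the CES-D total (persons
missing CES-D are excluded from both means). Null draws preserve the
observed group-size multiset and either resample members from the entire
dataset without replacement (`global_pool`) or permute members within each
organization (`within_org`). The one-tailed empirical p uses the add-one
correction (1 + #{null ≤ observed})/(B + 1), so it lies in (0, 1] and can
never be exactly zero.

The activity sweep rebuilds, per threshold, the network of active + mixed
episodes ("active net", inactive episodes removed) and of inactive + mixed
episodes ("inactive net"), recomputes the four clustering variants and
their correlations, and reports the fraction of classifiable episodes
removed. Keeping mixed episodes in both sub-networks makes each
sub-network a removal of exactly one class, so the two removal fractions
are independently interpretable.

## Synthetic-data generator

The generator emulates the statistical structure the analysis relies on,
not the full texture of real badge data.

Mechanics: persons are partitioned into organizations and, within them,
planted communities. Per dyad and day the number of episodes is Poisson
with rate `lambda_in` (same community) or `lambda_out` (different
community, same organization; never across organizations). Episode
lengths are geometric with mean `duration_mean`, placed uniformly inside
the workday; both badges record every episode minute symmetrically. An
optional `dropout` deletes interior minutes to exercise gap-merging, and
`lambda_in_spread` jitters each community's internal rate to plant
group-level density heterogeneity.

Movement per episode minute is
max(0, round(base_i + context_e − duration_slope·ln(dur_e) + noise)):
`base_i` is a person's habitual activity level, the shared episode
component `context_e` makes partners' movement positively correlated, and
the log-duration term makes long (formal) interactions calmer. In
`movement_mode="full"`, non-interacting workday minutes carry baseline
movement so wear time is defined. When a person is in two overlapping
episodes, the first episode's samples win for the shared minutes; this
slightly attenuates partner correlation at high interaction rates, as
overlapping talk plausibly would.

CES-D: latent = cesd_mean + beta_depress · z(Barrat clustering) +
Normal(0, cesd_sd), rounded and clamped to 0–60, then decomposed into 20
item scores (0–3 each) by randomized round-robin allocation under the
per-item cap, with the four positive items stored reverse-keyed so that
standard scoring reproduces the total exactly.

Defaults are the study conditions the pipeline targets: 449 persons in 10
organizations (nine of 45, one of 44), 3 communities per organization,
5 workdays of 480 minutes (09:00–17:00), lambda_in = 0.8 and lambda_out =
0.05 episodes/dyad/day, mean episode length 5 min, movement baseline
130 ± 20 zero-cross/min with context SD 25, noise SD 15 and slope 10 per
log-minute (placing typical episode movement near the 100–160 band where
activity thresholds are interesting), CES-D mean 13 and residual SD 9
(typical working-population values). `beta_depress = −1.75` is calibrated
so the realized population Pearson correlation between Barrat clustering
and the CES-D total is ≈ −0.18 at n = 449 (the calibration accounts for
the ~3% attenuation from clamping at 0); across 100 replicate seeds the
mean recovered coefficient is −0.179 (SD 0.042). No distributional detail
is claimed for episode durations or zero-cross counts beyond monotone
shape; those laws are free modelling choices and marked as such.

Not emulated: circadian and weekly rhythms, device noise and battery
artifacts, partial questionnaire missingness, cross-organization contact,
and person-level heterogeneity in sociability beyond what the planted
communities induce. Passing tests therefore demonstrate correctness of
the pipeline's computations and calibration of its inference under the
stated generative assumptions — not robustness to every property of real
badge data.

## Randomness and determinism

All randomness flows from explicit integer seeds. The generator derives
independent per-purpose streams from the base seed via `SeedSequence`
spawn keys; ensembles and permutation tests derive child seeds the same
way. Identical seeds give byte-identical outputs end to end (CLI runs are
compared byte-for-byte in the tests).

## Problem sizes used by the test suite and acceptance script

The acceptance script runs the full 449-person deployment once, a
1440-person (8 × 60 × 3-community) group-structure scenario, and a
200-person activity-sweep scenario, with permutation/bootstrap sizes of
1000 and a 100-run detection ensemble; replicate-based tests use 100
seeds at full scale with movement generation disabled. These sizes are
the package's own defaults for a reproducible desk-scale run; the
production-scale values (5000 nulls, 5000 ensemble runs, 1000 bootstrap)
remain the library defaults.

## Known limitations

- Correlations treat persons as exchangeable; network dependence between
  neighbours' clustering values is not corrected.
- The community-scale test conditions on the detected partition; partition
  uncertainty beyond the randomized-order ensemble is not propagated.
- The episode-count weight ignores episode duration (by design; a
  minutes-based switch exists).
- The power-1/4 exponent is taken as a fixed convention rather than
  re-derived per dataset.
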