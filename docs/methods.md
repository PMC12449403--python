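# Methods

## Data model

A cohort is three tables. **Providers** carry an opaque id and a role from a
closed vocabulary: `registered_nurse`, `frontline_provider` (advanced
practice providers plus housestaff, analyzed as one role),
`physician` (attendings), `nursing_assistant`, `pharmacist`,
`respiratory_therapist`, `other` (the catch-all for the long tail of
miscellaneous roles; unknown labels map here with a warning). **Encounters**
are inpatient admissions with admit/discharge timestamps and zero or more
deterioration events — activations of the hospital-wide rapid response or
code team. *Time 0* of an encounter is its **first** deterioration; later
activations are ignored for epoch anchoring. This is a convention of this
package (the anchoring rule for multi-activation encounters is genuinely
open); it keeps every encounter's epoch clock single-valued. **Messages**
carry sender, a non-empty recipient list, a minute-resolution timestamp, an
optional encounter link, minutes-to-first-read and character count — never
message text. All timestamps are stored and compared at minute resolution
and serialized as ISO-8601 (`YYYY-MM-DDTHH:MM`).

Ingest rules: rows with an empty recipient list are dropped and counted
(dropped + retained = input rows, asserted in tests); a row whose admit is
not strictly before discharge, or whose deterioration falls outside the
admission window, raises a validation error naming the encounter;
unresolvable encounter references are retained as unlinked and excluded
from encounter-level analyses.

## Network construction

A message with k recipients contributes weight 1 to each of k directed
(sender → recipient) edges; edge weight is therefore the count of delivered
(message, recipient) pairs for that ordered pair — the only reading of
"volume between source and target pairs" that defines a pairwise weight.
Self-recipients are dropped silently with a counter and never create
self-loops. Node sets are message-derived; no isolated nodes are injected.
Total edge weight always equals retained delivered pairs minus self-pairs
(a conservation identity asserted across the suite).

"Prior to deterioration" is strict: a message stamped exactly at Time 0 is
excluded. Epoch windows are half-open `[lower, upper)` in hours relative to
Time 0, so a message at exactly −12 h belongs to `[−12, 0)` and one at
−36.01 h to no window. Deterioration encounters whose every message falls
at/after Time 0 are the *post-only* subnetworks; they are counted and
excluded from pre-deterioration comparisons. Windows with no messages
produce no graph, so the per-window subnetwork counts shrink with distance
from Time 0 — earlier windows are more often truncated by admission.

## Measures

* **Betweenness** — pair-dependency accumulation (one BFS per source,
  dependencies propagated down the shortest-path DAG) on the *unweighted
  undirected* projection; raw scores divided by (n−1)(n−2)/2; all zeros for
  n < 3; unreachable pairs contribute nothing.
* **Closeness** — Wasserman–Faust reachable-set form
  `C(v) = (|R|/(n−1)) · (|R|/Σ_{u∈R} d(v,u))`, undirected unweighted;
  isolated nodes score 0. This keeps scores comparable across the highly
  fragmented encounter networks.
* **Eigenvector** — leading eigenvector of the *weighted undirected*
  adjacency, scaled so the maximum entry is 1. Power iteration starts from
  the all-ones vector with convergence when the successive max-norm
  difference falls below 1e−10 (cap 10,000 iterations, error with the
  residual on failure). The iteration applies A + I rather than A: the unit
  diagonal shift leaves eigenvectors unchanged but prevents sign
  oscillation on bipartite components (a bare 3-path would otherwise never
  converge from a symmetric start). Nodes outside the dominant component
  converge to near-zero values; an edgeless graph returns zeros.
* **Density** — directed edge count over n(n−1); **eccentricity /
  diameter / radius** — per-component undirected BFS distances, no
  infinite-distance placeholders; **global clustering** — transitivity,
  3·triangles / connected triples, with the mean-local-clustering variant
  exposed separately; **degree** — distinct in-neighbours plus distinct
  out-neighbours (weights ignored; a mutual pair contributes 2).

Distance-based measures deliberately use the unweighted undirected
projection and eigenvector the weighted one. A library-default analysis of
such data could equally use directed or weighted distances; those readings
are exposed as switches (`directed=` in the metric functions,
`directed_distances` in the pipeline config) but the defaults above are the
ones under which fragmented encounter graphs behave sensibly (radius
medians of 1, a large mass of exactly-zero betweenness from isolated
dyads). Single-node graphs report density 0, diameter 0, radius 0,
clustering 0.

All implementations are validated against an exhaustive simple-path
enumeration oracle and a dense symmetric eigensolver on hundreds of random
graphs (n ≤ 7), against networkx, and against star/path closed forms for
3 ≤ n ≤ 25.

## Statistics

Quantiles use linear interpolation (the common statistical-package
default; the convention matters for small samples and is therefore pinned
here). Mann-Whitney U is two-sided, exact by enumeration when both n ≤ 8
and the pooled sample is tie-free, otherwise normal approximation with tie
and continuity corrections; U is reported for the first sample.
Kruskal-Wallis uses the tie-corrected H against chi-square with k−1 df; a
table in which every value is identical returns H = 0, p = 1 rather than an
error. Bonferroni multiplies by the number of comparisons actually
performed in a family and caps at 1. The chi-square/Fisher switch
(any expected 2×2 cell < 5 → Fisher) operationalizes "where appropriate".
Monte-Carlo calibration tests pin the type-I error of both rank tests to
[0.03, 0.07] at α = 0.05.

Node-level group comparisons pool node-in-subnetwork observations (each
node in each subnetwork is one observation), with no within-encounter
clustering adjustment — the reading consistent with role-stratified medians
over thousands of subnetworks; per-network summarizing first would be the
alternative and is easy to build from the emitted per-network tables.

Cohort summary percentages keep the raw proportion alongside a displayed
value rounded to the printed precision of each quantity (integer percent
for encounter linkage, one decimal elsewhere). With the published marginal
counts this reproduces 47% linked encounters, 8.4% of hospital days, 9.9%
of message volume, and 4,314 analyzed subnetworks (4,328 linked minus 14
post-only).

## Synthetic cohort generator

The generator emulates what the analysis assumes about real logs, with one
`numpy` Generator seeded once (same seed + config → byte-identical cohort):

* **Providers**: 800 by default at the observed role mix (41% RN, 13%
  frontline, 10% physician, remainder split across supporting roles), each
  with an activity weight `1 + Pareto(1.5)`. One shared pool serves all
  encounters, so high-weight providers recur across care teams and become
  the hubs behind the right-skewed global degree distribution (max degree
  ≥ 10× median at defaults, asserted). An optional
  `role_activity_multiplier` scales weights by role; it exists to plant
  known role effects for recovery tests.
* **Encounters**: 1,000 by default; lognormal length of stay (median 5.9 d,
  σ = 1.0, hence mean ≈ 9.8 d, matching cohort days per encounter implied
  by the published marginals); 47% message-linked; linked encounters
  deteriorate with probability 120/4328 ≈ 2.8%. Admission-to-deterioration
  is lognormal with median 1.6 d and σ = 2.1 — σ solves
  `exp(±0.6745σ)·1.6 = (0.4, 6.6)`, the published IQR — resampled (up to
  1,000 attempts, then a configuration error) until it falls inside the
  stay, avoiding a probability mass at discharge that clipping would create.
  Deterioration indications are drawn with 54% respiratory, per the
  published majority; the remaining indication and activating-service mixes
  are pragmatic non-published defaults.
* **Messages**: homogeneous Poisson process at `base_rate` = 1 message per
  encounter-hour (≈25/day, the volume per hospital day implied by the
  published totals), multiplied by `escalation_multiplier` (default 2.0)
  inside the 12 h before Time 0 — a step change, the simplest mechanism
  that makes the pre-deterioration node/edge growth recoverable; the
  magnitude is a knob, not an observed value. Sender roles follow the
  observed origination mix (35% RN, 29% frontline); the sender is a
  weight-proportional team member of that role. Recipient counts are
  geometric (support ≥ 1, p = 0.6, capped at team size − 1); recipients are
  drawn weight-proportionally without replacement from teammates excluding
  the sender (Efraimidis–Spirakis keys) — weighting recipients, not just
  senders, lets role-level activity boosts propagate to in-links. Message
  length and minutes-to-first-read are lognormal with pragmatic defaults
  (no published distributional detail exists for either; both are
  descriptive fields only).

What the generator does **not** emulate: provider shift schedules, message
content, read-receipt dynamics, unit/ward structure, diurnal rhythm, or any
correlation between acuity and team composition. Passing recovery tests
therefore shows the *pipeline* detects the structures it is built to
detect — not that real hospitals exhibit them.

## Epoch-trend experiments

Two facts about the epoch design interact. First, under the calibrated
deterioration-time distribution (median 1.6 d ≈ 38 h), many encounters
deteriorate within 36 h of admission, so earlier windows are often
truncated or empty: even at a flat message rate, node and edge counts rise
toward Time 0. The escalation-recovery check runs under exactly these
defaults (100 deteriorating encounters, multiplier 2.0) and the combination
of exposure gradient and rate step yields strictly increasing median nodes
and edges with Kruskal-Wallis p < 0.05. Second, a *null* calibration of the
same test is only meaningful when the windows are exchangeable, so the
null arm uses an exposure-matched configuration (deterioration at median
4 d with σ = 0.25 and 12-day stays, every window fully inside the stay,
multiplier 1.0); under it the rejection rate at α = 0.05 sits in
[0.03, 0.07] over 200 replicates. Without exposure matching the truncation
gradient is a real effect and no rejection-rate bound could hold.

## Problem sizes and determinism

Default test/acceptance problem sizes — a 1,000-encounter (~110k-message)
cohort, 200-replicate null calibrations, 500-replicate type-I checks,
200 random oracle graphs — were chosen so the full suite runs in about a
minute on one core while keeping Monte-Carlo noise well inside the asserted
bands. Every stochastic step takes an explicit seed; the pipeline writes a
manifest (config snapshot, seed, input checksums, stage counters) and
identical seed + config reproduce byte-identical outputs.

## Known limitations

* Conventions the underlying study left unstated (distance mode,
  eigenvector scaling, clustering variant, window boundaries) are pinned
  here and switchable; its table values are not numerically reproducible
  even in principle without the original data.
* No clustering/mixed-effects adjustment for repeated nodes across
  subnetworks; p-values inherit the pooling assumption.
* The generator's escalation is a single step change; real escalation is
  presumably gradual and heterogeneous.
* Read-latency and message-length fields are carried and summarized but not
  modelled.
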