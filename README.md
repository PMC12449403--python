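# carenet

Social network analysis of clinician secure-messaging **metadata** around
inpatient clinical deterioration events.

Hospitals increasingly route interdisciplinary communication through secure,
EHR-integrated text messaging. Every message leaves metadata — sender role,
recipient roles, timestamp, time-to-first-read, length — from which the
communication structure of a care team can be reconstructed as a directed,
weighted graph: nodes are providers, an edge `u → v` carries the count of
messages delivered from `u` to `v`. `carenet` implements a three-stage
analysis of such message logs for researchers in clinical informatics and
patient safety:

1. a **global network** over all encounter-linked messages in a study
   window;
2. **encounter subnetworks**, one per hospital admission — for admissions
   with a clinical deterioration (rapid-response or code-team activation,
   whose time is *Time 0*), restricted to messages sent strictly before
   Time 0;
3. **epoch subnetworks** from messages in 12-hour windows anchored at
   Time 0: `[−36,−24)`, `[−24,−12)`, `[−12,0)` hours.

For every network it computes, from first principles, normalized
betweenness, closeness (Wasserman–Faust reachable-set form) and
eigenvector centrality (power iteration, max-entry scaling), plus density,
eccentricity, diameter, radius, transitivity and the degree–frequency
distribution; group comparisons use Mann-Whitney U / Kruskal-Wallis with
Bonferroni correction, and chi-square / Fisher's exact for categorical
tables.

Because real hospital message logs cannot be shared, the package includes a
seeded **synthetic cohort generator** that reproduces the statistical
structure such logs exhibit: a heavy-tailed provider activity distribution
(so the global network has hubs), a realistic role mix (41% registered
nurses; 35% of messages RN-originated), 47% of encounters linked to
messaging, a ~2.8% deterioration rate among linked encounters, lognormal
admission-to-deterioration times (median 1.6 days, IQR ≈ 0.4–6.6), and a
configurable message-rate escalation in the hours before Time 0.

## Worked example

```python
from carenet import pipeline

manifest = pipeline.run_full_analysis(
    {"simulate": True,
     "simulation": {"seed": 1, "n_total_encounters": 400,
                    "p_deterioration": 0.10, "base_rate": 0.5}},
    "demo")
print(manifest.counts)
```

produces (exact numbers for this seed and config):

```
{'messages_read': 24610, 'messages_dropped_no_recipient': 0,
 'messages_linked': 24610, 'messages_unlinked': 0,
 'encounters': 400, 'encounters_with_messages': 192,
 'encounter_subnetworks': 191, 'deterioration_subnetworks': 16,
 'subnetworks_excluded_post_only': 1, 'epoch_subnetworks': 36}
```

192 of 400 encounters were message-linked; 17 deteriorated, of which one
had only post-Time-0 messages and is therefore excluded from the
pre-deterioration analysis (the `subnetworks_excluded_post_only` counter).
`demo/` now holds the output tables. The global network
(`global_summary.csv`):

```
network_id  n_nodes  n_edges  density  diameter  radius  clustering
    global      624     7161  0.01842         4       2    0.142736
```

and the epoch comparison (`table2_epoch_comparisons.csv`, network-level
rows) shows node and edge counts rising toward deterioration, driven by the
generator's 2× rate escalation in the final 12 h plus the shorter exposure
of the earlier windows:

```
variable         H   p_value  median (-36,-24)  median (-24,-12)  median (-12,0)
 n_nodes  8.707334  0.012860               9.0               6.0            10.0
 n_edges 10.460868  0.005351               9.0               8.0            13.0
```

The same run is available from a shell:

```bash
carenet simulate --seed 1 --out data/           # providers/encounters/messages CSVs
carenet run --config cfg.yaml --out demo/       # full three-stage analysis
carenet build --stage global --messages data/messages.csv \
  --providers data/providers.csv --encounters data/encounters.csv --out graphs/
carenet metrics --graph graphs/global.graphml \
  --out-centrality centrality.csv --out-summary summary.csv
```

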