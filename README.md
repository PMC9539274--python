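# popburst

Analysis of synchronous **population bursts** in multi-unit spike-train
recordings and of directional **effective connectivity** between dorsal-horn
neurons and backfiring primary afferents — with a seeded synthetic-data
generator that plants recoverable ground truth.

Spontaneous activity in spinal dorsal-horn networks organises into irregular,
~100–200 ms synchronous events ("population bursts", ~0.17 Hz). This package
takes tables of sorted spike time stamps (unit id, kind, time) and:

- detects population bursts on the collapsed population channel using the
  event-triggered mean-frequency formula
  `f = (n−1)/(te−tl)` if `(te−tl) > tb/2`, else `n/tb` (bin `tb = 0.2 s`),
  marking each burst at its spike-density crest;
- computes each unit's **grouping index** — the percentage of its spikes in
  the `[−50, +150) ms` windows around burst marks — against a 100-repetition
  uniform-redistribution null;
- builds per-unit **burst-shape** histograms (5 ms bins) and compares groups
  with a split-plot two-way ANOVA plus Sidak per-bin post hocs;
- classifies single-unit firing patterns into the 8 classes
  IS/RS/IFB/RFB/ISB/RSB/IMB/RMB from ISI regularity (CV) and burstiness, and
  applies the ≥ 70%-rate-reduction blocker-sensitivity criterion;
- screens neuron–afferent pairs for effective connectivity with a
  decision-tree classifier on 50 ms pre-spike count windows, scored by the
  Matthews correlation coefficient
  `MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`,
  calling MCC ≥ 0.18 a putative monosynaptic link and assigning
  presynaptic / postsynaptic / bidirectional direction labels;
- estimates the intracluster correlation (ICC, between-animal variance over
  total) and runs the standard nonparametric and contingency comparisons.

See `docs/methods.md` for the model, parameter defaults and design choices.

## Worked example

Simulate a matched naive/treated pair (20 neurons, 600 s, grouping targets
51.7% vs 65.5%) and run the full pipeline:

```python
from popburst import run_pipeline

summary = run_pipeline(
    {"seed": 1,
     "simulate": {"n_neurons": 20, "duration": 600.0},
     "analysis": {"null_reps": 100}},
    "demo_out")
```

Output (abridged `summary.json`):

```json
{
 "contrast": {
  "mann_whitney_p": 6.795615128173358e-08,
  "anova_group_p": 0.2933427203953259
 },
 "groups": {
  "naive":   {"burst_rate_hz": 0.163333, "grouping_mean_pct": 53.6115,
              "grouping_sem_pct": 0.5562, "n_units": 20},
  "treated": {"burst_rate_hz": 0.163333, "grouping_mean_pct": 66.474,
              "grouping_sem_pct": 0.7156, "n_units": 20}
 },
 "seed": 1
}
```

Reading: bursts were detected at ~0.163 Hz in both conditions (the planted
rate is 0.175 Hz; a few marks fall below threshold); the mean grouping index
rose from 53.6% (naive) to 66.5% (treated), close to the planted 51.7% and
65.5%, and the Mann–Whitney comparison of per-unit grouping is strongly
significant. The shape-ANOVA group effect is underpowered at 20 units per
group — it becomes reliable at the ~150-units-per-group scale used in the
validation suite. The run directory also contains per-unit tables
(`units_*.csv` with pattern class, rate, grouping and its null), burst lists,
and 40-bin shape matrices.

The same steps are scriptable from a shell:

```sh
popburst simulate --seed 1 --pair --out demo/
popburst bursts --spikes demo/spikes_naive.csv --metadata demo/meta_naive.json --out demo/bursts.csv
popburst grouping --spikes demo/spikes_naive.csv --metadata demo/meta_naive.json \
         --bursts demo/bursts.csv --null-reps 100 --seed 0 --out demo/grouping.csv
popburst connectivity --spikes demo/spikes_naive.csv --metadata demo/meta_naive.json --seed 0 --out demo/edges.csv
```

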