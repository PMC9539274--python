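# Methods

## Scope and model

`popburst` analyses tables of sorted spike time stamps from multielectrode
recordings of spinal dorsal-horn neurons and primary afferents. The central
phenomenon is the *population burst*: a transient (~100–200 ms) clustering of
spikes across many simultaneously recorded units, recurring irregularly at
roughly 0.17 Hz. The package measures (i) how strongly each unit's firing is
grouped into these bursts, (ii) the within-burst time course of firing, and
(iii) directional effective connectivity between dorsal-horn neurons and
backfiring primary afferents. Because the original recordings are not
publicly deposited, a first-class synthetic generator reproduces the
statistical structure the analysis assumes and provides planted ground truth
for closed-loop validation.

All times are seconds from recording start; every window and histogram bin is
half-open `[start, end)`, so no spike is ever counted twice at an edge.

## Population-burst detection

The collapsed stream of all neuron spikes is converted to an event-triggered
mean-frequency series. At each event time `te`, with `tl` the first event and
`n` the event count in the trailing range `(te − tb, te]` (bin size
`tb = 0.2 s`):

    f = (n − 1) / (te − tl)   if (te − tl) > tb / 2
    f = n / tb                otherwise.

Maximal runs of samples at or above a threshold are candidate bursts.

**Threshold.** The classical workflow sets the level manually "just above
baseline". The automated default calibrates on a homogeneous-Poisson null at
the collapsed mean rate: the threshold is the smallest trailing-window count
(converted to Hz) whose expected number of suprathreshold events per
recording is ≤ 0.1. On rate-matched uncoordinated populations this yields ≤ 2
false bursts per 600 s; a median + 5·MAD rule (`threshold_method="mad"`) and
an absolute override (`threshold_hz`) are also available. The MAD rule is not
the default because the event-triggered series samples densely inside bursts,
so at high grouping the median itself is dominated by burst samples and the
rule becomes unusable (it also passes 16–31 false bursts per 600 s on
uncoordinated controls).

**Mark placement.** The trailing-range formula places its maximal sample near
the *end* of a burst (the trailing window only contains the full burst once
the burst is over), roughly 75 ms after the spike-density crest. Each
suprathreshold run is therefore marked at the local collapsed-spike-density
peak: the spike time maximising the count in a centred 40 ms window, earliest
on ties. `refine_marks=False` restores the literal maximum-frequency-sample
convention. A symmetric density window wider than the burst's 25 ms rise
would bias the mark toward the longer decay side (analytically ≈ half-width/2
for the 25/75 ms kernel); 40 ms keeps the measured median mark error ≈ 9 ms
with 97% of marks within ±25 ms of the planted truth at default conditions.
Marks closer than the 200 ms analysis window are merged keeping the higher
peak, so grouping windows never overlap.

**Analysis windows.** Each mark defines the window `[mark − 50 ms,
mark + 150 ms)`, clipped at the recording bounds (clipped width recorded).

## Grouping index and randomisation null

A unit's grouping index is the percentage of its spikes falling inside burst
windows. Its chance level is estimated by redistributing the same number of
spikes uniformly over the whole recording and recounting against the same
windows, 100 times with distinct substreams; the null mean equals the window
coverage fraction (e.g. 3.33% for 100 disjoint 200 ms windows in 600 s). The
null is uniform over the full recording, not locally rate-matched.

## Burst shape

Per unit, spike counts in 5 ms bins across `[−50, +150) ms` around each mark
are averaged over bursts, giving a 40-bin row whose sum is the unit's mean
spikes per burst. An F-test df structure of the shape comparison (below)
nominally implies 41 time levels; 200 ms / 5 ms gives 40 bins, which is what
is implemented.

## Firing-pattern classification

Eight classes: irregular/regular × single-spike, fast-burst, slow-burst,
mixed-burst (IS, RS, IFB, RFB, ISB, RSB, IMB, RMB). The published
classification algorithm's numeric criteria are not restated in the source
description, so the thresholds here are explicit package defaults, all
exposed in `ClassifierConfig`:

- *bursts*: maximal runs of ≥ 2 spikes with consecutive ISIs ≤ 100 ms;
- *bursty train*: ≥ 20% of spikes inside bursts;
- *fast vs slow vs mixed*: share of intra-burst ISIs ≤ 30 ms (≥ 75% fast,
  ≤ 25% slow, otherwise mixed);
- *regularity*: coefficient of variation ≤ 0.5, computed on burst onsets for
  bursty trains (the burst is the event) and on all ISIs otherwise. Judging
  regularity on onsets rather than raw ISIs is a package decision; raw ISIs
  of a bursty train are bimodal and would call every bursty unit irregular.

Trains with fewer than 10 spikes are reported as unclassifiable; a CV needs
at least 3 spikes and is otherwise NaN, never 0. The blocker-sensitivity
criterion compares equal-length pre/post windows (default 300 s): sensitive
at ≥ 70% rate reduction (boundary inclusive), increased at > 160% of the
control rate, insensitive otherwise; a silent pre-window is undefined.

## Effective connectivity

For a (target, attribute) pair, each target spike contributes a positive
instance: the attribute's spike counts in ten 5 ms bins covering the 50 ms
before the spike. An equal number of negative instances is drawn uniformly
from times at least 50 ms from every target spike (balanced classes keep the
score comparable across targets; the negative-sampling rule is a package
decision). A decision tree with information-gain (entropy) splits and no
boosting — a rule-inducing stand-in for the proprietary C5.0 — is fit on a
seeded stratified 70% split and scored on the held-out 30% with the Matthews
correlation coefficient,

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

defined as 0 when a denominator factor vanishes. MCC ≥ 0.18 for a single
attribute marks a putative monosynaptic connection (threshold calibrated in
prior work on synthetic circuits and retained here). The split is random and
stratified rather than chronological because bursty nonstationarity would
bias a chronological split. For each neuron–afferent pair the screen runs
both directions: neuron-as-attribute/afferent-as-target (presynaptic
evidence) and the reverse (postsynaptic evidence); reaching threshold in one,
the other, both or neither yields presynaptic / postsynaptic / bidirectional
/ none. Common drive can inflate both directions; the labels are statistical,
not anatomical.

## Group statistics

- **ICC**: one-way random-effects intracluster correlation by ANOVA method
  of moments with the unbalanced group-size correction; negative
  between-group estimates truncate to 0. Used to ask whether units recorded
  from the same animal can be treated as independent observations.
- **Two-group comparisons**: Mann–Whitney (unpaired), Wilcoxon signed-rank
  (paired), Fisher exact and chi-square for contingency tables, all
  two-sided by default (Fisher's two-sided p is the sum of no-more-likely
  tables under fixed margins).
- **Shape comparison**: split-plot two-way ANOVA — group is a between-unit
  factor tested against the unit-within-group mean square (df N − g); time
  bin and group × bin are within-unit factors tested against the residual
  (df (N − g)(b − 1)). This is the partition identified by the reported df
  structure (e.g. F(1, 308) for the group factor with 310 units). Post hoc,
  per-bin two-sample t tests with a Sidak correction over the 40-bin family.
  SEM is sd/√n with n = units.

## Synthetic generator

The generator's defaults are the study conditions: 600 s recordings, 20
neurons, burst marks as a renewal process with rate exactly 0.175 Hz and a
0.5 s refractory floor (intervals = 0.5 s + exponential, mean matched), burst
kernel an asymmetric triangle rising over 25 ms and decaying over 75 ms
around the mark, grouping targets 0.517 (naive) and 0.655 (treated),
background rate 0.72 Hz for irregular superficial classes. Each neuron
splits its spike budget: a Poisson-distributed `grouping_target` fraction is
placed by the kernel around uniformly assigned marks, the remainder comes
from its pattern-class renewal process. Pattern trains use exponential ISIs
(CV 1) for irregular classes and gamma ISIs with shape 36 (CV 1/6) for
regular ones; burst classes emit three-spike clusters at one third of the
nominal rate with intra-cluster ISIs of 4–18 ms (fast), 45–90 ms (slow) or
one of each (mixed). Afferents fire once within the 25 ms rising phase of a
burst with probability `p_backfire` (default 0.8); planted edges add
latency-shifted copies of afferent spikes to the coupled neuron's train with
the edge's reliability. One global seed expands into independent per-stream
generators (marks, each unit, afferents, couplings), so adding a unit never
perturbs the others.

What the generator does *not* emulate: slow nonstationarity and electrode
drift, spike-sorting errors, per-neuron heterogeneity of grouping within a
condition (every unit gets the recording's target), burst-to-burst amplitude
variability beyond Poisson allocation, subthreshold dorsal-root potentials,
and biophysical constraints (refractoriness within a unit beyond the pattern
process). Passing closed-loop tests therefore shows the analysis recovers
the planted structure under these idealised conditions, not that it is
robust to every artifact of real recordings.

A note on classification in full recordings: allocating half of a unit's
spikes to dense burst windows makes the unit look like a fast-burst type
regardless of its background class — which mirrors the empirical observation
that strongly burst-grouped neurons are predominantly fast-burst — so
class-recovery validation uses canonical single-pattern trains.

## Problem sizes and validation scales

Validation uses the generator's default conditions: burst-mark recovery over
30 seeds (20 neurons, 600 s), grouping recovery at targets {0.3, 0.5, 0.65,
0.9} over 30 seeds, connectivity screens over 20 seeds (6 neurons + 1
afferent; independent units are simulated without burst coupling so that the
specificity check is not confounded by common drive), pattern recovery over
100 replicates per class, and the naive/treated contrast over 20 seeds at
150 units per group (the scale at which the split-plot group effect is well
powered; at 20 units per group the direction reproduces but the shape ANOVA
is underpowered, as expected for a ~14-point grouping difference spread over
40 bins).

## Known limitations

- The 0.18 MCC threshold is inherited, not re-calibrated here; with other
  window/bin encodings it would need re-validation.
- Direction labels cannot distinguish reciprocal coupling from common drive.
- The burst detector assumes a stationary baseline; a slowly drifting
  background rate would need the manual threshold.
- Fisher's exact test on the sensitivity-by-class table (27, 5 | 29, 32)
  gives 0.0007 two-sided and 0.0004 one-sided; both are computed in the
  tests.
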