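"""Seeded generator of multi-unit recordings with planted ground truth.

Emulates the statistical structure of dorsal-horn multielectrode recordings:
eight single-unit firing-pattern classes, irregular population bursts
(~0.17 Hz, ~25 ms rise / ~75 ms decay around the mark), a controllable
fraction of each neuron's spikes grouped into those bursts, primary-afferent
"backfiring" locked to the burst rising phase, and designated pre-/post-
synaptic neuron-afferent couplings with fixed latency and reliability.

Everything is driven from one integer seed expanded into independent
per-stream generators (burst marks, each unit, afferents, couplings), so
adding a unit never perturbs the spikes of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Recording, SpikeTrain, ValidationError

PATTERN_CLASSES = ("IS", "RS", "IFB", "RFB", "ISB", "RSB", "IMB", "RMB")

#: Default class mix: irregular single-spike and fast-burst units dominate
#: superficial dorsal-horn samples, regular classes are a deep-lamina minority.
DEFAULT_CLASS_MIX = {
    "IS": 0.40, "IFB": 0.25, "ISB": 0.06, "IMB": 0.06,
    "RS": 0.11, "RFB": 0.04, "RSB": 0.04, "RMB": 0.04,
}

#: Default background rates (Hz). Irregular superficial classes sit near the
#: observed 0.72 Hz population mean; regular single-spike units fire tonically
#: at a much higher rate.
DEFAULT_CLASS_RATES = {
    "IS": 0.72, "IFB": 0.72, "ISB": 0.60, "IMB": 0.60,
    "RS": 2.50, "RFB": 1.00, "RSB": 1.00, "RMB": 1.00,
}

_GAMMA_SHAPE_REGULAR = 36.0   # ISI CV = 1/6, comfortably below any CV cut
_SPIKES_PER_CLUSTER = 3
_FAST_ISI_RANGE = (0.004, 0.018)   # intra-cluster ISIs of fast-burst units
_SLOW_ISI_RANGE = (0.045, 0.090)   # slow-burst units: bursty but > 30 ms


@dataclass(frozen=True)
class Edge:
    """A planted neuron-afferent coupling."""

    unit_id: str
    afferent_id: str
    direction: str            # "presynaptic" or "postsynaptic"
    latency: float            # seconds between coupled spikes
    reliability: float = 0.9  # probability the coupled spike is emitted


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for one synthetic recording."""

    duration: float = 600.0
    n_neurons: int = 20
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    class_rates: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_RATES))
    burst_rate: float = 0.175
    rise: float = 0.025
    decay: float = 0.075
    min_burst_separation: float = 0.5
    grouping_target: float = 0.517
    grouping_target_treated: float = 0.655
    n_afferents: int = 0
    p_backfire: float = 0.8
    edges: tuple[Edge, ...] = ()
    condition: str = "naive"
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_mix must sum to 1, got {total}")
        if not 0.0 <= self.grouping_target <= 1.0:
            raise ValidationError("grouping_target must lie in [0, 1]")
        if self.burst_rate * self.duration < 1:
            raise ValidationError("expected burst count below 1; extend duration")
        if self.rise + self.decay > 0.2:
            raise ValidationError("burst kernel wider than the analysis window")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator planted, for closed-loop recovery tests."""

    burst_marks: np.ndarray
    class_labels: dict
    edges: tuple[Edge, ...]
    grouping: dict                  # unit_id -> planted grouping fraction
    sensitivity_labels: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Single-train pattern generator

def _renewal_onsets(rng, rate: float, duration: float, regular: bool) -> np.ndarray:
    """Renewal-process event times: exponential (CV 1) or gamma (CV 1/6) ISIs."""
    n_max = int(rate * duration + 6 * np.sqrt(rate * duration + 1)) + 10
    if regular:
        isis = rng.gamma(_GAMMA_SHAPE_REGULAR, 1.0 / (_GAMMA_SHAPE_REGULAR * rate), n_max)
    else:
        isis = rng.exponential(1.0 / rate, n_max)
    t = np.cumsum(isis)
    while t.size and t[-1] < duration:      # top up in the rare short draw
        extra = rng.exponential(1.0 / rate, 100) if not regular else \
            rng.gamma(_GAMMA_SHAPE_REGULAR, 1.0 / (_GAMMA_SHAPE_REGULAR * rate), 100)
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    return t[t < duration]


def _cluster_isis(rng, burstiness: str) -> np.ndarray:
    """Intra-cluster ISIs for one spike cluster of a bursty unit."""
    k = _SPIKES_PER_CLUSTER - 1
    if burstiness == "FB":
        return rng.uniform(*_FAST_ISI_RANGE, k)
    if burstiness == "SB":
        return rng.uniform(*_SLOW_ISI_RANGE, k)
    # mixed: every cluster carries one fast and one slow interval
    isis = np.array([rng.uniform(*_FAST_ISI_RANGE), rng.uniform(*_SLOW_ISI_RANGE)])
    return rng.permutation(isis)


def generate_pattern_train(pattern_class: str, rate: float, duration: float,
                           seed) -> np.ndarray:
    """Generate spike times of one unit of the given firing-pattern class.

    ``rate`` is the overall spike rate in Hz. Single-spike classes are plain
    renewal processes; burst classes emit three-spike clusters whose onsets
    follow the renewal process at ``rate``/3, with intra-cluster ISIs in the
    fast (< 30 ms), slow (45-90 ms) or mixed regime.
    """
    if pattern_class not in PATTERN_CLASSES:
        raise ValidationError(f"unknown pattern class {pattern_class!r}")
    if rate <= 0:
        raise ValidationError("rate must be positive")
    rng = np.random.default_rng(seed)
    regular = pattern_class[0] == "R"
    burstiness = pattern_class[1:]
    if burstiness == "S":
        times = _renewal_onsets(rng, rate, duration, regular)
    else:
        onsets = _renewal_onsets(rng, rate / _SPIKES_PER_CLUSTER, duration, regular)
        parts = [onsets]
        offs = np.stack([_cluster_isis(rng, burstiness) for _ in onsets]) \
            if onsets.size else np.empty((0, _SPIKES_PER_CLUSTER - 1))
        if onsets.size:
            parts.append((onsets[:, None] + np.cumsum(offs, axis=1)).ravel())
        times = np.concatenate(parts)
    times = np.unique(times)
    return times[(times >= 0) & (times < duration)]


# ---------------------------------------------------------------------------
# Whole-recording generator

def _burst_marks(rng, params: GeneratorParams) -> np.ndarray:
    """Irregular burst marks: renewal with a hard refractory floor.

    Intervals are ``min_burst_separation`` plus an exponential whose mean is
    chosen so the marginal mark rate equals ``burst_rate`` exactly.
    """
    mean_gap = 1.0 / params.burst_rate - params.min_burst_separation
    if mean_gap <= 0:
        raise ValidationError("burst_rate incompatible with minimum separation")
    n_max = int(params.burst_rate * params.duration * 2) + 20
    gaps = params.min_burst_separation + rng.exponential(mean_gap, n_max)
    marks = np.cumsum(gaps)
    return marks[marks < params.duration - params.decay]


def _kernel_offsets(rng, n: int, rise: float, decay: float) -> np.ndarray:
    """Spike offsets around a mark: asymmetric triangle peaking at the mark."""
    return rng.triangular(-rise, 0.0, decay, n)


def generate_recording(params: GeneratorParams) -> tuple[Recording, GroundTruth]:
    """Generate one Recording plus the ground truth planted in it.

    Each neuron splits its expected spike budget between population bursts
    (fraction ``grouping_target``, placed by the rise/decay kernel around the
    marks) and background firing drawn from its pattern class. Afferents fire
    within the rising phase of a burst with probability ``p_backfire``;
    planted edges add latency-shifted copies of afferent spikes to the coupled
    neurons' trains.
    """
    ss = np.random.SeedSequence(params.seed)
    marks_rng, class_rng, aff_rng, edge_rng = \
        [np.random.default_rng(s) for s in ss.spawn(4)]
    unit_seeds = np.random.SeedSequence(params.seed, spawn_key=(100,)).spawn(
        params.n_neurons)

    marks = _burst_marks(marks_rng, params)
    if params.grouping_target > 0 and marks.size == 0:
        raise ValidationError("no bursts generated; grouping target infeasible")

    classes = list(params.class_mix)
    probs = np.array([params.class_mix[c] for c in classes])
    labels = class_rng.choice(classes, size=params.n_neurons, p=probs)

    trains: list[SpikeTrain] = []
    grouping: dict[str, float] = {}
    class_labels: dict[str, str] = {}
    g = params.grouping_target
    for i in range(params.n_neurons):
        uid = f"n{i:03d}"
        rng = np.random.default_rng(unit_seeds[i])
        cls = str(labels[i])
        rate = params.class_rates[cls]
        background = generate_pattern_train(
            cls, max(rate * (1 - g), 1e-6), params.duration, rng.integers(2**31))
        n_burst = rng.poisson(g * rate * params.duration)
        if n_burst and marks.size:
            which = rng.integers(0, marks.size, n_burst)
            burst_spikes = marks[which] + _kernel_offsets(
                rng, n_burst, params.rise, params.decay)
        else:
            burst_spikes = np.empty(0)
        times = np.unique(np.concatenate([background, burst_spikes]))
        times = times[(times >= 0) & (times < params.duration)]
        trains.append(SpikeTrain(uid, "neuron", times,
                                 depth_label="superficial",
                                 condition=params.condition))
        grouping[uid] = g
        class_labels[uid] = cls

    # afferent backfiring: one spike in the rising phase of a subset of bursts
    aff_times: dict[str, np.ndarray] = {}
    for j in range(params.n_afferents):
        aid = f"a{j:02d}"
        fire = aff_rng.random(marks.size) < params.p_backfire
        t = marks[fire] - aff_rng.uniform(0.0, params.rise, int(fire.sum()))
        aff_times[aid] = np.unique(t[(t >= 0) & (t < params.duration)])

    # planted couplings ride on the afferent spikes
    coupled: dict[str, list[np.ndarray]] = {}
    for edge in params.edges:
        if edge.afferent_id not in aff_times:
            raise ValidationError(f"edge references unknown afferent {edge.afferent_id!r}")
        src = aff_times[edge.afferent_id]
        keep = edge_rng.random(src.size) < edge.reliability
        dt = -edge.latency if edge.direction == "presynaptic" else edge.latency
        coupled.setdefault(edge.unit_id, []).append(src[keep] + dt)

    final_trains = []
    known = {t.unit_id for t in trains}
    for edge in params.edges:
        if edge.unit_id not in known:
            raise ValidationError(f"edge references unknown unit {edge.unit_id!r}")
    for train in trains:
        if train.unit_id in coupled:
            t = np.unique(np.concatenate([train.times, *coupled[train.unit_id]]))
            t = t[(t >= 0) & (t < params.duration)]
            train = replace(train, times=t)
        final_trains.append(train)
    for aid, t in aff_times.items():
        final_trains.append(SpikeTrain(aid, "afferent", t,
                                       depth_label="unknown",
                                       condition=params.condition))

    rec = Recording(
        recording_id=f"synthetic-{params.condition}-seed{params.seed}",
        duration=params.duration,
        trains=tuple(final_trains),
        annotations={"condition": params.condition, "seed": params.seed},
    )
    truth = GroundTruth(burst_marks=marks, class_labels=class_labels,
                        edges=tuple(params.edges), grouping=grouping)
    return rec, truth


def generate_condition_pair(params: GeneratorParams):
    """Matched naive/treated pair differing only in the grouping target."""
    naive = replace(params, condition="naive")
    treated = replace(params, condition="treated",
                      grouping_target=params.grouping_target_treated)
    rec_n, gt_n = generate_recording(naive)
    rec_t, gt_t = generate_recording(treated)
    return rec_n, rec_t, (gt_n, gt_t)


def generate_ptx_scenario(params: GeneratorParams, multipliers: dict,
                          epoch: float = 300.0) -> tuple[Recording, GroundTruth]:
    """Two-epoch recording emulating a GABA_A-blocker washin experiment.

    Each unit fires as a Poisson process at its class rate during the first
    half and at ``multiplier`` times that rate during the second half.
    Ground-truth labels follow the rate-change criteria: sensitive when the
    multiplier is at most 0.3 (a >= 70% reduction), increased when above 1.6,
    insensitive otherwise. ``epoch`` is the recommended pre/post window length
    stored in the annotations.
    """
    if any(m <= 0 for m in multipliers.values()):
        raise ValidationError("rate multipliers must be positive")
    ss = np.random.SeedSequence(params.seed, spawn_key=(7,))
    seeds = ss.spawn(len(multipliers))
    half = params.duration / 2
    trains = []
    labels = {}
    for (uid, mult), s in zip(sorted(multipliers.items()), seeds):
        rng = np.random.default_rng(s)
        rate = DEFAULT_CLASS_RATES["IS"]
        pre = _renewal_onsets(rng, rate, half, regular=False)
        post = half + _renewal_onsets(rng, rate * mult, half, regular=False)
        trains.append(SpikeTrain(uid, "neuron", np.unique(np.concatenate([pre, post])),
                                 condition=params.condition))
        if mult <= 0.3:
            labels[uid] = "sensitive"
        elif mult > 1.6:
            labels[uid] = "increased"
        else:
            labels[uid] = "insensitive"
    rec = Recording(
        recording_id=f"synthetic-ptx-seed{params.seed}",
        duration=params.duration,
        trains=tuple(trains),
        annotations={"pre_window": [half - epoch, half],
                     "post_window": [params.duration - epoch, params.duration]},
    )
    truth = GroundTruth(burst_marks=np.empty(0), class_labels={}, edges=(),
                        grouping={}, sensitivity_labels=labels)
    return rec, truth
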