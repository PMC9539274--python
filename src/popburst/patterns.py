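"""Interspike-interval statistics, firing-pattern classification and the
picrotoxin-sensitivity criterion.

Single units fall into eight firing-pattern classes: single-spike, fast-burst,
slow-burst or mixed-burst firing, each in an irregular (IS, IFB, ISB, IMB) and
a regular (RS, RFB, RSB, RMB) variant. Regularity is judged by the coefficient
of variation of inter-event intervals; burstiness by maximal runs of spikes
with short consecutive ISIs and by the intra-burst ISI regime (fast vs slow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnalysisConfig, SpikeTrain, ValidationError

#: Burstiness codes appended to the regularity prefix (I/R).
BURSTINESS_CODES = {"single_spike": "S", "fast_burst": "FB",
                    "slow_burst": "SB", "mixed_burst": "MB"}

MIN_SPIKES_FOR_CV = 3
MIN_SPIKES_FOR_CLASS = 10


@dataclass(frozen=True)
class ClassifierConfig:
    """Numeric criteria of the pattern classifier.

    All thresholds are explicit, tunable artifact defaults: regularity cut at
    CV 0.5; spikes separated by ISIs <= 100 ms form a burst; intra-burst ISIs
    <= 30 ms are "fast"; a train is bursty when >= 20% of its spikes sit in
    bursts of >= 2 spikes.
    """

    cv_regular_max: float = 0.5
    burst_isi_max: float = 0.100
    fast_isi_max: float = 0.030
    min_burst_spikes: int = 2
    burst_fraction_min: float = 0.20
    #: Fraction of intra-burst ISIs in the fast regime above which a bursty
    #: train is "fast", below one minus which it is "slow"; in between, mixed.
    fast_fraction_split: float = 0.75

    def __post_init__(self):
        if not self.fast_isi_max < self.burst_isi_max:
            raise ValidationError("fast_isi_max must be below burst_isi_max")
        if min(self.cv_regular_max, self.burst_isi_max, self.fast_isi_max) <= 0:
            raise ValidationError("classifier thresholds must be positive")


@dataclass(frozen=True)
class PatternLabel:
    regularity: str    # "regular" | "irregular"
    burstiness: str    # "single_spike" | "fast_burst" | "slow_burst" | "mixed_burst"

    @property
    def code(self) -> str:
        return ("R" if self.regularity == "regular" else "I") \
            + BURSTINESS_CODES[self.burstiness]


@dataclass(frozen=True)
class PtxResult:
    """Outcome of the rate-change sensitivity criterion for one unit."""

    unit_id: str
    pre_rate: float
    post_rate: float
    reduction: float          # percent; NaN when pre_rate is 0
    label: str                # sensitive | insensitive | increased | undefined


# ---------------------------------------------------------------------------

def isi_stats(train: SpikeTrain, duration: float) -> dict:
    """Spike count, mean rate, mean ISI and ISI coefficient of variation.

    The CV of a train with fewer than three spikes is undefined and reported
    as NaN (never as 0); the rate always uses the full duration.
    """
    t = train.times
    n = t.size
    out = {"n_spikes": int(n), "mean_rate": n / duration,
           "isi_mean": float("nan"), "isi_cv": float("nan")}
    if n >= 2:
        isis = np.diff(t)
        out["isi_mean"] = float(isis.mean())
        if n >= MIN_SPIKES_FOR_CV:
            m = isis.mean()
            out["isi_cv"] = float(isis.std(ddof=0) / m) if m > 0 else float("nan")
    return out


def _burst_runs(times: np.ndarray, cfg: ClassifierConfig):
    """Maximal runs of >= min_burst_spikes spikes with consecutive ISIs <= burst_isi_max.

    Returns (list of (start_idx, stop_idx) half-open, intra-burst ISIs array).
    """
    if times.size < 2:
        return [], np.empty(0)
    short = np.diff(times) <= cfg.burst_isi_max
    runs = []
    i = 0
    n_isi = short.size
    while i < n_isi:
        if short[i]:
            j = i
            while j < n_isi and short[j]:
                j += 1
            if (j - i + 1) >= cfg.min_burst_spikes:
                runs.append((i, j + 1))
            i = j
        i += 1
    if not runs:
        return [], np.empty(0)
    intra = np.concatenate([np.diff(times[a:b]) for a, b in runs])
    return runs, intra


def classify_pattern(train: SpikeTrain,
                     config: ClassifierConfig | None = None) -> PatternLabel | None:
    """Assign one of the eight firing-pattern classes, or None if the train
    has fewer than 10 spikes (reported separately as unclassifiable).

    Burstiness: the fraction of spikes inside burst runs decides bursty vs
    single-spike; among bursty trains the share of intra-burst ISIs in the
    fast regime (<= ``fast_isi_max``) separates fast, slow and mixed bursting.
    Regularity: CV of burst-onset intervals for bursty trains (the burst is
    the event), CV of all ISIs otherwise, against ``cv_regular_max``.
    """
    cfg = config or ClassifierConfig()
    t = train.times
    if t.size < MIN_SPIKES_FOR_CLASS:
        return None
    runs, intra = _burst_runs(t, cfg)
    n_in_bursts = sum(b - a for a, b in runs)
    bursty = runs and (n_in_bursts / t.size) >= cfg.burst_fraction_min

    if bursty:
        frac_fast = float(np.mean(intra <= cfg.fast_isi_max))
        if frac_fast >= cfg.fast_fraction_split:
            burstiness = "fast_burst"
        elif frac_fast <= 1.0 - cfg.fast_fraction_split:
            burstiness = "slow_burst"
        else:
            burstiness = "mixed_burst"
        events = t[[a for a, _ in runs]]          # burst onsets
    else:
        burstiness = "single_spike"
        events = t

    intervals = np.diff(events)
    if intervals.size >= 2 and intervals.mean() > 0:
        cv = intervals.std(ddof=0) / intervals.mean()
    else:
        cv = float("inf")   # too few events to call regular
    regularity = "regular" if cv <= cfg.cv_regular_max else "irregular"
    return PatternLabel(regularity=regularity, burstiness=burstiness)


def ptx_sensitivity(train: SpikeTrain, pre_window: tuple[float, float],
                    post_window: tuple[float, float],
                    config: AnalysisConfig | None = None) -> PtxResult:
    """Classify a unit's response to the blocker from pre/post firing rates.

    Sensitive when the rate drops by at least the reduction threshold
    (default 70%, boundary inclusive); increased when the post rate exceeds
    160% of the pre rate; insensitive otherwise. A silent pre-window makes
    the label undefined. Both windows must have equal length.
    """
    cfg = config or AnalysisConfig()
    (a0, a1), (b0, b1) = pre_window, post_window
    if a1 <= a0 or b1 <= b0:
        raise ValidationError("windows must have positive length")
    if abs((a1 - a0) - (b1 - b0)) > 1e-9:
        raise ValidationError("pre and post windows must have equal length")
    t = train.times
    pre_rate = float(np.sum((t >= a0) & (t < a1)) / (a1 - a0))
    post_rate = float(np.sum((t >= b0) & (t < b1)) / (b1 - b0))
    if pre_rate == 0:
        return PtxResult(train.unit_id, 0.0, post_rate, float("nan"), "undefined")
    reduction = 100.0 * (1.0 - post_rate / pre_rate)
    if reduction >= cfg.ptx_reduction_threshold:
        label = "sensitive"
    elif post_rate > 1.6 * pre_rate:
        label = "increased"
    else:
        label = "insensitive"
    return PtxResult(train.unit_id, pre_rate, post_rate, reduction, label)
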