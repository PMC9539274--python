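"""Domain types, spike-table I/O, validation and shared configuration.

A recording is a set of sorted single-unit spike trains sharing one clock.
Times are seconds from recording start; every analysis window is half-open
``[start, end)`` so no spike is ever counted twice at a bin edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

KINDS = ("neuron", "afferent")
DEPTH_LABELS = ("superficial", "deep", "unknown")
CONDITIONS = ("naive", "treated", "unknown")

#: Sentinel for statistics that are undefined on too-short trains (e.g. the
#: ISI coefficient of variation of a two-spike train).
UNDEFINED = float("nan")


class ValidationError(ValueError):
    """Raised when a spike table or Recording violates its invariants."""


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Normalise an int or SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's sorted event times plus identity metadata.

    Parameters
    ----------
    unit_id : str
        Identifier, unique within a Recording.
    kind : {"neuron", "afferent"}
        Dorsal-horn neuron or primary-afferent unit.
    times : numpy.ndarray
        Strictly increasing spike times in seconds.
    depth_label : {"superficial", "deep", "unknown"}
        Laminar location, consumed as metadata (never recomputed here).
    condition : {"naive", "treated", "unknown"}
        Treatment group of the animal the unit was recorded from.
    """

    unit_id: str
    kind: str = "neuron"
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    depth_label: str = "unknown"
    condition: str = "unknown"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.kind not in KINDS:
            raise ValidationError(f"unknown kind {self.kind!r} for unit {self.unit_id}")
        if self.depth_label not in DEPTH_LABELS:
            raise ValidationError(f"unknown depth_label {self.depth_label!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def rate(self, duration: float) -> float:
        """Mean firing rate in Hz over the full recording duration."""
        return self.n_spikes / duration

    def shifted(self, dt: float) -> "SpikeTrain":
        return replace(self, times=self.times + dt)


@dataclass(frozen=True)
class Recording:
    """A set of spike trains sharing a clock and a duration."""

    recording_id: str
    duration: float
    trains: tuple[SpikeTrain, ...] = ()
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "trains", tuple(self.trains))
        if self.duration <= 0:
            raise ValidationError("duration must be positive")

    def __iter__(self):
        return iter(self.trains)

    def __len__(self) -> int:
        return len(self.trains)

    def unit_ids(self) -> list[str]:
        return [t.unit_id for t in self.trains]

    def train(self, unit_id: str) -> SpikeTrain:
        for t in self.trains:
            if t.unit_id == unit_id:
                return t
        raise KeyError(unit_id)

    def neurons(self) -> list[SpikeTrain]:
        return [t for t in self.trains if t.kind == "neuron"]

    def afferents(self) -> list[SpikeTrain]:
        return [t for t in self.trains if t.kind == "afferent"]

    def collapsed_times(self, kind: str = "neuron",
                        unit_filter: Iterable[str] | None = None) -> np.ndarray:
        """All spike times of the selected units merged into one sorted stream."""
        keep = None if unit_filter is None else set(unit_filter)
        parts = [t.times for t in self.trains
                 if t.kind == kind and (keep is None or t.unit_id in keep)]
        if not parts:
            return np.empty(0)
        return np.sort(np.concatenate(parts))


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable analysis parameters with their field-standard defaults.

    ``tb`` is the bin size of the mean-frequency formula (0.2 s); the
    population-burst window runs from ``window_pre`` before to
    ``window_post`` after the burst mark (50/150 ms) and is histogrammed in
    ``shape_bin`` (5 ms) steps; the randomisation null uses ``null_reps``
    redistributions; effective connectivity looks at ``connectivity_window``
    (50 ms) before each target spike split into ``connectivity_bins`` count
    bins, with ``mcc_threshold`` (0.18) marking putative monosynaptic links;
    ``ptx_reduction_threshold`` (70%) defines picrotoxin sensitivity.
    """

    tb: float = 0.2
    window_pre: float = 0.050
    window_post: float = 0.150
    shape_bin: float = 0.005
    null_reps: int = 100
    connectivity_window: float = 0.050
    connectivity_bins: int = 10
    mcc_threshold: float = 0.18
    ptx_reduction_threshold: float = 70.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("tb", "window_pre", "window_post", "shape_bin",
                     "connectivity_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.mcc_threshold < 1:
            raise ValidationError("mcc_threshold must lie in (0, 1)")
        span = self.window_pre + self.window_post
        n = span / self.shape_bin
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("window span must be divisible by shape_bin")

    @property
    def window_span(self) -> float:
        return self.window_pre + self.window_post

    @property
    def n_shape_bins(self) -> int:
        return int(round(self.window_span / self.shape_bin))


# ---------------------------------------------------------------------------
# Validation

def validate_recording(recording: Recording) -> list[str]:
    """Report every invariant violation in ``recording``; empty list if valid.

    Pure reporting: never raises, never mutates.
    """
    report: list[str] = []
    seen: set[str] = set()
    for train in recording.trains:
        uid = train.unit_id
        if uid in seen:
            report.append(f"duplicate unit_id {uid!r}")
        seen.add(uid)
        t = train.times
        if t.size and np.any(np.diff(t) < 0):
            report.append(f"unit {uid!r}: times not sorted")
        if t.size and np.any(np.diff(t) == 0):
            report.append(f"unit {uid!r}: duplicate timestamps")
        if t.size and t[0] < 0:
            report.append(f"unit {uid!r}: negative time {t[0]:.6f}")
        if t.size and t[-1] >= recording.duration:
            report.append(
                f"unit {uid!r}: time {t[-1]:.6f} >= duration {recording.duration:.6f}"
            )
    return report


# ---------------------------------------------------------------------------
# Spike-table I/O
#
# Format: CSV with columns unit_id,kind,time_s plus a JSON sidecar
# {recording_id, duration_s, units: {unit_id: {depth_label, condition}}}.

def read_spike_table(path, metadata_path) -> Recording:
    """Read a spike-table CSV and its JSON metadata into a Recording.

    Raises :class:`ValidationError` naming the offending row on missing
    columns, negative times, times at or past the duration, or duplicate
    (unit_id, time) rows.
    """
    df = pd.read_csv(path, dtype={"unit_id": str})
    missing = {"unit_id", "kind", "time_s"} - set(df.columns)
    if missing:
        raise ValidationError(f"spike table missing columns: {sorted(missing)}")
    meta = json.loads(Path(metadata_path).read_text())
    duration = float(meta["duration_s"])
    units_meta: Mapping = meta.get("units", {})

    bad = df.index[df["time_s"] < 0]
    if len(bad):
        raise ValidationError(f"row {bad[0]}: negative time_s {df.loc[bad[0], 'time_s']}")
    bad = df.index[df["time_s"] >= duration]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: time_s {df.loc[bad[0], 'time_s']} >= duration {duration}"
        )
    dup = df.duplicated(subset=["unit_id", "time_s"])
    if dup.any():
        i = df.index[dup][0]
        raise ValidationError(
            f"row {i}: duplicate (unit_id, time) ({df.loc[i, 'unit_id']}, {df.loc[i, 'time_s']})"
        )

    trains = []
    for uid, sub in df.groupby("unit_id", sort=True):
        kinds = sub["kind"].unique()
        if len(kinds) != 1:
            raise ValidationError(f"unit {uid!r} has inconsistent kind labels {list(kinds)}")
        um = units_meta.get(uid, {})
        trains.append(SpikeTrain(
            unit_id=str(uid),
            kind=str(kinds[0]),
            times=np.sort(sub["time_s"].to_numpy(dtype=float)),
            depth_label=um.get("depth_label", "unknown"),
            condition=um.get("condition", "unknown"),
        ))
    return Recording(
        recording_id=str(meta.get("recording_id", Path(path).stem)),
        duration=duration,
        trains=tuple(trains),
        annotations=dict(meta.get("annotations", {})),
    )


def write_spike_table(recording: Recording, path, metadata_path) -> None:
    """Write a Recording as spike-table CSV + JSON metadata (6-decimal times)."""
    rows = []
    for train in sorted(recording.trains, key=lambda t: t.unit_id):
        for t in train.times:
            rows.append((train.unit_id, train.kind, f"{t:.6f}"))
    df = pd.DataFrame(rows, columns=["unit_id", "kind", "time_s"])
    df.to_csv(path, index=False)
    meta = {
        "recording_id": recording.recording_id,
        "duration_s": recording.duration,
        "units": {
            t.unit_id: {"depth_label": t.depth_label, "condition": t.condition}
            for t in sorted(recording.trains, key=lambda t: t.unit_id)
        },
        "annotations": recording.annotations,
    }
    Path(metadata_path).write_text(json.dumps(meta, indent=1, sort_keys=True))
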