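"""Decision-tree effective connectivity between spike trains.

One train is the prediction target, others are attributes. For every target
spike, the attribute activity in the 50 ms preceding the spike (10 count bins
of 5 ms) forms a positive instance; an equal number of negative instances is
sampled from epochs at least 50 ms away from every target spike. A
rule-inducing decision tree (information-gain splits, no boosting) is trained
on a stratified random subset and scored on the held-out remainder with the
Matthews correlation coefficient (MCC); MCC >= 0.18 with a single unit as
attribute marks a putative monosynaptic connection. Running each
neuron-afferent pair in both directions (afferent as target = presynaptic
evidence; neuron as target = postsynaptic evidence) yields a direction label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .core import (AnalysisConfig, Recording, SpikeTrain, ValidationError,
                   as_seed_sequence)

MIN_TARGET_SPIKES = 20
MIN_INSTANCES_PER_CLASS = 10


@dataclass(frozen=True)
class InstanceSet:
    """Feature matrix and labels for one target train."""

    features: np.ndarray       # instances x (n_attributes * n_bins), int counts
    labels: np.ndarray         # 1 = target spiked, 0 = quiet epoch
    instance_times: np.ndarray
    attribute_ids: tuple[str, ...]
    n_bins: int


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class ConnectivityResult:
    attribute_id: str
    target_id: str
    mcc: float
    confusion: ConfusionMatrix
    n_rules: int
    direction: str = "none"    # presynaptic | postsynaptic | bidirectional | none
    status: str = "ok"


def mcc(confusion: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); by convention 0
    when any denominator factor vanishes. Bounded by [-1, 1], reaching 1 only
    for a perfect confusion matrix.
    """
    tp, fp, tn, fn = confusion.TP, confusion.FP, confusion.TN, confusion.FN
    if tp + fp + tn + fn == 0:
        raise ValidationError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


# ---------------------------------------------------------------------------
# Instance construction

def _window_counts(attr_times: np.ndarray, t: float, window: float,
                   n_bins: int) -> np.ndarray:
    edges = t - window + (window / n_bins) * np.arange(n_bins + 1)
    lo = np.searchsorted(attr_times, edges[:-1], side="left")
    hi = np.searchsorted(attr_times, edges[1:], side="left")
    return hi - lo


def build_instances(target_train: SpikeTrain,
                    attribute_trains: list[SpikeTrain],
                    duration: float,
                    config: AnalysisConfig | None = None,
                    seed=0) -> InstanceSet:
    """Build balanced positive/negative instances for one target train.

    Positives: per-attribute spike counts in the ``connectivity_bins`` equal
    sub-bins of the 50 ms window before each target spike. Negatives: the
    same features at uniformly drawn times at least one window away from
    every target spike, count-matched to the positives.
    """
    cfg = config or AnalysisConfig()
    w, n_bins = cfg.connectivity_window, cfg.connectivity_bins
    if not attribute_trains:
        raise ValidationError("need at least one attribute train")
    tgt = target_train.times
    tgt = tgt[tgt >= w]                      # full window must fit
    if tgt.size < MIN_TARGET_SPIKES:
        raise ValidationError(
            f"target {target_train.unit_id!r} has {tgt.size} usable spikes; "
            f"need >= {MIN_TARGET_SPIKES}")
    if duration <= 2 * w:
        raise ValidationError("recording shorter than the analysis window")

    rng = np.random.default_rng(as_seed_sequence(seed))
    neg_times = []
    all_tgt = target_train.times
    tries = 0
    while len(neg_times) < tgt.size:
        cand = rng.uniform(w, duration, tgt.size)
        i = np.searchsorted(all_tgt, cand)
        d_next = np.where(i < all_tgt.size, all_tgt[np.minimum(i, all_tgt.size - 1)] - cand,
                          np.inf)
        d_prev = np.where(i > 0, cand - all_tgt[np.maximum(i - 1, 0)], np.inf)
        ok = (d_next >= w) & (d_prev >= w)
        neg_times.extend(cand[ok].tolist())
        tries += 1
        if tries > 1000:
            raise ValidationError("cannot place negative instances away from target spikes")
    neg_times = np.array(sorted(neg_times[: tgt.size]))

    def feats(ts):
        rows = np.empty((ts.size, len(attribute_trains) * n_bins), dtype=int)
        for j, at in enumerate(attribute_trains):
            for i, t in enumerate(ts):
                rows[i, j * n_bins:(j + 1) * n_bins] = \
                    _window_counts(at.times, t, w, n_bins)
        return rows

    X = np.vstack([feats(tgt), feats(neg_times)])
    y = np.concatenate([np.ones(tgt.size, dtype=int),
                        np.zeros(neg_times.size, dtype=int)])
    times = np.concatenate([tgt, neg_times])
    return InstanceSet(X, y, times,
                       tuple(a.unit_id for a in attribute_trains), n_bins)


# ---------------------------------------------------------------------------
# Training and evaluation

def train_evaluate(instances: InstanceSet, split_fraction: float = 0.7,
                   seed=0) -> tuple[ConfusionMatrix, dict]:
    """Fit the decision tree on a stratified split and score the held-out part.

    Returns the test-set confusion matrix and a rule summary (number of
    leaves, depth, feature importances by attribute).
    """
    y = instances.labels
    if min(np.sum(y == 0), np.sum(y == 1)) < MIN_INSTANCES_PER_CLASS:
        raise ValidationError(
            f"need >= {MIN_INSTANCES_PER_CLASS} instances per class")
    rng_seed = int(as_seed_sequence(seed).generate_state(1)[0] % (2**31))
    X_tr, X_te, y_tr, y_te = train_test_split(
        instances.features, y, train_size=split_fraction, stratify=y,
        random_state=rng_seed)
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValidationError("degenerate single-class split; provide more data")
    tree = DecisionTreeClassifier(criterion="entropy", random_state=rng_seed)
    tree.fit(X_tr, y_tr)
    pred = tree.predict(X_te)
    tp = int(np.sum((pred == 1) & (y_te == 1)))
    fp = int(np.sum((pred == 1) & (y_te == 0)))
    tn = int(np.sum((pred == 0) & (y_te == 0)))
    fn = int(np.sum((pred == 0) & (y_te == 1)))
    conf = ConfusionMatrix(tp, fp, tn, fn)
    n_bins = instances.n_bins
    importances = tree.feature_importances_
    summary = {
        "n_rules": int(tree.get_n_leaves()),
        "depth": int(tree.get_depth()),
        "importance_by_attribute": {
            aid: float(importances[j * n_bins:(j + 1) * n_bins].sum())
            for j, aid in enumerate(instances.attribute_ids)
        },
    }
    return conf, summary


def pair_mcc(recording: Recording, attribute_id: str, target_id: str,
             config: AnalysisConfig | None = None, seed=0,
             split_fraction: float = 0.7) -> ConnectivityResult:
    """Single attribute -> target analysis returning the held-out MCC."""
    cfg = config or AnalysisConfig()
    inst = build_instances(recording.train(target_id),
                           [recording.train(attribute_id)],
                           recording.duration, cfg, seed=seed)
    conf, summary = train_evaluate(inst, split_fraction, seed=seed)
    return ConnectivityResult(attribute_id, target_id, mcc(conf), conf,
                              summary["n_rules"])


def connectivity_screen(recording: Recording, afferent_ids=None,
                        config: AnalysisConfig | None = None,
                        seed=0, split_fraction: float = 0.7) -> pd.DataFrame:
    """Directional neuron-afferent screen over all pairs.

    For each (neuron, afferent) pair, the neuron-as-attribute / afferent-as-
    target MCC is presynaptic evidence, the reverse is postsynaptic evidence;
    the direction label follows which of the two reaches ``mcc_threshold``.
    Per-pair failures (sparse targets, degenerate splits) are recorded in the
    ``status`` column, not raised.
    """
    cfg = config or AnalysisConfig()
    if afferent_ids is None:
        afferent_ids = [a.unit_id for a in recording.afferents()]
    neurons = recording.neurons()
    rows = []
    ss = as_seed_sequence(seed)
    for aid in afferent_ids:
        for neuron in neurons:
            sub = ss.spawn(2)
            pre_mcc = post_mcc = float("nan")
            pre_conf = post_conf = ConfusionMatrix(0, 0, 0, 0)
            n_rules = 0
            status = "ok"
            try:
                r_pre = pair_mcc(recording, neuron.unit_id, aid, cfg,
                                 seed=sub[0], split_fraction=split_fraction)
                pre_mcc, pre_conf = r_pre.mcc, r_pre.confusion
                r_post = pair_mcc(recording, aid, neuron.unit_id, cfg,
                                  seed=sub[1], split_fraction=split_fraction)
                post_mcc, post_conf, n_rules = r_post.mcc, r_post.confusion, r_post.n_rules
            except ValidationError as exc:
                status = str(exc)
            pre_hit = pre_mcc >= cfg.mcc_threshold if np.isfinite(pre_mcc) else False
            post_hit = post_mcc >= cfg.mcc_threshold if np.isfinite(post_mcc) else False
            direction = {(True, True): "bidirectional", (True, False): "presynaptic",
                         (False, True): "postsynaptic", (False, False): "none"}[
                (pre_hit, post_hit)]
            rows.append({
                "attribute_id": neuron.unit_id, "target_id": aid,
                "mcc_presynaptic": pre_mcc, "mcc_postsynaptic": post_mcc,
                "TP": pre_conf.TP, "FP": pre_conf.FP,
                "TN": pre_conf.TN, "FN": pre_conf.FN,
                "direction": direction, "status": status,
            })
    return pd.DataFrame(rows)
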