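import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from popburst import (AnalysisConfig, ConfusionMatrix, Edge, GeneratorParams,
                      InstanceSet, Recording, SpikeTrain, ValidationError,
                      build_instances, connectivity_screen, generate_recording,
                      mcc, pair_mcc, train_evaluate)


def _coupled_pair(seed=0, duration=600.0, p=1.0, attr_rate=1.0, bg_rate=0.0):
    """Attribute Poisson train; target fires 3 ms after each attribute spike."""
    rng = np.random.default_rng(seed)
    attr = np.cumsum(rng.exponential(1 / attr_rate, int(attr_rate * duration * 2)))
    attr = attr[attr < duration - 0.01]
    keep = rng.random(attr.size) < p
    tgt = attr[keep] + 0.003
    if bg_rate > 0:
        bg = np.sort(rng.uniform(0, duration, rng.poisson(bg_rate * duration)))
        tgt = np.unique(np.concatenate([tgt, bg]))
    return (SpikeTrain("attr", "neuron", attr),
            SpikeTrain("tgt", "neuron", np.sort(tgt)))


class TestMcc:
    def test_perfect_matrix_is_one(self):
        assert mcc(ConfusionMatrix(50, 0, 50, 0)) == 1.0

    def test_uninformative_matrix_is_zero(self):
        assert mcc(ConfusionMatrix(25, 25, 25, 25)) == 0.0

    def test_hand_evaluated_case(self):
        # (4*8 - 1*2) / sqrt(5*6*9*10) = 30 / sqrt(2700)
        assert mcc(ConfusionMatrix(TP=4, FP=1, TN=8, FN=2)) == \
            pytest.approx(30 / np.sqrt(2700), abs=1e-9)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionMatrix(10, 0, 0, 0)) == 0.0

    @given(st.tuples(*[st.integers(0, 200)] * 4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_swap_symmetric(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        v = mcc(ConfusionMatrix(tp, fp, tn, fn))
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(mcc(ConfusionMatrix(tn, fn, tp, fp)), abs=1e-12)

    def test_matches_sklearn_on_labelled_data(self):
        y_true = np.array([1] * 6 + [0] * 9)
        y_pred = np.array([1, 1, 1, 1, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        assert mcc(ConfusionMatrix(tp, fp, tn, fn)) == \
            pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestBuildInstances:
    def test_shapes_and_balance(self):
        attr, tgt = _coupled_pair(seed=1)
        inst = build_instances(tgt, [attr], 600.0, seed=0)
        n_pos = int(inst.labels.sum())
        assert inst.features.shape == (2 * n_pos, 10)
        assert (inst.labels == 0).sum() == n_pos
        assert (inst.features >= 0).all()

    def test_silent_attribute_gives_zero_features(self):
        _, tgt = _coupled_pair(seed=2)
        silent = SpikeTrain("s", "neuron", np.empty(0))
        inst = build_instances(tgt, [silent], 600.0, seed=0)
        assert not inst.features.any()

    def test_tightly_coupled_attribute_fills_last_bin(self):
        attr, tgt = _coupled_pair(seed=3, p=1.0)
        inst = build_instances(tgt, [attr], 600.0, seed=0)
        pos = inst.features[inst.labels == 1]
        neg = inst.features[inst.labels == 0]
        # the 3 ms lag falls in the last 5 ms bin before the target spike
        assert (pos[:, -1] >= 1).mean() > 0.99
        assert neg.sum() < 0.2 * neg.shape[0]

    def test_sparse_target_rejected(self):
        attr, _ = _coupled_pair(seed=4)
        tgt = SpikeTrain("t", "neuron", np.linspace(1, 599, 10))
        with pytest.raises(ValidationError, match="usable spikes"):
            build_instances(tgt, [attr], 600.0)

    def test_negative_times_stay_away_from_target_spikes(self):
        attr, tgt = _coupled_pair(seed=5)
        inst = build_instances(tgt, [attr], 600.0, seed=1)
        neg_times = inst.instance_times[inst.labels == 0]
        d = np.min(np.abs(neg_times[:, None] - tgt.times[None, :]), axis=1)
        assert (d >= 0.05).all()


class TestTrainEvaluate:
    def test_separable_fixture_reaches_high_mcc(self):
        scores = []
        for seed in range(20):
            attr, tgt = _coupled_pair(seed=seed)
            inst = build_instances(tgt, [attr], 600.0, seed=seed)
            conf, _ = train_evaluate(inst, seed=seed)
            scores.append(mcc(conf))
        assert np.mean(np.asarray(scores) >= 0.9) >= 0.95

    def test_permuted_labels_give_chance_mcc(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(2000, 10))
        hits = 0
        for seed in range(20):
            y = np.zeros(2000, dtype=int)
            y[np.random.default_rng(seed).permutation(2000)[:1000]] = 1
            inst = InstanceSet(X, y, np.arange(2000.0), ("a",), 10)
            conf, _ = train_evaluate(inst, seed=seed)
            hits += abs(mcc(conf)) <= 0.1
        assert hits >= 18

    def test_single_feature_separable_tree_is_shallow(self):
        X = np.zeros((60, 10), dtype=int)
        y = np.array([1] * 30 + [0] * 30)
        X[:30, -1] = 1
        inst = InstanceSet(X, y, np.arange(60.0), ("a",), 10)
        conf, summary = train_evaluate(inst, seed=0)
        assert summary["n_rules"] <= 2
        assert mcc(conf) == 1.0

    def test_too_few_instances_rejected(self):
        X = np.zeros((10, 10), dtype=int)
        y = np.array([1] * 5 + [0] * 5)
        inst = InstanceSet(X, y, np.arange(10.0), ("a",), 10)
        with pytest.raises(ValidationError):
            train_evaluate(inst)


def _best_single_split_predictions(X, y):
    """Exhaustive single-split oracle: best (feature, threshold) by
    information gain, majority vote on each side, applied to X itself."""
    def entropy(labels):
        if labels.size == 0:
            return 0.0
        p = labels.mean()
        if p in (0.0, 1.0):
            return 0.0
        return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))

    best, best_gain = None, -1.0
    base = entropy(y)
    for j in range(X.shape[1]):
        for c in np.unique(X[:, j])[:-1]:
            left = X[:, j] <= c
            h = (left.mean() * entropy(y[left])
                 + (1 - left.mean()) * entropy(y[~left]))
            gain = base - h
            if gain > best_gain + 1e-12:
                best, best_gain = (j, c), gain
    j, c = best
    left = X[:, j] <= c
    pred = np.empty_like(y)
    pred[left] = int(round(y[left].mean()))
    pred[~left] = int(round(y[~left].mean()))
    return pred


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_tree_matches_single_split_enumeration(self, seed):
        """On tiny single-split-separable sets, the tree's predictions equal
        the exhaustive best-split oracle's."""
        rng = np.random.default_rng(seed)
        n = 12
        y = np.array([1] * 6 + [0] * 6)
        X = np.zeros((n, 2), dtype=int)
        X[:, 0] = y                       # feature 0 separates perfectly
        X[:, 1] = rng.integers(0, 2, n)   # feature 1 is noise
        from sklearn.tree import DecisionTreeClassifier
        tree = DecisionTreeClassifier(criterion="entropy", random_state=0)
        tree.fit(X, y)
        np.testing.assert_array_equal(tree.predict(X),
                                      _best_single_split_predictions(X, y))


@pytest.fixture(scope="module")
def planted_recording():
    params = GeneratorParams(
        seed=0, n_neurons=6, grouping_target=0.0, n_afferents=1,
        p_backfire=0.8,
        edges=(Edge("n000", "a00", "presynaptic", 0.003, 0.9),
               Edge("n001", "a00", "postsynaptic", 0.004, 0.9)))
    return generate_recording(params)


class TestConnectivityScreen:
    def test_planted_edges_and_directions(self, planted_recording):
        rec, _ = planted_recording
        df = connectivity_screen(rec, seed=0)
        by_attr = df.set_index("attribute_id")
        assert by_attr.loc["n000", "direction"] in ("presynaptic", "bidirectional")
        assert by_attr.loc["n001", "direction"] == "postsynaptic"
        others = by_attr.drop(["n000", "n001"])
        assert (others["direction"] == "none").all()

    def test_no_afferents_gives_empty_table(self):
        rec, _ = generate_recording(GeneratorParams(seed=1, n_neurons=4))
        assert connectivity_screen(rec, seed=0).empty

    def test_deterministic_given_seed(self, planted_recording):
        rec, _ = planted_recording
        a = connectivity_screen(rec, seed=5)
        b = connectivity_screen(rec, seed=5)
        assert a.equals(b)

    def test_delayed_copy_neuron_dominates(self):
        # afferent is an exact 3 ms-delayed copy of one neuron
        rng = np.random.default_rng(9)
        base = np.sort(rng.uniform(0.1, 599, 400))
        trains = [SpikeTrain("src", "neuron", base),
                  SpikeTrain("aff", "afferent", base + 0.003)]
        for i in range(4):
            trains.append(SpikeTrain(
                f"ind{i}", "neuron",
                np.sort(rng.uniform(0, 600, 400))))
        rec = Recording("copy", 600.0, tuple(trains))
        df = connectivity_screen(rec, seed=0).set_index("attribute_id")
        src = df.loc["src", "mcc_presynaptic"]
        assert src >= 0.18
        assert (df.drop("src")["mcc_presynaptic"] < src).all()
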