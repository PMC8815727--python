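import numpy as np
import pytest

from openlook.classifier import (
    DEFAULT_LABEL_MAP,
    ClassifierSpec,
    MLPNetwork,
    TrainConfig,
    TrainedClassifier,
    build_network,
    load_classifier,
    predict_frames,
    save_classifier,
    split_frames,
    train_classifier,
)
from openlook.errors import ConfigError
from openlook.features import FeatureMatrix, Standardizer
from openlook.protocol import AOI, AOILabelSeries
from openlook.quality import QualityConfig

from conftest import make_gaze_table

QUICK = TrainConfig(epochs=60, patience=15, n_ensemble=1, seed=0)


def cluster_problem(n_per_class=120, sep=3.0, noise=0.3, n_features=6, seed=0):
    """Three well-separated gaussian clusters; returns (matrix, labels, table)."""
    rng = np.random.default_rng(seed)
    centers = np.zeros((3, n_features))
    centers[0, 0] = -sep
    centers[2, 0] = sep
    values = np.vstack([rng.normal(c, noise, size=(n_per_class, n_features)) for c in centers])
    codes = np.repeat([AOI.LEFT, AOI.CENTER, AOI.RIGHT], n_per_class).astype(np.int8)
    perm = rng.permutation(len(codes))
    values, codes = values[perm], codes[perm]
    matrix = FeatureMatrix(
        values=values,
        column_names=[f"f{i}" for i in range(n_features)],
        frame_index=np.arange(len(codes)),
    )
    labels = AOILabelSeries(codes, source="coder")
    table = make_gaze_table(np.ones(len(codes)))
    return matrix, labels, table


class TestSplit:
    def test_even_split_disjoint_and_complete(self):
        s = split_frames(np.arange(10), 0.5, seed=3)
        assert len(s.train_rows) == len(s.test_rows) == 5
        assert not set(s.train_rows) & set(s.test_rows)
        assert sorted([*s.train_rows, *s.test_rows]) == list(range(10))

    def test_same_seed_same_split(self):
        a = split_frames(np.arange(100), 0.5, seed=9)
        b = split_frames(np.arange(100), 0.5, seed=9)
        np.testing.assert_array_equal(a.train_rows, b.train_rows)

    def test_published_session_size_splits_in_half(self):
        s = split_frames(np.arange(3270), 0.5, seed=0)
        assert len(s.train_rows) == 1635

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            split_frames(np.arange(10), 1.5, seed=0)


class TestArchitecture:
    def test_default_topology(self):
        spec = ClassifierSpec(input_dim=712)
        assert spec.n_hidden_layers == 3
        assert spec.n_linear_layers == 4
        assert spec.dropout_p == 0.2
        assert spec.n_classes == 3
        assert spec.batchnorm
        net = build_network(spec, seed=0)
        weights = [k for k in net.params if k.startswith("W")]
        assert sorted(weights) == ["W0", "W1", "W2", "W3"]
        assert net.params["W0"].shape == (712, 64)
        assert net.params["W3"].shape == (64, 3)
        assert {"gamma0", "gamma1", "gamma2"} <= set(net.params)

    def test_softmax_output_normalised(self):
        net = build_network(ClassifierSpec(input_dim=5), seed=1)
        p = net.predict_proba(np.random.default_rng(0).normal(size=(7, 5)))
        assert p.shape == (7, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_wrong_input_dim_rejected(self):
        net = build_network(ClassifierSpec(input_dim=5), seed=1)
        with pytest.raises(ConfigError, match="features"):
            net.predict_proba(np.zeros((3, 4)))


class TestTraining:
    def test_separable_clusters_reach_high_heldout_agreement(self):
        matrix, labels, _ = cluster_problem()
        split = split_frames(np.arange(len(labels)), 0.5, seed=5)
        model = train_classifier(
            ClassifierSpec(input_dim=matrix.n_features),
            matrix,
            labels,
            split,
            TrainConfig(n_ensemble=1, seed=0),  # default epoch budget
        )
        pred = model.predict_proba(matrix.values[split.test_rows]).argmax(axis=1)
        truth = labels.codes[split.test_rows]
        assert (pred == truth).mean() >= 0.99

    def test_sklearn_agrees_on_separable_clusters(self):
        """Independent cross-check with a reference MLP implementation."""
        sklearn = pytest.importorskip("sklearn.neural_network")
        matrix, labels, _ = cluster_problem()
        split = split_frames(np.arange(len(labels)), 0.5, seed=5)
        ref = sklearn.MLPClassifier(
            hidden_layer_sizes=(64, 64, 64), max_iter=500, random_state=0
        ).fit(matrix.values[split.train_rows], labels.codes[split.train_rows])
        acc = ref.score(matrix.values[split.test_rows], labels.codes[split.test_rows])
        assert acc >= 0.99

    def test_shuffled_labels_stay_at_chance(self):
        matrix, labels, _ = cluster_problem(n_per_class=700)
        rng = np.random.default_rng(11)
        shuffled = AOILabelSeries(rng.permutation(labels.codes), source="coder")
        split = split_frames(np.arange(len(shuffled)), 0.5, seed=5)
        model = train_classifier(
            ClassifierSpec(input_dim=matrix.n_features), matrix, shuffled, split, QUICK
        )
        pred = model.predict_proba(matrix.values[split.test_rows]).argmax(axis=1)
        acc = (pred == shuffled.codes[split.test_rows]).mean()
        assert acc == pytest.approx(1 / 3, abs=0.06)

    def test_same_seed_identical_predictions(self):
        matrix, labels, table = cluster_problem(n_per_class=60)
        split = split_frames(np.arange(len(labels)), 0.5, seed=2)
        spec = ClassifierSpec(input_dim=matrix.n_features)
        a = train_classifier(spec, matrix, labels, split, QUICK)
        b = train_classifier(spec, matrix, labels, split, QUICK)
        pa = predict_frames(a, table, matrix, QualityConfig(min_confidence=0.0))
        pb = predict_frames(b, table, matrix, QualityConfig(min_confidence=0.0))
        np.testing.assert_array_equal(pa.codes, pb.codes)

    def test_training_never_touches_test_rows(self):
        """Dropping the test rows entirely reproduces identical weights."""
        matrix, labels, _ = cluster_problem(n_per_class=60)
        split = split_frames(np.arange(len(labels)), 0.5, seed=2)
        spec = ClassifierSpec(input_dim=matrix.n_features)
        full = train_classifier(spec, matrix, labels, split, QUICK)

        keep = np.sort(split.train_rows)
        sub_matrix = FeatureMatrix(
            values=matrix.values[keep],
            column_names=list(matrix.column_names),
            frame_index=np.arange(keep.size),
        )
        sub_labels = AOILabelSeries(labels.codes[keep], source=labels.source)
        sub_split = split_frames(np.arange(keep.size), 0.9, seed=0)
        sub_split = type(sub_split)(
            train_rows=np.arange(keep.size),
            test_rows=np.array([], dtype=int),
            fraction=1.0,
            seed=0,
        )
        reduced = train_classifier(spec, sub_matrix, sub_labels, sub_split, QUICK)
        for wa, wb in zip(full.networks[0].params.values(), reduced.networks[0].params.values()):
            np.testing.assert_array_equal(wa, wb)

    def test_absent_class_warns(self):
        matrix, labels, _ = cluster_problem(n_per_class=40)
        two_class = AOILabelSeries(
            np.where(labels.codes == AOI.RIGHT, AOI.CENTER, labels.codes).astype(np.int8),
            source="coder",
        )
        split = split_frames(np.arange(len(two_class)), 0.5, seed=1)
        quick = TrainConfig(epochs=3, n_ensemble=1, seed=0)
        with pytest.warns(UserWarning, match="RIGHT"):
            train_classifier(
                ClassifierSpec(input_dim=matrix.n_features), matrix, two_class, split, quick
            )

    def test_no_labeled_rows_rejected(self):
        matrix, labels, _ = cluster_problem(n_per_class=10)
        off = AOILabelSeries(np.full(len(labels), AOI.OFF, dtype=np.int8), source="coder")
        split = split_frames(np.arange(len(off)), 0.5, seed=1)
        with pytest.raises(ConfigError):
            train_classifier(
                ClassifierSpec(input_dim=matrix.n_features), matrix, off, split, QUICK
            )


class TestPrediction:
    def _uniform_model(self, n_features=4):
        """All-zero final layer: exact three-way probability tie everywhere."""
        spec = ClassifierSpec(input_dim=n_features)
        net = build_network(spec, seed=0)
        net.params["W3"][:] = 0.0
        net.params["b3"][:] = 0.0
        return TrainedClassifier(spec=spec, networks=[net])

    def test_exact_tie_breaks_to_center(self):
        model = self._uniform_model()
        table = make_gaze_table([1.0, 1.0])
        matrix = FeatureMatrix(
            values=np.random.default_rng(0).normal(size=(2, 4)),
            column_names=list("abcd"),
            frame_index=np.arange(2),
        )
        pred = predict_frames(model, table, matrix)
        assert (pred.codes == AOI.CENTER).all()

    def test_unusable_frames_get_off(self):
        model = self._uniform_model()
        table = make_gaze_table([0.99, 0.2], success=[0, 1])
        matrix = FeatureMatrix(
            values=np.zeros((2, 4)),
            column_names=list("abcd"),
            frame_index=np.arange(2),
        )
        pred = predict_frames(model, table, matrix, QualityConfig(min_confidence=0.75))
        assert pred.codes[0] == AOI.OFF  # success = 0
        assert pred.codes[1] == AOI.OFF  # confidence below threshold
        assert pred.source == "model"

    def test_memorises_separable_training_frames(self):
        matrix, labels, table = cluster_problem(n_per_class=60)
        split = split_frames(np.arange(len(labels)), 0.5, seed=2)
        model = train_classifier(
            ClassifierSpec(input_dim=matrix.n_features),
            matrix,
            labels,
            split,
            TrainConfig(n_ensemble=1, seed=0),
        )
        pred = predict_frames(model, table, matrix, QualityConfig(min_confidence=0.0))
        rows = split.train_rows
        assert (pred.codes[rows] == labels.codes[rows]).mean() >= 0.99


def test_save_load_roundtrip(tmp_path):
    matrix, labels, table = cluster_problem(n_per_class=40)
    split = split_frames(np.arange(len(labels)), 0.5, seed=2)
    model = train_classifier(
        ClassifierSpec(input_dim=matrix.n_features), matrix, labels, split, QUICK
    )
    path = tmp_path / "model.json"
    save_classifier(model, path)
    back = load_classifier(path)
    np.testing.assert_allclose(
        back.predict_proba(matrix.values), model.predict_proba(matrix.values), atol=1e-12
    )
    assert back.label_map == DEFAULT_LABEL_MAP
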