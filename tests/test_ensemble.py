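import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from profold import (
    ClassifierSpec,
    FeatureGroupMatrix,
    SyntheticDatasetSpec,
    TrainedEnsemble,
    cross_validate_roster,
    fast_roster,
    gen_labelled_dataset,
    load_ensemble,
    predict,
    q_accuracy,
    roster_from_config,
    save_ensemble,
    select_classifier,
    train_ensemble,
)

# -- published-style 5-fold CV accuracy table used to exercise the
#    selection rule (one column per feature group, roster order preserved)
CV_TABLE = {
    "DSSP": [("LMT", 43.0), ("RandomForest", 51.3), ("LibSVM", 46.4),
             ("SimpleLogistic", 43.0), ("RotationForest", 49.7), ("SMO", 36.4),
             ("NaiveBayes", 43.4), ("RandomTree", 32.8), ("FT", 42.4),
             ("SimpleCart", 37.7)],
    "AAsCPP": [("LMT", 32.5), ("RandomForest", 35.4), ("LibSVM", 34.4),
               ("SimpleLogistic", 32.5), ("RotationForest", 27.7), ("SMO", 34.4),
               ("NaiveBayes", 28.3), ("RandomTree", 11.6), ("FT", 34.4),
               ("SimpleCart", 20.6)],
    "PSSM": [("LMT", 56.3), ("RandomForest", 53.7), ("LibSVM", 57.2),
             ("SimpleLogistic", 55.9), ("RotationForest", 56.1), ("SMO", 30.2),
             ("NaiveBayes", 42.4), ("RandomTree", 29.6), ("FT", 49.5),
             ("SimpleCart", 33.4)],
    "FunD": [("LMT", 42.1), ("RandomForest", 43.1), ("LibSVM", 21.2),
             ("SimpleLogistic", 43.1), ("RotationForest", 41.8), ("SMO", 38.9),
             ("NaiveBayes", 38.3), ("RandomTree", 39.9), ("FT", 44.1),
             ("SimpleCart", 34.7)],
}


class _FixedProba:
    """A 'fitted model' that returns a predetermined probability matrix."""

    def __init__(self, proba, classes):
        self._proba = np.asarray(proba, dtype=float)
        self.classes_ = np.asarray(classes, dtype=object)

    def predict_proba(self, X):
        assert len(X) == len(self._proba)
        return self._proba


def _fm(group, values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return FeatureGroupMatrix(
        group, sample_ids or [f"s{i}" for i in range(n)], values,
        [f"{group}.f{j}" for j in range(d)],
    )


def _mock_ensemble(per_group_proba, classes):
    return TrainedEnsemble(
        class_labels=list(classes),
        per_group={
            g: (f"mock-{g}", _FixedProba(p, classes))
            for g, p in per_group_proba.items()
        },
    )


class TestSelectionRule:
    @pytest.mark.parametrize(
        "group, winner",
        [("DSSP", "RandomForest"), ("AAsCPP", "RandomForest"),
         ("PSSM", "LibSVM"), ("FunD", "FT")],
    )
    def test_argmax_winner_per_group(self, group, winner):
        assert select_classifier(CV_TABLE[group]) == winner

    def test_ties_resolve_to_earliest_entry(self):
        assert select_classifier([("a", 0.5), ("b", 0.5), ("c", 0.4)]) == "a"

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            select_classifier([])


class TestCrossValidation:
    def _separable(self, seed=0):
        groups, labels = gen_labelled_dataset(
            SyntheticDatasetSpec(
                n_classes=3, n_per_class=10, separation=8.0,
                group_dims={"DSSP": 10}, seed=seed,
            )
        )
        return groups["DSSP"], labels

    def test_strong_classifier_beats_random_guesser(self):
        from sklearn.dummy import DummyClassifier
        from sklearn.linear_model import LogisticRegression

        fm, labels = self._separable()
        roster = [
            ClassifierSpec("random", lambda s: DummyClassifier(
                strategy="uniform", random_state=s)),
            ClassifierSpec("logreg", lambda s: LogisticRegression(max_iter=500)),
        ]
        report = cross_validate_roster(fm, labels, roster, seed=0)
        assert report.selected == "logreg"
        accs = dict(report.entries)
        assert accs["logreg"] > accs["random"]

    def test_deterministic_given_seed(self):
        fm, labels = self._separable()
        r1 = cross_validate_roster(fm, labels, fast_roster(), seed=3)
        r2 = cross_validate_roster(fm, labels, fast_roster(), seed=3)
        assert r1.entries == r2.entries and r1.selected == r2.selected

    def test_single_class_rejected(self):
        fm, _ = self._separable()
        with pytest.raises(ValueError):
            cross_validate_roster(fm, ["x"] * fm.n_samples, fast_roster())

    def test_empty_roster_rejected(self):
        fm, labels = self._separable()
        with pytest.raises(ValueError):
            cross_validate_roster(fm, labels, [])

    def test_small_class_degrades_folds_with_warning(self):
        fm, labels = self._separable()
        labels = list(labels)
        # shrink one class to 3 members (below the default 5 folds)
        labels = ["fold1"] * 17 + ["fold2"] * 10 + ["fold3"] * 3
        with pytest.warns(UserWarning, match="reducing folds"):
            report = cross_validate_roster(fm, labels, fast_roster(), k_folds=5)
        assert report.selected in {s.name for s in fast_roster()}


class TestTrainPredict:
    def _dataset(self, seed=0, separation=8.0):
        spec = SyntheticDatasetSpec(
            n_classes=4, n_per_class=12, separation=separation,
            group_dims={"DSSP": 8, "AAsCPP": 12, "PSSM": 6, "FunD": 10},
            seed=seed,
        )
        return gen_labelled_dataset(spec)

    def test_four_group_training_produces_four_models(self):
        groups, labels = self._dataset()
        ens = train_ensemble(groups, labels, fast_roster(), seed=0)
        assert sorted(ens.groups_used) == sorted(groups)
        assert len(ens.cv_reports) == 4
        assert ens.class_labels == sorted(set(labels))

    def test_single_group_ensemble_is_valid(self):
        groups, labels = self._dataset()
        ens = train_ensemble({"PSSM": groups["PSSM"]}, labels, fast_roster(), seed=0)
        pred, proba = predict(ens, {"PSSM": groups["PSSM"]})
        assert len(pred) == groups["PSSM"].n_samples
        assert proba.shape == (groups["PSSM"].n_samples, 4)

    def test_same_seed_same_selections(self):
        groups, labels = self._dataset()
        e1 = train_ensemble(groups, labels, fast_roster(), seed=7)
        e2 = train_ensemble(groups, labels, fast_roster(), seed=7)
        assert {g: n for g, (n, _) in e1.per_group.items()} == {
            g: n for g, (n, _) in e2.per_group.items()
        }

    def test_sample_id_mismatch_names_group(self):
        groups, labels = self._dataset()
        bad = groups["PSSM"]
        bad.sample_ids = list(reversed(bad.sample_ids))
        with pytest.raises(ValueError, match="PSSM"):
            train_ensemble(groups, labels, fast_roster())

    def test_missing_group_at_prediction_refused(self):
        groups, labels = self._dataset()
        ens = train_ensemble(groups, labels, fast_roster(), seed=0)
        subset = {g: m for g, m in groups.items() if g != "FunD"}
        with pytest.raises(ValueError, match="FunD"):
            predict(ens, subset)
        # explicit opt-in averages over the groups present
        pred, proba = predict(ens, subset, allow_missing_groups=True)
        assert proba.shape[1] == len(ens.class_labels)

    def test_dimension_mismatch_refused(self):
        groups, labels = self._dataset()
        ens = train_ensemble(groups, labels, fast_roster(), seed=0)
        wrong = dict(groups)
        wrong["PSSM"] = _fm("PSSM", np.zeros((48, 3)),
                            sample_ids=groups["PSSM"].sample_ids)
        with pytest.raises(ValueError, match="PSSM"):
            predict(ens, wrong)


class TestProbabilityAveraging:
    def test_hand_computed_average(self):
        p = {
            "g1": [[0.6, 0.3, 0.1]], "g2": [[0.2, 0.5, 0.3]],
            "g3": [[0.4, 0.4, 0.2]], "g4": [[0.5, 0.2, 0.3]],
        }
        ens = _mock_ensemble(p, classes=["c1", "c2", "c3"])
        fms = {g: _fm(g, [[0.0]]) for g in p}
        labels, proba = predict(ens, fms)
        assert proba[0] == pytest.approx([0.425, 0.35, 0.225])
        assert labels == ["c1"]

    def test_identical_distributions_are_fixed_point(self):
        row = [0.2, 0.7, 0.1]
        ens = _mock_ensemble({g: [row] for g in "abc"}, classes=["x", "y", "z"])
        _, proba = predict(ens, {g: _fm(g, [[0.0]]) for g in "abc"})
        assert proba[0] == pytest.approx(row)

    def test_rows_remain_distributions(self, rng):
        raw = rng.dirichlet(np.ones(5), size=(3, 8))  # 3 views, 8 samples
        ens = _mock_ensemble(
            {f"g{i}": raw[i] for i in range(3)}, classes=[f"c{j}" for j in range(5)]
        )
        _, proba = predict(ens, {f"g{i}": _fm(f"g{i}", np.zeros((8, 1))) for i in range(3)})
        assert proba.sum(axis=1) == pytest.approx(np.ones(8), abs=1e-9)

    def test_unanimous_argmax_is_preserved(self, rng):
        # every view puts its maximum on class 2
        per_group = {}
        for i in range(4):
            p = rng.dirichlet(np.ones(4), size=6)
            top = p.max(axis=1) + 0.01
            p[:, 2] = top
            p /= p.sum(axis=1, keepdims=True)
            per_group[f"g{i}"] = p
        ens = _mock_ensemble(per_group, classes=list("wxyz"))
        labels, _ = predict(ens, {g: _fm(g, np.zeros((6, 1))) for g in per_group})
        assert labels == ["y"] * 6

    def test_disjoint_error_fixture_ensemble_dominates(self):
        # 3 views, 3 classes, 12 samples; view i is confidently wrong on its
        # own third of the samples and moderately right elsewhere
        classes = ["c1", "c2", "c3"]
        y_true = [classes[i % 3] for i in range(12)]
        per_group = {}
        for v in range(3):
            rows = []
            for i, t in enumerate(y_true):
                ti = classes.index(t)
                wrong = (ti + 1) % 3
                row = np.full(3, 0.2)
                if v * 4 <= i < (v + 1) * 4:  # this view's error block
                    row[wrong] = 0.6
                    row[ti] = 0.3
                    row[3 - ti - wrong] = 0.1
                else:
                    row[ti] = 0.6
                    row[wrong] = 0.3
                    row[3 - ti - wrong] = 0.1
                rows.append(row)
            per_group[f"view{v}"] = np.array(rows)
        ens = _mock_ensemble(per_group, classes)
        fms = {g: _fm(g, np.zeros((12, 1))) for g in per_group}
        labels, _ = predict(ens, fms)
        ensemble_q = q_accuracy(y_true, labels, classes).Q

        single_qs = []
        for g in per_group:
            single = _mock_ensemble({g: per_group[g]}, classes)
            lab, _ = predict(single, {g: fms[g]})
            single_qs.append(q_accuracy(y_true, lab, classes).Q)
        assert ensemble_q >= max(single_qs)
        assert ensemble_q == 1.0 and max(single_qs) == pytest.approx(8 / 12)


class TestQAccuracy:
    def test_direct_count(self):
        y_true = ["a"] * 5 + ["b"] * 5
        y_pred = ["a"] * 4 + ["b"] + ["b"] * 3 + ["a"] * 2
        result = q_accuracy(y_true, y_pred)
        assert result.Q == pytest.approx(0.7)
        assert result.N == 10 and result.C == 7

    def test_perfect_prediction(self):
        y = ["a", "b", "c", "a"]
        result = q_accuracy(y, list(y))
        assert result.Q == 1.0
        assert np.all(result.per_class_accuracy == 1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            q_accuracy(["a"], ["a", "b"])
        with pytest.raises(ValueError):
            q_accuracy(["a", "b"], ["a", "z"], class_labels=["a", "b"])

    @given(st.integers(2, 27), st.integers(0, 10_000))
    @settings(max_examples=40)
    def test_matches_counting_oracle(self, k, seed):
        rng = np.random.default_rng(seed)
        classes = [f"f{i}" for i in range(k)]
        n = int(rng.integers(k, 200))
        y_true = [classes[i] for i in rng.integers(0, k, size=n)]
        y_pred = [classes[i] for i in rng.integers(0, k, size=n)]
        result = q_accuracy(y_true, y_pred, classes)
        n_o, c_o, N_o, C_o, q_o = oracles.q_counts(y_true, y_pred, classes)
        assert result.Q == q_o
        assert result.N == N_o and result.C == C_o
        assert list(result.n) == [n_o[c] for c in classes]
        assert list(result.c) == [c_o[c] for c in classes]
        # Eq identity: Q equals the per-class table recomputed
        assert result.Q == result.c.sum() / result.n.sum()


class TestPersistence:
    def test_round_trip_identical_predictions(self, tmp_path):
        spec = SyntheticDatasetSpec(
            n_classes=3, n_per_class=10, separation=4.0,
            group_dims={"DSSP": 6, "PSSM": 5}, seed=1,
        )
        groups, labels = gen_labelled_dataset(spec)
        ens = train_ensemble(groups, labels, fast_roster(), seed=1)
        save_ensemble(ens, tmp_path / "bundle")
        loaded = load_ensemble(tmp_path / "bundle")

        held_out, _ = gen_labelled_dataset(
            SyntheticDatasetSpec(
                n_classes=3, n_per_class=5, separation=4.0,
                group_dims={"DSSP": 6, "PSSM": 5}, seed=99,
            )
        )
        l1, p1 = predict(ens, held_out)
        l2, p2 = predict(loaded, held_out)
        assert l1 == l2
        assert np.array_equal(p1, p2)

    def test_missing_model_file_names_group(self, tmp_path):
        spec = SyntheticDatasetSpec(
            n_classes=2, n_per_class=6, separation=4.0,
            group_dims={"DSSP": 4}, seed=0,
        )
        groups, labels = gen_labelled_dataset(spec)
        ens = train_ensemble(groups, labels, fast_roster(), seed=0)
        save_ensemble(ens, tmp_path / "b")
        (tmp_path / "b" / "model_DSSP.joblib").unlink()
        with pytest.raises(FileNotFoundError, match="DSSP"):
            load_ensemble(tmp_path / "b")

    def test_missing_manifest_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_ensemble(tmp_path)


class TestRosterConfig:
    def test_config_driven_roster(self):
        roster = roster_from_config([
            {"name": "rf", "estimator": "RandomForestClassifier",
             "params": {"n_estimators": 10}},
            {"name": "nb", "estimator": "GaussianNB"},
        ])
        assert [s.name for s in roster] == ["rf", "nb"]
        est = roster[0].build(5)
        assert est.get_params()["n_estimators"] == 10
        assert est.get_params()["random_state"] == 5

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            roster_from_config([{"name": "x", "estimator": "NotAClassifier"}])
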