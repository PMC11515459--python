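"""The resampled random-forest protocol: search, evaluation, summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (ParameterGrid, StratifiedKFold,
                                     cross_val_score, train_test_split)

from bonepmi.rf_protocol import (RFConfig, hyperparameter_search,
                                 mean_importance, performance_summary,
                                 resampled_evaluation, shap_summary)

FAST = RFConfig(n_estimators=60, max_depth=10)


@pytest.fixture(scope="module")
def planted_records(tibia_late):
    from bonepmi.synthetic import PLANTED_BIOMARKERS
    table, meta = tibia_late
    return resampled_evaluation(table[PLANTED_BIOMARKERS],
                                meta["pmi_class"].to_numpy(),
                                FAST, n_iter=20, base_seed=5)


class TestHyperparameterSearch:
    grid = {"n_estimators": [15, 30], "max_depth": [2, 4],
            "min_samples_split": [2], "min_samples_leaf": [2],
            "max_features": ["sqrt"]}

    def test_single_configuration_returned_as_is(self, tibia_late):
        table, meta = tibia_late
        single = {k: v[:1] for k, v in self.grid.items()}
        cfg = hyperparameter_search(table, meta["pmi_class"], single,
                                    n_candidates=1, seed=0)
        assert cfg == RFConfig(15, 2, 2, 2, "sqrt")

    def test_result_lies_inside_grid(self, tibia_late):
        table, meta = tibia_late
        cfg = hyperparameter_search(table, meta["pmi_class"], self.grid,
                                    n_candidates=4, seed=1)
        assert cfg.n_estimators in self.grid["n_estimators"]
        assert cfg.max_depth in self.grid["max_depth"]

    def test_exhaustive_search_matches_brute_force_cv(self, tibia_late):
        table, meta = tibia_late
        y = meta["pmi_class"].to_numpy()
        cfg = hyperparameter_search(table, y, self.grid,
                                    n_candidates=4, seed=3)
        # independent brute force over the whole grid, same split protocol
        X = np.log10(1.0 + table.fillna(0.0).to_numpy())
        X_train, _, y_train, _ = train_test_split(
            X, y, train_size=0.6, stratify=y, random_state=3)
        scores = {}
        for params in ParameterGrid(self.grid):
            est = RandomForestClassifier(random_state=3, **params)
            scores[tuple(sorted(params.items()))] = cross_val_score(
                est, X_train, y_train, cv=StratifiedKFold(3),
                scoring="accuracy").mean()
        best_score = max(scores.values())
        chosen = tuple(sorted({
            "n_estimators": cfg.n_estimators, "max_depth": cfg.max_depth,
            "min_samples_split": cfg.min_samples_split,
            "min_samples_leaf": cfg.min_samples_leaf,
            "max_features": cfg.max_features}.items()))
        assert scores[chosen] == pytest.approx(best_score)

    def test_class_with_single_sample_rejected(self, tibia_late):
        table, _ = tibia_late
        labels = ["A"] + ["B"] * (len(table) - 1)
        with pytest.raises(ValueError, match="< 2 samples"):
            hyperparameter_search(table, labels, self.grid, 2, seed=0)


class TestResampledEvaluation:
    def test_deterministic_given_seeds(self, tibia_late):
        table, meta = tibia_late
        y = meta["pmi_class"].to_numpy()
        a = resampled_evaluation(table, y, FAST, n_iter=5, base_seed=2)
        b = resampled_evaluation(table, y, FAST, n_iter=5, base_seed=2)
        for ra, rb in zip(a, b):
            assert ra.accuracy == rb.accuracy and ra.f1 == rb.f1
            assert ra.test_ids == rb.test_ids
            pd.testing.assert_series_equal(ra.importance, rb.importance)
            for cls in ra.shap:
                pd.testing.assert_frame_equal(ra.shap[cls], rb.shap[cls])

    def test_record_invariants(self, planted_records, tibia_late):
        table, _ = tibia_late
        all_ids = set(table.index)
        for rec in planted_records:
            assert 0.0 <= rec.accuracy <= 1.0 and 0.0 <= rec.f1 <= 1.0
            assert set(rec.train_ids) | set(rec.test_ids) == all_ids
            assert not set(rec.train_ids) & set(rec.test_ids)
            assert rec.importance.sum() == pytest.approx(1.0, abs=1e-9)
            # TreeSHAP local accuracy against the forest's probabilities
            for cls, frame in rec.shap.items():
                total = frame.sum(axis=1) + rec.base_values[cls]
                np.testing.assert_allclose(total, rec.proba[cls], atol=1e-6)

    def test_every_sample_covered_in_train_and_test(self, planted_records):
        seen_train, seen_test = set(), set()
        for rec in planted_records:
            seen_train.update(rec.train_ids)
            seen_test.update(rec.test_ids)
        assert seen_train == seen_test

    def test_planted_biomarkers_classify_perfectly(self, planted_records):
        perf = performance_summary(planted_records)
        assert perf["mean_accuracy"] == 1.0
        assert perf["mean_f1"] == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        # Independent null studies: a single 10-sample dataset resampled
        # many times has a dataset-conditional accuracy that can sit far
        # from 0.5 (chance in-draw structure), so the binomial band is
        # only valid when predictions come from many independent draws.
        rng = np.random.default_rng(0)
        records = []
        for draw in range(40):
            table = pd.DataFrame(
                10 ** rng.normal(6, 0.25, size=(10, 8)),
                index=pd.Index([f"s{i}" for i in range(10)],
                               name="sample_id"),
                columns=[f"N{i}" for i in range(8)])
            y = np.array(["A"] * 5 + ["B"] * 5)
            rng.shuffle(y)
            records += resampled_evaluation(
                table, y, RFConfig(100, 15), n_iter=2, base_seed=draw,
                compute_shap=False, ensure_coverage=False)
        mean_acc = performance_summary(records)["mean_accuracy"]
        se = np.sqrt(0.25 / (2 * len(records)))   # 2 test samples / iteration
        assert abs(mean_acc - 0.5) <= 3 * se

    def test_invalid_arguments_rejected(self, tibia_late):
        table, meta = tibia_late
        with pytest.raises(ValueError, match="n_iter"):
            resampled_evaluation(table, meta["pmi_class"], FAST, n_iter=0)


def fabricate_record(i, importance, shap_by_class, labels):
    from bonepmi.rf_protocol import IterationRecord
    ids = list(next(iter(shap_by_class.values())).index)
    return IterationRecord(
        iteration=i, seed=i, train_ids=[], test_ids=ids, test_labels=labels,
        accuracy=1.0, f1=1.0,
        importance=pd.Series(importance) if importance else None,
        shap=shap_by_class, base_values={c: 0.5 for c in shap_by_class},
        proba=None)


class TestSummaries:
    def test_mean_importance_arithmetic(self):
        sh = {"A": pd.DataFrame({"x": [0.0]}, index=["s"])}
        recs = [fabricate_record(0, {"A": 0.6, "B": 0.4}, sh, ["A"]),
                fabricate_record(1, {"A": 0.2, "B": 0.8}, sh, ["A"])]
        mi = mean_importance(recs)
        assert mi["A"] == pytest.approx(0.4) and mi["B"] == pytest.approx(0.6)

    def test_mean_importance_random_matches_per_key_average(self):
        rng = np.random.default_rng(1)
        raw = rng.dirichlet(np.ones(4), size=6)
        sh = {"A": pd.DataFrame({"x": [0.0]}, index=["s"])}
        recs = [fabricate_record(i, dict(zip("wxyz", row)), sh, ["A"])
                for i, row in enumerate(raw)]
        np.testing.assert_allclose(mean_importance(recs).to_numpy(),
                                   raw.mean(axis=0))

    def test_mean_importance_inconsistent_sets_rejected(self):
        sh = {"A": pd.DataFrame({"x": [0.0]}, index=["s"])}
        recs = [fabricate_record(0, {"A": 1.0}, sh, ["A"]),
                fabricate_record(1, {"B": 1.0}, sh, ["A"])]
        with pytest.raises(ValueError, match="inconsistent"):
            mean_importance(recs)

    def test_shap_summary_single_value(self):
        sh = {"A": pd.DataFrame({"p": [0.3]}, index=["s1"]),
              "B": pd.DataFrame({"p": [-0.3]}, index=["s1"])}
        s = shap_summary([fabricate_record(0, None, sh, ["A"])], "A")
        assert s.loc["p", "median"] == s.loc["p", "min"] == s.loc["p", "max"] == 0.3

    def test_shap_summary_pools_order_statistics(self):
        frames = [{"A": pd.DataFrame({"p": [v]}, index=["s"])}
                  for v in (-1.0, 0.0, 2.0)]
        recs = [fabricate_record(i, None, f, ["A"]) for i, f in enumerate(frames)]
        s = shap_summary(recs, "A")
        assert (s.loc["p", "median"], s.loc["p", "min"], s.loc["p", "max"]) \
            == (0.0, -1.0, 2.0)

    def test_shap_summary_pools_only_matching_class_samples(self):
        sh = {"A": pd.DataFrame({"p": [0.5, -0.5]}, index=["sa", "sb"])}
        recs = [fabricate_record(0, None, sh, ["A", "B"])]
        s = shap_summary(recs, "A")       # only sample sa has true label A
        assert s.loc["p", "median"] == 0.5

    def test_shap_summary_unknown_class_rejected(self):
        sh = {"A": pd.DataFrame({"p": [0.1]}, index=["s"])}
        with pytest.raises(KeyError, match="C"):
            shap_summary([fabricate_record(0, None, sh, ["A"])], "C")
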