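"""Normalization, ensemble voting, classification metrics, RSD."""

import numpy as np
import pandas as pd
import pytest

from gliorad import (
    DataError,
    DomainError,
    SchemaError,
    evaluate_classification,
    repeated_split_eval,
    rsd,
    soft_vote_predict,
    train_ensemble,
    zscore_apply,
    zscore_fit,
)
from gliorad.survival_model import CLASS_LABELS, prediction_csv


def _table(X: np.ndarray, y=None, prefix="f") -> pd.DataFrame:
    df = pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(X.shape[1])])
    df.index = [f"s{i}" for i in range(len(df))]
    df.index.name = "subject_id"
    if y is not None:
        df["os_class"] = y
    return df


def _separable(n_per_class=20, seed=0):
    rng = np.random.default_rng(seed)
    rows, ys = [], []
    for k, cls in enumerate(CLASS_LABELS):
        rows.append(rng.normal(loc=8 * k, scale=0.5, size=(n_per_class, 3)))
        ys += [cls] * n_per_class
    return _table(np.vstack(rows), ys)


class TestZScore:
    def test_train_stats_applied_to_test_value(self):
        train = _table(np.array([[0.0], [2.0]]))
        stats = zscore_fit(train)
        test = _table(np.array([[3.0]]))
        assert zscore_apply(test, stats)["f0"].iloc[0] == pytest.approx(2.0)

    def test_constant_feature_maps_to_zero(self):
        train = _table(np.array([[5.0, 1.0], [5.0, 3.0]]))
        stats = zscore_fit(train)
        z = zscore_apply(train, stats)
        assert (z["f0"] == 0.0).all()

    def test_train_table_centered_after_transform(self, rng):
        train = _table(rng.normal(3, 2, size=(30, 4)))
        z = zscore_apply(train, zscore_fit(train))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_schema_mismatch_rejected(self, rng):
        stats = zscore_fit(_table(rng.normal(size=(5, 2))))
        with pytest.raises(SchemaError):
            zscore_apply(_table(rng.normal(size=(5, 3))), stats)


class TestEnsemble:
    def test_fixed_seed_reproducible(self):
        train = _separable()
        a = train_ensemble(train, n_members=3, rf_params={"n_estimators": 20}, master_seed=5)
        b = train_ensemble(train, n_members=3, rf_params={"n_estimators": 20}, master_seed=5)
        probs_a, _ = soft_vote_predict(a, train.drop(columns="os_class"))
        probs_b, _ = soft_vote_predict(b, train.drop(columns="os_class"))
        pd.testing.assert_frame_equal(probs_a, probs_b)

    def test_separable_data_high_training_accuracy(self):
        train = _separable()
        model = train_ensemble(train, n_members=2, rf_params={"n_estimators": 50}, master_seed=0)
        _, hard = soft_vote_predict(model, train.drop(columns="os_class"))
        acc = (hard == train["os_class"]).mean()
        assert acc > 0.95

    def test_single_member_matches_one_forest(self):
        train = _separable(n_per_class=8)
        model = train_ensemble(train, n_members=1, rf_params={"n_estimators": 20}, master_seed=3)
        probs, _ = soft_vote_predict(model, train.drop(columns="os_class"))
        solo = model.members[0].predict_proba(train.drop(columns="os_class").to_numpy())
        col = {c: i for i, c in enumerate(model.members[0].classes_)}
        for k, cls in enumerate(CLASS_LABELS):
            np.testing.assert_allclose(probs[cls].to_numpy(), solo[:, col[cls]])

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(DataError):
            train_ensemble(_table(X, ["short"] * 10), n_members=1)


class TestSoftVote:
    def test_probability_rows_sum_to_one_and_convexity(self):
        train = _separable(n_per_class=10, seed=2)
        model = train_ensemble(train, n_members=4, rf_params={"n_estimators": 10}, master_seed=1)
        X = train.drop(columns="os_class")
        probs, _ = soft_vote_predict(model, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        order = [list(model.members[0].classes_).index(c) for c in CLASS_LABELS]
        member = np.stack(
            [m.predict_proba(X.to_numpy())[:, order] for m in model.members]
        )
        np.testing.assert_allclose(probs.to_numpy(), member.mean(axis=0), atol=1e-12)
        assert (probs.to_numpy() >= member.min(axis=0) - 1e-12).all()
        assert (probs.to_numpy() <= member.max(axis=0) + 1e-12).all()

    def test_argmax_tie_goes_to_earlier_class(self):
        probs = pd.DataFrame(
            [[0.5, 0.5, 0.0], [0.2, 0.4, 0.4]], columns=list(CLASS_LABELS)
        )
        hard = probs.idxmax(axis=1)
        assert list(hard) == ["short", "medium"]


class TestEvaluate:
    def test_perfect_ranking(self):
        probs = pd.DataFrame(
            [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]],
            columns=list(CLASS_LABELS),
            index=["a", "b", "c"],
        )
        truth = pd.Series(["short", "medium", "long"], index=["a", "b", "c"])
        rep = evaluate_classification(probs, truth)
        assert all(v == 1.0 for v in rep.per_class_auc.values())
        assert rep.weighted_auc == 1.0 and rep.accuracy_pct == 100.0

    def test_auc_matches_concordance_oracle(self, rng):
        # 6-subject worked set: per-class AUC equals the Mann-Whitney
        # pairwise-concordance count
        probs = pd.DataFrame(
            rng.uniform(size=(6, 3)), columns=list(CLASS_LABELS),
            index=[f"s{i}" for i in range(6)],
        )
        probs = probs.div(probs.sum(axis=1), axis=0)
        truth = pd.Series(
            ["short", "short", "medium", "long", "long", "medium"], index=probs.index
        )
        rep = evaluate_classification(probs, truth)
        for cls in CLASS_LABELS:
            pos = probs.loc[truth == cls, cls].to_numpy()
            neg = probs.loc[truth != cls, cls].to_numpy()
            conc = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
            assert rep.per_class_auc[cls] == pytest.approx(conc)

    def test_random_probabilities_near_half(self):
        rng = np.random.default_rng(99)
        n = 3000
        probs = pd.DataFrame(rng.uniform(size=(n, 3)), columns=list(CLASS_LABELS))
        probs = probs.div(probs.sum(axis=1), axis=0)
        truth = pd.Series(rng.choice(CLASS_LABELS, size=n), index=probs.index)
        rep = evaluate_classification(probs, truth)
        assert 0.47 <= rep.weighted_auc <= 0.53

    def test_absent_class_flagged_and_excluded(self):
        probs = pd.DataFrame(
            [[0.6, 0.2, 0.2], [0.2, 0.2, 0.6]], columns=list(CLASS_LABELS), index=["a", "b"]
        )
        truth = pd.Series(["short", "long"], index=["a", "b"])
        rep = evaluate_classification(probs, truth)
        assert rep.per_class_auc["medium"] is None
        assert rep.weighted_auc == 1.0


class TestRepeatedSplits:
    def test_splits_preserve_class_proportions(self):
        train = _separable(n_per_class=10, seed=4)
        rep = repeated_split_eval(
            train, n_repeats=5, n_members=1, rf_params={"n_estimators": 10}, master_seed=0
        )
        assert rep.n_repeats == 5
        # sklearn's stratified splitter guarantees per-class deviation <= 1

    def test_reproducible_for_fixed_seed(self):
        train = _separable(n_per_class=6, seed=8)
        kw = dict(n_repeats=3, n_members=1, rf_params={"n_estimators": 10}, master_seed=11)
        a = repeated_split_eval(train, **kw)
        b = repeated_split_eval(train, **kw)
        assert a.mean_weighted_auc == b.mean_weighted_auc
        assert a.sd_weighted_auc == b.sd_weighted_auc

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(1).normal(size=(7, 2))
        y = ["short"] * 3 + ["medium"] * 3 + ["long"]
        with pytest.raises(DataError):
            repeated_split_eval(_table(X, y), n_repeats=2)


class TestRSD:
    def test_identical_values_zero(self):
        assert rsd([0.7, 0.7, 0.7]) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_arithmetic(self):
        assert rsd([1.0, 3.0]) == pytest.approx(50.0)

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.5, 0.9, size=6)
        assert rsd(x) == pytest.approx(rsd(10 * x))
        assert rsd(x) == pytest.approx(rsd(0.01 * x))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            rsd([0.7])
        with pytest.raises(DomainError):
            rsd([0.5, -0.5])


def test_prediction_csv_day_proxies(tmp_path):
    hard = pd.Series(["short", "long"], index=["a", "b"])
    df = prediction_csv(hard, tmp_path / "pred.csv")
    assert list(df["survival_days_proxy"]) == [150.0, 796.0]
    assert (tmp_path / "pred.csv").exists()
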