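"""ML pipeline: normalization, nested CV, ensemble, FDR threshold,
prediction rules, permutation importance."""

import numpy as np
import pandas as pd
import pytest

from xprio.ml import (ClassifierSpec, DisorderGeneEnsemble, MinMaxImputeScaler,
                      build_ensemble, default_registry, dummy_registry,
                      ensemble_probabilities, estimate_fdr_threshold,
                      final_prediction, nested_cv, normalize_features,
                      permutation_importance)
from xprio.synth import SynthConfig, generate_feature_table


class TestScaler:
    def test_affine_map(self):
        ref = pd.DataFrame({"f": [2.0, 6.0]})
        s = MinMaxImputeScaler().fit(ref)
        out = s.transform(pd.DataFrame({"f": [4.0]}))
        assert out.loc[0, "f"] == pytest.approx(0.5)

    def test_clipping_outside_reference_range(self):
        s = MinMaxImputeScaler().fit(pd.DataFrame({"f": [2.0, 6.0]}))
        out = s.transform(pd.DataFrame({"f": [0.0, 10.0]}))
        assert out["f"].tolist() == [0.0, 1.0]

    def test_constant_feature_maps_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            s = MinMaxImputeScaler().fit(pd.DataFrame({"f": [3.0, 3.0]}))
        out = s.transform(pd.DataFrame({"f": [3.0, 99.0]}))
        assert out["f"].tolist() == [0.5, 0.5]

    def test_median_imputation_recorded(self):
        ref = pd.DataFrame({"f": [0.0, 10.0, 20.0]})
        s = MinMaxImputeScaler().fit(ref)
        X = pd.DataFrame({"f": [np.nan, 0.0]})
        assert s.imputed_mask(X)["f"].tolist() == [True, False]
        assert s.transform(X)["f"].iloc[0] == pytest.approx(0.5)  # median 10 of 0..20

    def test_normalize_features_uses_reference_only(self):
        table = pd.DataFrame({"f": [0.0, 5.0, 10.0, 100.0]},
                             index=list("abcd"))
        out, _ = normalize_features(table, ["a", "c"])   # ref range 0..10
        assert out.loc["b", "f"] == pytest.approx(0.5)
        assert out.loc["d", "f"] == 1.0                  # clipped


def _separable(n=300, seed=0, n_features=6):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, n_features)) + 4.0 * y[:, None]
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)]), y


class TestNestedCV:
    def test_deterministic_given_seed(self):
        X, y = _separable(120, seed=1)
        reg = [default_registry(light=True)[2]]          # linear max-margin
        a = nested_cv(X, y, reg, outer_folds=4, inner_folds=3, seed=5)
        b = nested_cv(X, y, reg, outer_folds=4, inner_folds=3, seed=5)
        assert a[0].fold_mccs == b[0].fold_mccs
        assert a[0].best_params == b[0].best_params

    def test_separable_data_reaches_high_mcc(self):
        X, y = _separable(300, seed=2)
        reg = [default_registry(light=True)[2]]
        res = nested_cv(X, y, reg, outer_folds=5, inner_folds=3, seed=0)
        assert res[0].mcc_mean > 0.95

    def test_single_class_rejected(self):
        X, _ = _separable(50)
        with pytest.raises(ValueError, match="both classes"):
            nested_cv(X, np.zeros(50, dtype=int), dummy_registry())

    def test_too_many_outer_folds_rejected(self):
        X, y = _separable(30)
        with pytest.raises(ValueError, match="outer_folds"):
            nested_cv(X, y, dummy_registry(), outer_folds=25)


class _StubModel:
    """Pretends to be a fitted probabilistic classifier."""

    classes_ = [0, 1]

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        p = np.full(len(X), self.p)
        return np.column_stack([1 - p, p])


class TestEnsembleProbabilities:
    def test_constant_members(self):
        fitted = [(f"m{i}", _StubModel(0.6)) for i in range(5)]
        df = ensemble_probabilities(fitted, pd.DataFrame(np.zeros((3, 2))))
        assert df["mean_probability"].tolist() == pytest.approx([0.6] * 3)
        assert df["all_above_half"].all()

    def test_one_low_member_blocks_conjunction(self):
        probs = [0.9, 0.9, 0.9, 0.9, 0.4]
        fitted = [(f"m{i}", _StubModel(p)) for i, p in enumerate(probs)]
        df = ensemble_probabilities(fitted, pd.DataFrame(np.zeros((1, 2))))
        assert df["mean_probability"].iloc[0] == pytest.approx(0.8)
        assert not df["all_above_half"].iloc[0]


class TestFdrThreshold:
    def test_hand_enumeration(self):
        res = estimate_fdr_threshold([0.95, 0.9, 0.8, 0.7], [0.85, 0.3], d=0.25)
        assert res.ok and res.threshold == pytest.approx(0.9)

    def test_perfect_separation_returns_min_positive_score(self):
        res = estimate_fdr_threshold([0.9, 0.8, 0.7], [0.4, 0.2], d=0.5)
        assert res.threshold == pytest.approx(0.7)
        assert res.realized_fdr == 0.0

    def test_top_scored_negative_fails(self):
        res = estimate_fdr_threshold([0.5, 0.4], [0.99], d=0.1)
        assert not res.ok and res.threshold is None

    def test_decreasing_d_never_enlarges_prediction_set(self, rng):
        b = rng.beta(6, 2, 200)
        d_neg = rng.beta(2, 4, 300)
        sets = []
        for d in (0.2, 0.1, 0.05, 0.01):
            res = estimate_fdr_threshold(b, d_neg, d=d)
            thr = res.threshold if res.ok else np.inf
            sets.append((b >= thr).sum() + (d_neg >= thr).sum())
        assert all(a >= b_ for a, b_ in zip(sets, sets[1:]))

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            estimate_fdr_threshold([], [0.5])


class TestFinalPrediction:
    def _frame(self, probs):
        members = {f"m{i}": [p] for i, p in enumerate(probs)}
        df = pd.DataFrame(members)
        df["mean_probability"] = df.mean(axis=1)
        df["all_above_half"] = (df[[f"m{i}" for i in range(len(probs))]] > 0.5).all(axis=1)
        return df

    def test_both_rules_agree_on_clear_positive(self):
        df = self._frame([0.95] * 5)
        assert final_prediction(df, 0.82, "conjunction").iloc[0]
        assert final_prediction(df, 0.82, "disjunction").iloc[0]

    def test_low_member_high_mean_disjunction_only(self):
        df = self._frame([0.95, 0.95, 0.95, 0.95, 0.45])
        assert not final_prediction(df, 0.82, "conjunction").iloc[0]
        assert final_prediction(df, 0.82, "disjunction").iloc[0]

    def test_low_mean_all_above_half_disjunction_only(self):
        df = self._frame([0.81] * 5)
        assert not final_prediction(df, 0.82, "conjunction").iloc[0]
        assert final_prediction(df, 0.82, "disjunction").iloc[0]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            final_prediction(self._frame([0.9] * 5), 0.8, "xor")


class TestBuildEnsemble:
    def test_unusable_family_promoted_past(self):
        from sklearn.base import BaseEstimator

        class NoScore(BaseEstimator):
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        X, y = _separable(80, seed=3)
        registry = [ClassifierSpec("noscore", lambda rs: NoScore()),
                    *default_registry(light=True)]
        from xprio.ml import CVResult
        cv = [CVResult("noscore", [], 0.99, 0.0, {})] + [
            CVResult(s.name, [], 0.5, 0.1, {k: v[0] for k, v in s.param_grid.items()})
            for s in default_registry(light=True)]
        with pytest.warns(UserWarning, match="noscore"):
            fitted = build_ensemble(cv, registry, X, y, top_k=5, seed=0)
        assert "noscore" not in [n for n, _ in fitted]
        assert len(fitted) == 5


class TestPermutationImportance:
    def test_planted_signal_feature_ranks_first(self):
        rng = np.random.default_rng(4)
        n = 400
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"signal": y + rng.normal(0, 0.1, n),
                          "noise1": rng.normal(size=n),
                          "noise2": rng.normal(size=n)})
        from sklearn.linear_model import LogisticRegression
        model = LogisticRegression().fit(X, y)
        imp = permutation_importance([("lr", model)], X, y, n_repeats=3, seed=0)
        assert imp.idxmax() == "signal"
        assert imp["signal"] > 0.3

    def test_constant_feature_importance_near_zero(self):
        rng = np.random.default_rng(5)
        n = 300
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"signal": y + rng.normal(0, 0.2, n),
                          "flat": np.ones(n)})
        from sklearn.linear_model import LogisticRegression
        model = LogisticRegression().fit(X, y)
        imp = permutation_importance([("lr", model)], X, y, n_repeats=3, seed=1)
        assert abs(imp["flat"]) < 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 200)
        X = pd.DataFrame({"a": y + rng.normal(0, 0.5, 200),
                          "b": rng.normal(size=200)})
        from sklearn.linear_model import LogisticRegression
        model = LogisticRegression().fit(X, y)
        a = permutation_importance([("lr", model)], X, y, n_repeats=4, seed=9)
        b = permutation_importance([("lr", model)], X, y, n_repeats=4, seed=9)
        assert a.equals(b)


def _training_frame(n=900, seed=0):
    cfg = SynthConfig(
        n_genes=n, seed=seed,
        class_proportions={"confirmed": 0.4, "PMT": 0.0, "no_disorder": 0.6},
        brain_fraction=1.0,
        lof_tolerant_fraction_by_class={"confirmed": 0.0, "PMT": 0.0,
                                        "no_disorder": 1.0})
    table, labels = generate_feature_table(cfg)
    train = labels["subgroup"].isin(["Cbi", "NDt"])
    return table.values[train], (labels.loc[train, "subgroup"] == "Cbi").astype(int)


@pytest.fixture(scope="module")
def fitted():
    X, y = _training_frame()
    model = DisorderGeneEnsemble(registry=default_registry(light=True),
                                 select=False, random_state=0)
    return model.fit(X, y), X, y


class TestDisorderGeneEnsemble:

    def test_five_members_and_threshold(self, fitted):
        model, X, y = fitted
        assert len(model.estimators_) == 5
        assert model.fdr_.ok
        assert 0 < model.fdr_.threshold <= 1

    def test_planted_separation_recovered(self, fitted):
        model, X, y = fitted
        preds = model.predict(X)
        sens = preds[y.to_numpy() == 1].mean()
        assert sens > 0.8

    def test_prediction_frame_contract(self, fitted):
        model, X, y = fitted
        frame = model.prediction_frame(X)
        member_cols = [n for n, _ in model.estimators_]
        assert frame["mean_probability"].equals(
            frame[member_cols].mean(axis=1))
        # predicted implies mean above the FDR threshold (conjunction rule)
        assert (frame.loc[frame["predicted"], "mean_probability"]
                > model.fdr_.threshold).all()

    def test_refit_determinism(self):
        X, y = _training_frame(400, seed=2)
        kw = dict(registry=default_registry(light=True), select=False,
                  random_state=3)
        p1 = DisorderGeneEnsemble(**kw).fit(X, y).prediction_frame(X)
        p2 = DisorderGeneEnsemble(**kw).fit(X, y).prediction_frame(X)
        pd.testing.assert_frame_equal(p1, p2)
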