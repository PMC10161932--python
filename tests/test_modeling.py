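"""Entry-holdout splitting, correlation filter, RF protocol, importance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from peafuse.errors import DataError, SplitError
from peafuse.modeling import (
    SplitSpec,
    correlate_with_yield,
    correlation_filter,
    evaluate,
    fit_rf,
    holdout_by_entry,
    holdout_by_plot,
    oob_permutation_importance,
    run_experiment,
    tuning_grid,
)


def _table(n_entries=10, n_reps=3, n_features=3, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    entries = np.repeat([f"E{i:03d}" for i in range(n_entries)], n_reps)
    y = 2000 + rng.normal(0, 400, size=n_entries).repeat(n_reps) + rng.normal(0, 100, len(entries))
    X = rng.normal(size=(len(entries), n_features))
    if signal:
        X[:, 0] = (y - y.mean()) / y.std() + rng.normal(0, 0.1, len(entries))
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    df["entry_id"] = entries
    df["replicate"] = np.tile(np.arange(1, n_reps + 1), n_entries)
    df["yield_kg_ha"] = y
    df.index = pd.Index([f"P{i:04d}" for i in range(len(df))], name="plot_id")
    return df


class TestCorrelationScreen:
    def test_feature_equal_to_yield(self):
        df = _table()
        df["f0"] = df["yield_kg_ha"]
        out = correlate_with_yield(df)
        assert out.loc["f0", "r"] == pytest.approx(1.0)

    def test_negated_feature(self):
        df = _table()
        df["f1"] = -df["yield_kg_ha"] + 5.0
        out = correlate_with_yield(df)
        assert out.loc["f1", "r"] == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        df = _table(seed=3)
        out = correlate_with_yield(df)
        x = df["f2"].to_numpy()
        y = df["yield_kg_ha"].to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        n = len(x)
        t = r * math.sqrt((n - 2) / (1 - r**2))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), n - 2)
        assert out.loc["f2", "r"] == pytest.approx(r, rel=1e-10)
        assert out.loc["f2", "p"] == pytest.approx(p, rel=1e-8)

    def test_zero_variance_feature_reported_missing(self):
        df = _table()
        df["f1"] = 7.0
        out = correlate_with_yield(df)
        assert np.isnan(out.loc["f1", "r"])


class TestHoldout:
    def test_entry_arithmetic_10x3(self):
        df = _table(n_entries=10, n_reps=3)
        tr, te = holdout_by_entry(df, SplitSpec(seed=0))
        assert len(tr) == 24 and len(te) == 6

    def test_no_entry_on_both_sides_over_seeds(self):
        df = _table(n_entries=12, n_reps=3)
        for seed in range(100):
            tr, te = holdout_by_entry(df, SplitSpec(seed=seed))
            assert not (set(df.loc[tr, "entry_id"]) & set(df.loc[te, "entry_id"]))

    def test_site1_like_training_size(self):
        from peafuse.simulate import simulate_site

        plots = simulate_site("site1", seed=1)
        df = plots.to_dataframe()
        df["f0"] = 1.0
        sizes = []
        for seed in range(10):
            tr, _ = holdout_by_entry(df, SplitSpec(seed=seed))
            sizes.append(len(tr))
        assert 155 <= np.mean(sizes) <= 172  # ~164 of 203 plots

    def test_single_entry_rejected(self):
        df = _table(n_entries=1, n_reps=3)
        with pytest.raises(SplitError):
            holdout_by_entry(df, SplitSpec(seed=0))

    def test_plot_holdout_sizes(self):
        df = _table(n_entries=10, n_reps=3)
        tr, te = holdout_by_plot(df, SplitSpec(mode="plot", seed=0))
        assert len(tr) == 24 and len(te) == 6
        assert not (set(tr) & set(te))


class TestCorrelationFilter:
    def test_duplicate_column_drops_exactly_one(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X["b"] = X["a"]
        X["c"] = rng.normal(size=50)
        kept = correlation_filter(X, 0.99)
        assert "c" in kept and len(kept) == 2
        assert ("a" in kept) ^ ("b" in kept)

    def test_orthogonal_features_all_retained(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {f"s{k}": np.sin(2 * np.pi * k * t / n) for k in range(1, 5)}
        )
        assert correlation_filter(X, 0.99) == list(X.columns)

    def test_brute_force_minimal_removal_oracle(self, rng):
        # A, B, C pairwise-correlated beyond threshold; D, E independent
        base = rng.normal(size=400)
        X = pd.DataFrame(
            {
                "A": base,
                "B": base + rng.normal(0, 0.01, 400),
                "C": base + rng.normal(0, 0.01, 400),
                "D": rng.normal(size=400),
                "E": rng.normal(size=400),
            }
        )
        corr = X.corr().abs()
        assert (corr.loc[["A", "B", "C"], ["A", "B", "C"]] >= 0.99).to_numpy().all()
        kept = correlation_filter(X, 0.99)
        # exhaustive oracle: the largest subset with no pair above threshold
        best = 0
        for r in range(5, 0, -1):
            for combo in itertools.combinations(X.columns, r):
                sub = corr.loc[list(combo), list(combo)].to_numpy()
                np.fill_diagonal(sub, 0)
                if sub.max() < 0.99:
                    best = r
                    break
            if best:
                break
        assert len(kept) == best == 3

    def test_idempotent(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 6)), columns=list("abcdef"))
        X["g"] = X["a"] * 1.0001 + 1e-6
        kept = correlation_filter(X, 0.99)
        assert correlation_filter(X[kept], 0.99) == kept


class TestFitEvaluate:
    def test_grid_is_five_values_in_range(self):
        assert tuning_grid(9) == [1, 3, 5, 7, 9]
        assert tuning_grid(1) == [1]
        assert tuning_grid(2) == [1, 2]

    def test_single_feature_forces_mtry_one(self):
        df = _table(n_features=1)
        model, mtry, _ = fit_rf(df[["f0"]], df["yield_kg_ha"], seed=0, cv_repeats=1)
        assert mtry == 1

    def test_perfect_predictions(self):
        df = _table()

        class Identity:
            def predict(self, X):
                return X[:, 0]

        X = pd.DataFrame({"x": df["yield_kg_ha"]})
        r2, rmse = evaluate(Identity(), X, df["yield_kg_ha"])
        assert r2 == pytest.approx(1.0) and rmse == pytest.approx(0.0)

    def test_shifted_predictions(self):
        df = _table()

        class Shift:
            def predict(self, X):
                return X[:, 0] + 100.0

        X = pd.DataFrame({"x": df["yield_kg_ha"]})
        r2, rmse = evaluate(Shift(), X, df["yield_kg_ha"])
        assert r2 == pytest.approx(1.0) and rmse == pytest.approx(100.0)

    def test_closed_form_oracle(self, rng):
        obs = rng.normal(size=30)
        pred = 0.5 * obs + rng.normal(0, 0.3, 30)

        class Fixed:
            def predict(self, X):
                return pred

        r2, rmse = evaluate(Fixed(), pd.DataFrame({"x": obs}), pd.Series(obs))
        assert r2 == pytest.approx(np.corrcoef(pred, obs)[0, 1] ** 2, rel=1e-10)
        assert rmse == pytest.approx(np.sqrt(np.mean((pred - obs) ** 2)), rel=1e-10)

    def test_ss_variant_differs_for_biased_predictions(self):
        class Shift:
            def predict(self, X):
                return X[:, 0] + 100.0

        obs = pd.Series(np.arange(20, dtype=float))
        X = pd.DataFrame({"x": obs})
        r2_ss, _ = evaluate(Shift(), X, obs, r2_kind="ss")
        assert r2_ss < 1.0

    def test_noise_target_near_zero_r2(self):
        # null oracle: with no signal, held-out squared correlation stays small
        r2s = []
        for seed in range(6):
            df = _table(n_entries=40, n_reps=5, n_features=4, seed=seed, signal=False)
            tr, te = holdout_by_entry(df, SplitSpec(seed=seed))
            feats = [f"f{i}" for i in range(4)]
            model, _, _ = fit_rf(
                df.loc[tr, feats], df.loc[tr, "yield_kg_ha"], seed=seed,
                cv_repeats=1, n_estimators=200,
            )
            r2, _ = evaluate(model, df.loc[te, feats], df.loc[te, "yield_kg_ha"])
            r2s.append(r2)
        assert np.median(r2s) < 0.1

    def test_strong_signal_recovered(self):
        df = _table(n_entries=40, n_reps=5, n_features=4, seed=1, signal=True)
        tr, te = holdout_by_entry(df, SplitSpec(seed=1))
        feats = [f"f{i}" for i in range(4)]
        model, _, _ = fit_rf(
            df.loc[tr, feats], df.loc[tr, "yield_kg_ha"], seed=1, cv_repeats=2
        )
        r2, _ = evaluate(model, df.loc[te, feats], df.loc[te, "yield_kg_ha"])
        assert r2 > 0.8

    def test_all_missing_feature_rejected(self):
        df = _table()
        df["f1"] = np.nan
        with pytest.raises(DataError):
            fit_rf(df[["f0", "f1"]], df["yield_kg_ha"], seed=0, cv_repeats=1)


class TestPermutationImportance:
    def _fitted(self, df, feats, seed=0):
        model, _, _ = fit_rf(
            df[feats], df["yield_kg_ha"], seed=seed, cv_repeats=1, n_estimators=300
        )
        return model

    def test_constant_column_exactly_zero(self):
        df = _table(n_features=3, seed=5)
        df["f2"] = 3.3
        feats = ["f0", "f1", "f2"]
        model = self._fitted(df, feats)
        imp = oob_permutation_importance(model, df[feats], df["yield_kg_ha"], seed=0)
        assert imp["f2"] == 0.0

    def test_informative_feature_dominates(self):
        df = _table(n_entries=40, n_reps=5, n_features=5, seed=2, signal=True)
        feats = [f"f{i}" for i in range(5)]
        model = self._fitted(df, feats, seed=2)
        imp = oob_permutation_importance(model, df[feats], df["yield_kg_ha"], seed=2)
        assert imp.idxmax() == "f0"
        assert imp["f0"] > 2 * imp.drop("f0").max()

    def test_independent_feature_near_zero(self):
        vals = []
        for seed in range(5):
            df = _table(n_entries=50, n_reps=4, n_features=3, seed=seed, signal=True)
            feats = ["f0", "f1", "f2"]
            model = self._fitted(df, feats, seed=seed)
            imp = oob_permutation_importance(model, df[feats], df["yield_kg_ha"], seed=seed)
            vals.append(abs(imp["f1"]))
        assert np.median(vals) < 5.0


class TestRunExperiment:
    def test_single_run_sd_zero(self):
        df = _table()
        ens = run_experiment(df, n_runs=1, base_seed=0, cv_repeats=1)
        agg = ens.aggregate()
        assert agg["r2_test_sd"] == 0.0

    def test_same_seed_identical_runs(self):
        df = _table()
        a = run_experiment(df, n_runs=1, base_seed=4, cv_repeats=1).runs[0]
        b = run_experiment(df, n_runs=1, base_seed=4, cv_repeats=1).runs[0]
        assert a.r2_test == b.r2_test
        assert a.importance == b.importance
        assert a.retained_features == b.retained_features

    def test_aggregate_recomputable_from_runs(self):
        df = _table(n_entries=15)
        ens = run_experiment(df, n_runs=3, base_seed=0, cv_repeats=1)
        agg = ens.aggregate()
        vals = [r.r2_test for r in ens.runs]
        assert agg["r2_test_mean"] == pytest.approx(np.mean(vals))
        assert agg["r2_test_sd"] == pytest.approx(np.std(vals, ddof=1))

    def test_entry_disjointness_in_every_run(self):
        df = _table(n_entries=15)
        ens = run_experiment(df, n_runs=5, base_seed=0, cv_repeats=1)
        assert all(r.n_train + r.n_test == len(df) for r in ens.runs)
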