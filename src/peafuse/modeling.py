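"""Entry-holdout random-forest yield prediction protocol.

One *run* of the protocol: split plots by breeding entry (all replicates of
a held-out entry go to the test side), drop highly correlated features on
the training side (|r| ≥ 0.99, greedy), tune the number of variables per
split by repeated 3-fold cross-validation, refit a 500-tree forest, and
record train/test R²/RMSE plus out-of-bag permutation importance (%IncMSE).
An *ensemble* repeats this over several seeds and reports mean ± SD.

R² is the squared Pearson correlation between predictions and observations
(the caret convention); the 1 − SS_res/SS_tot variant is available behind a
flag. Features enter the models unscaled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .errors import DataError, SplitError

log = logging.getLogger(__name__)

META_COLUMNS = ("entry_id", "replicate", "yield_kg_ha")
YIELD_COLUMN = "yield_kg_ha"


@dataclass(frozen=True)
class SplitSpec:
    """Holdout configuration: by entry (default) or by plot, 80/20."""

    mode: str = "entry"
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("entry", "plot"):
            raise SplitError(f"unknown holdout mode {self.mode!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise SplitError("train_fraction must lie in (0, 1)")


@dataclass
class RunResult:
    seed: int
    retained_features: list[str]
    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float
    importance: dict[str, float]
    chosen_mtry: int
    n_train: int
    n_test: int


@dataclass
class Ensemble:
    runs: list[RunResult] = field(default_factory=list)

    def aggregate(self) -> dict[str, float]:
        """Mean ± SD per metric, recomputed from the stored runs."""
        out: dict[str, float] = {"n_runs": len(self.runs)}
        for metric in ("r2_train", "rmse_train", "r2_test", "rmse_test"):
            vals = np.array([getattr(r, metric) for r in self.runs], dtype=float)
            out[f"{metric}_mean"] = float(np.nanmean(vals))
            out[f"{metric}_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": [r.seed for r in self.runs],
                "n_features": [len(r.retained_features) for r in self.runs],
                "chosen_mtry": [r.chosen_mtry for r in self.runs],
                "r2_train": [r.r2_train for r in self.runs],
                "rmse_train": [r.rmse_train for r in self.runs],
                "r2_test": [r.r2_test for r in self.runs],
                "rmse_test": [r.rmse_test for r in self.runs],
            }
        )


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# Correlation screen
# ---------------------------------------------------------------------------

def correlate_with_yield(table: pd.DataFrame, yield_col: str = YIELD_COLUMN) -> pd.DataFrame:
    """Pairwise-complete Pearson r (and two-sided p) of each feature vs yield."""
    if yield_col not in table.columns:
        raise DataError(f"table has no {yield_col!r} column")
    rows = []
    y = table[yield_col].astype(float)
    for col in feature_columns(table):
        x = table[col].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            rows.append({"feature": col, "r": np.nan, "p": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"feature": col, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def holdout_by_entry(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.Index, pd.Index]:
    """Partition rows so no entry appears on both sides.

    ``ceil(train_fraction · E)`` entries train; every plot follows its entry.
    """
    entries = np.array(sorted(table["entry_id"].unique()))
    if entries.size < 2:
        raise SplitError("entry holdout needs at least two entries")
    rng = np.random.default_rng(spec.seed)
    n_train = math.ceil(spec.train_fraction * entries.size)
    if n_train >= entries.size:
        n_train = entries.size - 1
    chosen = set(rng.permutation(entries)[:n_train].tolist())
    is_train = table["entry_id"].isin(chosen)
    return table.index[is_train], table.index[~is_train]


def holdout_by_plot(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.Index, pd.Index]:
    """Plain row-level holdout, ignoring entry structure."""
    rng = np.random.default_rng(spec.seed)
    n = len(table)
    if n < 2:
        raise SplitError("need at least two plots")
    n_train = min(n - 1, math.ceil(spec.train_fraction * n))
    order = rng.permutation(n)
    return table.index[np.sort(order[:n_train])], table.index[np.sort(order[n_train:])]


def holdout(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.Index, pd.Index]:
    fn = holdout_by_entry if spec.mode == "entry" else holdout_by_plot
    return fn(table, spec)


# ---------------------------------------------------------------------------
# Correlation filter
# ---------------------------------------------------------------------------

def correlation_filter(features: pd.DataFrame, threshold: float = 0.99) -> list[str]:
    """Greedy elimination of highly correlated features.

    While any pair satisfies |r| ≥ threshold, take the worst-offending pair
    and drop the member with the larger mean absolute correlation to all
    remaining features (ties drop the later column). Survivors come back in
    original column order; the operation is idempotent.
    """
    if not 0.0 < threshold <= 1.0:
        raise DataError("threshold must lie in (0, 1]")
    cols = list(features.columns)
    if len(cols) < 2:
        return cols
    X = features.astype(float)
    corr = X.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)
    alive = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or np.nanmax(sub) < threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        mean_i = sub[i_loc].mean()
        mean_j = sub[j_loc].mean()
        if mean_i > mean_j:
            drop_loc = i_loc
        elif mean_j > mean_i:
            drop_loc = j_loc
        else:  # tie → later column order
            drop_loc = max(i_loc, j_loc, key=lambda loc: alive[loc])
        alive.pop(drop_loc)
    return [cols[i] for i in alive]


# ---------------------------------------------------------------------------
# Fitting and evaluation
# ---------------------------------------------------------------------------

def tuning_grid(n_features: int, size: int = 5) -> list[int]:
    """``size`` integers evenly spaced in [1, p], deduplicated."""
    if n_features < 1:
        raise DataError("need at least one feature")
    return sorted(set(np.linspace(1, n_features, size).round().astype(int).tolist()))


def fit_rf(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int,
    n_estimators: int = 500,
    cv_folds: int = 3,
    cv_repeats: int = 15,
    grid_size: int = 5,
    cv_n_estimators: int = 100,
) -> tuple[RandomForestRegressor, int, pd.DataFrame]:
    """Tune variables-per-split by repeated CV, then refit on all rows.

    The grid holds 5 integers evenly spaced in [1, p]; each candidate is
    scored by mean RMSE over ``cv_folds``-fold CV repeated ``cv_repeats``
    times (shared folds across candidates). The minimizing value wins, ties
    going to the smaller value; the final model uses ``n_estimators`` trees.
    CV models use ``cv_n_estimators`` trees — enough to rank five candidates
    while keeping a 10-run ensemble tractable on one CPU.
    """
    if len(X) < 10:
        raise DataError(f"need >= 10 training rows, got {len(X)}")
    if X.isna().all().any():
        bad = X.columns[X.isna().all()].tolist()
        raise DataError(f"features with all-missing values: {bad}")
    Xv = X.to_numpy(dtype=np.float64)
    yv = y.to_numpy(dtype=np.float64)
    grid = tuning_grid(X.shape[1], grid_size)
    if len(grid) == 1:
        best = grid[0]
        cv_table = pd.DataFrame({"mtry": grid, "cv_rmse": [np.nan]})
    else:
        rkf = RepeatedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
        folds = list(rkf.split(Xv))
        scores = []
        for mtry in grid:
            sq = 0.0
            cnt = 0
            for f_i, (tr, te) in enumerate(folds):
                model = RandomForestRegressor(
                    n_estimators=cv_n_estimators,
                    max_features=mtry,
                    random_state=seed + 7919 * f_i,
                    n_jobs=1,
                )
                model.fit(Xv[tr], yv[tr])
                resid = model.predict(Xv[te]) - yv[te]
                sq += float(np.mean(resid**2))
                cnt += 1
            scores.append(math.sqrt(sq / cnt))
        cv_table = pd.DataFrame({"mtry": grid, "cv_rmse": scores})
        best = int(cv_table.loc[cv_table["cv_rmse"].idxmin(), "mtry"])
    final = RandomForestRegressor(
        n_estimators=n_estimators, max_features=best, random_state=seed, n_jobs=1
    )
    final.fit(Xv, yv)
    return final, best, cv_table


def evaluate(
    model: RandomForestRegressor,
    X: pd.DataFrame,
    y: pd.Series,
    r2_kind: str = "pearson",
) -> tuple[float, float]:
    """R² and RMSE (kg/ha) on an evaluation set.

    ``r2_kind="pearson"`` (default): squared Pearson correlation of
    predictions vs observations. ``"ss"`` switches to 1 − SS_res/SS_tot.
    Constant predictions make the Pearson R² undefined (NaN); RMSE is
    always returned.
    """
    if len(X) == 0:
        raise DataError("empty evaluation set")
    pred = model.predict(X.to_numpy(dtype=np.float64))
    obs = y.to_numpy(dtype=np.float64)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if r2_kind == "ss":
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum((pred - obs) ** 2)) / ss_tot
    elif r2_kind == "pearson":
        if np.std(pred) == 0 or np.std(obs) == 0:
            r2 = float("nan")
        else:
            r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
    else:
        raise DataError(f"unknown r2_kind {r2_kind!r}")
    return r2, rmse


def oob_permutation_importance(
    model: RandomForestRegressor, X: pd.DataFrame, y: pd.Series, seed: int = 0
) -> pd.Series:
    """%IncMSE per feature from out-of-bag samples.

    Per tree: the baseline MSE on its OOB rows and the MSE after permuting
    one feature's OOB values; the per-tree percent increase
    ``100 · (MSE_perm − MSE_base)/MSE_base`` is averaged over trees.
    Permuting a constant column changes nothing, giving exactly 0.
    """
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=np.float64)
    yv = y.to_numpy(dtype=np.float64)
    n, p = Xv.shape
    totals = np.zeros(p)
    counts = np.zeros(p)
    for tree, samples in zip(model.estimators_, model.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[samples] = False
        idx = np.flatnonzero(oob)
        if idx.size < 2:
            continue
        Xo = Xv[idx]
        base = tree.predict(Xo)
        mse_base = float(np.mean((base - yv[idx]) ** 2))
        if mse_base == 0:
            continue
        for j in range(p):
            perm = rng.permutation(idx.size)
            col = Xo[:, j].copy()
            Xo[:, j] = col[perm]
            if np.array_equal(Xo[:, j], col):
                Xo[:, j] = col
                counts[j] += 1
                continue
            mse_perm = float(np.mean((tree.predict(Xo) - yv[idx]) ** 2))
            Xo[:, j] = col
            totals[j] += 100.0 * (mse_perm - mse_base) / mse_base
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        imp = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    return pd.Series(imp, index=X.columns, name="pct_inc_mse")


# ---------------------------------------------------------------------------
# Multi-run protocol
# ---------------------------------------------------------------------------

def run_experiment(
    table: pd.DataFrame,
    n_runs: int = 10,
    base_seed: int = 0,
    split_mode: str = "entry",
    train_fraction: float = 0.8,
    corr_threshold: float = 0.99,
    **fit_kwargs,
) -> Ensemble:
    """The full multi-run protocol on one feature table.

    ``table`` must carry the metadata columns (entry_id, replicate,
    yield_kg_ha) plus feature columns. Rows with missing features or yield
    are dropped with a warning. Run seeds are ``base_seed + i``.
    """
    feats = feature_columns(table)
    if not feats:
        raise DataError("feature table has no feature columns")
    usable = table.dropna(subset=list(feats) + [YIELD_COLUMN])
    dropped = len(table) - len(usable)
    if dropped:
        log.warning("dropped %d plots with missing features or yield", dropped)
    ensemble = Ensemble()
    for i in range(n_runs):
        seed = base_seed + i
        spec = SplitSpec(mode=split_mode, train_fraction=train_fraction, seed=seed)
        tr_idx, te_idx = holdout(usable, spec)
        train, test = usable.loc[tr_idx], usable.loc[te_idx]
        retained = correlation_filter(train[feats], threshold=corr_threshold)
        model, mtry, _ = fit_rf(train[retained], train[YIELD_COLUMN], seed=seed, **fit_kwargs)
        r2_tr, rmse_tr = evaluate(model, train[retained], train[YIELD_COLUMN])
        r2_te, rmse_te = evaluate(model, test[retained], test[YIELD_COLUMN])
        imp = oob_permutation_importance(model, train[retained], train[YIELD_COLUMN], seed=seed)
        ensemble.runs.append(
            RunResult(
                seed=seed,
                retained_features=retained,
                r2_train=r2_tr,
                rmse_train=rmse_tr,
                r2_test=r2_te,
                rmse_test=rmse_te,
                importance=imp.to_dict(),
                chosen_mtry=mtry,
                n_train=len(train),
                n_test=len(test),
            )
        )
    return ensemble
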