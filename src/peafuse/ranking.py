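"""Stability-aware feature importance: the adjusted rank.

Permutation importance from a multi-run ensemble is aggregated per feature
through three factor ranks:

* **R1** — rank of the minimum %IncMSE across runs (descending: a large
  worst-case importance ranks first);
* **R2** — rank of the coefficient of variation of %IncMSE across runs
  (ascending: stable importance ranks first);
* **R3** — rank of the selection frequency, i.e. in how many runs the
  feature survived the correlation filter (descending).

Ties receive average ranks. The adjusted rank is

    R_A = 1 − (R1 + R2 + R3) / (max R1 + max R2 + max R3)

with the maxima taken over eligible features (those selected in more than
one run — a single observation has no CV), and is reported normalized to
percent of the best feature: norm = 100 · R_A / max(R_A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError
from .modeling import Ensemble

log = logging.getLogger(__name__)


@dataclass
class ImportanceRecord:
    """Per-feature %IncMSE values from the runs where the feature survived."""

    feature: str
    values: list[float] = field(default_factory=list)

    @property
    def occurrence(self) -> int:
        return len(self.values)

    @property
    def eligible(self) -> bool:
        return self.occurrence > 1


def records_from_ensemble(ensemble: Ensemble) -> list[ImportanceRecord]:
    """Collect importance records across an ensemble's runs."""
    by_feature: dict[str, ImportanceRecord] = {}
    for run in ensemble.runs:
        for feat, val in run.importance.items():
            if not np.isfinite(val):
                continue
            by_feature.setdefault(feat, ImportanceRecord(feat)).values.append(float(val))
    return list(by_feature.values())


@dataclass
class FactorRanks:
    """Per-feature factor ranks plus the within-factor maxima."""

    table: pd.DataFrame  # index: feature; columns: min_incmse, cv_pct, occurrence, R1, R2, R3
    max_r1: float
    max_r2: float
    max_r3: float


def compute_factors(records: list[ImportanceRecord], n_runs: int) -> FactorRanks:
    """Rank eligible features on the three stability factors.

    Features with occurrence ≤ 1 are excluded (marked ineligible upstream).
    A feature whose mean %IncMSE is ≤ 0 carries no real importance signal;
    its CV is set to +inf so it takes the worst R2 ranks (logged).
    """
    eligible = [r for r in records if r.eligible]
    if not eligible:
        raise DataError("no feature was selected more than once; nothing to rank")
    if any(r.occurrence > n_runs for r in eligible):
        raise DataError("a feature occurs more often than the number of runs")
    feats = [r.feature for r in eligible]
    mins = np.array([min(r.values) for r in eligible])
    means = np.array([np.mean(r.values) for r in eligible])
    sds = np.array([np.std(r.values, ddof=1) for r in eligible])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sds / np.abs(means)
    nonpos = means <= 0
    if nonpos.any():
        log.info("features with mean %%IncMSE <= 0 ranked worst on CV: %s",
                 [f for f, m in zip(feats, nonpos) if m])
        cv[nonpos] = np.inf
    occ = np.array([r.occurrence for r in eligible], dtype=float)
    r1 = rankdata(-mins, method="average")
    r2 = rankdata(cv, method="average")
    r3 = rankdata(-occ, method="average")
    table = pd.DataFrame(
        {
            "min_incmse": mins,
            "cv_pct": cv,
            "occurrence": occ.astype(int),
            "R1": r1,
            "R2": r2,
            "R3": r3,
        },
        index=pd.Index(feats, name="feature"),
    )
    return FactorRanks(
        table=table, max_r1=float(r1.max()), max_r2=float(r2.max()), max_r3=float(r3.max())
    )


def adjusted_rank(factors: FactorRanks) -> pd.DataFrame:
    """Apply the adjusted-rank formula per eligible feature."""
    t = factors.table.copy()
    denom = factors.max_r1 + factors.max_r2 + factors.max_r3
    t["adjusted"] = 1.0 - (t["R1"] + t["R2"] + t["R3"]) / denom
    return t


def normalize_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Scale adjusted ranks so the best eligible feature scores exactly 100."""
    best = table["adjusted"].max()
    if not best > 0:
        raise DataError("max adjusted rank is 0: all features tied at the worst rank")
    out = table.copy()
    out["normalized_pct"] = 100.0 * out["adjusted"] / best
    return out


def rank_table(records: list[ImportanceRecord], n_runs: int) -> pd.DataFrame:
    """Full RankTable: eligible features ranked, ineligible ones kept with
    occurrence but blank ranks (mirroring a sparse importance grid)."""
    factors = compute_factors(records, n_runs)
    ranked = normalize_rank(adjusted_rank(factors))
    ineligible = [r for r in records if not r.eligible]
    if ineligible:
        extra = pd.DataFrame(
            {
                "min_incmse": [min(r.values) if r.values else np.nan for r in ineligible],
                "cv_pct": np.nan,
                "occurrence": [r.occurrence for r in ineligible],
                "R1": np.nan,
                "R2": np.nan,
                "R3": np.nan,
                "adjusted": np.nan,
                "normalized_pct": np.nan,
            },
            index=pd.Index([r.feature for r in ineligible], name="feature"),
        )
        ranked = pd.concat([ranked, extra])
    return ranked.sort_values("normalized_pct", ascending=False, na_position="last")
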