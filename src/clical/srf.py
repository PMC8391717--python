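"""Survival-random-forest validation stage.

The forest internals are delegated to :class:`sksurv.ensemble.RandomSurvivalForest`
(log-rank splitting, per-leaf Nelson-Aalen/Kaplan-Meier estimates, bootstrap
out-of-bag protocol); this module owns the feature encoding, the tuning loop
over the tree-count/mtry/node-size grid with out-of-bag model selection, the
fixed-horizon survival-probability predictions, and the probability-threshold
risk grouping.

The out-of-bag "error" is ``1 - OOB concordance``, the convention of the
survival-forest package family this stage mirrors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

logger = logging.getLogger(__name__)

__all__ = [
    "SRFConfig",
    "SRFModel",
    "RiskGroupAssignment",
    "split_cohort",
    "tune_srf",
    "fit_srf",
    "predict_survival_prob",
    "assign_risk_groups",
    "SRF_FEATURES",
]

#: the seven model features
SRF_FEATURES = (
    "age_group",
    "braf",
    "ldh_category",
    "cns_met",
    "prior_treatment",
    "eosinophil_category",
    "nlr_category",
)

# ordinal codes, unfavorable-to-favorable; trees only need an ordering
_ENCODINGS: dict[str, dict[str, int]] = {
    "age_group": {"younger": 0, "older": 1},
    "braf": {"mutated": 0, "wildtype": 1},
    "ldh_category": {"very_high": 0, "high": 1, "normal": 2},
    "cns_met": {"yes": 0, "no": 1},
    "prior_treatment": {
        "target": 0,
        "target_and_immunotherapy": 1,
        "cytostatic": 2,
        "immunotherapy": 3,
        "naive": 4,
    },
    "pre_target": {"yes": 0, "no": 1},
    "eosinophil_category": {"elevated": 0, "normal": 1},
    "nlr_category": {"abnormal": 0, "normal": 1},
}


@dataclass
class SRFConfig:
    """Tuning grid and split settings."""

    ntree_grid: tuple[int, ...] = (50, 100, 200, 500, 1000)
    mtry_start: int = 2
    mtry_grid: tuple[int, ...] | None = None  # None -> mtry_start..n_features
    nodesize_grid: tuple[int, ...] = (1, 3, 6, 10, 15, 25)
    train_fraction: float = 0.8
    horizons: tuple[float, ...] = (12.0, 24.0, 36.0, 60.0)
    seed: int = 0
    treatment_encoding: str = "five_level"  # or "pre_target"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if list(self.horizons) != sorted(self.horizons) or min(self.horizons) <= 0:
            raise ValueError("horizons must be positive and increasing")
        if self.treatment_encoding not in ("five_level", "pre_target"):
            raise ValueError("treatment_encoding must be 'five_level' or 'pre_target'")


@dataclass
class SRFModel:
    """Fitted forest plus its chosen parameters and OOB error."""

    ntree: int
    mtry: int
    nodesize: int
    oob_error: float
    features: tuple[str, ...]
    forest: RandomSurvivalForest
    seed: int

    def predict_risk(self, encoded: np.ndarray) -> np.ndarray:
        return self.forest.predict(encoded)


@dataclass
class RiskGroupAssignment:
    mode: str
    thresholds: tuple[float, ...]
    labels: pd.Series  # per-patient group label


def _features(config_encoding: str) -> tuple[str, ...]:
    feats = list(SRF_FEATURES)
    if config_encoding == "pre_target":
        feats[feats.index("prior_treatment")] = "pre_target"
    return tuple(feats)


def encode_features(df: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    """Ordinal-encode the feature columns; unseen levels are an error."""
    cols = []
    for f in features:
        mapping = _ENCODINGS[f]
        col = df[f].map(mapping)
        if col.isna().any():
            bad = df.loc[col.isna(), f].iloc[0]
            raise ValueError(f"unseen level {bad!r} in feature {f!r}")
        cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def _surv_y(df: pd.DataFrame):
    return Surv.from_arrays(
        event=df["os_event"].to_numpy(dtype=bool),
        time=df["os_months"].to_numpy(dtype=float),
    )


def split_cohort(cohort, train_fraction: float = 0.8, seed: int = 0):
    """Seeded train/validation split stratified on the event indicator.

    Within each event stratum, round(fraction * stratum size) records go to
    training, so the event fractions of the two halves agree to within one
    subject.
    """
    df = getattr(cohort, "data", cohort)
    rng = np.random.default_rng(seed)
    train_idx = []
    for _, stratum in df.groupby("os_event"):
        idx = stratum.index.to_numpy()
        rng.shuffle(idx)
        k = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[:k])
    train_mask = df.index.isin(train_idx)
    train = df.loc[train_mask]
    valid = df.loc[~train_mask]
    if len(train) == 0 or len(valid) == 0:
        raise ValueError("cohort too small to populate both split halves")
    return train, valid


def _fit_forest(X, y, ntree, mtry, nodesize, seed, oob=True, bootstrap=True):
    forest = RandomSurvivalForest(
        n_estimators=ntree,
        max_features=mtry,
        min_samples_leaf=nodesize,
        min_samples_split=max(2, 2 * nodesize),
        bootstrap=bootstrap,
        oob_score=oob and bootstrap,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def tune_srf(train, config: SRFConfig) -> tuple[tuple[int, int, int], pd.DataFrame]:
    """Grid-search tree count, mtry and node size by out-of-bag error.

    Returns the chosen ``(ntree, mtry, nodesize)`` and the full OOB error
    table.  Ties break toward fewer trees, then smaller node size.  Constant
    (degenerate) features are excluded from the mtry upper bound.
    """
    df = getattr(train, "data", train)
    feats = _features(config.treatment_encoding)
    X = encode_features(df, feats)
    if len(df) < 30 or df["os_event"].sum() < 10:
        raise ValueError("tuning needs >= 30 training records with >= 10 events")
    informative = int(sum(len(np.unique(X[:, j])) > 1 for j in range(X.shape[1])))
    if informative < X.shape[1]:
        logger.warning(
            "%d constant feature(s) excluded from the mtry range",
            X.shape[1] - informative,
        )
    y = _surv_y(df)
    mtry_grid = config.mtry_grid or tuple(range(config.mtry_start, informative + 1))
    rows = []
    for ntree in config.ntree_grid:
        for mtry in mtry_grid:
            for nodesize in config.nodesize_grid:
                forest = _fit_forest(X, y, ntree, mtry, nodesize, config.seed)
                err = 1.0 - float(forest.oob_score_)
                rows.append({"ntree": ntree, "mtry": mtry, "nodesize": nodesize, "oob_error": err})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["oob_error", "ntree", "nodesize"], kind="stable"
    ).iloc[0]
    chosen = (int(best["ntree"]), int(best["mtry"]), int(best["nodesize"]))
    return chosen, table


def fit_srf(
    data,
    params: tuple[int, int, int],
    seed: int = 0,
    treatment_encoding: str = "five_level",
    bootstrap: bool = True,
) -> SRFModel:
    """Fit the survival forest with the given ``(ntree, mtry, nodesize)``."""
    df = getattr(data, "data", data)
    if df["os_event"].sum() == 0:
        raise ValueError("cannot fit a survival forest with zero events")
    feats = _features(treatment_encoding)
    X = encode_features(df, feats)
    y = _surv_y(df)
    ntree, mtry, nodesize = params
    forest = _fit_forest(X, y, ntree, mtry, nodesize, seed, oob=bootstrap, bootstrap=bootstrap)
    oob_err = 1.0 - float(forest.oob_score_) if bootstrap else float("nan")
    return SRFModel(ntree, mtry, nodesize, oob_err, feats, forest, seed)


def predict_survival_prob(
    model: SRFModel, records, horizons: Sequence[float] = (12.0, 24.0, 36.0, 60.0)
) -> pd.DataFrame:
    """Ensemble survival probabilities at fixed horizons (step lookup).

    Returns one row per record with one column per horizon (``p12`` etc.);
    a horizon before the first event time yields probability 1.
    """
    df = getattr(records, "data", records)
    X = encode_features(df, model.features)
    surv = model.forest.predict_survival_function(X, return_array=True)
    times = model.forest.unique_times_
    out = {}
    for h in horizons:
        idx = int(np.searchsorted(times, h, side="right")) - 1
        out[f"p{int(h)}"] = np.ones(len(df)) if idx < 0 else surv[:, idx]
    res = pd.DataFrame(out, index=df.index)
    if "patient_id" in df.columns:
        res.insert(0, "patient_id", df["patient_id"])
    return res


def assign_risk_groups(
    probs_at_60,
    mode: str = "three_group",
    thresholds: tuple[float, ...] | None = None,
) -> RiskGroupAssignment:
    """Group patients by predicted 60-month survival probability.

    ``three_group``: below 0.2 -> high risk, 0.41 and above -> low risk,
    in between -> medium risk.  ``five_signature``: quantile cuts sized to
    the published signature proportions (worst 9.1% -> I, ... best 6.4% -> V)
    so the forest-derived groups are size-matched to the score-derived ones.
    """
    p = pd.Series(probs_at_60, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("survival probabilities must lie in [0, 1]")
    if mode == "three_group":
        if thresholds is None:
            thresholds = (0.2, 0.41)
        if len(thresholds) != 2:
            raise ValueError("three_group mode takes exactly two thresholds")
        lo, hi = thresholds
        labels = pd.Series(
            np.where(p < lo, "high", np.where(p >= hi, "low", "medium")),
            index=p.index,
        )
    elif mode == "five_signature":
        if thresholds is None:
            thresholds = (0.091, 0.232, 0.453, 0.936)
        if sorted(thresholds) != list(thresholds) or len(thresholds) != 4:
            raise ValueError("five_signature mode takes four increasing quantile cuts")
        # rank-based quantile grouping: lowest predicted survival -> Signature I
        ranks = p.rank(method="first") / len(p)
        bins = [0.0, *thresholds, 1.0 + 1e-12]
        labels = pd.cut(
            ranks, bins=bins, labels=["I", "II", "III", "IV", "V"], include_lowest=True
        ).astype(str)
        labels = pd.Series(labels, index=p.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if labels.nunique() == 1:
        logger.warning("all patients fell into a single risk group (%s)", labels.iloc[0])
    return RiskGroupAssignment(mode, tuple(thresholds), labels)
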