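"""Model evaluation: time-dependent ROC/AUC with inverse-probability-of-
censoring weighting (IPCW), Brier prediction error, and the end-to-end
pipeline driver.

The ROC uses the cumulative-cases / dynamic-controls definition at a horizon
``t``: cases experienced the event by ``t``, controls are event-free at ``t``,
and subjects censored before ``t`` are handled by reweighting with the
Kaplan-Meier estimate of the censoring distribution.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CLICAL_VARIABLES,
    CohortTable,
    complete_case_filter,
    read_cohort,
    write_cohort,
)
from .estimators import concordance_index, cox_fit, km_estimate, log_rank, na_cumhaz
from .score import default_signature_map, default_weight_scheme, score_cohort
from .simulate import GeneratorConfig, generate
from . import srf as srf_mod

logger = logging.getLogger(__name__)

__all__ = [
    "TimeDependentROC",
    "PredictionErrorResult",
    "RocComputationError",
    "td_roc",
    "brier_prediction_error",
    "run_pipeline",
]


class RocComputationError(RuntimeError):
    """Raised when a horizon has no cases or no controls."""


@dataclass
class TimeDependentROC:
    horizon: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int
    censoring_weight_model: str = "Kaplan-Meier of the censoring distribution"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


@dataclass
class PredictionErrorResult:
    horizon: float
    brier_score: float
    reference_brier: float


def _censoring_km(times, events):
    """KM of the censoring distribution (censorings treated as events)."""
    return km_estimate(times, 1 - np.asarray(events, dtype=int))


def _g_left(curve, t: float) -> float:
    """Left-continuous censoring-survival lookup G(t-)."""
    idx = np.searchsorted(curve.event_times, t, side="left") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def td_roc(marker, times, events, horizon: float) -> TimeDependentROC:
    """IPCW time-dependent ROC at ``horizon`` (cumulative/dynamic definition).

    Cases: event observed by the horizon (weight ``1/G(T-)``); controls:
    still event-free at the horizon (weight ``1/G(horizon)``).  Higher marker
    must mean higher risk.  The AUC is the trapezoidal area of the weighted
    curve, identical to the weighted rank statistic with ties counting 1/2.
    """
    m = np.asarray(marker, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    n_cases, n_controls = int(cases.sum()), int(controls.sum())
    if n_cases == 0 or n_controls == 0:
        raise RocComputationError(
            f"cannot compute a ROC at t={horizon}: {n_cases} case(s), "
            f"{n_controls} control(s)"
        )
    g = _censoring_km(t, e)
    w = np.zeros_like(m)
    for i in np.flatnonzero(cases):
        gi = _g_left(g, t[i])
        if gi <= 0:
            raise RocComputationError(f"zero censoring-survival weight at T={t[i]}")
        w[i] = 1.0 / gi
    g_h = g.at(horizon)
    if g_h <= 0:
        raise RocComputationError(f"zero censoring-survival weight at horizon {horizon}")
    w[controls] = 1.0 / g_h

    # sweep thresholds from high to low marker
    order = np.argsort(-m, kind="stable")
    w_case = np.where(cases, w, 0.0)[order]
    w_ctrl = np.where(controls, w, 0.0)[order]
    m_sorted = m[order]
    # merge tied marker values into single steps (diagonal segments)
    boundaries = np.flatnonzero(np.diff(m_sorted)) + 1
    cum_case = np.concatenate([[0.0], np.add.accumulate(w_case)[np.append(boundaries - 1, len(m) - 1)]])
    cum_ctrl = np.concatenate([[0.0], np.add.accumulate(w_ctrl)[np.append(boundaries - 1, len(m) - 1)]])
    tpr = cum_case / cum_case[-1]
    fpr = cum_ctrl / cum_ctrl[-1]
    auc = float(np.trapezoid(tpr, fpr))
    return TimeDependentROC(horizon, fpr, tpr, auc, n_cases, n_controls)


def brier_prediction_error(
    predicted_survival_at_horizon, times, events, horizon: float
) -> PredictionErrorResult:
    """IPCW Brier score at a horizon, with the marginal KM as null reference."""
    s = np.asarray(predicted_survival_at_horizon, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    km = km_estimate(t, e)
    null_pred = np.full_like(s, km.at(horizon))

    def _score(pred):
        g = _censoring_km(t, e)
        g_h = g.at(horizon)
        total = 0.0
        for i in range(len(t)):
            if t[i] <= horizon and e[i] == 1:
                gi = _g_left(g, t[i])
                if gi <= 0:
                    raise RocComputationError(f"zero IPCW weight at T={t[i]}")
                total += (0.0 - pred[i]) ** 2 / gi
            elif t[i] > horizon:
                if g_h <= 0:
                    raise RocComputationError(f"zero IPCW weight at horizon {horizon}")
                total += (1.0 - pred[i]) ** 2 / g_h
        return total / len(t)

    return PredictionErrorResult(horizon, _score(s), _score(null_pred))


# ---------------------------------------------------------------------------
# pipeline driver


def _km_table_by(df: pd.DataFrame, group_col: str) -> pd.DataFrame:
    frames = []
    for g, sub in df.groupby(group_col):
        curve = km_estimate(sub["os_months"], sub["os_event"])
        f = curve.to_frame()
        f.insert(0, group_col, g)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _na_table_by(df: pd.DataFrame, group_col: str) -> pd.DataFrame:
    frames = []
    for g, sub in df.groupby(group_col):
        curve = na_cumhaz(sub["os_months"], sub["os_event"])
        f = curve.to_frame()
        f.insert(0, group_col, g)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _log_rank_by(df: pd.DataFrame, group_col: str) -> dict:
    groups = [
        (sub["os_months"].to_numpy(), sub["os_event"].to_numpy())
        for _, sub in df.groupby(group_col)
    ]
    if len(groups) < 2:
        return {"error": f"fewer than two {group_col} groups"}
    r = log_rank(groups)
    return {"chi_square": r.chi_square, "df": r.df, "p_value": r.p_value}


def _cox_linear_predictor(fit, design_frame: pd.DataFrame) -> np.ndarray:
    beta = fit.summary["coef"]
    X = design_frame.reindex(columns=beta.index, fill_value=0.0)
    return X.to_numpy(dtype=float) @ beta.to_numpy()


def run_pipeline(config: Mapping | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis and write a report bundle.

    ``config`` is a mapping (or YAML path) with either a ``cohort_csv`` key or
    a ``generator`` section, plus optional ``seed``, ``outdir``, ``srf`` and
    ``horizons`` settings.  Artifacts (CSV tables, JSON results, run manifest)
    are written under ``outdir``.  Returns the manifest.  A stage failure
    aborts with the stage name; partial outputs stay on disk.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    outdir = Path(outdir or cfg.get("outdir", "clical_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    horizons = tuple(cfg.get("horizons", (12.0, 24.0, 36.0, 60.0)))
    manifest: dict = {
        "seed": seed,
        "stages": {},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    stage = "input"
    try:
        if "cohort_csv" in cfg:
            cohort = read_cohort(cfg["cohort_csv"])
            manifest["input"] = str(cfg["cohort_csv"])
        else:
            gen_cfg = GeneratorConfig.from_dict({"seed": seed, **cfg.get("generator", {})})
            cohort, gen_manifest = generate(gen_cfg)
            write_cohort(cohort, outdir / "cohort.csv")
            manifest["generator"] = gen_manifest
        manifest["stages"][stage] = f"ok ({len(cohort)} records)"

        stage = "complete_case_filter"
        complete = complete_case_filter(cohort)
        manifest["stages"][stage] = f"ok ({len(complete)} of {len(cohort)} retained)"

        stage = "scoring"
        scores, summary = score_cohort(complete, default_weight_scheme(), default_signature_map())
        scores.to_csv(outdir / "scores.csv", index=False)
        summary.to_csv(outdir / "score_summary.csv", index=False)
        df = complete.data.reset_index(drop=True).join(
            scores[["weight_sum", "score", "signature"]]
        )
        manifest["stages"][stage] = f"ok ({scores['signature'].nunique()} signatures)"

        stage = "survival_curves"
        logrank_results = {}
        for group_col in ("signature", "ici_agent", "pre_target"):
            _km_table_by(df, group_col).to_csv(outdir / f"km_by_{group_col}.csv", index=False)
            _na_table_by(df, group_col).to_csv(outdir / f"na_by_{group_col}.csv", index=False)
            logrank_results[group_col] = _log_rank_by(df, group_col)
        (outdir / "log_rank.json").write_text(json.dumps(logrank_results, indent=2))
        manifest["stages"][stage] = "ok"

        stage = "cox"
        uni_tables = []
        for var in CLICAL_VARIABLES:
            try:
                fit = cox_fit(df, [var])
            except ValueError as exc:
                logger.warning("univariate Cox for %s skipped: %s", var, exc)
                continue
            t = fit.forest_table()
            t.insert(0, "model", f"univariate:{var}")
            uni_tables.append(t)
        multi_fit = cox_fit(df, list(CLICAL_VARIABLES))
        mt = multi_fit.forest_table()
        mt.insert(0, "model", "multivariate")
        forest = pd.concat(uni_tables + [mt])
        forest.to_csv(outdir / "cox_forest.csv", index_label="covariate")
        manifest["stages"][stage] = f"ok (multivariate converged={multi_fit.converged})"

        stage = "cox_validation"
        train, valid = split_cohort_frames(df, cfg, seed)
        cox_val = cox_fit(train, list(CLICAL_VARIABLES))
        lp_valid = _cox_linear_predictor(cox_val, _design_matrix_like(train, valid))
        aucs = {}
        for h in horizons:
            try:
                roc = td_roc(lp_valid, valid["os_months"], valid["os_event"], h)
                aucs[str(int(h))] = roc.auc
            except RocComputationError as exc:
                aucs[str(int(h))] = None
                logger.warning("ROC at %s months not computable: %s", h, exc)
        (outdir / "cox_validation_auc.json").write_text(json.dumps(aucs, indent=2))
        manifest["stages"][stage] = "ok"
        manifest["cox_validation_auc"] = aucs

        stage = "srf"
        # desk-scale default grid; pass an "srf" section to widen it
        srf_defaults = {
            "ntree_grid": (50, 100, 200),
            "mtry_grid": (2, 3, 5),
            "nodesize_grid": (6, 15),
        }
        srf_cfg = srf_mod.SRFConfig(seed=seed, **{**srf_defaults, **cfg.get("srf", {})})
        try:
            chosen, oob_table = srf_mod.tune_srf(train, srf_cfg)
            oob_table.to_csv(outdir / "srf_oob.csv", index=False)
            model = srf_mod.fit_srf(df, chosen, seed=seed,
                                    treatment_encoding=srf_cfg.treatment_encoding)
            preds = srf_mod.predict_survival_prob(model, df, srf_cfg.horizons)
            three = srf_mod.assign_risk_groups(preds["p60"], "three_group")
            five = srf_mod.assign_risk_groups(preds["p60"], "five_signature")
            preds["risk_group"] = three.labels.to_numpy()
            preds["srf_signature"] = five.labels.to_numpy()
            preds.to_csv(outdir / "srf_predictions.csv", index=False)
            (outdir / "srf_params.json").write_text(
                json.dumps(
                    {"ntree": model.ntree, "mtry": model.mtry,
                     "nodesize": model.nodesize, "oob_error": model.oob_error},
                    indent=2,
                )
            )
            df_srf = df.assign(srf_signature=five.labels.to_numpy())
            _km_table_by(df_srf, "srf_signature").to_csv(
                outdir / "km_by_srf_signature.csv", index=False
            )
            manifest["stages"][stage] = f"ok (ntree={model.ntree}, mtry={model.mtry}, nodesize={model.nodesize})"
            manifest["srf_params"] = {"ntree": model.ntree, "mtry": model.mtry, "nodesize": model.nodesize}
        except ValueError as exc:
            manifest["stages"][stage] = f"skipped ({exc})"
            logger.warning("SRF stage skipped: %s", exc)

        manifest["signature_counts"] = (
            df["signature"].value_counts().sort_index().to_dict()
        )
        manifest["n_complete"] = len(df)
    except Exception as exc:
        manifest["stages"][stage] = f"failed ({exc})"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def split_cohort_frames(df: pd.DataFrame, cfg: Mapping, seed: int):
    frac = float(cfg.get("train_fraction", 0.8))
    return srf_mod.split_cohort(df, frac, seed)


def _design_matrix_like(train: pd.DataFrame, valid: pd.DataFrame) -> pd.DataFrame:
    """Validation design matrix with the training frame's dummy columns."""
    from .estimators import _design_matrix

    combined = pd.concat([train, valid])
    design = _design_matrix(combined, list(CLICAL_VARIABLES))
    return design.loc[valid.index]
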