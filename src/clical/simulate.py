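"""Seeded synthetic survival-cohort generator.

Covariates are drawn from configurable category marginals (defaults match the
published cohort description), with one structural constraint: prior targeted
therapy can only occur in mutation-positive patients, so the treatment-group
variable is sampled hierarchically below the mutation status.  Survival is a
per-signature two-piece exponential — constant hazard up to a knot (32 months
by default) reproducing the configured cumulative hazard there, then the same
hazard scaled by a plateau factor ``c`` calibrated so the cohort-level
survival hits a late target (20% at 70 months by default).  Censoring is
administrative and uniform.  Missingness is MCAR at per-variable rates, and a
response label is drawn from a signature-tilted multinomial.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, COHORT_COLUMNS, derive_pre_target
from .score import SIGNATURE_LABELS, default_signature_map, default_weight_scheme

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "CalibrationError",
    "sample_covariates",
    "calibrate_plateau",
    "mixture_survival",
    "sample_survival",
    "sample_response",
    "apply_missingness",
    "generate",
]


class CalibrationError(RuntimeError):
    pass


def _default_marginals() -> dict[str, dict[str, float]]:
    return {
        "sex": {"male": 0.55, "female": 0.45},
        "age_group": {"older": 0.55, "younger": 0.45},
        "braf": {"mutated": 0.43, "wildtype": 0.57},
        "cns_met": {"yes": 0.28, "no": 0.72},
        "ldh_category": {"very_high": 0.14, "high": 0.20, "normal": 0.66},
        "eosinophil_category": {"elevated": 0.09, "normal": 0.91},
        "nlr_category": {"abnormal": 0.45, "normal": 0.55},
        "prior_treatment": {
            "naive": 0.34,
            "immunotherapy": 0.25,
            "target": 0.18,
            "target_and_immunotherapy": 0.10,
            "cytostatic": 0.13,
        },
        "ici_agent": {"anti_ctla4": 0.51, "nivolumab": 0.26, "pembrolizumab": 0.23},
    }


def _default_hazards() -> dict[str, float]:
    return {"I": 3.42, "II": 2.41, "III": 1.70, "IV": 1.08, "V": 0.48}


def _default_missingness() -> dict[str, float]:
    return {
        "braf": 30 / 578,
        "cns_met": 6 / 578,
        "ldh_category": 43 / 578,
        "eosinophil_category": 35 / 578,
        "nlr_category": 27 / 578,
    }


def _default_response_probs() -> dict[str, float]:
    # exact count fractions (32/74/103/369 of 578) so the vector sums to 1;
    # they round to the published 5.5/12.8/17.8/63.8 percentages
    return {"CR": 32 / 578, "PR": 74 / 578, "SD": 103 / 578, "PD": 369 / 578}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic generator; defaults reproduce the published
    cohort's marginals, per-signature 32-month hazards and late survival."""

    n: int = 578
    seed: int = 0
    marginals: dict = field(default_factory=_default_marginals)
    pre_target_given_mutated: float = 161 / 234
    signature_hazard_32: dict = field(default_factory=_default_hazards)
    signature_proportions: dict = field(
        default_factory=lambda: {"I": 0.091, "II": 0.141, "III": 0.221, "IV": 0.483, "V": 0.064}
    )
    plateau_factor_c: float | None = None  # None -> calibrate
    knot_months: float = 32.0
    target_survival: tuple[float, float] = (70.0, 0.20)
    censoring: tuple[float, float] = (14.0, 84.0)  # uniform horizon bounds, months
    missingness_rates: dict = field(default_factory=_default_missingness)
    response_probs: dict = field(default_factory=_default_response_probs)
    response_tilt: float = 0.6
    age_cutoff: float = 65.0

    def validate(self) -> None:
        for name, probs in list(self.marginals.items()) + [
            ("response_probs", self.response_probs),
            ("signature_proportions", self.signature_proportions),
        ]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities for {name!r} sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative probability in {name!r}")
        h = [self.signature_hazard_32[s] for s in SIGNATURE_LABELS]
        if not all(a > b for a, b in zip(h, h[1:])):
            raise ValueError("signature hazards must be strictly decreasing I -> V")
        if self.plateau_factor_c is not None and self.plateau_factor_c < 0:
            raise ValueError("plateau factor must be non-negative")
        if not 0 <= self.pre_target_given_mutated <= 1:
            raise ValueError("pre_target_given_mutated must be a probability")
        lo, hi = self.censoring
        if lo < 0 or hi < lo:
            raise ValueError("censoring bounds must satisfy 0 <= lo <= hi")
        for var, r in self.missingness_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"missingness rate for {var!r} outside [0, 1]")
        if self.n < 0:
            raise ValueError("n must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_survival"] = list(self.target_survival)
        d["censoring"] = list(self.censoring)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        kwargs = dict(d)
        if "target_survival" in kwargs:
            kwargs["target_survival"] = tuple(kwargs["target_survival"])
        if "censoring" in kwargs:
            kwargs["censoring"] = tuple(kwargs["censoring"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _latent_braf_rate(m: float, q: float, mask_frac: float) -> float:
    """Latent mutation probability whose among-tested fraction equals ``m``.

    The published mutation marginal is a fraction of *tested* patients, and
    untested patients are drawn exclusively from the no-prior-target group
    (masking a pre-target patient would contradict the structural constraint).
    Removing only no-target patients concentrates the all-mutated pre-target
    group among the tested, so the latent rate must sit slightly below ``m``.
    ``q`` is P(pre-target | mutated) and ``mask_frac`` the expected untested
    fraction of the whole cohort.
    """
    if mask_frac <= 0:
        return m
    from scipy.optimize import brentq

    def tested_fraction(p):
        pre = p * q
        mut_no_target = p * (1 - q)
        masked_mut = mask_frac * (mut_no_target / (1 - pre) if pre < 1 else 0.0)
        return (p - masked_mut) / (1 - mask_frac)

    return float(brentq(lambda p: tested_fraction(p) - m, 1e-9, 1 - 1e-9, xtol=1e-12))


def _draw(rng, probs: Mapping[str, float], size: int) -> np.ndarray:
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=size, p=p)


def sample_covariates(config: GeneratorConfig, rng: np.random.Generator | None = None) -> CohortTable:
    """Draw covariates for ``config.n`` patients (no survival columns yet).

    All variables are independent except the treatment-group hierarchy: the
    mutation status is drawn first; mutation-positive patients receive prior
    targeted therapy with probability ``pre_target_given_mutated`` (the
    specific target group proportional to its marginal), everyone else draws
    from the non-target groups renormalized.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n
    m = config.marginals
    df = pd.DataFrame({c: pd.Series([np.nan] * n, dtype=object) for c in COHORT_COLUMNS})
    df["patient_id"] = [f"S{i:06d}" for i in range(n)]
    for var in ("sex", "age_group", "cns_met", "ldh_category",
                "eosinophil_category", "nlr_category", "ici_agent"):
        df[var] = _draw(rng, m[var], n)

    cutoff = config.age_cutoff
    age = np.where(
        df["age_group"].to_numpy() == "older",
        rng.uniform(cutoff, 90.0, size=n),
        # keep the younger group's ages below the cutoff after 1-dp rounding
        rng.uniform(18.0, cutoff - 0.1, size=n),
    )
    df["age_years"] = np.round(age, 1)

    p_mut = _latent_braf_rate(
        m["braf"]["mutated"],
        config.pre_target_given_mutated,
        config.missingness_rates.get("braf", 0.0),
    )
    braf = np.where(rng.uniform(size=n) < p_mut, "mutated", "wildtype").astype(object)
    pt_probs = m["prior_treatment"]
    target_groups = {"target", "target_and_immunotherapy"}
    p_target = {g: pt_probs[g] for g in pt_probs if g in target_groups}
    p_nontarget = {g: pt_probs[g] for g in pt_probs if g not in target_groups}
    prior = np.empty(n, dtype=object)
    mutated = braf == "mutated"
    got_target = mutated & (rng.uniform(size=n) < config.pre_target_given_mutated)
    k = int(got_target.sum())
    if k:
        prior[got_target] = _draw(rng, p_target, k)
    rest = ~got_target
    prior[rest] = _draw(rng, p_nontarget, int(rest.sum()))
    df["braf"] = braf
    df["prior_treatment"] = prior
    df["pre_target"] = [derive_pre_target(g) for g in prior]
    df["response"] = "unknown"
    df["os_months"] = np.nan
    df["os_event"] = 0
    for col in ("ldh_ratio", "neutrophils", "lymphocytes", "nlr_value"):
        df[col] = np.nan
    return CohortTable(df[list(COHORT_COLUMNS)], provenance=f"synthetic seed={config.seed}")


def _piece_survival(t: float, h32: float, c: float, knot: float) -> float:
    lam1 = h32 / knot
    if t <= knot:
        return float(np.exp(-lam1 * t))
    return float(np.exp(-h32 - c * lam1 * (t - knot)))


def mixture_survival(
    t: float,
    c: float,
    proportions: Mapping[str, float],
    hazards: Mapping[str, float],
    knot: float = 32.0,
) -> float:
    """Closed-form survival of the signature mixture at time ``t``."""
    return float(
        sum(p * _piece_survival(t, hazards[s], c, knot) for s, p in proportions.items())
    )


def calibrate_plateau(
    config: GeneratorConfig,
    proportions: Mapping[str, float] | None = None,
    bracket: tuple[float, float] = (0.0, 5.0),
    tol: float = 1e-6,
) -> float:
    """Solve for the late-hazard multiplier ``c`` by bisection.

    Finds ``c`` such that the closed-form signature-mixture survival at the
    target time equals the target survival.  ``proportions`` defaults to the
    configured signature proportions; pass a cohort's empirical proportions to
    calibrate for that cohort.
    """
    props = dict(proportions) if proportions is not None else dict(config.signature_proportions)
    t_star, s_star = config.target_survival
    hz = config.signature_hazard_32
    knot = config.knot_months

    def f(c):
        return mixture_survival(t_star, c, props, hz, knot) - s_star

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise CalibrationError(
            f"no plateau factor in [{lo}, {hi}] reaches survival {s_star} at "
            f"t={t_star}: achievable range is "
            f"[{mixture_survival(t_star, hi, props, hz, knot):.4f}, "
            f"{mixture_survival(t_star, lo, props, hz, knot):.4f}]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def sample_survival(
    cohort: CohortTable,
    config: GeneratorConfig,
    signatures: Sequence[str],
    rng: np.random.Generator | None = None,
) -> CohortTable:
    """Draw event and censoring times; fill ``os_months`` / ``os_event``.

    Event times follow each record's per-signature two-piece exponential with
    the configured plateau factor; censoring is uniform on the configured
    interval; the observed time is the minimum.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    sig = np.asarray(signatures, dtype=object)
    if len(sig) != len(cohort):
        raise ValueError("one signature per record required")
    bad = ~np.isin(sig, SIGNATURE_LABELS)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} record(s) lack a valid signature; run the "
            "complete-case filter and score the cohort first"
        )
    c = config.plateau_factor_c
    if c is None:
        raise ValueError("plateau_factor_c unset; call calibrate_plateau first")
    knot = config.knot_months
    h32 = np.array([config.signature_hazard_32[s] for s in sig], dtype=float)
    lam1 = h32 / knot
    e = rng.exponential(size=len(sig))
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = np.where(c > 0, knot + (e - h32) / np.where(c > 0, c * lam1, 1.0), np.inf)
    t_event = np.where(e <= h32, e / lam1, tail)
    lo, hi = config.censoring
    t_cens = rng.uniform(lo, hi, size=len(sig)) if hi > lo else np.full(len(sig), float(lo))
    df = cohort.data.copy()
    df["os_months"] = np.round(np.minimum(t_event, t_cens), 4)
    df["os_event"] = (t_event <= t_cens).astype(int)
    return CohortTable(df, provenance=cohort.provenance)


def _responder_intercept(proportions: Mapping[str, float], tilt: float, target: float) -> float:
    """Intercept of the per-signature responder logit hitting the marginal target."""
    from scipy.optimize import brentq

    idx = {s: i + 1 for i, s in enumerate(SIGNATURE_LABELS)}

    def marginal(a):
        return sum(
            q / (1.0 + np.exp(-(a + tilt * (idx[s] - 3)))) for s, q in proportions.items()
        )

    return float(brentq(lambda a: marginal(a) - target, -30, 30, xtol=1e-12))


def sample_response(
    cohort: CohortTable,
    config: GeneratorConfig,
    signatures: Sequence[str],
    rng: np.random.Generator | None = None,
) -> CohortTable:
    """Draw response labels from a signature-tilted multinomial.

    The responder (CR/PR/SD) log-odds rise linearly with the signature index
    at slope ``response_tilt``; the intercept is solved so the cohort-level
    marginal matches ``response_probs``.  Conditional on responding, the
    CR/PR/SD split keeps the baseline ratios.  ``tilt=0`` reduces to i.i.d.
    baseline sampling.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    sig = np.asarray(signatures, dtype=object)
    base = config.response_probs
    p_resp = base["CR"] + base["PR"] + base["SD"]
    counts = pd.Series(sig).value_counts(normalize=True).to_dict()
    a = _responder_intercept(counts, config.response_tilt, p_resp)
    idx = {s: i + 1 for i, s in enumerate(SIGNATURE_LABELS)}
    shift = np.array([config.response_tilt * (idx[s] - 3) for s in sig], dtype=float)
    p_r = 1.0 / (1.0 + np.exp(-(a + shift)))
    responder = rng.uniform(size=len(sig)) < p_r
    cond = np.array([base["CR"], base["PR"], base["SD"]]) / p_resp
    labels = np.full(len(sig), "PD", dtype=object)
    k = int(responder.sum())
    if k:
        labels[responder] = rng.choice(["CR", "PR", "SD"], size=k, p=cond)
    df = cohort.data.copy()
    df["response"] = labels
    return CohortTable(df, provenance=cohort.provenance)


def apply_missingness(
    cohort: CohortTable,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> CohortTable:
    """Mask covariates missing-completely-at-random at the configured rates.

    The mutation-status mask is drawn only among no-prior-target records
    (masking a pre-target patient would contradict the structural constraint)
    with the rate inflated so the expected masked count still equals
    ``rate * n``.  Survival columns are never masked.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    df = cohort.data.copy()
    n = len(df)
    for var, rate in config.missingness_rates.items():
        if rate <= 0 or n == 0:
            continue
        token = "untested" if var == "braf" else "unknown"
        if var == "braf":
            eligible = (df["pre_target"] == "no").to_numpy()
            n_el = int(eligible.sum())
            if n_el == 0:
                continue
            eff = min(rate * n / n_el, 1.0)
            mask = eligible & (rng.uniform(size=n) < eff)
        else:
            mask = rng.uniform(size=n) < rate
        df.loc[mask, var] = token
    return CohortTable(df, provenance=cohort.provenance)


def generate(config: GeneratorConfig) -> tuple[CohortTable, dict]:
    """Full generator pipeline; returns the cohort and a provenance manifest.

    Steps: covariates -> per-record scoring (pre-masking, so every record has
    a true signature) -> plateau calibration against the cohort's empirical
    signature proportions -> survival -> response -> missingness.  A single
    seeded RNG drives every step, so identical config+seed reproduces the
    cohort exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohort = sample_covariates(config, rng)
    if len(cohort) == 0:
        return cohort, {"seed": config.seed, "n": 0, "config_hash": config.config_hash()}

    from .score import score_frame  # deferred to avoid cycles at import time

    signatures = score_frame(
        cohort.data, default_weight_scheme(), default_signature_map()
    )["signature"].to_numpy(dtype=object)
    props = pd.Series(signatures).value_counts(normalize=True).to_dict()
    cfg = dataclasses.replace(config)
    if cfg.plateau_factor_c is None:
        cfg.plateau_factor_c = calibrate_plateau(config, proportions=props)
        logger.info("calibrated plateau factor c = %.4f", cfg.plateau_factor_c)
    cohort = sample_survival(cohort, cfg, signatures, rng)
    cohort = sample_response(cohort, cfg, signatures, rng)
    cohort = apply_missingness(cohort, cfg, rng)
    manifest = {
        "seed": config.seed,
        "n": config.n,
        "plateau_factor_c": cfg.plateau_factor_c,
        "empirical_signature_proportions": {s: float(props.get(s, 0.0)) for s in SIGNATURE_LABELS},
        "config_hash": config.config_hash(),
    }
    return cohort, manifest
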