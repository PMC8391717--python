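"""Patient data model, lab-value categorization, CSV I/O and the complete-case filter.

A cohort is a :class:`CohortTable`: an ordered table of patients with
categorical clinical variables, overall-survival follow-up and an optional
treatment-response label.  Raw laboratory values (LDH ratio, neutrophil and
lymphocyte counts, age in years) are converted to the categorical variables the
scoring algorithm consumes by the ``categorize_*`` / ``derive_*`` helpers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "CohortTable",
    "CohortValidationError",
    "categorize_ldh",
    "categorize_nlr",
    "derive_age_group",
    "derive_pre_target",
    "complete_case_filter",
    "read_cohort",
    "write_cohort",
    "CLICAL_VARIABLES",
    "COHORT_COLUMNS",
    "MISSING_TOKENS",
]

#: the seven variables the scoring algorithm requires to be non-missing
CLICAL_VARIABLES = (
    "age_group",
    "braf",
    "cns_met",
    "ldh_category",
    "eosinophil_category",
    "nlr_category",
    "pre_target",
)

#: canonical CSV column order
COHORT_COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "age_group",
    "braf",
    "cns_met",
    "ldh_ratio",
    "ldh_category",
    "eosinophil_category",
    "neutrophils",
    "lymphocytes",
    "nlr_value",
    "nlr_category",
    "prior_treatment",
    "pre_target",
    "ici_agent",
    "os_months",
    "os_event",
    "response",
)

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male", "unknown"),
    "age_group": ("younger", "older"),
    "braf": ("mutated", "wildtype", "untested"),
    "cns_met": ("yes", "no", "unknown"),
    "ldh_category": ("normal", "high", "very_high", "unknown"),
    "eosinophil_category": ("normal", "elevated", "unknown"),
    "nlr_category": ("normal", "abnormal", "unknown"),
    "prior_treatment": (
        "naive",
        "immunotherapy",
        "target",
        "target_and_immunotherapy",
        "cytostatic",
    ),
    "pre_target": ("yes", "no"),
    "ici_agent": ("anti_ctla4", "nivolumab", "pembrolizumab"),
    "response": ("CR", "PR", "SD", "PD", "unknown"),
}

#: per-variable tokens meaning "value not available"
MISSING_TOKENS = {"unknown", "untested"}

_NUMERIC_COLUMNS = (
    "age_years",
    "ldh_ratio",
    "neutrophils",
    "lymphocytes",
    "nlr_value",
    "os_months",
)

#: groups implying prior exposure to targeted therapy
TARGET_GROUPS = ("target", "target_and_immunotherapy")


class CohortValidationError(ValueError):
    """Raised when a cohort violates a structural invariant or the CSV schema."""


@dataclass
class PatientRecord:
    """One patient's clinical variables and follow-up."""

    patient_id: str
    sex: str = "unknown"
    age_years: float = float("nan")
    age_group: str = "younger"
    braf: str = "untested"
    cns_met: str = "unknown"
    ldh_ratio: float = float("nan")
    ldh_category: str = "unknown"
    eosinophil_category: str = "unknown"
    neutrophils: float = float("nan")
    lymphocytes: float = float("nan")
    nlr_value: float = float("nan")
    nlr_category: str = "unknown"
    prior_treatment: str = "naive"
    pre_target: str = "no"
    ici_agent: str = "anti_ctla4"
    os_months: float = 0.0
    os_event: int = 0
    response: str = "unknown"

    def as_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in COHORT_COLUMNS})


@dataclass
class CohortTable:
    """Ordered patient table plus a free-text provenance label.

    ``data`` is a :class:`pandas.DataFrame` with the canonical columns of
    :data:`COHORT_COLUMNS`; rows keep their insertion order.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = self.data["patient_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5]
            raise CohortValidationError(f"duplicate patient_id values: {list(dupes)}")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord | Mapping], provenance: str = ""
    ) -> "CohortTable":
        rows = []
        for r in records:
            if isinstance(r, PatientRecord):
                rows.append(r.as_series())
            else:
                rows.append(pd.Series({c: r.get(c, PatientRecord("x").as_series()[c]) for c in COHORT_COLUMNS}))
        if rows:
            df = pd.DataFrame(rows).reset_index(drop=True)
        else:
            df = _empty_frame()
        return cls(df, provenance)

    def validate(self) -> None:
        """Check category vocabularies and structural invariants; raise on violation."""
        df = self.data
        for col, levels in CATEGORY_LEVELS.items():
            bad = ~df[col].isin(levels)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"invalid token {df[col].iloc[row]!r} in column {col!r} (row {row})"
                )
        if (df["os_months"] < 0).any():
            raise CohortValidationError("negative os_months")
        if not df["os_event"].isin([0, 1]).all():
            raise CohortValidationError("os_event must be 0 or 1")
        expected_pt = df["prior_treatment"].isin(TARGET_GROUPS).map({True: "yes", False: "no"})
        if (df["pre_target"] != expected_pt).any():
            n = int((df["pre_target"] != expected_pt).sum())
            raise CohortValidationError(
                f"pre_target inconsistent with prior_treatment in {n} record(s)"
            )
        # prior targeted therapy presupposes a documented activating mutation
        bad = (df["pre_target"] == "yes") & (df["braf"] != "mutated")
        if bad.any():
            ids = df.loc[bad, "patient_id"].tolist()[:5]
            raise CohortValidationError(
                f"{int(bad.sum())} record(s) with pre_target=yes but braf != mutated "
                f"(e.g. {ids}); targeted therapy requires a documented mutation"
            )


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})


def normalize_token(token: str) -> str:
    """Lower-case a category token and map hyphens/spaces to underscores.

    Response labels (CR/PR/SD/PD) are kept upper-case.
    """
    t = re.sub(r"[-\s]+", "_", str(token).strip())
    if t.upper() in {"CR", "PR", "SD", "PD"}:
        return t.upper()
    t = t.lower()
    # common synonyms
    aliases = {
        "wild_type": "wildtype",
        "wt": "wildtype",
        "anti_ctla_4": "anti_ctla4",
        "na": "unknown",
        "": "unknown",
        "nan": "unknown",
    }
    return aliases.get(t, t)


def categorize_ldh(ldh_value: float, llr_upper: float) -> str:
    """Categorize an LDH measurement against the local laboratory reference (LLR).

    ratio = ldh_value / llr_upper; ``normal`` if ratio <= 1, ``high`` if
    1 < ratio <= 2, ``very_high`` if ratio > 2.  The boundary at exactly 1x
    and 2x the reference is assigned to the lower category.
    """
    if ldh_value <= 0 or llr_upper <= 0:
        raise ValueError(f"LDH values must be positive, got ({ldh_value}, {llr_upper})")
    ratio = ldh_value / llr_upper
    return categorize_ldh_ratio(ratio)


def categorize_ldh_ratio(ratio: float) -> str:
    if ratio <= 0:
        raise ValueError(f"LDH ratio must be positive, got {ratio}")
    if ratio <= 1:
        return "normal"
    if ratio <= 2:
        return "high"
    return "very_high"


def categorize_nlr(neutrophils: float, lymphocytes: float) -> tuple[float, str]:
    """Neutrophil-to-lymphocyte ratio and its binary category.

    The ratio is ``normal`` inside the closed interval [1, 4]; values below 1
    or above 4 are both ``abnormal``.
    """
    if neutrophils <= 0 or lymphocytes <= 0:
        raise ValueError(
            f"cell counts must be positive, got ({neutrophils}, {lymphocytes})"
        )
    value = neutrophils / lymphocytes
    return value, categorize_nlr_value(value)


def categorize_nlr_value(value: float) -> str:
    return "normal" if 1.0 <= value <= 4.0 else "abnormal"


def derive_age_group(age_years: float, cutoff: float = 65.0) -> str:
    """Dichotomize age: ``older`` iff age >= cutoff (default 65), else ``younger``."""
    if age_years < 18:
        logger.warning("age %.1f below 18; classified anyway", age_years)
    return "older" if age_years >= cutoff else "younger"


def derive_pre_target(prior_treatment: str) -> str:
    return "yes" if prior_treatment in TARGET_GROUPS else "no"


def complete_case_filter(
    cohort: CohortTable,
    required_variables: Sequence[str] = CLICAL_VARIABLES,
) -> CohortTable:
    """Keep only records with no missing value among ``required_variables``.

    Order-preserving and idempotent.  Per-variable removal counts are logged;
    an empty result is a warning, not an error.
    """
    df = cohort.data
    keep = pd.Series(True, index=df.index)
    for var in required_variables:
        missing = df[var].isin(MISSING_TOKENS) | df[var].isna()
        if missing.any():
            logger.info("complete-case filter: %d record(s) missing %s", int(missing.sum()), var)
        keep &= ~missing
    out = df.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("complete-case filter removed every record")
    return CohortTable(out, provenance=cohort.provenance)


def _format_number(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    f = float(x)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return f"{f:.6g}"


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV in the canonical column order.

    Floats are rendered to 6 significant digits so write/read round-trips are
    byte-stable.
    """
    df = cohort.data.copy()
    for col in _NUMERIC_COLUMNS:
        df[col] = df[col].map(_format_number)
    df["os_event"] = df["os_event"].map(lambda v: str(int(v)))
    df[list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort(path, validate: bool = True, provenance: str | None = None) -> CohortTable:
    """Read a cohort CSV, normalizing category tokens and deriving categories.

    Derived columns (``age_group``, ``ldh_category``, ``nlr_value``,
    ``nlr_category``, ``pre_target``) are recomputed whenever the raw inputs
    are present; a disagreement with a stored category is a warning, not an
    error.  Missing mandatory columns raise :class:`CohortValidationError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mandatory = {"patient_id", "os_months", "os_event"}
    missing_cols = mandatory - set(df.columns)
    if missing_cols:
        raise CohortValidationError(f"missing mandatory column(s): {sorted(missing_cols)}")
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    for col, levels in CATEGORY_LEVELS.items():
        df[col] = df[col].map(normalize_token)
        # braf's missing token is "untested", not "unknown"
        if col == "braf":
            df[col] = df[col].replace({"unknown": "untested"})
        bad = ~df[col].isin(levels) & (df[col] != "unknown")
        if col in ("age_group", "pre_target", "ldh_category", "nlr_category"):
            # may be derivable below; tolerate blank here
            bad &= df[col] != ""
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"unknown token {df[col].iloc[row]!r} in column {col!r} (row {row})"
            )
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col].mask(df[col] == "", np.nan), errors="raise")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="raise").astype(int)

    _derive_columns(df)
    df = df[list(COHORT_COLUMNS)]
    cohort = CohortTable(df, provenance=provenance or str(path))
    if validate:
        cohort.validate()
    return cohort


def _derive_columns(df: pd.DataFrame) -> None:
    """Recompute derived columns in place where raw inputs are available."""

    def recompute(col, raw_mask, values):
        stored = df[col].copy()
        df.loc[raw_mask, col] = values[raw_mask]
        had = raw_mask & ~stored.isin(MISSING_TOKENS) & (stored != "")
        clash = had & (stored != df[col])
        if clash.any():
            logger.warning(
                "%d stored %s value(s) disagree with raw inputs; recomputed", int(clash.sum()), col
            )

    has_age = df["age_years"].notna()
    recompute("age_group", has_age, df["age_years"].map(lambda a: derive_age_group(a) if pd.notna(a) else ""))

    has_ldh = df["ldh_ratio"].notna()
    recompute("ldh_category", has_ldh, df["ldh_ratio"].map(lambda r: categorize_ldh_ratio(r) if pd.notna(r) else ""))

    has_counts = df["neutrophils"].notna() & df["lymphocytes"].notna()
    if has_counts.any():
        df.loc[has_counts, "nlr_value"] = (
            df.loc[has_counts, "neutrophils"] / df.loc[has_counts, "lymphocytes"]
        )
    has_nlr = df["nlr_value"].notna()
    recompute("nlr_category", has_nlr, df["nlr_value"].map(lambda v: categorize_nlr_value(v) if pd.notna(v) else ""))

    recompute(
        "pre_target",
        pd.Series(True, index=df.index),
        df["prior_treatment"].map(derive_pre_target),
    )

    # remaining blanks become explicit missing tokens
    for col, levels in CATEGORY_LEVELS.items():
        blank = df[col] == ""
        if blank.any():
            token = "untested" if col == "braf" else "unknown"
            if token not in levels:
                raise CohortValidationError(f"column {col!r} has blank entries and no missing token")
            df.loc[blank, col] = token
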