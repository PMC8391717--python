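"""Weighted categorical prognostic score and the score-to-signature grouping.

Each of seven clinical variables contributes an integer weight: 1 for its
unfavorable category, 2 for favorable, and 3 for the most favorable LDH level
(the only three-level variable).  The score is the weight sum divided by the
number of variables, kept as an exact rational internally and rendered to
three decimals at I/O.  Adjacent score levels with similar survival are merged
into five ordered signatures, I (worst) through V (best).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .cohort import CLICAL_VARIABLES, MISSING_TOKENS, CohortTable

__all__ = [
    "WeightScheme",
    "ClicalResult",
    "SignatureMap",
    "IncompleteRecordError",
    "default_weight_scheme",
    "default_signature_map",
    "compute_score",
    "assign_signature",
    "score_cohort",
    "SIGNATURE_LABELS",
]

SIGNATURE_LABELS = ("I", "II", "III", "IV", "V")


class IncompleteRecordError(ValueError):
    """A record has a missing value in a scored variable."""


@dataclass(frozen=True)
class WeightScheme:
    """Per-variable category -> integer weight map.

    Weight 1 marks the unfavorable (high-risk) category; 2 the favorable one;
    the three-level LDH variable adds weight 3 for its best category.
    """

    weights: Mapping[str, Mapping[str, int]]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.weights)

    @property
    def n_variables(self) -> int:
        return len(self.weights)

    def __post_init__(self) -> None:
        for var, table in self.weights.items():
            for cat, w in table.items():
                if w not in (1, 2, 3):
                    raise ValueError(f"weight {w} for {var}={cat} outside {{1,2,3}}")

    def min_sum(self) -> int:
        return sum(min(t.values()) for t in self.weights.values())

    def max_sum(self) -> int:
        return sum(max(t.values()) for t in self.weights.values())

    def to_dict(self) -> dict:
        return {v: dict(t) for v, t in self.weights.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "WeightScheme":
        return cls({v: {c: int(w) for c, w in t.items()} for v, t in d.items()})


def default_weight_scheme() -> WeightScheme:
    """The seven-variable default scheme.

    Age direction is deliberate: the younger group carries the unfavorable
    weight.  CNS involvement is the seventh (binary) variable completing the
    x/7 arithmetic.
    """
    return WeightScheme(
        {
            "age_group": {"younger": 1, "older": 2},
            "braf": {"mutated": 1, "wildtype": 2},
            "pre_target": {"yes": 1, "no": 2},
            "ldh_category": {"very_high": 1, "high": 2, "normal": 3},
            "nlr_category": {"abnormal": 1, "normal": 2},
            "eosinophil_category": {"elevated": 1, "normal": 2},
            "cns_met": {"yes": 1, "no": 2},
        }
    )


@dataclass(frozen=True)
class SignatureMap:
    """Weight-sum boundaries -> signature labels, monotone by construction.

    ``cuts[k]`` is the (inclusive) upper weight-sum bound of signature
    ``labels[k]``; the last bound must cover the scheme's maximum sum.
    """

    cuts: tuple[int, ...] = (9, 10, 11, 13, 15)
    labels: tuple[str, ...] = SIGNATURE_LABELS

    def __post_init__(self) -> None:
        if len(self.cuts) != len(self.labels):
            raise ValueError("cuts and labels must align")
        if list(self.cuts) != sorted(self.cuts):
            raise ValueError("cuts must be increasing")

    def assign(self, weight_sum: int) -> str:
        for cut, label in zip(self.cuts, self.labels):
            if weight_sum <= cut:
                return label
        raise ValueError(f"weight sum {weight_sum} above the top boundary {self.cuts[-1]}")


def default_signature_map() -> SignatureMap:
    return SignatureMap()


@dataclass(frozen=True)
class ClicalResult:
    """Integer weight sum, exact rational score and signature label."""

    weight_sum: int
    score: Fraction
    signature: str

    @property
    def score_3dp(self) -> float:
        """Score rendered to three decimals, the table convention."""
        return round(float(self.score), 3)


def compute_score(
    record: Mapping[str, str],
    scheme: WeightScheme | None = None,
    signature_map: SignatureMap | None = None,
) -> ClicalResult:
    """Score one record: sum the per-variable weights and divide by their count.

    Raises :class:`IncompleteRecordError` naming the variable if any scored
    variable is missing or carries an unweighted category.
    """
    scheme = scheme or default_weight_scheme()
    signature_map = signature_map or default_signature_map()
    total = 0
    for var, table in scheme.weights.items():
        try:
            cat = record[var]
        except (KeyError, IndexError) as exc:
            raise IncompleteRecordError(f"record lacks variable {var!r}") from exc
        if cat in MISSING_TOKENS or cat not in table:
            raise IncompleteRecordError(
                f"variable {var!r} has unscoreable value {cat!r}"
            )
        total += table[cat]
    score = Fraction(total, scheme.n_variables)
    return ClicalResult(total, score, signature_map.assign(total))


def assign_signature(score: Fraction | float, signature_map: SignatureMap | None = None,
                     n_variables: int = 7) -> str:
    """Map a score (multiple of 1/n_variables) to its signature label."""
    signature_map = signature_map or default_signature_map()
    frac = Fraction(score).limit_denominator(10**6) if not isinstance(score, Fraction) else score
    weight_sum = frac * n_variables
    if weight_sum.denominator != 1:
        # tolerate 3-decimal renderings such as 1.571
        nearest = round(float(score) * n_variables)
        if abs(float(score) * n_variables - nearest) > 5e-3 * n_variables:
            raise ValueError(f"score {score} is not a multiple of 1/{n_variables}")
        weight_sum = Fraction(nearest)
    return signature_map.assign(int(weight_sum))


def score_cohort(
    cohort: CohortTable,
    scheme: WeightScheme | None = None,
    signature_map: SignatureMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every record of a complete-case cohort.

    Returns ``(scores, summary)``: per-patient rows
    ``(patient_id, weight_sum, score, signature)`` and a per-score-level
    summary with signature totals in the published table layout.
    """
    scheme = scheme or default_weight_scheme()
    signature_map = signature_map or default_signature_map()
    rows = []
    for _, rec in cohort.data.iterrows():
        try:
            res = compute_score(rec, scheme, signature_map)
        except IncompleteRecordError as exc:
            raise IncompleteRecordError(f"patient {rec['patient_id']!r}: {exc}") from exc
        rows.append((rec["patient_id"], res.weight_sum, res.score_3dp, res.signature))
    scores = pd.DataFrame(rows, columns=["patient_id", "weight_sum", "score", "signature"])
    summary = summarize_levels(
        scores["weight_sum"].value_counts().to_dict(), scheme, signature_map
    )
    return scores, summary


def score_frame(
    df: pd.DataFrame,
    scheme: WeightScheme | None = None,
    signature_map: SignatureMap | None = None,
) -> pd.DataFrame:
    """Vectorized scoring of a complete-case DataFrame.

    Same arithmetic as :func:`compute_score`; raises
    :class:`IncompleteRecordError` if any scored cell is unweighted.
    """
    scheme = scheme or default_weight_scheme()
    signature_map = signature_map or default_signature_map()
    total = pd.Series(0, index=df.index, dtype=int)
    for var, table in scheme.weights.items():
        w = df[var].map(table)
        if w.isna().any():
            bad = df.loc[w.isna(), var].iloc[0]
            raise IncompleteRecordError(f"variable {var!r} has unscoreable value {bad!r}")
        total += w.astype(int)
    out = pd.DataFrame(index=df.index)
    out["weight_sum"] = total
    out["score"] = (total / scheme.n_variables).round(3)
    out["signature"] = total.map(signature_map.assign)
    return out


def summarize_levels(
    level_counts: Mapping[int, int],
    scheme: WeightScheme | None = None,
    signature_map: SignatureMap | None = None,
) -> pd.DataFrame:
    """Tabulate per-score-level counts with signature totals and percentages.

    ``level_counts`` maps integer weight sums to patient counts (so published
    per-level tallies can be summarized without patient-level data).
    """
    scheme = scheme or default_weight_scheme()
    signature_map = signature_map or default_signature_map()
    n = scheme.n_variables
    total = sum(level_counts.values())
    rows = []
    for ws in sorted(level_counts):
        sig = signature_map.assign(int(ws))
        rows.append(
            {
                "weight_sum": int(ws),
                "score": round(ws / n, 3),
                "n": int(level_counts[ws]),
                "signature": sig,
            }
        )
    df = pd.DataFrame(rows, columns=["weight_sum", "score", "n", "signature"])
    if len(df):
        sig_totals = df.groupby("signature")["n"].transform("sum")
        df["signature_n"] = sig_totals
        df["signature_pct"] = (100.0 * sig_totals / total).round(1)
    else:
        df["signature_n"] = pd.Series(dtype=int)
        df["signature_pct"] = pd.Series(dtype=float)
    return df
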