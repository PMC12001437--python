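"""qMSP marker evaluation: Ct calling, sensitivity/specificity screens, accuracy ranking.

A qMSP well is called positive when its cycle threshold (Ct) is strictly
below the cutoff (default 45 cycles); a well that never amplifies carries
the NA sentinel (NaN in memory) and is always negative.  Candidate markers
are screened in two steps mirroring a typical assay-development workflow:
a technical filter (sensitivity > 60% in tumor cell lines AND specificity
> 80% in non-cancerous urine, both strict), then an accuracy ranking on a
mixed clinical cohort from which the top ``n_select`` markers are taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenParams",
    "call_marker",
    "marker_sensitivity_specificity",
    "filter_candidates",
    "accuracy_rank",
    "validate_ct_table",
]

CT_SENTINEL_TOKENS = {"NA", "", None}


@dataclass(frozen=True)
class ScreenParams:
    ct_cutoff: float = 45.0
    cellline_sens_min: float = 0.60
    urine_spec_min: float = 0.80
    n_select: int = 3

    def __post_init__(self) -> None:
        for name in ("cellline_sens_min", "urine_spec_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.ct_cutoff <= 0:
            raise ValueError("ct_cutoff must be positive")
        if self.n_select <= 0:
            raise ValueError("n_select must be positive")


def call_marker(ct_value: float | None, cutoff: float = 45.0) -> bool:
    """Binary qMSP call: positive iff a numeric Ct is strictly below cutoff.

    The no-amplification sentinel (None or NaN) is negative.  A negative
    or infinite numeric Ct is physically impossible and raises.
    """
    if ct_value is None:
        return False
    ct = float(ct_value)
    if math.isnan(ct):
        return False
    if math.isinf(ct) or ct <= 0:
        raise ValueError(f"invalid Ct value: {ct_value!r}")
    return ct < cutoff


def validate_ct_table(table: pd.DataFrame, ct_cutoff: float = 45.0) -> pd.DataFrame:
    """Check CtTable structure: required columns, unique (sample, marker) pairs,
    numeric Ct in (0, cutoff).  Returns the table unchanged."""
    required = {"sample_id", "group", "marker", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["sample_id", "marker"])
    if dup.any():
        pairs = table.loc[dup, ["sample_id", "marker"]].to_records(index=False)
        raise ValueError(f"duplicate (sample, marker) rows: {list(pairs)[:5]}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    numeric = table["ct"].notna() if table["ct"].dtype.kind == "f" else ct.notna()
    bad = numeric & (~np.isfinite(ct) | (ct <= 0) | (ct >= ct_cutoff))
    if bad.any():
        raise ValueError(
            f"numeric Ct values must lie in (0, {ct_cutoff}); offending rows: "
            f"{table.index[bad].tolist()[:5]} (use the NA sentinel for no amplification)"
        )
    return table


def _calls_for_marker(table: pd.DataFrame, marker: str, cutoff: float) -> pd.DataFrame:
    sub = table[table["marker"] == marker]
    if sub.empty:
        raise ValueError(f"marker {marker!r} absent from Ct table")
    calls = sub["ct"].map(lambda v: call_marker(v, cutoff))
    return sub.assign(call=calls)


def marker_sensitivity_specificity(
    table: pd.DataFrame,
    marker: str,
    positive_groups: Sequence[str],
    negative_groups: Sequence[str],
    params: ScreenParams = ScreenParams(),
) -> tuple[float, float]:
    """Positive-call fraction among positive groups and negative-call
    fraction among negative groups, at the configured Ct cutoff."""
    sub = _calls_for_marker(table, marker, params.ct_cutoff)
    pos = sub[sub["group"].isin(positive_groups)]
    neg = sub[sub["group"].isin(negative_groups)]
    if pos.empty or neg.empty:
        raise ValueError("both positive and negative groups must be present in the table")
    sensitivity = float(pos["call"].mean())
    specificity = float((~neg["call"]).mean())
    return sensitivity, specificity


def filter_candidates(
    table: pd.DataFrame,
    markers: Sequence[str],
    positive_groups: Sequence[str],
    negative_groups: Sequence[str],
    params: ScreenParams = ScreenParams(),
) -> list[str]:
    """Markers passing both technical screens (strict inequalities)."""
    survivors = []
    for m in markers:
        sens, spec = marker_sensitivity_specificity(
            table, m, positive_groups, negative_groups, params
        )
        if sens > params.cellline_sens_min and spec > params.urine_spec_min:
            survivors.append(m)
    return survivors


def accuracy_rank(
    table: pd.DataFrame,
    markers: Sequence[str],
    truth_groups: Sequence[str],
    params: ScreenParams = ScreenParams(),
) -> pd.DataFrame:
    """Rank markers by diagnostic accuracy on a labeled cohort.

    ``truth_groups`` names the positive (UC) groups; everything else in
    the table is a negative.  Accuracy is (TP + TN) / N.  Ties break by
    higher sensitivity, then marker name; the top ``n_select`` rows carry
    ``selected=True``.
    """
    if table["group"].isna().any():
        bad = table.index[table["group"].isna()].tolist()[:5]
        raise ValueError(f"unlabeled samples at rows {bad}")
    rows = []
    for m in markers:
        sub = _calls_for_marker(table, m, params.ct_cutoff)
        is_pos = sub["group"].isin(truth_groups)
        tp = int((sub["call"] & is_pos).sum())
        tn = int((~sub["call"] & ~is_pos).sum())
        n = len(sub)
        sens = tp / max(int(is_pos.sum()), 1)
        rows.append({"marker": m, "accuracy": (tp + tn) / n, "sensitivity": sens,
                     "tp": tp, "tn": tn, "n": n})
    out = pd.DataFrame(rows).sort_values(
        by=["accuracy", "sensitivity", "marker"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out["rank"] = out.index + 1
    out["selected"] = out["rank"] <= params.n_select
    return out
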