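"""Diagnostic-performance evaluation for multi-group case/control cohorts.

The positive class is the urothelial-cancer (UC) group; the negative side of
the cohort is heterogeneous (non-neoplastic urinary-tract disorders, benign
lesions, other cancers), so specificity is reported both per group and as the
true-negative-weighted pool across all negative groups.  All point estimates
are carried as exact integer ratios; confidence intervals are exact two-sided
binomial (Clopper-Pearson) intervals.  Percent rendering uses
round-half-away-from-zero at two decimals, matching the convention of
clinical reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta_dist

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "confusion",
    "metrics",
    "clopper_pearson",
    "stage_stratified_sensitivity",
    "pattern_and_overlap_tables",
    "reconstruct_counts",
    "recover_counts",
    "render_percent",
]

UNKNOWN_STAGE = "unknown"


def render_percent(x: float | Fraction, decimals: int = 2) -> str:
    """Render a fraction in [0, 1] as a percentage string.

    Rounding is half-away-from-zero (so 102/108 renders "94.44", and
    0.125 at one decimal renders "12.5").
    """
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator) * 100
    else:
        d = Decimal(repr(float(x))) * 100
    q = Decimal(1).scaleb(-decimals)
    return str(d.quantize(q, rounding=ROUND_HALF_UP))


def _round_half_up(value: Decimal) -> int:
    return int(value.quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Confusion counts for one positive group against named negative groups.

    ``tp + fn`` equals the positive-group size; for each negative group g,
    ``tn_by_group[g] + fp_by_group[g]`` equals that group's size.
    """

    tp: int
    fn: int
    tn_by_group: dict[str, int]
    fp_by_group: dict[str, int]

    def __post_init__(self) -> None:
        counts = [self.tp, self.fn, *self.tn_by_group.values(), *self.fp_by_group.values()]
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if set(self.tn_by_group) != set(self.fp_by_group):
            raise ValueError("tn_by_group and fp_by_group must share the same groups")

    @property
    def tn(self) -> int:
        return sum(self.tn_by_group.values())

    @property
    def fp(self) -> int:
        return sum(self.fp_by_group.values())

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative


@dataclass
class PerformanceReport:
    """Point estimates (exact ratios) with exact 95% binomial CIs.

    Each metric is a ``(Fraction, (lo, hi), (x, n))`` triple — the exact
    value, the Clopper-Pearson bounds, and the unreduced integer counts;
    a metric whose denominator is zero is ``None`` rather than raising.
    """

    sensitivity: tuple[Fraction, tuple[float, float], tuple[int, int]] | None
    specificity_overall: tuple[Fraction, tuple[float, float], tuple[int, int]] | None
    specificity_per_group: dict[str, tuple[Fraction, tuple[float, float], tuple[int, int]]]
    accuracy: tuple[Fraction, tuple[float, float], tuple[int, int]] | None
    ppv: tuple[Fraction, tuple[float, float], tuple[int, int]] | None
    npv: tuple[Fraction, tuple[float, float], tuple[int, int]] | None
    stage_sensitivities: dict[str, tuple[int, int, Fraction, tuple[float, float]]] = field(
        default_factory=dict
    )
    pattern_counts: pd.DataFrame | None = None
    overlap_counts: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-ready summary: percentages at 2 decimals plus exact counts."""
        out: dict = {}

        def pack(entry):
            if entry is None:
                return None
            frac, (lo, hi), (x, n) = entry
            return {
                "x": x,
                "n": n,
                "percent": float(render_percent(frac)),
                "ci95_percent": [float(render_percent(lo)), float(render_percent(hi))],
            }

        out["sensitivity"] = pack(self.sensitivity)
        out["specificity_overall"] = pack(self.specificity_overall)
        out["specificity_per_group"] = {g: pack(v) for g, v in self.specificity_per_group.items()}
        out["accuracy"] = pack(self.accuracy)
        out["ppv"] = pack(self.ppv)
        out["npv"] = pack(self.npv)
        out["stage_sensitivities"] = {
            s: {
                "x": x,
                "n": n,
                "percent": float(render_percent(frac)),
                "ci95_percent": [float(render_percent(lo)), float(render_percent(hi))],
            }
            for s, (x, n, frac, (lo, hi)) in self.stage_sensitivities.items()
        }
        out["warnings"] = list(self.warnings)
        return out


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval.

    Bounds are the beta-distribution quantiles
    ``lo = B(alpha/2; x, n-x+1)`` and ``hi = B(1-alpha/2; x+1, n-x)``
    with the conventions ``lo = 0`` at x = 0 and ``hi = 1`` at x = n.
    """
    if n < 1 or x < 0 or x > n:
        raise ValueError(f"invalid counts x={x}, n={n}")
    if not (0 < conf < 1):
        raise ValueError("conf must be in (0, 1)")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(_beta_dist.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(_beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def confusion(calls: pd.DataFrame, positive_group: str = "UC",
              negative_groups: Sequence[str] | None = None) -> ConfusionMatrix:
    """Tally per-group confusion counts from a per-sample call table.

    ``calls`` needs columns ``sample_id, group, call`` (call is boolean).
    Groups other than ``positive_group`` are treated as negatives unless
    ``negative_groups`` restricts them; an unexpected group label raises.
    """
    if calls.empty:
        raise ValueError("empty call table")
    required = {"sample_id", "group", "call"}
    if not required.issubset(calls.columns):
        raise ValueError(f"call table must have columns {sorted(required)}")
    groups = set(calls["group"].unique())
    if positive_group not in groups:
        raise ValueError(f"positive group {positive_group!r} absent from call table")
    if negative_groups is None:
        negative_groups = sorted(groups - {positive_group})
    else:
        unknown = groups - {positive_group} - set(negative_groups)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
    pos = calls[calls["group"] == positive_group]
    tp = int(pos["call"].sum())
    fn = len(pos) - tp
    tn_by_group, fp_by_group = {}, {}
    for g in negative_groups:
        sub = calls[calls["group"] == g]
        fp_g = int(sub["call"].sum())
        fp_by_group[g] = fp_g
        tn_by_group[g] = len(sub) - fp_g
    return ConfusionMatrix(tp=tp, fn=fn, tn_by_group=tn_by_group, fp_by_group=fp_by_group)


def _ratio_ci(x: int, n: int) -> tuple[Fraction, tuple[float, float], tuple[int, int]] | None:
    if n == 0:
        return None
    return Fraction(x, n), clopper_pearson(x, n), (x, n)


def metrics(cm: ConfusionMatrix) -> PerformanceReport:
    """Standard diagnostic metrics from confusion counts.

    Overall specificity pools true negatives across negative groups
    (never the unweighted mean of per-group specificities).
    """
    per_group = {}
    for g, tn_g in cm.tn_by_group.items():
        n_g = tn_g + cm.fp_by_group[g]
        entry = _ratio_ci(tn_g, n_g)
        if entry is not None:
            per_group[g] = entry
    return PerformanceReport(
        sensitivity=_ratio_ci(cm.tp, cm.tp + cm.fn),
        specificity_overall=_ratio_ci(cm.tn, cm.tn + cm.fp),
        specificity_per_group=per_group,
        accuracy=_ratio_ci(cm.tp + cm.tn, cm.total),
        ppv=_ratio_ci(cm.tp, cm.tp + cm.fp),
        npv=_ratio_ci(cm.tn, cm.tn + cm.fn),
    )


def stage_stratified_sensitivity(
    calls: pd.DataFrame,
    positive_group: str = "UC",
    unknown_label: str = UNKNOWN_STAGE,
) -> dict[str, tuple[int, int, Fraction, tuple[float, float]]]:
    """Per-stage positive fraction among UC samples, with exact 95% CIs.

    Samples whose stage is the ``unknown_label`` (or missing) are excluded;
    the exclusion count is emitted as a warning so it is never silent.
    """
    pos = calls[calls["group"] == positive_group]
    staged = pos[pos["stage"].notna() & (pos["stage"] != unknown_label)]
    n_dropped = len(pos) - len(staged)
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} {positive_group} samples without stage", stacklevel=2)
    out: dict[str, tuple[int, int, Fraction, tuple[float, float]]] = {}
    for stage, sub in staged.groupby("stage", sort=True):
        n = len(sub)
        if n == 0:
            continue
        x = int(sub["call"].sum())
        out[str(stage)] = (x, n, Fraction(x, n), clopper_pearson(x, n))
    return out


def pattern_and_overlap_tables(
    calls: pd.DataFrame,
    markers: Sequence[str],
    positive_group: str = "UC",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call-pattern and marker-overlap tabulations.

    ``calls`` must carry one boolean column per marker (the per-marker
    calls) besides ``group``.  Returns

    * pattern_counts — exact-pattern counts (e.g. ``VIM+TMEM220-PPM1N-``)
      split by clinical group; every sample is counted in exactly one
      pattern, so the table sums to the cohort size;
    * overlap_counts — per marker subset, the number of positive-group
      samples positive for exactly that subset and for at least that
      subset.  The union over single markers of "at least" counts equals
      the model's true-positive count.
    """
    missing = [m for m in markers if m not in calls.columns]
    if missing:
        raise ValueError(f"per-marker call columns missing: {missing}")
    flags = calls[list(markers)].astype(bool)
    pattern = flags.apply(
        lambda row: "".join(f"{m}{'+' if row[m] else '-'}" for m in markers), axis=1
    )
    pattern_counts = (
        pd.crosstab(pattern, calls["group"]).rename_axis(index="pattern", columns="group")
    )

    pos_flags = flags[calls["group"] == positive_group]
    rows = []
    n_markers = len(markers)
    for mask in range(1, 2**n_markers):
        subset = tuple(markers[i] for i in range(n_markers) if mask >> i & 1)
        in_subset = np.array([(mask >> i & 1) == 1 for i in range(n_markers)])
        vals = pos_flags.to_numpy()
        exactly = int(np.all(vals == in_subset, axis=1).sum())
        at_least = int(np.all(vals[:, in_subset], axis=1).sum()) if in_subset.any() else 0
        rows.append({"subset": "+".join(subset), "exactly": exactly, "at_least": at_least})
    overlap_counts = pd.DataFrame(rows).set_index("subset")
    return pattern_counts, overlap_counts


def reconstruct_counts(
    group_sizes: Mapping[str, int],
    printed_rates: Mapping[str, float],
    tp_or_sens: float | int,
    positive_group: str = "UC",
) -> tuple[ConfusionMatrix, list[str]]:
    """Rebuild integer confusion counts from published summary rates.

    Per negative group, ``tn_g = round(rate_g * n_g)`` with half rounded
    away from zero; the positive side takes ``tp`` directly when
    ``tp_or_sens`` is an integer, else ``tp = round(sens * n_pos)``.
    Each rate is re-rendered from the integer count; a mismatch at two
    decimals is reported as a warning string (summary tables occasionally
    print a rate no integer count reproduces).
    """
    for g, r in printed_rates.items():
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"rate for group {g!r} outside [0, 1]: {r}")
    if positive_group not in group_sizes:
        raise ValueError(f"positive group {positive_group!r} missing from group_sizes")
    n_pos = group_sizes[positive_group]
    if isinstance(tp_or_sens, int):
        tp = tp_or_sens
    else:
        tp = _round_half_up(Decimal(repr(tp_or_sens)) * n_pos)
    if not (0 <= tp <= n_pos):
        raise ValueError(f"tp={tp} incompatible with positive group size {n_pos}")

    notes: list[str] = []
    tn_by_group, fp_by_group = {}, {}
    for g, rate in printed_rates.items():
        if g not in group_sizes:
            raise ValueError(f"group {g!r} has a rate but no size")
        n_g = group_sizes[g]
        tn_g = _round_half_up(Decimal(repr(rate)) * n_g)
        tn_by_group[g] = tn_g
        fp_by_group[g] = n_g - tn_g
        rendered = render_percent(Fraction(tn_g, n_g))
        printed = render_percent(rate)
        if rendered != printed:
            notes.append(
                f"group {g!r}: printed rate {printed}% not reproduced by any integer count; "
                f"carrying {tn_g}/{n_g} = {rendered}%"
            )
    cm = ConfusionMatrix(tp=tp, fn=n_pos - tp, tn_by_group=tn_by_group, fp_by_group=fp_by_group)
    return cm, notes


def _decimals(printed: str) -> int:
    s = printed.strip().rstrip("%")
    return len(s.split(".")[1]) if "." in s else 0


def recover_counts(
    printed_pct: str,
    printed_ci: tuple[str, str],
    n_max: int = 200,
    conf: float = 0.95,
) -> list[tuple[int, int]]:
    """Recover (successes, trials) from a printed percentage-plus-CI triple.

    Exhaustively searches x <= n <= n_max for counts whose point estimate
    and Clopper-Pearson bounds re-render, at the decimal precision of each
    printed string, to the printed values.  Returns every consistent pair;
    a caller asserting uniqueness should check ``len(result) == 1``.
    """
    pct_dec = _decimals(printed_pct)
    lo_str, hi_str = printed_ci
    lo_dec, hi_dec = _decimals(lo_str), _decimals(hi_str)
    want = (
        printed_pct.strip().rstrip("%"),
        lo_str.strip().rstrip("%"),
        hi_str.strip().rstrip("%"),
    )
    hits = []
    for n in range(1, n_max + 1):
        for x in range(0, n + 1):
            if render_percent(Fraction(x, n), pct_dec) != want[0]:
                continue
            lo, hi = clopper_pearson(x, n, conf)
            if render_percent(lo, lo_dec) != want[1]:
                continue
            if render_percent(hi, hi_dec) != want[2]:
                continue
            hits.append((x, n))
    return hits
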