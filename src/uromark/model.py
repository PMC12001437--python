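"""The three-marker parallel (OR-rule) urothelial-cancer classifier.

A sample is called UC-positive if ANY of the panel markers amplifies below
the Ct cutoff, and negative only when all markers are negative.  The
continuous companion of the rule is the per-marker risk score
``cutoff - Ct`` (0 for non-amplifying wells) combined by max across
markers: thresholding the combined score at any level t reproduces the OR
rule with per-marker Ct cutoff ``cutoff - t``, so its ROC curve is the
operating family of the parallel rule itself.  A maximum-likelihood
logistic regression on the per-marker scores is provided as a comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .screen import call_marker

__all__ = ["DiagnosticRule", "classify", "risk_scores", "roc_curve", "logistic_comparator"]

DEFAULT_MARKERS = ("VIM", "TMEM220", "PPM1N")


@dataclass(frozen=True)
class DiagnosticRule:
    """Marker panel + Ct cutoff + combination logic (parallel OR)."""

    markers: tuple[str, ...] = DEFAULT_MARKERS
    ct_cutoff: float = 45.0
    combination: str = "parallel_or"

    def __post_init__(self) -> None:
        if len(self.markers) < 1:
            raise ValueError("rule needs at least one marker")
        if self.ct_cutoff <= 0:
            raise ValueError("ct_cutoff must be positive")
        if self.combination != "parallel_or":
            raise ValueError(f"unknown combination rule: {self.combination}")


def _wide_ct(table: pd.DataFrame, rule: DiagnosticRule) -> pd.DataFrame:
    """Pivot the long Ct table to samples x markers, erroring on omissions."""
    sub = table[table["marker"].isin(rule.markers)]
    wide = sub.pivot(index="sample_id", columns="marker", values="ct")
    missing_cols = [m for m in rule.markers if m not in wide.columns]
    if missing_cols:
        raise ValueError(f"markers absent from table: {missing_cols}")
    # a sample missing a marker row shows up as a column NaN only if other
    # markers exist for it; distinguish from the NA sentinel via row counts
    counts = sub.groupby("sample_id")["marker"].nunique()
    short = counts[counts < len(rule.markers)]
    if len(short):
        raise ValueError(
            f"samples missing marker rows: {short.index.tolist()[:5]}"
        )
    return wide[list(rule.markers)]


def _sample_meta(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("group", "stage") if c in table.columns]
    return table.drop_duplicates("sample_id").set_index("sample_id")[cols]


def classify(table: pd.DataFrame, rule: DiagnosticRule = DiagnosticRule()) -> pd.DataFrame:
    """Per-sample OR-rule calls with the per-marker call pattern.

    Returns one row per sample: group/stage metadata, one boolean column
    per marker, the pattern string (e.g. ``VIM+TMEM220-PPM1N-``) and the
    combined boolean ``call``.
    """
    wide = _wide_ct(table, rule)
    calls = wide.apply(lambda col: col.map(lambda v: call_marker(v, rule.ct_cutoff)))
    pattern = calls.apply(
        lambda row: "".join(f"{m}{'+' if row[m] else '-'}" for m in rule.markers), axis=1
    )
    out = _sample_meta(table).reindex(wide.index)
    out[list(rule.markers)] = calls
    out["pattern"] = pattern
    out["call"] = calls.any(axis=1)
    return out.reset_index()


def risk_scores(table: pd.DataFrame, rule: DiagnosticRule = DiagnosticRule()) -> pd.DataFrame:
    """Per-marker risk score ``cutoff - Ct`` (0 when no amplification) and
    the combined per-sample score ``max`` over markers."""
    wide = _wide_ct(table, rule)
    scores = (rule.ct_cutoff - wide).clip(lower=0.0).fillna(0.0)
    out = _sample_meta(table).reindex(scores.index)
    out[list(rule.markers)] = scores
    out["combined"] = scores.max(axis=1)
    return out.reset_index()


def roc_curve(scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series
              ) -> tuple[pd.DataFrame, float]:
    """ROC over all score thresholds, AUC by trapezoid.

    ``labels`` is boolean (True = UC).  Tied scores move together, so the
    AUC equals the Mann-Whitney U statistic over pairs with half credit
    for ties.  Raises when only one class is present.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return points, auc


def logistic_comparator(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict:
    """Maximum-likelihood logistic regression on per-marker risk scores.

    Fits by Newton/IRLS; perfect separation is flagged rather than fatal
    (coefficients are then reported at the iteration cap).  Zero-variance
    features are dropped before fitting; if none remain the model is
    intercept-only with AUC 0.5.  Returns coefficients (including
    ``const``), the AUC of the fitted probabilities, and flags.
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("logistic comparator needs both classes present")
    kept = [c for c in features.columns if features[c].nunique() > 1]
    dropped = [c for c in features.columns if c not in kept]
    X = sm.add_constant(features[kept].astype(float), has_constant="add")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=False)
        except Exception:  # perfect separation aborts Newton in statsmodels
            separated = True
            res = model.fit(method="bfgs", maxiter=max_iter, disp=False)
        if not res.mle_retvals.get("converged", True):
            separated = separated or np.abs(res.params).max() > 50
    proba = res.predict(X)
    auc = 0.5 if not kept else float(roc_auc_score(y, proba))
    return {
        "coefficients": dict(res.params),
        "auc": auc,
        "separation_flag": separated,
        "dropped_features": dropped,
        "converged": bool(res.mle_retvals.get("converged", True)),
    }
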