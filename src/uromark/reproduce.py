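"""Recompute the published validation-cohort statistics from printed inputs.

The patient-level Ct data behind the published three-marker model are not
deposited, but every headline statistic is recomputable from the printed
summary numbers: group sizes and per-group specificity rates pin down the
integer confusion matrix (``reconstruct_counts``), from which sensitivity,
pooled specificity, PPV, NPV and accuracy follow as exact ratios; each
stage stratum's success/trial counts are uniquely recovered from its
printed percentage-plus-CI triple (``recover_counts``), and the exact
binomial bounds are then recomputed from those counts.  This module wires
those steps together from the bundled summary file.
"""

from __future__ import annotations

from fractions import Fraction
from importlib import resources

import yaml

from .performance import (
    clopper_pearson,
    metrics,
    reconstruct_counts,
    recover_counts,
    render_percent,
)

__all__ = ["published_summary", "reproduce_published_summary"]


def published_summary() -> dict:
    """The bundled published-cohort summary (printed sizes, rates, CIs)."""
    text = resources.files("uromark.data").joinpath("published_summary.yaml").read_text()
    return yaml.safe_load(text)


def reproduce_published_summary(summary: dict | None = None) -> dict:
    """Reconstruct counts, recompute all metrics and stage CIs.

    Returns a dict with the reconstructed confusion counts, recomputed
    headline metrics (percent, 2 decimals) side by side with the printed
    values, per-stratum recovered counts with recomputed exact CIs, the
    single-marker (VIM) worked examples, and any reconstruction warnings.
    """
    s = summary or published_summary()
    cm, notes = reconstruct_counts(
        group_sizes=s["group_sizes"],
        printed_rates=s["specificity_rates"],
        tp_or_sens=int(s["tp"]),
        positive_group=s["positive_group"],
    )
    rep = metrics(cm)

    def pct(entry) -> float:
        return float(render_percent(entry[0]))

    headline = {
        "sensitivity": pct(rep.sensitivity),
        "specificity_overall": pct(rep.specificity_overall),
        "ppv": pct(rep.ppv),
        "npv": pct(rep.npv),
        "accuracy": pct(rep.accuracy),
    }
    ratios = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity_overall": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }

    strata = {}
    for stage, printed in s["stage_strata"].items():
        hits = recover_counts(str(printed["percent"]), tuple(printed["ci"]),
                              n_max=s["group_sizes"][s["positive_group"]])
        entry: dict = {"printed": printed, "candidates": hits}
        if len(hits) == 1:
            x, n = hits[0]
            lo, hi = clopper_pearson(x, n)
            entry.update(
                x=x,
                n=n,
                percent=float(render_percent(Fraction(x, n))),
                ci_lo_percent=float(render_percent(lo)),
                ci_hi_percent=float(render_percent(hi)),
            )
        strata[stage] = entry

    n_uc = s["group_sizes"][s["positive_group"]]
    total = sum(s["group_sizes"].values())
    vim = {
        "sensitivity_percent": float(render_percent(Fraction(int(s["vim"]["tp"]), n_uc))),
        "accuracy_percent": float(render_percent(Fraction(int(s["vim"]["correct"]), total))),
    }

    return {
        "confusion": {
            "tp": cm.tp,
            "fn": cm.fn,
            "tn_by_group": dict(cm.tn_by_group),
            "fp_by_group": dict(cm.fp_by_group),
            "tn": cm.tn,
            "fp": cm.fp,
        },
        "metrics_percent": headline,
        "printed_percent": dict(s.get("printed_percent", {})),
        "exact_ratios": {k: f"{x}/{n}" for k, (x, n) in ratios.items()},
        "stage_strata": strata,
        "vim": vim,
        "warnings": notes,
    }
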