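"""Differential-methylation marker discovery cascade.

Three data streams feed the candidate funnel:

* a 450K-style beta-value matrix (tumor vs adjacent-normal tissue), from
  which hypermethylated probes are selected by a two-group test with
  Benjamini-Hochberg correction and a tumor-minus-normal effect-size
  threshold, then screened against a blood-leukocyte background panel
  (urinary cell-free DNA is contaminated by leukocyte DNA, so a usable
  marker must be unmethylated in leukocytes);
* WGBS-style per-CpG methylation calls, scanned in fixed-width genomic
  intervals for differential-site density and filtered site-wise on the
  tumor-minus-normal difference;
* a targeted panel built from promoters (2.5 kb upstream / 500 bp
  downstream of each TSS, strand-aware) merged with CpG-island, shore and
  shelf intervals, on which a urine-based differential analysis refines
  the candidate list.

All genomic coordinates are 0-based half-open; all printed thresholds are
applied as strict inequalities; selection is one-directional
(hypermethylated in tumor only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "DiscoveryParams",
    "DmpRecord",
    "GenomicInterval",
    "filter_probes_by_missingness",
    "differential_probes",
    "leukocyte_filter",
    "rank_and_select",
    "wgbs_interval_scan",
    "wgbs_differential_sites",
    "intersect_candidates",
    "build_panel_regions",
    "panel_urine_differential",
    "records_to_frame",
]


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with per-sample group labels.

    ``values`` is a DataFrame indexed by probe id with sample-id columns;
    missing measurements are NaN; non-missing entries lie in [0, 1].
    """

    values: pd.DataFrame
    group_of: pd.Series  # sample_id -> group label

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("probe ids must be unique")
        unlabeled = set(self.values.columns) - set(self.group_of.index)
        if unlabeled:
            raise ValueError(f"samples without group label: {sorted(unlabeled)[:5]}")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of.get(s) == group]

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)], self.group_of)


@dataclass(frozen=True)
class DiscoveryParams:
    """Every threshold of the discovery cascade, strict as printed."""

    missing_probe_max: float = 0.70
    p_adj_max: float = 0.01
    array_delta_min: float = 0.2
    leukocyte_mean_max: float = 0.1
    wgbs_delta_min: float = 0.1
    interval_size: int = 100_000
    interval_site_delta_min: float = 0.05
    top_k_array: int = 100
    top_k_intersect: int = 25

    def __post_init__(self) -> None:
        for name in ("missing_probe_max", "p_adj_max", "array_delta_min",
                     "leukocyte_mean_max", "wgbs_delta_min", "interval_site_delta_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("interval_size", "top_k_array", "top_k_intersect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DmpRecord:
    """One differentially methylated probe with its filter provenance."""

    probe_id: str
    mean_tumor: float
    mean_normal: float
    delta: float
    p_raw: float
    p_adj: float
    leukocyte_mean: float | None = None
    passes: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class GenomicInterval:
    chromosome: str
    start: int
    end: int
    n_sites: int
    n_differential: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")
        if self.n_differential > self.n_sites:
            raise ValueError("n_differential cannot exceed n_sites")


def records_to_frame(records: Sequence[DmpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "mean_tumor": [r.mean_tumor for r in records],
            "mean_normal": [r.mean_normal for r in records],
            "delta": [r.delta for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
            "leukocyte_mean": [r.leukocyte_mean for r in records],
            "passes": [",".join(sorted(r.passes)) for r in records],
        }
    )


def filter_probes_by_missingness(m: BetaMatrix, max_missing: float = 0.70) -> BetaMatrix:
    """Drop probes whose missing-value fraction exceeds ``max_missing``.

    Probes at exactly the threshold are retained ("exceeding" is strict);
    probe order is preserved.
    """
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    if m.values.empty:
        return m
    frac_missing = m.values.isna().mean(axis=1)
    keep = frac_missing[frac_missing <= max_missing].index
    return BetaMatrix(m.values.loc[keep], m.group_of)


def differential_probes(
    m: BetaMatrix,
    params: DiscoveryParams = DiscoveryParams(),
    tumor_group: str = "tumor",
    normal_group: str = "normal",
) -> list[DmpRecord]:
    """Per-probe Welch t-test on betas with BH correction.

    The ``significance`` flag requires BH-adjusted p < ``p_adj_max`` AND
    tumor-minus-normal mean difference > ``array_delta_min`` (strict,
    hypermethylated-in-tumor only).  BH correction spans every tested
    probe.  A probe with no variance in either group gets p = 1 when the
    group means are equal and p = 0 when they differ deterministically.
    """
    for g in (tumor_group, normal_group):
        if len(m.samples_in(g)) < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    tum = m.values[m.samples_in(tumor_group)].to_numpy(dtype=float)
    nor = m.values[m.samples_in(normal_group)].to_numpy(dtype=float)
    mean_t = np.nanmean(tum, axis=1)
    mean_n = np.nanmean(nor, axis=1)
    delta = mean_t - mean_n
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_raw = stats.ttest_ind(tum, nor, axis=1, equal_var=False, nan_policy="omit")
    p_raw = np.asarray(p_raw, dtype=float)
    # degenerate rows (zero variance both groups): exact tie -> 1, else 0
    bad = ~np.isfinite(p_raw)
    p_raw[bad] = np.where(np.isclose(delta[bad], 0.0), 1.0, 0.0)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    records = []
    for i, probe in enumerate(m.values.index):
        passes = set()
        if p_adj[i] < params.p_adj_max and delta[i] > params.array_delta_min:
            passes.add("significance")
        records.append(
            DmpRecord(
                probe_id=str(probe),
                mean_tumor=float(mean_t[i]),
                mean_normal=float(mean_n[i]),
                delta=float(delta[i]),
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                passes=passes,
            )
        )
    return records


def leukocyte_filter(
    records: Sequence[DmpRecord],
    leuko: BetaMatrix,
    max_mean: float = 0.1,
    leukocyte_group: str = "leukocyte",
) -> list[DmpRecord]:
    """Annotate records with the leukocyte background mean.

    The ``leukocyte`` flag is set iff the leukocyte mean is strictly
    below ``max_mean``.  Failing records stay in the output without the
    flag — selection happens in :func:`rank_and_select`.  Records whose
    probe is absent from the leukocyte matrix raise.
    """
    samples = leuko.samples_in(leukocyte_group) or list(leuko.values.columns)
    missing = [r.probe_id for r in records if r.probe_id not in leuko.values.index]
    if missing:
        raise ValueError(f"probes absent from leukocyte matrix: {missing[:10]}")
    means = leuko.values[samples].mean(axis=1, skipna=True)
    out = []
    for r in records:
        lm = float(means.loc[r.probe_id])
        passes = set(r.passes)
        if lm < max_mean:
            passes.add("leukocyte")
        out.append(
            DmpRecord(
                probe_id=r.probe_id,
                mean_tumor=r.mean_tumor,
                mean_normal=r.mean_normal,
                delta=r.delta,
                p_raw=r.p_raw,
                p_adj=r.p_adj,
                leukocyte_mean=lm,
                passes=passes,
            )
        )
    return out


def rank_and_select(records: Sequence[DmpRecord], k: int = 100) -> list[str]:
    """Top-k probe ids among records passing every applied filter.

    Ordering: descending delta, ties by ascending adjusted p, then
    lexicographic probe id.  A record must carry the ``significance``
    flag, and the ``leukocyte`` flag whenever its leukocyte mean was
    measured.
    """
    if k <= 0:
        raise ValueError("k must be positive")

    def survives(r: DmpRecord) -> bool:
        if "significance" not in r.passes:
            return False
        if r.leukocyte_mean is not None and "leukocyte" not in r.passes:
            return False
        return True

    ranked = sorted(
        (r for r in records if survives(r)),
        key=lambda r: (-r.delta, r.p_adj, r.probe_id),
    )
    return [r.probe_id for r in ranked[:k]]


def wgbs_interval_scan(
    sites: pd.DataFrame,
    params: DiscoveryParams = DiscoveryParams(),
    genome_layout: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Count differential CpGs per fixed-width genomic interval.

    ``sites`` needs columns ``chrom, start, mean_tumor, mean_normal``.
    Intervals are [i*w, (i+1)*w) anchored at position 0 per chromosome; a
    site qualifies when |tumor - normal| strictly exceeds
    ``interval_site_delta_min``.  Only intervals containing at least one
    site are emitted; the emitted differential counts partition the
    qualifying sites exactly.
    """
    w = params.interval_size
    if genome_layout is not None:
        for chrom, sub in sites.groupby("chrom"):
            limit = genome_layout.get(str(chrom))
            if limit is None:
                raise ValueError(f"chromosome {chrom!r} not in genome layout")
            beyond = sub["start"] >= limit
            if beyond.any():
                raise ValueError(
                    f"sites beyond {chrom} length {limit}: rows {sub.index[beyond].tolist()[:5]}"
                )
    # round at 1e-9 so printed decimal thresholds act as strict inequalities
    # despite binary float representation (0.55 - 0.50 must not exceed 0.05)
    delta = (sites["mean_tumor"] - sites["mean_normal"]).round(9)
    qualifying = delta.abs() > params.interval_site_delta_min
    idx = sites["start"] // w
    out = []
    grouped = sites.assign(_bin=idx, _q=qualifying).groupby(["chrom", "_bin"], sort=True)
    for (chrom, b), sub in grouped:
        out.append(
            GenomicInterval(
                chromosome=str(chrom),
                start=int(b) * w,
                end=(int(b) + 1) * w,
                n_sites=len(sub),
                n_differential=int(sub["_q"].sum()),
            )
        )
    return out


def wgbs_differential_sites(sites: pd.DataFrame, delta_min: float = 0.1) -> set:
    """Site ids with tumor mean minus normal mean strictly above
    ``delta_min`` (one-directional, hypermethylated in tumor)."""
    delta = (sites["mean_tumor"] - sites["mean_normal"]).round(9)
    mask = delta > delta_min
    if "site_id" in sites.columns:
        return set(sites.loc[mask, "site_id"])
    return set(sites.index[mask])


def intersect_candidates(
    array_top: Sequence[str],
    wgbs_top: Iterable[str],
    gene_map: Mapping[str, str],
    k: int = 25,
) -> list[str]:
    """Genes present in both ranked candidate streams.

    Both id lists map to gene symbols via ``gene_map``; unmapped ids are
    skipped with a warning.  Output preserves the array-stream ranking
    and is truncated to ``k``.
    """

    def to_genes(ids: Iterable[str]) -> list[str]:
        genes, seen = [], set()
        for i in ids:
            g = gene_map.get(i)
            if g is None:
                logger.warning("id %r has no gene mapping; skipped", i)
                continue
            if g not in seen:
                seen.add(g)
                genes.append(g)
        return genes

    array_genes = to_genes(array_top)
    wgbs_genes = set(to_genes(wgbs_top))
    return [g for g in array_genes if g in wgbs_genes][:k]


def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of half-open intervals, sorted, with touching runs coalesced."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    out = []
    for chrom in sorted(by_chrom):
        merged: list[list[int]] = []
        for start, end in sorted(by_chrom[chrom]):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        out.extend((chrom, s, e) for s, e in merged)
    return out


def build_panel_regions(
    tss_records: Sequence[tuple[str, str, str, int]],
    cgi_intervals: Sequence[tuple[str, int, int]] = (),
    dmp_positions: Sequence[tuple[str, int]] = (),
    upstream: int = 2500,
    downstream: int = 500,
) -> list[tuple[str, int, int]]:
    """Targeted-panel regions: strand-aware promoters merged with CGI
    (island/shore/shelf) intervals and optional single-CpG positions.

    ``tss_records`` rows are (gene, chromosome, strand, TSS).  On the +
    strand the promoter is [TSS - upstream, TSS + downstream); on the -
    strand [TSS - downstream, TSS + upstream); both clipped at 0.  Output
    is a merged, sorted, non-overlapping interval list.
    """
    pieces: list[tuple[str, int, int]] = []
    for gene, chrom, strand, tss in tss_records:
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        elif strand == "-":
            start, end = tss - downstream, tss + upstream
        else:
            raise ValueError(f"gene {gene!r}: strand must be '+' or '-', got {strand!r}")
        pieces.append((chrom, max(0, start), max(1, end)))
    pieces.extend((c, s, e) for c, s, e in cgi_intervals)
    pieces.extend((c, p, p + 1) for c, p in dmp_positions)
    return merge_intervals(pieces)


def panel_urine_differential(
    urine_sites: pd.DataFrame,
    gene_map: Mapping[str, str],
    candidate_genes: Sequence[str],
    delta_min: float = 0.1,
) -> list[str]:
    """Genes with at least one panel site exceeding the UC-vs-non-UC
    urine methylation difference, restricted to the prior candidate set.

    ``urine_sites`` needs ``site_id, mean_tumor, mean_normal`` (means
    over UC and non-UC urine samples).  Output preserves candidate order.
    """
    hits = wgbs_differential_sites(urine_sites, delta_min)
    hit_genes = {gene_map[s] for s in hits if s in gene_map}
    return [g for g in candidate_genes if g in hit_genes]
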