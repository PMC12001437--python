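"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators cover the three data streams of the discovery/validation
cascade:

* :func:`gen_beta_matrix` — a 450K-style beta-value matrix for tumor,
  adjacent-normal and blood-leukocyte groups with a planted set of
  hypermethylated probes (tumor mean = normal mean + delta, leukocyte
  mean kept low so the planted probes survive the leukocyte screen).
  Per-probe values are Beta-distributed around the target mean, the
  standard bounded-support noise model for methylation fractions.
* :func:`gen_wgbs_sites` — genome-scattered CpGs with binomial
  (read-depth limited) methylation estimates and differential sites
  concentrated in a subset of "hot" fixed-width intervals.
* :func:`gen_qmsp_cohort` — a four-group urine qMSP cohort (UC with stage
  labels, non-neoplastic, benign, other cancers).  Within-patient marker
  dependence uses a shared-latent-factor Gaussian copula: independence
  cannot reproduce the observed triple-positive / triple-negative
  pattern frequencies.  Default per-group per-marker positivity
  probabilities are calibrated (see ``data/qmsp_defaults.yaml``) so the
  expected OR-rule sensitivity and per-group specificities match the
  published validation-cohort rates.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, truncnorm

from .discovery import BetaMatrix

__all__ = [
    "ArraySimConfig",
    "WgbsSimConfig",
    "QmspSimConfig",
    "AnnotationSet",
    "gen_beta_matrix",
    "gen_wgbs_sites",
    "gen_qmsp_cohort",
    "gen_annotation",
    "union_positive_prob",
    "load_qmsp_defaults",
]

CT_MAX = 45.0


def load_qmsp_defaults() -> dict:
    """Versioned default qMSP-cohort configuration (calibrated rates)."""
    text = resources.files("uromark.data").joinpath("qmsp_defaults.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class ArraySimConfig:
    """450K-style simulation: group sizes, planted effect and noise."""

    n_probes: int = 1000
    n_tumor: int = 50
    n_normal: int = 50
    n_leukocyte: int = 50
    n_planted: int = 50
    planted_delta: float = 0.3
    background_beta_params: tuple[float, float] = (0.8, 0.8)
    leukocyte_mean_planted: float = 0.05
    noise_dispersion: float = 50.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_probes:
            raise ValueError("n_planted cannot exceed n_probes")
        if not (0.0 < self.planted_delta <= 1.0):
            raise ValueError("planted_delta must be in (0, 1]")
        a, b = self.background_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("background beta shape parameters must be positive")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


def _beta_around(rng: np.random.Generator, mean: np.ndarray, kappa: float,
                 size: tuple[int, ...]) -> np.ndarray:
    """Beta draws with the given mean and precision kappa (a+b = kappa)."""
    mu = np.clip(mean, 1e-3, 1 - 1e-3)
    return rng.beta(mu * kappa, (1 - mu) * kappa, size=size)


def gen_beta_matrix(cfg: ArraySimConfig) -> tuple[BetaMatrix, set[str]]:
    """Beta matrix over tumor/normal/leukocyte groups plus the planted truth set."""
    rng = np.random.default_rng(cfg.seed)
    probe_ids = np.array([f"cg{i:06d}" for i in range(cfg.n_probes)])
    planted_idx = rng.choice(cfg.n_probes, size=cfg.n_planted, replace=False)
    planted = set(probe_ids[planted_idx])

    a, b = cfg.background_beta_params
    base_mu = np.clip(rng.beta(a, b, size=cfg.n_probes), 0.01, 0.99)
    mu_normal = base_mu.copy()
    mu_tumor = base_mu.copy()
    mu_leuko = base_mu.copy()
    # planted probes: low in normal tissue and leukocytes, elevated in tumor
    lo, hi = 0.02, max(0.02 + 1e-6, min(0.25, 0.99 - cfg.planted_delta))
    mu_normal[planted_idx] = rng.uniform(lo, hi, size=cfg.n_planted)
    mu_tumor[planted_idx] = mu_normal[planted_idx] + cfg.planted_delta
    mu_leuko[planted_idx] = cfg.leukocyte_mean_planted

    k = cfg.noise_dispersion
    blocks, samples, groups = [], [], []
    for mu, n, tag in (
        (mu_tumor, cfg.n_tumor, "tumor"),
        (mu_normal, cfg.n_normal, "normal"),
        (mu_leuko, cfg.n_leukocyte, "leukocyte"),
    ):
        blocks.append(_beta_around(rng, mu[:, None], k, (cfg.n_probes, n)))
        samples.extend(f"{tag}_{j:03d}" for j in range(n))
        groups.extend([tag] * n)
    values = np.concatenate(blocks, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values = np.where(mask, np.nan, values)
    frame = pd.DataFrame(values, index=probe_ids, columns=samples)
    matrix = BetaMatrix(frame, pd.Series(groups, index=samples, name="group"))
    return matrix, planted


@dataclass(frozen=True)
class WgbsSimConfig:
    """WGBS-style simulation: CpG layout, differential signal and depth."""

    genome_layout: tuple[tuple[str, int], ...] = (("chr1", 2_000_000), ("chr2", 1_500_000))
    n_cpgs: int = 5000
    n_differential: int = 100
    differential_delta: float = 0.2
    interval_size: int = 100_000
    hot_interval_fraction: float = 0.1
    read_depth: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genome_layout:
            raise ValueError("genome_layout must be non-empty")
        if self.interval_size <= 0:
            raise ValueError("interval_size must be positive")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if not (0.0 < self.hot_interval_fraction <= 1.0):
            raise ValueError("hot_interval_fraction must be in (0, 1]")


def gen_wgbs_sites(cfg: WgbsSimConfig) -> tuple[pd.DataFrame, set[str]]:
    """BED-like per-site tumor/normal methylation table plus the truth set.

    Differential sites (tumor mean = normal mean + delta) are placed only
    inside a randomly chosen "hot" subset of the fixed-width intervals;
    methylation estimates are binomial at ``read_depth``.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = dict(cfg.genome_layout)
    total = sum(layout.values())
    rows = []
    for chrom, length in cfg.genome_layout:
        n_c = max(1, round(cfg.n_cpgs * length / total))
        pos = np.sort(rng.choice(length, size=min(n_c, length), replace=False))
        for p in pos:
            rows.append((chrom, int(p)))
    sites = pd.DataFrame(rows, columns=["chrom", "start"])
    sites["end"] = sites["start"] + 1
    sites["site_id"] = [f"{c}:{s}" for c, s in zip(sites["chrom"], sites["start"])]

    w = cfg.interval_size
    interval_key = sites["chrom"].astype(str) + ":" + (sites["start"] // w).astype(str)
    all_intervals = interval_key.unique()
    n_hot = max(1, round(len(all_intervals) * cfg.hot_interval_fraction))
    hot = set(rng.choice(all_intervals, size=n_hot, replace=False))
    in_hot = interval_key.isin(hot).to_numpy()

    n_diff = min(cfg.n_differential, int(in_hot.sum()))
    diff_idx = rng.choice(np.flatnonzero(in_hot), size=n_diff, replace=False)
    mu_normal = rng.uniform(0.05, 0.95, size=len(sites))
    mu_normal[diff_idx] = rng.uniform(0.05, 0.95 - cfg.differential_delta, size=n_diff)
    mu_tumor = mu_normal.copy()
    mu_tumor[diff_idx] += cfg.differential_delta

    d = cfg.read_depth
    sites["mean_tumor"] = rng.binomial(d, mu_tumor) / d
    sites["mean_normal"] = rng.binomial(d, mu_normal) / d
    truth = set(sites["site_id"].iloc[diff_idx])
    return sites, truth


@dataclass(frozen=True)
class QmspSimConfig:
    """Four-group urine qMSP cohort with copula-dependent marker calls.

    Defaults (when fields are None) come from the versioned configuration
    in ``data/qmsp_defaults.yaml``: group sizes 108/191/76/57, stage
    counts 10/35/21/12 + 30 unstaged within UC, and positivity
    probabilities calibrated to the published OR-rule operating point.
    """

    group_sizes: Mapping[str, int] | None = None
    stage_distribution: Mapping[str, int] | None = None
    markers: tuple[str, ...] | None = None
    positivity_probs: Mapping[str, Mapping[str, float]] | None = None
    positive_ct_params: Mapping[str, Mapping[str, float]] | None = None
    marker_correlation: float | None = None
    seed: int = 0

    def resolved(self) -> dict:
        d = load_qmsp_defaults()
        out = {
            "group_sizes": dict(self.group_sizes or d["group_sizes"]),
            "stage_distribution": dict(self.stage_distribution or d["stage_distribution"]),
            "markers": tuple(self.markers or d["markers"]),
            "positivity_probs": {
                g: dict(m) for g, m in (self.positivity_probs or d["positivity_probs"]).items()
            },
            "positive_ct_params": {
                g: dict(m) for g, m in (self.positive_ct_params or d["positive_ct_params"]).items()
            },
            "marker_correlation": (
                d["marker_correlation"] if self.marker_correlation is None
                else self.marker_correlation
            ),
            "seed": self.seed,
        }
        if any(n <= 0 for n in out["group_sizes"].values()):
            raise ValueError("group sizes must be positive")
        if not out["markers"]:
            raise ValueError("marker list must be non-empty")
        for g, mp in out["positivity_probs"].items():
            for m, p in mp.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"positivity prob for ({g}, {m}) outside [0, 1]: {p}")
        rho = out["marker_correlation"]
        if not (0.0 <= rho < 1.0):
            raise ValueError("marker_correlation must be in [0, 1)")
        return out


def union_positive_prob(probs: Sequence[float], rho: float, n_nodes: int = 64) -> float:
    """P(at least one marker positive) under the shared-factor copula.

    Marker m is positive iff sqrt(rho)*Z + sqrt(1-rho)*E_m < Phi^-1(p_m)
    with Z shared per patient; the integral over Z uses Gauss-Hermite
    quadrature.  Used to calibrate default positivity probabilities.
    """
    z, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / np.sqrt(2 * np.pi)
    t = norm.ppf(np.asarray(probs, dtype=float))
    s = np.sqrt(rho)
    all_neg = np.ones_like(z)
    for tm in t:
        cond = norm.cdf((tm - s * z) / np.sqrt(1 - rho))
        all_neg *= 1 - cond
    return float(1 - np.sum(w * all_neg))


def _stage_labels(rng: np.random.Generator, n_uc: int,
                  stage_distribution: Mapping[str, int]) -> np.ndarray:
    labels = []
    for stage, count in stage_distribution.items():
        labels.extend([stage] * count)
    if len(labels) != n_uc:
        raise ValueError(
            f"stage distribution totals {len(labels)} but UC group has {n_uc} samples"
        )
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    return labels


def gen_qmsp_cohort(cfg: QmspSimConfig = QmspSimConfig()) -> pd.DataFrame:
    """Long-format Ct table: one row per (sample, marker).

    Positive wells draw Ct from a per-group truncated normal strictly
    below 45; negative wells carry NaN (the no-amplification sentinel).
    UC samples get stage labels per the configured stage counts
    ("unknown" marks unstaged cases); non-UC samples have no stage.
    """
    c = cfg.resolved()
    rng = np.random.default_rng(c["seed"])
    markers = c["markers"]
    rho = c["marker_correlation"]
    s, r = np.sqrt(rho), np.sqrt(1 - rho)
    ct_defaults = c["positive_ct_params"].get("default", {"mean": 38.0, "sd": 3.0})

    rows = []
    for group in c["group_sizes"]:
        n = c["group_sizes"][group]
        probs = c["positivity_probs"].get(group)
        if probs is None:
            raise ValueError(f"no positivity probabilities for group {group!r}")
        thresholds = {m: norm.ppf(probs[m]) for m in markers}
        ct_par = c["positive_ct_params"].get(group, ct_defaults)
        mu, sd = float(ct_par["mean"]), float(ct_par["sd"])
        a, b = (5.0 - mu) / sd, (CT_MAX - 1e-6 - mu) / sd
        stages = (
            _stage_labels(rng, n, c["stage_distribution"]) if group == "UC" else [None] * n
        )
        for i in range(n):
            sid = f"{group}_{i:03d}"
            z = rng.standard_normal()
            for m in markers:
                latent = s * z + r * rng.standard_normal()
                positive = latent < thresholds[m]
                ct = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)) \
                    if positive else np.nan
                rows.append((sid, group, stages[i], m, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "stage", "marker", "ct"])


@dataclass
class AnnotationSet:
    """Gene TSS records and CpG-island/shore/shelf intervals."""

    tss_records: list[tuple[str, str, str, int]]  # (gene, chrom, strand, tss)
    cgi_intervals: list[tuple[str, int, int, str]]  # (chrom, start, end, class)

    def __post_init__(self) -> None:
        for gene, chrom, strand, tss in self.tss_records:
            if strand not in {"+", "-"}:
                raise ValueError(f"gene {gene!r}: bad strand {strand!r}")
            if tss < 0:
                raise ValueError(f"gene {gene!r}: negative TSS")
        for chrom, start, end, cls in self.cgi_intervals:
            if start < 0 or end <= start:
                raise ValueError(f"invalid CGI interval {chrom}:{start}-{end}")
            if cls not in {"island", "shore", "shelf"}:
                raise ValueError(f"unknown CGI class {cls!r}")


def gen_annotation(
    n_genes: int,
    genome_layout: Sequence[tuple[str, int]],
    seed: int = 0,
) -> AnnotationSet:
    """Random but structurally valid TSS and CGI annotation.

    Each gene gets a CpG island overlapping its TSS plus flanking shore
    (within 2 kb) and shelf (2-4 kb) intervals, the standard genomic
    decomposition around CpG islands.
    """
    if not genome_layout:
        raise ValueError("genome_layout must be non-empty")
    rng = np.random.default_rng(seed)
    layout = list(genome_layout)
    total = sum(length for _, length in layout)
    tss_records, cgi = [], []
    for g in range(n_genes):
        chrom, length = layout[int(rng.integers(len(layout)))]
        tss = int(rng.integers(10_000, max(10_001, length - 10_000)))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_records.append((f"GENE{g:04d}", chrom, strand, tss))
        half = int(rng.integers(250, 1000))
        island = (max(0, tss - half), min(length, tss + half))
        cgi.append((chrom, island[0], island[1], "island"))
        cgi.append((chrom, max(0, island[0] - 2000), island[0], "shore"))
        cgi.append((chrom, island[1], min(length, island[1] + 2000), "shore"))
        cgi.append((chrom, max(0, island[0] - 4000), max(0, island[0] - 2000), "shelf"))
        cgi.append((chrom, island[1] + 2000, min(length, island[1] + 4000), "shelf"))
    cgi = [(c, s, e, k) for c, s, e, k in cgi if e > s]
    return AnnotationSet(tss_records=tss_records, cgi_intervals=cgi)
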