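"""File formats: beta-matrix TSV, BED-like site/interval tables, Ct CSV, config.

Dialects: UTF-8, tab-separated for matrices and genomic tables,
comma-separated for the clinical Ct table, "NA" as the universal
missing/no-amplification token, 0-based half-open genomic coordinates.
Readers validate schemas and report offending line numbers; write-then-read
is the identity on valid data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .discovery import BetaMatrix, GenomicInterval
from .screen import validate_ct_table

__all__ = [
    "read_beta_tsv",
    "write_beta_tsv",
    "read_sites_bed",
    "write_sites_bed",
    "write_intervals_bed",
    "read_ct_csv",
    "write_ct_csv",
    "write_calls_csv",
    "read_gene_map",
    "read_config",
]

NA_TOKEN = "NA"


def write_beta_tsv(m: BetaMatrix, matrix_path: str | Path, samples_path: str | Path) -> None:
    """Matrix TSV (header = sample ids, first column = probe id) plus a
    sample-sheet CSV with columns sample_id, group."""
    out = m.values.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t", na_rep=NA_TOKEN, float_format="%.6g")
    sheet = pd.DataFrame({"sample_id": m.values.columns,
                          "group": [m.group_of[s] for s in m.values.columns]})
    sheet.to_csv(samples_path, index=False)


def read_beta_tsv(matrix_path: str | Path, samples_path: str | Path) -> BetaMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="probe_id", na_values=[NA_TOKEN])
    sheet = pd.read_csv(samples_path)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise ValueError(f"{samples_path}: sample sheet missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{samples_path}: duplicate sample ids {dups[:5]}")
    arr = values.to_numpy(dtype=float)
    bad = np.isfinite(arr) & ((arr < 0) | (arr > 1))
    if bad.any():
        rows = np.flatnonzero(bad.any(axis=1))[:5]
        raise ValueError(
            f"{matrix_path}: beta values outside [0, 1] at data lines "
            f"{[int(r) + 2 for r in rows]}"
        )
    groups = sheet.set_index("sample_id")["group"]
    return BetaMatrix(values.rename_axis(None), groups)


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """BED-like TSV: chrom, start, end, site_id, then group-mean columns."""
    cols = ["chrom", "start", "end", "site_id", "mean_tumor", "mean_normal"]
    extra = [c for c in sites.columns if c not in cols]
    sites[cols + extra].to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN,
                               float_format="%.6g")


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN])
    required = {"chrom", "start", "end", "mean_tumor", "mean_normal"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = (sites["end"] <= sites["start"]) | (sites["start"] < 0)
    if bad.any():
        lines = [int(i) + 2 for i in sites.index[bad][:5]]
        raise ValueError(f"{path}: invalid intervals (end <= start or negative) at lines {lines}")
    return sites


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(iv.chromosome, iv.start, iv.end, iv.n_sites, iv.n_differential) for iv in intervals],
        columns=["chrom", "start", "end", "n_sites", "n_differential"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_ct_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Ct CSV: sample_id, group, stage, marker, ct ("NA" = no amplification)."""
    out = table[["sample_id", "group", "stage", "marker", "ct"]].copy()
    out.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.4f")


def read_ct_csv(path: str | Path, ct_cutoff: float = 45.0) -> pd.DataFrame:
    table = pd.read_csv(path, na_values=[NA_TOKEN], dtype={"stage": "object"})
    required = {"sample_id", "group", "marker", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "stage" not in table.columns:
        table["stage"] = None
    try:
        validate_ct_table(table, ct_cutoff=ct_cutoff)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None
    return table


def write_calls_csv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id, gene) -> mapping; duplicate ids rejected."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["id", "gene"], dtype=str,
                        comment="#")
    if frame["id"].duplicated().any():
        dups = frame.loc[frame["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate ids in gene map: {dups[:5]}")
    return dict(zip(frame["id"], frame["gene"]))


def read_config(path: str | Path) -> dict:
    """YAML pipeline configuration; must parse to a mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key/value mapping")
    return cfg
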