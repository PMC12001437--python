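import numpy as np
import pandas as pd
import pytest

MARKERS = ("VIM", "TMEM220", "PPM1N")


def ct_table_from_calls(call_map, groups, stages=None, positive_ct=35.0, markers=MARKERS):
    """Build a long-format Ct table from per-sample marker call booleans.

    call_map: {sample_id: (bool per marker)}; positive wells get a fixed
    numeric Ct, negative wells the NaN sentinel.
    """
    rows = []
    for sid, flags in call_map.items():
        for m, flag in zip(markers, flags):
            ct = positive_ct if flag else np.nan
            stage = (stages or {}).get(sid)
            rows.append((sid, groups[sid], stage, m, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "stage", "marker", "ct"])


@pytest.fixture
def exhaustive_pattern_table():
    """Eight samples, one per marker call pattern (synthetic truth table)."""
    call_map, groups = {}, {}
    for mask in range(8):
        sid = f"S{mask}"
        call_map[sid] = tuple(bool(mask >> i & 1) for i in range(3))
        groups[sid] = "UC"
    return ct_table_from_calls(call_map, groups)


@pytest.fixture
def sixty_sample_table():
    """Synthetic 60-sample screening cohort: 20 UC, 20 non-neoplastic,
    20 other-cancer; one marker detecting 16/20 UC with 4 false positives
    spread over the negatives (accuracy (16+36)/60)."""
    call_map, groups = {}, {}
    for i in range(20):
        sid = f"UC_{i:02d}"
        groups[sid] = "UC"
        call_map[sid] = (i < 16,)
    for gi, g in enumerate(("non_neoplastic", "other_cancer")):
        for i in range(20):
            sid = f"{g}_{i:02d}"
            groups[sid] = g
            call_map[sid] = (i < 2,)  # 2 false positives per negative group
    return ct_table_from_calls(call_map, groups, markers=("M1",))


def auc_bruteforce(scores, labels):
    """Pairwise Mann-Whitney AUC with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def interval_counts_bruteforce(sites, width, delta_min):
    """Double loop over sites x intervals (oracle for the scan)."""
    out = {}
    for _, row in sites.iterrows():
        b = int(row["start"]) // width
        key = (row["chrom"], b * width, (b + 1) * width)
        n_sites, n_diff = out.get(key, (0, 0))
        # shares the declared tie convention: deltas compared at 1e-9 resolution
        q = abs(round(row["mean_tumor"] - row["mean_normal"], 9)) > delta_min
        out[key] = (n_sites + 1, n_diff + int(q))
    return out


def merged_bases_bruteforce(intervals):
    """Base-wise union of half-open intervals (oracle for merging)."""
    bases = set()
    for chrom, start, end in intervals:
        for p in range(start, end):
            bases.add((chrom, p))
    return bases
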