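"""Differential-methylation cascade: filters, scans, panel construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uromark import simulate
from uromark.discovery import (
    BetaMatrix,
    DiscoveryParams,
    DmpRecord,
    build_panel_regions,
    differential_probes,
    filter_probes_by_missingness,
    intersect_candidates,
    leukocyte_filter,
    merge_intervals,
    panel_urine_differential,
    rank_and_select,
    wgbs_differential_sites,
    wgbs_interval_scan,
)

from conftest import interval_counts_bruteforce, merged_bases_bruteforce


def _matrix(values, groups):
    frame = pd.DataFrame(values)
    frame.index = [f"p{i}" for i in range(len(frame))]
    return BetaMatrix(frame, pd.Series(groups))


class TestMissingness:
    def test_exceeding_threshold_excluded_at_exact_retained(self):
        vals = np.full((3, 10), 0.5)
        vals[0, :8] = np.nan  # 80% missing -> out
        vals[1, :7] = np.nan  # 70% missing -> exactly at threshold, retained
        m = _matrix(
            {f"s{j}": vals[:, j] for j in range(10)},
            {f"s{j}": "tumor" for j in range(10)},
        )
        kept = filter_probes_by_missingness(m, 0.70)
        assert list(kept.values.index) == ["p1", "p2"]

    def test_max_missing_one_is_identity(self):
        vals = np.full((2, 4), np.nan)
        m = _matrix({f"s{j}": vals[:, j] for j in range(4)},
                    {f"s{j}": "tumor" for j in range(4)})
        assert list(filter_probes_by_missingness(m, 1.0).values.index) == ["p0", "p1"]

    def test_empty_matrix_passes_through(self):
        m = BetaMatrix(pd.DataFrame(), pd.Series(dtype=object))
        assert filter_probes_by_missingness(m, 0.7).values.empty


class TestDifferentialProbes:
    def test_planted_probes_recovered(self):
        m, truth = simulate.gen_beta_matrix(simulate.ArraySimConfig(seed=11))
        records = differential_probes(m)
        flagged = {r.probe_id for r in records if "significance" in r.passes}
        assert len(flagged & truth) / len(truth) >= 0.95

    def test_identical_groups_not_flagged(self):
        vals = np.tile(np.array([0.4, 0.6]), (6, 1)).T
        m = _matrix(
            {f"s{j}": vals[:, j] for j in range(6)},
            {f"s{j}": ("tumor" if j < 3 else "normal") for j in range(6)},
        )
        records = differential_probes(m)
        assert all(r.delta == 0 and "significance" not in r.passes for r in records)

    def test_small_group_rejected_by_name(self):
        m = _matrix({"s0": [0.1], "s1": [0.2], "s2": [0.3]},
                    {"s0": "tumor", "s1": "tumor", "s2": "normal"})
        with pytest.raises(ValueError, match="normal"):
            differential_probes(m)

    def test_null_flag_rate_controlled(self):
        rates = []
        for seed in range(5):
            m, _ = simulate.gen_beta_matrix(
                simulate.ArraySimConfig(n_planted=0, n_probes=500, seed=seed)
            )
            records = differential_probes(m)
            rates.append(np.mean([("significance" in r.passes) for r in records]))
        assert np.mean(rates) <= 0.01

    def test_padj_never_below_praw(self):
        m, _ = simulate.gen_beta_matrix(simulate.ArraySimConfig(n_probes=200, seed=4))
        for r in differential_probes(m):
            assert r.p_adj >= r.p_raw - 1e-12


class TestLeukocyteFilter:
    def _records(self):
        return [DmpRecord("p0", 0.5, 0.1, 0.4, 1e-5, 1e-4, passes={"significance"})]

    def _leuko(self, mean):
        return _matrix({"l0": [mean], "l1": [mean]},
                       {"l0": "leukocyte", "l1": "leukocyte"})

    def test_low_background_flagged(self):
        out = leukocyte_filter(self._records(), self._leuko(0.05))
        assert out[0].leukocyte_mean == pytest.approx(0.05)
        assert "leukocyte" in out[0].passes

    def test_exact_threshold_not_flagged(self):
        out = leukocyte_filter(self._records(), self._leuko(0.1))
        assert "leukocyte" not in out[0].passes  # strict "<"

    def test_failing_record_retained_without_flag(self):
        out = leukocyte_filter(self._records(), self._leuko(0.5))
        assert len(out) == 1 and "leukocyte" not in out[0].passes

    def test_missing_probe_raises(self):
        leuko = _matrix({"l0": [0.1]}, {"l0": "leukocyte"})
        recs = [DmpRecord("absent", 0.5, 0.1, 0.4, 0.1, 0.2)]
        with pytest.raises(ValueError, match="absent"):
            leukocyte_filter(recs, leuko)

    def test_empty_records(self):
        assert leukocyte_filter([], self._leuko(0.1)) == []


class TestRankAndSelect:
    def test_fewer_survivors_than_k(self):
        recs = [DmpRecord(f"p{i}", 0.5, 0.1, 0.4, 0.001, 0.001, passes={"significance"})
                for i in range(3)]
        assert len(rank_and_select(recs, 100)) == 3

    def test_tie_breaks_by_padj_then_id(self):
        recs = [
            DmpRecord("pB", 0.5, 0.2, 0.3, 0.002, 0.002, passes={"significance"}),
            DmpRecord("pA", 0.5, 0.2, 0.3, 0.001, 0.001, passes={"significance"}),
            DmpRecord("pC", 0.5, 0.2, 0.3, 0.002, 0.002, passes={"significance"}),
        ]
        assert rank_and_select(recs, 3) == ["pA", "pB", "pC"]

    def test_selection_precision_on_planted_simulation(self):
        m, truth = simulate.gen_beta_matrix(simulate.ArraySimConfig(seed=21))
        records = leukocyte_filter(differential_probes(m), m)
        selected = set(rank_and_select(records, 100))
        assert len(selected & truth) / max(len(selected), 1) >= 0.9

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            rank_and_select([], 0)


class TestIntervalScan:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "mean_tumor", "mean_normal"])

    def test_half_open_boundary_assignment(self):
        sites = self._sites([("chr1", 100_000, 0.9, 0.1)])
        (iv,) = wgbs_interval_scan(sites)
        assert (iv.start, iv.end) == (100_000, 200_000)

    def test_exact_delta_not_differential(self):
        sites = self._sites([("chr1", 10, 0.55, 0.50), ("chr1", 20, 0.45, 0.50)])
        (iv,) = wgbs_interval_scan(sites)  # |delta| = 0.05 exactly, strict ">"
        assert iv.n_sites == 2 and iv.n_differential == 0

    def test_site_beyond_chromosome_rejected(self):
        sites = self._sites([("chr1", 500, 0.9, 0.1)])
        with pytest.raises(ValueError, match="beyond"):
            wgbs_interval_scan(sites, genome_layout={"chr1": 400})

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 500))
        sites = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], size=n),
            "start": rng.integers(0, 1_000_000, size=n),
            "mean_tumor": rng.random(n),
            "mean_normal": rng.random(n),
        })
        params = DiscoveryParams()
        got = {
            (iv.chromosome, iv.start, iv.end): (iv.n_sites, iv.n_differential)
            for iv in wgbs_interval_scan(sites, params)
        }
        expected = interval_counts_bruteforce(sites, params.interval_size,
                                              params.interval_site_delta_min)
        assert got == expected
        # conservation: differential counts partition the qualifying sites
        qualifying = ((sites.mean_tumor - sites.mean_normal).round(9).abs()
                      > params.interval_site_delta_min).sum()
        assert sum(v[1] for v in got.values()) == qualifying


class TestDifferentialSites:
    @pytest.mark.parametrize("delta, included", [(0.15, True), (0.1, False), (-0.3, False)])
    def test_strict_one_directional_threshold(self, delta, included):
        sites = pd.DataFrame({"site_id": ["s"], "mean_tumor": [0.5 + delta],
                              "mean_normal": [0.5]})
        got = wgbs_differential_sites(sites, 0.1)
        assert ("s" in got) is included


class TestIntersect:
    def test_disjoint_lists_empty(self):
        gm = {"a": "A", "b": "B"}
        assert intersect_candidates(["a"], ["b"], gm) == []

    def test_order_follows_array_ranking(self):
        gm = {x: x.upper() for x in "abc"}
        assert intersect_candidates(["a", "b", "c"], ["c", "a"], gm, k=25) == ["A", "C"]

    def test_truncation_to_k(self):
        gm = {f"g{i}": f"G{i}" for i in range(30)}
        ids = [f"g{i}" for i in range(30)]
        assert len(intersect_candidates(ids, ids, gm, k=25)) == 25

    def test_unmapped_ids_skipped(self, caplog):
        gm = {"a": "A"}
        assert intersect_candidates(["a", "zz"], ["a", "zz"], gm) == ["A"]


class TestPanelRegions:
    def test_plus_strand_promoter(self):
        (region,) = build_panel_regions([("G", "chr1", "+", 10_000)])
        assert region == ("chr1", 7_500, 10_500)

    def test_minus_strand_promoter_mirrored(self):
        (region,) = build_panel_regions([("G", "chr1", "-", 10_000)])
        assert region == ("chr1", 9_500, 12_500)

    def test_clipped_at_zero(self):
        (region,) = build_panel_regions([("G", "chr1", "+", 1_000)])
        assert region == ("chr1", 0, 1_500)

    def test_overlapping_promoters_merge_to_union(self):
        regions = build_panel_regions(
            [("G1", "chr1", "+", 10_000), ("G2", "chr1", "+", 11_000)]
        )
        assert regions == [("chr1", 7_500, 11_500)]

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_matches_basewise_union(self, seed):
        rng = np.random.default_rng(seed)
        intervals = []
        for _ in range(int(rng.integers(5, 100))):
            start = int(rng.integers(0, 2000))
            intervals.append((str(rng.choice(["chr1", "chr2"])), start,
                              start + int(rng.integers(1, 120))))
        merged = merge_intervals(intervals)
        got_bases = merged_bases_bruteforce(merged)
        assert got_bases == merged_bases_bruteforce(intervals)
        # merged output is sorted and non-overlapping
        for (c1, s1, e1), (c2, s2, e2) in zip(merged, merged[1:]):
            assert (c1, e1) <= (c2, s2) or c1 < c2


class TestUrinePanelDifferential:
    def test_planted_genes_recovered(self):
        genes = [f"G{i}" for i in range(25)]
        planted = set(genes[:12])
        rows, gm = [], {}
        for i, g in enumerate(genes):
            sid = f"site{i}"
            gm[sid] = g
            delta = 0.3 if g in planted else 0.0
            rows.append((sid, 0.3 + delta, 0.3))
        sites = pd.DataFrame(rows, columns=["site_id", "mean_tumor", "mean_normal"])
        assert panel_urine_differential(sites, gm, genes) == sorted(planted, key=genes.index)

    def test_impossible_threshold_empty(self):
        sites = pd.DataFrame({"site_id": ["s"], "mean_tumor": [0.9], "mean_normal": [0.1]})
        assert panel_urine_differential(sites, {"s": "G"}, ["G"], delta_min=1.0) == []

    def test_empty_candidate_set(self):
        sites = pd.DataFrame({"site_id": ["s"], "mean_tumor": [0.9], "mean_normal": [0.1]})
        assert panel_urine_differential(sites, {"s": "G"}, []) == []


@settings(derandomize=True, max_examples=30)
@given(delta_min=st.floats(min_value=0.0, max_value=0.5),
       bump=st.floats(min_value=0.01, max_value=0.4))
def test_raising_delta_threshold_never_enlarges_set(delta_min, bump):
    rng = np.random.default_rng(0)
    sites = pd.DataFrame({
        "site_id": [f"s{i}" for i in range(50)],
        "mean_tumor": rng.random(50),
        "mean_normal": rng.random(50),
    })
    loose = wgbs_differential_sites(sites, delta_min)
    tight = wgbs_differential_sites(sites, delta_min + bump)
    assert tight <= loose
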