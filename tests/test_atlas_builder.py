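"""Atlas construction: replicate aggregation, DMS calling, region rules,
Fisher scoring and marker selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from metdecode_kit.atlas_builder import (
    MarkerRegionStats,
    aggregate_replicates,
    build_count_atlas,
    detect_dms,
    extend_to_regions,
    fisher_test_region,
    score_regions,
    select_markers,
)
from metdecode_kit.io_formats import CpGSiteTable, MarkerRegion, ValidationError


def table(name, rows):
    return CpGSiteTable.from_records(name, rows)


class TestAggregateReplicates:
    def test_concordant_replicates_are_summed(self):
        t1 = table("x", [("chr1", 100, 3, 10)])
        t2 = table("x", [("chr1", 100, 2, 10)])
        out = aggregate_replicates([t1, t2], cutoff=0.25)
        assert out.records.iloc[0][["meth", "total"]].tolist() == [5, 20]

    def test_highly_variant_cpg_dropped(self):
        t1 = table("x", [("chr1", 100, 9, 10)])
        t2 = table("x", [("chr1", 100, 1, 10)])
        out = aggregate_replicates([t1, t2], cutoff=0.25)
        assert len(out) == 0

    def test_shallow_replicates_do_not_trigger_the_variance_filter(self):
        # depth < 5 replicates are excluded from the range computation
        t1 = table("x", [("chr1", 100, 4, 4)])
        t2 = table("x", [("chr1", 100, 0, 4)])
        out = aggregate_replicates([t1, t2], cutoff=0.25, min_depth=5)
        assert out.records.iloc[0][["meth", "total"]].tolist() == [4, 8]

    def test_single_replicate_is_identity(self):
        t1 = table("x", [("chr1", 100, 3, 10), ("chr2", 5, 0, 2)])
        out = aggregate_replicates([t1], cutoff=0.25)
        pd.testing.assert_frame_equal(out.records, t1.records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_replicates([], cutoff=0.25)


class TestDetectDms:
    def _tables(self, ratios, depth=10):
        # one shared CpG; ratios maps entity -> methylation ratio
        return [
            table(name, [("chr1", 100, int(round(r * depth)), depth)])
            for name, r in ratios.items()
        ]

    def test_margin_satisfied_yields_hyper_dms(self):
        tabs = self._tables({"t": 0.9, "a": 0.6, "b": 0.5, "c": 0.0})
        dms = detect_dms(tabs, margin=0.30)
        row = dms[dms["entity"] == "t"]
        assert len(row) == 1 and row.iloc[0]["direction"] == "hyper"

    def test_margin_violated_by_one_entity_blocks_the_call(self):
        tabs = self._tables({"t": 0.9, "a": 0.65, "b": 0.5, "c": 0.0}, depth=20)
        dms = detect_dms(tabs, margin=0.30)
        assert (dms["entity"] != "t").all()

    def test_hypomethylated_target_detected(self):
        tabs = self._tables({"t": 0.0, "a": 0.3, "b": 0.5, "c": 0.9})
        dms = detect_dms(tabs, margin=0.30)
        row = dms[dms["entity"] == "t"]
        assert len(row) == 1 and row.iloc[0]["direction"] == "hypo"

    def test_uncovered_site_skipped_without_error(self):
        tabs = [
            table("t", [("chr1", 100, 9, 10), ("chr1", 200, 9, 10)]),
            table("a", [("chr1", 100, 0, 10)]),  # misses pos 200
        ]
        dms = detect_dms(tabs, margin=0.30)
        assert set(dms["pos"]) == {100}


class TestExtendToRegions:
    def _dms(self, positions, entity="t", direction="hyper"):
        return pd.DataFrame(
            {"entity": entity, "chrom": "chr1", "pos": positions, "direction": direction}
        )

    def test_chain_within_gap_is_kept(self):
        bed = extend_to_regions(self._dms([100, 180, 300, 450]), 4, 500, 100)
        assert len(bed) == 1
        assert (bed[0].start, bed[0].end) == (100, 451)

    def test_large_gap_breaks_the_chain(self):
        bed = extend_to_regions(self._dms([100, 200, 300, 900]), 4, 500, 100)
        assert len(bed) == 0  # the 3-CpG fragment fails min_cpgs

    def test_short_region_rejected_on_length(self):
        bed = extend_to_regions(self._dms([0, 10, 25, 39]), 4, 500, 50)
        assert len(bed) == 0

    def test_empty_input_gives_empty_output(self):
        assert len(extend_to_regions(self._dms([])[0:0], 4, 500, 100)) == 0

    def test_entities_and_directions_never_mix(self):
        dms = pd.concat(
            [self._dms([100, 200]), self._dms([300, 400], direction="hypo")],
            ignore_index=True,
        )
        bed = extend_to_regions(dms, 2, 500, 50)
        assert {r.direction for r in bed} == {"hyper", "hypo"}
        assert all(r.length >= 50 for r in bed)


class TestFisher:
    def test_balanced_table_is_null(self):
        assert fisher_test_region(np.array([5, 5]), np.array([10, 10]), 0) == 1.0

    def test_perfect_separation_matches_enumeration(self):
        # [[10,0],[0,10]]: only a=10 and a=0 are as extreme; p = 2/C(20,10)
        p = fisher_test_region(np.array([10, 0]), np.array([10, 10]), 0)
        assert p == pytest.approx(2.0 / 184756.0, abs=1e-12)

    def test_all_zero_table_is_one_by_convention(self):
        assert fisher_test_region(np.array([0, 0, 0]), np.array([0, 0, 0]), 0) == 1.0

    def test_pooling_over_remaining_entities(self):
        # target [3,10]; rest pooled (1+0, 10+10) -> same as 2x2 vs [1,20]
        p_multi = fisher_test_region(np.array([3, 1, 0]), np.array([10, 10, 10]), 0)
        p_pooled = fisher_test_region(np.array([3, 1]), np.array([10, 20]), 0)
        assert p_multi == pytest.approx(p_pooled, abs=1e-15)

    def test_agrees_with_hypergeometric_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            r1, r2 = rng.integers(0, 25, size=2)
            a = rng.integers(0, r1 + 1)
            c = rng.integers(0, r2 + 1)
            p = fisher_test_region(np.array([a, c]), np.array([r1, r2]), 0)
            N, c1 = r1 + r2, a + c
            if N == 0:
                assert p == 1.0
                continue
            xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
            pmf = hypergeom.pmf(xs, N, r1, c1)
            oracle = pmf[pmf <= pmf[xs == a][0] * (1 + 1e-7)].sum()
            assert p == pytest.approx(oracle, abs=1e-10)


def _stats(name, entity, p, n, length=100, start=None):
    start = start if start is not None else 1000 * n
    region = MarkerRegion("chr1", start, start + length, name, entity, "hyper")
    s = MarkerRegionStats(region, np.array([1, 0]), np.array([1, 1]), p)
    return s


class TestSelectMarkers:
    def test_bonferroni_keeps_strong_signal(self):
        stats = [_stats(f"r{i}", "A", 1e-7 if i == 0 else 0.5, i) for i in range(10)]
        for s in stats:
            s.corrected_p = min(1.0, s.fisher_p * 1000)
        kept = select_markers(stats, alpha=0.001, mode="significant")
        assert [r.name for r in kept] == ["r0"]

    def test_bonferroni_drops_signal_under_heavy_multiplicity(self):
        s = _stats("r0", "A", 1e-7, 0)
        s.corrected_p = min(1.0, s.fisher_p * 10**5)
        assert len(select_markers([s], alpha=0.001, mode="significant")) == 0

    def test_balanced_mode_yields_top_k_per_entity(self):
        stats = []
        for e in range(13):
            for i in range(30):
                stats.append(_stats(f"e{e}_r{i}", f"E{e:02d}", (i + 1) * 1e-6, e * 30 + i))
        kept = select_markers(stats, mode="balanced", top_k=23)
        assert len(kept) == 23 * 13 == 299

    def test_balanced_mode_short_entity_keeps_all(self):
        stats = [_stats(f"r{i}", "A", 0.5, i) for i in range(3)]
        assert len(select_markers(stats, mode="balanced", top_k=23)) == 3

    def test_selected_sets_are_nested(self):
        rng = np.random.default_rng(1)
        stats = [_stats(f"r{i}", f"E{i % 3}", float(rng.uniform()), i) for i in range(60)]
        for s in stats:
            s.corrected_p = min(1.0, s.fisher_p * len(stats))
        names = lambda bed: {r.name for r in bed}
        all_set = names(select_markers(stats, mode="all"))
        sig = names(select_markers(stats, alpha=0.5, mode="significant"))
        bal = names(select_markers(stats, mode="balanced", top_k=5))
        assert sig <= all_set and bal <= all_set

    def test_balanced_ties_prefer_longer_then_leftmost(self):
        a = _stats("short", "A", 0.01, 0, length=80, start=5000)
        b = _stats("long", "A", 0.01, 1, length=200, start=9000)
        c = _stats("left", "A", 0.01, 2, length=200, start=100)
        kept = select_markers([a, b, c], mode="balanced", top_k=2)
        assert {r.name for r in kept} == {"left", "long"}


class TestBuildCountAtlas:
    def test_region_sums_cpg_counts(self):
        t = table("x", [("chr1", 100, 3, 10), ("chr1", 150, 2, 10), ("chr1", 900, 5, 5)])
        bed = extend_to_regions(
            pd.DataFrame({"entity": "x", "chrom": "chr1", "pos": [100, 150], "direction": "hyper"}),
            2, 500, 50,
        )
        atlas = build_count_atlas([t], bed)
        assert atlas.M[0, 0] == 5 and atlas.D[0, 0] == 20

    def test_full_atlas_keeps_replicate_rows_with_shared_tissue(self):
        t1 = table("x.rep1", [("chr1", 100, 3, 10)])
        t2 = table("x.rep2", [("chr1", 100, 1, 10)])
        bed = extend_to_regions(
            pd.DataFrame({"entity": "x", "chrom": "chr1", "pos": [100, 140], "direction": "hyper"}),
            2, 500, 40,
        )
        atlas = build_count_atlas([t1, t2], bed, condensed=False, tissue_labels=["x", "x"])
        assert atlas.n_entities == 2 and atlas.tissues == ["x", "x"]

    def test_empty_region_list_gives_zero_columns(self):
        t = table("x", [("chr1", 100, 3, 10)])
        atlas = build_count_atlas([t], extend_to_regions(pd.DataFrame(
            columns=["entity", "chrom", "pos", "direction"]), 4, 500, 100))
        assert atlas.D.shape == (1, 0)

    def test_entity_with_no_cpgs_in_region_gets_zero_counts(self):
        t1 = table("x", [("chr1", 100, 3, 10), ("chr1", 150, 1, 10)])
        t2 = table("y", [("chr2", 100, 3, 10)])
        bed = extend_to_regions(
            pd.DataFrame({"entity": "x", "chrom": "chr1", "pos": [100, 150], "direction": "hyper"}),
            2, 500, 50,
        )
        atlas = build_count_atlas([t1, t2], bed)
        assert atlas.D[1, 0] == 0 and atlas.M[1, 0] == 0
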