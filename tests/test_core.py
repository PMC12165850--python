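"""Pairwise projection, bridged-path search and DC/IC/NC classification."""

import numpy as np
import pytest

from ippoint.anchor_index import build_index
from ippoint.chain_io import AnchorBlock, GenomicInterval
from ippoint.core import (
    ConservationClass,
    PairwiseProjection,
    ProjectionParams,
    ProjectionPath,
    best_bridged_path,
    classify,
    project_pairwise,
    project_point,
    project_regions,
)
from ippoint.simulate import oracle_project

from conftest import make_indexes


def _blk(sp_a, sp_b, a_start, a_end, b_start, orientation="same", chrom="chr1"):
    length = a_end - a_start
    return AnchorBlock(
        sp_a,
        sp_b,
        GenomicInterval(chrom, a_start, a_end),
        GenomicInterval(chrom, b_start, b_start + length),
        orientation,
    )


class TestProjectPairwise:
    def test_in_block_exact_offset(self):
        idx = build_index([_blk("A", "B", 1000, 1100, 2000)])
        proj = project_pairwise("A", "chr1", 1050, idx)
        assert proj.mode == "in_block" and proj.d == 0
        assert proj.target == ("B", "chr1", 2050)

    def test_interpolated_between_anchors(self):
        # gap 1100..1500 on A maps onto 2100..3000 on B; pos 1300 is halfway
        idx = build_index(
            [_blk("A", "B", 1000, 1100, 2000), _blk("A", "B", 1500, 1600, 3000)]
        )
        proj = project_pairwise("A", "chr1", 1300, idx)
        assert proj.mode == "interpolated"
        assert proj.target == ("B", "chr1", 2550)
        assert proj.d == 200

    def test_inverted_in_block(self):
        idx = build_index([_blk("A", "B", 1000, 1100, 5000, "inverted")])
        proj = project_pairwise("A", "chr1", 1010, idx)
        assert proj.target == ("B", "chr1", 5089)  # 5100-1-(1010-1000)
        assert proj.d == 0
        # block endpoints land on the partner's endpoints, swapped
        assert project_pairwise("A", "chr1", 1000, idx).target[2] == 5099
        assert project_pairwise("A", "chr1", 1099, idx).target[2] == 5000

    def test_one_sided_extrapolation(self):
        idx = build_index([_blk("A", "B", 1000, 1100, 2000)])
        proj = project_pairwise("A", "chr1", 1250, idx)
        assert proj.mode == "one_sided"
        assert proj.target == ("B", "chr1", 2250)
        assert proj.d == 150

    def test_orientation_mismatch_falls_back_to_one_sided(self):
        idx = build_index(
            [
                _blk("A", "B", 1000, 1100, 2000, "same"),
                _blk("A", "B", 1500, 1600, 3000, "inverted"),
            ]
        )
        proj = project_pairwise("A", "chr1", 1150, idx)
        assert proj.mode == "one_sided"

    def test_no_anchors_returns_none(self):
        idx = build_index([_blk("A", "B", 1000, 1100, 2000)])
        assert project_pairwise("A", "chrZ", 50, idx) is None

    def test_round_trip_in_block_is_exact(self, small_fixture):
        sim, _, _ = small_fixture
        indexes = make_indexes(sim)
        pair, idx = next(iter(indexes.items()))
        rng = np.random.default_rng(3)
        anchors = idx.anchors
        for _ in range(200):
            blk = anchors[int(rng.integers(len(anchors)))]
            pos = int(rng.integers(blk.a.start, blk.a.end))
            fwd = project_pairwise(pair[0], blk.a.chrom, pos, idx)
            back = project_pairwise(pair[1], fwd.target[1], fwd.target[2], idx)
            assert back.target[2] == pos


class TestBestBridgedPath:
    def _three_species(self):
        # A->C direct anchor is far (d=5000); A->B near (400); B->C near (600)
        idxs = {
            ("A", "C"): build_index([_blk("A", "C", 15000, 15100, 15000)]),
            ("A", "B"): build_index([_blk("A", "B", 10400, 10500, 10400)]),
            ("B", "C"): build_index([_blk("B", "C", 9700, 9800, 9700)]),
        }
        return idxs

    def test_bridge_beats_direct(self):
        # query at A:10000 -> direct A->C d=5000-100=4900; via B: 400+?
        idxs = self._three_species()
        path = best_bridged_path("A", "chr1", 10000, "C", idxs, ProjectionParams())
        assert path.species_sequence == ("A", "B", "C")
        # hop A->B: d=10400-10000=400, one-sided target B:10000
        # hop B->C: nearest anchor 9700-9800, d=10000-9800=200
        assert path.total_distance == 600

    def test_exhaustive_enumeration_equivalence(self):
        idxs = self._three_species()
        params = ProjectionParams()
        best = best_bridged_path("A", "chr1", 10000, "C", idxs, params)
        # enumerate the only two candidate species paths by hand
        direct = project_pairwise("A", "chr1", 10000, idxs[("A", "C")])
        via_b1 = project_pairwise("A", "chr1", 10000, idxs[("A", "B")])
        via_b2 = project_pairwise("B", via_b1.target[1], via_b1.target[2], idxs[("B", "C")])
        candidates = [direct.d, via_b1.d + via_b2.d]
        assert best.total_distance == min(candidates)

    def test_query_inside_direct_anchor(self):
        idxs = self._three_species()
        path = best_bridged_path("A", "chr1", 15050, "C", idxs, ProjectionParams())
        assert path.species_sequence == ("A", "C")
        assert path.total_distance == 0

    def test_all_paths_pruned_returns_none(self):
        idxs = self._three_species()
        params = ProjectionParams(ic_threshold=300)
        assert best_bridged_path("A", "chr1", 10000, "C", idxs, params) is None

    def test_max_hops_limits_path_length(self):
        idxs = self._three_species()
        params = ProjectionParams(ic_threshold=10000, max_hops=1)
        path = best_bridged_path("A", "chr1", 10000, "C", idxs, params)
        assert path.species_sequence == ("A", "C")
        assert path.total_distance == 5000  # forced direct despite the bridge

    def test_total_distance_additivity(self, small_fixture):
        sim, queries, _ = small_fixture
        indexes = make_indexes(sim)
        for q in queries[:40]:
            path = best_bridged_path(
                sim.species[0], "chr1", int(q), sim.species[-1], indexes,
                ProjectionParams(),
            )
            if path is not None:
                assert path.total_distance == sum(h.d for h in path.per_hop)
                assert len(set(path.species_sequence)) == len(path.species_sequence)


class TestClassify:
    def _direct(self, d):
        return PairwiseProjection(("A", "chr1", 0), ("B", "chr1", 0), d,
                                  "in_block" if d == 0 else "interpolated")

    def _bridged(self, total):
        hop = PairwiseProjection(("A", "chr1", 0), ("B", "chr1", 0), total,
                                 "interpolated" if total else "in_block")
        return ProjectionPath(("A", "B"), (hop,), total, ("chr1", 0))

    @pytest.mark.parametrize(
        "d_direct,bridged_total,expected",
        [
            (150, None, "DC"),
            (300, None, "DC"),  # boundary inclusive: "within 300 bp"
            (301, None, "NC"),
            (5000, 1800, "IC"),
            (5000, 2499, "IC"),
            (5000, 2500, "NC"),  # boundary exclusive: "less than 2.5 kb"
            (None, 1000, "IC"),
            (None, None, "UNPROJECTABLE"),
            (400, None, "NC"),
        ],
    )
    def test_threshold_rules(self, d_direct, bridged_total, expected):
        direct = self._direct(d_direct) if d_direct is not None else None
        bridged = self._bridged(bridged_total) if bridged_total is not None else None
        assert classify(direct, bridged).value == expected

    def test_dc_independent_of_bridging_set(self, small_fixture):
        sim, queries, _ = small_fixture
        sp = sim.species
        full = make_indexes(sim)
        direct_only = make_indexes(sim, {sp[0], sp[-1]})
        params = ProjectionParams()
        for q in queries[:60]:
            _, _, c_full = project_point(sp[0], "chr1", int(q), sp[-1], full, params)
            _, _, c_min = project_point(sp[0], "chr1", int(q), sp[-1], direct_only, params)
            assert (c_full == ConservationClass.DC) == (c_min == ConservationClass.DC)


class TestProjectRegions:
    def test_empty_bed(self, small_fixture):
        sim, _, _ = small_fixture
        table = project_regions([], sim.species[0], sim.species[-1],
                                make_indexes(sim))
        assert len(table) == 0

    def test_unknown_chromosome_is_unprojectable(self, small_fixture):
        sim, _, _ = small_fixture
        regions = [GenomicInterval("chr_unknown", 100, 200)]
        table = project_regions(regions, sim.species[0], sim.species[-1],
                                make_indexes(sim))
        assert table.iloc[0]["class"] == "UNPROJECTABLE"

    def test_classes_match_oracle(self, small_fixture):
        sim, queries, truth = small_fixture
        regions = [GenomicInterval("chr1", max(0, int(q) - 1), int(q) + 1)
                   for q in queries]
        table = project_regions(regions, sim.species[0], sim.species[-1],
                                make_indexes(sim),
                                summits=[int(q) for q in queries])
        assert list(table["class"]) == list(truth.table["expected_class"])

    def test_midpoint_is_default_projection_point(self, small_fixture):
        sim, _, _ = small_fixture
        table = project_regions([GenomicInterval("chr1", 100, 200)],
                                sim.species[0], sim.species[-1], make_indexes(sim))
        assert table.iloc[0]["point"] == 150


class TestMonotoneBridging:
    def test_adding_bridges_never_hurts(self, small_fixture):
        sim, queries, _ = small_fixture
        sp = sim.species
        params = ProjectionParams()
        subsets = [
            {sp[0], sp[-1]},
            {sp[0], sp[1], sp[-1]},
            {sp[0], sp[1], sp[2], sp[-1]},
        ]
        prev_best, prev_dcic, prev_dc = None, None, None
        for subset in subsets:
            indexes = make_indexes(sim, subset)
            bests, dcic, dc = [], 0, 0
            for q in queries:
                _, bridged, cls = project_point(sp[0], "chr1", int(q), sp[-1],
                                                indexes, params)
                bests.append(bridged.total_distance if bridged else 10**12)
                dcic += cls.value in ("DC", "IC")
                dc += cls.value == "DC"
            if prev_best is not None:
                assert all(b <= p for b, p in zip(bests, prev_best))
                assert dcic >= prev_dcic
                assert dc == prev_dc
            prev_best, prev_dcic, prev_dc = bests, dcic, dc
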