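import numpy as np
import pytest

from dsakit.io_formats import VariantRecord
from dsakit.representation_shift import (
    ClusterParams,
    LiftBlock,
    LiftMap,
    build_benchmark_regions,
    classify_representation,
    compare_cluster_sets,
    detect_clusters,
    lift_variant,
)
from dsakit.synthetic_data import simulate_representation_scenario


def _simple_map():
    # dsa: [0,1000) -> ref [0,1000); [1020,2000) -> ref [1000,1980)
    return LiftMap(
        [
            LiftBlock("d", 0, 1000, "r", 0, 1000),
            LiftBlock("d", 1020, 2000, "r", 1000, 1980),
        ]
    )


class TestLift:
    def test_inside_single_block_exact_offsets(self):
        res = lift_variant("d", 400, 401, _simple_map(), slop=50)
        assert res.status == "lifted"
        chrom, s, e, strand = res.intervals[0]
        assert (chrom, s, e) == ("r", 350, 451)

    def test_unmapped_expansion_is_unliftable(self):
        m = LiftMap([LiftBlock("d", 0, 100, "r", 0, 100)])
        assert lift_variant("d", 5_000, 5_001, m, slop=50).status == "unliftable"

    def test_two_disjoint_targets_is_multi_lift(self):
        m = LiftMap(
            [
                LiftBlock("d", 0, 500, "r", 0, 500),
                LiftBlock("d", 500, 1000, "r", 100_000, 100_500),
            ]
        )
        # window straddles both runs (non-colinear: huge ref jump groups split)
        res = lift_variant("d", 480, 520, m, slop=50)
        assert res.status == "multi_lift"

    def test_min_match_fraction_gates_targets(self):
        # only 5 of 101 window bases are mapped -> below the 10% floor
        m = LiftMap([LiftBlock("d", 0, 455, "r", 0, 455)], min_match=0.1)
        assert lift_variant("d", 500, 501, m, slop=50).status == "unliftable"

    def test_round_trip_through_inverse_map(self):
        m = _simple_map()
        inv = LiftMap(
            [
                LiftBlock(b.ref_chrom, b.ref_start, b.ref_end,
                          b.dsa_chrom, b.dsa_start, b.dsa_end)
                for b in m.blocks
            ]
        )
        for pos in (100, 700, 1500):
            fwd = m.project_point("d", pos)
            assert fwd is not None
            back = inv.project_point(*fwd)
            assert back == ("d", pos)


class TestRepresentationClasses:
    def _scenario(self, seed=0, rate=0.3, n=120):
        return simulate_representation_scenario(
            n_segments=n, interference_rate=rate, seed=seed
        )

    def test_expected_classes_recovered(self):
        ref, dsa, lmap, somatic, expected, _ = self._scenario()
        got = [
            classify_representation(v, dsa, ref, lmap) for v in somatic
        ]
        mismatch = [(g, e) for g, e in zip(got, expected) if g != e]
        assert not mismatch

    def test_classes_partition_all_variants(self):
        from dsakit.representation_shift import REPRESENTATION_CLASSES

        ref, dsa, lmap, somatic, _, _ = self._scenario(seed=3)
        for v in somatic:
            k = classify_representation(v, dsa, ref, lmap)
            assert k in REPRESENTATION_CLASSES

    def test_interference_rate_recovered(self):
        """Constructed overlap rate r=0.3 is recovered within binomial error."""
        ref, dsa, lmap, somatic, _, _ = simulate_representation_scenario(
            n_segments=400, interference_rate=0.3, seed=1
        )
        hit = sum(
            classify_representation(v, dsa, ref, lmap)
            in ("type_changed", "size_changed", "reverts_germline")
            for v in somatic
        )
        frac = hit / len(somatic)
        se = np.sqrt(0.3 * 0.7 / len(somatic))
        assert abs(frac - 0.3) < 3 * se

    def test_germline_cnv_bed_takes_precedence(self):
        ref, dsa, lmap, somatic, expected, _ = self._scenario()
        i = expected.index("unchanged")
        v = somatic[i]
        lift = lift_variant(v.chrom, v.pos, v.end, lmap)
        rchrom, rs, re_, _ = lift.intervals[0]
        k = classify_representation(
            v, dsa, ref, lmap, germline_cnv={rchrom: [(rs, re_)]}
        )
        assert k == "in_germline_cnv"

    def test_difficult_region_tag(self):
        ref, dsa, lmap, somatic, expected, _ = self._scenario()
        i = expected.index("unchanged")
        v = somatic[i]
        lift = lift_variant(v.chrom, v.pos, v.end, lmap)
        rchrom, rs, re_, _ = lift.intervals[0]
        k = classify_representation(
            v, dsa, ref, lmap, difficult={rchrom: [(rs, re_)]}
        )
        assert k == "difficult_region"


class TestBenchmarkRegions:
    def _variants(self):
        return [
            {"chrom": "r", "start": 100, "end": 201, "rep_class": "unchanged",
             "subclonal": False},
            {"chrom": "r", "start": 300, "end": 401, "rep_class": "size_changed",
             "subclonal": False},
            {"chrom": "r", "start": 500, "end": 601, "rep_class": "unchanged",
             "subclonal": True},
        ]

    def test_tiers_nest_as_documented(self):
        tiers = build_benchmark_regions(self._variants())
        assert tiers["all"]["r"] == [(100, 201), (300, 401)]
        # subclonal region absent everywhere
        assert all((500, 601) not in t.get("r", []) for t in tiers.values())
        # germline-interference region removed from tier 2 only
        assert tiers["nogermlineinterference"]["r"] == [(100, 201)]

    def test_sv_breakpoint_exclusion_hits_all_tiers(self):
        tiers = build_benchmark_regions(
            self._variants(), exclusions={"r": [(150, 160)]}
        )
        for t in tiers.values():
            assert (100, 201) not in t.get("r", [])
            assert (100, 150) in t.get("r", [])

    def test_germline_proximity_only_affects_strictest_tier(self):
        tiers = build_benchmark_regions(
            self._variants(), germline_positions=[("r", 130)]
        )
        assert (100, 201) in tiers["all"]["r"]
        assert (100, 201) not in tiers["nogermlinewithin50bp"]["r"]
        # 50 bp on each side of the germline site is cut out
        assert (100, 80) not in tiers["nogermlinewithin50bp"]["r"]

    def test_no_exclusions_no_germline_tiers_identical(self):
        vs = [v for v in self._variants() if v["rep_class"] == "unchanged"
              and not v["subclonal"]]
        tiers = build_benchmark_regions(vs)
        assert tiers["all"] == tiers["nogermlineinterference"] == tiers["nogermlinewithin50bp"]


def _cluster_oracle(variants, params):
    """Brute force: all maximal same-haplotype runs with gaps <= max_gap."""
    out = []
    tracks = {}
    for chrom, pos, hap, vid in variants:
        tracks.setdefault((chrom, hap), []).append((pos, vid))
    for (chrom, hap), items in tracks.items():
        items.sort()
        i = 0
        while i < len(items):
            j = i
            while j + 1 < len(items) and items[j + 1][0] - items[j][0] <= params.max_gap:
                j += 1
            n = j - i + 1
            if n >= params.kataegis_min:
                out.append((chrom, hap, i, j, "kataegis"))
            elif params.omikli_min <= n <= params.omikli_max:
                out.append((chrom, hap, i, j, "omikli"))
            i = j + 1
    return out


class TestClusters:
    def test_seven_snvs_form_one_kataegis(self):
        vs = [("c", 1000 + 800 * i, "hap1", f"v{i}") for i in range(7)]
        calls = detect_clusters(vs)
        assert len(calls) == 1 and calls[0].klass == "kataegis"
        assert len(calls[0].members) == 7

    def test_three_close_snvs_form_omikli(self):
        vs = [("c", 100, "hap1", "a"), ("c", 500, "hap1", "b"), ("c", 900, "hap1", "c")]
        calls = detect_clusters(vs)
        assert [c.klass for c in calls] == ["omikli"]

    def test_isolated_snv_no_cluster(self):
        assert detect_clusters([("c", 100, "hap1", "a")]) == []

    def test_haplotypes_tracked_separately(self):
        vs = [("c", 100, "hap1", "a"), ("c", 300, "hap2", "b"), ("c", 500, "hap1", "c")]
        calls = detect_clusters(vs)
        assert [c.klass for c in calls] == ["omikli"]
        assert calls[0].members == ["a", "c"]

    def test_matches_bruteforce_on_large_simulation(self):
        rng = np.random.default_rng(0)
        params = ClusterParams()
        pos = np.cumsum(rng.exponential(700, size=10_000)).astype(int)
        haps = rng.choice(["hap1", "hap2"], size=10_000)
        vs = [("c", int(p), h, f"v{i}") for i, (p, h) in enumerate(zip(pos, haps))]
        calls = detect_clusters(vs, params)
        oracle = _cluster_oracle(vs, params)
        assert len(calls) == len(oracle)
        got = sorted((c.chrom, c.haplotype, len(c.members), c.klass) for c in calls)
        exp = sorted((chrom, hap, j - i + 1, k) for chrom, hap, i, j, k in oracle)
        assert got == exp


class TestClusterComparison:
    def test_opposite_haplotype_false_omikli(self):
        """Variants clustered on the reference but split across haplotypes."""
        dsa_vs = [("c_h1", 100, "hap1", "a"), ("c_h2", 900, "hap2", "b"),
                  ("c_h1", 1700, "hap1", "c")]
        ref_vs = [("r", 100, "ref", "a"), ("r", 900, "ref", "b"), ("r", 1700, "ref", "c")]
        dsa = detect_clusters(dsa_vs)  # hap1 gap 1600 -> no clusters
        ref = detect_clusters(ref_vs, provenance="reference")
        assert dsa == [] and len(ref) == 1
        table = compare_cluster_sets(
            dsa, ref, {"a": "hap1", "b": "hap2", "c": "hap1"}
        )
        row = table.iloc[0]
        assert (row.status, row.cause) == ("false", "opposite_haplotypes")

    def test_germline_interaction_attribution(self):
        ref = detect_clusters([("r", 100, "ref", "a"), ("r", 500, "ref", "b")],
                              provenance="reference")
        table = compare_cluster_sets(
            [], ref, {"a": "hap1", "b": "hap1"},
            variant_rep_class={"a": "size_changed", "b": "unchanged"},
        )
        assert table.iloc[0].cause == "germline_interaction"

    def test_dsa_cluster_in_unliftable_region_is_reference_missed(self):
        dsa = detect_clusters(
            [("sat_h1", 100 + 300 * i, "hap1", f"v{i}") for i in range(6)]
        )
        table = compare_cluster_sets(dsa, [], {f"v{i}": "hap1" for i in range(6)})
        assert list(table.status) == ["reference_missed"]

    def test_identical_sets_no_false_no_missed(self):
        vs = [("c", 100 * i, "hap1", f"v{i}") for i in range(4)]
        a = detect_clusters(vs)
        b = detect_clusters(vs, provenance="reference")
        table = compare_cluster_sets(a, b, {f"v{i}": "hap1" for i in range(4)})
        assert set(table.status) == {"matched"}
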