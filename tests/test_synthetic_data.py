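import numpy as np
import pandas as pd
import pytest

from dsakit.synthetic_data import (
    ALPHA_MONOMER,
    GenomeConfig,
    SomaticConfig,
    TechProfile,
    apply_edits,
    build_normal_genome,
    derive_tumor_genome,
    shift_coordinate,
    simulate_kmer_coverage,
    simulate_methylation,
    simulate_support_tables,
)


class TestNormalGenome:
    def test_dj_units_counted(self, default_normal):
        """5 acrocentric arms x 2 haplotypes carry 10 DJ units."""
        assert len(default_normal.features("dj")) == 10

    def test_rdna_units_counted(self, default_normal):
        # 8 copies x 5 arms x 2 haplotypes
        assert len(default_normal.features("rdna_unit")) == 80

    def test_dj_sequence_unique_per_arm(self, default_normal):
        """The DJ sequence occurs exactly once per acrocentric arm per haplotype."""
        rows = default_normal.features("dj")
        dj_seqs = {
            default_normal.sequences[r.chrom][r.start : r.end]
            for r in rows.itertuples()
        }
        assert len(dj_seqs) == 1  # shared across arms
        dj = dj_seqs.pop()
        for name, seq in default_normal.sequences.items():
            expected = 1 if name.startswith("acro") else 0
            assert seq.count(dj) == expected

    def test_ledger_indexes_fasta_exactly(self, default_normal):
        g = default_normal
        for r in g.ledger.itertuples():
            s = g.sequences[r.chrom][r.start : r.end]
            if r.feature == "homopolymer":
                assert set(s) <= {r.base}
                # run is maximal: guarded on both sides
                seq = g.sequences[r.chrom]
                assert r.start == 0 or seq[r.start - 1] != r.base
                assert r.end == len(seq) or seq[r.end] != r.base
            elif r.feature in ("diTR", "TR"):
                assert s[: len(r.unit)] == r.unit

    def test_zero_het_rate_gives_identical_haplotypes(self):
        cfg = GenomeConfig(n_autosome_mimics=1, n_acrocentric_mimics=1,
                           chrom_length=80_000, array_length=40 * 171,
                           rdna_copies_per_arm=2, dj_unit_length=1_000,
                           germline_het_rate=0.0, seed=3)
        g = build_normal_genome(cfg)
        for chrom in g.chromosome_names():
            assert g.sequences[f"{chrom}_hap1"] == g.sequences[f"{chrom}_hap2"]
        assert g.germline == []

    def test_seed_determinism(self):
        cfg = GenomeConfig(n_autosome_mimics=1, n_acrocentric_mimics=1,
                           chrom_length=80_000, array_length=40 * 171,
                           rdna_copies_per_arm=2, dj_unit_length=1_000, seed=9)
        a, b = build_normal_genome(cfg), build_normal_genome(cfg)
        assert a.sequences == b.sequences
        assert a.ledger.equals(b.ledger)

    def test_satellite_array_is_monomer_tiling(self, default_normal):
        row = default_normal.features("satellite_alpha").iloc[0]
        # hap1 arrays without germline hits start as exact monomer tilings in
        # the backbone; check the array length is a monomer multiple
        assert (row.end - row.start) % len(ALPHA_MONOMER) == 0

    def test_overfull_config_rejected(self):
        with pytest.raises(ValueError, match="chrom_length|need"):
            build_normal_genome(GenomeConfig(chrom_length=30_000))


class TestTumorDerivation:
    def test_null_somatic_config_is_identity(self, small_normal):
        cfg = SomaticConfig(snv_rate=0, indel_rate_by_context={},
                            n_satellite_svs=0, rdna_loss_fraction=0, seed=1)
        tumor, truth = derive_tumor_genome(small_normal, cfg)
        assert len(truth) == 0
        assert tumor.sequences == small_normal.sequences

    def test_round_trip_truth_reproduces_tumor(self, small_tumor_pair, small_normal):
        tumor, truth = small_tumor_pair
        for name, seq in small_normal.sequences.items():
            edits = [(v.pos, v.ref, v.alt) for v in truth.on_haplotype(name)]
            assert apply_edits(seq, edits) == tumor.sequences[name]

    def test_satellite_sv_sizes_are_monomer_multiples(self, small_tumor_pair):
        _, truth = small_tumor_pair
        sizes = [v.size for v in truth if v.mechanism == "unequal_crossover"]
        assert sizes and all(s % len(ALPHA_MONOMER) == 0 for s in sizes)

    def test_rdna_loss_fraction_respected(self, default_normal):
        tumor, truth = derive_tumor_genome(
            default_normal, SomaticConfig(rdna_loss_fraction=0.5, seed=2)
        )
        assert len(tumor.features("rdna_unit")) == 40  # of 80

    def test_clonality_split(self, small_tumor_pair):
        _, truth = small_tumor_pair
        cfs = np.array([v.cell_fraction for v in truth])
        assert ((cfs == 1.0) | ((cfs > 0) & (cfs < 1))).all()
        assert (cfs == 1.0).sum() > 0

    def test_no_overlapping_events_per_haplotype(self, small_tumor_pair):
        _, truth = small_tumor_pair
        for name in {v.chrom for v in truth}:
            vs = truth.on_haplotype(name)
            for a, b in zip(vs, vs[1:]):
                assert a.end <= b.pos

    def test_seed_determinism(self, small_normal):
        cfg = SomaticConfig(seed=4)
        t1 = derive_tumor_genome(small_normal, cfg)[1].to_dataframe()
        t2 = derive_tumor_genome(small_normal, cfg)[1].to_dataframe()
        assert t1.equals(t2)


class TestEditPrimitives:
    def test_apply_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            apply_edits("ACGTACGT", [(2, "GTA", "G"), (3, "T", "A")])

    def test_apply_rejects_ref_mismatch(self):
        with pytest.raises(ValueError, match="REF"):
            apply_edits("ACGT", [(1, "G", "T")])

    def test_shift_through_indels(self):
        edits = [(2, "GTA", "G"), (10, "A", "ACC")]
        assert shift_coordinate(0, edits) == 0
        assert shift_coordinate(5, edits) == 3  # after a 2 bp deletion
        assert shift_coordinate(12, edits) == 12  # after +2 insertion and -2 del


class TestKmerCoverage:
    def test_poisson_means_by_multiplicity(self, small_normal):
        table = simulate_kmer_coverage(small_normal, k=21, depth=30, seed=0)
        uni = table.counts[table.multiplicity == 2]  # diploid single-copy
        assert len(uni) > 1000
        se = np.sqrt(60 / len(uni))
        assert abs(uni.mean() - 60) < 3 * se

    def test_zero_depth_zero_counts(self, small_normal):
        table = simulate_kmer_coverage(small_normal, k=21, depth=0, seed=0)
        assert table.counts.sum() == 0

    def test_k_floor(self, small_normal):
        with pytest.raises(ValueError):
            simulate_kmer_coverage(small_normal, k=9, depth=30, seed=0)


class TestSupportTables:
    def test_zero_noise_limit(self, small_tumor_pair):
        _, truth = small_tumor_pair
        prof = [TechProfile("element", depth=30, base_error=0.0)]
        recs = simulate_support_tables(truth, prof, sampling="expected")
        for v, r in zip(truth, recs):
            c = r.counts["element"]
            assert c.tumor_cov == 30 and c.normal_alt == 0
            if v.truncal:
                assert c.tumor_alt == 30

    def test_vaf_concentrates_at_cell_fraction(self):
        from dsakit.synthetic_data import SomaticTruthSet, SomaticVariant

        v = SomaticVariant("c_hap1", 10, "A", "T", "hap1", 0.5, "none", "snv")
        prof = [TechProfile("element", depth=4000, base_error=0.0)]
        recs = simulate_support_tables(SomaticTruthSet([v]), prof, seed=3)
        c = recs[0].counts["element"]
        assert abs(c.tumor_alt / c.tumor_cov - 0.5) < 0.05

    def test_context_flags_from_ledger(self, small_normal):
        from dsakit.synthetic_data import SomaticTruthSet, SomaticVariant

        hp = small_normal.features("homopolymer").iloc[0]
        v = SomaticVariant(hp.chrom, int(hp.start) + 1, "X", "Y", "hap1", 1.0,
                           "homopolymer", "slippage")
        recs = simulate_support_tables(
            SomaticTruthSet([v]), ledger=small_normal.ledger, sampling="expected"
        )
        assert recs[0].homopolymer_len == hp.end - hp.start

    def test_empty_profiles_rejected(self, small_tumor_pair):
        with pytest.raises(ValueError):
            simulate_support_tables(small_tumor_pair[1], [])


class TestMethylation:
    SEQ = ("ACGTT" * 40 + "CG" * 30 + "TTACG" * 40)  # CpG-bearing toy unit

    def test_extreme_means_saturate(self):
        regions = {"a": (0, len(self.SEQ))}
        hi = simulate_methylation(self.SEQ, regions, {"a": (1.0, 0.0, 100)}, 0)
        lo = simulate_methylation(self.SEQ, regions, {"a": (0.0, 0.0, 100)}, 0)
        assert (hi.modified == hi.coverage).all()
        assert (lo.modified == 0).all()

    def test_coverage_column_constant(self):
        df = simulate_methylation(self.SEQ, {"a": (0, len(self.SEQ))},
                                  {"a": (0.5, 0.1, 150)}, 0)
        assert (df.coverage == 150).all()

    def test_mean_recovery(self):
        df = simulate_methylation(self.SEQ, {"a": (0, len(self.SEQ))},
                                  {"a": (0.8, 0.01, 200)}, 1)
        assert df.modified.sum() / df.coverage.sum() == pytest.approx(0.8, abs=0.05)
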