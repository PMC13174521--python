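import itertools

import pytest

from dsakit.evidence_rules import (
    PolishCandidate,
    SupportRecord,
    TechCounts,
    TruncalThresholds,
    classify_truncal,
    evaluate_polish_candidate,
    merge_polish_edits,
)
from dsakit.io_formats import VariantRecord


# -- independent brute-force oracles, coded straight from the stated rules --


def _polish_oracle(c: PolishCandidate) -> bool:
    if c.genotype != "hom":
        return False
    if c.gq <= 4:
        return False
    if c.local_coverage >= 2 * c.mean_coverage:
        return False
    if c.technology == "ont":
        if c.homopolymer_len > 6 or c.ditr_len > 11:
            return False
        if c.variant_type != "snv" and c.indel_size in (1, 2):
            return False
        if c.gq < 10:
            return False
    if c.technology == "hifi":
        if (c.homopolymer_len > 6 or c.ditr_len > 11) and c.element_small_indel_present:
            return False
    return True


def _truncal_oracle(r: SupportRecord, classes) -> str:
    hp_covered = r.homopolymer_len > 6 and r.short_read_cov > 5
    ignore_short = r.indel_size > 10 or r.low_mq
    votes = []
    for tech, c in r.counts.items():
        if classes[tech] == "long" and hp_covered:
            continue
        if classes[tech] == "short" and ignore_short:
            continue
        if c.tumor_cov <= 5 or c.normal_cov <= 5:
            continue
        tgate = 0.30 if r.in_somatic_duplication else 0.50
        votes.append(
            c.tumor_alt / c.tumor_cov > tgate and c.normal_alt / c.normal_cov < 0.10
        )
    hap_votes = []
    if not ignore_short:
        for hap, c in r.hap_counts.items():
            if c.tumor_cov <= 5 or c.normal_cov <= 5:
                continue
            tv, nv = c.tumor_alt / c.tumor_cov, c.normal_alt / c.normal_cov
            hap_votes.append((tv > 0.30 and nv < 0.10) or (tv > 0.90 and nv < 0.70))
    if not votes and not hap_votes:
        return "insufficient_evidence"
    ok = all(votes) and (any(hap_votes) if hap_votes else True)
    return "truncal" if ok else "not_somatic"


class TestPolishRules:
    @pytest.mark.parametrize(
        "kwargs,accept,reason_part",
        [
            (dict(technology="ont", genotype="hom", gq=9, local_coverage=30,
                  mean_coverage=30), False, "GQ<10"),
            (dict(technology="ont", genotype="hom", gq=30, local_coverage=30,
                  mean_coverage=30, variant_type="ins", indel_size=1), False, "indel"),
            (dict(technology="hifi", genotype="hom", gq=30, local_coverage=30,
                  mean_coverage=30, variant_type="del", indel_size=1,
                  homopolymer_len=8, element_small_indel_present=True), False, "short-accurate"),
            (dict(technology="short-accurate", genotype="hom", gq=4,
                  local_coverage=30, mean_coverage=30), False, "GQ"),
            (dict(technology="short-accurate", genotype="hom", gq=40,
                  local_coverage=36, mean_coverage=30), True, ""),
            (dict(technology="hifi", genotype="hom", gq=30, local_coverage=30,
                  mean_coverage=30, homopolymer_len=8,
                  element_small_indel_present=False), True, ""),
            (dict(technology="ont", genotype="het", gq=40, local_coverage=30,
                  mean_coverage=30), False, "het"),
        ],
    )
    def test_stated_rules(self, kwargs, accept, reason_part):
        d = evaluate_polish_candidate(PolishCandidate(**kwargs))
        assert d.accept is accept
        if not accept:
            assert reason_part.lower() in d.reason.lower()

    def test_unknown_technology_raises(self):
        with pytest.raises(ValueError):
            evaluate_polish_candidate(
                PolishCandidate("nanopore2", "hom", 30, 30, 30)
            )

    def test_exhaustive_grid_matches_oracle(self):
        """>=10^4 combinations agree with an independently coded oracle."""
        n = 0
        for tech, gt, gq, cov_ratio, vtype, isize, hp, ditr, elem in itertools.product(
            ("short-accurate", "hifi", "ont"),
            ("hom", "het"),
            (0, 4, 5, 9, 10, 40),
            (0.5, 1.0, 1.9, 2.0, 2.5),
            ("snv", "ins", "del"),
            (0, 1, 2, 3),
            (0, 6, 7, 12),
            (0, 11, 12),
            (False, True),
        ):
            if vtype == "snv" and isize:
                continue
            if vtype != "snv" and not isize:
                continue
            c = PolishCandidate(
                technology=tech, genotype=gt, gq=gq,
                local_coverage=30 * cov_ratio, mean_coverage=30,
                variant_type=vtype, indel_size=isize,
                homopolymer_len=hp, ditr_len=ditr,
                element_small_indel_present=elem,
            )
            assert evaluate_polish_candidate(c).accept == _polish_oracle(c)
            n += 1
        assert n >= 10_000


class TestMergePolishEdits:
    def test_identical_calls_deduplicate(self):
        v = VariantRecord("c", 10, "A", "T")
        out = merge_polish_edits({"short-accurate": [v], "ont": [VariantRecord("c", 10, "A", "T")]})
        assert len(out) == 1

    def test_edit_near_sv_removed(self):
        v = VariantRecord("c", 100, "A", "T")
        out = merge_polish_edits({"hifi": [v]}, {"c": [103]})
        assert out == []
        far = merge_polish_edits({"hifi": [v]}, {"c": [106]})
        assert len(far) == 1

    def test_conflict_resolved_by_priority(self):
        ont = VariantRecord("c", 50, "AT", "A")
        elem = VariantRecord("c", 51, "T", "G")
        out = merge_polish_edits({"ont": [ont], "short-accurate": [elem]})
        assert [v.key() for v in out] == [elem.key()]

    def test_conflicts_match_bruteforce_resolver(self):
        """Pairwise-overlap scan with priority picks the same survivors."""
        calls = {
            "short-accurate": [VariantRecord("c", 10, "AAA", "A"),
                               VariantRecord("c", 40, "G", "C")],
            "hifi": [VariantRecord("c", 11, "A", "T"),
                     VariantRecord("c", 20, "C", "G")],
            "ont": [VariantRecord("c", 40, "GT", "G"),
                    VariantRecord("c", 60, "T", "A")],
        }
        out = {v.key() for v in merge_polish_edits(calls)}
        # oracle: sort all calls by priority then greedily keep non-overlapping
        prio = {"short-accurate": 0, "hifi": 1, "ont": 2}
        pool = sorted(
            ((prio[t], v) for t, vs in calls.items() for v in vs),
            key=lambda x: (x[0], x[1].pos),
        )
        kept = []
        for _, v in pool:
            if all(not (v.end > k.pos and k.end > v.pos) for k in kept):
                kept.append(v)
        assert out == {v.key() for v in kept}


def _record(tumor, normal, hap=None, **flags):
    counts = {
        tech: TechCounts(*tumor[tech], *normal[tech]) for tech in tumor
    }
    hap_counts = {h: TechCounts(*v) for h, v in (hap or {}).items()}
    return SupportRecord("v", counts, hap_counts, **flags)


class TestTruncalClassifier:
    def test_clear_truncal(self):
        r = _record({"element": (18, 30)}, {"element": (1, 28)})
        assert classify_truncal(r).label == "truncal"

    def test_duplication_relaxes_tumor_gate(self):
        r = _record({"element": (10, 30)}, {"element": (0, 25)},
                    in_somatic_duplication=True)
        assert classify_truncal(r).label == "truncal"
        r2 = _record({"element": (10, 30)}, {"element": (0, 25)})
        assert classify_truncal(r2).label == "not_somatic"

    def test_haplotype_alternative_gate(self):
        r = SupportRecord(
            "v", {}, {"hap1": TechCounts(19, 20, 13, 20)}  # 0.95 / 0.65
        )
        assert classify_truncal(r).label == "truncal"

    def test_low_coverage_is_insufficient(self):
        r = _record({"element": (3, 5)}, {"element": (0, 5)})
        assert classify_truncal(r).label == "insufficient_evidence"

    def test_long_reads_ignored_in_short_covered_homopolymer(self):
        r = _record(
            {"hifi": (2, 30), "element": (20, 30)},
            {"hifi": (0, 30), "element": (0, 30)},
            homopolymer_len=9, short_read_cov=30,
        )
        # HiFi would fail the 50% gate but is not applicable here
        assert classify_truncal(r).label == "truncal"
        assert "ignored" in classify_truncal(r).tech_verdicts["hifi"]

    def test_short_reads_ignored_for_large_indels(self):
        r = _record(
            {"element": (1, 30), "hifi": (25, 30)},
            {"element": (0, 30), "hifi": (0, 30)},
            indel_size=15,
        )
        assert classify_truncal(r).label == "truncal"

    def test_exhaustive_grid_matches_oracle(self):
        """>=10^4 support patterns agree with the independent truth-table oracle."""
        classes = {"element": "short", "hifi": "long"}
        alts = (0, 3, 8, 15, 16, 20, 27, 28, 30)
        n = 0
        for ta, na, ha, hn, dup, hp, isz in itertools.product(
            alts, (0, 1, 2, 3, 4), alts, (0, 2, 14, 20, 22, 30),
            (False, True), (0, 8), (0, 12),
        ):
            r = SupportRecord(
                "v",
                {"element": TechCounts(ta, 30, na, 30),
                 "hifi": TechCounts(min(ta + 2, 30), 30, na, 30)},
                {"hap1": TechCounts(ha, 30, hn, 30)},
                in_somatic_duplication=dup,
                homopolymer_len=hp,
                short_read_cov=30,
                indel_size=isz,
            )
            got = classify_truncal(r, tech_classes=classes).label
            assert got == _truncal_oracle(r, classes)
            n += 1
        assert n >= 10_000

    def test_monotone_in_tumor_alt(self):
        """Raising tumor support never flips truncal -> not_somatic."""
        prev = None
        for ta in range(31):
            r = _record({"element": (ta, 30)}, {"element": (1, 30)})
            lab = classify_truncal(r).label
            if prev == "truncal":
                assert lab == "truncal"
            prev = lab

    def test_zero_noise_recovery_from_simulator(self, small_tumor_pair):
        """Deterministic zero-error support recovers truth clonality exactly."""
        from dsakit.synthetic_data import TechProfile, simulate_support_tables

        tumor, truth = small_tumor_pair
        profiles = [
            TechProfile("element", depth=30, base_error=0.0, read_class="short"),
            TechProfile("hifi", depth=30, base_error=0.0, read_class="long"),
        ]
        records = simulate_support_tables(truth, profiles, sampling="expected")
        for v, rec in zip(truth, records):
            lab = classify_truncal(rec).label
            assert (lab == "truncal") == v.truncal
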