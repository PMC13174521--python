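"""Rule engines for assembly polishing and truncal somatic classification.

Two independent engines:

* ``evaluate_polish_candidate`` / ``merge_polish_edits`` — decide which
  DeepVariant-style calls against a draft assembly become consensus edits.
  Only homozygous calls with GQ > 4 and local coverage under twice the mean
  are candidates; ONT calls are additionally dropped in homopolymers > 6 bp,
  dinucleotide TRs > 11 bp, for 1-2 bp indels, and below GQ 10; HiFi calls
  in those repeat contexts are dropped when a short-accurate (Element-class)
  callset reports a 1-4 bp indel there, because accurate short reads win in
  such repeats when mappable.  Accepted calls are merged across
  technologies, deduplicated, pruned within 5 bp of a somatic SV breakpoint,
  and overlapping conflicts resolve by technology priority
  short-accurate > HiFi > ONT.

* ``classify_truncal`` — label a candidate somatic variant from
  per-technology tumor/normal read support.  Applicable technologies must
  show tumor VAF > 50% (30% inside somatic duplications) and normal
  VAF < 10% at coverage > 5; long reads are ignored for homopolymers
  covered by short reads, short reads for indels > 10 bp or low-MQ sites;
  per-haplotype short-read evidence passes at (>30% tumor and <10% normal)
  or (>90% tumor and <70% normal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import VariantRecord

TECH_PRIORITY = {"short-accurate": 0, "hifi": 1, "ont": 2}


# ---------------------------------------------------------------------------
# Polishing
# ---------------------------------------------------------------------------


@dataclass
class PolishCandidate:
    technology: str  # short-accurate | hifi | ont
    genotype: str  # hom | het
    gq: float
    local_coverage: float
    mean_coverage: float
    variant_type: str = "snv"  # snv | ins | del
    indel_size: int = 0
    homopolymer_len: int = 0
    ditr_len: int = 0
    element_small_indel_present: bool = False
    mapping_mode: str = "combined"  # combined | per-haplotype
    distance_to_somatic_sv: float = float("inf")
    variant: VariantRecord | None = None


@dataclass
class PolishDecision:
    accept: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.accept


def evaluate_polish_candidate(c: PolishCandidate) -> PolishDecision:
    """Apply the per-technology polishing gates to one candidate call."""
    if c.technology not in TECH_PRIORITY:
        raise ValueError(f"unknown technology {c.technology!r}")
    if c.genotype != "hom":
        return PolishDecision(False, "heterozygous")
    if not c.gq > 4:
        return PolishDecision(False, "GQ<=4")
    if c.local_coverage >= 2 * c.mean_coverage:
        return PolishDecision(False, "coverage>=2x mean")
    if c.technology == "ont":
        if c.homopolymer_len > 6:
            return PolishDecision(False, "ONT in homopolymer>6bp")
        if c.ditr_len > 11:
            return PolishDecision(False, "ONT in diTR>11bp")
        if c.variant_type in ("ins", "del") and c.indel_size in (1, 2):
            return PolishDecision(False, "ONT 1-2bp indel")
        if c.gq < 10:
            return PolishDecision(False, "ONT GQ<10")
    if c.technology == "hifi":
        if (c.homopolymer_len > 6 or c.ditr_len > 11) and c.element_small_indel_present:
            return PolishDecision(False, "HiFi deferred to short-accurate indel in repeat")
    return PolishDecision(True, "")


def merge_polish_edits(
    accepted: Mapping[str, Sequence[VariantRecord]],
    somatic_sv_positions: Mapping[str, Sequence[int]] | None = None,
    exclusion_radius: int = 5,
) -> list[VariantRecord]:
    """Merge accepted calls across technologies into a final edit set.

    ``accepted`` maps technology -> normalized calls.  Identical calls
    deduplicate; edits within ``exclusion_radius`` bp of a somatic SV
    breakpoint are removed; overlapping conflicting edits resolve by
    technology priority (short-accurate > HiFi > ONT), ties by position.
    """
    sv = {c: sorted(p) for c, p in (somatic_sv_positions or {}).items()}
    best: dict[tuple, tuple[int, VariantRecord]] = {}
    for tech, calls in accepted.items():
        if tech not in TECH_PRIORITY:
            raise ValueError(f"unknown technology {tech!r}")
        prio = TECH_PRIORITY[tech]
        for v in calls:
            k = v.key()
            if k not in best or prio < best[k][0]:
                best[k] = (prio, v)

    def near_sv(v: VariantRecord) -> bool:
        return any(
            abs(p - edge) <= exclusion_radius
            for p in sv.get(v.chrom, ())
            for edge in (v.pos, v.end - 1)
        )

    survivors = sorted(
        ((prio, v) for prio, v in best.values() if not near_sv(v)),
        key=lambda t: (t[1].chrom, t[1].pos, t[0]),
    )
    out: list[VariantRecord] = []
    out_prio: list[int] = []
    for prio, v in survivors:
        clash = None
        for i in range(len(out) - 1, -1, -1):
            if out[i].chrom != v.chrom:
                break
            if out[i].end > v.pos and v.end > out[i].pos:
                clash = i
                break
        if clash is None:
            out.append(v)
            out_prio.append(prio)
        elif prio < out_prio[clash]:
            out[clash] = v
            out_prio[clash] = prio
    return out


def apply_polish_edits(seq: str, edits: Sequence[VariantRecord]) -> str:
    """Apply non-overlapping edits to a sequence (built-in consensus)."""
    from .synthetic_data import apply_edits

    return apply_edits(seq, [(v.pos, v.ref, v.alt) for v in edits])


# ---------------------------------------------------------------------------
# Truncal classification
# ---------------------------------------------------------------------------


@dataclass
class TechCounts:
    tumor_alt: int
    tumor_cov: int
    normal_alt: int
    normal_cov: int

    def __post_init__(self) -> None:
        if self.tumor_alt > self.tumor_cov or self.normal_alt > self.normal_cov:
            raise ValueError("alt count exceeds coverage")

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_cov if self.tumor_cov else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_cov if self.normal_cov else 0.0


@dataclass
class SupportRecord:
    """Read support for one candidate somatic variant.

    ``counts`` holds combined-haplotype-mapping counts per technology;
    ``hap_counts`` holds short-read counts per haplotype.
    """

    variant_id: str
    counts: dict[str, TechCounts] = field(default_factory=dict)
    hap_counts: dict[str, TechCounts] = field(default_factory=dict)
    in_somatic_duplication: bool = False
    homopolymer_len: int = 0
    ditr_len: int = 0
    short_read_cov: int = 0
    low_mq: bool = False
    indel_size: int = 0


@dataclass
class TruncalThresholds:
    tumor_vaf_min: float = 0.50
    normal_vaf_max: float = 0.10
    min_coverage: int = 5  # strict >
    dup_tumor_vaf_min: float = 0.30
    hap_tumor_vaf_min: float = 0.30
    hap_normal_vaf_max: float = 0.10
    hap_alt_tumor_vaf_min: float = 0.90
    hap_alt_normal_vaf_max: float = 0.70
    long_read_indel_ignore_size: int = 10
    homopolymer_ignore_len: int = 6


DEFAULT_TECH_CLASSES = {
    "element": "short", "onso": "short", "illumina": "short",
    "short-accurate": "short", "hifi": "long", "ont": "long",
}


@dataclass
class TruncalVerdict:
    label: str  # truncal | not_somatic | insufficient_evidence
    tech_verdicts: dict[str, str] = field(default_factory=dict)
    hap_verdicts: dict[str, str] = field(default_factory=dict)


def classify_truncal(
    r: SupportRecord,
    t: TruncalThresholds | None = None,
    tech_classes: Mapping[str, str] | None = None,
) -> TruncalVerdict:
    """Label one support record as truncal / not_somatic / insufficient_evidence.

    Technology applicability is decided first: long-read evidence is ignored
    for homopolymers (> ``homopolymer_ignore_len``) covered by short reads,
    short-read evidence for indels > 10 bp or low-MQ sites.  Each applicable
    technology with coverage > ``min_coverage`` in both samples votes; ALL
    votes must pass for a truncal label; no votes at all (and no haplotype
    evidence) means insufficient evidence.  Per-haplotype short-read evidence
    passes when at least one haplotype satisfies either the
    (>30%, <10%) or the (>90%, <70%) tumor/normal VAF gate.
    """
    t = t or TruncalThresholds()
    classes = dict(DEFAULT_TECH_CLASSES)
    if tech_classes:
        classes.update(tech_classes)
    hp_short_covered = (
        r.homopolymer_len > t.homopolymer_ignore_len and r.short_read_cov > t.min_coverage
    )
    tumor_gate = t.dup_tumor_vaf_min if r.in_somatic_duplication else t.tumor_vaf_min

    verdicts: dict[str, str] = {}
    votes: list[bool] = []
    for tech, c in r.counts.items():
        cls = classes.get(tech, "short")
        if cls == "long" and hp_short_covered:
            verdicts[tech] = "ignored:homopolymer_covered_by_short_reads"
            continue
        if cls == "short" and (r.indel_size > t.long_read_indel_ignore_size or r.low_mq):
            verdicts[tech] = "ignored:large_indel_or_low_mq"
            continue
        if not (c.tumor_cov > t.min_coverage and c.normal_cov > t.min_coverage):
            verdicts[tech] = "no_vote:coverage"
            continue
        ok = c.tumor_vaf > tumor_gate and c.normal_vaf < t.normal_vaf_max
        verdicts[tech] = "pass" if ok else "fail"
        votes.append(ok)

    hap_verdicts: dict[str, str] = {}
    hap_votes: list[bool] = []
    hap_applicable = not (r.indel_size > t.long_read_indel_ignore_size or r.low_mq)
    if hap_applicable:
        for hap, c in r.hap_counts.items():
            if not (c.tumor_cov > t.min_coverage and c.normal_cov > t.min_coverage):
                hap_verdicts[hap] = "no_vote:coverage"
                continue
            ok = (
                c.tumor_vaf > t.hap_tumor_vaf_min and c.normal_vaf < t.hap_normal_vaf_max
            ) or (
                c.tumor_vaf > t.hap_alt_tumor_vaf_min
                and c.normal_vaf < t.hap_alt_normal_vaf_max
            )
            hap_verdicts[hap] = "pass" if ok else "fail"
            hap_votes.append(ok)

    if not votes and not hap_votes:
        return TruncalVerdict("insufficient_evidence", verdicts, hap_verdicts)
    combined_ok = all(votes) if votes else True
    hap_ok = any(hap_votes) if hap_votes else True
    label = "truncal" if combined_ok and hap_ok else "not_somatic"
    return TruncalVerdict(label, verdicts, hap_verdicts)
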