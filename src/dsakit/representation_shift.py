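"""Somatic-variant representation shift between a donor assembly and a reference.

Somatic variants called against a donor-specific assembly (DSA) can look
completely different when projected onto a generic reference, because the
projection composes the somatic change with the donor's germline variation.
This module lifts variants through an explicit block alignment map,
re-derives each variant's reference-based representation by local
realignment, classifies the change, builds the tiered benchmark regions,
and detects kataegis/omikli SNV clusters with haplotype-aware attribution
of clusters that only exist in the reference projection.

Representation classes, in precedence order: unliftable > multi_lift >
in_germline_cnv > reverts_germline > type_changed > size_changed >
difficult_region > position_shift_only > unchanged.  Type is compared at
SNV-vs-indel granularity, so a somatic deletion that surfaces as a net
insertion of different length on the reference is a size change, while a
somatic SNV surfacing as an indel is a type change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .io_formats import (
    VariantRecord,
    merge_intervals,
    normalize_variant,
    parse_cigar,
    revcomp,
    subtract_intervals,
)

REPRESENTATION_CLASSES = (
    "unliftable",
    "multi_lift",
    "in_germline_cnv",
    "reverts_germline",
    "type_changed",
    "size_changed",
    "difficult_region",
    "position_shift_only",
    "unchanged",
)

GERMLINE_INTERFERENCE = {"type_changed", "size_changed", "reverts_germline"}


# ---------------------------------------------------------------------------
# Lift map
# ---------------------------------------------------------------------------


@dataclass
class LiftBlock:
    dsa_chrom: str
    dsa_start: int
    dsa_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.dsa_end - self.dsa_start != self.ref_end - self.ref_start:
            raise ValueError("block sides differ in length")


@dataclass
class LiftMap:
    """Ordered, DSA-non-overlapping alignment blocks (chain-file-like)."""

    blocks: list[LiftBlock]
    min_match: float = 0.1

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: (b.dsa_chrom, b.dsa_start))
        prev: LiftBlock | None = None
        for b in self.blocks:
            if prev and prev.dsa_chrom == b.dsa_chrom and b.dsa_start < prev.dsa_end:
                raise ValueError("blocks overlap on the DSA side")
            prev = b

    @classmethod
    def from_tsv(cls, path: str, min_match: float = 0.1) -> "LiftMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                LiftBlock(r.dsa_chrom, r.dsa_start, r.dsa_end,
                          r.ref_chrom, r.ref_start, r.ref_end, r.strand)
                for r in df.itertuples()
            ],
            min_match,
        )

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            [
                {
                    "dsa_chrom": b.dsa_chrom, "dsa_start": b.dsa_start,
                    "dsa_end": b.dsa_end, "ref_chrom": b.ref_chrom,
                    "ref_start": b.ref_start, "ref_end": b.ref_end,
                    "strand": b.strand,
                }
                for b in self.blocks
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_germline_edits(
        cls,
        ref_lengths: Mapping[str, int],
        edits: Mapping[str, Sequence[tuple[int, str, str]]],
        dsa_suffix: str = "",
        min_match: float = 0.1,
    ) -> "LiftMap":
        """Exact map for a DSA built by applying (pos, ref, alt) edits.

        Matched segments between consecutive edits become blocks; edited
        spans are left unmapped (so large DSA-only insertions are
        unliftable territory).
        """
        blocks = []
        for chrom, length in ref_lengths.items():
            dsa_chrom = chrom + dsa_suffix
            evs = sorted(edits.get(chrom, []), key=lambda e: e[0])
            rpos = dpos = 0
            for pos, ref, alt in evs:
                if pos > rpos:
                    blocks.append(
                        LiftBlock(dsa_chrom, dpos, dpos + pos - rpos, chrom, rpos, pos)
                    )
                dpos += (pos - rpos) + len(alt)
                rpos = pos + len(ref)
            if rpos < length:
                blocks.append(
                    LiftBlock(dsa_chrom, dpos, dpos + length - rpos, chrom, rpos, length)
                )
        return cls(blocks, min_match)

    def project_point(self, chrom: str, pos: int) -> tuple[str, int] | None:
        for b in self.blocks:
            if b.dsa_chrom == chrom and b.dsa_start <= pos < b.dsa_end:
                off = pos - b.dsa_start
                if b.strand == "+":
                    return b.ref_chrom, b.ref_start + off
                return b.ref_chrom, b.ref_end - 1 - off
        return None


@dataclass
class LiftResult:
    status: str  # lifted | unliftable | multi_lift
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)


def lift_variant(
    chrom: str,
    start: int,
    end: int,
    lift_map: LiftMap,
    slop: int = 50,
) -> LiftResult:
    """Project a slopped DSA interval through the block map.

    The interval is extended by ``slop`` on each side; overlapping blocks
    are grouped into colinear runs (same reference sequence and strand,
    monotone order); a run is a target when it covers at least ``min_match``
    of the slopped interval.  No targets -> unliftable; two or more disjoint
    reference targets -> multi_lift.
    """
    s = max(0, start - slop)
    e = end + slop
    span = e - s
    blocks = [
        b
        for b in lift_map.blocks
        if b.dsa_chrom == chrom and b.dsa_start < e and b.dsa_end > s
    ]
    runs: list[list[LiftBlock]] = []
    for b in blocks:
        if runs and _colinear(runs[-1][-1], b):
            runs[-1].append(b)
        else:
            runs.append([b])
    targets: list[tuple[str, int, int, str]] = []
    for run in runs:
        covered = sum(min(b.dsa_end, e) - max(b.dsa_start, s) for b in run)
        if covered / span < lift_map.min_match:
            continue
        pts = []
        for b in run:
            lo, hi = max(b.dsa_start, s), min(b.dsa_end, e)
            for p in (lo, hi - 1):
                off = p - b.dsa_start
                pts.append(
                    b.ref_start + off if b.strand == "+" else b.ref_end - 1 - off
                )
        targets.append((run[0].ref_chrom, min(pts), max(pts) + 1, run[0].strand))
    if not targets:
        return LiftResult("unliftable")
    merged: list[tuple[str, int, int, str]] = []
    for t in sorted(targets):
        if merged and merged[-1][0] == t[0] and t[1] <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (prev[0], prev[1], max(prev[2], t[2]), prev[3])
        else:
            merged.append(t)
    if len(merged) > 1:
        return LiftResult("multi_lift", merged)
    return LiftResult("lifted", merged)


#: largest reference-gap excess (bp) over the DSA gap for two blocks to count
#: as one colinear chain; larger jumps are treated as distinct lift targets
MAX_CHAIN_GAP = 5_000


def _colinear(a: LiftBlock, b: LiftBlock) -> bool:
    if a.ref_chrom != b.ref_chrom or a.strand != b.strand or a.dsa_chrom != b.dsa_chrom:
        return False
    dsa_gap = b.dsa_start - a.dsa_end
    if a.strand == "+":
        ref_gap = b.ref_start - a.ref_end
        return ref_gap >= 0 and ref_gap - dsa_gap <= MAX_CHAIN_GAP
    ref_gap = a.ref_start - b.ref_end
    return ref_gap >= 0 and ref_gap - dsa_gap <= MAX_CHAIN_GAP


# ---------------------------------------------------------------------------
# Representation classification
# ---------------------------------------------------------------------------


def _align_variants(query: str, target: str, offset: int, chrom: str) -> list[VariantRecord]:
    """VCF-style anchored diffs of query vs target from a global alignment."""
    if query == target:
        return []
    res = edlib.align(query, target, task="path")
    out: list[VariantRecord] = []
    qi = ti = 0
    for n, op in parse_cigar(res["cigar"]):
        if op == "=":
            qi += n
            ti += n
        elif op == "X":
            for j in range(n):
                out.append(
                    VariantRecord(chrom, offset + ti + j, target[ti + j], query[qi + j])
                )
            qi += n
            ti += n
        elif op == "I":  # present in query, absent in target
            anchor = ti - 1
            if anchor < 0:
                qi += n
                continue
            out.append(
                VariantRecord(
                    chrom, offset + anchor,
                    target[anchor], target[anchor] + query[qi : qi + n],
                )
            )
            qi += n
        elif op == "D":
            anchor = ti - 1
            if anchor < 0:
                ti += n
                continue
            out.append(
                VariantRecord(
                    chrom, offset + anchor,
                    target[anchor : ti + n], target[anchor],
                )
            )
            ti += n
    return out


def _merge_adjacent_diffs(
    diffs: list[VariantRecord], target: str, gap: int = 3
) -> list[VariantRecord]:
    """Collapse alignment-fragment diffs separated by <= ``gap`` matched bases.

    Optimal edit-distance alignments are not unique: one biological event can
    surface as several interleaved fragments.  Fragments of a single local
    event are merged into one replacement variant (then normalized), so the
    comparison sees the event the way a variant caller would emit it.
    """
    if not diffs:
        return []
    diffs = sorted(diffs, key=lambda v: (v.pos, v.end))
    groups: list[list[VariantRecord]] = [[diffs[0]]]
    for v in diffs[1:]:
        if v.pos - groups[-1][-1].end <= gap:
            groups[-1].append(v)
        else:
            groups.append([v])
    out = []
    for g in groups:
        if len(g) == 1:
            out.append(normalize_variant(g[0], target))
            continue
        s = min(v.pos for v in g)
        e = max(v.end for v in g)
        alt_parts = []
        cur = s
        for v in g:
            alt_parts.append(target[cur : v.pos])
            alt_parts.append(v.alt)
            cur = v.end
        alt_parts.append(target[cur:e])
        out.append(
            normalize_variant(
                VariantRecord(g[0].chrom, s, target[s:e], "".join(alt_parts)), target
            )
        )
    return out


def _snv_or_indel(v) -> str:
    return "snv" if len(v.ref) == 1 and len(v.alt) == 1 else "indel"


def classify_representation(
    somatic,
    dsa_sequences: Mapping[str, str],
    ref_sequences: Mapping[str, str],
    lift_map: LiftMap,
    germline_cnv: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    difficult: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    slop: int = 50,
) -> str:
    """How does this DSA somatic variant look when called on the reference?

    ``somatic`` needs chrom/pos/ref/alt on DSA coordinates.  The +-slop
    window is lifted, the local tumor haplotype (DSA + somatic) and the
    local reference are realigned, the germline-only diffs (DSA vs
    reference) are subtracted, and the residual reference-based
    representation is compared with the truth.
    """
    chrom = somatic.chrom
    v_end = somatic.pos + len(somatic.ref)
    lift = lift_variant(chrom, somatic.pos, v_end, lift_map, slop)
    if lift.status == "unliftable":
        return "unliftable"
    if lift.status == "multi_lift":
        return "multi_lift"
    ref_chrom, r_s, r_e, strand = lift.intervals[0]
    for s, e in (germline_cnv or {}).get(ref_chrom, ()):
        if s < r_e and e > r_s:
            return "in_germline_cnv"
    dsa_seq = dsa_sequences[chrom]
    a = max(0, somatic.pos - slop)
    b = min(len(dsa_seq), v_end + slop)
    window = dsa_seq[a:b]
    off = somatic.pos - a
    if window[off : off + len(somatic.ref)] != somatic.ref:
        raise ValueError("somatic REF does not match the DSA sequence")
    tumor_window = window[:off] + somatic.alt + window[off + len(somatic.ref) :]
    if ref_chrom not in ref_sequences:
        raise ValueError(f"reference window unavailable for {ref_chrom}")
    ref_window = ref_sequences[ref_chrom][r_s:r_e]
    if strand == "-":
        ref_window = revcomp(ref_window)

    germ = _merge_adjacent_diffs(
        _align_variants(window, ref_window, 0, ref_chrom), ref_window
    )
    tum = _merge_adjacent_diffs(
        _align_variants(tumor_window, ref_window, 0, ref_chrom), ref_window
    )
    germ_keys = {g.key() for g in germ}
    residual = [t for t in tum if t.key() not in germ_keys]
    if not residual:
        return "reverts_germline"

    cat = _snv_or_indel(somatic)
    res_cats = {_snv_or_indel(t) for t in residual}
    if res_cats != {cat}:
        return "type_changed"
    klass = None
    if len(residual) > 1:
        klass = "size_changed" if cat == "indel" else "type_changed"
    else:
        d = normalize_variant(residual[0], ref_window)
        if cat == "indel":
            same = (
                abs(len(d.alt) - len(d.ref)) == abs(len(somatic.alt) - len(somatic.ref))
                and (len(d.alt) > len(d.ref)) == (len(somatic.alt) > len(somatic.ref))
            )
            if not same:
                klass = "size_changed"
        else:
            if d.alt != somatic.alt:
                klass = "type_changed"
        if klass is None:
            for s, e in (difficult or {}).get(ref_chrom, ()):
                if s < r_e and e > r_s:
                    klass = "difficult_region"
                    break
        if klass is None:
            naive = lift_map.project_point(chrom, somatic.pos)
            expected = naive[1] - r_s if naive else None
            klass = "unchanged" if expected is not None and d.pos == expected else "position_shift_only"
    if klass is None:
        klass = "size_changed"
    if klass in ("unchanged",):
        return klass
    if klass == "position_shift_only":
        for s, e in (difficult or {}).get(ref_chrom, ()):
            if s < r_e and e > r_s:
                return "difficult_region"
    return klass


# ---------------------------------------------------------------------------
# Benchmark region tiers
# ---------------------------------------------------------------------------


def build_benchmark_regions(
    variant_regions: Sequence[dict],
    exclusions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    germline_positions: Sequence[tuple[str, int]] = (),
    germline_slop: int = 50,
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Three benchmark BED tiers from classified, lifted somatic regions.

    ``variant_regions`` entries need chrom/start/end (lifted, slopped,
    reference coordinates), ``rep_class`` and ``subclonal``.  Tier ``all``
    is every confidently-lifted truncal region minus the exclusion set;
    ``nogermlineinterference`` further removes regions whose variant's
    representation class shows germline interference; ``nogermlinewithin50bp``
    removes any region within ``germline_slop`` of a germline variant.
    """
    excl = {c: merge_intervals(list(iv)) for c, iv in (exclusions or {}).items()}
    base: dict[str, list[tuple[int, int]]] = {}
    interfere: dict[str, list[tuple[int, int]]] = {}
    for v in variant_regions:
        if v.get("subclonal"):
            continue
        if v.get("rep_class") in ("unliftable", "multi_lift"):
            continue
        base.setdefault(v["chrom"], []).append((v["start"], v["end"]))
        if v.get("rep_class") in GERMLINE_INTERFERENCE:
            interfere.setdefault(v["chrom"], []).append((v["start"], v["end"]))
    tier1 = {
        c: subtract_intervals(iv, excl.get(c, [])) for c, iv in base.items()
    }
    tier2 = {
        c: subtract_intervals(iv, interfere.get(c, [])) for c, iv in tier1.items()
    }
    germ: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos in germline_positions:
        germ.setdefault(chrom, []).append((pos - germline_slop, pos + germline_slop + 1))
    tier3 = {c: subtract_intervals(iv, germ.get(c, [])) for c, iv in tier1.items()}
    return {
        "all": {c: iv for c, iv in tier1.items() if iv},
        "nogermlineinterference": {c: iv for c, iv in tier2.items() if iv},
        "nogermlinewithin50bp": {c: iv for c, iv in tier3.items() if iv},
    }


# ---------------------------------------------------------------------------
# Kataegis / omikli clusters
# ---------------------------------------------------------------------------


@dataclass
class ClusterParams:
    max_gap: int = 1_000
    kataegis_min: int = 6
    omikli_min: int = 2
    omikli_max: int = 5

    def __post_init__(self) -> None:
        if not self.omikli_max < self.kataegis_min:
            raise ValueError("omikli_max must be < kataegis_min")


@dataclass
class ClusterCall:
    chrom: str
    start: int
    end: int
    members: list[str]
    klass: str  # kataegis | omikli
    haplotype: str | None = None
    provenance: str = "dsa"  # dsa | reference


def detect_clusters(
    variants: Sequence[tuple[str, int, str, str]],
    params: ClusterParams | None = None,
    provenance: str = "dsa",
) -> list[ClusterCall]:
    """Greedy maximal runs of nearby same-haplotype SNVs.

    ``variants`` are (chrom, pos, haplotype, id) tuples (SNVs).  Consecutive
    variants on one (chrom, haplotype) track join a run while the gap is
    <= ``max_gap``; runs of >= ``kataegis_min`` members are kataegis, runs
    inside [omikli_min, omikli_max] are omikli, smaller runs are dropped.
    """
    params = params or ClusterParams()
    tracks: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for chrom, pos, hap, vid in variants:
        tracks.setdefault((chrom, hap), []).append((pos, vid))
    out: list[ClusterCall] = []
    for (chrom, hap), items in tracks.items():
        items.sort()
        run: list[tuple[int, str]] = []
        for pos, vid in items + [(None, None)]:
            if run and (pos is None or pos - run[-1][0] > params.max_gap):
                n = len(run)
                if n >= params.kataegis_min:
                    klass = "kataegis"
                elif params.omikli_min <= n <= params.omikli_max:
                    klass = "omikli"
                else:
                    klass = None
                if klass:
                    out.append(
                        ClusterCall(
                            chrom, run[0][0], run[-1][0] + 1,
                            [v for _, v in run], klass, hap, provenance,
                        )
                    )
                run = []
            if pos is not None:
                run.append((pos, vid))
    out.sort(key=lambda c: (c.chrom, c.start))
    return out


def compare_cluster_sets(
    dsa_clusters: Sequence[ClusterCall],
    ref_clusters: Sequence[ClusterCall],
    variant_haplotype: Mapping[str, str],
    variant_rep_class: Mapping[str, str] | None = None,
    overlap_min: float = 0.5,
) -> pd.DataFrame:
    """Attribute reference-projected clusters without a DSA counterpart.

    A reference cluster is matched when some single DSA cluster contains at
    least ``overlap_min`` of its members.  Unmatched ("false") clusters are
    attributed to opposite_haplotypes when their members span both
    haplotypes, else to germline_interaction when any member's
    representation class shows germline interference, else to "other".
    DSA clusters with no matching reference cluster are reference_missed.
    """
    rep = variant_rep_class or {}
    dsa_sets = [set(c.members) for c in dsa_clusters]
    rows = []
    matched_dsa: set[int] = set()
    for c in ref_clusters:
        mem = set(c.members)
        best_i, best_frac = None, 0.0
        for i, d in enumerate(dsa_sets):
            frac = len(mem & d) / len(mem)
            if frac > best_frac:
                best_i, best_frac = i, frac
        if best_frac >= overlap_min:
            matched_dsa.add(best_i)
            rows.append(_row(c, "matched", ""))
            continue
        haps = {variant_haplotype[m] for m in mem if m in variant_haplotype}
        if len(haps) > 1:
            cause = "opposite_haplotypes"
        elif any(rep.get(m) in GERMLINE_INTERFERENCE | {"in_germline_cnv"} for m in mem):
            cause = "germline_interaction"
        else:
            cause = "other"
        rows.append(_row(c, "false", cause))
    ref_sets = [set(c.members) for c in ref_clusters]
    for i, c in enumerate(dsa_clusters):
        mem = set(c.members)
        best = max((len(mem & r) / len(mem) for r in ref_sets), default=0.0)
        if i not in matched_dsa and best < overlap_min:
            rows.append(_row(c, "reference_missed", ""))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "class", "provenance", "n_members",
                 "status", "cause"],
    )


def _row(c: ClusterCall, status: str, cause: str) -> dict:
    return {
        "chrom": c.chrom, "start": c.start, "end": c.end, "class": c.klass,
        "provenance": c.provenance, "n_members": len(c.members),
        "status": status, "cause": cause,
    }
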