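"""Readers, writers and normalizers for the formats every stage touches.

All coordinates are 0-based half-open internally; only VCF I/O shifts to
1-based.  PAF is the alignment dialect of record; SAM is accepted via
conversion upstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """A small variant with 0-based position and explicit REF/ALT strings.

    ``pos`` is the 0-based coordinate of the first REF base.  ``info`` carries
    free-form key/value tags (HAP, CF, MECH ... at I/O time).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    quality: float | None = None
    genotype: str | None = None
    info: dict = field(default_factory=dict)

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snv"
        if len(self.alt) > len(self.ref):
            return "ins"
        if len(self.alt) < len(self.ref):
            return "del"
        return "mnv"

    @property
    def size(self) -> int:
        """Net size change in bp (0 for SNV/MNV)."""
        return abs(len(self.alt) - len(self.ref))

    @property
    def end(self) -> int:
        """0-based half-open end on the reference."""
        return self.pos + len(self.ref)

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize_variant(v: VariantRecord, seq: str) -> VariantRecord:
    """Left-align and parsimony-trim a variant against its sequence.

    Idempotent.  ``seq`` is the full sequence of ``v.chrom``.  SNVs pass
    through untouched; indels are trimmed to the minimal representation then
    shifted left while the last base of the longer allele equals the base
    preceding the variant.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    # trim common suffix (keep at least one base per allele)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # left-align indels: while both alleles end in the same base, drop it and
    # prepend the preceding reference base
    if len(ref) != len(alt):
        while pos > 0 and ref[-1] == alt[-1]:
            prev = seq[pos - 1]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
    return VariantRecord(v.chrom, pos, ref, alt, v.quality, v.genotype, dict(v.info))


def read_variants(path: str) -> list[VariantRecord]:
    """Read a VCF (v4.2+) into internal records, splitting multiallelics."""
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                info = {k: rec.info[k] for k in rec.info}
                gt = None
                if rec.samples:
                    s = rec.samples[0]
                    if "GT" in s and s["GT"] is not None:
                        gt = "/".join("." if a is None else str(a) for a in s["GT"])
                out.append(
                    VariantRecord(
                        rec.chrom,
                        rec.pos - 1,
                        rec.ref,
                        str(alt),
                        rec.qual,
                        gt,
                        info,
                    )
                )
    return out


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=HAP,Number=1,Type=String,Description="Haplotype carrying the variant">
##INFO=<ID=CF,Number=1,Type=Float,Description="Cell fraction">
##INFO=<ID=MECH,Number=1,Type=String,Description="Generating mechanism">
##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Repeat context class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_variants(path: str, variants: Iterable[VariantRecord], contigs: dict[str, int] | None = None, sample: str = "sample") -> None:
    """Write records as VCF v4.2 (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n" % sample)
        for v in variants:
            info = ";".join(
                f"{k}={v.info[k]:.4g}" if isinstance(v.info[k], float) else f"{k}={v.info[k]}"
                for k in v.info
            ) or "."
            qual = "." if v.quality is None else f"{v.quality:g}"
            gt = v.genotype or "./."
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t{qual}\tPASS\t{info}\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# Intervals (BED)
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Sequence[tuple[int, int]], merge_adjacent: bool = True
) -> list[tuple[int, int]]:
    """Sort and merge half-open intervals on one sequence.

    Overlapping intervals always merge; abutting (end == start) intervals
    merge only when ``merge_adjacent``.
    """
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s < out[-1][1] or (merge_adjacent and s == out[-1][1]):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(
    base: Sequence[tuple[int, int]], minus: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set-subtract ``minus`` from ``base`` (both half-open, one sequence)."""
    base = merge_intervals(base)
    minus = merge_intervals(minus)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in base:
        cur = s
        while j < len(minus) and minus[j][1] <= cur:
            j += 1
        k = j
        while k < len(minus) and minus[k][0] < e:
            ms, me = minus[k]
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if me >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intervals_total_bp(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def read_intervals(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read BED (3+ columns) into per-sequence half-open interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start > end:
                raise ValueError(f"{path}:{i}: start > end")
            out.setdefault(chrom, []).append((start, end))
    return out


def write_intervals(path: str, intervals: dict[str, list[tuple[int, int]]]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Alignments (PAF / CIGAR)
# ---------------------------------------------------------------------------


@dataclass
class AlignmentRecord:
    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_start: int
    target_end: int
    n_matches: int
    alignment_length: int
    cigar: str | None = None
    tags: dict = field(default_factory=dict)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


def gap_compressed_identity(cigar: str) -> float:
    """matches / (matches + mismatches + gap openings) from an extended CIGAR.

    Requires ``=``/``X`` ops; a CIGAR using ambiguous ``M`` is rejected.
    Each run of I or D counts as a single difference event.
    """
    ops = parse_cigar(cigar)
    if any(op == "M" for _, op in ops):
        raise ValueError("ambiguous 'M' op: gap-compressed identity needs =/X CIGAR")
    matches = sum(n for n, op in ops if op == "=")
    mismatches = sum(n for n, op in ops if op == "X")
    gap_openings = sum(1 for _, op in ops if op in "ID")
    denom = matches + mismatches + gap_openings
    if denom == 0:
        raise ValueError("empty alignment")
    return matches / denom


def read_paf(path: str) -> list[AlignmentRecord]:
    """Parse a PAF file, retaining cg/gi tags when present."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{i}: PAF needs >= 12 columns")
            tags = {}
            for tag in f[12:]:
                name, typ, val = tag.split(":", 2)
                tags[name] = int(val) if typ == "i" else float(val) if typ == "f" else val
            out.append(
                AlignmentRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                    f[5], int(f[7]), int(f[8]), int(f[9]), int(f[10]),
                    cigar=tags.get("cg"), tags=tags,
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(path: str, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(path, rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
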