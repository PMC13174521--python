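"""Synthetic diploid tumor/normal genome pairs with known ground truth.

The generator emulates, at miniature scale, the genome structures the rest of
the toolkit analyses: α-satellite-like arrays built from a ~171 bp monomer
repeated in higher-order units, acrocentric-mimic arms carrying a single-copy
distal-junction (DJ)-like unit shared across arms plus a tandem array of
scaled-down rDNA-like units, homopolymer and tandem-repeat tracts,
heterozygous germline variation, and a tumor derivative carrying truncal and
subclonal somatic SNVs/indels plus monomer-multiple satellite SVs and rDNA
unit loss.

Coordinates are 0-based half-open throughout; the feature ledger indexes the
emitted per-haplotype sequences exactly.  Everything is deterministic given
the config seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import VariantRecord, revcomp
from .kmer_copynum import KmerCountTable, count_kmers, encode_kmers

#: Synthetic α-satellite-like monomer (171 bp, fixed arbitrary sequence with
#: ~50% GC; a stand-in for the canonical alphoid monomer, not the real
#: consensus).
ALPHA_MONOMER = (
    "TAGTCGCCGTCGGCTCGTGGTACTAGACAAATGGTTATTTATAGGAGCATGATACAGCCT"
    "CGGCACCTAAGTCGAGCACAACAGCGGTACTCCGCTAGTGAGAGGGGCTTTTGAAATACC"
    "GGGTGGACACTTGTGGTTCCCGGCTATTAGTTAAGCCAACTGCTCAAATTC"
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class GenomeConfig:
    """Layout of the miniature diploid genome.

    Each autosome mimic carries one satellite array plus homopolymer/TR
    tracts; each acrocentric mimic additionally carries one DJ-like unit
    (the same sequence on every acrocentric arm, once per arm per haplotype)
    and a tandem array of rDNA-like units.
    """

    n_autosome_mimics: int = 2
    n_acrocentric_mimics: int = 5
    chrom_length: int = 200_000
    satellite_monomer: str = ALPHA_MONOMER
    hor_order: int = 6
    array_length: int = 120 * 171  # 120 monomers
    rdna_unit_length: int = 2_000
    rdna_copies_per_arm: int = 8
    dj_unit_length: int = 5_000
    homopolymer_spec: tuple = (
        ("A", 8, 6), ("A", 12, 4), ("A", 20, 2), ("A", 35, 2),
        ("T", 10, 4), ("C", 8, 4), ("C", 12, 2), ("G", 15, 2),
    )
    tr_spec: tuple = (("AT", 12, 4), ("AC", 14, 3), ("AGC", 8, 2), ("ACGGT", 6, 2))
    germline_het_rate: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        n_mono = self.array_length // len(self.satellite_monomer)
        if n_mono < 1:
            raise ValueError("array_length shorter than one monomer")
        feat = (
            self.array_length
            + self.dj_unit_length
            + self.rdna_unit_length * self.rdna_copies_per_arm
        )
        n_small = sum(c for _, _, c in self.homopolymer_spec) + sum(
            c for _, _, c in self.tr_spec
        )
        small_bp = sum(l * c for _, l, c in self.homopolymer_spec) + sum(
            len(u) * n * c for u, n, c in self.tr_spec
        )
        need = feat + small_bp + 50 * (n_small + 4)
        if need > self.chrom_length:
            raise ValueError(
                f"features need ~{need} bp but chrom_length is {self.chrom_length}"
            )


@dataclass
class SomaticConfig:
    """Somatic mutation process applied to the normal genome."""

    snv_rate: float = 2e-5
    indel_rate_by_context: dict = field(
        default_factory=lambda: {"homopolymer": 2e-3, "diTR": 1e-3, "none": 2e-6}
    )
    n_satellite_svs: int = 40
    monomer_count_low: int = 1
    monomer_count_high: int = 20  # inclusive
    rdna_loss_fraction: float = 0.5
    subclonal_fraction: float = 0.2
    cell_fraction_distribution: tuple = ("uniform", 0.1, 0.45)
    seed: int = 0

    def draw_cell_fraction(self, rng: np.random.Generator) -> float:
        kind = self.cell_fraction_distribution[0]
        if kind == "uniform":
            lo, hi = self.cell_fraction_distribution[1:3]
            return float(rng.uniform(lo, hi))
        if kind == "beta":
            a, b = self.cell_fraction_distribution[1:3]
            return float(rng.beta(a, b))
        raise ValueError(f"unknown cell-fraction distribution {kind!r}")


@dataclass
class TechProfile:
    """Behavior of one sequencing technology in the support simulator."""

    name: str
    depth: float = 30.0
    base_error: float = 1e-3
    indel_error_by_homopolymer: dict = field(default_factory=dict)
    mappable_in_duplications: bool = True
    read_class: str = "short"  # "short" or "long"

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.base_error <= 1:
            raise ValueError("base_error must be in [0,1]")
        if self.read_class not in ("short", "long"):
            raise ValueError("read_class must be 'short' or 'long'")


DEFAULT_TECH_PROFILES = (
    TechProfile("element", depth=30, base_error=2e-4, read_class="short"),
    TechProfile("onso", depth=30, base_error=1e-4, read_class="short"),
    TechProfile("hifi", depth=30, base_error=1e-3, read_class="long",
                indel_error_by_homopolymer={8: 0.01, 12: 0.03, 20: 0.08, 35: 0.15}),
    TechProfile("ont", depth=30, base_error=5e-3, read_class="long",
                indel_error_by_homopolymer={8: 0.05, 12: 0.10, 20: 0.20, 35: 0.35}),
)


# ---------------------------------------------------------------------------
# Genome containers
# ---------------------------------------------------------------------------

LEDGER_COLUMNS = ["chrom", "start", "end", "feature", "name", "base", "unit"]


@dataclass
class DiploidGenome:
    """Haplotype-resolved sequences plus feature ledger and germline variants.

    ``sequences`` maps per-haplotype names like ``chr1_hap1`` to sequence;
    ``ledger`` rows (0-based half-open) index those sequences exactly;
    ``germline`` records are on backbone (pre-variant) coordinates with an
    HAP info tag naming the carrier haplotype.
    """

    sequences: dict[str, str]
    ledger: pd.DataFrame
    germline: list[VariantRecord]
    config: GenomeConfig | None = None

    @property
    def haplotypes(self) -> list[str]:
        return ["hap1", "hap2"]

    def chromosome_names(self) -> list[str]:
        seen = []
        for name in self.sequences:
            base = name.rsplit("_hap", 1)[0]
            if base not in seen:
                seen.append(base)
        return seen

    def features(self, feature: str, chrom: str | None = None) -> pd.DataFrame:
        df = self.ledger[self.ledger.feature == feature]
        if chrom is not None:
            df = df[df.chrom == chrom]
        return df

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class SomaticVariant:
    """One ground-truth somatic event on a haplotype sequence."""

    chrom: str  # per-haplotype sequence name, e.g. "acro1_hap2"
    pos: int  # 0-based on the NORMAL haplotype sequence
    ref: str
    alt: str
    haplotype: str
    cell_fraction: float
    context: str
    mechanism: str

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snv"
        return "ins" if len(self.alt) > len(self.ref) else "del"

    @property
    def size(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)

    @property
    def truncal(self) -> bool:
        return self.cell_fraction == 1.0

    def to_record(self) -> VariantRecord:
        return VariantRecord(
            self.chrom, self.pos, self.ref, self.alt,
            info={
                "HAP": self.haplotype,
                "CF": self.cell_fraction,
                "MECH": self.mechanism,
                "CONTEXT": self.context,
            },
        )


@dataclass
class SomaticTruthSet:
    variants: list[SomaticVariant]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def on_haplotype(self, chrom: str) -> list[SomaticVariant]:
        return sorted((v for v in self.variants if v.chrom == chrom), key=lambda v: v.pos)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "type": v.vtype, "size": v.size, "haplotype": v.haplotype,
                    "cell_fraction": v.cell_fraction, "context": v.context,
                    "mechanism": v.mechanism,
                }
                for v in self.variants
            ]
        )


# ---------------------------------------------------------------------------
# Edit application with coordinate bookkeeping
# ---------------------------------------------------------------------------


def apply_edits(seq: str, edits: Sequence[tuple[int, str, str]]) -> str:
    """Apply (pos, ref, alt) replacements; rejects overlapping edits."""
    edits = sorted(edits, key=lambda e: e[0])
    out = []
    cur = 0
    for pos, ref, alt in edits:
        if pos < cur:
            raise ValueError(f"overlapping edits at position {pos}")
        if seq[pos : pos + len(ref)] != ref:
            raise ValueError(f"REF mismatch at {pos}: expected {ref!r}")
        out.append(seq[cur:pos])
        out.append(alt)
        cur = pos + len(ref)
    out.append(seq[cur:])
    return "".join(out)


def shift_coordinate(pos: int, edits: Sequence[tuple[int, str, str]]) -> int:
    """Map a pre-edit coordinate to the post-edit sequence.

    Positions inside a replaced span clamp to the span's post-edit start.
    ``edits`` must be sorted and non-overlapping.
    """
    delta = 0
    for epos, ref, alt in edits:
        if epos + len(ref) <= pos:
            delta += len(alt) - len(ref)
        elif epos < pos:
            return epos + delta + min(pos - epos, len(alt))
        else:
            break
    return pos + delta


# ---------------------------------------------------------------------------
# Normal genome construction
# ---------------------------------------------------------------------------


def _build_backbone(config: GenomeConfig, rng: np.random.Generator):
    """Per-chromosome backbone sequence and feature rows (haplotype-agnostic)."""
    mono = config.satellite_monomer.upper()
    n_mono = config.array_length // len(mono)
    # DJ unit: one shared sequence across all acrocentric arms
    dj_seq = _random_seq(rng, config.dj_unit_length)
    # rDNA-like unit: fixed sequence with proportional 45S-like subregions
    rdna_seq = _random_seq(rng, config.rdna_unit_length)
    chroms: dict[str, str] = {}
    rows: list[dict] = []
    names = [f"chr{i + 1}" for i in range(config.n_autosome_mimics)] + [
        f"acro{i + 1}" for i in range(config.n_acrocentric_mimics)
    ]
    for name in names:
        is_acro = name.startswith("acro")
        big: list[tuple[str, str, str, dict]] = []
        if is_acro:
            big.append(("dj", dj_seq, "DJ", {}))
            for j in range(config.rdna_copies_per_arm):
                big.append(("rdna_unit", rdna_seq, f"rDNA_{j + 1}", {}))
        big.append(("satellite_alpha", mono * n_mono, "satArray", {"unit": mono}))
        feats = list(big)
        small: list[tuple[str, str, str, dict]] = []
        for base, length, cnt in config.homopolymer_spec:
            for _ in range(cnt):
                small.append(("homopolymer", base * length, f"hp{base}{length}", {"base": base}))
        for unit, copies, cnt in config.tr_spec:
            cls = "diTR" if len(unit) == 2 else "TR"
            for _ in range(cnt):
                small.append((cls, unit * copies, f"tr{unit}x{copies}", {"unit": unit}))
        for feat in small:
            # insert at a random slot but never between consecutive rDNA units
            while True:
                idx = int(rng.integers(0, len(feats) + 1))
                if 0 < idx < len(feats) and feats[idx - 1][0] == "rdna_unit" and feats[idx][0] == "rdna_unit":
                    continue
                break
            feats.insert(idx, feat)
        feat_bp = sum(len(s) for _, s, _, _ in feats)
        filler_total = config.chrom_length - feat_bp
        n_gaps = len(feats) + 1
        if filler_total < 50 * n_gaps:
            raise ValueError("features overlap beyond available chromosome length")
        extra = rng.multinomial(filler_total - 50 * n_gaps, np.ones(n_gaps) / n_gaps)
        gaps = (50 + extra).tolist()
        # rDNA units are tandem: zero gap between consecutive units
        parts: list[str] = []
        pos = 0
        for i, (cls, seq, fname, info) in enumerate(feats):
            g = gaps[i]
            if i > 0 and feats[i - 1][0] == "rdna_unit" and cls == "rdna_unit":
                g = 0
            filler = _random_seq(rng, g)
            parts.append(filler)
            pos += g
            rows.append(
                {
                    "chrom": name, "start": pos, "end": pos + len(seq),
                    "feature": cls, "name": fname,
                    "base": info.get("base", ""), "unit": info.get("unit", ""),
                }
            )
            parts.append(seq)
            pos += len(seq)
        parts.append(_random_seq(rng, gaps[-1]))
        pos += gaps[-1]
        seq = "".join(parts)
        # guard homopolymer boundaries so the ledger length is the maximal run
        buf = bytearray(seq.encode())
        for r in rows:
            if r["chrom"] == name and r["feature"] == "homopolymer":
                b = r["base"].encode()[0]
                for edge in (r["start"] - 1, r["end"]):
                    if 0 <= edge < len(buf) and buf[edge] == b:
                        buf[edge] = {65: 67, 67: 71, 71: 84, 84: 65}[b]
        chroms[name] = buf.decode()
    return chroms, rows


def build_normal_genome(config: GenomeConfig | None = None) -> DiploidGenome:
    """Construct the diploid normal genome from a layout config.

    Both haplotypes share one backbone; heterozygous germline variants
    (SNVs and 1-3 bp indels, indels kept out of satellite/rDNA/DJ features)
    are then applied to one haplotype each at ``germline_het_rate`` per bp.
    """
    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms, rows = _build_backbone(config, rng)
    backbone_ledger = pd.DataFrame(rows, columns=LEDGER_COLUMNS)

    protected = {"satellite_alpha", "rdna_unit"}  # SNV-only divergence
    dj_free = {"dj"}  # no germline variation: DJ copies stay identical
    sequences: dict[str, str] = {}
    out_rows: list[dict] = []
    germline: list[VariantRecord] = []
    for chrom, seq in chroms.items():
        n = len(seq)
        n_var = rng.binomial(n, config.germline_het_rate)
        positions = np.sort(rng.choice(n - 10, size=n_var, replace=False)) if n_var else np.array([], int)
        feat_rows = backbone_ledger[backbone_ledger.chrom == chrom]
        prot_iv = [
            (r.start, r.end) for r in feat_rows.itertuples() if r.feature in protected
        ]
        dj_iv = [
            (r.start, r.end) for r in feat_rows.itertuples() if r.feature in dj_free
        ]
        per_hap_edits: dict[str, list[tuple[int, str, str]]] = {"hap1": [], "hap2": []}
        last_end = -1
        for p in positions:
            p = int(p)
            if p < last_end:
                continue
            hap = "hap1" if rng.random() < 0.5 else "hap2"
            kind = rng.random()
            if any(s <= p < e for s, e in dj_iv):
                continue
            in_prot = any(s <= p < e for s, e in prot_iv)
            if kind < 0.8 or in_prot:
                ref = seq[p]
                alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
            elif kind < 0.9:
                size = int(rng.integers(1, 4))
                ref = seq[p]
                alt = ref + _random_seq(rng, size)
            else:
                size = int(rng.integers(1, 4))
                ref = seq[p : p + 1 + size]
                alt = seq[p]
            per_hap_edits[hap].append((p, ref, alt))
            last_end = p + len(ref)
            gt = "1|0" if hap == "hap1" else "0|1"
            germline.append(
                VariantRecord(chrom, p, ref, alt, genotype=gt, info={"HAP": hap})
            )
        for hap in ("hap1", "hap2"):
            edits = per_hap_edits[hap]
            sequences[f"{chrom}_{hap}"] = apply_edits(seq, edits)
            for r in feat_rows.itertuples():
                out_rows.append(
                    {
                        "chrom": f"{chrom}_{hap}",
                        "start": shift_coordinate(r.start, edits),
                        "end": shift_coordinate(r.end, edits),
                        "feature": r.feature, "name": r.name,
                        "base": r.base, "unit": r.unit,
                    }
                )
    ledger = pd.DataFrame(out_rows, columns=LEDGER_COLUMNS)
    return DiploidGenome(sequences, ledger, germline, config)


# ---------------------------------------------------------------------------
# Tumor derivation
# ---------------------------------------------------------------------------


def _context_at(ledger: pd.DataFrame, chrom: str, pos: int, end: int) -> str:
    rows = ledger[(ledger.chrom == chrom) & (ledger.start < end) & (ledger.end > pos)]
    if len(rows) == 0:
        return "none"
    order = ["satellite_alpha", "rdna_unit", "dj", "TR", "diTR", "homopolymer"]
    present = set(rows.feature)
    for cls in order:
        if cls in present:
            return cls
    return "none"


def derive_tumor_genome(
    normal: DiploidGenome, somatic: SomaticConfig
) -> tuple[DiploidGenome, SomaticTruthSet]:
    """Apply a sampled somatic mutation process to the normal genome.

    Returns the tumor genome (all truth variants applied, truncal and
    subclonal alike — the sequences represent the dominant clone's alleles)
    plus the ground-truth set.  Events never overlap on a haplotype;
    satellite SV sizes are exact monomer multiples; ``rdna_loss_fraction``
    of rDNA units per haplotype are removed as whole-unit deletions.
    """
    rng = np.random.default_rng(somatic.seed)
    truth: list[SomaticVariant] = []
    tumor_seqs: dict[str, str] = {}
    tumor_rows: list[dict] = []
    monomer = (normal.config.satellite_monomer if normal.config else ALPHA_MONOMER).upper()
    mlen = len(monomer)

    for hapseq_name, seq in normal.sequences.items():
        hap = "hap" + hapseq_name.rsplit("_hap", 1)[1]
        feats = normal.ledger[normal.ledger.chrom == hapseq_name]
        candidates: list[SomaticVariant] = []

        def _cf() -> float:
            if rng.random() < somatic.subclonal_fraction:
                return somatic.draw_cell_fraction(rng)
            return 1.0

        # SNVs, genome-wide
        n_snv = rng.binomial(len(seq), somatic.snv_rate)
        for p in rng.choice(max(len(seq) - 2, 1), size=n_snv, replace=False):
            p = int(p)
            ref = seq[p]
            if ref not in "ACGT":
                continue
            alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
            ctx = _context_at(normal.ledger, hapseq_name, p, p + 1)
            candidates.append(
                SomaticVariant(hapseq_name, p, ref, alt, hap, _cf(), ctx, "snv")
            )

        # context-dependent 1 bp indels
        for cls, rate in somatic.indel_rate_by_context.items():
            if rate <= 0:
                continue
            if cls == "none":
                n = rng.binomial(len(seq), rate)
                pos_pool = rng.integers(1, len(seq) - 2, size=n)
            else:
                sub = feats[feats.feature == cls]
                spans = [(r.start, r.end) for r in sub.itertuples()]
                total = sum(e - s for s, e in spans)
                if total == 0:
                    continue
                n = rng.binomial(total, rate)
                pos_pool = []
                for _ in range(n):
                    s, e = spans[int(rng.integers(0, len(spans)))]
                    pos_pool.append(int(rng.integers(s, e)))
            for p in pos_pool:
                p = int(p)
                if p < 1 or p + 2 >= len(seq):
                    continue
                anchor = seq[p]
                if rng.random() < 0.5:
                    ref, alt = anchor, anchor + seq[p + 1]  # 1 bp duplication-style ins
                else:
                    ref, alt = seq[p : p + 2], anchor
                ctx = _context_at(normal.ledger, hapseq_name, p, p + len(ref))
                candidates.append(
                    SomaticVariant(hapseq_name, p, ref, alt, hap, _cf(), ctx, "slippage")
                )

        # monomer-multiple satellite SVs (unequal crossover); the configured
        # event count is a genome-wide total spread over haplotype sequences
        arrays = feats[feats.feature == "satellite_alpha"]
        n_arr_events = (
            max(1, round(somatic.n_satellite_svs / len(normal.sequences)))
            if len(arrays) and somatic.n_satellite_svs > 0
            else 0
        )
        for _ in range(n_arr_events):
            arr = arrays.iloc[int(rng.integers(0, len(arrays)))]
            n_mono_arr = (arr.end - arr.start) // mlen
            m = int(rng.integers(somatic.monomer_count_low, somatic.monomer_count_high + 1))
            if m + 2 >= n_mono_arr:
                continue
            j = int(rng.integers(1, n_mono_arr - m - 1))
            p = int(arr.start) + j * mlen - 1  # anchor base before the boundary
            if rng.random() < 0.5:
                ref = seq[p : p + m * mlen + 1]
                alt = seq[p]
            else:
                ref = seq[p]
                alt = seq[p] + seq[p + 1 : p + 1 + m * mlen]
            candidates.append(
                SomaticVariant(
                    hapseq_name, p, ref, alt, hap, _cf(),
                    "satellite_alpha", "unequal_crossover",
                )
            )

        # rDNA unit loss (always truncal: a clonal array contraction);
        # contiguous lost units collapse into one deletion event
        loss_events: list[SomaticVariant] = []
        lost_unit_starts: set[int] = set()
        units = feats[feats.feature == "rdna_unit"].sort_values("start")
        n_loss = int(round(somatic.rdna_loss_fraction * len(units)))
        if n_loss:
            lost_idx = sorted(rng.choice(len(units), size=n_loss, replace=False).tolist())
            runs: list[list[int]] = [[lost_idx[0]]]
            for i in lost_idx[1:]:
                u_prev = units.iloc[runs[-1][-1]]
                u_cur = units.iloc[i]
                if i == runs[-1][-1] + 1 and int(u_cur.start) == int(u_prev.end):
                    runs[-1].append(i)
                else:
                    runs.append([i])
            for run in runs:
                s = int(units.iloc[run[0]].start)
                e = int(units.iloc[run[-1]].end)
                p = s - 1
                loss_events.append(
                    SomaticVariant(
                        hapseq_name, p, seq[p:e], seq[p], hap, 1.0,
                        "rdna_unit", "rdna_loss",
                    )
                )
            lost_unit_starts = {int(units.iloc[i].start) for i in lost_idx}

        # resolve overlaps: rDNA-loss events take priority, then earlier wins
        loss_iv = [(v.pos, v.end) for v in loss_events]
        candidates.sort(key=lambda v: (v.pos, -v.size))
        accepted: list[SomaticVariant] = list(loss_events)
        last_end = -1
        for v in candidates:
            if v.pos <= last_end:
                continue
            if any(v.pos < e and v.end > s for s, e in loss_iv):
                continue
            accepted.append(v)
            last_end = v.end
        accepted.sort(key=lambda v: v.pos)
        truth.extend(accepted)

        edits = [(v.pos, v.ref, v.alt) for v in accepted]
        tumor_seqs[hapseq_name] = apply_edits(seq, edits)
        for r in feats.itertuples():
            if r.feature == "rdna_unit" and r.start in lost_unit_starts:
                continue
            tumor_rows.append(
                {
                    "chrom": hapseq_name,
                    "start": shift_coordinate(r.start, edits),
                    "end": shift_coordinate(r.end, edits),
                    "feature": r.feature, "name": r.name,
                    "base": r.base, "unit": r.unit,
                }
            )

    tumor = DiploidGenome(
        tumor_seqs,
        pd.DataFrame(tumor_rows, columns=LEDGER_COLUMNS),
        normal.germline,
        normal.config,
    )
    return tumor, SomaticTruthSet(truth)


# ---------------------------------------------------------------------------
# Coverage / support / methylation simulators
# ---------------------------------------------------------------------------


def simulate_kmer_coverage(
    genome: DiploidGenome | dict[str, str], k: int, depth: float, seed: int
) -> KmerCountTable:
    """Poisson k-mer counts: each k-mer draws Poisson(depth x multiplicity).

    ``depth`` is per genome copy, so a k-mer present on both haplotypes of a
    single-copy locus (multiplicity 2) has expectation 2 x depth.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    seqs = genome.sequences if isinstance(genome, DiploidGenome) else genome
    kmers, mult = count_kmers(seqs.values(), k)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(depth * mult).astype(float) if depth > 0 else np.zeros(len(kmers))
    return KmerCountTable(kmers, counts, mult, k)


def simulate_support_tables(
    truth: SomaticTruthSet,
    profiles: Sequence[TechProfile] = DEFAULT_TECH_PROFILES,
    germline: Sequence[VariantRecord] = (),
    seed: int = 0,
    ledger: pd.DataFrame | None = None,
    duplication_regions: dict[str, list[tuple[int, int]]] | None = None,
    sampling: str = "binomial",
):
    """Per-variant per-technology tumor/normal allele counts.

    Combined-haplotype mapping is haplotype-aware (reads resolve to their
    contig of origin), so a truncal variant's expected VAF on its own
    haplotype contig equals its cell fraction.  ``sampling="expected"``
    emits rounded expected counts (the zero-noise limit); ``"binomial"``
    draws Binomial(coverage, p).
    """
    from .evidence_rules import SupportRecord, TechCounts

    if not profiles:
        raise ValueError("profiles must be nonempty")
    if sampling not in ("binomial", "expected"):
        raise ValueError("sampling must be 'binomial' or 'expected'")
    rng = np.random.default_rng(seed)
    dup = duplication_regions or {}
    records = []
    for i, v in enumerate(truth):
        hp_len = 0
        ditr_len = 0
        if ledger is not None:
            rows = ledger[
                (ledger.chrom == v.chrom) & (ledger.start <= v.end) & (ledger.end >= v.pos)
            ]
            for r in rows.itertuples():
                if r.feature == "homopolymer":
                    hp_len = max(hp_len, r.end - r.start)
                elif r.feature == "diTR":
                    ditr_len = max(ditr_len, r.end - r.start)
        in_dup = any(
            s <= v.pos < e for s, e in dup.get(v.chrom, [])
        )
        counts: dict[str, TechCounts] = {}
        short_cov = 0
        for prof in profiles:
            err = prof.base_error
            for L in sorted(prof.indel_error_by_homopolymer):
                if hp_len >= L and v.vtype in ("ins", "del"):
                    err = max(err, prof.indel_error_by_homopolymer[L])
            if in_dup and not prof.mappable_in_duplications:
                counts[prof.name] = TechCounts(0, 0, 0, 0)
                continue
            p_alt = v.cell_fraction * (1 - err) + (1 - v.cell_fraction) * err
            if sampling == "expected":
                t_cov = n_cov = int(round(prof.depth))
                t_alt = int(round(t_cov * p_alt))
                n_alt = int(round(n_cov * err))
            else:
                t_cov = int(rng.poisson(prof.depth))
                n_cov = int(rng.poisson(prof.depth))
                t_alt = int(rng.binomial(t_cov, p_alt)) if t_cov else 0
                n_alt = int(rng.binomial(n_cov, err)) if n_cov else 0
            counts[prof.name] = TechCounts(t_alt, t_cov, n_alt, n_cov)
            if prof.read_class == "short":
                short_cov = max(short_cov, t_cov)
        hap_counts: dict[str, TechCounts] = {}
        short = [p for p in profiles if p.read_class == "short"]
        if short:
            prof = short[0]
            for hap in ("hap1", "hap2"):
                carrier = hap == v.haplotype
                p_alt = v.cell_fraction if carrier else 0.0
                p_alt = p_alt * (1 - prof.base_error) + (1 - p_alt) * prof.base_error
                if sampling == "expected":
                    t_cov = n_cov = int(round(prof.depth))
                    t_alt = int(round(t_cov * p_alt))
                    n_alt = int(round(n_cov * prof.base_error))
                else:
                    t_cov = int(rng.poisson(prof.depth))
                    n_cov = int(rng.poisson(prof.depth))
                    t_alt = int(rng.binomial(t_cov, p_alt)) if t_cov else 0
                    n_alt = int(rng.binomial(n_cov, prof.base_error)) if n_cov else 0
                hap_counts[hap] = TechCounts(t_alt, t_cov, n_alt, n_cov)
        records.append(
            SupportRecord(
                variant_id=f"var{i}",
                counts=counts,
                hap_counts=hap_counts,
                in_somatic_duplication=in_dup,
                homopolymer_len=hp_len,
                ditr_len=ditr_len,
                short_read_cov=short_cov,
                low_mq=False,
                indel_size=v.size,
            )
        )
    return records


def simulate_methylation(
    sequence: str,
    regions: dict[str, tuple[int, int]],
    profiles: dict[str, tuple[float, float, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Beta-binomial per-CpG methylation pileup over a reference sequence.

    ``profiles[name] = (mean, dispersion, coverage)``; dispersion is the
    beta-binomial rho in [0,1) (0 = pure binomial; with mean 0 or 1 the
    sites are exactly un/fully modified).  Returns a bedmethyl-like frame
    (chrom, start, end, coverage, modified).
    """
    rng = np.random.default_rng(seed)
    cpg = [i for i in range(len(sequence) - 1) if sequence[i : i + 2].upper() == "CG"]
    rows = []
    for name, (s, e) in regions.items():
        mean, disp, cov = profiles[name]
        if not 0 <= mean <= 1:
            raise ValueError("methylation mean must be in [0,1]")
        for p in cpg:
            if not s <= p < e:
                continue
            if disp <= 0 or mean in (0.0, 1.0):
                prob = mean
            else:
                a = mean * (1 / disp - 1)
                b = (1 - mean) * (1 / disp - 1)
                prob = rng.beta(a, b)
            mod = int(rng.binomial(cov, prob)) if prob > 0 else 0
            if prob >= 1.0:
                mod = cov
            rows.append({"chrom": "rdna", "start": p, "end": p + 2,
                         "coverage": cov, "modified": mod, "region": name})
    return pd.DataFrame(rows)


def simulate_representation_scenario(
    n_segments: int = 200,
    interference_rate: float = 0.3,
    segment: int = 400,
    seed: int = 0,
):
    """Reference + DSA pair with somatic variants of known representation fate.

    One reference chromosome is divided into ``n_segments`` well-separated
    segments; each receives one somatic variant on the DSA.  With
    probability ``interference_rate`` the segment also carries a germline
    variant arranged to interfere: a germline SNV the somatic SNV reverts,
    a germline 10 bp insertion containing a somatic 2 bp deletion (size
    change on the reference), or a germline 2 bp insertion containing a
    somatic SNV (type change).  Remaining segments get a clean somatic SNV
    (representation unchanged).

    Returns (ref_sequences, dsa_sequences, lift_map, somatic_variants,
    expected_classes, germline_edits).
    """
    from .representation_shift import LiftMap

    rng = np.random.default_rng(seed)
    length = n_segments * segment + 200
    ref = _random_seq(rng, length)
    germline: list[tuple[int, str, str]] = []
    plan: list[tuple[str, int]] = []  # (mode, ref position)
    for i in range(n_segments):
        c = i * segment + segment // 2
        if rng.random() < interference_rate:
            mode = ("revert", "size", "type")[int(rng.integers(0, 3))]
        else:
            mode = "clean"
        plan.append((mode, c))
    delta = 0
    somatic: list[VariantRecord] = []
    expected: list[str] = []
    dsa_parts_edits: list[tuple[int, str, str]] = []
    for mode, c in plan:
        b = ref[c]
        if mode == "revert":
            x = "ACGT".replace(b, "")[int(rng.integers(0, 3))]
            germline.append((c, b, x))
            somatic.append(VariantRecord("dsa", c + delta, x, b))
            expected.append("reverts_germline")
        elif mode == "size":
            ins = _random_seq(rng, 10)
            germline.append((c, b, b + ins))
            p = c + delta + 3  # anchor inside the inserted run
            dsa_ref = (b + ins)[3:6]
            somatic.append(VariantRecord("dsa", p, dsa_ref, dsa_ref[0]))
            expected.append("size_changed")
            delta += 10
        elif mode == "type":
            ins = _random_seq(rng, 2)
            germline.append((c, b, b + ins))
            p = c + delta + 1
            alt = "ACGT".replace(ins[0], "")[int(rng.integers(0, 3))]
            somatic.append(VariantRecord("dsa", p, ins[0], alt))
            expected.append("type_changed")
            delta += 2
        else:
            somatic.append(VariantRecord("dsa", c + delta, b,
                                         "ACGT".replace(b, "")[int(rng.integers(0, 3))]))
            expected.append("unchanged")
    dsa = apply_edits(ref, germline)
    lift_map = LiftMap.from_germline_edits(
        {"chr_ref": length}, {"chr_ref": germline}
    )
    # rename DSA chromosome in the map to match the emitted sequence name
    for blk in lift_map.blocks:
        blk.dsa_chrom = "dsa"
    return {"chr_ref": ref}, {"dsa": dsa}, lift_map, somatic, expected, germline


def simulate_read_methylation(
    n_reads: int,
    n_cpg: int,
    populations: Sequence[tuple[float, float, float]],
    coverage_fraction: tuple[float, float] = (0.75, 1.0),
    identity: tuple[float, float] = (0.92, 0.99),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-read CpG methylation calls from a mixture of read populations.

    ``populations`` is a list of (weight, mean, sd-of-read-mean); each read
    draws its regional methylation level from its population, then per-CpG
    binary states Bernoulli(level) with a random per-call confidence.
    Returns one row per (read, cpg) with read-level alignment covariates.
    """
    rng = np.random.default_rng(seed)
    w = np.array([p[0] for p in populations], float)
    w = w / w.sum()
    rows = []
    for r in range(n_reads):
        pop = int(rng.choice(len(populations), p=w))
        _, mu, sd = populations[pop]
        level = float(np.clip(rng.normal(mu, sd), 0, 1))
        covf = float(rng.uniform(*coverage_fraction))
        ident = float(rng.uniform(*identity))
        states = rng.random(n_cpg) < level
        conf = rng.uniform(0.5, 1.0, n_cpg)
        for j in range(n_cpg):
            rows.append(
                {
                    "read": f"read{r}", "cpg_index": j,
                    "methylated": bool(states[j]), "confidence": float(conf[j]),
                    "ref_coverage_fraction": covf, "identity": ident,
                    "population": pop,
                }
            )
    return pd.DataFrame(rows)
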