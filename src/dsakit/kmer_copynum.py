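"""K-mer based copy-number estimation.

Two estimators live here:

* GC-matched background-bin estimation for tandem features such as rDNA:
  the copy number of a feature is the median count of its k-mers divided by
  the median count of k-mers from same-chromosome background bins of similar
  GC content, optionally divided by a ploidy divisor (2 when the background
  chromosome is haploid in the sample).
* Diploid-peak normalization for single-copy-per-arm features such as the
  acrocentric distal junction (DJ): copies = 2 x median(feature k-mer counts)
  / modal count of the genome-wide k-mer spectrum.

K-mers are canonical (lexicographic minimum of a k-mer and its reverse
complement) because sequencing reads are unstranded.  Counts of k-mers that
occur multiple times in the reference are divided by their genomic
multiplicity before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lower case


def _encode_forward(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-packed forward k-mer codes and a validity mask (no ambiguous base)."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j : n + j].astype(np.uint64)
    bad = codes == 255
    if bad.any():
        valid = ~(np.convolve(bad.astype(np.intp), np.ones(k, dtype=np.intp))[k - 1 : len(codes)] > 0)
    else:
        valid = np.ones(n, dtype=bool)
    return out, valid


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-collapsed) k-mer codes of a sequence, 5'->3' order."""
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31] for 64-bit packing")
    fwd, valid = _encode_forward(seq, k)
    from .io_formats import revcomp

    rev, _ = _encode_forward(revcomp(seq), k)
    rev = rev[::-1]  # rev[i] is the RC of the k-mer at position i
    out = np.minimum(fwd, rev)
    return out[valid]


def decode_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


def count_kmers(seqs: Iterable[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Unique canonical k-mers and their multiplicities across sequences."""
    parts = [encode_kmers(s, k) for s in seqs]
    allk = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    return np.unique(allk, return_counts=True)


@dataclass
class ConkordParams:
    """Parameters of the GC-matched-bin copy-number estimator."""

    k: int = 31
    bin_size: int = 2000
    sd_cutoff: float = 3.0
    gc_tolerance: float = 0.02
    background_chromosome: str | None = None
    ploidy_divisor: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("k must be >= 11")
        if self.bin_size < self.k:
            raise ValueError("bin_size must be >= k")
        if self.ploidy_divisor <= 0:
            raise ValueError("ploidy_divisor must be positive")


@dataclass
class KmerCountTable:
    """Canonical k-mer -> (observed count, reference multiplicity).

    Stored as parallel arrays sorted by packed k-mer code.
    """

    kmers: np.ndarray  # uint64 codes, sorted ascending
    counts: np.ndarray  # float (may be multiplicity-adjusted)
    multiplicity: np.ndarray  # int reference multiplicity
    k: int

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        order = np.argsort(self.kmers, kind="stable")
        self.kmers = np.asarray(self.kmers, dtype=np.uint64)[order]
        self.counts = np.asarray(self.counts, dtype=float)[order]
        self.multiplicity = np.asarray(self.multiplicity, dtype=np.int64)[order]

    def __len__(self) -> int:
        return len(self.kmers)

    @classmethod
    def from_strings(cls, entries: dict[str, tuple[float, int]], k: int) -> "KmerCountTable":
        """Build from ``{kmer: (count, multiplicity)}`` with string k-mers.

        K-mers are canonicalized; duplicate canonical forms are rejected.
        """
        from .io_formats import revcomp

        codes, counts, mult = [], [], []
        for km, (c, m) in entries.items():
            canon = min(km.upper(), revcomp(km.upper()))
            codes.append(encode_kmers(canon, k)[0])
            counts.append(c)
            mult.append(m)
        arr = np.array(codes, dtype=np.uint64)
        if len(np.unique(arr)) != len(arr):
            raise ValueError("duplicate canonical k-mers")
        return cls(arr, np.array(counts, float), np.array(mult), k)

    def subset(self, kmers: np.ndarray) -> "KmerCountTable":
        """Rows whose k-mer code is in ``kmers`` (codes assumed canonical)."""
        mask = np.isin(self.kmers, kmers)
        return KmerCountTable(self.kmers[mask], self.counts[mask], self.multiplicity[mask], self.k)

    def lookup(self, kmers: np.ndarray, default: float = 0.0) -> np.ndarray:
        """Counts for the given canonical codes (``default`` where absent)."""
        idx = np.searchsorted(self.kmers, kmers)
        idx = np.clip(idx, 0, len(self.kmers) - 1)
        found = len(self.kmers) > 0
        out = np.full(len(kmers), default, dtype=float)
        if found:
            hit = self.kmers[idx] == kmers
            out[hit] = self.counts[idx[hit]]
        return out


@dataclass
class CopyNumberEstimate:
    value: float
    feature_kmer_median: float
    bin_kmer_median: float
    n_kmers_used: int
    n_kmers_filtered: int

    def rounded(self) -> int:
        """Integer copy call, round-half-to-even."""
        return int(np.round(self.value))


@dataclass
class BinSet:
    """Non-overlapping background windows matched to a feature's GC content."""

    chromosome: str
    intervals: list[tuple[int, int]]
    gc_fractions: list[float]
    feature_gc: float


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def select_matched_bins(
    reference: dict[str, str], feature: str, params: ConkordParams
) -> BinSet:
    """Tile the background chromosome into bins GC-matched to the feature.

    Windows are non-overlapping, complete ``bin_size`` tiles; a window is
    selected when |GC(window) - GC(feature)| <= gc_tolerance.
    """
    chrom = params.background_chromosome
    if chrom is None or chrom not in reference:
        raise ValueError(f"background chromosome {chrom!r} not in reference")
    seq = reference[chrom]
    if len(seq) < params.bin_size:
        raise ValueError("background chromosome shorter than bin_size")
    fgc = gc_fraction(feature)
    intervals, gcs = [], []
    for s in range(0, len(seq) - params.bin_size + 1, params.bin_size):
        w = seq[s : s + params.bin_size]
        g = gc_fraction(w)
        if abs(g - fgc) <= params.gc_tolerance:
            intervals.append((s, s + params.bin_size))
            gcs.append(g)
    if not intervals:
        raise ValueError(
            "no background bin within gc_tolerance of the feature; widen gc_tolerance"
        )
    return BinSet(chrom, intervals, gcs, fgc)


def filter_kmer_counts(
    table: KmerCountTable,
    params: ConkordParams,
    reference_kmers: np.ndarray | None = None,
) -> KmerCountTable:
    """Apply the count filters before median estimation.

    Removes k-mers with zero observed count, k-mers whose count exceeds the
    set mean by more than ``sd_cutoff`` sample standard deviations (single
    pass, non-iterative; SD uses the n-1 denominator and an SD of 0 removes
    nothing), and — when ``reference_kmers`` is given — k-mers absent from
    that reference set.  Surviving counts are divided by their reference
    multiplicity where it exceeds 1.
    """
    if len(table) == 0:
        raise ValueError("empty k-mer table")
    keep = table.counts > 0
    if reference_kmers is not None:
        keep &= np.isin(table.kmers, reference_kmers)
    c = table.counts
    if keep.sum() > 1:
        mean = c[keep].mean()
        sd = c[keep].std(ddof=1)
        if sd > 0:
            keep &= c <= mean + params.sd_cutoff * sd
    if not keep.any():
        raise ValueError("all k-mers removed by filtering")
    counts = c[keep].astype(float)
    mult = table.multiplicity[keep]
    adj = mult > 1
    counts[adj] = counts[adj] / mult[adj]
    return KmerCountTable(table.kmers[keep], counts, mult, table.k)


def estimate_copy_number(
    feature_counts: KmerCountTable,
    bin_counts: KmerCountTable,
    params: ConkordParams,
) -> CopyNumberEstimate:
    """median(feature counts) / median(bin counts) / ploidy_divisor."""
    if len(feature_counts) == 0 or len(bin_counts) == 0:
        raise ValueError("empty count table")
    fmed = float(np.median(feature_counts.counts))
    bmed = float(np.median(bin_counts.counts))
    if bmed == 0:
        raise ValueError("background bin median is zero")
    return CopyNumberEstimate(
        value=fmed / bmed / params.ploidy_divisor,
        feature_kmer_median=fmed,
        bin_kmer_median=bmed,
        n_kmers_used=len(feature_counts),
        n_kmers_filtered=0,
    )


def conkord_estimate(
    reference: dict[str, str],
    feature_seq: str,
    sample_counts: KmerCountTable,
    params: ConkordParams,
) -> CopyNumberEstimate:
    """End-to-end GC-matched-bin estimate from sequences and a count table.

    Multiplicities are taken within the feature sequence and within the
    matched-bin set respectively (a k-mer repeated inside the feature has
    its read count divided by that internal multiplicity); bin k-mers also
    present in the feature are not exclusive to the bins and are removed.
    """
    bins = select_matched_bins(reference, feature_seq, params)
    seq = reference[bins.chromosome]
    feat_kmers, feat_mult = count_kmers([feature_seq], params.k)
    bin_kmers, bin_mult = count_kmers(
        [seq[s:e] for s, e in bins.intervals], params.k
    )
    excl = ~np.isin(bin_kmers, feat_kmers)
    bin_kmers, bin_mult = bin_kmers[excl], bin_mult[excl]
    feat_table = KmerCountTable(
        feat_kmers, sample_counts.lookup(feat_kmers), feat_mult, params.k
    )
    bin_table = KmerCountTable(
        bin_kmers, sample_counts.lookup(bin_kmers), bin_mult, params.k
    )
    n_before = len(feat_table) + len(bin_table)
    feat = filter_kmer_counts(feat_table, params)
    back = filter_kmer_counts(bin_table, params)
    est = estimate_copy_number(feat, back, params)
    est.n_kmers_used = len(feat) + len(back)
    est.n_kmers_filtered = n_before - est.n_kmers_used
    return est


def diploid_peak(spectrum: np.ndarray, min_peak_count: int) -> int:
    """Modal count of a k-mer count spectrum after excluding error k-mers.

    ``spectrum`` is the list/array of per-k-mer observed counts; counts below
    ``min_peak_count`` are excluded before taking the integer mode.
    """
    spectrum = np.asarray(spectrum)
    kept = spectrum[spectrum >= max(min_peak_count, 1)]
    if len(kept) == 0:
        raise ValueError("no k-mer count at or above min_peak_count; no diploid peak")
    hist = np.bincount(kept.astype(np.int64))
    return int(hist.argmax())


def estimate_dj_copy_number(
    dj_counts: KmerCountTable,
    genome_spectrum: np.ndarray,
    min_peak_count: int,
) -> CopyNumberEstimate:
    """copies = 2 x median(DJ k-mer counts) / diploid-peak count."""
    if len(dj_counts) == 0:
        raise ValueError("empty DJ k-mer table")
    peak = diploid_peak(genome_spectrum, min_peak_count)
    dj_med = float(np.median(dj_counts.counts))
    return CopyNumberEstimate(
        value=2.0 * dj_med / peak,
        feature_kmer_median=dj_med,
        bin_kmer_median=float(peak),
        n_kmers_used=len(dj_counts),
        n_kmers_filtered=0,
    )
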