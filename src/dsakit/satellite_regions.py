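"""Satellite array calling and SV-size periodicity.

Implements the candidate-motif length filter (a motif must be an integer
multiple of the ~170 bp monomer, n <= 5 for α-satellite or n <= 42 for
HSat1A, within 2% of the multiple), divergence-filtered monomer-hit merging
into arrays (gap <= 100 kbp, core >= 30 kbp, slop 1 Mbp), chromosome-name
assignment by aligned fraction (>= 5%, argmax, ties unassigned), and a
modular-deviation periodicity estimator for satellite SV sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass
class SatelliteParams:
    base_monomer: int = 170
    length_tolerance: float = 0.02
    max_n_alpha: int = 5
    max_n_hsat1a: int = 42
    max_seq_div: float = 0.30
    merge_distance: int = 100_000
    min_array: int = 30_000
    slop: int = 1_000_000
    min_chrom_align_pct: float = 0.05
    kmer_len: int = 171
    kmer_min_occurrences: int = 10

    def __post_init__(self) -> None:
        for f in (self.length_tolerance, self.max_seq_div, self.min_chrom_align_pct):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0,1]")
        if self.max_n_alpha > self.max_n_hsat1a:
            raise ValueError("max_n_alpha must be <= max_n_hsat1a")

    def max_n(self, satellite_class: str) -> int:
        if satellite_class == "alpha":
            return self.max_n_alpha
        if satellite_class == "hsat1a":
            return self.max_n_hsat1a
        raise ValueError(f"unknown satellite class {satellite_class!r}")


@dataclass
class MotifCandidate:
    id: str
    length: int
    has_monomer_annotation: bool
    satellite_class: str = "alpha"


@dataclass
class MonomerHit:
    chrom: str
    start: int
    end: int
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty interval")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0,1]")


@dataclass
class SatelliteRegion:
    chrom: str
    core_start: int
    core_end: int
    slop_start: int
    slop_end: int
    n_monomers: int
    satellite_class: str = "alpha"


def motif_passes_length_filter(
    length: int, satellite_class: str, params: SatelliteParams | None = None,
    has_monomer_annotation: bool = True,
) -> bool:
    """Is ``length`` within tolerance of n x base_monomer for allowed n?

    Relative difference is measured against the target multiple
    n x base_monomer.  Motifs lacking a monomer annotation always fail.
    """
    params = params or SatelliteParams()
    if length <= 0:
        raise ValueError("length must be > 0")
    if not has_monomer_annotation:
        return False
    for n in range(1, params.max_n(satellite_class) + 1):
        target = n * params.base_monomer
        if abs(length - target) / target <= params.length_tolerance:
            return True
    return False


def filter_motifs(
    motifs: Iterable[MotifCandidate], params: SatelliteParams | None = None
) -> list[MotifCandidate]:
    params = params or SatelliteParams()
    return [
        m
        for m in motifs
        if motif_passes_length_filter(
            m.length, m.satellite_class, params, m.has_monomer_annotation
        )
    ]


def call_satellite_regions(
    hits: Sequence[MonomerHit],
    params: SatelliteParams | None = None,
    sequence_lengths: Mapping[str, int] | None = None,
    satellite_class: str = "alpha",
) -> list[SatelliteRegion]:
    """Merge monomer hits into satellite arrays.

    Hits above ``max_seq_div`` are discarded; remaining hits on one sequence
    merge transitively while the inter-hit gap (interval-end to next
    interval-start) is <= ``merge_distance``; merged cores shorter than
    ``min_array`` drop; surviving cores are extended by ``slop`` on each
    side, clipped to the sequence bounds when lengths are supplied.
    """
    params = params or SatelliteParams()
    by_chrom: dict[str, list[MonomerHit]] = {}
    for h in hits:
        if h.divergence > params.max_seq_div:
            continue
        by_chrom.setdefault(h.chrom, []).append(h)
    out: list[SatelliteRegion] = []
    for chrom, hs in by_chrom.items():
        hs.sort(key=lambda h: (h.start, h.end))
        clusters: list[list[MonomerHit]] = [[hs[0]]]
        cur_end = hs[0].end
        for h in hs[1:]:
            if h.start - cur_end <= params.merge_distance:
                clusters[-1].append(h)
                cur_end = max(cur_end, h.end)
            else:
                clusters.append([h])
                cur_end = h.end
        for cl in clusters:
            s = min(h.start for h in cl)
            e = max(h.end for h in cl)
            if e - s < params.min_array:
                continue
            lo = s - params.slop
            hi = e + params.slop
            lo = max(lo, 0)
            if sequence_lengths is not None and chrom in sequence_lengths:
                hi = min(hi, sequence_lengths[chrom])
            out.append(SatelliteRegion(chrom, s, e, lo, hi, len(cl), satellite_class))
    out.sort(key=lambda r: (r.chrom, r.core_start))
    return out


def assign_region_chromosome(
    alignment_fractions: Mapping[str, float], params: SatelliteParams | None = None
) -> str | None:
    """Name a contig after the chromosome with the largest aligned fraction.

    Requires the winner to reach ``min_chrom_align_pct``; an exact tie for
    the top fraction returns unassigned (None) rather than fabricating a
    name.
    """
    params = params or SatelliteParams()
    if not alignment_fractions:
        return None
    for f in alignment_fractions.values():
        if not 0 <= f <= 1:
            raise ValueError("aligned fractions must be in [0,1]")
    best = max(alignment_fractions.values())
    if best < params.min_chrom_align_pct:
        return None
    winners = [c for c, f in alignment_fractions.items() if f == best]
    return winners[0] if len(winners) == 1 else None


def periodicity_scores(
    sv_sizes: Sequence[int], candidate_range: tuple[int, int] = (50, 500)
) -> tuple[np.ndarray, np.ndarray]:
    """Deviation score per candidate period.

    score(p) = mean over sizes of min(s mod p, p - s mod p) / p — the mean
    relative distance of each size to its nearest multiple of p.
    """
    sizes = np.asarray([s for s in sv_sizes], dtype=float)
    lo, hi = candidate_range
    periods = np.arange(lo, hi + 1, dtype=float)
    mods = sizes[:, None] % periods[None, :]
    dev = np.minimum(mods, periods[None, :] - mods) / periods[None, :]
    return periods.astype(int), dev.mean(axis=0)


def estimate_sv_periodicity(
    sv_sizes: Sequence[int],
    candidate_range: tuple[int, int] = (50, 500),
    tolerance: float = 1e-6,
    max_size: int = 5_000,
) -> int:
    """Dominant period of a set of SV sizes.

    Sizes are filtered to < ``max_size``; at least 3 must remain.  Returns
    the LARGEST candidate period whose deviation score is within
    ``tolerance`` of the minimum — every divisor of the true period scores
    identically, so the largest near-optimal period is the period itself.
    """
    sizes = [s for s in sv_sizes if s < max_size]
    if len(sizes) < 3:
        raise ValueError("need at least 3 SV sizes below the size cap")
    periods, scores = periodicity_scores(sizes, candidate_range)
    best = scores.min()
    near = periods[scores <= best + tolerance]
    return int(near.max())


def kmer_prefilter(
    sequences: Mapping[str, str], params: SatelliteParams | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Naive repeat prefilter: positions of k-mers occurring > threshold.

    A desk-scale stand-in for the KMC repeat-detection stage: marks, per
    sequence, the intervals covered by ``kmer_len``-mers seen more than
    ``kmer_min_occurrences`` times genome-wide.
    """
    from .io_formats import merge_intervals
    from .kmer_copynum import encode_kmers

    params = params or SatelliteParams()
    k = params.kmer_len
    if k > 31:
        # pack on a 31-mer proxy anchored at each k-mer start
        k_eff = 31
    else:
        k_eff = k
    counts: dict[int, int] = {}
    per_seq: dict[str, np.ndarray] = {}
    for name, seq in sequences.items():
        codes = encode_kmers(seq, k_eff)
        per_seq[name] = codes
        uniq, c = np.unique(codes, return_counts=True)
        for u, n in zip(uniq.tolist(), c.tolist()):
            counts[u] = counts.get(u, 0) + n
    out: dict[str, list[tuple[int, int]]] = {}
    for name, codes in per_seq.items():
        hot = [i for i, c in enumerate(codes.tolist()) if counts[c] > params.kmer_min_occurrences]
        out[name] = merge_intervals([(i, i + k) for i in hot])
    return out
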