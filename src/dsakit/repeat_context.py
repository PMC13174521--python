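"""Repeat-context annotation and descriptive somatic-variant statistics.

Provides the stratifications behind the toolkit's summary tables: per-variant
repeat-context labels (homopolymer and dinucleotide-TR runs detected directly
from sequence, other classes from annotation BEDs, with a fixed precedence),
variant-density enrichment folds by repeat class, SBS96 trinucleotide
substitution profiles with a per-region goodness-of-fit test against the
genome-wide profile, 1 bp indel rates versus homopolymer length with Wilson
confidence intervals, and LINE poly-A tail length measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .io_formats import revcomp

#: annotation precedence, highest first (sequence-derived homopolymer/diTR
#: rank below interval annotations)
CONTEXT_PRECEDENCE = (
    "satellite_alpha",
    "satellite_hsat",
    "telomere",
    "segdup",
    "VNTR",
    "STR",
    "diTR",
    "homopolymer",
)

MIN_HOMOPOLYMER = 4  # shortest run reported as a homopolymer


@dataclass
class RepeatContext:
    klass: str = "none"
    homopolymer_base: str | None = None
    homopolymer_len: int = 0
    tr_unit_len: int = 0
    tr_span: int = 0


def _maximal_run(seq: str, pos: int) -> tuple[str, int, int, int]:
    """Maximal single-base run containing or abutting ``pos``.

    Returns (base, start, end, length) of the longest candidate run among
    those touching positions pos-1, pos, pos+1.
    """
    best = ("", 0, 0, 0)
    for p in (pos - 1, pos, pos + 1):
        if not 0 <= p < len(seq):
            continue
        b = seq[p]
        s = p
        while s > 0 and seq[s - 1] == b:
            s -= 1
        e = p + 1
        while e < len(seq) and seq[e] == b:
            e += 1
        if e - s > best[3]:
            best = (b, s, e, e - s)
    return best


def _ditr_run(seq: str, pos: int) -> tuple[int, int]:
    """(unit length, span) of a dinucleotide TR containing ``pos``, else (0,0)."""
    for p in (pos, pos - 1):
        if not 0 <= p < len(seq) - 1:
            continue
        for phase in (0, 1):
            s = p - phase
            if s < 0 or s + 2 > len(seq):
                continue
            unit = seq[s : s + 2]
            if unit[0] == unit[1]:
                continue
            a = s
            while a - 2 >= 0 and seq[a - 2 : a] == unit:
                a -= 2
            b = s + 2
            while b + 2 <= len(seq) and seq[b : b + 2] == unit:
                b += 2
            if b - a >= 6:  # >= 3 copies
                return 2, b - a
    return 0, 0


def annotate_repeat_context(
    chrom: str,
    pos: int,
    end: int,
    sequences: Mapping[str, str],
    annotations: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]] | None = None,
) -> RepeatContext:
    """Repeat context of a variant at [pos, end) on ``chrom``.

    ``annotations`` maps class name -> per-chromosome BED intervals for the
    interval-based classes; homopolymers and dinucleotide TRs are detected
    from the sequence itself.
    """
    ann = annotations or {}
    for klass in CONTEXT_PRECEDENCE:
        if klass in ("homopolymer", "diTR"):
            continue
        for s, e in ann.get(klass, {}).get(chrom, ()):
            if s < end and e > pos:
                return RepeatContext(klass=klass)
    seq = sequences[chrom]
    unit_len, span = _ditr_run(seq, pos)
    if unit_len:
        return RepeatContext(klass="diTR", tr_unit_len=unit_len, tr_span=span)
    base, s, e, length = _maximal_run(seq, pos)
    if length >= MIN_HOMOPOLYMER:
        return RepeatContext(
            klass="homopolymer", homopolymer_base=base, homopolymer_len=length
        )
    return RepeatContext()


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentRow:
    variant_type: str
    repeat_class: str
    n_variants: int
    class_bp: int
    density: float
    genome_density: float
    fold: float | None  # None when class_bp == 0


def enrichment_table(
    contexts: Sequence[tuple[str, str]],
    composition_bp: Mapping[str, int],
    genome_bp: int,
) -> list[EnrichmentRow]:
    """Fold enrichment of variant density per repeat class.

    ``contexts`` is (variant type, repeat class) per variant;
    ``composition_bp`` the genome bp per class.  fold =
    (n_class / bp_class) / (n_total / bp_total) per variant type.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    df = pd.DataFrame(contexts, columns=["vtype", "klass"])
    out = []
    for vtype, sub in df.groupby("vtype"):
        total = len(sub)
        gdens = total / genome_bp
        for klass in sorted(set(composition_bp) | set(sub.klass)):
            n = int((sub.klass == klass).sum())
            bp = int(composition_bp.get(klass, 0))
            dens = n / bp if bp else float("nan")
            fold = (dens / gdens) if bp and gdens > 0 else (None if not bp else 0.0)
            out.append(EnrichmentRow(vtype, klass, n, bp, dens, gdens, fold))
    return out


# ---------------------------------------------------------------------------
# SBS96
# ---------------------------------------------------------------------------

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
SBS96_LABELS = tuple(
    f"{f}[{sub}]{t}" for sub in _SUBS for f in "ACGT" for t in "ACGT"
)
_SBS_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def sbs96_class(ref: str, alt: str, five: str, three: str) -> str | None:
    """Pyrimidine-strand SBS96 label, None for ambiguous context bases."""
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    if ref in "AG":  # purine: flip to the pyrimidine strand
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    if any(b not in "ACGT" for b in (ref, alt, five, three)) or ref == alt:
        return None
    return f"{five}[{ref}>{alt}]{three}"


def sbs96_profile(
    snvs: Iterable[tuple[str, int, str, str]], sequences: Mapping[str, str]
) -> tuple[np.ndarray, int]:
    """96-vector of trinucleotide-context substitution counts.

    Returns (counts, n_ambiguous) where ambiguous-context SNVs (edge of a
    sequence or non-ACGT bases) are counted separately.
    """
    counts = np.zeros(96, dtype=int)
    ambiguous = 0
    for chrom, pos, ref, alt in snvs:
        seq = sequences[chrom]
        if pos < 1 or pos + 1 >= len(seq):
            ambiguous += 1
            continue
        lab = sbs96_class(ref, alt, seq[pos - 1], seq[pos + 1])
        if lab is None:
            ambiguous += 1
            continue
        counts[_SBS_INDEX[lab]] += 1
    return counts, ambiguous


def genome_trinucleotide_profile(sequences: Mapping[str, str]) -> np.ndarray:
    """Null SBS96 proportions from genome trinucleotide frequencies.

    Each substitution from a context is weighted by the genome frequency of
    the context (the three alts of a pyrimidine context share its
    frequency), normalized to sum to 1.
    """
    tri = np.zeros(96)
    for seq in sequences.values():
        s = seq.upper()
        for i in range(1, len(s) - 1):
            for alt in "ACGT":
                if alt == s[i]:
                    continue
                lab = sbs96_class(s[i], alt, s[i - 1], s[i + 1])
                if lab is not None:
                    tri[_SBS_INDEX[lab]] += 1
    total = tri.sum()
    if total == 0:
        raise ValueError("no usable trinucleotides in the genome")
    return tri / total


def sbs96_gof_test(counts: np.ndarray, null_probs: np.ndarray) -> float:
    """Chi-square goodness-of-fit p-value against fixed null proportions.

    Categories with expected count < 1 are pooled into one category before
    the test (df = remaining categories - 1).
    """
    counts = np.asarray(counts, float)
    n = counts.sum()
    if n == 0:
        raise ValueError("region has no classified SNVs")
    expected = n * np.asarray(null_probs, float)
    keep = expected >= 1
    obs = np.append(counts[keep], counts[~keep].sum())
    exp = np.append(expected[keep], expected[~keep].sum())
    if exp[-1] == 0:
        obs, exp = obs[:-1], exp[:-1]
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(stat, df=len(obs) - 1))


def sbs96_gof_test_batch(counts: np.ndarray, null_probs: np.ndarray) -> np.ndarray:
    """Vectorized ``sbs96_gof_test`` over rows of a (regions x 96) matrix.

    Pooling is per row, identical to the scalar routine.
    """
    counts = np.asarray(counts, float)
    n = counts.sum(axis=1, keepdims=True)
    expected = n * np.asarray(null_probs, float)[None, :]
    keep = expected >= 1
    obs_kept = np.where(keep, counts, 0.0)
    exp_kept = np.where(keep, expected, 0.0)
    pooled_obs = (counts - obs_kept).sum(axis=1)
    pooled_exp = (expected - exp_kept).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp_kept > 0, (obs_kept - exp_kept) ** 2 / exp_kept, 0.0)
    stat = terms.sum(axis=1)
    has_pool = pooled_exp > 0
    stat = stat + np.where(has_pool, (pooled_obs - pooled_exp) ** 2 / np.where(has_pool, pooled_exp, 1.0), 0.0)
    df = keep.sum(axis=1) + has_pool.astype(int) - 1
    return stats.chi2.sf(stat, df=df)


def sbs96_profile_and_test(
    snvs_by_region: Mapping[str, Sequence[tuple[str, int, str, str]]],
    sequences: Mapping[str, str],
    null_probs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region SBS96 profile with chi-square p and BH-FDR across regions."""
    if null_probs is None:
        null_probs = genome_trinucleotide_profile(sequences)
    rows = []
    for region, snvs in snvs_by_region.items():
        counts, ambiguous = sbs96_profile(snvs, sequences)
        if counts.sum() == 0:
            import warnings

            warnings.warn(f"region {region!r} has no classified SNVs; skipped")
            continue
        p = sbs96_gof_test(counts, null_probs)
        rows.append({"region": region, "n_snvs": int(counts.sum()),
                     "n_ambiguous": ambiguous, "p_value": p, "counts": counts})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df.p_value, method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Homopolymer indel-rate curves
# ---------------------------------------------------------------------------


def homopolymer_census(
    sequences: Mapping[str, str], min_len: int = MIN_HOMOPOLYMER
) -> pd.DataFrame:
    """All maximal single-base runs >= min_len: chrom, start, end, base, length."""
    rows = []
    for chrom, seq in sequences.items():
        i = 0
        n = len(seq)
        while i < n:
            j = i + 1
            while j < n and seq[j] == seq[i]:
                j += 1
            if j - i >= min_len and seq[i] in "ACGT":
                rows.append({"chrom": chrom, "start": i, "end": j,
                             "base": seq[i], "length": j - i})
            i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "base", "length"])


@dataclass
class IndelRatePoint:
    base_class: str  # "A/T" or "C/G"
    length: int
    event_type: str  # ins | del
    n_sites: int
    n_events: int
    rate: float
    ci_low: float
    ci_high: float


def homopolymer_indel_rate(
    variants: Sequence[tuple[str, int, str, str]],
    sequences: Mapping[str, str],
    census: pd.DataFrame | None = None,
) -> list[IndelRatePoint]:
    """1 bp indel rate per homopolymer length and base class, Wilson 95% CI.

    The denominator is the number of genomic homopolymer sites of that
    length and base class; the numerator counts 1 bp insertions/deletions
    whose position falls in (or abuts) such a run.
    """
    if census is None:
        census = homopolymer_census(sequences)
    census = census.assign(
        base_class=np.where(census.base.isin(["A", "T"]), "A/T", "C/G")
    )
    site_counts = census.groupby(["base_class", "length"]).size()
    events: dict[tuple[str, int, str], int] = {}
    for chrom, pos, ref, alt in variants:
        if abs(len(ref) - len(alt)) != 1:
            continue
        etype = "ins" if len(alt) > len(ref) else "del"
        base, s, e, length = _maximal_run(sequences[chrom], pos)
        if length < MIN_HOMOPOLYMER:
            continue
        bc = "A/T" if base in "AT" else "C/G"
        events[(bc, length, etype)] = events.get((bc, length, etype), 0) + 1
    out = []
    for (bc, length), n_sites in site_counts.items():
        for etype in ("ins", "del"):
            n_ev = events.get((bc, length, etype), 0)
            rate = n_ev / n_sites
            lo, hi = proportion_confint(min(n_ev, n_sites), n_sites, method="wilson")
            out.append(IndelRatePoint(bc, int(length), etype, int(n_sites), n_ev,
                                      rate, float(lo), float(hi)))
    return out


# ---------------------------------------------------------------------------
# Poly-A tails
# ---------------------------------------------------------------------------


def polya_tail_length(sequence: str, tolerance: int = 0) -> int:
    """Length of the 3'-terminal poly-A tail of an insertion sequence.

    With tolerance 0 this is the maximal uninterrupted terminal A run.  With
    tolerance t, the longest terminal suffix containing at most t non-A
    bases, each flanked by at least 5 A's on both sides, counts.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    n = len(s)
    if tolerance <= 0:
        i = n
        while i > 0 and s[i - 1] == "A":
            i -= 1
        return n - i
    best = 0
    for start in range(n - 1, -1, -1):
        suffix = s[start:]
        non_a = [i for i, b in enumerate(suffix) if b != "A"]
        if len(non_a) > tolerance:
            break
        ok = True
        for i in non_a:
            left = suffix[max(0, i - 5) : i]
            right = suffix[i + 1 : i + 6]
            if not (left == "A" * 5 and right == "A" * 5):
                ok = False
                break
        if ok and (not suffix or suffix[-1] == "A"):
            best = len(suffix)
    return best
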