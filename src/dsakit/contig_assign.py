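"""Assign unplaced contigs to chromosomes against a haplotype panel.

Each contig is aligned to every haplotype assembly in a panel; per
(haplotype, chromosome) cell the score is the product of query coverage
(merged alignment intervals / contig length) and the alignment-length-
weighted mean gap-compressed identity.  Chromosomes are ranked by the mean
score across ALL panel haplotypes (absent cells count 0); the contig is
assigned to the top chromosome only when the fraction of haplotypes whose
own best chromosome is that one reaches the unanimity threshold and the top
mean score clears the score floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import merge_intervals


@dataclass
class AssignParams:
    unanimity_min: float = 0.95
    score_min: float = 0.60

    def __post_init__(self) -> None:
        if not (0 <= self.unanimity_min <= 1 and 0 <= self.score_min <= 1):
            raise ValueError("thresholds must be in [0,1]")


@dataclass
class ContigAlignment:
    query_start: int
    query_end: int
    alignment_length: int
    identity: float  # gap-compressed

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1:
            raise ValueError("identity must be in [0,1]")


@dataclass
class ContigAlignmentSet:
    contig: str
    length: int
    cells: dict[tuple[str, str], list[ContigAlignment]] = field(default_factory=dict)

    def add(self, haplotype: str, chromosome: str, aln: ContigAlignment) -> None:
        if not (0 <= aln.query_start < aln.query_end <= self.length):
            raise ValueError("alignment interval outside contig")
        self.cells.setdefault((haplotype, chromosome), []).append(aln)


def score_contig(alignments: ContigAlignmentSet) -> dict[tuple[str, str], float]:
    """coverage x weighted identity per (haplotype, chromosome) cell."""
    if alignments.length <= 0:
        raise ValueError("zero-length contig")
    scores: dict[tuple[str, str], float] = {}
    for cell, alns in alignments.cells.items():
        covered = sum(
            e - s for s, e in merge_intervals([(a.query_start, a.query_end) for a in alns])
        )
        coverage = covered / alignments.length
        wsum = sum(a.alignment_length for a in alns)
        identity = (
            sum(a.alignment_length * a.identity for a in alns) / wsum if wsum else 0.0
        )
        scores[cell] = coverage * identity
    return scores


@dataclass
class Assignment:
    contig: str
    chromosome: str | None
    mean_score: float
    unanimity: float
    status: str  # assigned | unassigned


def assign_contig(
    scores: Mapping[tuple[str, str], float],
    haplotypes: Sequence[str],
    params: AssignParams | None = None,
    contig: str = "",
) -> Assignment:
    """Rank chromosomes by panel-mean score and apply the unanimity rule.

    Haplotypes with no alignments (all-zero scores) stay in the unanimity
    denominator but agree with no chromosome; a haplotype whose best score
    is tied between chromosomes likewise does not agree.
    """
    params = params or AssignParams()
    if not haplotypes:
        raise ValueError("empty haplotype panel")
    chroms = sorted({c for _, c in scores})
    if not chroms:
        return Assignment(contig, None, 0.0, 0.0, "unassigned")
    n_hap = len(haplotypes)
    mean_scores = {
        c: sum(scores.get((h, c), 0.0) for h in haplotypes) / n_hap for c in chroms
    }
    top = max(mean_scores, key=lambda c: (mean_scores[c], c))
    agree = 0
    for h in haplotypes:
        per = {c: scores.get((h, c), 0.0) for c in chroms}
        best = max(per.values())
        if best <= 0:
            continue
        winners = [c for c, v in per.items() if v == best]
        if len(winners) == 1 and winners[0] == top:
            agree += 1
    unanimity = agree / n_hap
    ok = unanimity >= params.unanimity_min and mean_scores[top] >= params.score_min
    return Assignment(
        contig,
        top if ok else None,
        mean_scores[top],
        unanimity,
        "assigned" if ok else "unassigned",
    )
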