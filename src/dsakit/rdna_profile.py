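"""rDNA methylation and variant profiling on a collapsed repeat unit.

Reads from rDNA arrays cannot be assigned to individual chromosomes, so all
analyses run against a single repeat-unit reference: coverage-filtered
binned CpG methylation, per-read regional methylation with alignment-quality
filters and removal of the least-confident calls, and per-region variant
density after quality and allele-frequency filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class RdnaParams:
    bin_size: int = 200
    min_site_coverage: int = 100
    min_read_ref_coverage: float = 0.70
    min_read_identity: float = 0.90
    confidence_drop_fraction: float = 0.10
    min_variant_quality: float = 30.0
    min_allele_frequency: float = 0.05

    def __post_init__(self) -> None:
        for f in (
            self.min_read_ref_coverage,
            self.min_read_identity,
            self.confidence_drop_fraction,
            self.min_allele_frequency,
        ):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0,1]")


@dataclass
class RegionSet:
    """Named non-overlapping intervals on the rDNA repeat unit."""

    regions: dict[str, tuple[int, int]]
    unit_length: int

    def __post_init__(self) -> None:
        ivs = sorted(self.regions.values())
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("regions overlap")
        for s, e in ivs:
            if not 0 <= s < e <= self.unit_length:
                raise ValueError("region outside reference")

    @classmethod
    def proportional(cls, unit_length: int) -> "RegionSet":
        """45S-like layout scaled to a miniature unit.

        Promoter, 18S-, 5.8S- and 28S-like subregions occupy the first
        ~half (the gene body); the rest is IGS-like spacer, mirroring the
        real unit's proportions.
        """
        f = lambda x: int(round(x * unit_length))
        return cls(
            {
                "promoter": (0, f(0.04)),
                "18S": (f(0.08), f(0.22)),
                "5.8S": (f(0.26), f(0.28)),
                "28S": (f(0.32), f(0.52)),
                "IGS": (f(0.56), unit_length),
            },
            unit_length,
        )

    def gene_body(self) -> tuple[int, int]:
        return self.regions["18S"][0], self.regions["28S"][1]


def bin_methylation(
    pileup: pd.DataFrame, params: RdnaParams | None = None, unit_length: int | None = None
) -> pd.DataFrame:
    """Coverage-filtered CpG methylation aggregated into fixed-size bins.

    ``pileup`` needs columns start, coverage, modified (bedmethyl-like,
    sorted or not).  Sites below ``min_site_coverage`` are excluded; each
    bin's mean is the pooled ratio sum(modified)/sum(coverage) over the
    retained sites; bins with no retained site get NaN, not zero.
    """
    params = params or RdnaParams()
    df = pileup[pileup.coverage >= params.min_site_coverage].copy()
    length = unit_length or (int(pileup.start.max()) + 1 if len(pileup) else 0)
    n_bins = max(1, int(np.ceil(length / params.bin_size)))
    df["bin"] = (df.start // params.bin_size).astype(int)
    agg = df.groupby("bin").agg(modified=("modified", "sum"), coverage=("coverage", "sum"))
    out = pd.DataFrame(
        {
            "bin": range(n_bins),
            "start": [b * params.bin_size for b in range(n_bins)],
            "end": [min((b + 1) * params.bin_size, length) for b in range(n_bins)],
        }
    ).set_index("bin")
    out["mean_methylation"] = agg.modified / agg.coverage
    return out.reset_index()


def per_read_region_methylation(
    reads: pd.DataFrame,
    region_cpg_indices: Sequence[int] | None = None,
    params: RdnaParams | None = None,
) -> pd.Series:
    """Per-read mean methylation over a region's CpGs after filtering.

    ``reads`` has one row per (read, cpg) with columns read, cpg_index,
    methylated, confidence, ref_coverage_fraction, identity.  Reads failing
    the alignment coverage/identity gates drop; then the globally
    lowest-confidence fraction of calls is removed (a single sample-wide
    quantile); per-read means are over the surviving calls in the region.
    """
    params = params or RdnaParams()
    df = reads[
        (reads.ref_coverage_fraction > params.min_read_ref_coverage)
        & (reads.identity > params.min_read_identity)
    ]
    if region_cpg_indices is not None:
        df = df[df.cpg_index.isin(set(region_cpg_indices))]
    if len(df) == 0:
        return pd.Series(dtype=float)
    if params.confidence_drop_fraction > 0:
        k = int(np.floor(params.confidence_drop_fraction * len(df)))
        if k > 0:
            order = np.argsort(df.confidence.to_numpy(), kind="stable")
            df = df.iloc[order[k:]]
    return df.groupby("read").methylated.mean()


def variant_density(
    variants: Sequence[tuple[int, float, float]],
    regions: RegionSet,
    params: RdnaParams | None = None,
) -> pd.DataFrame:
    """Variants per kb per region after quality and AF filters.

    ``variants`` are (position, quality, allele frequency); those with
    quality < ``min_variant_quality`` or AF < ``min_allele_frequency`` are
    excluded.
    """
    params = params or RdnaParams()
    kept = [
        (p, q, af)
        for p, q, af in variants
        if q >= params.min_variant_quality and af >= params.min_allele_frequency
    ]
    rows = []
    for name, (s, e) in regions.regions.items():
        if e <= s:
            raise ValueError(f"region {name} has non-positive length")
        n = sum(1 for p, _, _ in kept if s <= p < e)
        rows.append(
            {
                "region": name, "start": s, "end": e, "n_variants": n,
                "density_per_kb": n / ((e - s) / 1000.0),
            }
        )
    return pd.DataFrame(rows)
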