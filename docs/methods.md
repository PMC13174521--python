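# Methods

This note records the models, parameter choices and known limitations behind
`dsakit`, in the order a user meets them.

## The synthetic diploid genome

`synthetic_data.build_normal_genome` emits a miniature diploid genome whose
structure carries every feature the downstream stages consume. Defaults
(all `GenomeConfig` fields):

- **2 autosome mimics + 5 acrocentric mimics**, 200 kbp each per haplotype
  (~2.6 Mbp diploid total). Five acrocentric arms mirror the normal human
  acrocentric complement, which is what makes the distal-junction copy
  number of a normal diploid genome equal 10.
- **α-satellite-like arrays**: a fixed synthetic 171 bp monomer (arbitrary
  ~50% GC sequence, *not* the real alphoid consensus) tiled into
  higher-order-repeat-style arrays of 120 monomers (~20.5 kbp) on every
  chromosome. Arrays are exact monomer tilings before germline divergence.
- **Distal-junction (DJ) unit**: one 5 kbp random sequence placed exactly
  once per acrocentric arm per haplotype and *shared* across arms, so its
  31-mers have genome multiplicity 10. DJ units receive no germline
  variation — their defining property is an identical k-mer set across
  copies; real DJs diverge slightly, which the median-based estimator
  tolerates but the generator does not model.
- **rDNA-like units**: 2 kbp units (scaled from the real ~45 kbp 45S unit),
  8 per acrocentric arm, placed in tandem with zero spacing.
  `rdna_profile.RegionSet.proportional` lays promoter/18S/5.8S/28S/IGS-like
  subregions at positions proportional to the real unit.
- **Homopolymers and TRs** per chromosome: A/C/G/T runs of 8–35 bp and
  di-/tri-/penta-nucleotide repeats, each ledgered with base and unit.
  Boundary bases are forced to differ from the run base so ledger
  coordinates delimit *maximal* runs.
- **Germline heterozygosity** at 1e-4 per bp: 80% SNVs, 20% 1–3 bp indels,
  each assigned to one haplotype. Indels inside satellite or rDNA features
  are converted to SNVs (divergence without breaking monomer-multiple
  arithmetic); DJ units are skipped entirely (above).

Coordinates are 0-based half-open throughout; the feature ledger indexes the
emitted per-haplotype FASTA exactly (germline edits shift ledger rows via
explicit offset mapping). Everything is a pure function of the config seed.

## The somatic process

`derive_tumor_genome` applies, per haplotype: SNVs at 2e-5/bp; 1 bp
slippage indels at context-dependent rates (2e-3/bp in homopolymers,
1e-3/bp in dinucleotide TRs, 2e-6 elsewhere); ~40 genome-wide satellite SVs
drawn as unequal-crossover events — deletions or tandem duplications of
1–20 whole monomers anchored at monomer boundaries, so truth SV sizes are
exact multiples of 171 bp; and loss of 50% of rDNA units per haplotype,
with contiguous lost units collapsed into single deletion events (always
clonal). 20% of point variants are subclonal with cell fraction drawn from
Uniform(0.1, 0.45); truncal variants have cell fraction exactly 1. The
subclonal band deliberately sits below 0.5 so that, in the zero-noise
limit, the truncal classifier's 50% VAF gate separates clonality classes
exactly; real tumors have subclones at any fraction, and nothing in the
classifier depends on this choice. Overlapping sampled events are resolved
by keeping rDNA-loss events first, then earlier events; the truth set
applied to the normal sequences reproduces the tumor sequences
byte-for-byte (tested).

Noise models are the simplest ones consistent with the statistics computed
downstream: Poisson k-mer counts (`count ~ Poisson(depth × multiplicity)`,
with depth per genome copy, so the diploid peak sits at 2 × depth),
binomial read support (tumor alt ~ Binomial(cov, cell fraction adjusted for
error); `sampling="expected"` gives the deterministic zero-noise limit as
rounded expectations), and beta-binomial methylation (per-CpG level ~
Beta(mean, dispersion ρ); ρ→0 degenerates to binomial, mean 0/1 saturate
exactly). The generator does not model read mapping, quality strings,
haplotype-mapping ambiguity of short reads, or coverage waviness — so
passing tests demonstrate correctness of the *rules and estimators*, not
robustness to alignment artifacts.

## k-mer copy number

K-mers are canonical (min of forward and reverse-complement encodings,
2-bit packed, k ≤ 31). The GC-matched-bin estimator tiles the background
chromosome into non-overlapping 2 kbp windows, keeps those within 0.02
absolute GC fraction of the feature (the matching tolerance is a choice;
"similar GC" has no canonical definition), and computes
`median(feature counts) / median(bin counts) / ploidy_divisor`. Count
filtering is single-pass: zero-count k-mers drop, counts more than 3 sample
standard deviations (n−1 denominator) above the set mean drop, and an SD of
0 (all counts equal) removes nothing — the rule is a strict inequality.
The filter is applied separately to the feature set and the bin set; k-mers
repeated *within* the feature or bin sequences have their counts divided by
that internal multiplicity, and bin k-mers also present in the feature are
discarded as non-exclusive. `ploidy_divisor=2` is for samples where the
background chromosome is haploid (e.g. a tumor that lost one copy).

The DJ estimator needs no background bins: it normalizes
`2 × median(DJ k-mer counts)` by the diploid coverage peak, taken as the
integer mode of the genome-wide k-mer count spectrum after excluding counts
below `min_peak_count` (default depth/4) to suppress error k-mers. Estimates
are reported as reals; integer calls use round-half-to-even on request.

## Satellite arrays and periodicity

The motif length filter accepts a length iff some n ≤ class maximum (5 for
α-satellite, 42 for HSat1A) puts it within 2% of n × 170 bp, with the
*target multiple* as the denominator — the rule tests closeness to the
multiple, not to the motif. Monomer hits above 30% divergence are discarded;
survivors merge transitively while the end-to-start gap is ≤ 100 kbp
(inclusive; measured on interval ends, not midpoints); merged cores under
30 kbp drop; survivors get ±1 Mbp slop clipped to sequence bounds.
Chromosome naming takes the argmax aligned fraction if ≥ 5%, with exact
ties left unassigned rather than fabricating a name.

Periodicity: for each candidate period p in [50, 500], the score is the
mean over SV sizes (< 5 kbp, ≥ 3 required) of
`min(s mod p, p − s mod p) / p`. Every divisor of the true period scores
identically, so the estimator returns the *largest* period within 1e-6 of
the minimal score.

## Evidence rules

Both engines implement their gates with strict inequalities exactly as
stated (`GQ > 4`, `< 2× mean`, `> 50%`, `< 10%`, `coverage > 5`, …).
Decisions recorded as open choices:

- "low MQ" is a caller-supplied boolean on the support record (MQ < 20
  suggested at I/O time); no MQ model exists in the simulator.
- "homopolymer covered by short reads" = homopolymer longer than 6 bp with
  short-read coverage > 5 at the site, mirroring the polishing bound.
- The combined-technology vote is a conservative AND over all applicable
  technologies; per-technology verdicts are emitted for audit. A technology
  with coverage ≤ 5 in either sample abstains rather than failing.
- Per-haplotype short-read evidence passes when at least one haplotype
  satisfies (> 30% tumor and < 10% normal) or (> 90% and < 70%) — the
  carrier haplotype is the one expected to show signal.
- When a variant sits in a somatic duplication the 30% gate replaces the
  50% gate; the per-haplotype rule still applies alongside it, combined
  conservatively.
- Polish-merge conflicts resolve by technology priority short-accurate >
  HiFi > ONT, matching the relative indel accuracy ordering that motivates
  the per-technology filters.

## Representation shift

The lift map is an explicit block list (chain-file-like); no external
liftOver binary is involved, because synthetic genomes ship with their true
alignment (`LiftMap.from_germline_edits`). Projection gives a ±50 bp
slopped interval a target when a colinear block run covers ≥ 10% of it;
blocks chain only while the reference gap exceeds the DSA gap by ≤ 5 kbp,
so duplicated placements become `multi_lift` instead of one absurd chain.

Classification realigns the local tumor haplotype (DSA window + somatic)
against the lifted reference window with edlib and subtracts the
germline-only diffs (DSA window vs reference window). Because optimal
edit-distance alignments are not unique, fragmentary diffs separated by ≤ 3
matched bases are first collapsed into single replacement variants and
normalized (left-aligned, parsimony-trimmed) — the comparison then sees
events the way a caller emits them. Type is compared at SNV-vs-indel
granularity: a somatic 2 bp deletion surfacing as a net 8 bp insertion is a
*size* change (the event is still an indel); a somatic SNV surfacing as an
indel is a *type* change. Precedence: unliftable > multi_lift >
in_germline_cnv > reverts_germline > type_changed > size_changed >
difficult_region > position_shift_only > unchanged. `difficult_region` is
an input BED tag, never computed.

Kataegis/omikli use gap ≤ 1 kbp with ≥ 6 members (kataegis) or 2–5
(omikli) — standard literature definitions, exposed as parameters since no
single canonical threshold exists. Cluster-set comparison matches a
reference-projected cluster to a DSA cluster when one DSA cluster contains
≥ 50% of its members (parameterized); unmatched reference clusters are
attributed to opposite-haplotype mixing first, then to germline
interference of any member, else "other".

## Repeat context and rDNA

Context precedence is fixed: satellite > segdup > VNTR > STR > diTR >
homopolymer > none; interval classes come from annotation BEDs, while
homopolymers (minimum reportable length 4) and dinucleotide TRs (≥ 3
copies) are detected directly from sequence around the variant, including
runs the variant merely abuts. Enrichment folds are per-bp of repeat class
(not per element). The SBS96 test is a chi-square goodness-of-fit against
the genome-wide trinucleotide-weighted profile with categories pooled below
expected count 1 and BH correction across regions; the choice of test is
ours — only the thresholds (p < 1e-4, FDR < 0.01) are inherited
conventions. Simulated calibration uses 500 SNVs per region, large enough
for the chi-square tail to be accurate at the 1e-4 level (verified against
1e5 null regions in the test suite). Homopolymer indel rates use
per-*site* denominators (events at length-L homopolymers / number of
genomic length-L homopolymers) with Wilson 95% intervals.

rDNA binning weights sites by coverage — a bin mean is the pooled
modified/total ratio, not the mean of per-site ratios — after excluding
sites under 100 reads. The 10% least-confident methylation calls are
dropped as a single sample-wide quantile (matching upstream tooling); a
per-read alternative would drop 10% of each read's calls and is not the
default. Variant density keeps quality ≥ 30 and allele frequency ≥ 5%.
Reads cannot be assigned to individual rDNA-bearing chromosomes, so all
profiles describe the collapsed repeat unit.

## Problem sizes and determinism

Defaults were chosen so the full test suite runs in well under a minute of
CPU: miniature chromosomes (80–200 kbp), 2–5 acrocentric mimics, 30×
coverage, 400-k-mer calibration tables, 1e5 simulated regions for test
calibration, 10 seeds per recovery check. All generators take explicit
integer seeds; identical configs and seeds reproduce identical FASTA, VCF
and tables. `scripts/acceptance.py` derives every stream from its single
`--seed` argument.

## Known limitations

- The α-satellite monomer, DJ and rDNA sequences are synthetic stand-ins;
  no sequence-level realism (HOR phasing, CENP-B boxes, rDNA promoter
  motifs) is attempted.
- SRF/TRF motif discovery, read alignment, and variant calling engines are
  out of scope: the toolkit consumes their outputs (motif tables, monomer
  BEDs, PAFs, VCFs, support tables).
- The support simulator models haplotype-aware mapping as exact; it cannot
  produce the reference-bias or mapping-ambiguity failure modes the
  classifier's ignore-rules exist for — those rules are tested as stated
  logic, not rediscovered.
- `compare_cluster_sets` attributes causes from supplied per-variant
  metadata; it does not itself recompute representation classes.
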