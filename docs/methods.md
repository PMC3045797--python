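# Methods

## Overview

`splicetrap` models, at the sequence level, a cDNA library protocol that
enriches for alternative-splicing (AS) variants by trapping heteroduplexes:
two distinct splice variants of one gene re-anneal through their shared
exons, the variant-discordant region forms a single-stranded loop, and
loop-bearing restriction fragments are captured, amplified, cloned and
sequenced.  The package couples an in-silico simulator of that protocol to
the downstream analysis pipeline — read QC, consensus clustering,
alignment filtering, AS event detection/classification, coding-consequence
characterization, and expression-balance analysis — so that every stage
can be validated against planted ground truth.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention); GFF3 is converted
on read/write.  "5'" and "3'" always refer to transcription orientation:
the donor of an intron on the minus strand sits at its genomic *end*.
Event classification operates on genomic coordinates after strand
normalization of donor/acceptor roles, so alternative 5'/3' splice-site
labels are strand-correct.  Transcripts with introns shorter than 4 nt are
rejected on load (they cannot carry both splice dinucleotides).

## The simulator

### What it emulates

* **Abundances.** Per-variant copy numbers are log-normal
  (`abundance_mean_copies` = 50, `abundance_log_sd` = 1.0), producing the
  skewed variant balances that make heteroduplex formation informative.
* **Heteroduplex formation.** For every unordered variant pair of a gene,
  discordant regions are computed from an exact per-base genomic-position
  map of the two spliced sequences (the in-silico analogue of annealing
  anchored on shared exons).  Pair frequencies are proportional to the
  product of the two abundances.  Genes with a single variant form only
  homoduplexes.
* **One sequenced strand per clone.** The original protocol's
  non-phosphorylated adaptors meant each clone reported a single strand of
  the duplex.  Each simulated `DuplexRecord` is therefore one *strand
  perspective*: loops of the sequenced strand are proper intervals in its
  transcript coordinates, while partner-only sequence (e.g. a retained
  intron present only on the other strand) collapses to a zero-width
  insertion point annotated with the partner's single-stranded length.
* **Exonuclease VII.** The duplex retains only the region between the
  outermost base pairs shared by both variants; terminal single-stranded
  overhangs are removed before digestion.
* **DpnII digestion.** Cuts are placed immediately 5' of every GATC.
  Sites lying entirely within a single-stranded loop of the sequenced
  strand are not cut, since DpnII requires double-stranded substrate.
* **Capture.** A fragment is a capture target when it touches a loop of at
  least 25 single-stranded nucleotides — the length of the random
  biotinylated annealing oligo.  Targets are captured with probability
  1 − `capture_noise` (default noise 0.05); all other fragments with
  probability `capture_noise` (background carry-over).
* **PCR and sequencing.** Each captured fragment yields
  1 + Poisson(`pcr_redundancy` − 1) reads — the simplest one-parameter
  duplication model with a controllable mean.  The default
  `pcr_redundancy` = 6.6 corresponds to the ~85% post-clustering
  redundancy characteristic of un-normalized PCR-amplified libraries
  (redundancy ≈ 1 − 1/6.6).  Reads carry i.i.d. substitution errors
  (default 0.001/base) and Gaussian Phred strings (mean 30, sd 5,
  clipped to [2, 40]).

### Synthetic study design

`synthetic.synthesize_study(n_genes, seed)` builds one gene per small
chromosome: a 4–7-exon reference (exons 100–250 nt, introns 150–600 nt)
plus one alternative variant differing by exactly one planted event; event
types cycle through alternative 5' site, alternative 3' site, exon
skipping and intron retention.  Alternative-site shifts are 30–90 nt so
that every planted difference exceeds the 25-nt capture threshold.  All
intron boundaries of both variants carry canonical GT..AG dinucleotides
planted strand-aware in the chromosome sequence.

### What it does not emulate

No hybridization thermodynamics or annealing kinetics; no chimeras or
cloning-vector insertions; no 3'-end representation bias (the original
protocol showed none); no indel sequencing errors; genes do not share or
overlap loci.  Passing round-trip tests therefore demonstrate internal
consistency of the algorithms under idealized read generation, not
robustness to the full error structure of real capillary traces.

## Read processing

Quality control keeps, per read, the longest run of consecutive 20-nt
windows (advancing 1 nt) that each contain ≥ 15 bases with Phred ≥ 20;
multi-run reads keep the single longest run (the conventional
trimming choice where the one-sentence windowing rule underdetermines
behaviour).  Reads shorter than 50 nt after trimming are dropped.
Optional vector trimming removes maximal read prefixes/suffixes matching
the vector with one tolerated mismatch per 20 nt; matches under 12 nt are
ignored as chance hits.

Clustering replaces the original assembler (treated as a black box there)
with a specified greedy overlap-consensus procedure: reads are seeded
longest-first; a read joins the cluster with the best (identity, overlap)
among ungapped overlaps of ≥ 40 nt at ≥ 95% identity, located by k-mer
offset voting (k = 15); consensi are per-column majority votes with ties
broken toward the lexicographically smallest base.  The procedure is fully
deterministic for a given read set.  Ungapped overlap scoring is adequate
here because the simulator introduces substitutions only; it would
under-merge indel-rich data.

Redundancy is 100 × (reads − consensi) / reads, reported to two decimals.

## Alignment filtering

Spliced alignments are consumed from PSL (or BED12 chains plus a metrics
sidecar), never computed genome-wide.  Identity = 100 × matches / aligned
query bases (query gaps excluded, the PSL convention); coverage =
100 × aligned query bases / query length — "percentage of sequence length
aligned", i.e. the denominator is the post-trim consensus length, not the
genomic span.  Best hits maximize (matches, identity, coverage) with a
deterministic positional tie-break; match count leads because that is the
standard ranking of the aligner family these files come from.  The
retained set uses inclusive thresholds identity ≥ 93% and coverage ≥ 55%.
Assets with ≥ 2 alignment blocks (after merging target-adjacent blocks)
are multi-exon; single-block assets are intronless.

Inside the simulator pipeline, consensi are placed by infix edit-distance
alignment (edlib) against the spliced sequences of their gene's variants,
with the candidate gene short-listed from the truth manifest; coordinates,
identity and coverage come from that alignment.  This stands in for the
genome-wide spliced aligner of a real deployment, which is out of scope.

The positional profile rescales each asset's covered transcript interval
to 0–100 (0 = 5' end) and counts assets covering each integer percentile.

## Event detection

Assets and reference transcripts are clustered by single-linkage on ≥ 1 nt
*exonic* overlap on the same strand.  For each multi-exon asset and each
overlapping reference, events are sought within the window delimited by
the two outermost exonic overlaps of the pair; only introns entirely
inside the window are compared.  Classification rules, symmetric in the
two chains:

* identical introns — silent;
* same acceptor, different donor — `alt_5ss`, size = donor shift;
* same donor, different acceptor — `alt_3ss`, size = acceptor shift;
* an intron contained in a single exon of the partner —
  `intron_retention`, size = intron length;
* complete exons strictly inside a partner intron whose ends coincide with
  the flanking junctions — `exon_skipping`, size = sum of skipped exon
  lengths.  The two boundary-sharing intron pairs explained by a skipping
  event are suppressed from alternative-site reporting to avoid double
  counting; skipped exons that share a boundary with the host intron
  degrade to alternative-site events instead (strict containment).

Events are de-duplicated by (type, coordinates) within a cluster by
default; the switch `dedup_events=False` reports one event per
asset-reference pair instead (how multi-reference duplicates should count
is genuinely open).  Alternative-site shifts have no lower size bound.
Intronless assets are excluded from classification — without splice sites
their orientation is unknowable — and are instead reported as the fraction
whose span intersects any detected event region (strand-agnostic).

Mutually exclusive exons, alternative first/last exons and alternative
polyadenylation are outside the four-type scheme and are not classified.

## Variant characterization

Given an annotated translation start (projectable between variants through
the shared genome), the first in-frame TAA/TAG/TGA is located in the
spliced sequence.  The PTC distance is the transcript coordinate of the
last exon-exon junction minus the end of the stop codon (positive =
upstream).  NMD candidacy follows the canonical 50-nt rule with strict
inequality (distance > 50 nt), tunable via `rule_nt`.  Single-exon
transcripts have no junction and are flagged undefined rather than scored.

## Expression balance

Peak concentrations are divided by a per-sample reference-gene factor
(user-supplied; the assay used a housekeeping gene).  The per-sample
balance is normalized(ASSET)/normalized(variant); an undetected variant
peak yields a flag, not a ratio.  The cross-sample change is the signed
fold r if r ≥ 1 else −1/r — the convention implied by negative entries in
the published table, whose text defines only the plain ratio.  Reports
round half-away-from-zero at one decimal; internal computation is
unrounded.  |fold| ≥ 2 (inclusive) is called differential.

Ligation probes for a target junction are 20-nt arms abutting the
junction: left probe = forward-primer site (19 nt) + 38-nt stuffer +
upstream arm; right probe (5'-phosphorylated) = downstream arm +
reverse-primer site (23 nt); expected amplicon 19 + 38 + 2×20 + 23 =
120 bp.

## Numerical and determinism choices

* All randomness flows from one `numpy` `default_rng(seed)` per run;
  reruns are byte-identical.
* Rounding of reported ratios/percentages is half-away-from-zero
  (`Decimal`-based), matching how the published tables round.
* Majority-vote ties, best-hit ties and cluster-join ties all have
  documented deterministic tie-breaks.
* Degenerate inputs: empty read sets produce empty (but well-formed)
  reports; zero-read redundancy, zero reference factors, non-ATG starts
  and chains without exonic overlap raise informative errors.

## Problem sizes

The default end-to-end validation uses 50 genes (~700 reads, ~100
consensi), which represents every event type with a dozen or so instances
and runs in about a second; classifier stress tests use 1,000 random
chain pairs.  These sizes were chosen so the full validation suite stays
interactive while keeping Monte-Carlo assertions (redundancy band,
recall) well away from their thresholds.

## Known limitations

* The greedy clusterer is not an assembler: no gapped overlaps, no
  scaffolding; it is calibrated to the simulator's read lengths
  (~100–1,300 nt fragments).
* Consensus placement inside the pipeline relies on the truth manifest to
  short-list candidate transcripts; user-supplied alignments bypass this
  via PSL/BED12 ingestion.
* Event recall is measured against exact planted coordinates; real
  deployments would need fuzzier matching against curated annotation.
* The published study's own sequence data were never deposited; its
  genome-scale counts (214 tags, 164 clusters, 138 events and their type
  split) depend on 2007-era databases and are represented here only by
  the arithmetic and property checks above, with no claim to reproduce
  the original data.
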