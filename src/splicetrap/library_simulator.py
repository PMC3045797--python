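"""Sequence-level re-enactment of the heteroduplex-trapping library protocol.

The simulated protocol, per gene: transcript abundances are drawn, splice
variants are denatured/renatured into heteroduplexes, single-stranded
terminal overhangs are removed (exonuclease VII), the duplex is digested
with DpnII (GATC, cut 5' of the site), fragments whose single-stranded loop
is long enough for a 25-mer oligo to anneal are captured, and captured
fragments are PCR-amplified and sequenced with substitution errors.

Each :class:`DuplexRecord` represents one *sequenced strand* of a duplex
fragment (the protocol's non-phosphorylated adaptors mean each clone reports
a single variant's strand).  Loops are expressed in the transcript
coordinates of that strand: a discordant segment of the strand itself is a
proper interval, while extra sequence present only on the partner strand
collapses to a zero-width insertion point carrying the partner's
single-stranded length.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomic_model import (
    Genome,
    TranscriptModel,
    spliced_sequence,
    transcript_positions,
)

#: length of the random biotinylated annealing oligo; loops shorter than
#: this are not capture targets
OLIGO_NT = 25

_DPNII = re.compile("(?=GATC)")


@dataclass
class SimulationParams:
    """Tunable knobs of the in-silico library protocol.

    ``pcr_redundancy`` is the target mean number of reads per distinct
    captured fragment; its default 6.6 corresponds to a ~85% post-clustering
    redundancy (1 - 1/6.6).
    """

    seed: int = 7
    abundance_mean_copies: float = 50.0
    abundance_log_sd: float = 1.0
    pcr_redundancy: float = 6.6
    capture_noise: float = 0.05
    read_error_rate: float = 0.001
    mean_quality: float = 30.0
    quality_sd: float = 5.0
    min_loop_nt: int = OLIGO_NT

    def __post_init__(self) -> None:
        for p in (self.capture_noise, self.read_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.pcr_redundancy < 1:
            raise ValueError("pcr_redundancy must be >= 1")


@dataclass(frozen=True)
class Loop:
    """A single-stranded region, in sequenced-strand transcript coordinates.

    ``start == end`` marks an insertion point where only the partner strand
    carries sequence; ``ss_length`` is the single-stranded length on
    whichever strand is unpaired.
    """

    start: int
    end: int
    ss_length: int


@dataclass
class DuplexRecord:
    """One sequenced-strand fragment of a simulated duplex."""

    gene_id: str
    variant_a: str  # the sequenced strand
    variant_b: str  # the partner strand
    fragment: tuple[int, int]  # transcript coords of variant_a
    loop_intervals: tuple[Loop, ...]
    sequence: str
    chrom: str
    genomic_start: int
    genomic_end: int
    weight: float = 1.0
    captured: bool = False

    @property
    def loop_bearing(self) -> bool:
        return bool(self.loop_intervals)

    @property
    def max_loop_nt(self) -> int:
        return max((l.ss_length for l in self.loop_intervals), default=0)


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    gene_id: str = ""
    variant_a: str = ""
    variant_b: str = ""
    chrom: str = ""
    genomic_start: int = 0
    genomic_end: int = 0
    loop_flag: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")


def simulate_abundances(
    models: list[TranscriptModel], params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Log-normal per-variant copy numbers, reproducible under the seed."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    copies: dict[str, int] = {}
    mu = np.log(params.abundance_mean_copies)
    for m in sorted(models, key=lambda m: m.transcript_id):
        draw = rng.lognormal(mean=mu, sigma=params.abundance_log_sd)
        copies[m.transcript_id] = max(1, int(round(draw)))
    return copies


def dpnii_digest(sequence: str, offset: int = 0) -> list[tuple[int, str]]:
    """Cut immediately 5' of every GATC; return (offset, fragment) pairs.

    Empty fragments (adjacent sites, leading site) are dropped; the surviving
    fragments concatenate back to the input.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    cuts = [m.start() for m in _DPNII.finditer(sequence)]
    bounds = [0] + cuts + [len(sequence)]
    frags = []
    for a, b in zip(bounds, bounds[1:]):
        if b > a:
            frags.append((offset + a, sequence[a:b]))
    return frags


def _shared_runs(mask: list[bool]) -> list[tuple[int, int]]:
    """Maximal runs of False (discordant positions) as [start, end)."""
    runs = []
    start = None
    for i, shared in enumerate(mask):
        if not shared and start is None:
            start = i
        elif shared and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def form_heteroduplexes(
    variants: list[TranscriptModel],
    genome: Genome,
    abundances: dict[str, int],
    params: SimulationParams,
) -> list[DuplexRecord]:
    """Duplex fragments for every unordered variant pair of one gene.

    For each pair both sequenced-strand perspectives are generated.  The
    duplex is trimmed to the region between the outermost positions shared
    by both variants (exonuclease VII), then digested with DpnII; GATC sites
    lying entirely within a single-stranded loop of the sequenced strand are
    not cut.  Pair weights are proportional to the product of the two
    abundances.
    """
    gene_ids = {m.gene_id for m in variants}
    if len(gene_ids) != 1:
        raise ValueError(f"variants from different genes: {sorted(gene_ids)}")
    gene_id = gene_ids.pop()

    ordered = sorted(variants, key=lambda m: m.transcript_id)
    pairs: list[tuple[TranscriptModel, TranscriptModel]] = []
    if len(ordered) == 1:
        pairs.append((ordered[0], ordered[0]))  # homoduplex only
    else:
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                pairs.append((ordered[i], ordered[j]))
    total_weight = sum(
        abundances.get(x.transcript_id, 1) * abundances.get(y.transcript_id, 1)
        for x, y in pairs
    )

    records: list[DuplexRecord] = []
    for x, y in pairs:
        weight = (
            abundances.get(x.transcript_id, 1)
            * abundances.get(y.transcript_id, 1)
            / total_weight
        )
        perspectives = [(x, y)] if x is y else [(x, y), (y, x)]
        for seq_strand, partner in perspectives:
            records.extend(
                _strand_fragments(seq_strand, partner, genome, gene_id, weight)
            )
    return records


def _strand_fragments(
    x: TranscriptModel,
    y: TranscriptModel,
    genome: Genome,
    gene_id: str,
    weight: float,
) -> list[DuplexRecord]:
    pos_x = transcript_positions(x)
    pos_y = transcript_positions(y)
    set_y = set(pos_y)
    set_x = set(pos_x)
    shared = [p in set_y for p in pos_x]
    if not any(shared):
        return []  # nothing anneals; fully degraded by exonuclease

    # exonuclease VII: keep the region between the outermost shared bases
    lo = shared.index(True)
    hi = len(shared) - 1 - shared[::-1].index(True)
    region = slice(lo, hi + 1)

    loops: list[Loop] = []
    for a, b in _shared_runs(shared[region]):
        loops.append(Loop(lo + a, lo + b, b - a))
    # partner-only runs -> insertion points on x
    y_shared = [p in set_x for p in pos_y]
    genomic_to_tx = {p: i for i, p in enumerate(pos_x)}
    for a, b in _shared_runs(y_shared):
        if a == 0 or b == len(pos_y):
            continue  # terminal overhang of the partner, exo-trimmed
        anchor = genomic_to_tx.get(pos_y[a - 1])
        if anchor is None or not (lo <= anchor < hi):
            continue
        point = anchor + 1
        loops.append(Loop(point, point, b - a))
    loops.sort(key=lambda l: (l.start, l.end))

    seq = spliced_sequence(x, genome)
    sub = seq[lo : hi + 1]

    # DpnII: suppress cuts whose GATC lies fully inside an own-strand loop
    cuts = []
    for m in _DPNII.finditer(sub):
        p = lo + m.start()
        in_loop = any(l.start <= p and p + 4 <= l.end for l in loops if l.start < l.end)
        if not in_loop:
            cuts.append(p)
    bounds = [lo] + [c for c in cuts if lo < c < hi + 1] + [hi + 1]

    records = []
    for a, b in zip(bounds, bounds[1:]):
        if b <= a:
            continue
        frag_loops = tuple(
            l
            for l in loops
            if (l.start < l.end and l.start < b and a < l.end)
            or (l.start == l.end and a < l.start < b)
        )
        gpos = [pos_x[i] for i in range(a, b)]
        records.append(
            DuplexRecord(
                gene_id=gene_id,
                variant_a=x.transcript_id,
                variant_b=y.transcript_id,
                fragment=(a, b),
                loop_intervals=frag_loops,
                sequence=seq[a:b],
                chrom=x.chrom,
                genomic_start=min(gpos),
                genomic_end=max(gpos) + 1,
                weight=weight,
            )
        )
    return records


def capture_and_emit(
    duplexes: list[DuplexRecord],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Streptavidin capture, PCR duplication, read emission with errors.

    Loop-bearing fragments with a loop of >= ``min_loop_nt`` single-stranded
    nucleotides are captured with probability 1 - capture_noise; all other
    fragments with probability capture_noise.  Each captured fragment yields
    1 + Poisson(pcr_redundancy - 1) reads with per-base substitution errors
    and Gaussian Phred qualities.  Returns the reads and a truth manifest.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    reads: list[SimulatedRead] = []
    rows = []
    counter = 0
    for dup in duplexes:
        is_target = dup.loop_bearing and dup.max_loop_nt >= params.min_loop_nt
        p_capture = (1.0 - params.capture_noise) if is_target else params.capture_noise
        dup.captured = bool(rng.random() < p_capture)
        if not dup.captured:
            continue
        n_copies = 1 + int(rng.poisson(max(0.0, params.pcr_redundancy - 1.0)))
        for _ in range(n_copies):
            counter += 1
            seq = _mutate(dup.sequence, params.read_error_rate, rng)
            quals = np.clip(
                np.rint(rng.normal(params.mean_quality, params.quality_sd, len(seq))),
                2,
                40,
            ).astype(int)
            read = SimulatedRead(
                read_id=f"read{counter:06d}",
                sequence=seq,
                qualities=tuple(int(q) for q in quals),
                gene_id=dup.gene_id,
                variant_a=dup.variant_a,
                variant_b=dup.variant_b,
                chrom=dup.chrom,
                genomic_start=dup.genomic_start,
                genomic_end=dup.genomic_end,
                loop_flag=is_target,
            )
            reads.append(read)
            rows.append(
                {
                    "read_id": read.read_id,
                    "gene": read.gene_id,
                    "variant_a": read.variant_a,
                    "variant_b": read.variant_b,
                    "chrom": read.chrom,
                    "start": read.genomic_start,
                    "end": read.genomic_end,
                    "loop_flag": int(read.loop_flag),
                }
            )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "read_id", "gene", "variant_a", "variant_b",
            "chrom", "start", "end", "loop_flag",
        ],
    )
    return reads, manifest


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        options = bases[bases != arr[i]]
        arr[i] = options[rng.integers(0, len(options))]
    return arr.tobytes().decode()


def simulate_library(
    models: list[TranscriptModel],
    genome: Genome,
    params: SimulationParams,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Run the whole protocol over a variant catalogue (all genes)."""
    rng = np.random.default_rng(params.seed)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    abundances = simulate_abundances(models, params, rng)
    duplexes: list[DuplexRecord] = []
    for gene_id in sorted(by_gene):
        duplexes.extend(
            form_heteroduplexes(by_gene[gene_id], genome, abundances, params)
        )
    return capture_and_emit(duplexes, params, rng)


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)
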