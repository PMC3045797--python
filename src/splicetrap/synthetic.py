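"""Synthetic genomes and splice-variant catalogues for the simulator.

Each synthetic gene lives on its own small chromosome and carries a
reference transcript plus one alternative variant with a single planted
splicing difference (exon skipping, intron retention, or an alternative
5'/3' splice site).  All introns of both variants carry canonical GT..AG
dinucleotides (planted in the chromosome sequence, strand-aware), so the
whole catalogue passes a canonical splice-site check by construction.

Planted shift/loop sizes are kept >= 30 nt so that every planted event is a
valid heteroduplex capture target for the 25-mer annealing oligo.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_model import Genome, GenomicInterval, TranscriptModel, introns_of

EVENT_CYCLE = ("alt_5ss", "alt_3ss", "exon_skipping", "intron_retention")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one planted splicing difference."""

    gene_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    strand: str
    size: int


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _plant_site(seq: list[str], intron: GenomicInterval) -> None:
    """Write canonical splice dinucleotides for one intron, strand-aware."""
    if intron.strand == "+":
        seq[intron.start : intron.start + 2] = list("GT")
        seq[intron.end - 2 : intron.end] = list("AG")
    else:
        # transcription runs right to left: donor at the genomic end
        seq[intron.end - 2 : intron.end] = list("AC")
        seq[intron.start : intron.start + 2] = list("CT")


def synthesize_gene(
    rng: np.random.Generator,
    gene_id: str,
    event_type: str,
    n_exons: int | None = None,
    strand: str | None = None,
) -> tuple[str, list[TranscriptModel], PlantedEvent]:
    """One chromosome sequence, two splice variants, and the planted truth.

    The reference variant (``<gene>.ref``) has ``n_exons`` exons
    (default 4-7, 100-250 nt) separated by 150-600 nt introns; the
    alternative variant (``<gene>.alt``) differs by exactly one event of
    ``event_type``.
    """
    if event_type not in EVENT_CYCLE:
        raise ValueError(f"unknown event type {event_type!r}")
    if n_exons is None:
        n_exons = int(rng.integers(4, 8))
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    chrom = gene_id

    exon_lens = rng.integers(100, 251, size=n_exons)
    intron_lens = rng.integers(150, 601, size=n_exons - 1)
    margin = 100
    exons: list[GenomicInterval] = []
    pos = margin
    for i in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    chrom_len = pos + margin
    seq = list(random_sequence(rng, chrom_len))

    ref = TranscriptModel(f"{gene_id}.ref", gene_id, chrom, strand, tuple(exons))
    for intron in introns_of(ref):
        _plant_site(seq, intron)

    # choose an internal junction/exon to perturb
    if event_type == "exon_skipping":
        k = int(rng.integers(1, n_exons - 1))  # internal exon index
        alt_exons = exons[:k] + exons[k + 1 :]
        truth = PlantedEvent(
            gene_id, event_type, chrom, exons[k].start, exons[k].end, strand,
            exons[k].length,
        )
    elif event_type == "intron_retention":
        k = int(rng.integers(0, n_exons - 1))  # intron index to retain
        merged = GenomicInterval(chrom, exons[k].start, exons[k + 1].end, strand)
        alt_exons = exons[:k] + [merged] + exons[k + 2 :]
        intron = introns_of(ref)[k]
        truth = PlantedEvent(
            gene_id, event_type, chrom, intron.start, intron.end, strand,
            intron.length,
        )
    else:
        k = int(rng.integers(0, n_exons - 1))  # intron index whose boundary moves
        intron = introns_of(ref)[k]
        delta = int(rng.integers(30, min(91, intron.length - 20)))
        # decide which genomic boundary to move so that the transcription-
        # oriented label matches the requested event type
        move_start = (event_type == "alt_5ss") == (strand == "+")
        if move_start:
            # intron start shifts right: upstream exon elongates
            new_intron = GenomicInterval(chrom, intron.start + delta, intron.end, strand)
            alt_exons = (
                exons[:k]
                + [GenomicInterval(chrom, exons[k].start, intron.start + delta, strand)]
                + exons[k + 1 :]
            )
            truth = PlantedEvent(
                gene_id, event_type, chrom, intron.start, intron.start + delta,
                strand, delta,
            )
        else:
            new_intron = GenomicInterval(chrom, intron.start, intron.end - delta, strand)
            alt_exons = (
                exons[: k + 1]
                + [GenomicInterval(chrom, intron.end - delta, exons[k + 1].end, strand)]
                + exons[k + 2 :]
            )
            truth = PlantedEvent(
                gene_id, event_type, chrom, intron.end - delta, intron.end,
                strand, delta,
            )
        _plant_site(seq, new_intron)

    alt = TranscriptModel(f"{gene_id}.alt", gene_id, chrom, strand, tuple(alt_exons))
    for intron in introns_of(alt):
        _plant_site(seq, intron)
    # replanting may touch reference motifs only at shared boundaries, where
    # the motif is identical; re-assert reference sites for safety
    for intron in introns_of(ref):
        _plant_site(seq, intron)

    return "".join(seq), [ref, alt], truth


def synthesize_study(
    n_genes: int = 50, seed: int = 7
) -> tuple[Genome, list[TranscriptModel], list[PlantedEvent]]:
    """A planted-event study: one gene per chromosome, one event per gene.

    Event types cycle through the four classes so that all of them are
    represented at any ``n_genes`` >= 4.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    models: list[TranscriptModel] = []
    truths: list[PlantedEvent] = []
    for i in range(n_genes):
        gene_id = f"gene{i + 1:04d}"
        event_type = EVENT_CYCLE[i % len(EVENT_CYCLE)]
        seq, variants, truth = synthesize_gene(rng, gene_id, event_type)
        sequences[gene_id] = seq
        models.extend(variants)
        truths.append(truth)
    return Genome(sequences), models, truths


# ---------------------------------------------------------------------------
# random exon chains for classifier stress tests
# ---------------------------------------------------------------------------

def random_chain(
    rng: np.random.Generator,
    transcript_id: str = "tx",
    gene_id: str = "g",
    chrom: str = "chr1",
    strand: str = "+",
    max_exons: int = 6,
    region: int = 3000,
) -> TranscriptModel:
    """A random exon chain with up to ``max_exons`` exons."""
    n = int(rng.integers(1, max_exons + 1))
    cuts = np.sort(rng.choice(np.arange(1, region // 10), size=2 * n, replace=False)) * 10
    exons = tuple(
        GenomicInterval(chrom, int(cuts[2 * i]), int(cuts[2 * i + 1]), strand)
        for i in range(n)
    )
    return TranscriptModel(transcript_id, gene_id, chrom, strand, exons)


def perturb_chain(
    rng: np.random.Generator, model: TranscriptModel, transcript_id: str = "tx_b"
) -> TranscriptModel:
    """Apply 1-2 random structural edits to an exon chain.

    Edits: skip an internal exon, merge two exons (retain the intron), shift
    one intron boundary, or leave the chain unchanged.  Used to generate
    chain pairs that exercise every boundary relation of the event
    classifier, including boundary-sharing corner cases.
    """
    exons = list(model.exons)
    for _ in range(int(rng.integers(1, 3))):
        choice = rng.random()
        if choice < 0.25 and len(exons) >= 3:
            k = int(rng.integers(1, len(exons) - 1))
            exons.pop(k)
        elif choice < 0.5 and len(exons) >= 2:
            k = int(rng.integers(0, len(exons) - 1))
            merged = GenomicInterval(
                model.chrom, exons[k].start, exons[k + 1].end, model.strand
            )
            exons[k : k + 2] = [merged]
        elif choice < 0.9 and len(exons) >= 2:
            k = int(rng.integers(0, len(exons) - 1))
            left, right = exons[k], exons[k + 1]
            gap = right.start - left.end
            if rng.random() < 0.5:
                # move the intron's genomic-left boundary
                shift = int(rng.integers(-(left.length - 1), gap))
                exons[k] = GenomicInterval(
                    model.chrom, left.start, left.end + shift, model.strand
                )
            else:
                shift = int(rng.integers(-(gap - 1), right.length))
                exons[k + 1] = GenomicInterval(
                    model.chrom, right.start + shift, right.end, model.strand
                )
    return TranscriptModel(
        transcript_id, model.gene_id, model.chrom, model.strand, tuple(exons)
    )


def random_chain_pair(
    rng: np.random.Generator, strand: str | None = None, max_exons: int = 6
) -> tuple[TranscriptModel, TranscriptModel]:
    """A random exon chain and a structurally perturbed partner.

    The pair is guaranteed to overlap exonically (regenerated otherwise).
    """
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    while True:
        a = random_chain(rng, "tx_a", strand=strand, max_exons=max_exons)
        b = perturb_chain(rng, a)
        if any(ea.overlaps(eb) for ea in a.exons for eb in b.exons):
            return a, b
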