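"""Core genomic data types, standard-format I/O and splice-aware utilities.

Coordinates are 0-based half-open everywhere internally (BED convention);
GFF3 is converted on read/write.  "5'/3'" always refers to transcription
orientation: on the minus strand the donor of an intron sits at its genomic
*end* and the acceptor at its genomic *start*.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: canonical splice dinucleotides (donor, acceptor) in transcription orientation
CANONICAL_SPLICE = ("GT", "AG")

#: introns shorter than this cannot carry both splice dinucleotides and are
#: rejected when transcript models are loaded from disk
MIN_INTRON_NT = 4

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware ordered exon chain on one chromosome.

    Exons are stored in genomic order (sorted by start); transcription order
    on the minus strand is the reverse.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: zero-exon transcript")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: invalid strand")
        for e in exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon {e} disagrees on chrom/strand"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted and separated "
                    f"by at least 1 nt ({a.start}-{a.end} vs {b.start}-{b.end})"
                )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class Genome:
    """In-memory chromosome name -> uppercase nucleotide sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[name]), id=name, description="")
            for name in sorted(self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return seq[start:end]

    def covers(self, model: TranscriptModel) -> bool:
        return (
            model.chrom in self.sequences
            and model.span.end <= len(self.sequences[model.chrom])
        )


# ---------------------------------------------------------------------------
# splice-aware utilities
# ---------------------------------------------------------------------------

def introns_of(model: TranscriptModel) -> list[GenomicInterval]:
    """The n_exons - 1 intervals between successive exons (genomic order)."""
    return [
        GenomicInterval(model.chrom, a.end, b.start, model.strand)
        for a, b in zip(model.exons, model.exons[1:])
    ]


def donor_acceptor(intron: GenomicInterval) -> tuple[int, int]:
    """Genomic coordinates of (donor, acceptor) for an intron.

    On the plus strand the donor is the intron start and the acceptor its
    end; on the minus strand the roles swap genomically.
    """
    if intron.strand == "+":
        return intron.start, intron.end
    return intron.end, intron.start


def splice_dinucleotides(
    model: TranscriptModel, genome: Genome
) -> list[tuple[str, str]]:
    """Per intron (transcription order): donor and acceptor dinucleotides.

    Minus-strand introns are reverse-complemented so that a canonical site
    always reads ("GT", "AG").
    """
    pairs = []
    introns = introns_of(model)
    if model.strand == "-":
        introns = introns[::-1]
    for intron in introns:
        if intron.length < MIN_INTRON_NT:
            raise ValueError(
                f"{model.transcript_id}: intron {intron.start}-{intron.end} "
                f"shorter than {MIN_INTRON_NT} nt cannot carry splice sites"
            )
        left = genome.fetch(model.chrom, intron.start, intron.start + 2)
        right = genome.fetch(model.chrom, intron.end - 2, intron.end)
        if model.strand == "+":
            pairs.append((left, right))
        else:
            pairs.append((reverse_complement(right), reverse_complement(left)))
    return pairs


def is_canonical(donor: str, acceptor: str) -> bool:
    return (donor, acceptor) == CANONICAL_SPLICE


def spliced_sequence(model: TranscriptModel, genome: Genome) -> str:
    """Exon sequences concatenated in transcription order (mRNA sense)."""
    seq = "".join(genome.fetch(model.chrom, e.start, e.end) for e in model.exons)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq


def transcript_positions(model: TranscriptModel) -> list[int]:
    """Genomic position of every transcript base, in transcription order."""
    pos: list[int] = []
    for e in model.exons:
        pos.extend(range(e.start, e.end))
    if model.strand == "-":
        pos.reverse()
    return pos


def genomic_blocks(
    model: TranscriptModel, tstart: int, tend: int
) -> list[GenomicInterval]:
    """Genomic intervals covered by transcript coordinates [tstart, tend)."""
    if not (0 <= tstart < tend <= model.length):
        raise ValueError(
            f"transcript range {tstart}-{tend} outside 0-{model.length}"
        )
    positions = sorted(transcript_positions(model)[tstart:tend])
    blocks: list[GenomicInterval] = []
    run_start = prev = positions[0]
    for p in positions[1:]:
        if p != prev + 1:
            blocks.append(GenomicInterval(model.chrom, run_start, prev + 1, model.strand))
            run_start = p
        prev = p
    blocks.append(GenomicInterval(model.chrom, run_start, prev + 1, model.strand))
    return blocks


def transcript_coord_of(model: TranscriptModel, genomic_pos: int) -> int | None:
    """Transcript coordinate of a genomic position, or None if intronic."""
    offset = 0
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    for e in exons:
        if e.start <= genomic_pos < e.end:
            if model.strand == "+":
                return offset + (genomic_pos - e.start)
            return offset + (e.end - 1 - genomic_pos)
        offset += e.length
    return None


# ---------------------------------------------------------------------------
# transcript model I/O (BED12, GFF3)
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return "bed12"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    raise ValueError(f"cannot infer transcript model format from {path}")


def _split_name(name: str) -> tuple[str, str]:
    # BED12 has no gene column; the writer encodes "gene|transcript" when the
    # two differ, plain transcript ids otherwise.
    if "|" in name:
        gene, tx = name.split("|", 1)
        return gene, tx
    return name, name


def _check_introns(model: TranscriptModel, where: str) -> TranscriptModel:
    for intron in introns_of(model):
        if intron.length < MIN_INTRON_NT:
            raise ValueError(
                f"{where}: transcript {model.transcript_id} has an intron of "
                f"{intron.length} nt (< {MIN_INTRON_NT}); rejected"
            )
    return model


def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    fields = line.split()
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: BED12 requires 12 fields, got {len(fields)}")
    try:
        chrom = fields[0]
        start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed BED12 record: {exc}") from exc
    if block_count < 1:
        raise ValueError(f"line {lineno}: zero-exon transcript {name}")
    if len(sizes) != block_count or len(starts) != block_count:
        raise ValueError(f"line {lineno}: blockCount disagrees with block lists")
    gene_id, transcript_id = _split_name(name)
    exons = tuple(
        GenomicInterval(chrom, start + bs, start + bs + sz, strand)
        for bs, sz in zip(starts, sizes)
    )
    return TranscriptModel(transcript_id, gene_id, chrom, strand, exons)


def read_transcript_models(
    path: str | Path, format: str | None = None
) -> list[TranscriptModel]:
    """Read transcript models from BED12 or GFF3.

    BED12 blockStarts/blockSizes are converted to absolute 0-based half-open
    exon intervals; GFF3 exons are grouped by their transcript parent and
    sorted.  Transcripts with introns shorter than 4 nt are rejected.
    """
    fmt = format or _infer_format(path)
    if fmt == "bed12":
        models = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                models.append(_check_introns(_parse_bed12_line(line, lineno), str(path)))
        return models
    if fmt == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown transcript model format {fmt!r}")


def _read_gff3(path: str | Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        force=True,
    )
    models = []
    tx_types = [t for t in ("mRNA", "transcript") if t in set(db.featuretypes())]
    for tx_type in tx_types:
        for tx in db.features_of_type(tx_type, order_by="start"):
            gene_id = tx.attributes.get("Parent", [tx.id])[0]
            exons = sorted(
                db.children(tx, featuretype="exon"), key=lambda f: f.start
            )
            if not exons:
                raise ValueError(f"{path}: transcript {tx.id} has zero exons")
            intervals = tuple(
                GenomicInterval(tx.seqid, e.start - 1, e.end, tx.strand)
                for e in exons
            )
            models.append(
                _check_introns(
                    TranscriptModel(tx.id, gene_id, tx.seqid, tx.strand, intervals),
                    str(path),
                )
            )
    models.sort(key=lambda m: (m.chrom, m.span.start, m.transcript_id))
    return models


def write_transcript_models(
    models: Sequence[TranscriptModel], path: str | Path, format: str | None = None
) -> None:
    """Write models as BED12 or GFF3, deterministically sorted."""
    fmt = format or _infer_format(path)
    ordered = sorted(models, key=lambda m: (m.chrom, m.span.start, m.transcript_id))
    if fmt == "bed12":
        with open(path, "w") as fh:
            for m in ordered:
                span = m.span
                name = (
                    m.transcript_id
                    if m.gene_id == m.transcript_id
                    else f"{m.gene_id}|{m.transcript_id}"
                )
                sizes = ",".join(str(e.length) for e in m.exons)
                starts = ",".join(str(e.start - span.start) for e in m.exons)
                fh.write(
                    "\t".join(
                        [
                            m.chrom,
                            str(span.start),
                            str(span.end),
                            name,
                            "0",
                            m.strand,
                            str(span.start),
                            str(span.end),
                            "0",
                            str(m.n_exons),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            genes: dict[str, list[TranscriptModel]] = {}
            for m in ordered:
                genes.setdefault(m.gene_id, []).append(m)
            for gene_id in sorted(genes):
                members = genes[gene_id]
                gstart = min(m.span.start for m in members)
                gend = max(m.span.end for m in members)
                chrom, strand = members[0].chrom, members[0].strand
                fh.write(
                    f"{chrom}\tsplicetrap\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t"
                    f"ID={gene_id}\n"
                )
                for m in members:
                    fh.write(
                        f"{m.chrom}\tsplicetrap\tmRNA\t{m.span.start + 1}\t{m.span.end}"
                        f"\t.\t{m.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n"
                    )
                    for i, e in enumerate(m.exons, start=1):
                        fh.write(
                            f"{m.chrom}\tsplicetrap\texon\t{e.start + 1}\t{e.end}\t.\t"
                            f"{m.strand}\t.\tID={m.transcript_id}.exon{i};"
                            f"Parent={m.transcript_id}\n"
                        )
    else:
        raise ValueError(f"unknown transcript model format {fmt!r}")
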