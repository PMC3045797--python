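"""Coding consequence of a splice variant: stop scan, PTC distance, NMD.

A premature termination codon (PTC) lying more than 50 nt upstream of the
last exon-exon junction marks the transcript as a nonsense-mediated decay
(NMD) candidate (the canonical 50-nt rule; strict inequality, tunable).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genomic_model import (
    Genome,
    TranscriptModel,
    spliced_sequence,
    transcript_coord_of,
    transcript_positions,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NMD_RULE_NT = 50


@dataclass
class CodingAnnotation:
    transcript_id: str
    start_codon: int
    stop: int | None  # transcript coordinate of the stop codon start
    ptc_distance: int | None  # nt from stop end to the last junction
    nmd_candidate: bool


def find_stop(
    model: TranscriptModel, genome: Genome, start_codon: int
) -> int | None:
    """Transcript coordinate of the first in-frame stop codon, or None.

    ``start_codon`` is the 0-based transcript coordinate of an ATG.
    """
    seq = spliced_sequence(model, genome)
    if start_codon < 0 or start_codon >= len(seq):
        raise ValueError("start codon outside the transcript")
    if seq[start_codon : start_codon + 3] != "ATG":
        raise ValueError(
            f"{model.transcript_id}: no ATG at transcript position {start_codon}"
        )
    for p in range(start_codon, len(seq) - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            return p
    return None


def last_junction(model: TranscriptModel) -> int:
    """Transcript coordinate of the final exon-exon junction."""
    if model.n_exons < 2:
        raise ValueError(f"{model.transcript_id}: single-exon transcript has no junction")
    final_exon = model.exons[-1] if model.strand == "+" else model.exons[0]
    return model.length - final_exon.length


def ptc_distance(stop: int, model: TranscriptModel) -> int:
    """Distance (nt) from the end of the stop codon to the last junction.

    Positive values mean the stop lies upstream of the junction; negative
    values mean it falls in the final exon.
    """
    if model.n_exons < 2:
        raise ValueError(
            f"{model.transcript_id}: PTC distance undefined for single-exon transcripts"
        )
    return last_junction(model) - (stop + 3)


def nmd_candidate(distance: int, rule_nt: int = NMD_RULE_NT) -> bool:
    """The 50-nt rule: a stop > ``rule_nt`` nt upstream of the last junction."""
    return distance > rule_nt


def project_transcript_coord(
    source: TranscriptModel, coord: int, target: TranscriptModel
) -> int | None:
    """Map a transcript coordinate of one variant onto another via the genome.

    Returns None when the underlying genomic base is absent from the target
    (e.g. a start codon inside a skipped exon).
    """
    positions = transcript_positions(source)
    if not 0 <= coord < len(positions):
        raise ValueError("coordinate outside the source transcript")
    return transcript_coord_of(target, positions[coord])


def characterize(
    model: TranscriptModel,
    genome: Genome,
    start_codon: int,
    rule_nt: int = NMD_RULE_NT,
) -> CodingAnnotation:
    stop = find_stop(model, genome, start_codon)
    if stop is None or model.n_exons < 2:
        return CodingAnnotation(model.transcript_id, start_codon, stop, None, False)
    dist = ptc_distance(stop, model)
    return CodingAnnotation(
        model.transcript_id, start_codon, stop, dist, nmd_candidate(dist, rule_nt)
    )


def annotation_table(annotations: list[CodingAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": a.transcript_id,
                "start_codon": a.start_codon,
                "stop": -1 if a.stop is None else a.stop,
                "ptc_distance": "" if a.ptc_distance is None else a.ptc_distance,
                "nmd_candidate": int(a.nmd_candidate),
            }
            for a in annotations
        ],
        columns=["transcript_id", "start_codon", "stop", "ptc_distance", "nmd_candidate"],
    )
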