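"""Spliced-alignment ingestion, identity/coverage filtering and profiles.

Alignments of consensus sequences (ASSETs) are consumed from standard
formats (PSL, or BED12 chains plus a metrics sidecar) rather than computed
here.  Identity is matches over aligned query bases (query gaps excluded,
the PSL convention); coverage is aligned query bases over the full query
length.  The retained set uses the inclusive thresholds identity >= 93%
and coverage >= 55%.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_model import GenomicInterval, TranscriptModel, read_transcript_models

MIN_IDENTITY_PCT = 93.0
MIN_COVERAGE_PCT = 55.0


@dataclass
class AlignedAsset:
    """A consensus sequence with its best-hit spliced alignment."""

    asset_id: str
    chain: TranscriptModel
    matches: int
    aligned_length: int
    query_length: int

    def __post_init__(self) -> None:
        if not 0 < self.aligned_length:
            raise ValueError(f"{self.asset_id}: empty alignment")
        if self.matches > self.aligned_length:
            raise ValueError(f"{self.asset_id}: matches exceed aligned length")
        if self.aligned_length > self.query_length:
            raise ValueError(f"{self.asset_id}: aligned length exceeds query length")

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_length

    @property
    def coverage(self) -> float:
        return 100.0 * self.aligned_length / self.query_length

    @property
    def n_exons(self) -> int:
        return self.chain.n_exons


# ---------------------------------------------------------------------------
# input formats
# ---------------------------------------------------------------------------

def _merge_blocks(
    chrom: str, strand: str, starts: list[int], sizes: list[int]
) -> tuple[GenomicInterval, ...]:
    """Alignment blocks -> exon chain; target-adjacent blocks merged."""
    blocks: list[list[int]] = []
    for s, z in sorted(zip(starts, sizes)):
        if blocks and s <= blocks[-1][1]:
            blocks[-1][1] = max(blocks[-1][1], s + z)
        else:
            blocks.append([s, s + z])
    return tuple(GenomicInterval(chrom, a, b, strand) for a, b in blocks)


def _parse_psl_line(line: str, lineno: int) -> AlignedAsset:
    f = line.split("\t")
    if len(f) < 21:
        raise ValueError(f"line {lineno}: PSL requires 21 fields, got {len(f)}")
    try:
        matches, mismatches, rep, ncount = (int(x) for x in f[0:4])
        strand = f[8][0]
        qname, qsize = f[9], int(f[10])
        tname = f[13]
        sizes = [int(x) for x in f[18].rstrip(",").split(",")]
        tstarts = [int(x) for x in f[20].rstrip(",").split(",")]
    except (ValueError, IndexError) as exc:
        raise ValueError(f"line {lineno}: malformed PSL record: {exc}") from exc
    chain = TranscriptModel(
        qname, qname, tname, strand, _merge_blocks(tname, strand, tstarts, sizes)
    )
    aligned = matches + mismatches + rep + ncount
    return AlignedAsset(qname, chain, matches, aligned, qsize)


def read_alignments(
    path: str | Path, format: str = "psl", metrics_path: str | Path | None = None
) -> list[AlignedAsset]:
    """Read alignments from PSL, or BED12 plus a metrics TSV.

    The metrics sidecar (required for BED12) is a TSV with columns
    asset_id, matches, aligned_length, query_length.
    """
    if format == "psl":
        assets = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or not line[0].isdigit():
                    continue  # psLayout headers / separators
                assets.append(_parse_psl_line(line.rstrip("\n"), lineno))
        return assets
    if format == "bed12":
        if metrics_path is None:
            raise ValueError("BED12 alignments require a metrics table")
        chains = read_transcript_models(path, "bed12")
        metrics = pd.read_csv(metrics_path, sep="\t").set_index("asset_id")
        assets = []
        for chain in chains:
            if chain.transcript_id not in metrics.index:
                raise ValueError(f"metrics missing for asset {chain.transcript_id}")
            row = metrics.loc[chain.transcript_id]
            assets.append(
                AlignedAsset(
                    chain.transcript_id,
                    chain,
                    int(row["matches"]),
                    int(row["aligned_length"]),
                    int(row["query_length"]),
                )
            )
        return assets
    raise ValueError(f"unknown alignment format {format!r}")


def write_psl(assets: list[AlignedAsset], path: str | Path) -> None:
    """Emit assets as standard 21-column PSL (deterministic order)."""
    with open(path, "w") as fh:
        for a in sorted(assets, key=lambda a: a.asset_id):
            chain = a.chain
            sizes = [e.length for e in chain.exons]
            tstarts = [e.start for e in chain.exons]
            qstarts = np.cumsum([0] + sizes[:-1]).tolist()
            span = chain.span
            fields = [
                a.matches,
                a.aligned_length - a.matches,
                0,
                0,
                0,
                max(0, a.query_length - a.aligned_length),
                0,
                sum(
                    b.start - x.end for x, b in zip(chain.exons, chain.exons[1:])
                ),
                chain.strand,
                a.asset_id,
                a.query_length,
                0,
                a.aligned_length,
                chain.chrom,
                span.end,
                span.start,
                span.end,
                len(sizes),
                ",".join(map(str, sizes)) + ",",
                ",".join(map(str, qstarts)) + ",",
                ",".join(map(str, tstarts)) + ",",
            ]
            fh.write("\t".join(str(x) for x in fields) + "\n")


# ---------------------------------------------------------------------------
# selection and filtering
# ---------------------------------------------------------------------------

def best_hit(alignments: list[AlignedAsset]) -> AlignedAsset:
    """Best alignment of one asset: maximal (matches, identity, coverage),
    ties broken by (chrom, start)."""
    if not alignments:
        raise ValueError("best_hit of an empty alignment list")
    return sorted(
        alignments,
        key=lambda a: (
            -a.matches,
            -a.identity,
            -a.coverage,
            a.chain.chrom,
            a.chain.span.start,
        ),
    )[0]


def filter_alignments(
    assets: list[AlignedAsset],
    min_identity: float = MIN_IDENTITY_PCT,
    min_coverage: float = MIN_COVERAGE_PCT,
) -> list[AlignedAsset]:
    """Keep assets with identity and coverage at or above the thresholds."""
    return [
        a
        for a in assets
        if a.identity >= min_identity and a.coverage >= min_coverage
    ]


def classify_exon_count(asset: AlignedAsset) -> str:
    return "multi_exon" if asset.n_exons >= 2 else "intronless"


def relative_position_profile(
    placements: list[tuple[int, int, int]]
) -> np.ndarray:
    """Counts of assets covering each relative transcript percentile.

    Each placement is (start, end, transcript_length) in transcript
    coordinates (transcription orientation; 0 = 5' end).  Positions are
    rescaled to 0..100 and the returned array of 101 counts gives, per
    integer percentile, the number of assets covering it.
    """
    profile = np.zeros(101, dtype=int)
    for start, end, length in placements:
        if not (0 <= start < end <= length):
            raise ValueError(
                f"asset interval {start}-{end} outside transcript of {length} nt"
            )
        p0 = int(round(100.0 * start / length))
        p1 = int(round(100.0 * end / length))
        profile[p0 : p1 + 1] += 1
    return profile
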