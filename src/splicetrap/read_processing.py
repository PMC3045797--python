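"""Sequence cleaning and consensus clustering of library reads.

Quality control keeps, per read, the longest run of 20-nt windows in which
at least 15 bases reach Phred 20.  Clustering is a deterministic greedy
overlap-consensus procedure standing in for an assembler treated as a black
box by the protocol: reads are seeded longest-first and join a cluster when
their best ungapped overlap against the running consensus is long and clean
enough; consensi are per-column majority votes.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._util import round_half_away


@dataclass
class QCParams:
    window: int = 20
    min_good: int = 15
    min_quality: int = 20
    min_length: int = 50

    def __post_init__(self) -> None:
        if self.min_good > self.window:
            raise ValueError("min_good cannot exceed the window size")


@dataclass
class Read:
    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None


@dataclass
class Cluster:
    cluster_id: str
    members: tuple[str, ...]
    consensus: str

    @property
    def kind(self) -> str:
        return "contig" if len(self.members) >= 2 else "singlet"


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(rec.id, str(rec.seq).upper(),
                 tuple(rec.letter_annotations["phred_quality"]))
        )
    return reads


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def _longest_end_match(read: str, vector: str, per_nt: int, from_start: bool) -> int:
    """Longest read prefix (or suffix) matching somewhere in the vector,
    allowing one mismatch per ``per_nt`` matched nucleotides."""
    target = read if from_start else read[::-1]
    vec = vector if from_start else vector[::-1]
    best = 0
    for p in range(len(vec)):
        mismatches = 0
        limit = min(len(target), len(vec) - p)
        for i in range(limit):
            if target[i] != vec[p + i]:
                mismatches += 1
            if mismatches <= (i + 1) // per_nt:
                best = max(best, i + 1)
        if best == len(target):
            break
    return best


def trim_vector(
    read: Read, vector_sequence: str, min_match: int = 12, per_nt: int = 20
) -> Read:
    """Remove maximal vector-matching prefix/suffix from a read.

    Matches shorter than ``min_match`` nt are ignored (chance matches);
    within a match one mismatch is tolerated per ``per_nt`` nt.  A read that
    is entirely vector becomes empty (dropped downstream).
    """
    seq = read.sequence
    quals = read.qualities
    pre = _longest_end_match(seq, vector_sequence, per_nt, from_start=True)
    if pre >= min_match:
        seq = seq[pre:]
        quals = quals[pre:] if quals is not None else None
    suf = _longest_end_match(seq, vector_sequence, per_nt, from_start=False)
    if suf >= min_match:
        seq = seq[: len(seq) - suf]
        quals = quals[: len(seq)] if quals is not None else None
    return replace(read, sequence=seq, qualities=quals)


def trim_quality(read: Read, params: QCParams | None = None) -> Read | None:
    """Keep the longest run of consecutive good quality windows.

    Windows of ``params.window`` nt advance by 1 nt; a window is good when
    it holds at least ``params.min_good`` bases of Phred >= ``min_quality``.
    Returns None when the surviving read is shorter than ``min_length``.
    """
    params = params or QCParams()
    if read.qualities is None:
        raise ValueError(f"{read.read_id}: quality trimming requires qualities")
    q = np.asarray(read.qualities)
    w = params.window
    if len(q) < w:
        return None
    ok = (q >= params.min_quality).astype(int)
    counts = np.convolve(ok, np.ones(w, dtype=int), mode="valid")
    good = counts >= params.min_good
    # longest run of consecutive good windows (first on ties)
    best_len = best_start = 0
    run_start = None
    for i, g in enumerate(np.append(good, False)):
        if g and run_start is None:
            run_start = i
        elif not g and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len == 0:
        return None
    start, end = best_start, best_start + best_len - 1 + w
    if end - start < params.min_length:
        return None
    return replace(
        read,
        sequence=read.sequence[start:end],
        qualities=tuple(read.qualities[start:end]),
    )


def qc_reads(
    reads: list[Read],
    params: QCParams | None = None,
    vector_sequence: str | None = None,
) -> list[Read]:
    """Vector + quality trimming over a read set; short reads dropped."""
    params = params or QCParams()
    out = []
    for r in reads:
        if vector_sequence:
            r = trim_vector(r, vector_sequence)
        trimmed = trim_quality(r, params)
        if trimmed is not None and len(trimmed.sequence) >= params.min_length:
            out.append(trimmed)
    return out


# ---------------------------------------------------------------------------
# greedy overlap clustering
# ---------------------------------------------------------------------------

_KMER = 15


class _Building:
    __slots__ = ("members", "consensus", "index")

    def __init__(self, read: Read) -> None:
        self.members: list[tuple[Read, int]] = [(read, 0)]
        self.consensus = read.sequence
        self._reindex()

    def _reindex(self) -> None:
        index: dict[str, list[int]] = {}
        cons = self.consensus
        for i in range(0, len(cons) - _KMER + 1):
            index.setdefault(cons[i : i + _KMER], []).append(i)
        self.index = index

    def candidate_offsets(self, seq: str, top: int = 3) -> list[int]:
        votes: Counter[int] = Counter()
        for i in range(0, len(seq) - _KMER + 1, 7):
            for p in self.index.get(seq[i : i + _KMER], ()):
                votes[p - i] += 1
        return [off for off, _ in votes.most_common(top)]

    def score_overlap(self, seq: str, off: int) -> tuple[int, float] | None:
        cons = self.consensus
        a = max(0, -off)
        b = min(len(seq), len(cons) - off)
        ov = b - a
        if ov <= 0:
            return None
        matches = sum(1 for t in range(a, b) if seq[t] == cons[t + off])
        return ov, matches / ov

    def add(self, read: Read, off: int) -> None:
        self.members.append((read, off))
        shift = min(o for _, o in self.members)
        if shift < 0:
            self.members = [(r, o - shift) for r, o in self.members]
        length = max(o + len(r.sequence) for r, o in self.members)
        columns: list[Counter[str]] = [Counter() for _ in range(length)]
        for r, o in self.members:
            for i, base in enumerate(r.sequence):
                columns[o + i][base] += 1
        # majority, ties toward the lexicographically smallest base
        self.consensus = "".join(
            min(sorted(c), key=lambda b: (-c[b], b)) for c in columns
        )
        self._reindex()


def cluster_reads(
    reads: list[Read], min_overlap: int = 40, min_identity: float = 0.95
) -> list[Cluster]:
    """Greedy agglomeration of reads into contigs and singlets.

    Seeds are processed longest-first (read id breaking ties); a read joins
    the cluster offering the best (identity, overlap) among ungapped
    overlaps of >= ``min_overlap`` nt at >= ``min_identity``.  Deterministic
    for a given read set.
    """
    if not reads:
        return []
    order = sorted(reads, key=lambda r: (-len(r.sequence), r.read_id))
    building: list[_Building] = []
    for read in order:
        best: tuple[float, int, int, int] | None = None  # ident, ov, -ci, off
        for ci, cl in enumerate(building):
            for off in cl.candidate_offsets(read.sequence):
                scored = cl.score_overlap(read.sequence, off)
                if scored is None:
                    continue
                ov, ident = scored
                if ov < min_overlap or ident < min_identity:
                    continue
                key = (ident, ov, -ci, off)
                if best is None or key > best:
                    best = key
        if best is None:
            building.append(_Building(read))
        else:
            _, _, neg_ci, off = best
            building[-neg_ci].add(read, off)
    clusters = []
    for n, cl in enumerate(building, start=1):
        clusters.append(
            Cluster(
                cluster_id=f"cl{n:05d}",
                members=tuple(r.read_id for r, _ in cl.members),
                consensus=cl.consensus,
            )
        )
    return clusters


def redundancy(n_reads: int, n_consensus: int) -> float:
    """Percent of sequencing effort spent on duplicate molecules.

    100 * (n_reads - n_consensus) / n_reads, reported to two decimals.
    """
    if n_reads <= 0:
        raise ValueError("redundancy undefined for zero reads")
    if n_consensus > n_reads:
        raise ValueError("more consensus sequences than reads")
    return round_half_away(100.0 * (n_reads - n_consensus) / n_reads, 2)


def library_summary(library: str, n_reads: int, clusters: list[Cluster]) -> dict:
    n_contigs = sum(1 for c in clusters if c.kind == "contig")
    n_singlets = len(clusters) - n_contigs
    return {
        "library": library,
        "n_reads": n_reads,
        "n_contigs": n_contigs,
        "n_singlets": n_singlets,
        "n_consensus": len(clusters),
        "redundancy_pct": redundancy(n_reads, len(clusters)) if n_reads else 0.0,
    }
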