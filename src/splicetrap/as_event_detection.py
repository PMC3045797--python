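"""Alternative-splicing event detection and classification.

ASSETs are clustered with reference transcripts by exonic genomic overlap
(single linkage, same strand).  Within each cluster, exon/intron boundaries
of an ASSET chain and a reference chain are compared pairwise inside the
window delimited by their two outermost exonic overlaps, and differences
are classified into four event types:

* ``alt_5ss``   -- two introns share the acceptor but differ at the donor;
* ``alt_3ss``   -- two introns share the donor but differ at the acceptor;
* ``intron_retention`` -- an intron of one chain lies within one exon of
  the other;
* ``exon_skipping`` -- one or more complete exons of one chain lie strictly
  inside a single intron of the other whose boundaries match the flanking
  introns' outer boundaries.

Donor/acceptor roles follow transcription orientation, so labels are
strand-correct.  Intron pairs explained by an exon-skipping event are not
additionally reported as alternative-site events.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import percent, round_half_away
from .alignment_filter import AlignedAsset
from .genomic_model import (
    GenomicInterval,
    TranscriptModel,
    donor_acceptor,
    introns_of,
)

EVENT_TYPES = ("exon_skipping", "intron_retention", "alt_5ss", "alt_3ss")


@dataclass(frozen=True)
class ASEvent:
    """One classified splicing difference between two exon chains."""

    event_type: str
    chrom: str
    start: int
    end: int
    strand: str
    size: int
    gene_id: str = ""
    asset_id: str = ""
    reference_id: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.size < 1:
            raise ValueError("event size must be >= 1 nt")

    @property
    def coords(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.event_type, self.chrom, self.start, self.end)


@dataclass
class AssetCluster:
    """Assets and reference transcripts linked by exonic genomic overlap."""

    cluster_id: str
    assets: list[AlignedAsset]
    references: list[TranscriptModel]
    gene_id: str
    span: GenomicInterval

    @property
    def has_reference(self) -> bool:
        return bool(self.references)


# ---------------------------------------------------------------------------
# clustering with references
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_with_references(
    assets: list[AlignedAsset], references: list[TranscriptModel]
) -> list[AssetCluster]:
    """Single-linkage clustering by >= 1 nt exonic overlap, same strand.

    Every returned cluster contains at least one asset; reference-only
    components are dropped.
    """
    chains: list[TranscriptModel] = [a.chain for a in assets] + list(references)
    uf = _UnionFind(len(chains))
    # sweep exons per (chrom, strand); overlapping exons link their chains
    exon_list = [
        (e.chrom, e.strand, e.start, e.end, node)
        for node, chain in enumerate(chains)
        for e in chain.exons
    ]
    exon_list.sort()
    active_end = None
    active_node = None
    last_key = None
    for chrom, strand, start, end, node in exon_list:
        key = (chrom, strand)
        if key != last_key or start >= active_end:
            active_end, active_node = end, node
            last_key = key
        else:
            uf.union(active_node, node)
            active_end = max(active_end, end)
    groups: dict[int, list[int]] = {}
    for node in range(len(chains)):
        groups.setdefault(uf.find(node), []).append(node)
    clusters = []
    n = 0
    for root in sorted(groups):
        members = groups[root]
        member_assets = [assets[i] for i in members if i < len(assets)]
        member_refs = [chains[i] for i in members if i >= len(assets)]
        if not member_assets:
            continue
        n += 1
        start = min(chains[i].span.start for i in members)
        end = max(chains[i].span.end for i in members)
        chain0 = chains[members[0]]
        gene_ids = sorted({r.gene_id for r in member_refs}) or sorted(
            {a.chain.gene_id for a in member_assets}
        )
        clusters.append(
            AssetCluster(
                cluster_id=f"asc{n:04d}",
                assets=member_assets,
                references=member_refs,
                gene_id=",".join(gene_ids),
                span=GenomicInterval(chain0.chrom, start, end, chain0.strand),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# pairwise classification
# ---------------------------------------------------------------------------

def comparison_window(
    chain_a: TranscriptModel, chain_b: TranscriptModel
) -> GenomicInterval:
    """Region delimited by the two outermost exonic overlaps of two chains."""
    if chain_a.chrom != chain_b.chrom or chain_a.strand != chain_b.strand:
        raise ValueError("comparison window requires same chromosome and strand")
    starts, ends = [], []
    for ea in chain_a.exons:
        for eb in chain_b.exons:
            lo, hi = max(ea.start, eb.start), min(ea.end, eb.end)
            if lo < hi:
                starts.append(lo)
                ends.append(hi)
    if not starts:
        raise ValueError("chains share no exonic overlap")
    return GenomicInterval(chain_a.chrom, min(starts), max(ends), chain_a.strand)


def _within(intron: GenomicInterval, window: GenomicInterval) -> bool:
    return window.start <= intron.start and intron.end <= window.end


def classify_events(
    chain_a: TranscriptModel,
    chain_b: TranscriptModel,
    window: GenomicInterval | None = None,
    dedup: bool = True,
) -> list[ASEvent]:
    """Classify the splicing differences between two exon chains.

    Only introns lying entirely inside the comparison window are compared.
    The output is symmetric in the two chains.
    """
    if chain_a.chrom != chain_b.chrom or chain_a.strand != chain_b.strand:
        raise ValueError("cannot classify chains on different chromosome/strand")
    if window is None:
        window = comparison_window(chain_a, chain_b)
    chrom, strand = chain_a.chrom, chain_a.strand
    introns_a = [i for i in introns_of(chain_a) if _within(i, window)]
    introns_b = [i for i in introns_of(chain_b) if _within(i, window)]

    events: list[ASEvent] = []
    suppressed: set[tuple[tuple[int, int], tuple[int, int]]] = set()

    # exon skipping (both directions)
    for host_introns, exon_chain, host_is_a in (
        (introns_a, chain_b, True),
        (introns_b, chain_a, False),
    ):
        for host in host_introns:
            inside = [
                e
                for e in exon_chain.exons
                if host.start < e.start and e.end < host.end
            ]
            if not inside:
                continue
            flank_left = any(e.end == host.start for e in exon_chain.exons)
            flank_right = any(e.start == host.end for e in exon_chain.exons)
            if not (flank_left and flank_right):
                continue
            events.append(
                ASEvent(
                    "exon_skipping",
                    chrom,
                    inside[0].start,
                    inside[-1].end,
                    strand,
                    sum(e.length for e in inside),
                )
            )
            host_key = (host.start, host.end)
            for partner_key in (
                (host.start, inside[0].start),
                (inside[-1].end, host.end),
            ):
                pair = (
                    (host_key, partner_key) if host_is_a else (partner_key, host_key)
                )
                suppressed.add(pair)

    # intron retention (both directions)
    for host_introns, exon_chain in ((introns_a, chain_b), (introns_b, chain_a)):
        for intron in host_introns:
            if any(
                e.start <= intron.start and intron.end <= e.end
                for e in exon_chain.exons
            ):
                events.append(
                    ASEvent(
                        "intron_retention",
                        chrom,
                        intron.start,
                        intron.end,
                        strand,
                        intron.length,
                    )
                )

    # alternative 5'/3' splice sites
    for ia in introns_a:
        for ib in introns_b:
            if (ia.start, ia.end) == (ib.start, ib.end):
                continue
            if ((ia.start, ia.end), (ib.start, ib.end)) in suppressed:
                continue
            da, aa = donor_acceptor(ia)
            db, ab = donor_acceptor(ib)
            if aa == ab and da != db:
                events.append(
                    ASEvent(
                        "alt_5ss", chrom, min(da, db), max(da, db), strand,
                        abs(da - db),
                    )
                )
            elif da == db and aa != ab:
                events.append(
                    ASEvent(
                        "alt_3ss", chrom, min(aa, ab), max(aa, ab), strand,
                        abs(aa - ab),
                    )
                )

    if dedup:
        seen = set()
        unique = []
        for ev in events:
            if ev.key not in seen:
                seen.add(ev.key)
                unique.append(ev)
        events = unique
    return sorted(events, key=lambda e: (e.start, e.end, e.event_type))


def detect_cluster_events(
    cluster: AssetCluster, dedup: bool = True
) -> list[ASEvent]:
    """Classify every multi-exon asset against every overlapping reference.

    Events are annotated with gene/asset/reference ids and, when ``dedup``
    is set, de-duplicated by (type, coordinates) within the cluster.
    """
    events: list[ASEvent] = []
    seen: set[tuple[str, str, int, int]] = set()
    for asset in cluster.assets:
        if asset.n_exons < 2:
            continue
        for ref in cluster.references:
            if asset.chain.transcript_id == ref.transcript_id:
                continue
            try:
                window = comparison_window(asset.chain, ref)
            except ValueError:
                continue
            for ev in classify_events(asset.chain, ref, window, dedup=True):
                if dedup and ev.key in seen:
                    continue
                seen.add(ev.key)
                events.append(
                    ASEvent(
                        ev.event_type,
                        ev.chrom,
                        ev.start,
                        ev.end,
                        ev.strand,
                        ev.size,
                        gene_id=cluster.gene_id,
                        asset_id=asset.asset_id,
                        reference_id=ref.transcript_id,
                    )
                )
    return events


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_events(events: list[ASEvent]) -> dict:
    """Counts and one-decimal percentages by type, plus per-asset counts."""
    counts = {t: 0 for t in EVENT_TYPES}
    per_asset: dict[str, int] = {}
    for ev in events:
        counts[ev.event_type] += 1
        if ev.asset_id:
            per_asset[ev.asset_id] = per_asset.get(ev.asset_id, 0) + 1
    total = len(events)
    percentages = {
        t: (percent(c, total, 1) if total else 0.0) for t, c in counts.items()
    }
    return {
        "total": total,
        "counts": counts,
        "percentages": percentages,
        "per_asset": per_asset,
        "assets_with_events": len(per_asset),
    }


def events_table(events: list[ASEvent]) -> pd.DataFrame:
    rows = [
        {
            "chrom": e.chrom,
            "start": e.start,
            "end": e.end,
            "name": f"{e.event_type}:{e.asset_id}:{e.reference_id}",
            "score": e.size,
            "strand": e.strand,
            "event_type": e.event_type,
            "gene_id": e.gene_id,
        }
        for e in sorted(events, key=lambda e: (e.chrom, e.start, e.end, e.event_type))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "event_type", "gene_id",
        ],
    )


def flag_intronless_overlap(
    intronless_spans: list[GenomicInterval],
    event_coords: list[GenomicInterval],
) -> tuple[int, int, float]:
    """Fraction of intronless assets intersecting any known AS event region.

    Intronless alignments carry no strand information, so the intersection
    is strand-agnostic.  Returns (n_overlapping, n_total, one-decimal %).
    """
    n_hit = 0
    for span in intronless_spans:
        if any(
            span.chrom == ev.chrom and span.start < ev.end and ev.start < span.end
            for ev in event_coords
        ):
            n_hit += 1
    total = len(intronless_spans)
    pct = percent(n_hit, total, 1) if total else 0.0
    return n_hit, total, pct
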