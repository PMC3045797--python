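"""End-to-end orchestration: simulate -> QC -> cluster -> align -> events.

The pipeline consumes either simulator output (with its truth manifest) or
user-supplied reads and alignments.  Genome-scale spliced alignment is out
of scope: simulated consensi are placed by infix edit-distance alignment
(edlib) against the spliced sequences of their gene's variants, with the
candidate gene short-listed from the truth manifest; coordinates, identity
and coverage are computed from that alignment.  All randomness flows from
the single configured seed, and all outputs are deterministic.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
import yaml

from ._util import percent, round_half_away
from .alignment_filter import (
    AlignedAsset,
    classify_exon_count,
    filter_alignments,
    relative_position_profile,
    write_psl,
)
from .as_event_detection import (
    ASEvent,
    cluster_with_references,
    detect_cluster_events,
    events_table,
    flag_intronless_overlap,
    summarize_events,
)
from .genomic_model import (
    Genome,
    TranscriptModel,
    genomic_blocks,
    spliced_sequence,
    write_transcript_models,
)
from .library_simulator import (
    SimulationParams,
    simulate_library,
    write_fastq,
    write_manifest,
)
from .read_processing import (
    Cluster,
    QCParams,
    Read,
    cluster_reads,
    library_summary,
    qc_reads,
)
from .synthetic import PlantedEvent, synthesize_study

log = logging.getLogger("splicetrap")


@dataclass
class PipelineConfig:
    seed: int = 7
    n_genes: int = 50
    library_name: str = "sim_lib"
    simulation: SimulationParams = field(default_factory=SimulationParams)
    qc: QCParams = field(default_factory=QCParams)
    min_overlap: int = 40
    cluster_min_identity: float = 0.95
    min_alignment_identity: float = 93.0
    min_coverage: float = 55.0
    dedup_events: bool = True
    nmd_rule_nt: int = 50
    fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationParams(**self.simulation)
        if isinstance(self.qc, dict):
            self.qc = QCParams(**self.qc)
        self.simulation.seed = self.seed

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineReport:
    summary: dict
    clusters: list[Cluster]
    assets: list[AlignedAsset]
    events: list[ASEvent]
    event_summary: dict
    profile: np.ndarray
    recall: float | None = None
    intronless: tuple[int, int, float] | None = None


# ---------------------------------------------------------------------------
# consensus placement
# ---------------------------------------------------------------------------

def align_consensi(
    clusters: list[Cluster],
    manifest: pd.DataFrame,
    models: list[TranscriptModel],
    genome: Genome,
) -> list[AlignedAsset]:
    """Place each consensus on the genome via its gene's spliced transcripts.

    The candidate gene is the majority gene among the cluster's member reads
    (truth manifest); the consensus is infix-aligned (edlib) against the
    spliced sequence of each of that gene's variants and the best placement
    is converted to genomic blocks through the variant's exon chain.
    """
    by_read = manifest.set_index("read_id")
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    spliced_cache = {
        m.transcript_id: spliced_sequence(m, genome) for m in models
    }
    assets = []
    for cl in clusters:
        genes = [
            by_read.loc[r, "gene"] for r in cl.members if r in by_read.index
        ]
        if not genes:
            continue
        gene = pd.Series(genes).mode().iloc[0]
        best = None
        for variant in sorted(by_gene[gene], key=lambda m: m.transcript_id):
            target = spliced_cache[variant.transcript_id]
            aln = edlib.align(cl.consensus, target, mode="HW", task="locations")
            if aln["editDistance"] < 0:
                continue
            key = (aln["editDistance"], variant.transcript_id)
            if best is None or key < best[0]:
                ts, te = aln["locations"][0]
                best = (key, variant, ts, te + 1)
        if best is None:
            continue
        (dist, _), variant, ts, te = best
        blocks = genomic_blocks(variant, ts, te)
        chain = TranscriptModel(
            cl.cluster_id, variant.gene_id, variant.chrom, variant.strand,
            tuple(blocks),
        )
        qlen = len(cl.consensus)
        assets.append(
            AlignedAsset(
                asset_id=cl.cluster_id,
                chain=chain,
                matches=max(0, qlen - dist),
                aligned_length=qlen,
                query_length=qlen,
            )
        )
    return assets


def asset_placements(
    assets: list[AlignedAsset], models: list[TranscriptModel], genome: Genome
) -> list[tuple[int, int, int]]:
    """Transcript-relative (start, end, length) of each asset for profiles."""
    spliced_cache = {m.transcript_id: spliced_sequence(m, genome) for m in models}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    placements = []
    for a in assets:
        gene = a.chain.gene_id
        if gene not in by_gene:
            continue
        best = None
        for variant in sorted(by_gene[gene], key=lambda m: m.transcript_id):
            # locate the asset's transcript interval on the variant
            span = a.chain.span
            tcoords = [
                i
                for i, p in enumerate(_positions(variant))
                if span.start <= p < span.end
            ]
            if not tcoords:
                continue
            cov = len(tcoords)
            if best is None or cov > best[0]:
                best = (cov, min(tcoords), max(tcoords) + 1, variant.length)
        if best is not None:
            placements.append((best[1], best[2], best[3]))
    return placements


def _positions(model: TranscriptModel) -> list[int]:
    from .genomic_model import transcript_positions

    return transcript_positions(model)


def score_recovery(
    events: list[ASEvent], truths: list[PlantedEvent]
) -> tuple[float, pd.DataFrame]:
    """Fraction of planted events recovered with exact type and coordinates."""
    detected = {(e.event_type, e.chrom, e.start, e.end) for e in events}
    rows = []
    hits = 0
    for t in truths:
        hit = (t.event_type, t.chrom, t.start, t.end) in detected
        hits += hit
        rows.append(
            {
                "gene": t.gene_id,
                "event_type": t.event_type,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "recovered": int(hit),
            }
        )
    recall = hits / len(truths) if truths else float("nan")
    return recall, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig, out_dir: str | Path
) -> PipelineReport:
    """Simulate a library and run every downstream stage, writing reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("seed=%d n_genes=%d", config.seed, config.n_genes)
    config.to_yaml(out / "config.yaml")

    genome, models, truths = synthesize_study(config.n_genes, config.seed)
    genome.to_fasta(out / "genome.fa")
    write_transcript_models(models, out / "variants.bed", "bed12")

    sim_reads, manifest = simulate_library(models, genome, config.simulation)
    write_fastq(sim_reads, out / "reads.fastq")
    write_manifest(manifest, out / "manifest.tsv")
    log.info("simulated %d reads", len(sim_reads))

    reads = [Read(r.read_id, r.sequence, r.qualities) for r in sim_reads]
    return analyse_reads(
        config, out, reads, manifest=manifest, models=models, genome=genome,
        truths=truths,
    )


def analyse_reads(
    config: PipelineConfig,
    out: Path,
    reads: list[Read],
    manifest: pd.DataFrame,
    models: list[TranscriptModel],
    genome: Genome,
    truths: list[PlantedEvent] | None = None,
) -> PipelineReport:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    surviving = qc_reads(reads, config.qc)
    log.info("%d/%d reads survive QC", len(surviving), len(reads))

    clusters = cluster_reads(
        surviving, config.min_overlap, config.cluster_min_identity
    )
    summary = library_summary(config.library_name, len(surviving), clusters)
    pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
    with open(out / "consensus.fa", "w") as fh:
        for c in clusters:
            fh.write(f">{c.cluster_id} {c.kind} n={len(c.members)}\n{c.consensus}\n")
    pd.DataFrame(
        [
            {"cluster_id": c.cluster_id, "read_id": r}
            for c in clusters
            for r in c.members
        ]
    ).to_csv(out / "membership.tsv", sep="\t", index=False)

    if not clusters:
        empty = PipelineReport(
            summary, [], [], [], summarize_events([]), np.zeros(101, dtype=int)
        )
        events_table([]).to_csv(out / "events.bed", sep="\t", index=False)
        return empty

    aligned = align_consensi(clusters, manifest, models, genome)
    write_psl(aligned, out / "assets.psl")
    passing = filter_alignments(
        aligned, config.min_alignment_identity, config.min_coverage
    )
    metrics = pd.DataFrame(
        [
            {
                "asset_id": a.asset_id,
                "matches": a.matches,
                "aligned_length": a.aligned_length,
                "query_length": a.query_length,
                "identity": round_half_away(a.identity, 2),
                "coverage": round_half_away(a.coverage, 2),
                "n_exons": a.n_exons,
                "class": classify_exon_count(a),
                "passes_filter": int(a in passing),
            }
            for a in aligned
        ]
    )
    metrics.to_csv(out / "asset_metrics.tsv", sep="\t", index=False)

    multi = [a for a in passing if classify_exon_count(a) == "multi_exon"]
    intronless = [a for a in passing if a not in multi]
    log.info("%d multi-exon / %d intronless assets", len(multi), len(intronless))

    asset_clusters = cluster_with_references(multi, models)
    events: list[ASEvent] = []
    for ac in asset_clusters:
        events.extend(detect_cluster_events(ac, dedup=config.dedup_events))
    ev_summary = summarize_events(events)
    events_table(events).to_csv(out / "events.bed", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "event_type": t,
                "count": ev_summary["counts"][t],
                "percent": ev_summary["percentages"][t],
            }
            for t in ev_summary["counts"]
        ]
    ).to_csv(out / "event_summary.tsv", sep="\t", index=False)

    profile = relative_position_profile(
        asset_placements(passing, models, genome)
    )
    pd.DataFrame(
        {"percentile": np.arange(101), "coverage": profile}
    ).to_csv(out / "position_profile.tsv", sep="\t", index=False)

    n_hit, n_total, pct = flag_intronless_overlap(
        [a.chain.span for a in intronless], [e.coords for e in events]
    )

    recall = None
    if truths is not None:
        recall, recovery = score_recovery(events, truths)
        recovery.to_csv(out / "recovery.tsv", sep="\t", index=False)
        log.info("planted-event recall: %.3f", recall)

    return PipelineReport(
        summary=summary,
        clusters=clusters,
        assets=passing,
        events=events,
        event_summary=ev_summary,
        profile=profile,
        recall=recall,
        intronless=(n_hit, n_total, pct),
    )
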