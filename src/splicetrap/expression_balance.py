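"""Expression-balance analysis of variant pairs and ligation-probe design.

Electrophoresis peak concentrations are normalized against a reference gene
(GAPDH in the original assay), the ASSET/variant balance is taken per
sample, and the cross-sample change is expressed as a *signed fold*:
r = balance(sample 1) / balance(sample 2), reported as r when r >= 1 and
as -1/r otherwise, so a halving reads -2.0 rather than 0.5.  Genes with
|fold| >= 2 are called differentially balanced.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_away

FOLD_THRESHOLD = 2.0

FORWARD_PRIMER = "GGGTAGGCTAAGGGTAGGA"
STUFFER = "CCGTTGCCAGTCTGCTCAGACCTCCCTCGCGCCATCAG"
REVERSE_PRIMER = "TCTAGATTGGATCTTGCTGGCAC"


@dataclass
class PeakMeasurement:
    """One electrophoresis peak: a species of a gene in one sample."""

    gene: str
    sample: str
    species: str  # "asset" or "variant"
    size_bp: int
    concentration: float
    normalized: float | None = None

    def __post_init__(self) -> None:
        if self.species not in ("asset", "variant"):
            raise ValueError(f"species must be asset/variant, got {self.species!r}")
        if self.concentration < 0:
            raise ValueError("concentration cannot be negative")
        if self.size_bp <= 0:
            raise ValueError("peak size must be positive")


@dataclass
class BalanceRecord:
    gene: str
    balances: dict[str, float]  # sample -> asset/variant ratio
    fold: float | None
    differential: bool


def normalize(concentration: float, reference_factor: float) -> float:
    """Concentration divided by the reference-gene factor."""
    if reference_factor <= 0:
        raise ValueError("reference factor must be positive")
    return concentration / reference_factor


def balance(asset_normalized: float, variant_normalized: float) -> float | None:
    """ASSET/variant ratio; None when the variant peak is undetected."""
    if variant_normalized == 0:
        return None
    return asset_normalized / variant_normalized


def signed_fold(
    value_c52: float, value_hb4a: float, decimals: int | None = 1
) -> float:
    """Signed ratio of two positive values (first over second).

    r >= 1 is reported as r; r < 1 as -1/r.  ``decimals=None`` returns the
    unrounded value; reports use one decimal, half away from zero.
    """
    if value_c52 <= 0 or value_hb4a <= 0:
        raise ValueError("signed fold requires positive inputs")
    r = value_c52 / value_hb4a
    fold = r if r >= 1 else -1.0 / r
    if decimals is None:
        return fold
    return round_half_away(fold, decimals)


def call_differential(fold: float, threshold: float = FOLD_THRESHOLD) -> bool:
    """Differential balance when |fold| >= threshold (inclusive)."""
    return abs(fold) >= threshold


def balance_table(
    measurements: list[PeakMeasurement],
    reference_factors: dict[str, float],
    samples: tuple[str, str] = ("C5.2", "Hb4a"),
    threshold: float = FOLD_THRESHOLD,
) -> tuple[list[BalanceRecord], pd.DataFrame]:
    """Normalize peaks, compute per-sample balances and cross-sample folds.

    ``reference_factors`` maps sample -> reference-gene factor;
    ``samples`` names (numerator, denominator) of the fold.
    """
    for m in measurements:
        m.normalized = normalize(m.concentration, reference_factors[m.sample])
    by_gene: dict[str, dict[tuple[str, str], PeakMeasurement]] = {}
    for m in measurements:
        by_gene.setdefault(m.gene, {})[(m.sample, m.species)] = m
    records = []
    rows = []
    for gene in sorted(by_gene):
        peaks = by_gene[gene]
        balances: dict[str, float] = {}
        for sample in samples:
            asset = peaks.get((sample, "asset"))
            variant = peaks.get((sample, "variant"))
            if asset is None or variant is None:
                continue
            b = balance(asset.normalized, variant.normalized)
            if b is not None:
                balances[sample] = b
        fold = None
        differential = False
        if all(s in balances for s in samples):
            fold = signed_fold(balances[samples[0]], balances[samples[1]])
            differential = call_differential(fold, threshold)
        records.append(BalanceRecord(gene, balances, fold, differential))
        for sample in samples:
            for species in ("asset", "variant"):
                m = peaks.get((sample, species))
                if m is None:
                    continue
                rows.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "species": species,
                        "size_bp": m.size_bp,
                        "concentration": m.concentration,
                        "normalized": round_half_away(m.normalized, 1),
                        "balance": (
                            round_half_away(balances[sample], 1)
                            if sample in balances and species == "asset"
                            else ""
                        ),
                        "fold": (
                            fold
                            if fold is not None
                            and sample == samples[0]
                            and species == "asset"
                            else ""
                        ),
                        "differential": (
                            int(differential)
                            if sample == samples[0] and species == "asset"
                            else ""
                        ),
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "sample", "species", "size_bp", "concentration",
            "normalized", "balance", "fold", "differential",
        ],
    )
    return records, table


def read_peak_table(path) -> list[PeakMeasurement]:
    """TSV with columns gene, sample, species, size_bp, concentration."""
    df = pd.read_csv(path, sep="\t")
    return [
        PeakMeasurement(
            str(r.gene), str(r.sample), str(r.species), int(r.size_bp),
            float(r.concentration),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# ligation probes
# ---------------------------------------------------------------------------

@dataclass
class ProbePair:
    """Variant-specific ligation probes abutting one exon junction."""

    left_probe: str
    right_probe: str
    phosphorylated: bool
    amplicon_length: int


def design_ligation_probes(
    upstream_arm: str, downstream_arm: str, arm_length: int = 20
) -> ProbePair:
    """Build a left/right probe pair for a target exon junction.

    The arms are the variant's spliced sequence immediately upstream and
    downstream of the junction; the left probe carries the forward-primer
    site and a 38-nt stuffer, the right probe is 5'-phosphorylated and ends
    in the reverse-primer site.
    """
    if len(upstream_arm) < arm_length or len(downstream_arm) < arm_length:
        raise ValueError(f"both arms must provide >= {arm_length} nt")
    up = upstream_arm[-arm_length:]
    down = downstream_arm[:arm_length]
    left = FORWARD_PRIMER + STUFFER + up
    right = down + REVERSE_PRIMER
    amplicon = len(FORWARD_PRIMER) + len(STUFFER) + 2 * arm_length + len(REVERSE_PRIMER)
    return ProbePair(left, right, phosphorylated=True, amplicon_length=amplicon)


def probes_for_junction(spliced_seq: str, junction: int, arm_length: int = 20) -> ProbePair:
    """Probe pair for the junction at transcript coordinate ``junction``."""
    return design_ligation_probes(
        spliced_seq[:junction], spliced_seq[junction:], arm_length
    )


def write_probe_fasta(pairs: dict[str, ProbePair], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pairs):
            p = pairs[name]
            fh.write(f">{name}_left\n{p.left_probe}\n")
            phos = " 5'-phosphorylated" if p.phosphorylated else ""
            fh.write(f">{name}_right{phos}\n{p.right_probe}\n")
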