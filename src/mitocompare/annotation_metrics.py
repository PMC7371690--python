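"""Structural ledger of an annotated mitogenome.

Computes, from coordinates alone, the quantities a mitogenome
characterization reports: per-class totals, strand tallies, intergenic
spacers (IGS) and gene overlaps around the circle, the protein-coding
fraction of the genome, and tRNA size extremes.  With the sequence
attached, protein-coding genes are additionally checked for start codons,
(possibly incomplete) stop codons and internal stops under the vertebrate
mitochondrial code.

The adjacency ledger follows the GenBank-table convention of reporting,
for each gene, the gap to the *following* gene: positive values are
intergenic nucleotides, negative values overlapping nucleotides, zero
means the two genes abut.  The last feature pairs with the first through
the circular origin, so signed gaps and feature lengths always sum to the
genome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

from .codon_usage import GeneticCode
from .genome_model import (
    CoordinateError,
    GeneTable,
    MitoGenome,
    ValidationError,
    feature_length,
    slice_sequence,
    union_length,
)

__all__ = [
    "AdjacencyEntry",
    "AdjacencyLedger",
    "StructuralSummary",
    "PcgValidation",
    "adjacency_ledger",
    "structural_summary",
    "validate_pcg",
]


class AdjacencyEntry(NamedTuple):
    upstream: str
    downstream: str
    gap_bp: int  # > 0 spacer, < 0 overlap, 0 abutting


@dataclass
class AdjacencyLedger:
    """Signed gaps between consecutive features around the circle."""

    entries: list[AdjacencyEntry]

    @property
    def total_igs(self) -> int:
        return sum(e.gap_bp for e in self.entries if e.gap_bp > 0)

    @property
    def total_overlap(self) -> int:
        return sum(-e.gap_bp for e in self.entries if e.gap_bp < 0)

    @property
    def igs_regions(self) -> int:
        return sum(1 for e in self.entries if e.gap_bp > 0)

    @property
    def overlap_locations(self) -> int:
        return sum(1 for e in self.entries if e.gap_bp < 0)

    @property
    def abutting(self) -> int:
        return sum(1 for e in self.entries if e.gap_bp == 0)

    def largest_igs(self) -> AdjacencyEntry | None:
        pos = [e for e in self.entries if e.gap_bp > 0]
        return max(pos, key=lambda e: e.gap_bp) if pos else None

    def largest_overlap(self) -> AdjacencyEntry | None:
        neg = [e for e in self.entries if e.gap_bp < 0]
        return min(neg, key=lambda e: e.gap_bp) if neg else None


def adjacency_ledger(gt: GeneTable) -> AdjacencyLedger:
    """Compute the signed gap following each feature, circularly closed.

    Features fully contained in their predecessor are skipped with a
    warning (not observed in bovid mitogenomes).
    """
    L = gt.genome_length
    feats = sorted(gt.features, key=lambda f: (f.start, f.end))
    if [f.name for f in feats] != [f.name for f in gt.features]:
        warnings.warn("gene table was not sorted by start; sorting", stacklevel=2)
    kept = []
    for f in feats:
        if kept and not f.wraps and not kept[-1].wraps and f.end <= kept[-1].end:
            warnings.warn(
                f"feature {f.name} is contained within {kept[-1].name}; "
                "skipped in adjacency ledger", stacklevel=2,
            )
            continue
        kept.append(f)
    entries: list[AdjacencyEntry] = []
    for a, b in zip(kept, kept[1:]):
        gap = b.start - a.end - 1
        if abs(gap) > L:
            raise CoordinateError(f"gap between {a.name} and {b.name} exceeds genome")
        entries.append(AdjacencyEntry(a.name, b.name, gap))
    if len(kept) >= 1:
        a, b = kept[-1], kept[0]
        if a.wraps:
            gap = b.start - a.end - 1
        else:
            gap = (L - a.end) + (b.start - 1)
        entries.append(AdjacencyEntry(a.name, b.name, gap))
    return AdjacencyLedger(entries=entries)


@dataclass
class StructuralSummary:
    """Coordinate-derived structural statistics of one mitogenome."""

    genome_length: int
    counts_by_class: dict[str, int]
    strand_h: int
    strand_l: int
    class_union_bp: dict[str, int]
    pcg_union_bp: int
    pcg_sum_bp: int
    pcg_pct_of_genome: float
    total_overlap_bp: int
    overlap_locations: int
    largest_overlap: tuple[str, str, int] | None
    total_igs_bp: int
    igs_regions: int
    largest_igs: tuple[str, str, int] | None
    trna_min: tuple[str, int] | None
    trna_max: tuple[str, int] | None
    control_region_bp: int
    ledger: AdjacencyLedger = field(repr=False)

    def to_dict(self) -> dict:
        d = {
            "genome_length": self.genome_length,
            "counts_by_class": self.counts_by_class,
            "strand_h": self.strand_h,
            "strand_l": self.strand_l,
            "class_union_bp": self.class_union_bp,
            "pcg_union_bp": self.pcg_union_bp,
            "pcg_sum_bp": self.pcg_sum_bp,
            "pcg_pct_of_genome": self.pcg_pct_of_genome,
            "total_overlap_bp": self.total_overlap_bp,
            "overlap_locations": self.overlap_locations,
            "largest_overlap": list(self.largest_overlap) if self.largest_overlap else None,
            "total_igs_bp": self.total_igs_bp,
            "igs_regions": self.igs_regions,
            "largest_igs": list(self.largest_igs) if self.largest_igs else None,
            "trna_min": list(self.trna_min) if self.trna_min else None,
            "trna_max": list(self.trna_max) if self.trna_max else None,
            "control_region_bp": self.control_region_bp,
            "adjacency": [list(e) for e in self.ledger.entries],
        }
        return d


def structural_summary(gt: GeneTable, pcg_fraction_from_sum: bool = False) -> StructuralSummary:
    """Compute the full structural summary from coordinates alone.

    The protein-coding fraction of the genome uses the union of PCG
    positions (overlapping positions counted once) unless
    ``pcg_fraction_from_sum`` asks for the plain sum of gene sizes.
    """
    L = gt.genome_length
    ledger = adjacency_ledger(gt)
    counts = {c: len(gt.by_class(c)) for c in ("PCG", "tRNA", "rRNA", "control")}
    genes = [f for f in gt if f.feature_class != "control"]
    strand_h = sum(1 for f in genes if f.strand == "H")
    strand_l = sum(1 for f in genes if f.strand == "L")
    class_union = {
        c: union_length(gt.by_class(c), L)
        for c in ("PCG", "tRNA", "rRNA", "control")
    }
    pcg_union = class_union["PCG"]
    pcg_sum = sum(feature_length(f, L) for f in gt.by_class("PCG"))
    basis = pcg_sum if pcg_fraction_from_sum else pcg_union
    pcg_pct = round(100.0 * basis / L, 2)
    trnas = [(f.name, feature_length(f, L)) for f in gt.by_class("tRNA")]
    trna_min = min(trnas, key=lambda t: t[1]) if trnas else None
    trna_max = max(trnas, key=lambda t: t[1]) if trnas else None
    lo = ledger.largest_overlap()
    li = ledger.largest_igs()
    control = gt.by_class("control")
    control_bp = sum(feature_length(f, L) for f in control)
    return StructuralSummary(
        genome_length=L,
        counts_by_class=counts,
        strand_h=strand_h,
        strand_l=strand_l,
        class_union_bp=class_union,
        pcg_union_bp=pcg_union,
        pcg_sum_bp=pcg_sum,
        pcg_pct_of_genome=pcg_pct,
        total_overlap_bp=ledger.total_overlap,
        overlap_locations=ledger.overlap_locations,
        largest_overlap=(lo.upstream, lo.downstream, -lo.gap_bp) if lo else None,
        total_igs_bp=ledger.total_igs,
        igs_regions=ledger.igs_regions,
        largest_igs=(li.upstream, li.downstream, li.gap_bp) if li else None,
        trna_min=trna_min,
        trna_max=trna_max,
        control_region_bp=control_bp,
        ledger=ledger,
    )


@dataclass
class PcgValidation:
    """Reading-frame health report for one protein-coding gene."""

    name: str
    length_bp: int
    start_codon: str
    start_ok: bool
    stop_state: str  # complete | incomplete_T | incomplete_TA | none
    internal_stops: int

    @property
    def ok(self) -> bool:
        return self.start_ok and self.stop_state != "none" and self.internal_stops == 0


def validate_pcg(genome: MitoGenome, gt: GeneTable,
                 code: GeneticCode | None = None) -> list[PcgValidation]:
    """Check each PCG's start codon, terminal codon state, and internal stops.

    Vertebrate mitochondrial genes frequently end on an incomplete stop
    (T or TA) completed to UAA by polyadenylation; those are reported as
    ``incomplete_T`` / ``incomplete_TA``, not as failures.  All findings
    are reported as records; nothing raises unless a gene is shorter than
    two codons.
    """
    code = code or GeneticCode.vertebrate_mitochondrial()
    out = []
    for f in gt.by_class("PCG"):
        cds = slice_sequence(genome, f)
        if len(cds) < 6:
            raise ValidationError(f"{f.name}: PCG of {len(cds)} nt is too short")
        start = cds[:3]
        start_ok = start in code.start_codons
        n_full = len(cds) // 3
        tail = cds[n_full * 3:]
        codons = [cds[i * 3:(i + 1) * 3] for i in range(n_full)]
        if tail == "":
            if codons[-1] in code.stop_codons:
                stop_state = "complete"
                body = codons[:-1]
            else:
                stop_state = "none"
                body = codons
        elif tail == "T":
            stop_state = "incomplete_T"
            body = codons
        elif tail == "TA":
            stop_state = "incomplete_TA"
            body = codons
        else:
            stop_state = "none"
            body = codons
        internal = sum(1 for c in body[1:] if c in code.stop_codons)
        out.append(PcgValidation(
            name=f.name, length_bp=len(cds), start_codon=start, start_ok=start_ok,
            stop_state=stop_state, internal_stops=internal,
        ))
    return out
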