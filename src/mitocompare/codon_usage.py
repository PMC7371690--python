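"""Codon extraction, codon-usage frequencies, and RSCU.

Relative synonymous codon usage (RSCU) for codon *i* in a synonymous
family of size *k* with counts X:

    RSCU_i = X_i / mean(X over the family) = k · X_i / Σ_family X

RSCU = 1 means no bias within the family; stop codons are excluded.
The default genetic code is the vertebrate mitochondrial table
(NCBI transl_table 2), under which AGA/AGG are stops, ATA encodes Met
and TGA encodes Trp — so arginine is a four-codon family (CGN).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .genome_model import GeneTable, MitoGenome, slice_sequence

__all__ = [
    "GeneticCode",
    "CodonUsageTable",
    "extract_codons",
    "rscu",
    "aa_usage",
    "codon_rna",
]

_BASES = "TCAG"
ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def codon_rna(codon: str) -> str:
    """DNA codon label → RNA label (CTA → CUA)."""
    return codon.replace("T", "U")


@dataclass(frozen=True)
class GeneticCode:
    """A translation table: codon → amino acid, plus start/stop sets."""

    id: int
    name: str
    table: dict[str, str]          # sense codons only, DNA alphabet
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            id=table_id,
            name=t.names[0],
            table=dict(t.forward_table),
            start_codons=frozenset(t.start_codons),
            stop_codons=frozenset(t.stop_codons),
        )

    @classmethod
    def vertebrate_mitochondrial(cls) -> "GeneticCode":
        return cls.from_ncbi_id(2)

    @property
    def families(self) -> dict[str, list[str]]:
        """Amino acid → synonymous codons (sense codons only)."""
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.table.get(codon)
            if aa is not None:
                fams.setdefault(aa, []).append(codon)
        return fams


def extract_codons(genome: MitoGenome, gt: GeneTable,
                   code: GeneticCode | None = None,
                   include_stops: bool = False,
                   strict: bool = False) -> Counter:
    """Pool in-frame codon counts over all protein-coding genes.

    Each PCG is read on its coding strand from position 1.  A trailing
    1–2 nt (incomplete stop) is dropped; a terminal complete stop codon is
    excluded unless ``include_stops``.  Genes with internal stop codons
    are counted with a warning, or skipped under ``strict``.
    """
    code = code or GeneticCode.vertebrate_mitochondrial()
    counts: Counter = Counter()
    for f in gt.by_class("PCG"):
        cds = slice_sequence(genome, f)
        n_full = len(cds) // 3
        codons = [cds[i * 3:(i + 1) * 3] for i in range(n_full)]
        if codons and len(cds) % 3 == 0 and codons[-1] in code.stop_codons \
                and not include_stops:
            codons = codons[:-1]
        internal = sum(1 for c in codons[1:-1] if c in code.stop_codons)
        if internal:
            msg = f"{f.name}: {internal} internal stop codon(s) in frame"
            if strict:
                warnings.warn(msg + "; gene skipped", stacklevel=2)
                continue
            warnings.warn(msg, stacklevel=2)
        counts.update(c for c in codons if set(c) <= set("ACGT"))
    return counts


@dataclass
class CodonUsageTable:
    """Per-codon counts with RSCU values and per-amino-acid totals."""

    counts: dict[str, int]
    rscu: dict[str, float]
    aa_freq: dict[str, int]
    families: dict[str, list[str]] = field(repr=False)
    zero_families: list[str] = field(default_factory=list)

    def rows(self) -> list[dict]:
        """Per-codon report rows (RNA codon labels), grouped by amino acid."""
        out = []
        for aa in sorted(self.families):
            for codon in self.families[aa]:
                out.append({
                    "codon": codon_rna(codon),
                    "codon_dna": codon,
                    "amino_acid": aa,
                    "count": self.counts.get(codon, 0),
                    "rscu": round(self.rscu[codon], 3),
                })
        return out

    def top_codons(self, n: int = 4) -> list[str]:
        """The n highest-RSCU codons (RNA labels), ties broken by count."""
        ranked = sorted(self.rscu,
                        key=lambda c: (-self.rscu[c], -self.counts.get(c, 0), c))
        return [codon_rna(c) for c in ranked[:n]]


def rscu(counts: dict[str, int] | Counter,
         code: GeneticCode | None = None) -> CodonUsageTable:
    """Compute RSCU = k·X_i/ΣX per synonymous family.

    Families with zero total usage get RSCU 0 for every member and are
    listed in ``zero_families``.
    """
    code = code or GeneticCode.vertebrate_mitochondrial()
    fams = code.families
    values: dict[str, float] = {}
    zero: list[str] = []
    for aa, codons in fams.items():
        total = sum(counts.get(c, 0) for c in codons)
        k = len(codons)
        if total == 0:
            zero.append(aa)
            for c in codons:
                values[c] = 0.0
        else:
            for c in codons:
                values[c] = k * counts.get(c, 0) / total
    return CodonUsageTable(
        counts={c: counts.get(c, 0) for c in code.table},
        rscu=values,
        aa_freq=aa_usage(counts, code),
        families=fams,
        zero_families=sorted(zero),
    )


def aa_usage(counts: dict[str, int] | Counter,
             code: GeneticCode | None = None) -> dict[str, int]:
    """Total usage per amino acid (pooling all synonymous families).

    Under the vertebrate mitochondrial code leucine pools CTN with
    TTA/TTG and serine pools TCN with AGT/AGC.
    """
    code = code or GeneticCode.vertebrate_mitochondrial()
    out: dict[str, int] = {}
    for codon, aa in code.table.items():
        n = counts.get(codon, 0)
        if n:
            out[aa] = out.get(aa, 0) + n
    return out
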