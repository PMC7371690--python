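"""Nucleotide composition, AT/GC content, and strand-skew statistics.

Strand asymmetry is summarized by the classical skew statistics

    AT skew = (A − T) / (A + T)        GC skew = (G − C) / (G + C)

computed over counts or percentages (the two are identical — the
statistics are scale invariant).  Mitochondrial H strands of bovids are
A- and C-rich, giving a positive AT skew and a negative GC skew.

Ambiguity characters (N) and alignment gaps are excluded from the
effective denominator.  Zero denominators (e.g. a GC-free homopolymer)
yield a skew of 0.0 with an explicit flag rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import GeneTable, MitoGenome, MitoError, slice_sequence

__all__ = [
    "UndefinedCompositionError",
    "CompositionProfile",
    "composition",
    "skews",
    "class_profiles",
]


class UndefinedCompositionError(MitoError):
    """Raised for sequences with no unambiguous A/C/G/T bases."""


@dataclass
class CompositionProfile:
    """Base counts and derived composition/skew statistics for one label."""

    label: str
    counts: dict[str, int]
    n_effective: int
    n_other: int
    at_skew: float
    gc_skew: float
    at_denominator_zero: bool = False
    gc_denominator_zero: bool = False

    @property
    def pct(self) -> dict[str, float]:
        """Per-base percentages over unambiguous bases, to 1 decimal."""
        return {b: round(100.0 * self.counts[b] / self.n_effective, 1)
                for b in "ACGT"}

    @property
    def at_content(self) -> float:
        return round(100.0 * (self.counts["A"] + self.counts["T"]) / self.n_effective, 1)

    @property
    def gc_content(self) -> float:
        return round(100.0 * (self.counts["G"] + self.counts["C"]) / self.n_effective, 1)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            **{b: self.counts[b] for b in "ACGT"},
            "n_effective": self.n_effective,
            "n_other": self.n_other,
            **{f"pct{b}": self.pct[b] for b in "ACGT"},
            "at_content": self.at_content,
            "gc_content": self.gc_content,
            "at_skew": round(self.at_skew, 3),
            "gc_skew": round(self.gc_skew, 3),
            "at_skew_raw": self.at_skew,
            "gc_skew_raw": self.gc_skew,
        }


def skews(a: float, t: float, g: float, c: float) -> tuple[float, float]:
    """AT and GC skew from counts or percentages (scale invariant).

    Zero denominators yield 0.0 for that skew (callers needing the flag
    use :func:`composition`).
    """
    at = (a - t) / (a + t) if (a + t) > 0 else 0.0
    gc = (g - c) / (g + c) if (g + c) > 0 else 0.0
    return at, gc


def composition(seq: str, label: str = "") -> CompositionProfile:
    """Tally a sequence into a :class:`CompositionProfile`.

    Gaps ('-') and ambiguity codes count toward ``n_other`` only.
    """
    if not seq:
        raise UndefinedCompositionError(f"{label or 'sequence'}: empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    n_eff = sum(counts.values())
    if n_eff == 0:
        raise UndefinedCompositionError(
            f"{label or 'sequence'}: no unambiguous A/C/G/T bases"
        )
    at_skew, gc_skew = skews(counts["A"], counts["T"], counts["G"], counts["C"])
    return CompositionProfile(
        label=label,
        counts=counts,
        n_effective=n_eff,
        n_other=len(seq) - n_eff,
        at_skew=at_skew,
        gc_skew=gc_skew,
        at_denominator_zero=(counts["A"] + counts["T"] == 0),
        gc_denominator_zero=(counts["G"] + counts["C"] == 0),
    )


def class_profiles(genome: MitoGenome, gt: GeneTable,
                   per_gene: bool = False,
                   pcg_union: bool = False) -> list[CompositionProfile]:
    """Composition profiles for the whole genome and each feature class.

    Class profiles concatenate the coding-strand sequence of member genes
    (L-strand genes contribute their reverse complement), so positions in
    gene overlaps are counted once per gene — the convention matching
    codon-based analyses.  ``pcg_union=True`` instead profiles the genomic
    union of PCG positions on the H strand.
    """
    profiles = [composition(genome.sequence, "whole_genome")]
    for cls, label in (("PCG", "PCG"), ("rRNA", "rRNA"), ("tRNA", "tRNA"),
                       ("control", "control_region")):
        feats = gt.by_class(cls)
        if not feats:
            continue
        if cls == "PCG" and pcg_union:
            covered = sorted({p for f in feats
                              for p in _positions(f, gt.genome_length)})
            seq = "".join(genome.sequence[p - 1] for p in covered)
        else:
            seq = "".join(slice_sequence(genome, f) for f in feats)
        profiles.append(composition(seq, label))
    if per_gene:
        for f in gt:
            profiles.append(composition(slice_sequence(genome, f), f.name))
    return profiles


def _positions(f, L):
    from .genome_model import feature_positions
    return feature_positions(f, L)
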