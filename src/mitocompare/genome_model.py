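"""Core types and circular-coordinate arithmetic for mitochondrial genomes.

Coordinates throughout the package are 1-based and fully inclusive on the
heavy (H) strand, the convention used by GenBank gene ledgers for animal
mitogenomes.  A feature with ``start > end`` wraps through the circular
origin.  Strand ``L`` denotes a light-strand (complement) encoded feature;
its coding sequence is the reverse complement of the H-strand slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "MitoError",
    "CoordinateError",
    "FormatError",
    "ValidationError",
    "MitoGenome",
    "GeneFeature",
    "GeneTable",
    "FEATURE_CLASSES",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "classify_name",
    "reverse_complement",
    "feature_length",
    "feature_positions",
    "slice_sequence",
    "union_length",
]


class MitoError(Exception):
    """Base class for errors raised by this package."""


class CoordinateError(MitoError):
    """A feature coordinate falls outside the genome or is inconsistent."""


class FormatError(MitoError):
    """An input file violates its format contract."""


class ValidationError(MitoError):
    """A biological validity check failed under strict mode."""


SEQUENCE_ALPHABET = frozenset("ACGTN")

PCG_NAMES = frozenset(
    ["nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
     "cox1", "cox2", "cox3", "atp6", "atp8", "cob"]
)

#: the 22 standard mitochondrial tRNA labels (two leucine and two serine
#: isoacceptors, hence trnL1/trnL2 and trnS1/trnS2)
TRNA_NAMES = frozenset(
    ["trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG",
     "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
     "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV"]
)

RRNA_NAMES = frozenset(["rrnS", "rrnL"])

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_name(name: str) -> str | None:
    """Infer the feature class from a controlled-vocabulary gene name.

    Returns ``None`` for names outside the vocabulary.
    """
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES:
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == "control_region":
        return "control"
    return None


@dataclass
class MitoGenome:
    """A circular mitochondrial genome sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A strand-aware annotated feature on a circular genome.

    ``start > end`` denotes a feature wrapping through the origin.
    """

    name: str
    strand: str
    start: int
    end: int
    feature_class: str
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be 'H' or 'L', got {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"{self.name}: feature_class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}"
            )
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"{self.name}: coordinates are 1-based, got "
                                  f"({self.start}, {self.end})")
        if self.anticodon is not None and self.anticodon != "":
            if len(self.anticodon) != 3 or set(self.anticodon.upper()) - set("ACGT"):
                raise ValueError(f"{self.name}: anticodon must be a 3-mer over ACGT")
            self.anticodon = self.anticodon.upper()
        else:
            self.anticodon = None

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def check_within(self, genome_length: int) -> None:
        if self.start > genome_length or self.end > genome_length:
            raise CoordinateError(
                f"{self.name}: coordinates ({self.start}, {self.end}) exceed "
                f"genome length {genome_length}"
            )


@dataclass
class GeneTable:
    """An ordered annotation ledger for one mitogenome.

    Features are kept sorted by start coordinate on the H strand.  A
    complete vertebrate mitogenome carries 13 protein-coding genes, 22
    tRNAs, 2 rRNAs and one control region; :meth:`validate` checks those
    tallies (warning by default, error under strict mode).
    """

    features: list[GeneFeature] = field(default_factory=list)
    genome_length: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for f in self.features:
            f.check_within(self.genome_length)
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def by_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == feature_class]

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def validate(self, strict: bool = False) -> list[str]:
        """Completeness and vocabulary checks; returns the list of problems.

        Problems warn by default and raise :class:`ValidationError` when
        ``strict`` is true.
        """
        problems: list[str] = []
        counts = {c: len(self.by_class(c)) for c in FEATURE_CLASSES}
        expected = {"PCG": 13, "tRNA": 22, "rRNA": 2, "control": 1}
        for cls, want in expected.items():
            if counts[cls] != want:
                problems.append(f"expected {want} {cls} features, found {counts[cls]}")
        seen: dict[str, int] = {}
        for f in self.features:
            seen[f.name] = seen.get(f.name, 0) + 1
            if classify_name(f.name) is None:
                problems.append(f"unknown feature name {f.name!r}")
            elif classify_name(f.name) != f.feature_class:
                problems.append(
                    f"{f.name}: declared class {f.feature_class} does not match name"
                )
        for name, n in seen.items():
            if n > 1:
                problems.append(f"duplicate feature name {name!r} ({n} copies)")
        if problems:
            if strict:
                raise ValidationError("; ".join(problems))
            for p in problems:
                warnings.warn(p, stacklevel=2)
        return problems


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circular genome of the given length."""
    f.check_within(genome_length)
    if f.wraps:
        return (genome_length - f.start + 1) + f.end
    return f.end - f.start + 1


def feature_positions(f: GeneFeature, genome_length: int) -> Iterable[int]:
    """Yield the 1-based genome positions a feature covers, in 5'→3' H-strand order."""
    f.check_within(genome_length)
    if f.wraps:
        yield from range(f.start, genome_length + 1)
        yield from range(1, f.end + 1)
    else:
        yield from range(f.start, f.end + 1)


def slice_sequence(genome: MitoGenome, f: GeneFeature) -> str:
    """Extract the coding-strand sequence of a feature.

    H-strand features return the genome substring; L-strand features return
    its reverse complement.  Wrapping features concatenate the sequence tail
    and head (only legal on circular genomes).
    """
    L = len(genome)
    f.check_within(L)
    if f.wraps:
        if not genome.circular:
            raise CoordinateError(
                f"{f.name}: wrapping feature on a non-circular genome"
            )
        raw = genome.sequence[f.start - 1:] + genome.sequence[:f.end]
    else:
        raw = genome.sequence[f.start - 1:f.end]
    return reverse_complement(raw) if f.strand == "L" else raw


def union_length(features: Iterable[GeneFeature], genome_length: int) -> int:
    """Number of distinct genome positions covered by at least one feature.

    Overlapping positions are counted once; circularly aware.
    """
    covered: set[int] = set()
    for f in features:
        covered.update(feature_positions(f, genome_length))
    return len(covered)
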