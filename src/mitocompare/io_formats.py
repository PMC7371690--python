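"""Readers and writers for the formats the pipeline touches.

FASTA and GenBank flat files are handled through Biopython; Newick trees
through dendropy.  The gene-table TSV is this package's own interchange
format: columns ``name, strand, start, end, feature_class, anticodon``
(header required, ``#`` comment lines allowed, 1-based inclusive
coordinates).

GenBank support is deliberately minimal — only the fields a mitogenome
ledger needs (LOCUS length, gene/CDS/tRNA/rRNA/D-loop features with their
location and /gene or /product name, and the ORIGIN sequence).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .genome_model import (
    CoordinateError,
    FormatError,
    GeneFeature,
    GeneTable,
    MitoGenome,
    classify_name,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "AlignmentSet",
    "read_alignment_fasta",
    "read_groups_tsv",
    "write_groups_tsv",
    "read_gene_table",
    "write_gene_table",
    "read_genbank_lite",
    "write_newick",
    "read_newick",
]

FASTA_WRAP = 70


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``, uppercased."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: FASTA must start with a '>' header")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write records as FASTA wrapped at 70 columns."""
    if not records:
        raise FormatError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i:i + FASTA_WRAP] + "\n")


@dataclass
class AlignmentSet:
    """A gapped multiple alignment of haplotype sequences.

    ``group_of`` optionally maps sequence ids to population/group labels
    for the comparative statistics.
    """

    ids: list[str]
    rows: list[str]
    group_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"alignment rows differ in length: {sorted(lengths)}")
        for r in self.rows:
            bad = set(r) - set("ACGTN-")
            if bad:
                if "." in bad:
                    raise FormatError(
                        "'.' is not accepted as a gap character; use '-'"
                    )
                raise FormatError(f"alignment contains invalid characters: {sorted(bad)}")
        if self.group_of is not None:
            for sid, g in self.group_of.items():
                if not g:
                    raise ValueError(f"empty group label for {sid!r}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, sid: str) -> int:
        return self.ids.index(sid)

    def row(self, key: int | str) -> str:
        if isinstance(key, str):
            return self.rows[self.index(key)]
        return self.rows[key]

    def groups(self) -> dict[str, list[str]]:
        """Group label → list of member ids (requires ``group_of``)."""
        if self.group_of is None:
            raise ValueError("alignment has no group labels attached")
        out: dict[str, list[str]] = {}
        for sid in self.ids:
            out.setdefault(self.group_of[sid], []).append(sid)
        return out


def read_alignment_fasta(path: str | Path,
                         groups_path: str | Path | None = None) -> AlignmentSet:
    records = read_fasta(path)
    group_of = read_groups_tsv(groups_path) if groups_path else None
    aln = AlignmentSet([r[0] for r in records], [r[1] for r in records], group_of)
    if len(aln) < 2:
        raise FormatError(f"{path}: comparative analyses need ≥ 2 sequences")
    if group_of is not None:
        missing = [sid for sid in aln.ids if sid not in group_of]
        if missing:
            raise FormatError(f"no group label for: {missing}")
    return aln


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>group`` table (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: expected 'id<TAB>group', got {line!r}")
            if parts[0] == "id" and parts[1] == "group":
                continue
            out[parts[0]] = parts[1]
    if not out:
        raise FormatError(f"{path}: no group assignments found")
    return out


def write_groups_tsv(group_of: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgroup\n")
        for sid, g in group_of.items():
            fh.write(f"{sid}\t{g}\n")


GENE_TABLE_COLUMNS = ["name", "strand", "start", "end", "feature_class", "anticodon"]


def read_gene_table(path: str | Path, genome_length: int | None = None,
                    strict: bool = False) -> GeneTable:
    """Read a gene-table TSV.

    ``genome_length`` may be given explicitly, declared in a
    ``# genome_length: N`` comment line, or — failing both — inferred as
    the maximum feature end coordinate.
    """
    path = Path(path)
    declared_length: int | None = None
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        lines = []
        for raw in fh:
            if raw.startswith("#"):
                m = re.match(r"#\s*genome_length\s*:\s*(\d+)", raw)
                if m:
                    declared_length = int(m.group(1))
                continue
            if raw.strip():
                lines.append(raw)
    if not lines:
        raise FormatError(f"{path}: empty gene table")
    reader = csv.DictReader(lines, delimiter="\t")
    header = reader.fieldnames or []
    for col in GENE_TABLE_COLUMNS[:5]:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    for row in reader:
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: gene table has a header but no records")

    features = []
    for row in rows:
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: non-integer coordinates for {row.get('name')!r}"
            ) from None
        features.append(GeneFeature(
            name=row["name"],
            strand=row["strand"],
            start=start,
            end=end,
            feature_class=row["feature_class"],
            anticodon=(row.get("anticodon") or None),
        ))
    if genome_length is None:
        genome_length = declared_length
    if genome_length is None:
        genome_length = max(max(f.start, f.end) for f in features)
    gt = GeneTable(features=features, genome_length=genome_length)
    if strict:
        for f in gt:
            if classify_name(f.name) is None:
                raise FormatError(f"{path}: unknown feature name {f.name!r}")
    return gt


def write_gene_table(gt: GeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genome_length: {gt.genome_length}\n")
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for f in gt:
            fh.write("\t".join([
                f.name, f.strand, str(f.start), str(f.end), f.feature_class,
                f.anticodon or "",
            ]) + "\n")


# --- GenBank (minimal subset) -------------------------------------------------

_GENBANK_NAME_MAP = {
    # common annotation spellings → controlled vocabulary
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "cox1": "cox1", "coi": "cox1", "cox2": "cox2", "coii": "cox2",
    "cox3": "cox3", "coiii": "cox3",
    "atp6": "atp6", "atp8": "atp8",
    "cytb": "cob", "cob": "cob",
    "12s rrna": "rrnS", "12s ribosomal rna": "rrnS", "rrns": "rrnS",
    "s-rrna": "rrnS",
    "16s rrna": "rrnL", "16s ribosomal rna": "rrnL", "rrnl": "rrnL",
    "l-rrna": "rrnL",
    "d-loop": "control_region", "control region": "control_region",
    "control_region": "control_region",
}

_TRNA_AA_MAP = {
    "ala": "trnA", "arg": "trnR", "asn": "trnN", "asp": "trnD",
    "cys": "trnC", "gln": "trnQ", "glu": "trnE", "gly": "trnG",
    "his": "trnH", "ile": "trnI", "lys": "trnK", "met": "trnM",
    "phe": "trnF", "pro": "trnP", "thr": "trnT", "trp": "trnW",
    "tyr": "trnY", "val": "trnV",
}


def _normalize_feature_name(raw: str) -> str:
    low = raw.strip().lower()
    if low in _GENBANK_NAME_MAP:
        return _GENBANK_NAME_MAP[low]
    for nm in ("nad1", "nad2", "nad3", "nad4l", "nad4", "nad5", "nad6",
               "cox1", "cox2", "cox3", "atp6", "atp8"):
        if low == nm:
            return nm
    if low.startswith("trna-leu"):
        return "trnL2" if "taa" in low or "uur" in low else "trnL1"
    if low.startswith("trna-ser"):
        return "trnS2" if "tga" in low or "ucn" in low else "trnS1"
    m = re.match(r"trna-([a-z]{3})", low)
    if m and m.group(1) in _TRNA_AA_MAP:
        return _TRNA_AA_MAP[m.group(1)]
    m = re.fullmatch(r"trn([a-z])([12]?)", low)
    if m and ("trn" + m.group(1).upper()) in _GENE_TABLE_TRNAS:
        return "trn" + m.group(1).upper() + m.group(2)
    return raw.strip()


_GENE_TABLE_TRNAS = frozenset(
    "trn" + x for x in "ARNDCQEGHILKMFPSTWYV"
)


def read_genbank_lite(path: str | Path) -> tuple[MitoGenome, GeneTable]:
    """Parse a minimal GenBank flat file into a genome and its gene table.

    Only gene/CDS/tRNA/rRNA/D-loop/misc_feature entries are consumed;
    ``complement(a..b)`` maps to strand L; a two-segment ``join`` across
    the origin maps to a wrapping feature (start > end).
    """
    path = Path(path)
    text = path.read_text()
    if "ORIGIN" not in text:
        raise FormatError(f"{path}: GenBank file lacks an ORIGIN block")
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a parseable GenBank file: {exc}") from None
    sequence = str(rec.seq).upper()
    if not sequence:
        raise FormatError(f"{path}: empty ORIGIN sequence")
    genome = MitoGenome(id=rec.id or path.stem, sequence=sequence)
    L = len(sequence)

    kind_of = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
               "D-loop": "control", "misc_feature": "control"}
    candidates: dict[tuple[int, int, str], GeneFeature] = {}
    generic: dict[tuple[int, int, str], GeneFeature] = {}
    for feat in rec.features:
        if feat.type not in ("gene", "CDS", "tRNA", "rRNA", "D-loop", "misc_feature"):
            continue
        raw_name = (feat.qualifiers.get("gene") or feat.qualifiers.get("product")
                    or feat.qualifiers.get("note") or [feat.type])[0]
        name = _normalize_feature_name(raw_name)
        loc = feat.location
        strand = "L" if loc.strand == -1 else "H"
        if isinstance(loc, CompoundLocation):
            if len(loc.parts) != 2:
                raise FormatError(
                    f"{path}: only two-segment origin-spanning joins supported "
                    f"({name})"
                )
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            head, tail = parts[0], parts[1]
            if int(tail.end) != L or int(head.start) != 0:
                raise FormatError(
                    f"{path}: join location for {name} does not span the origin"
                )
            start, end = int(tail.start) + 1, int(head.end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        if end > L or start > L:
            raise CoordinateError(
                f"{path}: feature {name} ({start}..{end}) outside sequence of {L} bp"
            )
        cls = kind_of.get(feat.type) or classify_name(name)
        if cls is None:
            cls = classify_name(name) or "PCG"
        if name == "control_region":
            cls = "control"
        anticodon = None
        if "anticodon" in feat.qualifiers:
            m = re.search(r"seq:([acgtu]{3})", feat.qualifiers["anticodon"][0], re.I)
            if m:
                anticodon = m.group(1).upper().replace("U", "T")
        gf = GeneFeature(name=name, strand=strand, start=start, end=end,
                         feature_class=cls, anticodon=anticodon)
        key = (start, end, strand)
        if feat.type == "gene":
            generic[key] = gf
        else:
            candidates[key] = gf
    # keep specific features; fall back to bare gene entries not shadowed by one
    merged = dict(candidates)
    for key, gf in generic.items():
        if key not in merged:
            merged[key] = gf
    if not merged:
        raise FormatError(f"{path}: no usable features found")
    gt = GeneTable(features=list(merged.values()), genome_length=L)
    return genome, gt


# --- Newick -------------------------------------------------------------------

def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick with branch lengths and internal support labels."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError("cannot serialize a tree with unlabeled tips")
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")
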