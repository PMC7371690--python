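"""Synthetic mitogenomes and grouped haplotype alignments.

The generator emulates the statistical design of a small comparative
mitogenome study of bovid subspecies: a ~16.3 kb circular genome with the
bovid gene order, base composition biased toward A (A .335, T .272,
C .259, G .134 by default), a control region carrying planted TACAT/ATGTA
motifs and a terminal poly-C stretch, and grouped haplotypes separated by
tens of substitutions within groups and hundreds between groups
(defaults: 33 within the 4-member focal group; 304 and 634 substitutions
separating the two single-member comparison groups from the focal
ancestor).

Two mutation modes:

* ``exact`` — substitution counts are placed at disjoint sites, so
  realized pairwise counts are deterministic (no back-mutation);
* ``poisson`` — per-branch counts are Poisson draws around the targets,
  for statistical tests.

Alignments are generated gap-free (the emulated genomes are
length-identical) and everything is reproducible from the seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_usage import GeneticCode
from .genome_model import GeneFeature, GeneTable, MitoGenome, feature_positions
from .io_formats import AlignmentSet, write_fasta, write_gene_table, write_groups_tsv
from .reference import load_gaur_gene_table

__all__ = [
    "SimulationConfig",
    "generate_genome",
    "generate_haplotypes",
    "random_gene_table",
    "write_bundle",
]

_BASES = np.array(list("ACGT"))

DEFAULT_COMPOSITION = {"A": 0.335, "T": 0.272, "C": 0.259, "G": 0.134}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator."""

    seed: int = 0
    genome_length: int = 16345
    gene_order: str = "bovid_table1"          # bovid_table1 | random
    base_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("indian", 4), ("cambodian", 1), ("malayan", 1)])
    within_group_diffs: int = 33
    group_divergence_from_base: dict[str, int] | None = field(
        default_factory=lambda: {"indian": 0, "cambodian": 304, "malayan": 634})
    between_group_diffs: int | None = None
    mutation_mode: str = "exact"              # exact | poisson
    motif_counts: dict[str, int] = field(
        default_factory=lambda: {"TACAT": 4, "ATGTA": 4})
    polyc_length: int = 13
    coding_constraints: bool = True

    def __post_init__(self) -> None:
        total = sum(self.base_composition.get(b, 0.0) for b in "ACGT")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"base composition must sum to 1, got {total}")
        if self.within_group_diffs < 0:
            raise ValueError("within_group_diffs must be ≥ 0")
        if self.mutation_mode not in ("exact", "poisson"):
            raise ValueError(f"unknown mutation mode {self.mutation_mode!r}")
        if self.gene_order not in ("bovid_table1", "random"):
            raise ValueError(f"unknown gene order {self.gene_order!r}")
        if self.group_divergence_from_base is None:
            if self.between_group_diffs is None:
                raise ValueError(
                    "provide group_divergence_from_base or between_group_diffs")
            first = self.groups[0][0]
            self.group_divergence_from_base = {
                label: (0 if label == first else self.between_group_diffs)
                for label, _ in self.groups
            }
        needed = (max(self.group_divergence_from_base.values(), default=0)
                  + self.within_group_diffs)
        if needed > self.genome_length:
            raise ValueError("requested substitution counts exceed genome length")


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def _coding_index_map(f: GeneFeature, L: int) -> list[int]:
    """Genome indices (0-based) in coding-sequence order for a feature."""
    pos = list(feature_positions(f, L))
    idx = [p - 1 for p in pos]
    return idx[::-1] if f.strand == "L" else idx


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def _get_coding(seq: list[str], f: GeneFeature, L: int) -> str:
    idx = _coding_index_map(f, L)
    if f.strand == "L":
        return "".join(_COMP[seq[i]] for i in idx)
    return "".join(seq[i] for i in idx)


def _set_coding(seq: list[str], f: GeneFeature, L: int, coding: str) -> None:
    idx = _coding_index_map(f, L)
    if f.strand == "L":
        for i, ch in zip(idx, coding):
            seq[i] = _COMP[ch]
    else:
        for i, ch in zip(idx, coding):
            seq[i] = ch


def _repair_coding(seq: list[str], gt: GeneTable, rng: np.random.Generator,
                   max_rounds: int = 80) -> bool:
    """Impose start codons, terminal (possibly incomplete) stops, and
    absence of internal stops on every PCG.

    Overlapping genes constrain each other, so repairs iterate until a
    joint fixed point; returns True on convergence.
    """
    code = GeneticCode.vertebrate_mitochondrial()
    sense = sorted(set(code.table) - code.stop_codons)
    L = gt.genome_length
    pcgs = gt.by_class("PCG")
    for _ in range(max_rounds):
        dirty = False
        for f in pcgs:
            cds = list(_get_coding(seq, f, L))
            n = len(cds)
            n_full, tail = divmod(n, 3)
            if "".join(cds[:3]) != "ATG":
                cds[0:3] = "ATG"
                dirty = True
            if tail == 0:
                if "".join(cds[-3:]) not in code.stop_codons:
                    cds[-3:] = "TAA"
                    dirty = True
                body_end = n_full - 1
            else:
                want = "T" if tail == 1 else "TA"
                if "".join(cds[n_full * 3:]) != want:
                    cds[n_full * 3:] = list(want)
                    dirty = True
                body_end = n_full
            for k in range(1, body_end):
                codon = "".join(cds[3 * k:3 * k + 3])
                if codon in code.stop_codons:
                    cds[3 * k:3 * k + 3] = sense[rng.integers(0, len(sense))]
                    dirty = True
            _set_coding(seq, f, L, "".join(cds))
        if not dirty:
            return True
    return False


def _plant_control_region(seq: list[str], region: GeneFeature, L: int,
                          motif_counts: dict[str, int], polyc: int,
                          rng: np.random.Generator) -> None:
    idx = _coding_index_map(region, L) if region.strand == "H" else \
        [p - 1 for p in feature_positions(region, L)]
    n = len(idx)
    if polyc > n:
        raise ValueError("poly-C suffix longer than the control region")
    usable = n - polyc
    taken: list[tuple[int, int]] = []
    for motif, count in motif_counts.items():
        m = len(motif)
        for _ in range(count):
            for _attempt in range(1000):
                s = int(rng.integers(0, max(1, usable - m)))
                if all(s + m <= a or s >= a + b for a, b in taken):
                    taken.append((s, m))
                    for off, ch in enumerate(motif):
                        seq[idx[s + off]] = ch
                    break
            else:
                raise ValueError("could not place motifs without overlap")
    for k in range(polyc):
        seq[idx[n - polyc + k]] = "C"
    if 0 < polyc < n and seq[idx[n - polyc - 1]] == "C":
        # keep the terminal run exactly the configured length
        seq[idx[n - polyc - 1]] = "T"


def random_gene_table(rng: np.random.Generator,
                      genome_length: int = 16345) -> GeneTable:
    """A random non-pathological circular gene layout for property tests.

    Features tile the circle with gaps in [-40, 30] bp (never containment),
    and the final feature occasionally wraps through the origin.
    """
    feats: list[GeneFeature] = []
    classes = ["PCG", "tRNA", "rRNA"]
    start = int(rng.integers(1, 200))
    first_start = start
    i = 0
    while True:
        size = int(rng.integers(60, 1500))
        end = start + size - 1
        if end >= genome_length - 60:
            break
        feats.append(GeneFeature(
            name=f"g{i}", strand=("H" if rng.random() < 0.75 else "L"),
            start=start, end=end,
            feature_class=classes[int(rng.integers(0, 3))],
        ))
        gap = int(rng.integers(-min(40, size - 1, 59), 31))
        start = end + 1 + gap
        i += 1
    if len(feats) < 3:
        return random_gene_table(rng, genome_length)
    if rng.random() < 0.3 and first_start > 2:
        # wrapping final feature ending before the first feature starts
        wrap_start = feats[-1].end + 1 + int(rng.integers(0, 20))
        if wrap_start < genome_length:
            feats.append(GeneFeature(
                name=f"g{i}", strand="H",
                start=wrap_start, end=int(rng.integers(1, first_start - 1))
                if first_start > 2 else 1,
                feature_class="control",
            ))
    return GeneTable(features=feats, genome_length=genome_length)


def generate_genome(cfg: SimulationConfig) -> tuple[MitoGenome, GeneTable]:
    """Generate a seeded circular genome and its gene table.

    ``bovid_table1`` mode reuses the packaged gaur coordinates, so every
    coordinate-derived statistic matches the reference ledger regardless
    of the sequence realization.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.gene_order == "bovid_table1":
        gt = load_gaur_gene_table()
        L = gt.genome_length
    else:
        gt = random_gene_table(rng, cfg.genome_length)
        L = cfg.genome_length
    p = np.array([cfg.base_composition[b] for b in "ACGT"])
    seq = list(rng.choice(_BASES, size=L, p=p / p.sum()))
    controls = gt.by_class("control")
    if controls:
        _plant_control_region(seq, controls[0], L, cfg.motif_counts,
                              cfg.polyc_length, rng)
    if cfg.coding_constraints:
        _repair_coding(seq, gt, rng)
    genome = MitoGenome(id=f"synthetic_seed{cfg.seed}", sequence="".join(seq))
    return genome, gt


def generate_haplotypes(genome: MitoGenome,
                        cfg: SimulationConfig) -> tuple[AlignmentSet, dict]:
    """Grouped haplotypes derived from a base genome by planted substitutions.

    Each group descends from a group ancestor carrying
    ``group_divergence_from_base[label]`` substitutions relative to the
    base; group members then carry ~half the within-group pairwise target
    as private substitutions each.  In exact mode all mutated sites are
    disjoint, so realized pairwise counts follow by addition.  Returns the
    alignment plus a manifest of expected and realized counts.
    """
    rng = np.random.default_rng([cfg.seed, 7919])
    L = len(genome)
    base = np.array(list(genome.sequence))
    div = cfg.group_divergence_from_base
    w = cfg.within_group_diffs

    site_order = rng.permutation(L)
    cursor = 0

    def take_exact(k: int) -> np.ndarray:
        nonlocal cursor
        sites = site_order[cursor:cursor + k]
        if len(sites) < k:
            raise ValueError("ran out of distinct sites for exact placement")
        cursor += k
        return sites

    def draw_sites(k: int) -> np.ndarray:
        if cfg.mutation_mode == "exact":
            return take_exact(k)
        kk = int(rng.poisson(k)) if k > 0 else 0
        return rng.choice(L, size=min(kk, L), replace=False)

    ids: list[str] = []
    rows: list[str] = []
    group_of: dict[str, str] = {}
    for label, n_hap in cfg.groups:
        ancestor = base.copy()
        for s in draw_sites(div.get(label, 0)):
            ancestor[s] = _mutate_base(ancestor[s], rng)
        per_hap = [(w + (1 - k % 2)) // 2 for k in range(n_hap)]  # ceil, floor, ...
        for k in range(n_hap):
            hap = ancestor.copy()
            for s in draw_sites(per_hap[k] if n_hap > 1 else 0):
                hap[s] = _mutate_base(hap[s], rng)
            sid = f"{label}_{k + 1}"
            ids.append(sid)
            rows.append("".join(hap))
            group_of[sid] = label

    aln = AlignmentSet(ids=ids, rows=rows, group_of=group_of)

    from .comparative_popgen import pairwise_differences
    members = aln.groups()
    realized_within = {}
    for label, mem in members.items():
        pairs = [pairwise_differences(aln, a, b)
                 for a, b in itertools.combinations(mem, 2)]
        realized_within[label] = (float(np.mean(pairs)) if pairs else None)
    realized_between = {}
    for (la, ma), (lb, mb) in itertools.combinations(members.items(), 2):
        pairs = [pairwise_differences(aln, a, b) for a in ma for b in mb]
        realized_between[f"{la}|{lb}"] = float(np.mean(pairs))
    manifest = {
        "seed": cfg.seed,
        "mutation_mode": cfg.mutation_mode,
        "genome_length": L,
        "groups": {label: n for label, n in cfg.groups},
        "expected": {
            "within_group_diffs": w,
            "group_divergence_from_base": div,
        },
        "realized": {
            "within": realized_within,
            "between": realized_between,
        },
    }
    return aln, manifest


def write_bundle(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Generate a full simulated study bundle and write it to ``outdir``.

    Emits genome.fa, genes.tsv, haplotypes.fasta, groups.tsv and
    manifest.json; returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, gt = generate_genome(cfg)
    aln, manifest = generate_haplotypes(genome, cfg)
    write_fasta([(genome.id, genome.sequence)], outdir / "genome.fa")
    write_gene_table(gt, outdir / "genes.tsv")
    write_fasta(list(zip(aln.ids, aln.rows)), outdir / "haplotypes.fasta")
    write_groups_tsv(aln.group_of, outdir / "groups.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
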