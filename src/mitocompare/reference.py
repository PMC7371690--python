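"""Packaged reference annotation: the 16,345 bp Indian gaur mitogenome ledger.

The table carries the 37 genes (13 PCG, 22 tRNA, 2 rRNA) plus the control
region with their strands, 1-based inclusive coordinates and tRNA
anticodons.  One sequenced animal (GR01) carries an AAA anticodon for trnF
where the other three carry GAA; the table stores GAA and the variant is
recorded in :data:`TRNF_ANTICODON_VARIANTS`.
"""

from __future__ import annotations

from importlib import resources

from .genome_model import GeneTable
from .io_formats import read_gene_table

__all__ = ["GAUR_GENOME_LENGTH", "TRNF_ANTICODON_VARIANTS", "load_gaur_gene_table"]

GAUR_GENOME_LENGTH = 16345

#: anticodon polymorphism observed among the four sequenced Indian gaur
TRNF_ANTICODON_VARIANTS = {"GR01": "AAA", "GR02": "GAA", "GR03": "GAA", "GR04": "GAA"}


def load_gaur_gene_table() -> GeneTable:
    """Load the packaged Indian gaur gene table (38 features, 16,345 bp)."""
    ref = resources.files("mitocompare").joinpath("data/gaur_gene_table.tsv")
    with resources.as_file(ref) as path:
        return read_gene_table(path)
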