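"""Control-region motif detection.

Bovid mitochondrial control regions carry dispersed copies of the
palindromic pentamers TACAT / ATGTA (putative H-strand elongation
termination signals with hairpin-forming propensity) and terminate in a
characteristic poly-C stretch.  Occurrences are reported case
insensitively and *overlapping matches are counted* — the conservative
superset when no counting convention is prescribed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MotifReport", "scan_motifs", "terminal_polyc", "DEFAULT_MOTIFS"]

DEFAULT_MOTIFS = ("TACAT", "ATGTA")


@dataclass
class MotifReport:
    """Occurrences of one motif within a scanned region (1-based offsets)."""

    motif: str
    positions: list[int]
    terminal_polyc: int

    @property
    def count(self) -> int:
        return len(self.positions)

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "count": self.count,
            "positions": self.positions,
            "terminal_polyc": self.terminal_polyc,
            "overlapping_counted": True,
        }


def scan_motifs(region: str, motifs=DEFAULT_MOTIFS) -> list[MotifReport]:
    """Find all (overlapping) occurrences of each motif in a region."""
    if not region:
        raise ValueError("cannot scan an empty region")
    region_u = region.upper()
    polyc = terminal_polyc(region_u)
    reports = []
    for motif in motifs:
        m = motif.upper()
        if not m or set(m) - set("ACGT"):
            raise ValueError(f"motif must be a non-empty A/C/G/T string: {motif!r}")
        positions = []
        i = region_u.find(m)
        while i != -1:
            positions.append(i + 1)
            i = region_u.find(m, i + 1)
        reports.append(MotifReport(motif=m, positions=positions,
                                   terminal_polyc=polyc))
    return reports


def terminal_polyc(region: str) -> int:
    """Length of the maximal run of C ending at the region's last position."""
    if not region:
        raise ValueError("cannot scan an empty region")
    region_u = region.upper()
    n = 0
    for ch in reversed(region_u):
        if ch != "C":
            break
        n += 1
    return n
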