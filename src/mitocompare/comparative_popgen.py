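"""Pairwise substitution counts, sequence divergence, and haplotype AMOVA.

Distances
---------
* ``differences`` — raw count of differing sites (both rows unambiguous).
* ``p_distance`` — differences / comparable sites.
* ``k2p`` — Kimura two-parameter distance,
  d = −½·ln((1 − 2P − Q)·√(1 − 2Q)), with P and Q the transition
  (A↔G, C↔T) and transversion proportions over comparable sites.

Sites with a gap or ambiguity in either row are skipped pair by pair
("pairwise deletion", the default) or dropped from every comparison if
any row is ambiguous there ("complete deletion", the MEGA default).

AMOVA
-----
One-level analysis of molecular variance in the Excoffier framework on
squared pairwise differences: with N haplotypes in G groups of sizes n_g,

    SSD_total  = (1/N)  Σ_{i<j} d²_ij            (all pairs)
    SSD_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij
    SSD_among  = SSD_total − SSD_within
    σ²_w = SSD_within/(N−G)
    σ²_a = (SSD_among/(G−1) − σ²_w)/n̄ ,  n̄ = (N − Σ n_g²/N)/(G−1)
    Φ_ST = σ²_a/(σ²_a + σ²_w)

Significance is assessed by permuting haplotypes among groups; the
p-value is the fraction of permutations (the observed configuration
included) with Φ_ST at least as large as observed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .genome_model import MitoError
from .io_formats import AlignmentSet

__all__ = [
    "UndefinedDistanceError",
    "GroupingError",
    "DistanceMatrix",
    "pairwise_differences",
    "p_distance",
    "k2p_distance",
    "distance_matrix",
    "group_divergence",
    "amova",
    "AmovaResult",
]

TRANSITIONS = frozenset([("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")])
_UNAMBIGUOUS = frozenset("ACGT")


class UndefinedDistanceError(MitoError):
    """No comparable sites between two rows."""


class GroupingError(MitoError):
    """An invalid group structure was supplied."""


def _comparable_mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ok = np.isin(x, [b"A", b"C", b"G", b"T"]) & np.isin(y, [b"A", b"C", b"G", b"T"])
    return ok


def _resolve(aln: AlignmentSet, key: int | str) -> int:
    return aln.index(key) if isinstance(key, str) else key


def pairwise_differences(aln: AlignmentSet, i: int | str, j: int | str) -> int:
    """Number of sites at which rows i and j carry different unambiguous bases."""
    i, j = _resolve(aln, i), _resolve(aln, j)
    xi = np.frombuffer(aln.rows[i].encode("ascii"), dtype="S1")
    yj = np.frombuffer(aln.rows[j].encode("ascii"), dtype="S1")
    ok = _comparable_mask(xi, yj)
    return int(np.count_nonzero(ok & (xi != yj)))


def _pq(xi: np.ndarray, yj: np.ndarray,
        site_mask: np.ndarray | None = None) -> tuple[int, int, int]:
    """(transitions, transversions, comparable sites) between two rows."""
    ok = _comparable_mask(xi, yj)
    if site_mask is not None:
        ok &= site_mask
    n = int(np.count_nonzero(ok))
    diff = ok & (xi != yj)
    ts = 0
    for a, b in (("A", "G"), ("C", "T")):
        pa, pb = a.encode(), b.encode()
        ts += int(np.count_nonzero(diff & (((xi == pa) & (yj == pb))
                                           | ((xi == pb) & (yj == pa)))))
    tv = int(np.count_nonzero(diff)) - ts
    return ts, tv, n


def p_distance(aln: AlignmentSet, i: int | str, j: int | str) -> float:
    """Proportion of differing sites among pairwise-comparable sites."""
    i, j = _resolve(aln, i), _resolve(aln, j)
    xi = np.frombuffer(aln.rows[i].encode("ascii"), dtype="S1")
    yj = np.frombuffer(aln.rows[j].encode("ascii"), dtype="S1")
    ts, tv, n = _pq(xi, yj)
    if n == 0:
        raise UndefinedDistanceError(f"no comparable sites between rows {i} and {j}")
    return (ts + tv) / n


def k2p_distance(aln: AlignmentSet, i: int | str, j: int | str) -> float:
    """Kimura 2-parameter distance; returns ``inf`` on domain violations."""
    i, j = _resolve(aln, i), _resolve(aln, j)
    xi = np.frombuffer(aln.rows[i].encode("ascii"), dtype="S1")
    yj = np.frombuffer(aln.rows[j].encode("ascii"), dtype="S1")
    ts, tv, n = _pq(xi, yj)
    if n == 0:
        raise UndefinedDistanceError(f"no comparable sites between rows {i} and {j}")
    P, Q = ts / n, tv / n
    a, b = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return math.inf
    return -0.5 * math.log(a * math.sqrt(b))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix under a named model."""

    ids: list[str]
    matrix: np.ndarray
    model: str            # differences | p_distance | k2p
    site_handling: str = "pairwise_deletion"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def distance_matrix(aln: AlignmentSet, model: str = "p_distance",
                    site_handling: str = "pairwise_deletion") -> DistanceMatrix:
    """All-pairs distance matrix from an alignment."""
    if model not in ("differences", "p_distance", "k2p"):
        raise ValueError(f"unknown model {model!r}")
    if site_handling not in ("pairwise_deletion", "complete_deletion"):
        raise ValueError(f"unknown site handling {site_handling!r}")
    n = len(aln)
    arrs = [np.frombuffer(r.encode("ascii"), dtype="S1") for r in aln.rows]
    site_mask = None
    if site_handling == "complete_deletion":
        site_mask = np.ones(aln.n_sites, dtype=bool)
        for a in arrs:
            site_mask &= np.isin(a, [b"A", b"C", b"G", b"T"])
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ts, tv, nc = _pq(arrs[i], arrs[j], site_mask)
        if nc == 0:
            raise UndefinedDistanceError(
                f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
            )
        if model == "differences":
            d = float(ts + tv)
        elif model == "p_distance":
            d = (ts + tv) / nc
        else:
            P, Q = ts / nc, tv / nc
            a_, b_ = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            d = math.inf if (a_ <= 0 or b_ <= 0) else -0.5 * math.log(a_ * math.sqrt(b_))
        m[i, j] = m[j, i] = d
    return DistanceMatrix(ids=list(aln.ids), matrix=m, model=model,
                          site_handling=site_handling)


def group_divergence(aln: AlignmentSet, group_a: list[str], group_b: list[str],
                     model: str = "p_distance") -> float:
    """Mean between-group pairwise distance under the chosen model."""
    if not group_a or not group_b:
        raise GroupingError("both groups must be non-empty")
    dm = distance_matrix(aln, model=model)
    vals = [dm.get(a, b) for a in group_a for b in group_b]
    return float(np.mean(vals))


@dataclass
class AmovaResult:
    """One-level AMOVA decomposition with permutation test."""

    n_groups: int
    group_sizes: dict[str, int]
    ssd_total: float
    ssd_among: float
    ssd_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int | None
    negative_component: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_groups", "group_sizes", "ssd_total", "ssd_among", "ssd_within",
            "sigma2_among", "sigma2_within", "pct_among", "pct_within",
            "phi_st", "p_value", "n_permutations", "seed", "negative_component",
        )}


def _amova_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, ...]:
    """Variance components from a squared-distance matrix and group labels."""
    N = d2.shape[0]
    uniq = np.unique(labels)
    G = len(uniq)
    iu = np.triu_indices(N, k=1)
    ssd_total = float(d2[iu].sum()) / N
    ssd_within = 0.0
    sum_ng2 = 0
    for g in uniq:
        idx = np.where(labels == g)[0]
        ng = len(idx)
        sum_ng2 += ng * ng
        if ng > 1:
            sub = d2[np.ix_(idx, idx)]
            ssd_within += float(sub[np.triu_indices(ng, k=1)].sum()) / ng
    ssd_among = ssd_total - ssd_within
    df_within = N - G
    sigma2_w = ssd_within / df_within if df_within > 0 else 0.0
    nbar = (N - sum_ng2 / N) / (G - 1)
    sigma2_a = (ssd_among / (G - 1) - sigma2_w) / nbar
    return ssd_total, ssd_among, ssd_within, sigma2_a, sigma2_w


def amova(aln: AlignmentSet, groups: dict[str, str] | None = None,
          n_permutations: int = 1000, seed: int | None = None) -> AmovaResult:
    """AMOVA on squared pairwise substitution counts.

    ``groups`` maps sequence id → group label (defaults to the labels
    attached to the alignment).  Requires ≥ 2 groups; single-member
    groups are allowed with a warning-free best effort (they contribute
    no within-group pairs).
    """
    group_of = groups or aln.group_of
    if group_of is None:
        raise GroupingError("no group labels supplied")
    labels = np.array([group_of[sid] for sid in aln.ids])
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise GroupingError("AMOVA needs at least two groups")
    dm = distance_matrix(aln, model="differences")
    d2 = dm.matrix ** 2

    ssd_total, ssd_among, ssd_within, s2a, s2w = _amova_components(d2, labels)
    denom = s2a + s2w
    phi = s2a / denom if denom > 0 else 0.0
    pct_among = 100.0 * s2a / denom if denom != 0 else 0.0
    pct_within = 100.0 * s2w / denom if denom != 0 else 0.0

    rng = np.random.default_rng(seed)
    hits = 1  # the observed configuration counts
    for _ in range(n_permutations):
        perm = labels[rng.permutation(len(labels))]
        _, _, _, pa, pw = _amova_components(d2, perm)
        pd_ = pa + pw
        pphi = pa / pd_ if pd_ > 0 else 0.0
        if pphi >= phi - 1e-12:
            hits += 1
    p_value = hits / (n_permutations + 1)

    sizes = {str(g): int(np.count_nonzero(labels == g)) for g in uniq}
    return AmovaResult(
        n_groups=len(uniq),
        group_sizes=sizes,
        ssd_total=ssd_total,
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        sigma2_among=s2a,
        sigma2_within=s2w,
        pct_among=pct_among,
        pct_within=pct_within,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        negative_component=(s2a < 0 or s2w < 0),
    )
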