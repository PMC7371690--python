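"""Distance and parsimony tree inference with bootstrap support.

Neighbor joining follows Saitou & Nei's agglomerative algorithm: the pair
minimizing Q(i,j) = (n−2)·d(i,j) − r_i − r_j is joined, branch lengths
come from the standard three-point formulas, and the matrix is reduced
with d(u,k) = ½(d(i,k) + d(j,k) − d(i,j)).  Ties on Q are broken by the
lexicographically smallest pair of cluster representative labels, making
the output deterministic.

Parsimony scoring uses the Fitch set method (exact for any binary
topology and invariant under rooting); the exhaustive search enumerates
all unrooted binary topologies (3 → 1, 5 → 15, 7 → 945, 9 → 135,135 via
stepwise insertion) and reports every optimal tree.

Bootstrap support is the percentage of site-resampled replicates whose
inferred tree contains each internal bipartition of the point-estimate
tree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genome_model import MitoError
from .comparative_popgen import DistanceMatrix, distance_matrix
from .io_formats import AlignmentSet

__all__ = [
    "InferenceError",
    "nj_tree",
    "fitch_score",
    "mp_search",
    "MpResult",
    "bootstrap",
    "tree_bipartitions",
]


class InferenceError(MitoError):
    """Tree inference cannot proceed on the given input."""


# --- neighbor joining ---------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree; unrooted (trifurcation at the final join)."""
    n = len(dm.ids)
    if n < 3:
        raise InferenceError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes = []
    reps = []  # lexicographic representative (min tip label) per cluster
    for label in dm.ids:
        nd = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(nd)
        reps.append(label)
    D = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        bl_i = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bl_j = D[i, j] - bl_i
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, bl_i)
        nodes[j].edge.length = max(0.0, bl_j)
        # reduce: reuse slot i for the new cluster
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            D[i, k] = D[k, i] = duk
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    center = dendropy.Node()
    bl_a = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    bl_b = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    bl_c = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, bl in ((a, bl_a), (b, bl_b), (c, bl_c)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, bl)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# --- parsimony ----------------------------------------------------------------

_STATE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_FULL = 15  # gap/N: any state


def _site_patterns(aln: AlignmentSet, tips: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Compress alignment columns (restricted to ``tips``) into unique
    patterns of state bitmasks with multiplicities."""
    rows = [aln.row(t) for t in tips]
    patterns = Counter(zip(*rows))
    masks = np.array(
        [[_STATE_BIT.get(ch, _FULL) for ch in col] for col in patterns],
        dtype=np.int64,
    )  # shape (n_patterns, n_tips)
    counts = np.array(list(patterns.values()), dtype=np.int64)
    return masks, counts


def fitch_score(aln: AlignmentSet, tree: dendropy.Tree) -> int:
    """Minimum number of substitutions implied by a tree (Fitch count).

    Handles multifurcating nodes with the unit-cost Sankoff recursion,
    which is exact for any topology; gaps and Ns are free to take any
    state.  Invariant under rooting.
    """
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = set(tips) - set(aln.ids)
    if missing:
        raise InferenceError(f"tree tips absent from alignment: {sorted(missing)}")
    masks, counts = _site_patterns(aln, tips)
    n_pat = masks.shape[0]
    tip_col = {t: k for k, t in enumerate(tips)}
    BIG = 1 << 20
    cost: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            m = masks[:, tip_col[node.taxon.label]]
            c = np.full((n_pat, 4), BIG, dtype=np.int64)
            for s in range(4):
                c[:, s] = np.where((m >> s) & 1, 0, BIG)
            cost[id(node)] = c
        else:
            total = np.zeros((n_pat, 4), dtype=np.int64)
            for child in node.child_nodes():
                cc = cost.pop(id(child))
                mn = cc.min(axis=1, keepdims=True)
                total += np.minimum(cc, mn + 1)
            cost[id(node)] = total
    root_cost = cost[id(tree.seed_node)].min(axis=1)
    return int((root_cost * counts).sum())


def _rooted_topologies(labels: list[str]):
    """All rooted binary trees (nested pairs) over labels, by stepwise insertion."""
    if len(labels) == 1:
        yield labels[0]
        return
    for sub in _rooted_topologies(labels[:-1]):
        yield from _insertions(sub, labels[-1])


def _insertions(tree, x):
    yield (tree, x)
    if isinstance(tree, tuple):
        left, right = tree
        for nl in _insertions(left, x):
            yield (nl, right)
        for nr in _insertions(right, x):
            yield (left, nr)


def _canonical_newick(sub) -> str:
    if isinstance(sub, str):
        return sub
    parts = sorted(_canonical_newick(s) for s in sub)
    return "(" + ",".join(parts) + ")"


def _score_rooted(sub, leaf_masks, counts):
    """Fitch set-method score of a rooted nested-tuple tree, vectorized
    over site patterns with bitmask arrays."""

    def rec(t):
        if isinstance(t, str):
            return leaf_masks[t], 0
        (l, r) = t
        ml, cl = rec(l)
        mr, cr = rec(r)
        inter = ml & mr
        add = (inter == 0).astype(np.int64)
        mask = np.where(add.astype(bool), ml | mr, inter)
        return mask, cl + cr + add

    _, c = rec(sub)
    return int((c * counts).sum())


@dataclass
class MpResult:
    """Maximum-parsimony search result (all optimal topologies retained)."""

    tree: dendropy.Tree
    score: int
    optimal_newicks: list[str] = field(default_factory=list)
    n_topologies_searched: int = 0


def mp_search(aln: AlignmentSet, max_taxa: int = 9) -> MpResult:
    """Exhaustive maximum-parsimony search over unrooted topologies.

    The (2n−5)!! topologies are enumerated by rooting at the first taxon;
    refuse beyond ``max_taxa`` (use neighbor joining there instead).  The
    returned tree is the lexicographically smallest canonical Newick
    among the optimal set.
    """
    labels = sorted(aln.ids)
    n = len(labels)
    if n < 3:
        raise InferenceError("parsimony search needs at least 3 taxa")
    if n > max_taxa:
        raise InferenceError(
            f"{n} taxa exceeds the exhaustive-search limit of {max_taxa}; "
            "use nj_tree for larger problems"
        )
    masks, counts = _site_patterns(aln, labels)
    leaf_masks = {t: masks[:, k] for k, t in enumerate(labels)}
    anchor, rest = labels[0], labels[1:]
    best_score = None
    best: list = []
    searched = 0
    for sub in _rooted_topologies(rest):
        searched += 1
        # root the unrooted tree on the anchor's pendant edge
        s = _score_rooted((sub, anchor), leaf_masks, counts)
        if best_score is None or s < best_score:
            best_score, best = s, [sub]
        elif s == best_score:
            best.append(sub)

    newicks = []
    for sub in best:
        if isinstance(sub, tuple):
            l, r = sub
            parts = sorted([_canonical_newick(l), _canonical_newick(r), anchor])
        else:
            parts = sorted([sub, anchor])
        newicks.append("(" + ",".join(parts) + ");")
    newicks = sorted(set(newicks))
    tree = dendropy.Tree.get(data=newicks[0], schema="newick")
    tree.is_rooted = False
    return MpResult(tree=tree, score=best_score, optimal_newicks=newicks,
                    n_topologies_searched=searched)


# --- bootstrap ----------------------------------------------------------------

def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    tip-label set on the side *not* containing the lexicographically
    smallest tip."""
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = min(all_tips)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(side)
    return out


def _resample_columns(aln: AlignmentSet, rng: np.random.Generator) -> AlignmentSet:
    idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
    rows = ["".join(r[k] for k in idx) for r in aln.rows]
    return AlignmentSet(ids=list(aln.ids), rows=rows, group_of=aln.group_of)


def _infer(aln: AlignmentSet, method: str, model: str) -> dendropy.Tree:
    if method == "nj":
        return nj_tree(distance_matrix(aln, model=model))
    if method == "mp":
        return mp_search(aln).tree
    raise ValueError(f"unknown method {method!r}")


def bootstrap(aln: AlignmentSet, method: str = "nj", n_replicates: int = 100,
              seed: int | None = None, model: str = "p_distance",
              outgroup: str | None = None) -> dendropy.Tree:
    """Point-estimate tree annotated with bootstrap support percentages.

    Support for each internal edge of the point tree is the percentage of
    site-resampled replicates whose inferred tree contains the same
    bipartition; stored on the subtending node's label.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be ≥ 1")
    point = _infer(aln, method, model)
    all_tips = frozenset(leaf.taxon.label for leaf in point.leaf_node_iter())
    anchor = min(all_tips)
    rng = np.random.default_rng(seed)
    tally: Counter = Counter()
    for _ in range(n_replicates):
        rep = _infer(_resample_columns(aln, rng), method, model)
        tally.update(tree_bipartitions(rep))
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            support = 100.0 * tally[side] / n_replicates
            node.label = f"{support:g}"
    if outgroup is not None:
        og = point.find_node_with_taxon_label(outgroup)
        if og is None:
            raise InferenceError(f"outgroup {outgroup!r} not among the tips")
        point.to_outgroup_position(og, update_bipartitions=False)
    return point
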