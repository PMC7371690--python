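"""Neighbor joining, parsimony scoring and search, bootstrap support."""

import itertools

import dendropy
import numpy as np
import pytest

from mitocompare.comparative_popgen import DistanceMatrix, distance_matrix
from mitocompare.io_formats import AlignmentSet, read_newick, write_newick
from mitocompare.phylogeny import (
    InferenceError,
    bootstrap,
    fitch_score,
    mp_search,
    nj_tree,
    tree_bipartitions,
)


def _aln(ids, rows, groups=None):
    return AlignmentSet(ids=list(ids), rows=list(rows), group_of=groups)


def _path_distances(newick: str) -> dict[tuple[str, str], float]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(sorted(tree.taxon_namespace,
                                                key=lambda t: t.label), 2):
        out[(t1.label, t2.label)] = pdm.distance(t1, t2)
    return out


def _matrix_from_newick(newick: str) -> DistanceMatrix:
    pd = _path_distances(newick)
    ids = sorted({x for pair in pd for x in pair})
    m = np.zeros((len(ids), len(ids)))
    for (a, b), d in pd.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(ids=ids, matrix=m, model="p_distance")


class TestNeighborJoining:
    def test_three_taxa_three_point_solution(self):
        dm = DistanceMatrix(ids=["A", "B", "C"],
                            matrix=np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]],
                                            float),
                            model="p_distance")
        t = nj_tree(dm)
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in t.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 4.0})

    @pytest.mark.parametrize("newick", [
        "((A:1,B:2):1,(C:3,D:4):2);",
        "((A:1,B:2):1,((C:1.5,D:2.5):0.5,E:3):1,F:4);",
        "(((A:0.4,B:0.7):0.3,(C:1.1,D:0.2):0.6):0.5,(E:0.9,F:0.8):0.25,G:2.0);",
    ])
    def test_additive_matrix_recovered_exactly(self, newick):
        """NJ on an additive matrix returns the generating tree, topology
        and branch lengths (checked via induced path distances)."""
        dm = _matrix_from_newick(newick)
        t = nj_tree(dm)
        assert tree_bipartitions(t) == tree_bipartitions(read_newick(newick))
        recovered = _path_distances(write_newick(t))
        for pair, d in _path_distances(newick).items():
            assert recovered[pair] == pytest.approx(d, abs=1e-9)

    def test_agrees_with_skbio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        newick = "((A:1,B:2):1,((C:1.5,D:2.5):0.5,E:3):1,F:4);"
        dm = _matrix_from_newick(newick)
        ours = nj_tree(dm)
        sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.ids)
        sk_tree = read_newick(str(skbio.tree.nj(sk_dm)))
        assert tree_bipartitions(ours) == tree_bipartitions(sk_tree)

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(ids=["A", "B"], matrix=np.array([[0, 1], [1, 0]],
                                                            float),
                            model="p_distance")
        with pytest.raises(InferenceError):
            nj_tree(dm)

    def test_study_scale_clades(self):
        """Groups at the study's divergence scale: the mid-divergence group
        nests with the focal group, away from the outgroup clade."""
        from mitocompare.synthetic_data import (SimulationConfig,
                                                generate_genome,
                                                generate_haplotypes)
        cfg = SimulationConfig(
            seed=9,
            groups=[("gaur", 4), ("mithun", 2), ("outgroup", 2)],
            within_group_diffs=33,
            group_divergence_from_base={"gaur": 0, "mithun": 300,
                                        "outgroup": 1500},
        )
        genome, _ = generate_genome(cfg)
        aln, _ = generate_haplotypes(genome, cfg)
        t = nj_tree(distance_matrix(aln))
        bips = tree_bipartitions(t)
        assert frozenset({"outgroup_1", "outgroup_2"}) in bips
        assert frozenset({"mithun_1", "mithun_2"}) in bips


def _bruteforce_fitch(aln: AlignmentSet, tree: dendropy.Tree) -> int:
    """Exhaustive oracle: minimize substitutions over all internal-node
    state assignments, site by site."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    total = 0
    for site in range(aln.n_sites):
        obs = {leaf: aln.row(leaf.taxon.label)[site] for leaf in leaves}
        if any(ch not in "ACGT" for ch in obs.values()):
            allowed = {leaf: ("ACGT" if obs[leaf] not in "ACGT" else obs[leaf])
                       for leaf in leaves}
        else:
            allowed = {leaf: obs[leaf] for leaf in leaves}
        best = None
        for assignment in itertools.product("ACGT", repeat=len(internals)):
            state = dict(zip(internals, assignment))
            cost = 0
            ok = True
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                parent_state = state[nd.parent_node]
                if nd.is_leaf():
                    if all(parent_state != ch for ch in allowed[nd]):
                        cost += 1
                else:
                    cost += parent_state != state[nd]
            if ok and (best is None or cost < best):
                best = cost
        total += best
    return total


class TestFitchScore:
    def test_identical_sequences_score_zero(self):
        aln = _aln("ABCD", ["ACGT"] * 4)
        t = read_newick("((A,B),(C,D));")
        assert fitch_score(aln, t) == 0

    def test_single_congruent_split_costs_one(self):
        aln = _aln("ABCD", ["A", "A", "T", "T"])
        t = read_newick("((A,B),(C,D));")
        assert fitch_score(aln, t) == 1

    def test_matches_exhaustive_oracle_on_random_data(self, rng):
        for _ in range(5):
            rows = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(5)]
            aln = _aln("ABCDE", rows)
            t = read_newick("(((A,B),C),(D,E));")
            assert fitch_score(aln, t) == _bruteforce_fitch(aln, t)

    def test_invariant_under_rerooting(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(5)]
        aln = _aln("ABCDE", rows)
        t = read_newick("(((A,B),C),(D,E));")
        s0 = fitch_score(aln, t)
        node = t.find_node_with_taxon_label("D")
        t.reroot_at_edge(node.edge, update_bipartitions=False)
        assert fitch_score(aln, t) == s0

    def test_missing_tip_rejected(self):
        aln = _aln("AB", ["AC", "AC"])
        with pytest.raises(InferenceError):
            fitch_score(aln, read_newick("((A,B),X);"))


class TestMpSearch:
    def test_three_taxa_single_topology(self):
        res = mp_search(_aln("ABC", ["AA", "AT", "TT"]))
        assert res.n_topologies_searched == 1

    def test_all_identical_everything_ties_at_zero(self):
        res = mp_search(_aln("ABCDE", ["ACGT"] * 5))
        assert res.score == 0
        assert len(res.optimal_newicks) == 15  # all (2·5−5)!! topologies

    def test_recovers_generating_topology_with_ample_signal(self, rng):
        """Sequences simulated on ((A,B),(C,D),E) with clade-specific
        blocks recover that topology uniquely."""
        base = rng.choice(list("ACGT"), size=120)

        def mutate(arr, sites):
            arr = arr.copy()
            for s in sites:
                arr[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[s]]
            return arr

        ab = mutate(base, range(0, 30))
        cd = mutate(base, range(30, 60))
        rows = {
            "A": mutate(ab, [100]), "B": mutate(ab, [101]),
            "C": mutate(cd, [102]), "D": mutate(cd, [103]),
            "E": mutate(base, [104]),
        }
        aln = _aln("ABCDE", ["".join(rows[k]) for k in "ABCDE"])
        res = mp_search(aln)
        assert len(res.optimal_newicks) == 1
        bips = tree_bipartitions(res.tree)
        assert frozenset({"C", "D"}) in bips or frozenset({"A", "B"}) in bips

    def test_search_minimum_bounds_every_topology(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=25)) for _ in range(5)]
        aln = _aln("ABCDE", rows)
        res = mp_search(aln)
        # enumerate all 15 unrooted topologies independently and rescore
        from mitocompare.phylogeny import _rooted_topologies
        for sub in _rooted_topologies(list("BCDE")):
            def nwk(t):
                if isinstance(t, str):
                    return t
                return f"({nwk(t[0])},{nwk(t[1])})"
            tree = read_newick(f"(A,{nwk(sub)});")
            assert res.score <= fitch_score(aln, tree)

    def test_over_limit_refused(self):
        aln = _aln([f"t{i}" for i in range(10)], ["ACGT"] * 10)
        with pytest.raises(InferenceError):
            mp_search(aln, max_taxa=9)


class TestBootstrap:
    def _signal_aln(self, rng):
        base = rng.choice(list("ACGT"), size=400)
        left = base.copy()
        for s in range(0, 60):
            left[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[left[s]]
        rows = {}
        for i, anc in enumerate((left, left, left, base, base, base)):
            hap = anc.copy()
            hap[300 + i] = "A" if hap[300 + i] != "A" else "C"
            rows[f"t{i}"] = "".join(hap)
        return _aln(rows.keys(), rows.values())

    def test_separating_edge_has_high_support(self, rng):
        aln = self._signal_aln(rng)
        t = bootstrap(aln, method="nj", n_replicates=50, seed=5)
        split = frozenset({"t3", "t4", "t5"})
        supports = {}
        all_tips = frozenset(aln.ids)
        anchor = min(all_tips)
        for nd in t.preorder_node_iter():
            if nd is t.seed_node or nd.is_leaf() or nd.label is None:
                continue
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if anchor in side:
                side = all_tips - side
            supports[side] = float(nd.label)
        assert supports[split] >= 95.0

    def test_single_replicate_support_is_binary(self, rng):
        aln = self._signal_aln(rng)
        t = bootstrap(aln, n_replicates=1, seed=2)
        values = [float(nd.label) for nd in t.preorder_node_iter()
                  if nd.label is not None and not nd.is_leaf()]
        assert values and all(v in (0.0, 100.0) for v in values)

    def test_seed_reproducibility(self, rng):
        aln = self._signal_aln(rng)
        t1 = bootstrap(aln, n_replicates=20, seed=11)
        t2 = bootstrap(aln, n_replicates=20, seed=11)
        assert write_newick(t1) == write_newick(t2)
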