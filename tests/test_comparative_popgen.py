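"""Distances, divergence, and AMOVA."""

import itertools
import math

import numpy as np
import pytest

from mitocompare.comparative_popgen import (
    GroupingError,
    UndefinedDistanceError,
    amova,
    distance_matrix,
    group_divergence,
    k2p_distance,
    p_distance,
    pairwise_differences,
)
from mitocompare.io_formats import AlignmentSet


def _aln(*rows, groups=None):
    ids = [f"s{i}" for i in range(len(rows))]
    group_of = None
    if groups is not None:
        group_of = {ids[i]: g for i, g in enumerate(groups)}
    return AlignmentSet(ids=ids, rows=list(rows), group_of=group_of)


class TestPairwiseDifferences:
    def test_identical_rows(self):
        assert pairwise_differences(_aln("ACGT", "ACGT"), 0, 1) == 0

    def test_single_difference(self):
        assert pairwise_differences(_aln("ACGT", "ACGA"), 0, 1) == 1

    def test_gap_and_n_sites_skipped(self):
        assert pairwise_differences(_aln("ACGTA", "-CNTT"), 0, 1) == 1

    def test_planted_substitutions_recovered(self, rng):
        base = rng.choice(list("ACGT"), size=2000)
        for m in (0, 5, 33, 304):
            mutant = base.copy()
            sites = rng.choice(2000, size=m, replace=False)
            for s in sites:
                mutant[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[s]]
            aln = _aln("".join(base), "".join(mutant))
            assert pairwise_differences(aln, 0, 1) == m

    def test_matches_bruteforce_site_loop(self, rng):
        for _ in range(10):
            rows = ["".join(rng.choice(list("ACGTN-"), size=150)) for _ in range(3)]
            aln = _aln(*rows)
            for i, j in itertools.combinations(range(3), 2):
                expected = sum(
                    1 for a, b in zip(rows[i], rows[j])
                    if a in "ACGT" and b in "ACGT" and a != b
                )
                assert pairwise_differences(aln, i, j) == expected


class TestDistances:
    def test_p_distance_example(self):
        aln = _aln("AAAAAAAAAA", "AAAAAAAACC")
        assert p_distance(aln, 0, 1) == pytest.approx(0.2)

    def test_k2p_identity_limit(self):
        aln = _aln("ACGT", "ACGT")
        assert k2p_distance(aln, 0, 1) == 0.0

    def test_k2p_closed_form(self):
        # 20 sites: 2 transitions (A→G), 1 transversion (A→C) → P=0.1, Q=0.05
        x = "A" * 20
        y = "GG" + "C" + "A" * 17
        aln = _aln(x, y)
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert k2p_distance(aln, 0, 1) == pytest.approx(expected)
        assert expected == pytest.approx(0.1702, abs=5e-5)

    def test_k2p_approaches_p_for_small_divergence(self):
        # Q=0, P=0.005 over 1000 sites: agreement within 1%
        x = "A" * 1000
        y = "G" * 5 + "A" * 995
        aln = _aln(x, y)
        p = p_distance(aln, 0, 1)
        d = k2p_distance(aln, 0, 1)
        assert abs(d - p) / p < 0.01

    def test_k2p_domain_violation_is_infinite(self):
        aln = _aln("ACAC" * 5, "GTGT" * 5)  # all transitions, P > 0.5
        assert k2p_distance(aln, 0, 1) == math.inf

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance(_aln("NNNN", "ACGT"), 0, 1)

    def test_complete_deletion_drops_sites_globally(self):
        aln = _aln("ACGT", "ACGA", "ACGN")
        dm_pw = distance_matrix(aln, model="differences")
        dm_cd = distance_matrix(aln, model="differences",
                                site_handling="complete_deletion")
        assert dm_pw.get("s0", "s1") == 1.0
        assert dm_cd.get("s0", "s1") == 0.0  # site 4 removed (N in s2)


class TestGroupDivergence:
    def test_identical_groups_zero(self):
        aln = _aln("ACGT", "ACGT", "ACGT", "ACGT")
        assert group_divergence(aln, ["s0", "s1"], ["s2", "s3"]) == 0.0

    def test_one_vs_one_equals_pairwise(self):
        aln = _aln("AAAAAAAAAA", "AAAAAAAACC")
        assert group_divergence(aln, ["s0"], ["s1"]) == \
            pytest.approx(p_distance(aln, 0, 1))

    def test_recovers_generating_divergence(self):
        from mitocompare.synthetic_data import (SimulationConfig,
                                                generate_genome,
                                                generate_haplotypes)
        cfg = SimulationConfig(seed=3, mutation_mode="poisson")
        genome, _ = generate_genome(cfg)
        aln, manifest = generate_haplotypes(genome, cfg)
        members = aln.groups()
        d = group_divergence(aln, members["indian"], members["cambodian"])
        L = manifest["genome_length"]
        delta = (304 + 33 / 2) / L          # expected between-group p-distance
        se = math.sqrt(delta * (1 - delta) / L)
        assert abs(d - delta) <= 3 * se


class TestAmova:
    def test_fixed_differences_between_internally_identical_groups(self):
        aln = _aln("AAAA", "AAAA", "TTTT", "TTTT",
                   groups=["x", "x", "y", "y"])
        res = amova(aln, n_permutations=99, seed=1)
        assert res.pct_among == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_ssd_decomposition_identity(self, rng):
        for _ in range(10):
            rows = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(8)]
            labels = rng.choice(["x", "y", "z"], size=8)
            if len(set(labels)) < 2:
                continue
            aln = _aln(*rows, groups=labels)
            res = amova(aln, n_permutations=10, seed=0)
            assert res.ssd_among + res.ssd_within == \
                pytest.approx(res.ssd_total, abs=1e-9)

    def test_null_behaviour_on_exchangeable_sequences(self, rng):
        """Random labels on exchangeable rows: p near uniform, Φ near 0."""
        pvals, pcts = [], []
        for k in range(30):
            rows = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(8)]
            aln = _aln(*rows, groups=["x"] * 4 + ["y"] * 4)
            res = amova(aln, n_permutations=99, seed=k)
            pvals.append(res.p_value)
            pcts.append(res.pct_among)
        assert 0.3 < float(np.mean(pvals)) < 0.7
        assert abs(float(np.mean(pcts))) < 15.0

    def test_single_group_rejected(self):
        aln = _aln("ACGT", "ACGA", groups=["x", "x"])
        with pytest.raises(GroupingError):
            amova(aln, n_permutations=10, seed=0)

    def test_seeded_permutation_p_reproducible(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(6)]
        aln = _aln(*rows, groups=["x"] * 3 + ["y"] * 3)
        r1 = amova(aln, n_permutations=200, seed=7)
        r2 = amova(aln, n_permutations=200, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.to_dict() == r2.to_dict()
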