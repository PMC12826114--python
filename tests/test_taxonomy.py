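import itertools

import numpy as np
import pytest

from jumbophage.config import RunConfig
from jumbophage.synthetic import random_protein
from jumbophage.taxonomy import (OrthologueMatrix, build_tree,
                                 demarcate_families, detect_orthologues,
                                 orthologue_analysis,
                                 proteome_self_bit_score, proteomic_distance,
                                 shared_fraction)


@pytest.fixture(scope="module")
def proteome(rng_module):
    return {f"p{i}": random_protein(rng_module, 120, 200) for i in range(10)}


@pytest.fixture(scope="module")
def rng_module():
    return np.random.default_rng(777)


class TestOrthologues:
    def test_identical_proteomes_all_pairs(self, proteome):
        pairs = detect_orthologues(proteome, dict(proteome))
        assert len(pairs) == 10
        assert all(p.identity == 1.0 for p in pairs)

    def test_disjoint_random_proteomes_no_pairs(self, rng_module):
        a = {f"a{i}": random_protein(rng_module) for i in range(8)}
        b = {f"b{i}": random_protein(rng_module) for i in range(8)}
        assert detect_orthologues(a, b) == []

    def test_single_shared_protein(self, rng_module, proteome):
        shared = random_protein(rng_module, 150, 150)
        mutated = list(shared)
        for i in range(0, 150, 31):          # ~95% identity copy
            mutated[i] = "W" if mutated[i] != "W" else "Y"
        a = {"a0": shared,
             "a1": random_protein(rng_module)}
        b = {"b0": "".join(mutated),
             "b1": random_protein(rng_module)}
        pairs = detect_orthologues(a, b)
        assert [(p.id_a, p.id_b) for p in pairs] == [("a0", "b0")]
        assert pairs[0].identity >= 0.95

    def test_shared_fraction_uses_smaller_proteome(self, proteome):
        pairs = detect_orthologues(proteome, dict(proteome))
        big = {f"x{i}": "MW" * 60 for i in range(30)}
        assert shared_fraction(pairs, proteome, {**proteome, **big}) == \
            pytest.approx(1.0)
        assert shared_fraction([], proteome, proteome) == 0.0

    def test_shared_fraction_boundary_tenth(self):
        # 3 RBH pairs over proteomes of 30 and 60 → exactly 0.10
        a = {f"a{i}": "M" * 100 for i in range(30)}
        b = {f"b{i}": "M" * 100 for i in range(60)}

        class P:  # minimal stand-ins; only the count matters
            pass
        pairs = [P(), P(), P()]
        assert shared_fraction(pairs, a, b) == pytest.approx(0.10)


class TestProteomicDistance:
    def test_identical_proteomes_distance_zero(self, proteome, config):
        pairs = detect_orthologues(proteome, dict(proteome))
        s = proteome_self_bit_score(proteome)
        assert proteomic_distance(pairs, s, s) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_proteomes_distance_one(self, proteome):
        s = proteome_self_bit_score(proteome)
        assert proteomic_distance([], s, s) == 1.0

    def test_distance_decreases_with_sharing(self, rng_module):
        base = {f"c{i}": random_protein(rng_module, 150, 250)
                for i in range(10)}
        dists = []
        for n_shared in (2, 5, 8):
            other = {k: v for k, v in list(base.items())[:n_shared]}
            other.update({f"u{i}": random_protein(rng_module)
                          for i in range(10 - n_shared)})
            pairs = detect_orthologues(base, other)
            dists.append(proteomic_distance(
                pairs, proteome_self_bit_score(base),
                proteome_self_bit_score(other)))
        assert dists[0] > dists[1] > dists[2]

    def test_zero_self_score_is_error(self):
        with pytest.raises(ValueError):
            proteomic_distance([], 0.0, 10.0)


def _random_additive_matrix(rng, n):
    """Patristic matrix of a random binary tree with positive lengths."""
    nodes = {i: [(i, 0.0)] for i in range(n)}   # node → [(leaf, dist)]
    next_id = n
    dist = np.zeros((n, n))
    while len(nodes) > 1:
        a, b = rng.choice(list(nodes), size=2, replace=False)
        la, lb = rng.uniform(0.1, 2.0, size=2)
        for leaf_i, di in nodes[a]:
            for leaf_j, dj in nodes[b]:
                d = di + la + dj + lb
                dist[leaf_i, leaf_j] = dist[leaf_j, leaf_i] = d
        nodes[next_id] = [(l, d + la) for l, d in nodes[a]] + \
                         [(l, d + lb) for l, d in nodes[b]]
        del nodes[a], nodes[b]
        next_id += 1
    return dist


class TestNeighbourJoining:
    def test_three_taxon_closed_form(self):
        # d(A,B)=2, d(A,C)=d(B,C)=6 → branch lengths (1, 1, 5)
        dm = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        tree = build_tree(dm, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 5.0})

    def test_additive_four_taxon_patristic_exact(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) → known pairwise distances
        dm = np.array([[0, 3, 8, 9],
                       [3, 0, 9, 10],
                       [8, 9, 0, 9],
                       [9, 10, 9, 0]], dtype=float)
        tree = build_tree(dm, list("ABCD"))
        assert np.allclose(tree.patristic_matrix(), dm, atol=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_random_additive_matrices_reproduced(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            dm = _random_additive_matrix(rng, n)
            tree = build_tree(dm, [f"t{i}" for i in range(n)])
            assert np.allclose(tree.patristic_matrix(), dm, atol=1e-9)

    def test_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            build_tree(np.zeros((2, 2)), ["A", "B"])


def _matrix(ids, frac):
    n = len(ids)
    m = np.asarray(frac, dtype=float)
    return OrthologueMatrix(list(ids), m, (m * 10).astype(int))


class TestFamilyDemarcation:
    def test_planted_families_recovered(self, config):
        from jumbophage.synthetic import generate_proteome_families
        proteomes, truth = generate_proteome_families(
            [3, 3], within=0.6, between=0.0, seed=9, n_proteins=20,
            config=config)
        om, dist = orthologue_analysis(proteomes, config)
        tree = build_tree(dist, om.genome_ids)
        fam = demarcate_families(tree, om, config)
        expected = {}
        for g, f in truth.family_planted.items():
            expected.setdefault(f, set()).add(g)
        assert {frozenset(v) for v in fam.families.values()} == \
            {frozenset(v) for v in expected.values()}

    def test_identical_genomes_one_family(self):
        ids = list("ABC")
        om = _matrix(ids, np.ones((3, 3)))
        tree = build_tree(np.zeros((3, 3)), ids)
        fam = demarcate_families(tree, om)
        assert len(fam.families) == 1

    def test_shared_fraction_exactly_tenth_keeps_together(self):
        # distinctness needs sharing < 10%; exactly 0.10 stays together
        ids = list("ABC")
        frac = np.array([[1.0, 0.10, 0.0],
                         [0.10, 1.0, 0.0],
                         [0.0, 0.0, 1.0]])
        dm = np.array([[0, 1.0, 1.0], [1.0, 0, 1.0], [1.0, 1.0, 0]])
        fam = demarcate_families(build_tree(dm, ids), _matrix(ids, frac))
        assert fam.genome_to_family["A"] == fam.genome_to_family["B"]
        assert fam.genome_to_family["C"] != fam.genome_to_family["A"]

    def test_label_is_lexicographically_smallest_member(self):
        ids = ["zeta", "alpha", "mid"]
        om = _matrix(ids, np.ones((3, 3)))
        fam = demarcate_families(build_tree(np.zeros((3, 3)), ids), om)
        assert list(fam.families) == ["alpha"]

    def test_family_count_monotone_in_sharing_threshold(self, config):
        ids = list("ABCD")
        rng = np.random.default_rng(3)
        frac = np.eye(4)
        for i, j in itertools.combinations(range(4), 2):
            frac[i, j] = frac[j, i] = rng.uniform(0, 0.4)
        dm = 1.0 - frac
        np.fill_diagonal(dm, 0.0)
        tree = build_tree(dm, ids)
        counts = []
        for thr in (0.4, 0.3, 0.2, 0.1, 0.05):
            cfg = config.replace(family_shared_max=thr)
            counts.append(len(demarcate_families(tree, _matrix(ids, frac),
                                                 cfg).families))
        assert counts == sorted(counts, reverse=True)

    def test_input_order_invariance(self, config):
        ids = list("ABCD")
        frac = np.eye(4)
        frac[0, 1] = frac[1, 0] = 0.5
        frac[2, 3] = frac[3, 2] = 0.5
        dm = 1.0 - frac
        np.fill_diagonal(dm, 0.0)
        f1 = demarcate_families(build_tree(dm, ids), _matrix(ids, frac))
        perm = [3, 1, 0, 2]
        ids2 = [ids[i] for i in perm]
        frac2 = frac[np.ix_(perm, perm)]
        dm2 = dm[np.ix_(perm, perm)]
        f2 = demarcate_families(build_tree(dm2, ids2), _matrix(ids2, frac2))
        assert f1.genome_to_family == f2.genome_to_family
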