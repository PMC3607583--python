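"""Signed permutations, breakpoints, and exact inversion distances."""

import numpy as np
import pytest

from rhodoplast.synteny import (
    SignedPermutation,
    SyntenyError,
    apply_reversal,
    breakpoint_count,
    collapse_adjacencies,
    conserved_cluster_count,
    encode_permutation,
    inversion_distance,
    inversion_scenario,
)

from conftest import bfs_reversal_distances, make_record


def random_signed_permutation(rng, n):
    perm = rng.permutation(n) + 1
    signs = rng.choice([-1, 1], n)
    return SignedPermutation(tuple(int(p * s) for p, s in zip(perm, signs)))


class TestEncode:
    def test_direct_transcription(self):
        ref = make_record("ref", [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+")])
        qry = make_record("qry", [("a", "+"), ("c", "-"), ("b", "-"), ("d", "+")])
        assert encode_permutation(ref, qry).elements == (1, -3, -2, 4)

    def test_identity_for_identical_genomes(self):
        ref = make_record("ref", [("a", "+"), ("b", "-"), ("c", "+")])
        qry = make_record("qry", [("a", "+"), ("b", "-"), ("c", "+")])
        assert encode_permutation(ref, qry).is_identity()

    def test_absent_gene_is_excluded(self):
        ref = make_record("ref", [("a", "+"), ("e", "+"), ("b", "+")])
        qry = make_record("qry", [("a", "+"), ("b", "+")])
        perm = encode_permutation(ref, qry)
        assert perm.n == 2
        assert "e" not in perm.gene_labels.values()

    def test_multicopy_and_orfs_dropped(self):
        ref = make_record("ref", [("a", "+"), ("dup", "+"), ("dup", "+"), ("orf1", "+"), ("b", "+")])
        qry = make_record("qry", [("a", "+"), ("dup", "+"), ("b", "+"), ("orf1", "+")])
        perm = encode_permutation(ref, qry)
        assert set(perm.gene_labels.values()) == {"a", "b"}

    def test_no_shared_genes_is_error(self):
        ref = make_record("ref", [("a", "+")])
        qry = make_record("qry", [("b", "+")])
        with pytest.raises(SyntenyError):
            encode_permutation(ref, qry)

    def test_circular_linearized_at_anchor(self):
        # same circular order, different rotation and flipped reading
        ref = make_record("ref", [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+")])
        qry = make_record("qry", [("c", "-"), ("b", "-"), ("a", "-"), ("d", "-")])
        perm = encode_permutation(ref, qry)
        assert perm.is_identity()


class TestCollapse:
    def test_derived_example(self):
        perm = SignedPermutation((1, -3, -2, 4))
        assert collapse_adjacencies(perm).elements == (1, -2, 3)

    @pytest.mark.parametrize("n", [1, 2, 5, 9])
    def test_identity_collapses_to_single_block(self, n):
        perm = SignedPermutation(tuple(range(1, n + 1)))
        assert collapse_adjacencies(perm).elements == (1,)

    def test_nothing_collapsible(self):
        perm = SignedPermutation((2, 1))
        assert collapse_adjacencies(perm).elements == (2, 1)

    def test_never_changes_distance(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            perm = random_signed_permutation(rng, 6)
            assert inversion_distance(perm) == inversion_distance(
                collapse_adjacencies(perm)
            )


class TestBreakpoints:
    @pytest.mark.parametrize(
        "elements,expected",
        [((1, 2, 3), 0), ((2, 1), 3), ((-1,), 2), ((1, -3, -2, 4), 2)],
    )
    def test_examples(self, elements, expected):
        assert breakpoint_count(SignedPermutation(elements)) == expected


class TestInversionDistance:
    @pytest.mark.parametrize(
        "elements,expected",
        [((1, 2, 3, 4), 0), ((-1,), 1), ((2, 1), 3), ((1, -3, -2, 4), 1)],
    )
    def test_examples(self, elements, expected):
        assert inversion_distance(SignedPermutation(elements)) == expected

    def test_matches_bfs_oracle_small(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(1, 6))
            perm = random_signed_permutation(rng, n)
            oracle = bfs_reversal_distances(n)[perm.elements]
            assert inversion_distance(perm) == oracle

    def test_distance_of_inverse_is_equal(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            perm = random_signed_permutation(rng, 6)
            assert inversion_distance(perm) == inversion_distance(perm.inverse())

    def test_breakpoint_bounds(self):
        rng = np.random.default_rng(29)
        for _ in range(25):
            perm = random_signed_permutation(rng, 6)
            b = breakpoint_count(perm)
            d = inversion_distance(perm)
            assert b / 2 <= d <= b

    def test_planted_scenario_upper_bound(self):
        rng = np.random.default_rng(31)
        hits = 0
        trials = 30
        for _ in range(trials):
            n, k = 12, 3
            elements = tuple(range(1, n + 1))
            for _ in range(k):
                i = int(rng.integers(0, n))
                j = int(rng.integers(i, n))
                elements = apply_reversal(elements, i, j)
            perm = SignedPermutation(elements)
            d = inversion_distance(perm)
            assert d <= k
            hits += d == k
        # equality should be the common case for few reversals on many genes
        assert hits / trials > 0.5

    def test_guard_refuses_large_inputs(self):
        rng = np.random.default_rng(3)
        perm = random_signed_permutation(rng, 30)
        with pytest.raises(SyntenyError):
            inversion_distance(perm, max_blocks=25)


class TestScenario:
    def test_distance_one_case(self):
        scen = inversion_scenario(SignedPermutation((1, -3, -2, 4)))
        assert scen.distance == 1
        assert scen.reversals == ((1, 2),)

    def test_identity_is_empty(self):
        assert inversion_scenario(SignedPermutation((1, 2, 3))).reversals == ()

    def test_replay_reaches_identity(self):
        rng = np.random.default_rng(41)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            perm = random_signed_permutation(rng, n)
            scen = inversion_scenario(perm)
            elements = perm.elements
            for i, j in scen.reversals:
                elements = apply_reversal(elements, i, j)
            assert elements == tuple(range(1, n + 1))
            assert scen.distance == inversion_distance(perm)

    def test_deterministic_output(self):
        perm = SignedPermutation((3, -1, 2))
        assert inversion_scenario(perm).reversals == inversion_scenario(perm).reversals


class TestConservedClusters:
    def test_identical_genomes_single_cluster(self):
        a = make_record("a", [("x", "+"), ("y", "+"), ("z", "-")])
        b = make_record("b", [("x", "+"), ("y", "+"), ("z", "-")])
        assert conserved_cluster_count([a, b]) == 1

    def test_pairwise_equals_collapsed_blocks(self):
        ref = make_record("ref", [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+")])
        qry = make_record("qry", [("a", "+"), ("c", "-"), ("b", "-"), ("d", "+")])
        assert conserved_cluster_count([ref, qry]) == 3

    def test_monotone_under_added_genomes(self):
        ref = make_record("r1", [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+")])
        qry = make_record("r2", [("a", "+"), ("c", "-"), ("b", "-"), ("d", "+")])
        third = make_record("r3", [("a", "+"), ("b", "+"), ("d", "-"), ("c", "+")])
        pair = conserved_cluster_count([ref, qry])
        triple = conserved_cluster_count([ref, qry, third])
        assert triple >= pair
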