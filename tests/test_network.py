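"""Network-metric unit and property tests.

Expected values for the normalized entropy indices come from closed forms
(identity / uniform matrices) or exhaustive enumeration of integer
matrices with the observed marginals; strength and closeness examples are
hand arithmetic.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pollennet import (
    BipartiteNetwork,
    build_network,
    chao1_completeness,
    closeness_centrality,
    d_prime,
    h2_prime,
    links_per_species,
    species_strength,
)
from pollennet.enumeration import (
    d_min_exhaustive,
    iter_marginal_pairs,
    min_entropy_exhaustive,
)
from pollennet.network import min_entropy_given_marginals


def net_from(matrix, plants=None, pollinators=None):
    m = np.asarray(matrix, dtype=float)
    plants = plants or tuple(f"p{i}" for i in range(m.shape[0]))
    pollinators = pollinators or tuple(f"q{j}" for j in range(m.shape[1]))
    return BipartiteNetwork(m, tuple(plants), tuple(pollinators))


class TestBuildNetwork:
    def test_duplicate_edges_sum(self):
        net = build_network([("A", "X", 1), ("A", "X", 2), ("B", "Y", 1)])
        assert net.n_links == 2
        assert net.matrix[net.plants.index("A"), net.pollinators.index("X")] == 3
        assert net.total == 4

    def test_binarize(self):
        net = build_network([("A", "X", 3), ("B", "Y", 1)], binarize=True)
        assert net.total == 2
        assert set(net.matrix.ravel()) <= {0.0, 1.0}

    def test_empty_edge_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_network([])

    @pytest.mark.parametrize(
        "matrix, expected",
        [([[1, 0], [0, 1]], 0.5), ([[1, 1, 1]] * 3, 1.5)],
    )
    def test_links_per_species(self, matrix, expected):
        assert links_per_species(net_from(matrix)) == expected


class TestH2Prime:
    def test_perfect_specialization(self):
        res = h2_prime(net_from([[2, 0], [0, 2]]))
        assert res.observed == pytest.approx(math.log(2))
        assert res.maximum == pytest.approx(math.log(4))
        assert res.minimum == pytest.approx(math.log(2))
        assert res.h2_prime == pytest.approx(1.0)

    def test_marginal_independence_is_zero(self):
        res = h2_prime(net_from([[1, 1], [1, 1]]))
        assert res.observed == pytest.approx(math.log(4))
        assert res.h2_prime == pytest.approx(0.0, abs=1e-12)

    def test_m2110_matches_enumeration(self):
        # exhaustive minimum over marginals (3,1)/(3,1) is [[3,0],[0,1]]
        res = h2_prime(net_from([[2, 1], [1, 0]]))
        assert res.minimum == pytest.approx(0.5623351446, abs=1e-9)
        assert res.observed == pytest.approx(1.0397207708, abs=1e-9)
        assert res.maximum == pytest.approx(1.1246702892, abs=1e-9)
        assert res.h2_prime == pytest.approx(0.1511, abs=1e-4)

    def test_ordering_invariant(self):
        res = h2_prime(net_from([[4, 1, 0], [1, 2, 1], [0, 1, 4]]))
        assert res.minimum <= res.observed <= res.maximum + 1e-12
        assert 0.0 <= res.h2_prime <= 1.0

    @given(st.integers(2, 4), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance(self, n, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 4, size=(n, n))
        if mat.sum() == 0:
            mat[0, 0] = 1
        base = h2_prime(net_from(mat))
        perm = mat[rng.permutation(n)][:, rng.permutation(n)]
        shuffled = h2_prime(net_from(perm))
        assert shuffled.h2_prime == pytest.approx(base.h2_prime, abs=1e-9)


class TestMinEntropyOracle:
    def test_small_family_subset(self):
        # the full family (marginals <= 6, total <= 12) runs in the
        # acceptance suite; keep a fast spot-check here, including the
        # counterexamples where a pure concentration greedy is suboptimal
        for r, c in list(iter_marginal_pairs(8, 4)) + [
            ((4, 3), (3, 2, 2)),
            ((6, 5, 1), (4, 3, 3, 2)),
        ]:
            assert min_entropy_given_marginals(r, c) == pytest.approx(
                min_entropy_exhaustive(r, c), abs=1e-9
            ), (r, c)


class TestDPrime:
    def test_proportional_use_is_zero(self):
        # species using partners in proportion to availability has d = 0
        res = d_prime(net_from([[2, 1], [2, 1]]), continuous_dmin=True)
        assert res.loc["p0", "d"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["p0", "d_prime"] == 0.0

    def test_identity_fully_specialized(self):
        res = d_prime(net_from([[2, 0], [0, 2]]))
        assert res["d_prime"].tolist() == pytest.approx([1.0, 1.0])
        assert res["d"].tolist() == pytest.approx([math.log(2)] * 2)
        assert res["d_max"].tolist() == pytest.approx([math.log(2)] * 2)
        assert res["d_min"].tolist() == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_heuristic_dmin_matches_enumeration(self):
        mat = np.array([[4, 1, 0], [1, 2, 1], [0, 1, 4]])
        net = net_from(mat)
        res = d_prime(net)
        m = mat.sum()
        q = mat.sum(axis=0) / m
        for i, sp in enumerate(net.plants):
            assert res.loc[sp, "d_min"] == pytest.approx(
                d_min_exhaustive(int(mat[i].sum()), q), abs=1e-9
            )
            assert 0.0 <= res.loc[sp, "d_prime"] <= 1.0

    def test_zero_species_omitted(self):
        net = net_from([[2, 0], [0, 0], [0, 2]])
        res = d_prime(net)
        assert "p1" not in res.index


class TestSpeciesStrength:
    def test_hand_example(self):
        s = species_strength(net_from([[1, 1], [0, 1]]))
        assert s["p0"] == pytest.approx(1.5)
        assert s["p1"] == pytest.approx(0.5)

    def test_identity_all_ones(self):
        s = species_strength(net_from(np.eye(4)))
        assert s.tolist() == pytest.approx([1.0] * 4)

    @given(st.integers(2, 5), st.integers(2, 5), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, n_p, n_q, seed):
        # plant strengths sum to the number of (visited) pollinator species
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 5, size=(n_p, n_q)).astype(float)
        mat[0] += 1  # ensure every column positive
        mat[:, 0] += 1  # and every row positive (no absent species)
        net = net_from(mat)
        assert species_strength(net, "plants").sum() == pytest.approx(n_q, abs=1e-9)
        assert species_strength(net, "pollinators").sum() == pytest.approx(n_p, abs=1e-9)


class TestCloseness:
    def test_complete_2x2(self):
        res = closeness_centrality(net_from([[1, 1], [1, 1]]))
        # plant node: distances 1, 1 to pollinators and 2 to the other plant
        assert res["closeness"].tolist() == pytest.approx([0.75] * 4)

    def test_path_center(self):
        res = closeness_centrality(net_from([[1], [1]]))
        poll = res[res["mode"] == "pollinator"]["closeness"].iloc[0]
        assert poll == pytest.approx(1.0)

    def test_isolated_node_zero(self):
        net = net_from([[1, 1], [0, 0]])  # p1 isolated
        res = closeness_centrality(net).set_index("species")
        assert res.loc["p1", "closeness"] == 0.0
        assert (res["closeness"] <= 1.0).all()

    def test_harmonic_on_complete_bipartite(self):
        net = net_from([[1, 1], [1, 1]])
        res = closeness_centrality(net, variant="harmonic")
        # distances (1, 1, 2): harmonic = (1 + 1 + 1/2) / 3
        assert res["closeness"].tolist() == pytest.approx([2.5 / 3] * 4)


class TestChao1:
    def test_no_singletons_complete(self):
        res = chao1_completeness([3, 5, 2, 4], variant="classic")
        assert res.f1 == 0
        assert res.completeness == pytest.approx(100.0)

    def test_classic_hand_formula(self):
        # S_obs = 10, f1 = 4, f2 = 2 -> 10 + 16 / 4 = 14
        res = chao1_completeness([1, 1, 1, 1, 2, 2, 3, 3, 3, 3], variant="classic")
        assert (res.s_obs, res.f1, res.f2) == (10, 4, 2)
        assert res.estimate == pytest.approx(14.0)
        assert res.completeness == pytest.approx(100 * 10 / 14, abs=1e-9)

    def test_all_abundant_both_variants(self):
        for variant in ("classic", "bias_corrected"):
            res = chao1_completeness([3, 4, 5], variant=variant)
            assert res.completeness == pytest.approx(100.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chao1_completeness([0, 0])
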