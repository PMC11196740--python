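"""Null-network construction and modularity matrices B = A - P."""

import numpy as np
import pytest

from multifacet import (
    DegenerateNullError,
    EmptyLayerError,
    Layer,
    MultifacetError,
    MultiplexNetwork,
    NonBinaryLayerError,
    build_modularity_matrix,
    complement_binary,
    configuration_null,
    exclusion_matrix,
    inclusion_matrix,
    merge_layers,
    multi_matrix,
    normalize_null,
)

from conftest import random_multiplex


def _cycle4():
    """Undirected 4-cycle stored symmetrically: L = 8, every k_i(in+out) = 4."""
    w = np.zeros((4, 4))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
        w[i, j] = w[j, i] = 1.0
    return Layer("cycle", ("a", "b", "c", "d"), w)


class TestConfigurationNull:
    def test_cycle_reproduces_classic_newman_girvan(self):
        # classic k_i k_j / 2m with undirected degree 2 and m = 4: P_ij = 0.5
        Bm = configuration_null(_cycle4(), degree_mode="as_printed")
        np.testing.assert_allclose(Bm.P, 0.5)
        assert Bm.L == 8.0

    def test_single_edge_graph_has_zero_modularity_together(self):
        # both endpoints in one community: B_uv = 0.5, B_uu = -0.5 -> Q = 0
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 1.0
        Bm = configuration_null(Layer("e", ("u", "v"), w))
        assert Bm.B[0, 1] == pytest.approx(0.5)
        assert Bm.B.sum() == pytest.approx(0.0)

    @pytest.mark.parametrize("degree_mode", ["as_printed", "directed"])
    def test_null_mass_equals_observed_mass(self, rng, degree_mode):
        M = random_multiplex(rng, n=9)
        Bm = configuration_null(M.layer("l1"), degree_mode=degree_mode)
        assert Bm.P.sum() == pytest.approx(Bm.L, rel=1e-12)

    def test_directed_mode_uses_out_in_strengths(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[0, 2] = w[1, 2] = 1.0
        Bm = configuration_null(Layer("t", ("a", "b", "c"), w), degree_mode="directed")
        # P_ij = k_i^out k_j^in / L; node a: out 2, in 0
        assert Bm.P[0, 2] == pytest.approx(2 * 2 / 3)
        assert Bm.P[2, 0] == pytest.approx(0.0)

    def test_zero_weight_layer_rejected(self):
        with pytest.raises(EmptyLayerError):
            configuration_null(Layer("z", ("a", "b"), np.zeros((2, 2))))


class TestNormalizeNull:
    def test_already_balanced_null_is_unchanged(self, rng):
        P = rng.uniform(0, 1, (5, 5))
        np.fill_diagonal(P, 0.0)
        P *= 8.0 / P.sum()
        np.testing.assert_allclose(normalize_null(P, 8.0, 1.0), P)

    def test_denser_null_scaled_down_to_observed_mass(self):
        # 440-edge null against a 305-edge observed layer: unit edges -> 305/440
        P = np.zeros((30, 30))
        idx = np.unravel_index(np.arange(440), (30, 30))
        P[idx] = 1.0
        np.fill_diagonal(P, 0.0)
        scaled = normalize_null(P, 305.0, 1.0)
        nz = scaled[P > 0]
        np.testing.assert_allclose(nz, 305.0 / P.sum())
        assert scaled.sum() == pytest.approx(305.0)

    def test_gamma_zero_disables_null(self, rng):
        P = rng.uniform(0, 1, (4, 4))
        np.testing.assert_array_equal(normalize_null(P, 5.0, 0.0), np.zeros((4, 4)))

    def test_empty_null_rejected(self):
        with pytest.raises(DegenerateNullError):
            normalize_null(np.zeros((3, 3)), 5.0, 1.0)


class TestExclusionMatrix:
    def test_equal_density_binary_layers_give_table_of_cases(self):
        # same-density layers at gamma=1: P entries are 0/1, so B is
        # 0 (overlap), +1 (observed only), -1 (null only), 0 (neither)
        nodes = ("a", "b", "c")
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 2] = 1.0
        N = np.zeros((3, 3))
        N[0, 1] = N[2, 0] = 1.0
        M = MultiplexNetwork.from_layers(
            [Layer("obs", nodes, A), Layer("null", nodes, N)]
        )
        B = exclusion_matrix(M, "obs", "null", 1.0).B
        assert B[0, 1] == pytest.approx(0.0)  # no connectivity surplus
        assert B[1, 2] == pytest.approx(1.0)  # surplus in the observed layer
        assert B[2, 0] == pytest.approx(-1.0)  # connectivity deficit
        assert B[1, 0] == pytest.approx(0.0)  # irrelevant pair

    def test_gamma_zero_returns_observed_adjacency(self, rng):
        M = random_multiplex(rng)
        Bm = exclusion_matrix(M, "l1", "l2", 0.0)
        np.testing.assert_array_equal(Bm.B, M.layer("l1").weights)

    def test_matches_elementwise_oracle(self, rng):
        M = random_multiplex(rng, n=6)
        gamma = 1.5
        Bm = exclusion_matrix(M, "l1", "l2", gamma)
        A = M.layer("l1").weights
        N = M.layer("l2").weights
        s = gamma * A.sum() / N.sum()
        expected = np.array(
            [[A[i, j] - s * N[i, j] for j in range(6)] for i in range(6)]
        )
        np.testing.assert_allclose(Bm.B, expected)

    def test_observed_equals_null_rejected(self, rng):
        with pytest.raises(MultifacetError):
            exclusion_matrix(random_multiplex(rng), "l1", "l1", 1.0)


class TestInclusionMatrix:
    def test_overlapping_pair_is_not_penalized(self, rng):
        M = random_multiplex(rng, n=8)
        Bm = inclusion_matrix(M, "l1", "l2", 1.0)
        A = M.layer("l1").weights
        N = M.layer("l2").weights
        both = (A == 1) & (N == 1)
        if both.any():
            np.testing.assert_allclose(Bm.B[both], A[both])

    def test_non_overlapping_edge_penalized_by_scaled_unit(self, rng):
        M = random_multiplex(rng, n=8)
        gamma = 1.0
        Bm = inclusion_matrix(M, "l1", "l2", gamma)
        A = M.layer("l1").weights
        comp = complement_binary(M.layer("l2")).weights
        s = gamma * A.sum() / comp.sum()
        only_obs = (A == 1) & (comp == 1)
        np.testing.assert_allclose(Bm.B[only_obs], 1.0 - s)

    def test_dense_null_matches_elementwise_oracle(self):
        nodes = tuple("abcde")
        rng = np.random.default_rng(5)
        A = (rng.random((5, 5)) < 0.4).astype(float)
        np.fill_diagonal(A, 0.0)
        A[0, 1] = 1.0
        N = np.ones((5, 5)) - np.eye(5)
        N[0, 1] = 0.0  # complement nearly empty but not quite
        M = MultiplexNetwork.from_layers(
            [Layer("obs", nodes, A), Layer("null", nodes, N)]
        )
        Bm = inclusion_matrix(M, "obs", "null", 1.0)
        comp = 1.0 - N
        np.fill_diagonal(comp, 0.0)
        s = A.sum() / comp.sum()
        np.testing.assert_allclose(Bm.B, A - s * comp)

    def test_weighted_null_layer_redirected_to_multi(self, rng):
        M = random_multiplex(rng, n=5)
        weighted = Layer("w", M.nodes, 2.0 * M.layer("l1").weights)
        M2 = MultiplexNetwork.from_layers([M.layer("l1"), M.layer("l2"), weighted])
        with pytest.raises(NonBinaryLayerError, match="multi"):
            inclusion_matrix(M2, "l1", "w", 1.0)


class TestMultiMatrix:
    def test_saturated_null_merge_surfaces_degenerate_error(self):
        nodes = ("a", "b", "c")
        w = np.ones((3, 3)) - np.eye(3)
        M = MultiplexNetwork.from_layers(
            [Layer("l1", nodes, w), Layer("l2", nodes, w)]
        )
        with pytest.raises(DegenerateNullError):
            multi_matrix(M, ["l1", "l2"], ["l1", "l2"], 1.0)

    def test_single_binary_null_consistent_with_inclusion_on_merged(self, rng):
        M = random_multiplex(rng, n=7, n_layers=3)
        Bm_multi = multi_matrix(M, ["l1", "l2", "l3"], ["l2"], 1.0)
        merged = merge_layers(M, ["l1", "l2", "l3"])
        merged = Layer("merged", merged.node_order, merged.weights)
        M2 = MultiplexNetwork.from_layers([merged, M.layer("l2")])
        Bm_incl = inclusion_matrix(M2, "merged", "l2", 1.0)
        np.testing.assert_allclose(Bm_multi.B, Bm_incl.B)

    def test_matches_elementwise_oracle(self, rng):
        M = random_multiplex(rng, n=8, n_layers=3)
        gamma = 2.0
        Bm = multi_matrix(M, ["l1", "l2", "l3"], ["l1", "l3"], gamma)
        A = sum(M.layer(l).weights for l in ("l1", "l2", "l3"))
        Anull = M.layer("l1").weights + M.layer("l3").weights
        comp = Anull.max() - Anull
        np.fill_diagonal(comp, 0.0)
        s = gamma * A.sum() / comp.sum()
        np.testing.assert_allclose(Bm.B, A - s * comp)

    def test_null_must_be_subset_of_observed(self, rng):
        M = random_multiplex(rng, n_layers=3)
        with pytest.raises(MultifacetError, match="subset"):
            multi_matrix(M, ["l1", "l2"], ["l3"], 1.0)

    def test_empty_lists_rejected(self, rng):
        with pytest.raises(MultifacetError):
            multi_matrix(random_multiplex(rng), [], [], 1.0)


class TestMatrixProperties:
    @pytest.mark.parametrize("gamma", [0.5, 1.0, 2.0])
    def test_null_mass_is_gamma_times_observed(self, rng, gamma):
        M = random_multiplex(rng, n=9, n_layers=3)
        for Bm in (
            exclusion_matrix(M, "l1", "l2", gamma),
            inclusion_matrix(M, "l1", "l2", gamma),
            multi_matrix(M, ["l1", "l2", "l3"], ["l2"], gamma),
        ):
            assert abs(Bm.P.sum() - gamma * Bm.L) <= 1e-9 * Bm.L

    def test_gamma_affine_in_null_strength(self, rng):
        M = random_multiplex(rng, n=8)
        B1 = exclusion_matrix(M, "l1", "l2", 1.0)
        for gamma in (0.0, 0.7, 2.5):
            Bg = exclusion_matrix(M, "l1", "l2", gamma)
            expected = B1.A - gamma * (B1.A - B1.B)
            np.testing.assert_allclose(Bg.B, expected, atol=1e-12)

    def test_exclusion_and_inclusion_nulls_cover_all_pairs(self, rng):
        # binary layers: the two nulls' supports are complementary and their
        # union is exactly the full off-diagonal
        M = random_multiplex(rng, n=8)
        P_ex = exclusion_matrix(M, "l1", "l2", 1.0).P
        P_in = inclusion_matrix(M, "l1", "l2", 1.0).P
        off = ~np.eye(8, dtype=bool)
        assert not np.any((P_ex > 0) & (P_in > 0))
        np.testing.assert_array_equal((P_ex + P_in > 0)[off], np.ones(56, dtype=bool))


class TestBuildDispatch:
    def test_ng_merges_observed_layers(self, rng):
        M = random_multiplex(rng, n_layers=2)
        Bm = build_modularity_matrix(M, "ng", ["l1", "l2"])
        assert Bm.mode == "ng"
        assert Bm.L == pytest.approx(
            M.layer("l1").weights.sum() + M.layer("l2").weights.sum()
        )

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(MultifacetError, match="unknown mode"):
            build_modularity_matrix(random_multiplex(rng), "bogus", ["l1"])
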