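import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
import hypothesis.extra.numpy as hnp

from netlayers import (
    allegiance_matrix,
    coefficient_table,
    cooccurrence,
    integration,
    recruitment,
    summarize_by_network,
)
from oracle_utils import toy_atlas


class TestCooccurrence:
    def test_single_community_all_ones(self):
        m = cooccurrence(np.array([3, 3, 3, 3])).values
        assert np.all(m == 1)

    def test_singletons_identity(self):
        m = cooccurrence(np.array([0, 1, 2])).values
        np.testing.assert_array_equal(m, np.eye(3, dtype=np.int8))

    def test_partial_sharing(self):
        m = cooccurrence(np.array([1, 1, 2])).values
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        np.testing.assert_array_equal(m, expected)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cooccurrence(np.array([1.0, np.nan, 2.0]))


class TestAllegianceMatrix:
    def test_identical_layers_give_binary_entries(self):
        labels = np.tile(np.array([[0], [0], [1]]), (1, 5))
        P = allegiance_matrix(labels).values
        assert set(np.unique(P)) <= {0.0, 1.0}

    def test_fraction_of_layers(self):
        labels = np.array([[0, 0], [0, 1]])  # together in 1 of 2 layers
        P = allegiance_matrix(labels).values
        assert P[0, 1] == 0.5

    def test_toy_switching_node(self):
        """9 nodes, 3 planted communities, 3 layers; node 0 defects to the
        second community in one layer: its allegiance to old partners is 2/3."""
        base = np.repeat([0, 1, 2], 3)
        layers = np.tile(base[:, None], (1, 3))
        layers[0, 2] = 1  # node 0 switches once
        P = allegiance_matrix(layers).values
        assert P[0, 1] == pytest.approx(2 / 3)
        assert P[0, 2] == pytest.approx(2 / 3)
        assert P[0, 3] == pytest.approx(1 / 3)  # with its adoptive community once
        assert P[1, 2] == 1.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            allegiance_matrix(np.zeros((3, 2), dtype=int), layer_subset=[])

    def test_partition_of_layers_mixes_linearly(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=(6, 10))
        P_all = allegiance_matrix(labels).values
        P_1 = allegiance_matrix(labels, layer_subset=range(4)).values
        P_2 = allegiance_matrix(labels, layer_subset=range(4, 10)).values
        np.testing.assert_allclose(P_all, 0.4 * P_1 + 0.6 * P_2, atol=1e-12)

    @given(
        hnp.arrays(
            np.int64, st.tuples(st.integers(3, 8), st.integers(1, 6)),
            elements=st.integers(0, 4),
        )
    )
    def test_invariants(self, labels):
        P = allegiance_matrix(labels)
        v = P.values
        np.testing.assert_array_equal(v, v.T)
        assert np.all(np.diagonal(v) == 1.0)
        assert v.min() >= 0 and v.max() <= 1
        # entries are exact multiples of 1/L
        np.testing.assert_allclose(
            v * P.n_layers, np.round(v * P.n_layers), atol=1e-9
        )


class TestCoefficients:
    def test_intact_network_full_recruitment(self):
        atlas = toy_atlas(6, sizes=(3, 3))
        labels = np.tile(np.repeat([0, 1], 3)[:, None], (1, 4))
        P = allegiance_matrix(labels)
        R = recruitment(P, atlas)
        assert R == pytest.approx(np.ones(6))
        # communities == networks -> zero integration
        assert integration(P, atlas) == pytest.approx(np.zeros(6))

    def test_perpetual_singleton_floor(self):
        """A node alone in its own community in every layer has R = 1/n_s."""
        n = 11
        atlas = toy_atlas(n, sizes=(10, 1))
        labels = np.zeros((n, 3), dtype=int)
        labels[0] = 99  # node 0 of network S1 (size 10) is always a singleton
        R = recruitment(allegiance_matrix(labels), atlas)
        assert R[0] == pytest.approx(0.1)

    def test_one_global_community_full_integration(self):
        atlas = toy_atlas(6, sizes=(3, 3))
        P = allegiance_matrix(np.zeros((6, 4), dtype=int))
        assert integration(P, atlas) == pytest.approx(np.ones(6))

    def test_row_sum_identity_on_random_labels(self):
        """n_s R + (N - n_s) I equals the allegiance row sum (diagonal in)."""
        rng = np.random.default_rng(1)
        atlas = toy_atlas(9, sizes=(4, 5))
        n_s = np.array([4] * 4 + [5] * 5)
        for _ in range(25):
            labels = rng.integers(0, 4, size=(9, 6))
            P = allegiance_matrix(labels)
            R, I = recruitment(P, atlas), integration(P, atlas)
            lhs = n_s * R + (9 - n_s) * I
            np.testing.assert_allclose(lhs, P.values.sum(axis=1), atol=1e-12)

    def test_reordering_invariance(self):
        rng = np.random.default_rng(2)
        atlas = toy_atlas(8, sizes=(4, 4))
        labels = rng.integers(0, 3, size=(8, 5))
        P = allegiance_matrix(labels)
        R0 = recruitment(P, atlas)
        perm = rng.permutation(8)
        atlas_p = toy_atlas(8, sizes=(4, 4))
        # permute nodes consistently in P and in network membership
        from netlayers import ParcelAtlas

        atlas_p = ParcelAtlas(
            parcel_ids=tuple(range(1, 9)),
            names=tuple(np.asarray(atlas.names)[perm]),
            hemispheres=tuple(np.asarray(atlas.hemispheres)[perm]),
            networks=tuple(np.asarray(atlas.networks)[perm]),
        )
        Pp = P.values[np.ix_(perm, perm)]
        Rp = recruitment(Pp, atlas_p)
        np.testing.assert_allclose(Rp, R0[perm], atol=1e-12)

    def test_diagonal_exclusion_variant(self):
        atlas = toy_atlas(6, sizes=(3, 3))
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, size=(6, 4))
        P = allegiance_matrix(labels)
        R_in = recruitment(P, atlas, include_diagonal=True)
        R_ex = recruitment(P, atlas, include_diagonal=False)
        # excluding the always-1 diagonal can only lower the mean
        assert np.all(R_ex <= R_in + 1e-12)

    def test_network_covering_all_nodes_rejected(self):
        atlas = toy_atlas(4, sizes=(4,))
        P = allegiance_matrix(np.zeros((4, 2), dtype=int))
        with pytest.raises(ValueError, match="undefined"):
            integration(P, atlas)


class TestSummaries:
    def test_constant_network_value(self):
        atlas = toy_atlas(8, sizes=(4, 4))  # S1 all L, S2 all R
        table = coefficient_table(
            allegiance_matrix(np.tile(np.repeat([0, 1], 4)[:, None], (1, 3))), atlas
        )
        out = summarize_by_network(table)
        s1 = out[out.network == "S1"]
        assert len(s1) == 1 and s1.hemisphere.iloc[0] == "L"
        assert s1.recruitment.iloc[0] == pytest.approx(1.0)

    def test_arithmetic_mean_of_cell(self):
        table = pd.DataFrame(
            {
                "network": ["S1", "S1"],
                "hemisphere": ["L", "L"],
                "recruitment": [0.2, 0.4],
                "integration": [0.1, 0.3],
            }
        )
        out = summarize_by_network(table)
        assert out.recruitment.iloc[0] == pytest.approx(0.3)
        assert out.integration.iloc[0] == pytest.approx(0.2)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            summarize_by_network(pd.DataFrame({"network": []}))
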