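"""Controllability math: closed forms, conservation, Gramian oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctrlcascade.connectome import (
    CANONICAL_NETWORKS,
    ModalControllability,
    NetworkPartition,
    StructuralConnectome,
    aggregate_to_networks,
    apply_qa_threshold,
    controllability_gramian,
    modal_controllability,
    normalize_adjacency,
    read_connectome,
    write_connectome,
)
from conftest import random_stable_symmetric


def truncated_gramian(a, node, n_terms=200):
    """Independent oracle: partial sum of A^t B B' (A^t)'."""
    n = a.shape[0]
    b = np.zeros((n, 1))
    b[node - 1] = 1.0
    w = np.zeros((n, n))
    at = np.eye(n)
    for _ in range(n_terms):
        v = at @ b
        w += v @ v.T
        at = at @ a
    return w


class TestIO:
    def test_roundtrip_bit_exact(self, tmp_path):
        w = np.array([[0.0, 0.2, 0.01], [0.2, 0.0, 0.5], [0.01, 0.5, 0.0]])
        c = StructuralConnectome("s1", w)
        path = tmp_path / "s1.csv"
        write_connectome(c, path)
        back = read_connectome(path)
        assert np.array_equal(back.weights, c.weights)

    def test_nan_rejected_with_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0,1\nnan,0\n")
        with pytest.raises(ValueError, match="row 2"):
            read_connectome(path)

    def test_tiny_asymmetry_symmetrized(self):
        w = np.array([[0.0, 1.0], [1.0 + 1e-12, 0.0]])
        c = StructuralConnectome("s", w)
        assert np.allclose(c.weights, c.weights.T)

    def test_large_asymmetry_rejected(self):
        w = np.array([[0.0, 1.0], [1.1, 0.0]])
        with pytest.raises(ValueError, match="asymmetry"):
            StructuralConnectome("s", w)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            StructuralConnectome("s", np.array([[0.0, -0.1], [-0.1, 0.0]]))

    def test_whitespace_dialect(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("0 0.5\n0.5 0\n")
        c = read_connectome(path, dialect="dense-matrix-whitespace")
        assert c.weights[0, 1] == 0.5


class TestQAThreshold:
    def test_counts_retained_edges(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.0005
        w[0, 2] = w[2, 0] = 0.002
        w[1, 2] = w[2, 1] = 0.01
        _, n_edges = apply_qa_threshold(StructuralConnectome("s", w))
        assert n_edges == 2

    def test_boundary_is_strict(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.001
        filtered, n_edges = apply_qa_threshold(StructuralConnectome("s", w))
        assert n_edges == 0
        assert filtered.weights[0, 1] == 0.0

    def test_all_below_gives_zero_matrix_and_unit_phi(self):
        w = np.full((3, 3), 0.0001)
        np.fill_diagonal(w, 0.0)
        filtered, _ = apply_qa_threshold(StructuralConnectome("s", w))
        phi = modal_controllability(normalize_adjacency(filtered)).modal
        assert np.allclose(phi, 1.0)


class TestNormalization:
    def test_two_node_chain_by_hand(self):
        a = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(a.matrix, [[0.0, 0.5], [0.5, 0.0]])
        assert a.spectral_radius == pytest.approx(0.5)

    def test_zero_matrix_fixed(self):
        a = normalize_adjacency(np.zeros((4, 4)))
        assert np.all(a.matrix == 0) and a.spectral_radius == 0

    def test_spectral_radius_below_one(self, rng):
        w = rng.random((20, 20))
        w = np.triu(w, 1)
        w = w + w.T
        a = normalize_adjacency(StructuralConnectome("s", w))
        assert np.abs(np.linalg.eigvalsh(a.matrix)).max() < 1


class TestModalControllability:
    def test_zero_matrix_all_ones(self):
        prof = modal_controllability(np.zeros((3, 3)))
        assert np.allclose(prof.modal, 1.0)

    def test_two_node_chain_closed_form(self):
        prof = modal_controllability(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert np.allclose(prof.modal, [0.75, 0.75])

    def test_unstable_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            modal_controllability(np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            modal_controllability(np.array([[0.0, 0.4], [0.1, 0.0]]))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 15))
    def test_conservation_identity(self, seed, n):
        """sum_i phi_i = N - ||A||_F^2 for any symmetric stable matrix."""
        a = random_stable_symmetric(np.random.default_rng(seed), n)
        prof = modal_controllability(a)
        assert prof.modal.sum() == pytest.approx(n - np.sum(a**2), abs=1e-8)
        assert np.all(prof.modal >= 0) and np.all(prof.modal <= n)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, seed):
        gen = np.random.default_rng(seed)
        a = random_stable_symmetric(gen, 8)
        perm = gen.permutation(8)
        p = np.eye(8)[perm]
        phi = modal_controllability(a).modal
        phi_perm = modal_controllability(p @ a @ p.T).modal
        assert np.allclose(phi_perm, phi[perm], atol=1e-10)


class TestGramian:
    def test_zero_matrix_indicator(self):
        g = controllability_gramian(np.zeros((3, 3)), 1)
        assert np.allclose(g.gramian, np.diag([1.0, 0.0, 0.0]))

    def test_two_node_chain_geometric_series(self):
        g = controllability_gramian(np.array([[0.0, 0.5], [0.5, 0.0]]), 1)
        assert np.allclose(g.gramian, np.diag([16 / 15, 4 / 15]), atol=1e-12)

    def test_matches_truncated_series_and_psd(self, rng):
        a = random_stable_symmetric(rng, 15)
        g = controllability_gramian(a, 3)
        assert np.allclose(g.gramian, truncated_gramian(a, 3), atol=1e-8)
        assert g.min_eigenvalue >= -1e-10

    def test_out_of_range_node(self):
        with pytest.raises(ValueError, match="control_node"):
            controllability_gramian(np.zeros((3, 3)), 4)


class TestAggregation:
    def test_uniform_phi(self):
        part = NetworkPartition.contiguous({"MF": 2, "FP": 3})
        prof = modal_controllability(np.zeros((5, 5)))
        means = aggregate_to_networks(prof, part)
        assert means == {"MF": 1.0, "FP": 1.0}

    def test_two_network_arithmetic(self):
        part = NetworkPartition(np.array([1, 2, 3]), np.array(["A", "A", "B"]))
        means = aggregate_to_networks(np.array([0.2, 0.4, 0.9]), part)
        assert means["A"] == pytest.approx(0.3)
        assert means["B"] == pytest.approx(0.9)

    def test_relabeling_equivariance(self, rng):
        phi = rng.random(6)
        labels = np.array(["A", "B", "A", "C", "B", "C"], dtype=object)
        part = NetworkPartition(np.arange(1, 7), labels)
        perm = rng.permutation(6)
        part2 = NetworkPartition(np.arange(1, 7), labels[perm])
        assert aggregate_to_networks(phi[perm], part2) == aggregate_to_networks(phi, part)

    def test_size_mismatch(self):
        part = NetworkPartition.contiguous({"A": 2})
        with pytest.raises(ValueError, match="partition"):
            aggregate_to_networks(np.ones(3), part)


class TestEstimator:
    def test_transform_shape_and_network_table(self, rng):
        from ctrlcascade.synthgen import simulate_connectomes

        part = NetworkPartition.contiguous({lab: 3 for lab in CANONICAL_NETWORKS})
        conns = simulate_connectomes(4, 30, part, seed=0)
        mc = ModalControllability(partition=part).fit(conns)
        phi = mc.transform(conns)
        assert phi.shape == (4, 30)
        table = mc.network_table(conns)
        assert list(table.columns) == ["subject_id"] + list(CANONICAL_NETWORKS)

    def test_get_params_roundtrip(self):
        mc = ModalControllability(qa_threshold=0.01)
        assert ModalControllability(**mc.get_params()).qa_threshold == 0.01
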