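"""PDC standardization, edge classification and centrality."""

import numpy as np
import pytest

from panelgvar import engine
from panelgvar.networks import (
    NetworkEstimate,
    centrality,
    classify_edges,
    partial_corr_from_precision,
    temporal_pdc,
    to_networks,
)


def _pdc_schur_oracle(B, sigma_zeta):
    """Brute-force partial correlation from the lag-augmented covariance.

    Conditions node j at t-1 and node i at t on the remaining lagged nodes
    via the Schur-complement conditional covariance — an independent path
    from the precision-inversion used by the implementation.
    """
    p = B.shape[0]
    S0 = engine.stationary_within_cov(B, sigma_zeta)
    V = np.block([[S0, S0 @ B.T], [B @ S0, S0]])  # (y_{t-1}, y_t)
    out = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            x = j              # lagged predictor
            y = p + i          # current outcome
            z = [k for k in range(p) if k != j]
            Czz = V[np.ix_(z, z)]
            Cxz = V[x, z]
            Cyz = V[y, z]
            sol = np.linalg.solve(Czz, np.column_stack([Cxz, Cyz]))
            vxx = V[x, x] - Cxz @ sol[:, 0]
            vyy = V[y, y] - Cyz @ sol[:, 1]
            vxy = V[x, y] - Cxz @ sol[:, 1]
            out[i, j] = vxy / np.sqrt(vxx * vyy)
    return out


def _random_model(p, seed):
    rng = np.random.default_rng(seed)
    B = rng.normal(0, 0.25, (p, p))
    r = engine.spectral_radius(B)
    if r >= 0.6:
        B *= 0.6 / r
    A = rng.normal(0, 0.4, (p, p))
    sigma_z = A @ A.T + 0.3 * np.eye(p)
    return B, sigma_z


class TestTemporalPDC:
    def test_zero_temporal_matrix_gives_zero_pdc(self):
        p = 4
        _, sz = _random_model(p, 0)
        assert np.allclose(temporal_pdc(np.zeros((p, p)), sz), 0.0)

    def test_two_node_model_matches_oracle(self):
        B = np.array([[0.3, 0.15], [-0.1, 0.25]])
        sz = np.array([[1.0, 0.3], [0.3, 0.8]])
        assert np.allclose(
            temporal_pdc(B, sz), _pdc_schur_oracle(B, sz), atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_random_three_node_models_match_oracle(self, seed):
        B, sz = _random_model(3, seed)
        assert np.allclose(
            temporal_pdc(B, sz), _pdc_schur_oracle(B, sz), atol=1e-8
        )

    def test_sign_consistent_with_coefficients(self):
        for seed in range(5):
            B, sz = _random_model(4, seed + 50)
            pdc = temporal_pdc(B, sz)
            nz = B != 0
            assert np.all(np.sign(pdc[nz]) == np.sign(B[nz]))


def test_partial_corr_diagonal_precision_is_identity_structure():
    K = np.diag([2.0, 1.0, 0.5])
    R = partial_corr_from_precision(K)
    assert np.allclose(R, np.eye(3))


def test_partial_corr_known_two_by_two():
    K = np.array([[2.0, -0.6], [-0.6, 1.5]])
    R = partial_corr_from_precision(K)
    assert R[0, 1] == pytest.approx(0.6 / np.sqrt(3.0))


class TestClassifyEdges:
    def _net(self, M):
        p = M.shape[0]
        return NetworkEstimate(
            temporal=M, contemporaneous=np.eye(p), between=np.eye(p),
            node_labels=[f"n{i}" for i in range(p)],
        )

    def test_reciprocated_pair_is_bidirectional(self):
        M = np.zeros((3, 3))
        M[1, 0] = 0.04   # 0 -> 1
        M[0, 1] = 0.02   # 1 -> 0
        cls = classify_edges(self._net(M), threshold=0.0)
        assert (0, 1) in cls["bidirectional"]
        assert (1, 0) in cls["bidirectional"]
        assert not cls["unidirectional"]

    def test_diagonal_only_all_autocorrelative(self):
        M = np.diag([0.1, 0.2, 0.0])
        cls = classify_edges(self._net(M))
        assert cls["autocorrelative"] == [0, 1]
        assert not cls["unidirectional"] and not cls["bidirectional"]

    def test_threshold_breaks_weak_reciprocal(self):
        M = np.zeros((2, 2))
        M[1, 0] = 0.05
        M[0, 1] = 0.01
        cls = classify_edges(self._net(M), threshold=0.02)
        assert cls["unidirectional"] == [(0, 1)]

    def test_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(4)
        M = rng.normal(0, 1, (6, 6)) * (rng.random((6, 6)) < 0.3)
        cls = classify_edges(self._net(M))
        n_auto = n_uni = n_bi = 0
        for i in range(6):
            for j in range(6):
                if i == j:
                    n_auto += M[i, i] != 0
                elif M[i, j] != 0:
                    if M[j, i] != 0:
                        n_bi += 1
                    else:
                        n_uni += 1
        assert len(cls["autocorrelative"]) == n_auto
        assert len(cls["unidirectional"]) == n_uni
        assert len(cls["bidirectional"]) == n_bi


class TestCentrality:
    def _net(self, M):
        p = M.shape[0]
        return NetworkEstimate(
            temporal=M, contemporaneous=np.eye(p), between=np.eye(p),
            node_labels=[f"n{i}" for i in range(p)],
        )

    def test_diagonal_only_network_zero_centrality(self):
        tab = centrality(self._net(np.diag([0.5, 0.3, 0.2])))
        assert np.allclose(tab.c_in, 0.0)
        assert np.allclose(tab.c_out, 0.0)

    def test_toy_out_centrality(self):
        M = np.zeros((3, 3))
        M[1, 0] = 0.1
        M[2, 0] = -0.2
        tab = centrality(self._net(M))
        assert tab.c_out[0] == pytest.approx(0.3)
        assert tab.c_in[1] == pytest.approx(0.1)
        assert tab.c_in[2] == pytest.approx(0.2)

    def test_matches_brute_force_sums(self):
        rng = np.random.default_rng(8)
        M = rng.normal(0, 1, (5, 5))
        tab = centrality(self._net(M))
        for j in range(5):
            assert tab.c_out[j] == pytest.approx(
                sum(abs(M[i, j]) for i in range(5) if i != j)
            )
        for i in range(5):
            assert tab.c_in[i] == pytest.approx(
                sum(abs(M[i, j]) for j in range(5) if j != i)
            )

    def test_total_in_equals_total_out(self):
        rng = np.random.default_rng(9)
        M = rng.normal(0, 1, (6, 6))
        tab = centrality(self._net(M))
        assert tab.c_in.sum() == pytest.approx(tab.c_out.sum())

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        M = rng.normal(0, 1, (4, 4))
        perm = np.array([2, 3, 1, 0])
        tab = centrality(self._net(M))
        tab_p = centrality(self._net(M[np.ix_(perm, perm)]))
        assert np.allclose(tab_p.c_in, tab.c_in[perm])
        assert np.allclose(tab_p.c_out, tab.c_out[perm])


def test_to_networks_preserves_structural_zeros():
    B, sz = _random_model(4, 77)
    B[2, :] = 0.0
    B[2, 2] = 0.2
    omega_z = np.linalg.inv(sz)
    net = to_networks(B, omega_z, np.eye(4))
    assert np.all(net.temporal[B == 0.0] == 0.0)
    assert np.allclose(net.contemporaneous, net.contemporaneous.T)
    assert np.allclose(np.diag(net.contemporaneous), 1.0)
    assert np.abs(net.contemporaneous).max() <= 1.0 + 1e-12


# property-based checks over arbitrary weight matrices
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=30, deadline=None, derandomize=True)
@given(hnp.arrays(np.float64, (4, 4),
                  elements=st.floats(-1.0, 1.0, allow_nan=False)))
def test_centrality_mass_conservation_property(M):
    net = NetworkEstimate(
        temporal=M, contemporaneous=np.eye(4), between=np.eye(4),
        node_labels=[f"n{i}" for i in range(4)],
    )
    tab = centrality(net)
    off = np.abs(M).sum() - np.abs(np.diag(M)).sum()
    assert tab.c_in.sum() == pytest.approx(off)
    assert tab.c_out.sum() == pytest.approx(off)
    assert np.all(tab.c_in >= 0) and np.all(tab.c_out >= 0)
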