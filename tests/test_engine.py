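"""Selected-configuration estimators: local energies, expectations,
gradients, and the extend-and-select update."""

import numpy as np
import pytest

from vibnqs import engine
from vibnqs.ansatz import ModalMatrix, init_mbf
from vibnqs.engine import (
    OperatorCache,
    PenaltyOperator,
    SelectedSpace,
    expectation_w,
    extend_and_select,
    gradient_w,
    local_energy,
    penalized_cache,
    penalty_matrix,
)
from vibnqs.exactref import TableAnsatz, lowest_k, table_ansatz
from vibnqs.hamiltonian import build_operator, enumerate_basis, onv_to_index, to_matrix
from vibnqs.sampler import sample_force_field


@pytest.fixture(scope="module")
def toy2():
    """Random 2-mode anharmonic Hamiltonian with dense reference."""
    ff = sample_force_field(2, "moderate", "moderate", 21)
    H = build_operator(ff, 5)
    dense = to_matrix(H).toarray()
    basis = enumerate_basis(2, 6)
    return H, dense, basis


def random_table(rng, H):
    """Positive random table state over the full basis."""
    vec = rng.uniform(0.2, 1.0, size=H.dim)
    return TableAnsatz(vec, H.L, H.nmodal)


class TestLocalEnergy:
    def test_eigenvector_zero_variance(self, toy2):
        H, dense, basis = toy2
        spec = lowest_k(H, 2)
        psi = table_ansatz(spec, 0)
        support = basis[np.abs(spec.eigenvectors[:, 0]) > 1e-6]
        eloc = engine.local_energies(H, psi, support)
        np.testing.assert_allclose(eloc, spec.eigenvalues[0], atol=1e-7)

    def test_harmonic_one_hot(self, harmonic_ff3):
        H = build_operator(harmonic_ff3, 3)
        m = np.array([1, 0, 2])
        psi = init_mbf(ModalMatrix.one_hot(m, 4), 1.0, 0.0, 0)
        expected = float(((m + 0.5) * harmonic_ff3.w).sum())
        assert local_energy(H, psi, m) == pytest.approx(expected)

    def test_matches_dense_matvec(self, toy2):
        H, dense, basis = toy2
        rng = np.random.default_rng(0)
        psi = random_table(rng, H)
        eloc = engine.local_energies(H, psi, basis)
        expected = (dense @ psi.vector) / psi.vector
        np.testing.assert_allclose(eloc, expected, rtol=1e-12)

    def test_generic_path_matches_matrix_path(self, toy2):
        H, dense, basis = toy2
        rng = np.random.default_rng(1)
        psi = random_table(rng, H)
        fast = OperatorCache(H)
        slow = OperatorCache(H, matrix_guard=1)  # force connection path
        assert not slow.use_matrix
        sub = basis[::5]
        np.testing.assert_allclose(slow.local_energies(psi, sub),
                                   fast.local_energies(psi, sub), rtol=1e-10)


class TestExpectation:
    def test_full_space_is_rayleigh_quotient(self, toy2):
        H, dense, basis = toy2
        rng = np.random.default_rng(2)
        psi = random_table(rng, H)
        W = SelectedSpace(basis, psi.amplitudes(basis), ns=basis.shape[0], k=1)
        e = expectation_w(H, psi, W)
        v = psi.vector
        rq = float(v @ dense @ v / (v @ v))
        assert e == pytest.approx(rq, rel=1e-9)
        assert e >= float(np.linalg.eigvalsh(dense)[0]) - 1e-9

    def test_eigenvector_any_subset_exact(self, toy2):
        H, dense, basis = toy2
        spec = lowest_k(H, 1)
        psi = table_ansatz(spec, 0)
        sub = basis[np.argsort(-np.abs(spec.eigenvectors[:, 0]))[:7]]
        W = SelectedSpace(sub, psi.amplitudes(sub), ns=7, k=1)
        assert expectation_w(H, psi, W) == pytest.approx(spec.eigenvalues[0], abs=1e-8)

    def test_top_half_matches_dense_formula(self, toy2):
        """Asymmetric estimator: <Psi_W|H|Psi> / <Psi_W|Psi_W> from scratch."""
        H, dense, basis = toy2
        rng = np.random.default_rng(3)
        psi = random_table(rng, H)
        order = np.argsort(-np.abs(psi.vector))
        keep = order[: basis.shape[0] // 2]
        W = SelectedSpace(basis[keep], psi.vector[keep], ns=keep.size, k=1)
        vw = np.zeros_like(psi.vector)
        vw[keep] = psi.vector[keep]
        expected = float(vw @ dense @ psi.vector / (vw @ vw))
        assert expectation_w(H, psi, W) == pytest.approx(expected, rel=1e-12)

    def test_empty_space_rejected(self, toy2):
        H, _, _ = toy2
        rng = np.random.default_rng(4)
        psi = random_table(rng, H)
        with pytest.raises(ValueError):
            expectation_w(H, psi, SelectedSpace(np.empty((0, 2), dtype=int),
                                                np.empty(0), ns=1, k=1))


class TestGradient:
    def test_stationary_at_eigenvector(self, toy2):
        H, dense, basis = toy2
        spec = lowest_k(H, 1)
        psi = table_ansatz(spec, 0)
        W = SelectedSpace(basis, psi.amplitudes(basis), ns=basis.shape[0], k=1)
        grad = gradient_w(H, psi, W)
        assert np.abs(grad).max() < 1e-9

    def test_matches_finite_difference_full_space(self, toy2):
        """On full W the estimator gradient equals the exact derivative."""
        H, dense, basis = toy2
        rng = np.random.default_rng(5)
        psi = random_table(rng, H)
        W = SelectedSpace(basis, psi.amplitudes(basis), ns=basis.shape[0], k=1)
        grad = gradient_w(H, psi, W)
        p0 = psi.vector.copy()
        for m in rng.choice(p0.size, size=8, replace=False):
            h = 1e-6
            psi.vector = p0.copy(); psi.vector[m] += h
            Wp = SelectedSpace(basis, psi.amplitudes(basis), basis.shape[0], 1)
            ep = expectation_w(H, psi, Wp)
            psi.vector = p0.copy(); psi.vector[m] -= h
            Wm = SelectedSpace(basis, psi.amplitudes(basis), basis.shape[0], 1)
            em = expectation_w(H, psi, Wm)
            psi.vector = p0
            assert grad[m] == pytest.approx((ep - em) / (2 * h), rel=1e-4, abs=1e-8)

    def test_descent_direction(self, toy2):
        """A small step along -F lowers the energy (10/10 random states)."""
        H, dense, basis = toy2
        rng = np.random.default_rng(6)
        for _ in range(10):
            psi = random_table(rng, H)
            W = SelectedSpace(basis, psi.amplitudes(basis), basis.shape[0], 1)
            e0 = expectation_w(H, psi, W)
            grad = gradient_w(H, psi, W)
            psi.vector = psi.vector - 1e-6 * grad
            W1 = SelectedSpace(basis, psi.amplitudes(basis), basis.shape[0], 1)
            assert expectation_w(H, psi, W1) < e0


class TestExtendAndSelect:
    def test_exact_top_ns_when_pool_covered(self, toy2):
        """With K*Ns covering the whole connected union the update is the
        exact top-Ns by |Psi| (brute-force sort oracle)."""
        H, dense, basis = toy2
        rng = np.random.default_rng(7)
        psi = random_table(rng, H)
        W = SelectedSpace(basis, psi.amplitudes(basis), ns=10, k=1)
        W1 = extend_and_select(H, psi, W, ns=10, k=1, rng=rng)
        amps = np.abs(psi.amplitudes(basis))
        best = set(map(tuple, basis[np.argsort(-amps)[:10]]))
        assert {tuple(o) for o in W1.onvs} == best

    def test_ns_larger_than_reachable_space(self, harmonic_ff3):
        H = build_operator(harmonic_ff3, 2)
        psi = init_mbf(ModalMatrix.one_hot([0, 0, 0], 3), 1.0, 0.0, 0)
        W = SelectedSpace.seeded(np.zeros(3, dtype=int), psi, ns=50, k=2)
        rng = np.random.default_rng(8)
        W1 = extend_and_select(H, psi, W, rng=rng)
        W2 = extend_and_select(H, psi, W1, rng=rng)
        # harmonic H is diagonal: reachable set is just the seed
        assert len(W1) == 1 and len(W2) == 1

    def test_top_amplitudes_survive(self, toy2):
        H, _, basis = toy2
        vec = np.full(H.dim, 1e-6)
        idx = onv_to_index(np.array([[0, 0], [1, 0], [0, 1]]), H.nmodal)
        vec[idx] = [0.9, 0.5, 0.1]
        psi = TableAnsatz(vec, 2, 6)
        W = SelectedSpace(basis[idx], vec[idx], ns=2, k=1)
        W1 = extend_and_select(H, psi, W, ns=2, k=1, rng=np.random.default_rng(9))
        kept = {tuple(o) for o in W1.onvs}
        assert kept == {(0, 0), (1, 0)}

    def test_deterministic_given_seed(self, toy2):
        H, _, _ = toy2
        rng_a = np.random.default_rng(10)
        rng_b = np.random.default_rng(10)
        psi = random_table(np.random.default_rng(11), H)
        W0 = SelectedSpace.seeded(np.zeros(2, dtype=int), psi, ns=6, k=1)
        Wa, Wb = W0, W0
        for _ in range(4):
            Wa = extend_and_select(H, psi, Wa, rng=rng_a)
            Wb = extend_and_select(H, psi, Wb, rng=rng_b)
        np.testing.assert_array_equal(Wa.onvs, Wb.onvs)

    def test_pool_respects_k_times_ns(self, toy2):
        H, _, _ = toy2
        psi = random_table(np.random.default_rng(12), H)
        W = SelectedSpace.seeded(np.zeros(2, dtype=int), psi, ns=3, k=2)
        W1 = extend_and_select(H, psi, W, rng=np.random.default_rng(13))
        # candidates were 1 member + at most K*Ns = 6 sampled
        assert len(W1) <= 3

    def test_monotone_coverage_in_ns(self, toy2):
        H, _, basis = toy2
        psi = random_table(np.random.default_rng(14), H)
        norm2 = float(np.sum(psi.vector ** 2))
        cover = []
        for ns in (4, 8, 16, 36):
            W = SelectedSpace.seeded(np.zeros(2, dtype=int), psi, ns=ns, k=50)
            for _ in range(8):
                W = extend_and_select(H, psi, W, rng=np.random.default_rng(15))
            cover.append(float(np.sum(W.amps ** 2)) / norm2)
        assert all(b >= a - 1e-12 for a, b in zip(cover, cover[1:]))


class TestPenalty:
    def test_full_space_matches_penalty_matrix(self, toy2):
        H, dense, basis = toy2
        spec = lowest_k(H, 1)
        gs = spec.eigenvectors[:, 0]
        support = basis[np.abs(gs) > 1e-10]
        amps = gs[np.abs(gs) > 1e-10]
        cache = OperatorCache(H)
        pen_cache = penalized_cache(cache, [(support, amps)], z=5000.0, shift=-100.0)
        rng = np.random.default_rng(16)
        psi = random_table(rng, H)
        W = SelectedSpace(basis, psi.amplitudes(basis), basis.shape[0], 1)
        e = expectation_w(pen_cache, psi, W)
        pm = penalty_matrix(PenaltyOperator(H, [(support, amps)], 5000.0, -100.0))
        v = psi.vector
        assert e == pytest.approx(float(v @ pm @ v / (v @ v)), rel=1e-10)

    def test_penalty_ground_state_is_first_excited(self, toy2):
        H, dense, basis = toy2
        spec = lowest_k(H, 2)
        gs = spec.eigenvectors[:, 0]
        pm = penalty_matrix(PenaltyOperator(H, [(basis, gs)], 8000.0, 0.0))
        e0 = np.linalg.eigvalsh(pm)[0]
        assert e0 == pytest.approx(spec.eigenvalues[1], abs=1e-8)
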