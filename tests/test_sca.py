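"""Self-consistent distance dynamics: fixed points, initial conditions,
integrator cross-checks."""

import numpy as np
import pytest

from epifold import (
    ChainParams,
    DistanceMatrix,
    InteractionModel,
    contact_probability,
    evolve,
    find_fixed_points,
    init_coil,
    init_from_contact_map,
    init_globule,
    init_mps,
    make_block_sequence,
    sca_rhs,
)
from epifold.sca import (
    SCAParams,
    gram_from_distances,
    is_valid_embedding,
    polish_fixed_point,
)
from conftest import ideal_model


def rouse_profile(n, l=1.0):
    return np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * l**2 / 3.0


class TestRHS:
    def test_two_bead_ideal_chain_stationary_at_bond_variance(self):
        """For N=2 without interactions the rhs vanishes exactly at the
        ideal bond statistics D_12 = l^2/3 (i.e. <b^2> = l^2)."""
        seq = make_block_sequence([("A", 2)], 1)
        model = ideal_model(seq.alphabet)
        D = np.array([[0.0, 1 / 3], [1 / 3, 0.0]])
        np.testing.assert_allclose(sca_rhs(D, seq, model), 0.0, atol=1e-12)
        # off the fixed point the bond relaxes toward it
        assert sca_rhs(np.array([[0, 0.2], [0.2, 0]]), seq, model)[0, 1] > 0
        assert sca_rhs(np.array([[0, 0.5], [0.5, 0]]), seq, model)[0, 1] < 0

    def test_rouse_profile_is_exact_fixed_point(self):
        """D_mn = |m-n| l^2/3 solves the stationarity condition for any N
        (no noise-scale recalibration is needed)."""
        seq = make_block_sequence([("A", 15), ("B", 15)], 1)
        model = ideal_model(seq.alphabet)
        rhs = sca_rhs(rouse_profile(seq.n), seq, model)
        np.testing.assert_allclose(rhs, 0.0, atol=1e-10)

    def test_diagonal_identically_zero(self, toy_seq, rng):
        model = InteractionModel.uniform(-1.0, -2.0, toy_seq.alphabet)
        D = rouse_profile(toy_seq.n) * (1 + 0.1 * rng.random())
        rhs = sca_rhs(D, toy_seq, model)
        assert (np.diag(rhs) == 0).all()
        np.testing.assert_allclose(rhs, rhs.T, atol=1e-10)

    def test_reversal_type_swap_invariance(self, toy_seq):
        """(A10B10)6 with uniform U_s: the rhs commutes with chain
        reversal (which is also the A<->B type swap)."""
        model = InteractionModel.uniform(-1.5, -3.0, toy_seq.alphabet)
        n = toy_seq.n
        D = rouse_profile(n)
        rhs = sca_rhs(D, toy_seq, model)
        np.testing.assert_allclose(rhs, rhs[::-1, ::-1], atol=1e-10)

    def test_nonfinite_rejected(self, small_seq):
        D = rouse_profile(small_seq.n)
        D[0, 1] = D[1, 0] = np.inf
        with pytest.raises(ValueError):
            sca_rhs(D, small_seq, ideal_model(small_seq.alphabet))


class TestInits:
    def test_coil_small_matrix(self):
        seq = make_block_sequence([("A", 3)], 1)
        D = init_coil(seq, ideal_model(seq.alphabet)).D
        expected = np.array([[0, 1 / 3, 2 / 3], [1 / 3, 0, 1 / 3], [2 / 3, 1 / 3, 0]])
        np.testing.assert_allclose(D, expected)

    def test_coil_is_valid_embedding(self, toy_seq):
        D = init_coil(toy_seq, InteractionModel.uniform(0, 0, toy_seq.alphabet)).D
        assert is_valid_embedding(D)
        assert (np.abs(np.diag(D)) == 0).all()

    def test_globule_saturates_long_range(self, small_seq):
        model = InteractionModel.uniform(0, 0, small_seq.alphabet)
        D = init_globule(small_seq, model, plateau=1.0).D
        coil = init_coil(small_seq, model).D
        far = rouse_profile(small_seq.n) > 2.0
        assert D[far].max() <= 1.0 + 1e-8
        big = init_globule(small_seq, model, plateau=1e9).D
        np.testing.assert_allclose(big, coil, atol=1e-8)
        with pytest.raises(ValueError):
            init_globule(small_seq, model, plateau=-1.0)

    def test_mps_contrast_and_embedding(self, toy_seq):
        model = InteractionModel.uniform(0, 0, toy_seq.alphabet)
        dm = init_mps(toy_seq, model, intra=0.5, inter=8.0)
        from epifold import same_state_indicator

        delta = same_state_indicator(toy_seq).astype(bool)
        far = rouse_profile(toy_seq.n) > 4.0
        assert dm.D[far & delta].mean() < dm.D[far & ~delta].mean()
        assert is_valid_embedding(dm.D, tol=1e-6)
        with pytest.raises(ValueError):
            init_mps(toy_seq, model, intra=2.0, inter=1.0)

    def test_mps_single_type_reduces_to_globule_like(self):
        seq = make_block_sequence([("A", 12)], 1)
        model = InteractionModel.uniform(0, 0, seq.alphabet)
        dm = init_mps(seq, model, intra=0.5, inter=9.0)
        glob = init_globule(seq, model, plateau=0.5)
        np.testing.assert_allclose(dm.D, glob.D, atol=1e-8)

    def test_init_from_contact_map_round_trip(self, small_seq):
        model = InteractionModel.uniform(0, 0, small_seq.alphabet)
        D = init_coil(small_seq, model)
        cmap = contact_probability(D, A_mode=2.0)
        back = init_from_contact_map(cmap.P, 2.0)
        off = ~np.eye(small_seq.n, dtype=bool)
        np.testing.assert_allclose(back.D[off], D.D[off], rtol=1e-6)

    def test_init_from_contact_map_monotone_and_uniform(self):
        P = np.full((4, 4), 0.2)
        np.fill_diagonal(P, 1.0)
        D = init_from_contact_map(P, 1.0).D
        off = ~np.eye(4, dtype=bool)
        assert np.ptp(D[off]) < 1e-8
        P2 = P.copy()
        P2[0, 3] = P2[3, 0] = 0.05  # rarer contact -> larger distance
        D2 = init_from_contact_map(P2, 1.0).D
        assert D2[0, 3] > D2[0, 1]
        with pytest.raises(ValueError):
            init_from_contact_map(np.zeros((4, 4)), 1.0)


class TestEvolve:
    def test_zero_time_returns_input(self, small_seq):
        model = ideal_model(small_seq.alphabet)
        D0 = init_globule(small_seq, model, plateau=1.0)
        res = evolve(D0, small_seq, model, SCAParams(t_max=0.0))
        np.testing.assert_array_equal(res.distances.D, D0.D)

    @pytest.mark.parametrize("method", ["rk45", "exponential"])
    def test_ideal_chain_converges_to_rouse(self, method):
        seq = make_block_sequence([("A", 5), ("B", 5)], 1)
        model = ideal_model(seq.alphabet)
        D0 = init_globule(seq, model, plateau=1.0)
        params = SCAParams(steady_tol=1e-5, t_max=2e3)
        res = evolve(D0, seq, model, params, method=method)
        np.testing.assert_allclose(
            res.distances.D, rouse_profile(seq.n), rtol=5e-3, atol=5e-4
        )

    def test_methods_agree_with_interactions(self, small_seq):
        model = InteractionModel.uniform(-1.0, -1.0, small_seq.alphabet)
        D0 = init_coil(small_seq, model)
        r1 = evolve(D0, small_seq, model, SCAParams(steady_tol=1e-5, t_max=2e3), method="rk45")
        r2 = evolve(
            D0, small_seq, model, SCAParams(steady_tol=1e-7, t_max=2e3), method="exponential"
        )
        rel = np.linalg.norm(r1.distances.D - r2.distances.D) / np.linalg.norm(
            r2.distances.D
        )
        assert rel < 1e-2

    def test_snapshots_symmetric_zero_diagonal(self, small_seq):
        model = InteractionModel.uniform(-1.0, -1.0, small_seq.alphabet)
        D0 = init_coil(small_seq, model)
        params = SCAParams(
            steady_tol=1e-12, t_max=5.0, snapshot_times=(0.5, 2.0, 4.0), stall_steps=10**9
        )
        for method in ["rk45", "exponential"]:
            res = evolve(D0, small_seq, model, params, method=method)
            assert len(res.snapshots) == 3
            for t_snap, D in res.snapshots:
                np.testing.assert_allclose(D, D.T, atol=1e-9)
                np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-9)

    def test_transient_agreement_between_methods(self, small_seq):
        """The exponential stepper follows the same relaxation path as
        the reference DOPRI5 integrator, not just the same endpoint."""
        model = InteractionModel.uniform(-1.0, -1.0, small_seq.alphabet)
        D0 = init_coil(small_seq, model)
        p_rk = SCAParams(steady_tol=1e-12, t_max=4.0, snapshot_times=(1.0, 3.0), stall_steps=10**9)
        p_ex = SCAParams(
            steady_tol=1e-12, t_max=4.0, snapshot_times=(1.0, 3.0), exp_step_change=0.01
        )
        s_rk = evolve(D0, small_seq, model, p_rk, method="rk45").snapshots
        s_ex = evolve(D0, small_seq, model, p_ex, method="exponential").snapshots
        for (ta, Da), (tb, Db) in zip(s_rk, s_ex):
            assert ta == tb
            assert np.linalg.norm(Da - Db) / np.linalg.norm(Da) < 5e-3

    def test_monotone_compaction(self):
        """Strengthening non-specific attraction never swells the chain:
        mean long-range stationary D is non-increasing in |U_ns|."""
        seq = make_block_sequence([("A", 10), ("B", 10)], 2)
        params = SCAParams(steady_tol=1e-3, t_max=6e3, exp_step_change=0.2)
        far = rouse_profile(seq.n) >= 10 / 3
        means = []
        for u in [0.0, -1.0, -2.0, -3.0, -4.0]:
            model = InteractionModel.uniform(u, 0.0, seq.alphabet)
            res = evolve(init_coil(seq, model), seq, model, params, method="exponential")
            out = polish_fixed_point(res.distances, seq, model, params)
            D = out[0].D if out is not None else res.distances.D
            means.append(D[far].mean())
        assert all(a >= b - 1e-6 for a, b in zip(means[:-1], means[1:]))


class TestFixedPoints:
    def test_unique_fixed_point_without_interactions(self):
        seq = make_block_sequence([("A", 4), ("B", 4)], 1)
        model = ideal_model(seq.alphabet)
        fps = find_fixed_points(
            seq, model, SCAParams(steady_tol=1e-6, t_max=5e3), method="exponential"
        )
        assert fps.multiplicity == 1
        assert not fps.unconverged
        np.testing.assert_allclose(
            fps.representatives[0].D, rouse_profile(seq.n), rtol=1e-2, atol=1e-3
        )

    def test_identical_inits_single_cluster(self, small_seq):
        model = InteractionModel.uniform(-1.0, -1.0, small_seq.alphabet)
        D0 = init_coil(small_seq, model)
        fps = find_fixed_points(
            small_seq,
            model,
            SCAParams(steady_tol=3e-2, t_max=5e3),
            [D0, D0, D0],
            method="exponential",
            polish=True,
        )
        assert fps.multiplicity == 1
        assert fps.members == [[0, 1, 2]]

    def test_polish_reaches_machine_stationarity(self, small_seq):
        model = InteractionModel.uniform(-1.0, -1.0, small_seq.alphabet)
        params = SCAParams(steady_tol=3e-2, t_max=6e3)
        res = evolve(init_coil(small_seq, model), small_seq, model, params, method="exponential")
        out = polish_fixed_point(res.distances, small_seq, model, params)
        assert out is not None
        _, residual = out
        assert residual < 1e-5


class TestDistanceMatrixIO:
    def test_text_round_trip(self, tmp_path, small_seq):
        model = InteractionModel.uniform(0, 0, small_seq.alphabet)
        dm = init_coil(small_seq, model)
        dm.bin_size = 10_000
        path = tmp_path / "D.txt"
        dm.to_text(path)
        back = DistanceMatrix.from_text(path)
        np.testing.assert_allclose(back.D, dm.D)
        assert back.bin_size == 10_000 and back.l == 1.0

    def test_npz_container(self, tmp_path, small_seq):
        model = InteractionModel.uniform(0, 0, small_seq.alphabet)
        dm = init_coil(small_seq, model)
        path = tmp_path / "D.npz"
        dm.save_npz(path, times=[0.5, 1.0], snapshots=[dm.D, dm.D])
        data = np.load(path)
        assert set(data.files) == {"D", "times", "snapshots"}
        np.testing.assert_allclose(data["D"], dm.D)

    def test_validation_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            DistanceMatrix(D=np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            DistanceMatrix(D=np.array([[1.0, 1.0], [1.0, 0.0]]))  # diagonal

    def test_gram_double_centering_psd_for_coil(self, toy_seq):
        D = init_coil(toy_seq, InteractionModel.uniform(0, 0, toy_seq.alphabet)).D
        w = np.linalg.eigvalsh(gram_from_distances(D))
        assert w.min() > -1e-9 * w.max()
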