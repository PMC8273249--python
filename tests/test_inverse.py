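"""Matching-pursuit localization: correlation, selection, iteration."""

import numpy as np
import pytest

import spfdloc as sl
from spfdloc.forward import DipoleSource, dipole_source_term
from spfdloc.inverse import correlate_columns, mp_iterative, mp_localize
from spfdloc.leadfield import LeadFieldMatrix
from spfdloc.montage import ScalpPotentials


def _toy_lfm(rng, m=10, n_vox=10):
    """Small synthetic dictionary wrapped in LeadFieldMatrix bookkeeping."""
    grid = sl.VoxelGrid(shape=(5, 5, 5), spacing=2.0)
    labels = np.zeros((5, 5, 5), dtype=np.int16)
    flat = rng.choice(125, size=n_vox, replace=False)
    labels[np.unravel_index(np.sort(flat), (5, 5, 5))] = 1
    vol = sl.TissueLabelVolume(grid=grid, labels=labels, label_names={1: "gray matter"})
    gm = sl.gray_matter_index(vol)
    montage = sl.ElectrodeMontage(
        names=[f"e{i}" for i in range(m)],
        positions=rng.normal(size=(m, 3)),
        node_index=np.arange(3 * m).reshape(m, 3),
        ground=0,
        system="custom",
    )
    values = rng.normal(size=(m, 3 * n_vox))
    values[0] = 0.0  # ground row
    return LeadFieldMatrix(values=values, injection_current=1e-3, montage=montage, gm=gm)


class TestCorrelation:
    def test_matches_naive_per_column_loop(self, rng):
        L = _toy_lfm(rng)
        phi = rng.normal(size=10)
        phi[0] = 0.0
        got = correlate_columns(L, phi)
        expect = np.empty(30)
        for i in range(30):
            col = L.values[:, i]
            expect[i] = phi @ col / (np.linalg.norm(phi) * np.linalg.norm(col))
        np.testing.assert_allclose(got, expect, atol=1e-12)
        assert np.all(np.abs(got) <= 1.0 + 1e-12)

    def test_self_and_negated_column(self, rng):
        L = _toy_lfm(rng)
        c = 17
        phi = L.values[:, c].copy()
        corr = correlate_columns(L, phi)
        assert corr[c] == pytest.approx(1.0)
        assert correlate_columns(L, -phi)[c] == pytest.approx(-1.0)
        # abs mode still finds the column for reversed polarity
        assert mp_localize(L, -phi, mode="abs").est_column == c

    def test_zero_signal_rejected(self, rng):
        L = _toy_lfm(rng)
        with pytest.raises(ValueError, match="zero"):
            correlate_columns(L, np.zeros(10))

    def test_zero_norm_column_gets_zero_correlation(self, rng):
        L = _toy_lfm(rng)
        L.values[:, 5] = 0.0
        if hasattr(L, "_col_norms"):
            del L._col_norms
        corr = correlate_columns(L, L.values[:, 2])
        assert corr[5] == 0.0


class TestLocalize:
    def test_exact_column_recovers_itself(self, rng):
        L = _toy_lfm(rng)
        for c in (0, 13, 29):
            est = mp_localize(L, L.values[:, c].copy())
            assert est.est_column == c
            vox, axis = L.column_to_source(c)
            np.testing.assert_array_equal(est.est_voxel, vox)
            assert est.est_axis == axis

    def test_signed_mode_argmax(self, rng):
        L = _toy_lfm(rng)
        phi = -L.values[:, 8]
        signed = mp_localize(L, phi, mode="signed")
        # signed argmax avoids the negated true column
        assert signed.est_column != 8
        assert mp_localize(L, phi, mode="abs").est_column == 8

    def test_estimate_is_argmax_of_correlation_vector(self, rng):
        L = _toy_lfm(rng)
        phi = rng.normal(size=10)
        phi[0] = 0.0
        est = mp_localize(L, phi, keep_corr=True)
        assert est.est_column == int(np.argmax(np.abs(est.all_corr)))

    def test_noise_free_exact_recovery_on_matched_phantom(
        self, mini_lfm, mini_sigma, mini_gm, mini_1010, mini_solver, rng
    ):
        """50 random gray dipoles, matched forward/LFM model, no noise:
        localization error is 0 mm in every trial."""
        for _ in range(50):
            n = int(rng.integers(mini_gm.n))
            ax = int(rng.integers(3))
            sign = int(rng.choice([-1, 1]))
            d = DipoleSource.at_voxel(mini_sigma.grid, mini_gm.voxel_list[n], ax, sign)
            fld = mini_solver.solve(dipole_source_term(d, mini_sigma.grid))
            phi = sl.reference_potentials(fld, mini_1010)
            est = mp_localize(mini_lfm, phi)
            true_loc = mini_gm.grid.voxel_centers_mm(mini_gm.voxel_list[n])
            assert np.linalg.norm(est.est_location_mm - true_loc) == 0.0
            assert est.est_axis == ax

    def test_reference_invariance(self, mini_lfm, mini_sigma, mini_gm, mini_1010, mini_solver):
        """Re-referencing potentials and LFM rows to a common electrode
        leaves the matching-pursuit argmax unchanged."""
        n = mini_gm.n // 3
        d = DipoleSource.at_voxel(mini_sigma.grid, mini_gm.voxel_list[n], 1, 1)
        fld = mini_solver.solve(dipole_source_term(d, mini_sigma.grid))
        phi = sl.reference_potentials(fld, mini_1010)
        base = mp_localize(mini_lfm, phi)

        ref = 30  # re-reference both to electrode 30
        phi2 = ScalpPotentials(phi=phi.phi - phi.phi[ref], ground=ref)
        L2 = LeadFieldMatrix(
            values=mini_lfm.values - mini_lfm.values[ref],
            injection_current=mini_lfm.injection_current,
            montage=mini_lfm.montage,
            gm=mini_lfm.gm,
        )
        again = mp_localize(L2, phi2)
        assert again.est_column == base.est_column


class TestIterative:
    def test_k1_reduces_to_single_localization(self, rng):
        L = _toy_lfm(rng)
        phi = rng.normal(size=10)
        phi[0] = 0.0
        single = mp_localize(L, phi)
        results, hist = mp_iterative(L, phi, k_sources=1)
        assert len(results) == 1
        assert results[0].est_column == single.est_column
        assert hist[0] == pytest.approx(np.linalg.norm(phi))

    def test_two_near_orthogonal_columns_recovered(self, rng):
        L = _toy_lfm(rng, m=20, n_vox=6)
        # orthogonalize two columns explicitly
        a = L.values[:, 3].copy()
        b = L.values[:, 10].copy()
        b -= (b @ a) / (a @ a) * a
        L.values[:, 10] = b
        if hasattr(L, "_col_norms"):
            del L._col_norms
        phi = 2.0 * a - 3.0 * b
        results, hist = mp_iterative(L, phi, k_sources=2)
        assert {r.est_column for r in results} == {3, 10}
        assert hist[-1] < 1e-10 * hist[0]

    def test_residuals_nonincreasing(self, rng):
        L = _toy_lfm(rng)
        phi = rng.normal(size=10)
        phi[0] = 0.0
        _, hist = mp_iterative(L, phi, k_sources=5)
        assert np.all(np.diff(hist) <= 1e-12)


class TestReconstruction:
    def test_peak_current_at_estimated_dipole_and_deterministic(
        self, mini_lfm, mini_sigma, mini_gm, mini_1010, mini_solver
    ):
        n = mini_gm.n // 2
        vox = mini_gm.voxel_list[n]
        d = DipoleSource.at_voxel(mini_sigma.grid, vox, 2, 1)
        fld = mini_solver.solve(dipole_source_term(d, mini_sigma.grid))
        phi = sl.reference_potentials(fld, mini_1010)
        est = mp_localize(mini_lfm, phi)
        j1 = sl.reconstruct_distribution(est, mini_sigma, solver=mini_solver)
        j2 = sl.reconstruct_distribution(est, mini_sigma, solver=mini_solver)
        np.testing.assert_array_equal(j1.j, j2.j)
        peak = np.unravel_index(np.argmax(j1.magnitude()), mini_sigma.grid.shape)
        assert np.max(np.abs(np.array(peak) - vox)) <= 1
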