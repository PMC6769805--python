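"""χ² statistics, RMSF/PCA/DCCM, segmentation and conditioned χ²."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baroshift import (
    DihedralSeries,
    chi2,
    chi2_profile,
    conditional_chi2,
    dccm,
    dihedral_histogram,
    gen_dihedral_series,
    gen_latent_chain,
    gen_mode_trajectory,
    pca_modes,
    rmsf,
    segment_subensembles,
)
from baroshift.dynamics import DihedralHistogram
from tests.conftest import cosine


def brute_force_chi2(t1, t2, n=10):
    """Double-loop oracle, accumulated in exact rational arithmetic."""
    from fractions import Fraction

    total = Fraction(0)
    for i in range(n):
        for j in range(n):
            d = float(t1[i, j]) - float(t2[i, j])
            total += Fraction(d * d)
    return float(total) / n**2


def random_table(rng):
    t = rng.random((10, 10))
    return DihedralHistogram(table=t / t.sum(), n_samples=100)


class TestHistogram:
    def test_single_frame_single_cell(self):
        h = dihedral_histogram([-100.0], [130.0])
        assert h.n_samples == 1
        assert h.table.sum() == 1.0
        assert (h.table == 1.0).sum() == 1

    def test_uniform_grid_fills_all_cells(self):
        centers = np.linspace(-180, 180, 11)[:-1] + 18.0
        phi, psi = np.meshgrid(centers, centers)
        phi = np.tile(phi.ravel(), 2)  # any multiple keeps uniformity
        psi = np.tile(psi.ravel(), 2)
        h = dihedral_histogram(phi, psi)
        np.testing.assert_allclose(h.table, 0.01)

    def test_boundary_wrapping(self):
        h = dihedral_histogram([-180.0, 180.0], [-180.0, 180.0])
        assert h.table[0, 0] == 0.5  # -180 in the first bin
        assert h.table[9, 9] == 0.5  # +180 in the last bin

    def test_empty_input(self):
        h = dihedral_histogram([], [])
        assert h.n_samples == 0
        assert h.table.sum() == 0.0


class TestChi2:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(0)
        h = random_table(rng)
        assert chi2(h, h) == 0.0

    def test_disjoint_point_masses(self):
        a = np.zeros((10, 10))
        a[0, 0] = 1.0
        b = np.zeros((10, 10))
        b[5, 5] = 1.0
        val = chi2(
            DihedralHistogram(a, n_samples=1), DihedralHistogram(b, n_samples=1)
        )
        assert val == pytest.approx(0.02)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            f1, f2 = random_table(rng), random_table(rng)
            assert chi2(f1, f2) == brute_force_chi2(f1.table, f2.table)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        f1, f2 = random_table(rng), random_table(rng)
        assert chi2(f1, f2) == chi2(f2, f1)

    def test_mismatched_binning_rejected(self):
        rng = np.random.default_rng(1)
        f1, f2 = random_table(rng), random_table(rng)
        f2.edges = f2.edges + 1.0
        with pytest.raises(ValueError):
            chi2(f1, f2)


class TestChi2Profile:
    def test_identical_series_all_zero(self, wt_ensemble):
        ds = wt_ensemble["dihedrals"]
        profile = chi2_profile(ds, ds)
        assert np.nanmax(profile.chi2.to_numpy()) == 0.0

    def test_preset_contrast_localizes_to_coupled_residues(
        self, wt, wt_ensemble, d76n_ensemble
    ):
        profile = chi2_profile(
            wt_ensemble["dihedrals"], d76n_ensemble["dihedrals"]
        ).set_index("residue_id")
        coupled = set(wt.coupled_residues())
        elevated = set(profile.index[profile.chi2 > 1e-3])
        assert elevated == coupled
        assert profile.loc[~profile.index.isin(coupled), "chi2"].max() < 1e-3

    def test_null_chi2_shrinks_with_frames(self, wt):
        model = wt.dihedral_model()
        small_a = gen_dihedral_series(model, np.zeros(1000, dtype=int), seed=31)
        small_b = gen_dihedral_series(model, np.zeros(1000, dtype=int), seed=32)
        big_a = gen_dihedral_series(model, np.zeros(100_000, dtype=int), seed=31)
        big_b = gen_dihedral_series(model, np.zeros(100_000, dtype=int), seed=32)
        small = chi2_profile(small_a, small_b).chi2.mean()
        big = chi2_profile(big_a, big_b).chi2.mean()
        assert big < small


class TestRmsf:
    def test_static_trajectory_zero(self, wt):
        model = wt.mode_model()
        model.amp_sd[:] = 0.0
        model.noise_sd = 0.0
        traj = gen_mode_trajectory(model, 10, seed=0)
        assert np.allclose(rmsf(traj).rmsf, 0.0, atol=1e-12)

    def test_rigid_rotations_removed_by_superposition(self, wt):
        from scipy.spatial.transform import Rotation

        model = wt.mode_model()
        model.amp_sd[:] = 0.0
        model.noise_sd = 0.0
        traj = gen_mode_trajectory(model, 8, seed=0)
        rng = np.random.default_rng(5)
        for f in range(traj.n_frames):
            R = Rotation.random(random_state=rng).as_matrix()
            traj.coords[f] = traj.coords[f] @ R.T + rng.normal(0, 50, 3)
        assert np.allclose(rmsf(traj).rmsf, 0.0, atol=1e-8)

    def test_single_mode_amplitudes_proportional(self, wt):
        model = wt.mode_model()
        model.noise_sd = 0.0
        traj = gen_mode_trajectory(model, 10_000, seed=7)
        vals = rmsf(traj).rmsf.to_numpy()
        expected = model.amp_sd[0] * np.linalg.norm(model.modes[0], axis=1)
        ratio = vals / expected
        assert np.allclose(ratio, ratio.mean(), rtol=0.02)


class TestPcaModes:
    def test_single_mode_recovered(self, wt):
        model = wt.mode_model()
        traj = gen_mode_trajectory(model, 2000, seed=5)
        modes = pca_modes(traj)
        assert cosine(modes.eigenvectors[:, 0], model.modes[0].ravel()) >= 0.99

    def test_trace_identity(self, wt):
        traj = gen_mode_trajectory(wt.mode_model(), 500, seed=6)
        modes = pca_modes(traj)
        total = (rmsf(traj).rmsf.to_numpy() ** 2).sum()
        assert modes.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_isotropic_noise_gives_flat_spectrum(self, wt):
        model = wt.mode_model()
        model.amp_sd[:] = 0.0
        model.noise_sd = 0.5
        traj = gen_mode_trajectory(model, 4000, seed=8)
        ev = pca_modes(traj).eigenvalues
        # no dominant mode: the top eigenvalue stays within the
        # finite-sample (Marchenko-Pastur) spread of an unstructured
        # spectrum rather than towering above the bulk
        bulk = ev[: len(ev) - 6]  # superposition depletes 6 rigid directions
        p_over_n = len(bulk) / traj.n_frames
        mp_edge = (1.0 + np.sqrt(p_over_n)) ** 2
        assert bulk[0] / np.median(bulk) < 1.2 * mp_edge


class TestDccm:
    def _two_atom_traj(self, sign):
        rng = np.random.default_rng(9)
        # small amplitude keeps superposition in the linear regime
        amp = rng.normal(0, 0.05, 400)
        # well-separated static geometry plus a shared 1D mode
        base = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [5.0, 5.0, 7.0]])
        coords = np.tile(base, (400, 1, 1))
        coords[:, 0, 2] += amp
        coords[:, 1, 2] += sign * amp
        import pandas as pd

        from baroshift import Trajectory

        top = pd.DataFrame(
            {
                "residue_id": [1, 2, 3, 4],
                "residue_name": "ALA",
                "atom_name": "CA",
            }
        )
        return Trajectory(coords=coords, topology=top)

    def test_parallel_and_antiparallel_limits(self):
        # the generated frames share one latent amplitude and no rigid
        # motion, so on the pre-aligned coordinates the limit is exact
        for sign, expected in ((1.0, 1.0), (-1.0, -1.0)):
            traj = self._two_atom_traj(sign)
            c = dccm(traj, align=False)
            assert c.iloc[0, 1] == pytest.approx(expected, abs=1e-10)
            # note: after superposition the limit is no longer exact,
            # because this constructed motion carries rigid-body content
            # whose removal redistributes displacements

    def test_symmetry_unit_diagonal_and_range(self, wt):
        traj = gen_mode_trajectory(wt.mode_model(), 300, seed=10)
        c = dccm(traj).to_numpy()
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert np.all(c >= -1.0) and np.all(c <= 1.0)

    def test_rigid_motion_invariance(self, wt):
        from scipy.spatial.transform import Rotation

        traj = gen_mode_trajectory(wt.mode_model(), 200, seed=11)
        ref = dccm(traj).to_numpy()
        rng = np.random.default_rng(12)
        moved = traj.coords.copy()
        for f in range(traj.n_frames):
            R = Rotation.random(random_state=rng).as_matrix()
            moved[f] = moved[f] @ R.T + rng.normal(0, 30, 3)
        from baroshift import Trajectory

        shifted = Trajectory(coords=moved, topology=traj.topology)
        np.testing.assert_allclose(dccm(shifted).to_numpy(), ref, atol=1e-8)

    def test_collective_mode_strengthens_correlations(self, wt, wt_hp):
        traj_wt = gen_mode_trajectory(wt.mode_model(), 1000, seed=13)
        traj_hp = gen_mode_trajectory(wt_hp.mode_model(), 1000, seed=13)
        off = ~np.eye(99, dtype=bool)
        mean_wt = np.abs(dccm(traj_wt).to_numpy()[off]).mean()
        mean_hp = np.abs(dccm(traj_hp).to_numpy()[off]).mean()
        assert mean_wt > mean_hp


class TestSegmentation:
    def test_unimodal_sample_single_state(self):
        rng = np.random.default_rng(0)
        seg = segment_subensembles(rng.normal(5.0, 0.5, 5000))
        assert seg.n_states == 1
        assert len(seg.boundaries) == 0

    def test_three_state_preset_recovered(self, wt_ensemble):
        seg = wt_ensemble["segmentation"]
        labels = wt_ensemble["labels"]
        assert seg.n_states == 3
        assert (seg.labels == labels).mean() >= 0.99

    def test_merged_modes_are_one_state(self):
        rng = np.random.default_rng(1)
        d = np.concatenate([rng.normal(5.0, 0.5, 3000), rng.normal(5.5, 0.5, 3000)])
        assert segment_subensembles(d).n_states == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            segment_subensembles(np.ones(10))


class TestConditionalChi2:
    def test_planted_coupling_separated_tenfold(self, wt, wt_ensemble):
        cond = conditional_chi2(
            wt_ensemble["dihedrals"], wt_ensemble["segmentation"]
        ).set_index("residue_id")
        coupled = sorted(wt.coupled_residues())
        uncoupled_max = cond.loc[~cond.index.isin(coupled), "max_chi2"].max()
        coupled_min = cond.loc[coupled, "max_chi2"].min()
        assert uncoupled_max < 1e-3
        assert coupled_min >= 10.0 * uncoupled_max

    def test_detection_has_perfect_precision_and_recall(self, wt, wt_ensemble):
        cond = conditional_chi2(
            wt_ensemble["dihedrals"], wt_ensemble["segmentation"]
        ).set_index("residue_id")
        detected = set(cond.index[cond.max_chi2 > 1e-3])
        assert detected == set(wt.coupled_residues())

    def test_two_state_labels_single_pair(self, wt):
        labels_raw = np.tile([0, 1], 500)
        ds = gen_dihedral_series(wt.dihedral_model(), labels_raw, seed=40)
        from baroshift.dynamics import SubensembleLabels

        seg = SubensembleLabels(
            labels=labels_raw, boundaries=np.array([5.0]), mode_positions=np.array([3.0, 7.0])
        )
        cond = conditional_chi2(ds, seg)
        pair_cols = [c for c in cond.columns if c.startswith("chi2_")]
        assert pair_cols == ["chi2_a_b"]
        np.testing.assert_allclose(cond.max_chi2, cond.chi2_a_b)

    def test_small_subensemble_flagged(self, wt):
        labels_raw = np.array([0] * 960 + [1] * 40)
        ds = gen_dihedral_series(wt.dihedral_model(), labels_raw, seed=41)
        from baroshift.dynamics import SubensembleLabels

        seg = SubensembleLabels(
            labels=labels_raw, boundaries=np.array([5.0]), mode_positions=np.array([3.0, 7.0])
        )
        cond = conditional_chi2(ds, seg)
        assert cond.low_confidence.all()
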