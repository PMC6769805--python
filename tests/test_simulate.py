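"""Generator ground-truth and reproducibility checks."""

import numpy as np
import pytest

from baroshift import (
    DihedralModel,
    LatentStateChain,
    ModeTrajectoryModel,
    TwoStateShiftModel,
    gen_decay_curves,
    gen_dihedral_series,
    gen_distance_series,
    gen_latent_chain,
    gen_mode_trajectory,
    gen_pressure_series,
    gen_titration,
    fit_sigmoid,
)
from baroshift.simulate import R_GAS, wrap_degrees


def make_shift_model(n=2, **overrides):
    kwargs = dict(
        residue_ids=np.arange(1, n + 1),
        delta_h0=np.full(n, 8.0),
        delta_n0=np.full(n, 120.0),
        slope_h=np.zeros(n),
        slope_n=np.zeros(n),
        amp_h=np.zeros(n),
        amp_n=np.zeros(n),
        dG0=5000.0,
        dV=-50.0,
    )
    kwargs.update(overrides)
    return TwoStateShiftModel(**kwargs)


class TestTwoStateModel:
    def test_population_bounds_and_monotonicity(self):
        m = make_shift_model()
        p = np.linspace(0, 500, 200)
        fe = m.excited_population(p)
        assert np.all((fe >= 0) & (fe <= 1))
        assert np.all(np.diff(fe) > 0)  # dV < 0 favors the excited state

    def test_pure_compression_is_affine(self):
        m = make_shift_model(slope_h=np.array([1e-3, 2e-3]), amp_h=np.zeros(2))
        series = gen_pressure_series(m, [0.0, 50.0, 100.0], noise_sd=0.0)
        dh0 = series.lists[0].get(1).delta_h
        dh2 = series.lists[2].get(1).delta_h
        assert dh2 - dh0 == pytest.approx(0.1, abs=1e-12)

    def test_saturation_limit(self):
        m = make_shift_model(dG0=0.0, amp_h=np.array([0.5, 0.5]))
        series = gen_pressure_series(m, [0.0, 10.0, 1e6], noise_sd=0.0)
        assert series.lists[2].get(1).delta_h == pytest.approx(8.5, abs=1e-9)

    def test_transition_amplitude_identity(self):
        # with zero slopes the shift change between extreme pressures is
        # exactly amp * (f_E(p_max) - f_E(p_min))
        amp = np.array([0.3, -0.2])
        m = make_shift_model(amp_h=amp)
        p = [5.0, 100.0, 225.0]
        series = gen_pressure_series(m, p, noise_sd=0.0)
        dfe = m.excited_population(225.0) - m.excited_population(5.0)
        for i, rid in enumerate([1, 2]):
            delta = series.lists[2].get(rid).delta_h - series.lists[0].get(rid).delta_h
            assert delta == pytest.approx(amp[i] * dfe, abs=1e-12)

    def test_default_preset_dimensions(self, wt_series):
        assert len(wt_series) == 10
        assert len(wt_series.traceable_residues) == 82

    def test_errors(self):
        m = make_shift_model()
        with pytest.raises(ValueError):
            gen_pressure_series(m, [10.0, 5.0, 20.0])
        with pytest.raises(ValueError):
            gen_pressure_series(m, [0.0, 5.0, 10.0], noise_sd=-0.1)


class TestLatentChain:
    def test_identity_table_freezes_state(self):
        chain = LatentStateChain(np.eye(3), initial=[1.0, 0.0, 0.0])
        labels = gen_latent_chain(chain, 500, seed=0)
        assert np.all(labels == 0)

    def test_single_state(self):
        labels = gen_latent_chain(LatentStateChain(np.ones((1, 1))), 100, seed=0)
        assert np.all(labels == 0)

    def test_occupancy_converges_to_stationary(self):
        t = np.full((3, 3), 0.01)
        np.fill_diagonal(t, 0.98)
        chain = LatentStateChain(t)
        assert chain.stationary() == pytest.approx(np.full(3, 1 / 3), abs=1e-12)
        labels = gen_latent_chain(chain, 100_000, seed=1)
        occ = np.bincount(labels, minlength=3) / len(labels)
        assert np.all(np.abs(occ - 1 / 3) < 0.02)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            LatentStateChain(np.array([[0.5, 0.4], [0.5, 0.5]]))
        with pytest.raises(ValueError):
            LatentStateChain(np.array([[1.2, -0.2], [0.0, 1.0]]))


def make_dihedral_model(k=3, coupled=True, sep=60.0, kappa=8.0):
    mu_phi = np.full((1, k), -100.0)
    mu_psi = np.full((1, k), 130.0)
    if coupled and k > 1:
        mu_phi = mu_phi + np.arange(k) * sep
    return DihedralModel(
        residue_ids=np.array([1]),
        mu_phi=mu_phi,
        mu_psi=mu_psi,
        kappa_phi=np.full((1, k), kappa),
        kappa_psi=np.full((1, k), kappa),
        coupled=np.array([coupled]),
    )


class TestDihedralGenerator:
    def test_degenerate_concentration_pins_to_mean(self):
        m = make_dihedral_model(k=1, coupled=False, kappa=1e8)
        ds = gen_dihedral_series(m, np.zeros(200, dtype=int), seed=0)
        phi, psi = ds.angles(1)
        assert np.allclose(phi, -100.0, atol=0.05)
        assert np.allclose(psi, 130.0, atol=0.05)

    def test_uncoupled_ignores_label_permutation(self):
        m = make_dihedral_model(k=3, coupled=False)
        labels = np.tile([0, 1, 2], 100)
        rng = np.random.default_rng(0)
        perm = rng.permutation(labels)
        a = gen_dihedral_series(m, labels, seed=4)
        b = gen_dihedral_series(m, perm, seed=4)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.psi, b.psi)

    def test_coupled_states_give_bimodal_histogram(self):
        m = make_dihedral_model(k=2, sep=60.0, kappa=30.0)
        labels = np.tile([0, 1], 25_000)
        ds = gen_dihedral_series(m, labels, seed=5)
        phi, _ = ds.angles(1)
        from scipy.signal import find_peaks

        counts, edges = np.histogram(phi, bins=120, range=(-180, 180))
        centers = (edges[:-1] + edges[1:]) / 2
        idx, _ = find_peaks(counts, height=0.3 * counts.max(), distance=5)
        peaks = centers[idx]
        assert len(peaks) == 2
        assert np.min(np.abs(peaks - (-100.0))) < 5.0
        assert np.min(np.abs(peaks - (-40.0))) < 5.0

    def test_missing_state_parameters_rejected(self):
        m = make_dihedral_model(k=2)
        with pytest.raises(ValueError):
            gen_dihedral_series(m, np.array([0, 1, 2]), seed=0)

    def test_angles_in_convention(self):
        m = make_dihedral_model(k=1, coupled=False, kappa=0.01)
        ds = gen_dihedral_series(m, np.zeros(5000, dtype=int), seed=6)
        assert np.all(ds.phi > -180.0) and np.all(ds.phi <= 180.0)


class TestDistanceGenerator:
    def test_single_tight_state_is_constant(self):
        d = gen_distance_series([5.0], [1e-9], np.zeros(100, dtype=int), seed=0)
        assert np.allclose(d, 5.0, atol=1e-6)

    def test_distances_nonnegative(self):
        d = gen_distance_series([0.5], [1.0], np.zeros(5000, dtype=int), seed=1)
        assert np.all(d >= 0)

    def test_errors(self):
        with pytest.raises(ValueError):
            gen_distance_series([3.0], [0.0], np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            gen_distance_series([-1.0], [0.4], np.zeros(10, dtype=int))


class TestModeTrajectory:
    def _model(self, n_atoms=5, amp=1.0, noise=0.0, n_modes=1):
        rng = np.random.default_rng(3)
        mean = rng.normal(0, 5, (n_atoms, 3))
        raw = rng.normal(0, 1, (n_modes, n_atoms * 3))
        q, _ = np.linalg.qr(raw.T)
        modes = q.T[:n_modes].reshape(n_modes, n_atoms, 3)
        return ModeTrajectoryModel(
            mean=mean, modes=modes, amp_sd=np.full(n_modes, amp), noise_sd=noise
        )

    def test_zero_amplitude_zero_noise_gives_mean(self):
        m = self._model(amp=0.0)
        t = gen_mode_trajectory(m, 10, seed=0)
        assert np.allclose(t.coords, m.mean[None])

    def test_single_mode_covariance_rank_one(self):
        m = self._model(amp=1.0)
        t = gen_mode_trajectory(m, 200, seed=0)
        flat = t.coords.reshape(200, -1)
        dev = flat - flat.mean(axis=0)
        s = np.linalg.svd(dev, compute_uv=False)
        assert s[1] / s[0] < 1e-10

    def test_shared_mode_component_perfectly_correlated(self):
        m = self._model(amp=1.0)
        t = gen_mode_trajectory(m, 500, seed=1)
        # displacement along the mode direction is the same latent series
        # for every atom; project two atoms' displacements on their mode parts
        d0 = (t.coords[:, 0] - m.mean[0]) @ m.modes[0, 0] / np.linalg.norm(m.modes[0, 0]) ** 2
        d1 = (t.coords[:, 1] - m.mean[1]) @ m.modes[0, 1] / np.linalg.norm(m.modes[0, 1]) ** 2
        assert np.corrcoef(d0, d1)[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_non_orthogonal_modes_rejected(self):
        mean = np.zeros((4, 3))
        v = np.zeros((4, 3))
        v[0, 0] = 1.0
        with pytest.raises(ValueError):
            ModeTrajectoryModel(mean=mean, modes=np.stack([v, v]), amp_sd=np.ones(2))


class TestDecayGenerator:
    def test_zero_rate_constant(self):
        c = gen_decay_curves(0.0, [0.0, 1.0, 2.0])
        assert np.allclose(c.intensities, 1.0)

    def test_closed_form_point(self):
        c = gen_decay_curves(10.0, [0.0, 0.05, 0.1])
        assert c.intensities[2] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_r2_preset_delay_grid(self, wt):
        curves = wt.r2_curves(seed=0)
        delays = curves[0].times
        assert len(delays) == 7
        assert delays[0] == pytest.approx(0.0176)
        assert delays[-1] == pytest.approx(0.2288)
        assert np.allclose(np.diff(delays), 0.0352)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_decay_curves(-1.0, [0.0, 1.0])


class TestTitrationGenerator:
    def test_midpoint_symmetry(self):
        c = gen_titration(4.5, 2.0, (1.0, 3.0), [3.0, 4.0, 4.5, 5.0, 6.0])
        assert c.signal[2] == pytest.approx(2.0, abs=1e-12)

    def test_high_ph_reaches_folded_baseline(self):
        c = gen_titration(4.5, 2.0, (1.0, 3.0), [3.0, 4.0, 5.0, 6.0, 12.0])
        assert c.signal[-1] == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_refit(self, wt):
        fit = fit_sigmoid(wt.titration_curve(noiseless=True))
        assert fit.midpoint == pytest.approx(wt.unfolding_midpoint, abs=1e-6)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            gen_titration(4.5, 0.0, (1.0, 3.0), [3, 4, 5, 6, 7])


class TestReproducibility:
    def test_same_seed_same_stream(self, wt):
        a = gen_pressure_series(wt.shift_model(), wt.pressures, noise_sd=0.002, seed=9)
        b = gen_pressure_series(wt.shift_model(), wt.pressures, noise_sd=0.002, seed=9)
        for pa, pb in zip(a.lists[3].peaks, b.lists[3].peaks):
            assert pa == pb

    def test_adding_residues_preserves_existing_streams(self):
        m2 = make_shift_model(n=2)
        m3 = make_shift_model(n=3)
        a = gen_pressure_series(m2, [0, 50, 100], noise_sd=0.01, seed=2)
        b = gen_pressure_series(m3, [0, 50, 100], noise_sd=0.01, seed=2)
        for j in range(3):
            for rid in (1, 2):
                assert a.lists[j].get(rid) == b.lists[j].get(rid)


def test_wrap_degrees_convention():
    assert wrap_degrees(180.0) == 180.0
    assert wrap_degrees(-180.0) == 180.0
    assert wrap_degrees(360.0) == pytest.approx(0.0)
    assert wrap_degrees(190.0) == pytest.approx(-170.0)
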