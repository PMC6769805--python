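"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here, with
the statistical structure the analyses assume:

* pressure-dependent peak positions as the sum of a linear compression
  term and a two-state population-shift term (``δ(p) = δ0 + slope·p +
  f_E(p)·amp``), with the excited-state population following pressure
  through ``f_E(p) = 1/(1 + exp((ΔG0 + p·ΔV)/(R·T)))`` — ``ΔV < 0``
  makes the excited state grow with pressure;
* backbone dihedral and side-chain distance series conditioned on a small
  latent-state Markov chain (three states for a heterogeneous wild-type
  ensemble, one for a converged mutant/high-pressure ensemble);
* mode-plus-noise coordinate trajectories for fluctuation analyses;
* mono-exponential intensity decays and sigmoidal pH-titration curves.

All generators draw from per-item independent substreams keyed on
``(seed, stream tag, item id)``, so adding residues never perturbs the
draws of existing ones and identical seeds reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .peaklists import Peak, PeakList, PressureSeries
from .relaxation import DecayCurve
from .trajectory import DihedralSeries, Trajectory
from .unfolding import TitrationCurve, sigmoid

__all__ = [
    "R_GAS",
    "TwoStateShiftModel",
    "LatentStateChain",
    "DihedralModel",
    "ModeTrajectoryModel",
    "gen_pressure_series",
    "gen_latent_chain",
    "gen_dihedral_series",
    "gen_distance_series",
    "gen_mode_trajectory",
    "gen_decay_curves",
    "gen_titration",
    "wrap_degrees",
]

R_GAS = 8.314  # J/(mol K); 1 MPa·mL/mol = 1 J/mol

# stream tags keep generator substreams disjoint
_STREAM_SHIFT, _STREAM_CHAIN, _STREAM_DIHEDRAL = 1, 2, 3
_STREAM_DISTANCE, _STREAM_MODES, _STREAM_DECAY, _STREAM_TITRATION = 4, 5, 6, 7


def _rng(seed: int, stream: int, item: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream, item)))


def wrap_degrees(angle):
    """Map angles into the (−180, 180] convention."""
    return 180.0 - (180.0 - np.asarray(angle, dtype=float)) % 360.0


# ------------------------------------------------------------- chemical shifts


@dataclass
class TwoStateShiftModel:
    """Pressure response of per-residue amide shifts.

    Each residue moves linearly with pressure (compression, ``slope_H``/
    ``slope_N`` in ppm/MPa) and additionally tracks the excited-state
    population with amplitude ``amp_H``/``amp_N`` (ppm).  The global
    two-state thermodynamics are ``dG0`` (J/mol, excited minus ground at
    zero pressure) and ``dV`` (mL/mol); negative ``dV`` favors the
    excited state under pressure.
    """

    residue_ids: np.ndarray
    delta_h0: np.ndarray
    delta_n0: np.ndarray
    slope_h: np.ndarray
    slope_n: np.ndarray
    amp_h: np.ndarray
    amp_n: np.ndarray
    dG0: float
    dV: float
    temperature: float = 298.15
    residue_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = len(self.residue_ids)
        for name in ("delta_h0", "delta_n0", "slope_h", "slope_n", "amp_h", "amp_n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per residue")
            setattr(self, name, arr)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def excited_population(self, pressure) -> np.ndarray:
        """f_E(p) = 1 / (1 + exp((ΔG0 + p·ΔV)/(R·T))), in [0, 1]."""
        p = np.asarray(pressure, dtype=float)
        return 1.0 / (1.0 + np.exp((self.dG0 + p * self.dV) / (R_GAS * self.temperature)))

    def shifts_at(self, pressure: float) -> tuple[np.ndarray, np.ndarray]:
        fe = self.excited_population(pressure)
        dh = self.delta_h0 + self.slope_h * pressure + fe * self.amp_h
        dn = self.delta_n0 + self.slope_n * pressure + fe * self.amp_n
        return dh, dn


def gen_pressure_series(
    model: TwoStateShiftModel,
    pressures,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_sd_n: float | None = None,
    condition: str = "",
) -> PressureSeries:
    """Peak lists across a pressure titration.

    ``noise_sd`` is the Gaussian noise on the ¹H axis (ppm);
    ``noise_sd_n`` defaults to five times that, mirroring the wider ¹⁵N
    scale.  Noise is drawn per residue from independent substreams.
    """
    pressures = np.asarray(pressures, dtype=float)
    if len(pressures) < 3 or np.any(np.diff(pressures) <= 0):
        raise ValueError("pressures must be strictly increasing, length >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd_n is None:
        noise_sd_n = 5.0 * noise_sd
    P = len(pressures)
    names = (
        model.residue_names
        if model.residue_names is not None
        else [None] * len(model.residue_ids)
    )
    noise_h = np.zeros((len(model.residue_ids), P))
    noise_n = np.zeros_like(noise_h)
    for i, rid in enumerate(model.residue_ids):
        r = _rng(seed, _STREAM_SHIFT, int(rid))
        noise_h[i] = r.normal(0.0, noise_sd, P) if noise_sd else 0.0
        noise_n[i] = r.normal(0.0, noise_sd_n, P) if noise_sd_n else 0.0
    lists = []
    for j, p in enumerate(pressures):
        dh, dn = model.shifts_at(p)
        peaks = [
            Peak(
                residue_id=int(rid),
                residue_name=names[i],
                delta_h=float(dh[i] + noise_h[i, j]),
                delta_n=float(dn[i] + noise_n[i, j]),
            )
            for i, rid in enumerate(model.residue_ids)
        ]
        lists.append(PeakList(peaks, condition=condition, pressure=float(p)))
    return PressureSeries(lists, condition=condition)


# ------------------------------------------------------------- latent states


@dataclass
class LatentStateChain:
    """A small discrete-state Markov chain over trajectory frames."""

    transition: np.ndarray
    initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        k = self.transition.shape[0]
        if self.transition.shape != (k, k):
            raise ValueError("transition table must be square")
        if np.any(self.transition < 0) or np.any(self.transition > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(self.transition.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition rows must sum to 1 within 1e-12")
        if self.initial is None:
            self.initial = np.full(k, 1.0 / k)
        else:
            self.initial = np.asarray(self.initial, dtype=float)
            if self.initial.shape != (k,) or abs(self.initial.sum() - 1.0) > 1e-12:
                raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left Perron eigenvector)."""
        w, v = np.linalg.eig(self.transition.T)
        i = np.argmin(np.abs(w - 1.0))
        pi = np.real(v[:, i])
        return pi / pi.sum()


def gen_latent_chain(chain: LatentStateChain, n_frames: int, seed: int = 0) -> np.ndarray:
    """Sample per-frame state labels by Markov simulation."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    r = _rng(seed, _STREAM_CHAIN)
    labels = np.empty(n_frames, dtype=int)
    cum = np.cumsum(chain.transition, axis=1)
    labels[0] = r.choice(chain.n_states, p=chain.initial)
    u = r.random(n_frames - 1)
    for t in range(1, n_frames):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t - 1], side="right")
    return labels


# ----------------------------------------------------------------- dihedrals


@dataclass
class DihedralModel:
    """State-conditional von Mises (φ, ψ) parameters per residue.

    Arrays are (R, K): row per residue, column per latent state, angles in
    degrees and concentrations dimensionless.  Rows flagged uncoupled must
    carry identical parameters in every state and are sampled without
    reference to the state labels.
    """

    residue_ids: np.ndarray
    mu_phi: np.ndarray
    mu_psi: np.ndarray
    kappa_phi: np.ndarray
    kappa_psi: np.ndarray
    coupled: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        r = len(self.residue_ids)
        for name in ("mu_phi", "mu_psi", "kappa_phi", "kappa_psi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[0] != r:
                raise ValueError(f"{name} must be (n_residues, n_states)")
            setattr(self, name, arr)
        self.coupled = np.asarray(self.coupled, dtype=bool)
        if np.any(self.kappa_phi <= 0) or np.any(self.kappa_psi <= 0):
            raise ValueError("von Mises concentrations must be positive")
        for i in np.flatnonzero(~self.coupled):
            for name in ("mu_phi", "mu_psi", "kappa_phi", "kappa_psi"):
                arr = getattr(self, name)
                if not np.allclose(arr[i], arr[i, 0]):
                    raise ValueError(
                        f"uncoupled residue {self.residue_ids[i]} has "
                        f"state-dependent {name}"
                    )

    @property
    def n_states(self) -> int:
        return self.mu_phi.shape[1]


def gen_dihedral_series(
    model: DihedralModel, labels: np.ndarray, seed: int = 0
) -> DihedralSeries:
    """Sample (φ, ψ) series conditioned on latent-state labels.

    Coupled residues draw from the state-indexed von Mises pair of each
    frame's label; uncoupled residues ignore the labels entirely (their
    stream depends only on the seed and residue id).  Angles are degrees
    in (−180, 180].
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    observed = np.unique(labels)
    if observed.max() >= model.n_states or observed.min() < 0:
        raise ValueError(
            f"labels reference state {observed.max()} but model has "
            f"{model.n_states} states"
        )
    R = len(model.residue_ids)
    phi = np.empty((R, n))
    psi = np.empty((R, n))
    for i, rid in enumerate(model.residue_ids):
        r = _rng(seed, _STREAM_DIHEDRAL, int(rid))
        if model.coupled[i]:
            for s in observed:
                mask = labels == s
                m = int(mask.sum())
                phi[i, mask] = r.vonmises(np.radians(model.mu_phi[i, s]), model.kappa_phi[i, s], m)
                psi[i, mask] = r.vonmises(np.radians(model.mu_psi[i, s]), model.kappa_psi[i, s], m)
        else:
            phi[i] = r.vonmises(np.radians(model.mu_phi[i, 0]), model.kappa_phi[i, 0], n)
            psi[i] = r.vonmises(np.radians(model.mu_psi[i, 0]), model.kappa_psi[i, 0], n)
    return DihedralSeries(
        residue_ids=model.residue_ids,
        phi=wrap_degrees(np.degrees(phi)),
        psi=wrap_degrees(np.degrees(psi)),
    )


# ------------------------------------------------------------------ distances


def gen_distance_series(
    state_means, state_sds, labels: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Label-conditioned Gaussian distances (Å), truncated at zero."""
    means = np.asarray(state_means, dtype=float)
    sds = np.asarray(state_sds, dtype=float)
    if means.shape != sds.shape:
        raise ValueError("need one sd per state mean")
    if np.any(means <= 0):
        raise ValueError("state means must be positive distances")
    if np.any(sds <= 0):
        raise ValueError("state sds must be positive")
    labels = np.asarray(labels, dtype=int)
    if labels.max() >= len(means):
        raise ValueError("label references a state without distance parameters")
    r = _rng(seed, _STREAM_DISTANCE)
    out = np.empty(len(labels))
    for s in np.unique(labels):
        mask = labels == s
        a = (0.0 - means[s]) / sds[s]
        out[mask] = truncnorm.rvs(
            a, np.inf, loc=means[s], scale=sds[s], size=int(mask.sum()), random_state=r
        )
    return out


# ------------------------------------------------------------------- modes


@dataclass
class ModeTrajectoryModel:
    """Mean structure plus orthonormal collective modes and isotropic noise."""

    mean: np.ndarray  # (A, 3), Å
    modes: np.ndarray  # (M, A, 3), mutually orthogonal unit vectors
    amp_sd: np.ndarray  # (M,), Å
    noise_sd: float = 0.0
    residue_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        self.amp_sd = np.atleast_1d(np.asarray(self.amp_sd, dtype=float))
        if self.modes.ndim != 3 or self.modes.shape[1:] != self.mean.shape:
            raise ValueError("modes must be (n_modes, n_atoms, 3)")
        flat = self.modes.reshape(len(self.modes), -1)
        gram = flat @ flat.T
        if not np.allclose(gram, np.eye(len(flat)), atol=1e-8):
            raise ValueError("mode vectors must be orthonormal")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, len(self.mean) + 1)


def gen_mode_trajectory(
    model: ModeTrajectoryModel, n_frames: int, seed: int = 0
) -> Trajectory:
    """Frames = mean + Σ_k a_k(t)·mode_k + noise, a_k ~ N(0, amp_sd_k²).

    No global rotation or translation is applied.  The topology is one
    Cα pseudo-atom per residue.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    r = _rng(seed, _STREAM_MODES)
    M, A, _ = model.modes.shape
    amps = r.normal(0.0, 1.0, (n_frames, M)) * model.amp_sd[None, :]
    coords = model.mean[None, :, :] + np.einsum("fm,mad->fad", amps, model.modes)
    if model.noise_sd > 0:
        coords = coords + r.normal(0.0, model.noise_sd, coords.shape)
    topology = pd.DataFrame(
        {
            "residue_id": np.asarray(model.residue_ids, dtype=int),
            "residue_name": "ALA",
            "atom_name": "CA",
        }
    )
    return Trajectory(coords=coords, topology=topology)


# -------------------------------------------------------------------- decays


def gen_decay_curves(
    rate: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    residue_id: int | None = None,
    time_unit: str = "s",
) -> DecayCurve:
    """Mono-exponential decay ``I(t) = I0·exp(−rate·t)`` plus noise."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    times = np.asarray(times, dtype=float)
    y = amplitude * np.exp(-rate * times)
    if noise_sd > 0:
        r = _rng(seed, _STREAM_DECAY, residue_id or 0)
        y = y + r.normal(0.0, noise_sd, y.shape)
    return DecayCurve(times=times, intensities=y, residue_id=residue_id, time_unit=time_unit)


# ------------------------------------------------------------------ titration


def gen_titration(
    midpoint_ph: float,
    slope: float,
    baselines: tuple[float, float],
    ph_points,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Sigmoidal pH-unfolding curve with Gaussian noise.

    ``baselines`` is ``(s_folded, s_unfolded)``; with positive ``slope``
    the folded baseline is approached at high pH (acid unfolding).
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    ph = np.asarray(ph_points, dtype=float)
    if np.any(np.diff(ph) <= 0):
        raise ValueError("pH points must be strictly increasing")
    s_folded, s_unfolded = baselines
    y = sigmoid(ph, midpoint_ph, slope, s_folded, s_unfolded)
    if noise_sd > 0:
        r = _rng(seed, _STREAM_TITRATION)
        y = y + r.normal(0.0, noise_sd, y.shape)
    return TitrationCurve(ph=ph, signal=y)
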