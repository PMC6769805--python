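"""Named synthetic study conditions.

Three presets mirror the measurement conditions of the pressure/mutation
study design: ``WT_AP`` (wild type, ambient pressure — a heterogeneous
ensemble with three local subensembles and mobile peripheral loops),
``D76N_AP`` (the destabilized mutant at ambient pressure — converged to a
single subensemble) and ``WT_HP`` (wild type under high pressure, which
mimics the mutant).  Each preset is a plain-text key-value file shipped
in ``baroshift/data/presets`` and is the single source of ground truth
for recovery tests: per-residue model parameters are derived
deterministically from the recorded ``param_seed``, so WT/mutant pairs
sharing a seed differ exactly by the planted contrasts.
"""

from __future__ import annotations

import configparser
import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .decomposition import NITROGEN_SCALE
from .relaxation import DecayCurve
from .simulate import (
    DihedralModel,
    LatentStateChain,
    ModeTrajectoryModel,
    TwoStateShiftModel,
    gen_decay_curves,
    gen_titration,
)
from .unfolding import TitrationCurve

__all__ = ["Preset", "load_preset", "available_presets"]

# parameter-derivation stream tags (distinct from the generator streams)
_P_BASE, _P_SLOPE, _P_AMP, _P_DIHEDRAL, _P_MODE = 101, 102, 103, 104, 105


def _prng(param_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((param_seed, stream)))


def _ints(text: str) -> list[int]:
    return [int(tok) for tok in text.split()]


def _floats(text: str) -> np.ndarray:
    return np.array([float(tok) for tok in text.split()])


@dataclass
class Preset:
    """One study condition; builds every generator model on demand."""

    name: str
    config: configparser.ConfigParser

    # ----------------------------------------------------------- basics

    @property
    def description(self) -> str:
        return self.config["meta"]["description"]

    @property
    def sequence(self) -> str:
        return self.config["meta"]["sequence"]

    @property
    def param_seed(self) -> int:
        return int(self.config["meta"]["param_seed"])

    @property
    def pressures(self) -> np.ndarray:
        return _floats(self.config["pressure"]["pressures"])

    @property
    def noise_sd_h(self) -> float:
        return float(self.config["pressure"]["noise_sd_h"])

    def traceable_residues(self) -> np.ndarray:
        excluded = set(_ints(self.config["pressure"]["excluded_residues"]))
        return np.array(
            [i for i in range(1, len(self.sequence) + 1) if i not in excluded]
        )

    # ------------------------------------------------------ shift model

    def shift_model(self) -> TwoStateShiftModel:
        """Two-state pressure-shift model with seed-derived parameters.

        Baseline shifts, compression slopes and transition amplitudes are
        drawn from the recorded ``param_seed``; the transition amplitude
        vector is orthogonalized against the slope vector in the weighted
        (N/5) row space, consistent with the decomposition's assumption
        that the two responses are independent directions.  Mutation
        presets add fixed offsets to the baseline shifts of the residues
        listed in the config.
        """
        cfg = self.config["pressure"]
        rids = self.traceable_residues()
        n = len(rids)
        base = _prng(self.param_seed, _P_BASE)
        delta_h0 = 8.3 + 0.4 * base.standard_normal(n)
        delta_n0 = 119.0 + 4.0 * base.standard_normal(n)
        slope = _prng(self.param_seed, _P_SLOPE)
        slope_h = float(cfg["slope_sd_h"]) * slope.standard_normal(n)
        slope_n = float(cfg["slope_sd_n"]) * slope.standard_normal(n)
        amp = _prng(self.param_seed, _P_AMP)
        amp_h = float(cfg["amp_sd_h"]) * amp.standard_normal(n)
        amp_n = float(cfg["amp_sd_n"]) * amp.standard_normal(n)

        # orthogonalize the transition loading against the compression
        # loading in the weighted row metric
        c = np.empty(2 * n)
        a = np.empty(2 * n)
        c[0::2], c[1::2] = slope_h, slope_n * NITROGEN_SCALE
        a[0::2], a[1::2] = amp_h, amp_n * NITROGEN_SCALE
        a -= (a @ c) / (c @ c) * c
        amp_h, amp_n = a[0::2], a[1::2] / NITROGEN_SCALE

        offsets = _ints(cfg["mutation_offset_residues"])
        if offsets:
            off_h = float(cfg["mutation_offset_h"])
            off_n = float(cfg["mutation_offset_n"])
            mask = np.isin(rids, offsets)
            delta_h0 = delta_h0 + mask * off_h
            delta_n0 = delta_n0 + mask * off_n
        names = np.array([self.sequence[i - 1] for i in rids])
        return TwoStateShiftModel(
            residue_ids=rids,
            delta_h0=delta_h0,
            delta_n0=delta_n0,
            slope_h=slope_h,
            slope_n=slope_n,
            amp_h=amp_h,
            amp_n=amp_n,
            dG0=float(cfg["dg0_j_per_mol"]),
            dV=float(cfg["dv_ml_per_mol"]),
            temperature=float(cfg["temperature_k"]),
            residue_names=names,
        )

    # ------------------------------------------------------ latent chain

    def chain(self) -> LatentStateChain:
        cfg = self.config["chain"]
        k = int(cfg["n_states"])
        trans = _floats(cfg["transition"]).reshape(k, k)
        initial = None if cfg["initial"].strip() == "uniform" else _floats(cfg["initial"])
        return LatentStateChain(transition=trans, initial=initial)

    # -------------------------------------------------------- dihedrals

    def coupled_residues(self) -> list[int]:
        return _ints(self.config["dihedrals"]["coupled_residues"])

    def dihedral_model(self) -> DihedralModel:
        """State-conditional von Mises parameters for every residue.

        Base (φ, ψ) means are seed-derived per residue (shared across
        presets with the same ``param_seed``).  Coupled residues shift
        their means by ±``coupled_shift_deg`` in the higher latent states;
        the single-state presets therefore sit at the base parameters,
        i.e. exactly the wild type's first subensemble.
        """
        cfg = self.config["dihedrals"]
        k = int(self.config["chain"]["n_states"])
        kappa = float(cfg["kappa"])
        shift = float(cfg["coupled_shift_deg"])
        n_res = len(self.sequence)
        rids = np.arange(1, n_res + 1)
        r = _prng(self.param_seed, _P_DIHEDRAL)
        base_phi = r.uniform(-150.0, -70.0, n_res)
        base_psi = r.uniform(110.0, 160.0, n_res)
        state_shift = np.array([0.0, shift, -shift])[:k]
        mu_phi = base_phi[:, None] + np.zeros((n_res, k))
        mu_psi = base_psi[:, None] + np.zeros((n_res, k))
        coupled = np.isin(rids, self.coupled_residues())
        mu_phi[coupled] += state_shift[None, :]
        mu_psi[coupled] -= state_shift[None, :]
        return DihedralModel(
            residue_ids=rids,
            mu_phi=mu_phi,
            mu_psi=mu_psi,
            kappa_phi=np.full((n_res, k), kappa),
            kappa_psi=np.full((n_res, k), kappa),
            coupled=coupled,
        )

    # --------------------------------------------------------- distances

    @property
    def distance_means(self) -> np.ndarray:
        return _floats(self.config["distance"]["state_means"])

    @property
    def distance_sds(self) -> np.ndarray:
        return _floats(self.config["distance"]["state_sds"])

    # ------------------------------------------------------------- modes

    def mode_model(self) -> ModeTrajectoryModel:
        """One smooth collective mode over a helical Cα mean structure.

        The seed-derived mode is smoothed along the chain and projected
        onto the complement of the rigid-body subspace of the mean
        structure (net translations and infinitesimal rotations), since a
        collective *internal* motion carries no rigid-body component —
        and superposition during analysis would remove one anyway.
        """
        cfg = self.config["modes"]
        n = len(self.sequence)
        t = np.arange(n, dtype=float)
        mean = np.column_stack(
            [10.0 * np.cos(0.6 * t), 10.0 * np.sin(0.6 * t), 1.5 * t]
        )
        r = _prng(self.param_seed, _P_MODE)
        raw = r.standard_normal((n, 3))
        kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
        kernel /= kernel.sum()
        smooth = np.column_stack(
            [np.convolve(raw[:, d], kernel, mode="same") for d in range(3)]
        )
        # rigid-body subspace: 3 translations + 3 rotations about the centroid
        centered = mean - mean.mean(axis=0)
        rigid = np.zeros((6, n, 3))
        for d in range(3):
            rigid[d, :, d] = 1.0
            axis = np.zeros(3)
            axis[d] = 1.0
            rigid[3 + d] = np.cross(axis[None, :], centered)
        q, _ = np.linalg.qr(rigid.reshape(6, -1).T)
        flat = smooth.ravel()
        flat = flat - q @ (q.T @ flat)
        mode = (flat / np.linalg.norm(flat)).reshape(n, 3)
        return ModeTrajectoryModel(
            mean=mean,
            modes=mode[None, :, :],
            amp_sd=np.array([float(cfg["mode_amp_sd"])]),
            noise_sd=float(cfg["noise_sd"]),
            residue_ids=np.arange(1, n + 1),
        )

    # ---------------------------------------------------------------- R2

    def r2_true_rates(self) -> dict[int, float]:
        cfg = self.config["r2"]
        elevated = set(_ints(cfg["elevated_residues"]))
        base = float(cfg["baseline_rate"])
        elev = float(cfg["elevated_rate"])
        return {
            rid: (elev if rid in elevated else base)
            for rid in range(1, len(self.sequence) + 1)
        }

    def r2_curves(self, seed: int = 0) -> list[DecayCurve]:
        cfg = self.config["r2"]
        delays_s = _floats(cfg["delays_ms"]) / 1000.0
        noise = float(cfg["noise_sd"])
        return [
            gen_decay_curves(
                rate, delays_s, noise_sd=noise, seed=seed, residue_id=rid, time_unit="s"
            )
            for rid, rate in self.r2_true_rates().items()
        ]

    # ---------------------------------------------------------- exchange

    def exchange_true_rates(self) -> dict[int, float]:
        """Ground-truth chemical exchange rates (per minute)."""
        cfg = self.config["exchange"]
        rates = {}
        for rid in _ints(cfg["core_residues"]):
            rates[rid] = float(cfg["k_ex_core_per_min"])
        for rid in _ints(cfg["loop_residues"]):
            rates[rid] = float(cfg["k_ex_loop_per_min"])
        return rates

    @property
    def k_agg(self) -> float | None:
        k = float(self.config["exchange"]["k_agg_per_min"])
        return k if k > 0 else None

    def exchange_curves(self, seed: int = 0) -> list[DecayCurve]:
        """Observed decays: chemical exchange plus the aggregation channel."""
        cfg = self.config["exchange"]
        times = _floats(cfg["times_min"])
        noise = float(cfg["noise_sd"])
        k_agg = self.k_agg or 0.0
        return [
            gen_decay_curves(
                k_ex + k_agg, times, noise_sd=noise, seed=seed,
                residue_id=rid, time_unit="min",
            )
            for rid, k_ex in sorted(self.exchange_true_rates().items())
        ]

    # --------------------------------------------------------- unfolding

    @property
    def unfolding_midpoint(self) -> float:
        return float(self.config["unfolding"]["midpoint_ph"])

    def titration_curve(self, seed: int = 0, noiseless: bool = False) -> TitrationCurve:
        cfg = self.config["unfolding"]
        ph = np.linspace(float(cfg["ph_min"]), float(cfg["ph_max"]), int(cfg["n_points"]))
        baselines = (float(cfg["s_folded"]), float(cfg["s_unfolded"]))
        noise = 0.0 if noiseless else float(cfg["noise_fraction"]) * abs(
            baselines[1] - baselines[0]
        )
        return gen_titration(
            midpoint_ph=self.unfolding_midpoint,
            slope=float(cfg["slope"]),
            baselines=baselines,
            ph_points=ph,
            noise_sd=noise,
            seed=seed,
        )


def available_presets() -> list[str]:
    root = importlib.resources.files("baroshift").joinpath("data/presets")
    return sorted(p.name[:-4].upper() for p in root.iterdir() if p.name.endswith(".cfg"))


@lru_cache(maxsize=None)
def load_preset(name: str) -> Preset:
    """Load a preset by condition label (``WT_AP``, ``D76N_AP``, ``WT_HP``)."""
    fname = f"{name.lower()}.cfg"
    path = importlib.resources.files("baroshift").joinpath(f"data/presets/{fname}")
    if not path.is_file():
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}")
    cfg = configparser.ConfigParser()
    cfg.read_string(path.read_text())
    return Preset(name=cfg["meta"]["name"], config=cfg)
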