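"""Trajectory-derived dynamics statistics.

Covers the comparison toolkit for conformational ensembles: binned
backbone-dihedral distributions and their χ² difference statistic,
per-residue RMSF about an iteratively superposed mean structure,
principal-component (essential dynamics) modes, the dynamic
cross-correlation matrix (DCCM), kernel-density segmentation of a
side-chain distance into subensembles, and the subensemble-conditioned
χ² that flags residues whose backbone distribution depends on the local
state of a distant contact.

The χ² statistic between two binned (φ, ψ) distributions is

    χ² = (1/n²) · Σ_i Σ_j (f1(φ_i, ψ_j) − f2(φ_i, ψ_j))²

with n = 10 bins of 36° per axis and f the *fraction* of frames per cell,
which makes the value independent of frame count in expectation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from string import ascii_lowercase

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .trajectory import DihedralSeries, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "N_DIHEDRAL_BINS",
    "DIHEDRAL_BIN_WIDTH",
    "DihedralHistogram",
    "SubensembleLabels",
    "ModeSet",
    "dihedral_histogram",
    "chi2",
    "chi2_profile",
    "superpose",
    "rmsf",
    "pca_modes",
    "dccm",
    "segment_subensembles",
    "conditional_chi2",
]

N_DIHEDRAL_BINS = 10
DIHEDRAL_BIN_WIDTH = 36.0  # degrees


@dataclass
class DihedralHistogram:
    """Normalized 10x10 (φ, ψ) frequency table.

    Bins are half-open ``[−180+36k, −180+36(k+1))`` with the top edge of
    the last bin closed, so +180° falls in the last bin and −180° in the
    first.  ``table[i, j]`` is the fraction of frames with φ in bin *i*
    and ψ in bin *j*.
    """

    table: np.ndarray
    n_samples: int
    edges: np.ndarray = field(
        default_factory=lambda: np.linspace(-180.0, 180.0, N_DIHEDRAL_BINS + 1)
    )

    def __post_init__(self) -> None:
        if self.table.shape != (N_DIHEDRAL_BINS, N_DIHEDRAL_BINS):
            raise ValueError("dihedral histogram must be 10x10")


def _bin_index(angles: np.ndarray) -> np.ndarray:
    idx = np.floor((np.asarray(angles, dtype=float) + 180.0) / DIHEDRAL_BIN_WIDTH)
    return np.clip(idx, 0, N_DIHEDRAL_BINS - 1).astype(int)


def dihedral_histogram(phi: np.ndarray, psi: np.ndarray) -> DihedralHistogram:
    """Bin paired (φ, ψ) samples into the normalized 10x10 table."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have the same length")
    ok = ~(np.isnan(phi) | np.isnan(psi))
    phi, psi = phi[ok], psi[ok]
    table = np.zeros((N_DIHEDRAL_BINS, N_DIHEDRAL_BINS))
    n = phi.size
    if n:
        np.add.at(table, (_bin_index(phi), _bin_index(psi)), 1.0)
        table /= n
    return DihedralHistogram(table=table, n_samples=int(n))


def chi2(f1: DihedralHistogram, f2: DihedralHistogram) -> float:
    """χ² difference between two binned dihedral distributions.

    The 100 squared cell differences are accumulated with compensated
    (correctly rounded) summation, so the result is independent of
    traversal order.
    """
    if not np.array_equal(f1.edges, f2.edges):
        raise ValueError("histograms use different binnings")
    diff = f1.table - f2.table
    return math.fsum((diff * diff).ravel()) / N_DIHEDRAL_BINS**2


def chi2_profile(ds_a: DihedralSeries, ds_b: DihedralSeries) -> pd.DataFrame:
    """Per-residue χ² between two ensembles' dihedral distributions.

    Residues lacking a defined (φ, ψ) pair in either series are reported
    with NaN.  Returns a frame with columns ``residue_id`` and ``chi2``.
    """
    common = sorted(set(ds_a.residue_ids) & set(ds_b.residue_ids))
    if not common:
        raise ValueError("series share no residues")
    valid_a = set(ds_a.valid_residues())
    valid_b = set(ds_b.valid_residues())
    out = []
    for rid in common:
        if rid in valid_a and rid in valid_b:
            ha = dihedral_histogram(*ds_a.angles(rid))
            hb = dihedral_histogram(*ds_b.angles(rid))
            val = chi2(ha, hb)
        else:
            val = np.nan
        out.append({"residue_id": rid, "chi2": val})
    return pd.DataFrame(out)


# ---------------------------------------------------------------- fluctuations


def _kabsch_align(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose every frame onto a (centered) reference.

    Batched Kabsch: proper rotations only (reflections corrected via the
    determinant sign).
    """
    ref = reference - reference.mean(axis=0)
    x = coords - coords.mean(axis=1, keepdims=True)
    H = np.einsum("fni,nj->fij", x, ref)  # (F, 3, 3) cross-covariances
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt) * np.linalg.det(U))
    D = np.tile(np.eye(3), (len(d), 1, 1))
    D[:, 2, 2] = d
    R = np.einsum("fji,fjk,fkl->fil", Vt, D, np.transpose(U, (0, 2, 1)))
    return np.einsum("fji,fni->fnj", R, x)


def superpose(traj: Trajectory, selection: str = "CA", n_iter: int = 2) -> np.ndarray:
    """Superposed selected-atom coordinates, (F, R, 3).

    Frames are aligned onto the first frame and then, ``n_iter`` times,
    onto the refreshed mean structure — the usual iterative-mean scheme
    that removes the arbitrariness of a single reference frame.
    """
    idx = traj.select(selection)
    if len(idx) == 0:
        raise ValueError(f"no atoms named {selection!r}")
    coords = traj.coords[:, idx, :]
    if coords.shape[0] < 2:
        warnings.warn("single-frame trajectory: fluctuations are identically zero")
        return coords - coords.mean(axis=1, keepdims=True)
    if (coords == coords[0:1]).all():
        # exactly static: rotations are identity, keep fluctuations at 0
        return coords - coords.mean(axis=1, keepdims=True)
    aligned = _kabsch_align(coords, coords[0])
    for _ in range(n_iter):
        aligned = _kabsch_align(aligned, aligned.mean(axis=0))
    return aligned


def _frames(traj: Trajectory, selection: str, align: bool) -> np.ndarray:
    if align:
        return superpose(traj, selection)
    return traj.coords[:, traj.select(selection), :]


def rmsf(traj: Trajectory, selection: str = "CA", align: bool = True) -> pd.DataFrame:
    """Per-residue RMSF (Å) about the (superposed) mean structure.

    ``align=False`` skips superposition for trajectories that are already
    in a common frame.
    """
    aligned = _frames(traj, selection, align)
    if (aligned == aligned[0:1]).all():
        # static trajectory: exactly zero, immune to mean round-off
        vals = np.zeros(aligned.shape[1])
    else:
        mean = aligned.mean(axis=0)
        disp2 = ((aligned - mean) ** 2).sum(axis=2)  # (F, R)
        vals = np.sqrt(disp2.mean(axis=0))
    rids = traj.topology.loc[traj.select(selection), "residue_id"].to_numpy()
    return pd.DataFrame({"residue_id": rids, "rmsf": vals})


@dataclass
class ModeSet:
    """Principal modes of the superposed coordinate covariance.

    ``eigenvalues`` are in Å², descending; ``eigenvectors`` has one unit
    column per mode in 3R coordinate space; ``spikes`` holds the
    first-mode per-residue displacement vectors (the porcupine arrows).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    residue_ids: np.ndarray
    spikes: np.ndarray

    def spikes_frame(self, mode: int = 0) -> pd.DataFrame:
        v = self.eigenvectors[:, mode].reshape(-1, 3)
        return pd.DataFrame(
            {
                "residue_id": self.residue_ids,
                "dx": v[:, 0], "dy": v[:, 1], "dz": v[:, 2],
                "amplitude": np.linalg.norm(v, axis=1),
            }
        )


def pca_modes(traj: Trajectory, selection: str = "CA", align: bool = True) -> ModeSet:
    """Essential-dynamics PCA of the superposed coordinate fluctuations.

    Eigendecomposes the 3R x 3R covariance (1/F normalization, so the
    eigenvalue sum equals the summed squared RMSF).
    """
    aligned = _frames(traj, selection, align)
    F = aligned.shape[0]
    flat = aligned.reshape(F, -1)
    dev = flat - flat.mean(axis=0)
    cov = dev.T @ dev / F
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude entry positive
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    rids = traj.topology.loc[traj.select(selection), "residue_id"].to_numpy()
    return ModeSet(
        eigenvalues=evals,
        eigenvectors=evecs,
        residue_ids=rids,
        spikes=evecs[:, 0].reshape(-1, 3),
    )


def dccm(traj: Trajectory, selection: str = "CA", align: bool = True) -> pd.DataFrame:
    """Dynamic cross-correlation matrix of residue displacement vectors.

    ``C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)`` with Δr the
    displacement from the mean position after superposition.  +1 means
    fully parallel motion, −1 anti-parallel.  Zero-variance atoms give
    NaN rows/columns.  ``align=False`` skips superposition.
    """
    aligned = _frames(traj, selection, align)
    dev = aligned - aligned.mean(axis=0)
    inner = np.einsum("fik,fjk->ij", dev, dev) / dev.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-variance atoms: correlations undefined")
        var[zero] = np.nan
    denom = np.sqrt(np.outer(var, var))
    mat = inner / denom
    np.fill_diagonal(mat, np.where(zero, np.nan, 1.0))
    rids = traj.topology.loc[traj.select(selection), "residue_id"].to_numpy()
    return pd.DataFrame(np.clip(mat, -1.0, 1.0), index=rids, columns=rids)


# ------------------------------------------------------------- subensembles


@dataclass
class SubensembleLabels:
    """Per-frame subensemble assignment from a distance distribution.

    ``labels`` are integer state indices ordered by increasing distance;
    ``boundaries`` are the KDE-minima distances (Å) separating them.
    """

    labels: np.ndarray
    boundaries: np.ndarray
    mode_positions: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.boundaries) + 1

    @property
    def letters(self) -> np.ndarray:
        return np.array(list(ascii_lowercase))[self.labels]

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_states)


def segment_subensembles(
    distances: np.ndarray,
    mode_threshold: float = 0.05,
    grid_size: int = 1024,
) -> SubensembleLabels:
    """Split a distance distribution into subensembles at KDE minima.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a grid; local
    maxima exceeding ``mode_threshold`` of the global maximum count as
    modes, and the minimum between consecutive modes becomes a boundary.
    Frames are labeled 0, 1, 2, … (reported as a, b, c, …) by increasing
    distance.  Modes closer than about one bandwidth merge — a documented
    resolution limit of density-based segmentation.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    if d.size < 100:
        raise ValueError("need at least 100 samples to segment reliably")
    if np.ptp(d) == 0:
        return SubensembleLabels(
            labels=np.zeros(d.size, dtype=int),
            boundaries=np.array([]),
            mode_positions=np.array([d[0]]),
        )
    kde = gaussian_kde(d, bw_method="silverman")
    pad = 3 * d.std() * kde.factor
    grid = np.linspace(d.min() - pad, d.max() + pad, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    peaks = interior[dens[interior] >= mode_threshold * dens.max()]
    if len(peaks) <= 1:
        boundaries = np.array([])
        modes = grid[peaks] if len(peaks) else np.array([grid[np.argmax(dens)]])
    else:
        cuts = []
        for left, right in zip(peaks[:-1], peaks[1:]):
            seg = np.arange(left, right + 1)
            cuts.append(grid[seg[np.argmin(dens[seg])]])
        boundaries = np.asarray(cuts)
        modes = grid[peaks]
    labels = np.searchsorted(boundaries, d)
    return SubensembleLabels(labels=labels, boundaries=boundaries, mode_positions=modes)


def conditional_chi2(
    ds: DihedralSeries,
    labels: SubensembleLabels,
    min_frames: int = 50,
) -> pd.DataFrame:
    """Subensemble-conditioned dihedral χ² per residue.

    For each residue the (φ, ψ) distribution is recomputed within every
    subensemble and χ² evaluated for every unordered state pair; the
    maximum over pairs is the reported coupling statistic.  Pairs where
    either state holds fewer than ``min_frames`` frames are flagged
    low-confidence.  Columns: ``residue_id``, ``max_chi2``, one
    ``chi2_<a>_<b>`` column per pair, and ``low_confidence``.
    """
    lab = np.asarray(labels.labels)
    if len(lab) != ds.n_frames:
        raise ValueError("label count does not match frame count")
    states = np.unique(lab)
    if len(states) < 2:
        raise ValueError("need at least 2 subensembles for a conditional contrast")
    letters = {s: ascii_lowercase[s] for s in states}
    counts = {s: int((lab == s).sum()) for s in states}
    rows = []
    for rid in ds.valid_residues():
        phi, psi = ds.angles(rid)
        hists = {s: dihedral_histogram(phi[lab == s], psi[lab == s]) for s in states}
        row: dict = {"residue_id": int(rid)}
        best = 0.0
        low = False
        for a_i, a in enumerate(states):
            for b in states[a_i + 1 :]:
                val = chi2(hists[a], hists[b])
                row[f"chi2_{letters[a]}_{letters[b]}"] = val
                if counts[a] < min_frames or counts[b] < min_frames:
                    low = True
                else:
                    best = max(best, val)
        if low and best == 0.0:
            # every pair involved an under-populated state
            best = max(
                v for k, v in row.items() if isinstance(k, str) and k.startswith("chi2_")
            )
        row["max_chi2"] = best
        row["low_confidence"] = low
        rows.append(row)
    return pd.DataFrame(rows)
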