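"""Lightweight trajectory container with text I/O and backbone geometry.

A :class:`Trajectory` is a frames x atoms x 3 coordinate array (Å) plus a
topology table mapping each atom to a residue id, residue name and atom
name.  Frames are assumed pre-imaged (no periodic box handling).  Text
round-trip formats are multi-model PDB and plain XYZ frames with a TSV
topology sidecar, so generated trajectories stay human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "DihedralSeries",
    "make_backbone_topology",
    "compute_dihedrals",
    "atom_distance_series",
    "torsion_angle",
]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class Trajectory:
    """Coordinates (frames, atoms, 3, in Å) plus a topology table.

    ``topology`` columns: ``residue_id`` (int), ``residue_name`` (str,
    3-letter), ``atom_name`` (str).  Row order defines atom indices.
    """

    coords: np.ndarray
    topology: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError(
                f"{self.coords.shape[1]} atoms in coords but "
                f"{len(self.topology)} topology rows"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_ids(self) -> np.ndarray:
        return np.unique(self.topology["residue_id"].to_numpy())

    def atom_index(self, residue_id: int, atom_name: str) -> int:
        sel = self.topology.index[
            (self.topology["residue_id"] == residue_id)
            & (self.topology["atom_name"] == atom_name)
        ]
        if len(sel) == 0:
            raise KeyError(f"no atom {atom_name!r} in residue {residue_id}")
        return int(sel[0])

    def select(self, atom_name: str = "CA") -> np.ndarray:
        """Atom indices with the given name, in residue order."""
        mask = self.topology["atom_name"] == atom_name
        return self.topology.index[mask].to_numpy()

    # ------------------------------------------------------------------ I/O

    def write_pdb(self, path: str | Path) -> None:
        """Write as a multi-model PDB (one MODEL per frame)."""
        top = self.topology
        with Path(path).open("w") as fh:
            for f in range(self.n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                for a in range(self.n_atoms):
                    x, y, z = self.coords[f, a]
                    name = top.at[a, "atom_name"]
                    # PDB column rules: 4-char names start in col 13
                    pname = f" {name:<3s}" if len(name) < 4 else name
                    fh.write(
                        f"ATOM  {a + 1:5d} {pname:<4s} {top.at[a, 'residue_name']:<3s} "
                        f"A{top.at[a, 'residue_id']:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")

    def write_xyz(self, xyz_path: str | Path, topology_path: str | Path) -> None:
        """Write whitespace XYZ frames plus a TSV topology sidecar."""
        with Path(xyz_path).open("w") as fh:
            for f in range(self.n_frames):
                fh.write(f"{self.n_atoms}\nframe {f}\n")
                for a in range(self.n_atoms):
                    x, y, z = self.coords[f, a]
                    fh.write(
                        f"{self.topology.at[a, 'atom_name']} {x:.5f} {y:.5f} {z:.5f}\n"
                    )
        self.topology.to_csv(topology_path, sep="\t", index_label="atom_index")

    @classmethod
    def read_pdb(cls, path: str | Path) -> "Trajectory":
        frames: list[list[list[float]]] = []
        rows: list[dict] = []
        current: list[list[float]] | None = None
        first_model = True
        with Path(path).open() as fh:
            for line in fh:
                rec = line[:6]
                if rec == "MODEL ":
                    current = []
                elif rec == "ENDMDL":
                    if current is not None:
                        frames.append(current)
                        first_model = False
                    current = None
                elif rec in ("ATOM  ", "HETATM"):
                    if current is None:  # single-model file without MODEL cards
                        current = []
                    current.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                    if first_model:
                        rows.append(
                            {
                                "residue_id": int(line[22:26]),
                                "residue_name": line[17:20].strip(),
                                "atom_name": line[12:16].strip(),
                            }
                        )
        if current:  # file without ENDMDL
            frames.append(current)
        if not frames:
            raise ValueError(f"no coordinates found in {path}")
        return cls(np.asarray(frames), pd.DataFrame(rows))

    @classmethod
    def read_xyz(cls, xyz_path: str | Path, topology_path: str | Path) -> "Trajectory":
        top = pd.read_csv(topology_path, sep="\t", index_col="atom_index")
        top.index.name = None
        frames = []
        with Path(xyz_path).open() as fh:
            lines = fh.read().split("\n")
        i = 0
        while i < len(lines) and lines[i].strip():
            n = int(lines[i])
            block = lines[i + 2 : i + 2 + n]
            frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
            i += 2 + n
        return cls(np.asarray(frames), top.reset_index(drop=True))


def make_backbone_topology(
    sequence: str,
    sidechain_atoms: dict[int, list[str]] | None = None,
) -> pd.DataFrame:
    """Topology table with N, CA, C per residue plus named side-chain atoms.

    ``sequence`` is a one-letter string; residue ids are 1-based.
    ``sidechain_atoms`` maps residue id to extra atom names (e.g.
    ``{76: ["OD2"], 41: ["NZ"]}``).
    """
    sidechain_atoms = sidechain_atoms or {}
    rows = []
    for i, aa in enumerate(sequence, start=1):
        rname = _AA3.get(aa.upper(), "UNK")
        for atom in ("N", "CA", "C"):
            rows.append({"residue_id": i, "residue_name": rname, "atom_name": atom})
        for atom in sidechain_atoms.get(i, []):
            rows.append({"residue_id": i, "residue_name": rname, "atom_name": atom})
    return pd.DataFrame(rows)


def torsion_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle (degrees, IUPAC convention) for stacked frames.

    Inputs are (..., 3) arrays; the angle is that of the p0-p1-p2 and
    p1-p2-p3 planes viewed along p1->p2, positive clockwise.
    """
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # report in (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


@dataclass
class DihedralSeries:
    """Backbone (φ, ψ) time series per residue, degrees in (−180, 180].

    ``phi`` and ``psi`` are (R, F) arrays aligned with ``residue_ids``;
    undefined angles (φ of the first residue, ψ of the last, or residues
    with missing atoms) are NaN rows.
    """

    residue_ids: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape or self.phi.shape[0] != len(self.residue_ids):
            raise ValueError("phi/psi arrays must align with residue_ids")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[1]

    def valid_residues(self) -> np.ndarray:
        ok = ~(np.isnan(self.phi).any(axis=1) | np.isnan(self.psi).any(axis=1))
        return self.residue_ids[ok]

    def angles(self, residue_id: int) -> tuple[np.ndarray, np.ndarray]:
        i = int(np.flatnonzero(self.residue_ids == residue_id)[0])
        return self.phi[i], self.psi[i]


def compute_dihedrals(traj: Trajectory) -> DihedralSeries:
    """Backbone φ/ψ series from coordinates.

    φ(i) = C(i−1)–N(i)–CA(i)–C(i); ψ(i) = N(i)–CA(i)–C(i)–N(i+1).
    Residues whose required atoms are absent get NaN for that angle.
    """
    rids = traj.residue_ids
    F = traj.n_frames
    phi = np.full((len(rids), F), np.nan)
    psi = np.full((len(rids), F), np.nan)

    def _idx(rid: int, name: str) -> int | None:
        try:
            return traj.atom_index(int(rid), name)
        except KeyError:
            return None

    for k, rid in enumerate(rids):
        n = _idx(rid, "N")
        ca = _idx(rid, "CA")
        c = _idx(rid, "C")
        c_prev = _idx(rid - 1, "C")
        n_next = _idx(rid + 1, "N")
        if None not in (c_prev, n, ca, c):
            phi[k] = torsion_angle(
                traj.coords[:, c_prev], traj.coords[:, n],
                traj.coords[:, ca], traj.coords[:, c],
            )
        if None not in (n, ca, c, n_next):
            psi[k] = torsion_angle(
                traj.coords[:, n], traj.coords[:, ca],
                traj.coords[:, c], traj.coords[:, n_next],
            )
    return DihedralSeries(residue_ids=rids, phi=phi, psi=psi)


def atom_distance_series(
    traj: Trajectory,
    atom_a: tuple[int, str],
    atom_b: tuple[int, str],
) -> np.ndarray:
    """Per-frame Euclidean distance (Å) between two named atoms.

    Each atom is addressed as ``(residue_id, atom_name)``, e.g.
    ``(76, "OD2")`` and ``(41, "NZ")`` for the carboxylate–amine contact
    between the EF-loop aspartate and the CD-loop lysine.
    """
    ia = traj.atom_index(*atom_a)
    ib = traj.atom_index(*atom_b)
    return np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=-1)
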