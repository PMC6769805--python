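"""Decomposition of pressure-dependent chemical-shift changes.

High pressure perturbs an HSQC spectrum through two superimposed effects:
(i) *mechanical compression* — a roughly linear, within-state compaction
that moves every peak smoothly with pressure — and (ii) a *thermodynamic
transition* — a population shift between conformational subensembles with
different partial molar volumes, which turns on over a characteristic
pressure range.

The separation works on a matrix ``X`` whose rows are per-residue shift
coordinates (an ¹H row and a ¹⁵N row per residue, nitrogen scaled by 1/5
so the row metric matches the weighted apparent shift difference) and
whose columns are the spectra at each pressure.  After centering on the
lowest-pressure column, an SVD turns each pressure point into a point in
principal-component space.  The direction of the initial (low-pressure)
score step is taken as the compression direction; the transition direction
is its in-plane orthogonal complement.  Back-projection of either unit
direction through the left singular vectors gives the per-residue shift
pattern attributable to that effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .peaklists import PeakList, PressureSeries

logger = logging.getLogger(__name__)

__all__ = [
    "NITROGEN_SCALE",
    "delta_app",
    "DeltaPattern",
    "ShiftMatrix",
    "Decomposition",
    "compare_peaklists",
    "assemble_shift_matrix",
    "svd_shift_matrix",
    "identify_directions",
    "project_pattern",
    "decompose_pressure_series",
]

#: Weight applied to the nitrogen axis: amide 15N shift ranges are about
#: five times wider than 1H ranges, so dividing by 5 puts both axes on a
#: comparable ppm scale.
NITROGEN_SCALE = 0.2


def delta_app(delta_h, delta_n):
    """Weighted apparent chemical-shift difference (ppm).

    ``sqrt(ΔδH² + (ΔδN/5)²)`` — the standard combined ¹H/¹⁵N distance for
    HSQC peak displacements.  Accepts scalars or arrays.
    """
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    out = np.hypot(dh, dn * NITROGEN_SCALE)
    return float(out) if out.ndim == 0 else out


@dataclass
class DeltaPattern:
    """Per-residue shift differences between two conditions or directions."""

    residue_ids: np.ndarray
    delta_h: np.ndarray
    delta_n: np.ndarray
    missing_in_a: list[int] = field(default_factory=list)
    missing_in_b: list[int] = field(default_factory=list)

    @property
    def delta_n_scaled(self) -> np.ndarray:
        """Nitrogen differences on the weighted (divided-by-5) scale."""
        return self.delta_n * NITROGEN_SCALE

    @property
    def delta_app(self) -> np.ndarray:
        return delta_app(self.delta_h, self.delta_n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_id": self.residue_ids,
                "delta_h_ppm": self.delta_h,
                "delta_n_ppm": self.delta_n,
                "delta_n_scaled_ppm": self.delta_n_scaled,
                "delta_app_ppm": self.delta_app,
            }
        )


@dataclass
class ShiftMatrix:
    """2R x P shift matrix with row/column metadata.

    Rows are residue-major: the ¹H row then the (scaled) ¹⁵N row for each
    traceable residue.  Columns are pressure points.
    """

    values: np.ndarray
    residue_ids: np.ndarray
    axes: np.ndarray  # 'H' or 'N' per row
    pressures: np.ndarray
    nitrogen_scale: float = NITROGEN_SCALE

    def __post_init__(self) -> None:
        r, p = self.values.shape
        if r % 2 or r != len(self.residue_ids) or r != len(self.axes):
            raise ValueError("row metadata inconsistent with matrix shape")
        if p != len(self.pressures):
            raise ValueError("column metadata inconsistent with matrix shape")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0] // 2

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Decomposition:
    """SVD of a centered shift matrix plus identified direction patterns."""

    singular_values: np.ndarray
    left_vectors: np.ndarray  # (2R, k)
    scores: np.ndarray  # (P, k): pressure points in PC coordinates
    pressures: np.ndarray
    residue_ids: np.ndarray
    nitrogen_scale: float
    centering: str
    center_column: np.ndarray
    n_significant: int
    v_i: np.ndarray | None = None
    v_ii: np.ndarray | None = None
    pattern_i: DeltaPattern | None = None
    pattern_ii: DeltaPattern | None = None

    @property
    def variance_explained(self) -> np.ndarray:
        s2 = self.singular_values**2
        total = s2.sum()
        if total == 0:
            return np.zeros_like(s2)
        return s2 / total

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"pc{k + 1}": self.scores[:, k] for k in range(self.scores.shape[1])}
        return pd.DataFrame({"pressure_mpa": self.pressures, **cols})


def compare_peaklists(a: PeakList, b: PeakList) -> DeltaPattern:
    """Per-residue shift differences b - a over the shared residues."""
    shared = sorted(a.residue_ids & b.residue_ids)
    if not shared:
        raise ValueError("peak lists share no residues")
    pa = {p.residue_id: p for p in a.peaks}
    pb = {p.residue_id: p for p in b.peaks}
    dh = np.array([pb[r].delta_h - pa[r].delta_h for r in shared])
    dn = np.array([pb[r].delta_n - pa[r].delta_n for r in shared])
    return DeltaPattern(
        residue_ids=np.asarray(shared, dtype=int),
        delta_h=dh,
        delta_n=dn,
        missing_in_a=sorted(b.residue_ids - a.residue_ids),
        missing_in_b=sorted(a.residue_ids - b.residue_ids),
    )


def assemble_shift_matrix(
    series: PressureSeries, nitrogen_scale: float = NITROGEN_SCALE
) -> ShiftMatrix:
    """Stack a pressure series into the 2R x P matrix.

    Residues must be traceable (present at every pressure); rows are
    ordered residue-major with the ¹H row first, and nitrogen rows are
    multiplied by ``nitrogen_scale`` so distances in row space follow the
    weighted shift metric.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 pressure points to decompose")
    residues = series.traceable_residues
    if not residues:
        raise ValueError("no residues are traceable across all pressures")
    p = len(series)
    values = np.empty((2 * len(residues), p))
    for j, pl in enumerate(series.lists):
        for i, rid in enumerate(residues):
            peak = pl.get(rid)
            if peak is None:  # traceable set guards this; belt and braces
                raise ValueError(f"residue {rid} missing at pressure {pl.pressure}")
            values[2 * i, j] = peak.delta_h
            values[2 * i + 1, j] = peak.delta_n * nitrogen_scale
    axes = np.array(["H", "N"] * len(residues))
    rids = np.repeat(np.asarray(residues, dtype=int), 2)
    return ShiftMatrix(
        values=values,
        residue_ids=rids,
        axes=axes,
        pressures=series.pressures,
        nitrogen_scale=nitrogen_scale,
    )


def svd_shift_matrix(
    matrix: ShiftMatrix,
    centering: str = "first",
    sv_rtol: float = 1e-10,
) -> Decomposition:
    """Center the shift matrix and decompose it.

    With ``centering='first'`` every column has the lowest-pressure column
    subtracted, so the origin of PC space is the first spectrum (the
    plotted convention for pressure titrations); ``'mean'`` subtracts the
    column mean instead.  Scores are singular-value-weighted right singular
    vectors: row *j* of ``scores`` places pressure point *j* in PC space.
    """
    X = matrix.values
    if centering == "first":
        center = X[:, 0].copy()
    elif centering == "mean":
        center = X.mean(axis=1)
    else:
        raise ValueError(f"unknown centering {centering!r}")
    Xc = X - center[:, None]

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] == 0:
        warnings.warn("shift matrix is degenerate: all columns identical")
        n_sig = 0
    else:
        n_sig = int(np.sum(s > sv_rtol * s[0]))
    scores = (s[:, None] * Vt).T  # (P, k)

    # Orient each PC so the final pressure point scores non-negatively,
    # making the sign convention reproducible across BLAS backends.
    flip = np.where(scores[-1, :] < 0, -1.0, 1.0)
    scores = scores * flip[None, :]
    U = U * flip[None, :]

    return Decomposition(
        singular_values=s,
        left_vectors=U,
        scores=scores,
        pressures=matrix.pressures,
        residue_ids=matrix.residue_ids,
        nitrogen_scale=matrix.nitrogen_scale,
        centering=centering,
        center_column=center,
        n_significant=n_sig,
    )


def identify_directions(
    scores: np.ndarray, n_initial: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the compression and transition directions in the PC1-PC2 plane.

    The compression direction ``v_i`` is the unit secant from the first to
    the second pressure point (or, with ``n_initial > 2``, the principal
    direction of a least-squares line through the first ``n_initial``
    scores, oriented along the initial step).  The transition direction
    ``v_ii`` is ``v_i`` rotated by +90°, with its sign chosen so the net
    displacement from first to last pressure projects non-negatively onto
    it.
    """
    pts = np.asarray(scores)[:, :2]
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 pressure points")
    if n_initial < 2:
        raise ValueError("n_initial must be >= 2")
    if n_initial == 2:
        step = pts[1] - pts[0]
    else:
        seg = pts[:n_initial] - pts[:n_initial].mean(axis=0)
        _, _, vt = np.linalg.svd(seg, full_matrices=False)
        step = vt[0]
        if step @ (pts[n_initial - 1] - pts[0]) < 0:
            step = -step
    norm = np.linalg.norm(step)
    if norm < 1e-14:
        raise ValueError("first two pressure points coincide in the PC plane")
    v_i = step / norm
    v_ii = np.array([-v_i[1], v_i[0]])
    if (pts[-1] - pts[0]) @ v_ii < 0:
        v_ii = -v_ii
    return v_i, v_ii


def project_pattern(decomp: Decomposition, v: np.ndarray) -> DeltaPattern:
    """Back-project an in-plane unit direction to a per-residue shift pattern.

    The residue-space loading ``U[:, :2] @ v`` is scaled by the range of
    the score projections along ``v``, so the pattern has the amplitude
    (in ppm) actually traversed along that direction over the pressure
    series.  Nitrogen rows are reported both in plain ppm (scale undone)
    and via :attr:`DeltaPattern.delta_n_scaled`.
    """
    if decomp.left_vectors.shape[1] < 2:
        raise ValueError("decomposition does not expose two principal components")
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    w = decomp.left_vectors[:, :2] @ v
    proj = decomp.scores[:, :2] @ v
    scale = proj.max() - proj.min()
    pattern = w * scale
    h_rows = pattern[0::2]
    n_rows_scaled = pattern[1::2]
    return DeltaPattern(
        residue_ids=decomp.residue_ids[0::2].copy(),
        delta_h=h_rows,
        delta_n=n_rows_scaled / decomp.nitrogen_scale,
    )


def decompose_pressure_series(
    series: PressureSeries,
    centering: str = "first",
    n_initial: int = 2,
    out_dir: str | Path | None = None,
) -> Decomposition:
    """Full pipeline: assemble, decompose, identify directions, project.

    Optionally writes ``scores.tsv``, ``singular_values.tsv``,
    ``pattern_i.tsv`` and ``pattern_ii.tsv`` to ``out_dir``.
    """
    matrix = assemble_shift_matrix(series)
    decomp = svd_shift_matrix(matrix, centering=centering)
    v_i, v_ii = identify_directions(decomp.scores, n_initial=n_initial)
    decomp.v_i, decomp.v_ii = v_i, v_ii
    decomp.pattern_i = project_pattern(decomp, v_i)
    decomp.pattern_ii = project_pattern(decomp, v_ii)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        decomp.scores_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "component": np.arange(1, len(decomp.singular_values) + 1),
                "singular_value": decomp.singular_values,
                "variance_fraction": decomp.variance_explained,
            }
        ).to_csv(out / "singular_values.tsv", sep="\t", index=False)
        decomp.pattern_i.to_frame().to_csv(out / "pattern_i.tsv", sep="\t", index=False)
        decomp.pattern_ii.to_frame().to_csv(out / "pattern_ii.tsv", sep="\t", index=False)
        logger.info("decomposition outputs written to %s", out)
    return decomp
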