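"""Sparky-style peak lists and assignment tracking across a pressure series.

A peak list holds one backbone-amide cross peak per residue: the amide
proton shift (ppm), the amide nitrogen shift (ppm) and optionally a peak
height.  A :class:`PressureSeries` is an ordered stack of peak lists, one
per hydrostatic pressure, restricted downstream to the *traceable*
residues — those present at every pressure point.

The on-disk dialect is the Sparky ``.list`` export: a whitespace table with
columns ``Assignment  w1  w2  [Data Height]`` where ``w1`` is the nitrogen
axis and ``w2`` the proton axis, and assignments look like ``K41N-H``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakList",
    "PressureSeries",
    "PeakListParseError",
    "AmbiguousMatchError",
    "read_peaklist",
    "write_peaklist",
    "track_peaks",
]

_ASSIGNMENT_RE = re.compile(r"^([A-Za-z]?)(\d+)N-?H$")


class PeakListParseError(ValueError):
    """Raised for malformed peak-list lines; carries the line number."""


class AmbiguousMatchError(RuntimeError):
    """Raised when two peaks cannot be disambiguated during tracking."""


@dataclass(frozen=True)
class Peak:
    """One amide cross peak.

    Parameters
    ----------
    residue_id : int
        1-based residue number.
    delta_h, delta_n : float
        Proton and nitrogen chemical shifts in ppm.
    residue_name : str or None
        One-letter code, if the assignment string carried one.
    height : float or None
        Peak height in arbitrary units.
    """

    residue_id: int
    delta_h: float
    delta_n: float
    residue_name: str | None = None
    height: float | None = None

    def __post_init__(self) -> None:
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        if not (np.isfinite(self.delta_h) and np.isfinite(self.delta_n)):
            raise ValueError("chemical shifts must be finite")


@dataclass
class PeakList:
    """A collection of peaks recorded under one condition/pressure."""

    peaks: list[Peak]
    condition: str = ""
    pressure: float | None = None

    def __post_init__(self) -> None:
        ids = [p.residue_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate residue ids in peak list: {dupes}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def residue_ids(self) -> set[int]:
        return {p.residue_id for p in self.peaks}

    def get(self, residue_id: int) -> Peak | None:
        for p in self.peaks:
            if p.residue_id == residue_id:
                return p
        return None

    def sorted(self) -> "PeakList":
        return PeakList(
            sorted(self.peaks, key=lambda p: p.residue_id),
            condition=self.condition,
            pressure=self.pressure,
        )


@dataclass
class PressureSeries:
    """Ordered peak lists at strictly increasing pressures."""

    lists: list[PeakList]
    condition: str = ""

    def __post_init__(self) -> None:
        pressures = self.pressures
        if any(p is None for p in pressures):
            raise ValueError("every peak list in a series needs a pressure")
        if not np.all(np.diff(pressures) > 0):
            raise ValueError(f"pressures must be strictly increasing, got {pressures}")

    @property
    def pressures(self) -> np.ndarray:
        return np.asarray([pl.pressure for pl in self.lists], dtype=float)

    @property
    def traceable_residues(self) -> list[int]:
        """Residues present in every list, sorted ascending."""
        common: set[int] | None = None
        for pl in self.lists:
            common = pl.residue_ids if common is None else common & pl.residue_ids
        return sorted(common or ())

    def __len__(self) -> int:
        return len(self.lists)

    def __iter__(self):
        return iter(self.lists)


def _parse_assignment(token: str, lineno: int) -> tuple[str | None, int]:
    m = _ASSIGNMENT_RE.match(token)
    if not m:
        raise PeakListParseError(
            f"line {lineno}: cannot parse assignment {token!r} (expected e.g. K41N-H)"
        )
    name = m.group(1).upper() or None
    return name, int(m.group(2))


def read_peaklist(path: str | Path, condition: str = "", pressure: float | None = None) -> PeakList:
    """Read a Sparky-style ``.list`` file.

    A header line starting with ``Assignment`` is skipped; blank lines are
    ignored.  Columns are ``assignment  w1(15N)  w2(1H)  [height]``.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            fields = line.split()
            if len(fields) not in (3, 4):
                raise PeakListParseError(
                    f"line {lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            name, rid = _parse_assignment(fields[0], lineno)
            try:
                w1, w2 = float(fields[1]), float(fields[2])
                height = float(fields[3]) if len(fields) == 4 else None
            except ValueError as exc:
                raise PeakListParseError(f"line {lineno}: {exc}") from None
            peaks.append(
                Peak(residue_id=rid, residue_name=name, delta_n=w1, delta_h=w2, height=height)
            )
    if not peaks:
        logger.warning("empty peak list read from %s", path)
    return PeakList(peaks, condition=condition, pressure=pressure)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list in the Sparky dialect (w1 = 15N, w2 = 1H)."""
    path = Path(path)
    any_height = any(p.height is not None for p in peaklist.peaks)
    with path.open("w") as fh:
        header = f"{'Assignment':>12s} {'w1':>9s} {'w2':>9s}"
        if any_height:
            header += f" {'Data Height':>12s}"
        fh.write(header + "\n")
        for p in sorted(peaklist.peaks, key=lambda q: q.residue_id):
            tag = f"{p.residue_name or ''}{p.residue_id}N-H"
            line = f"{tag:>12s} {p.delta_n:9.4f} {p.delta_h:9.4f}"
            if any_height:
                h = p.height if p.height is not None else float("nan")
                line += f" {h:12.4f}"
            fh.write(line + "\n")


def _delta_app(dh: float, dn: float) -> float:
    # lazy import would be circular at module load; keep the metric local
    from .decomposition import delta_app

    return delta_app(dh, dn)


def track_peaks(
    unassigned: Sequence[PeakList],
    reference: PeakList,
    max_step: float = 0.05,
    ambiguity_ratio: float = 1.1,
) -> PressureSeries:
    """Propagate residue assignments through a pressure series.

    Each peak at pressure *k+1* inherits the assignment of the nearest
    tracked peak at pressure *k*, with distance measured by the weighted
    apparent shift difference (nitrogen scaled by 1/5).  A match farther
    than ``max_step`` ppm drops the residue from the traceable set.  Two
    candidates within ``max_step`` whose distances differ by less than
    ``ambiguity_ratio`` raise :class:`AmbiguousMatchError` rather than
    silently picking one; the same applies when two residues claim the
    same peak.

    Parameters
    ----------
    unassigned : sequence of PeakList
        Lists ordered by pressure.  Assignments on them are ignored; peak
        positions alone drive the tracking.
    reference : PeakList
        Fully assigned list at the first pressure.
    max_step : float
        Largest allowed per-step displacement (ppm, weighted metric).
    """
    if not unassigned:
        raise ValueError("need at least one peak list to track")
    # Current assigned positions, keyed by residue id.
    current: dict[int, Peak] = {p.residue_id: p for p in reference.peaks}
    tracked_lists: list[PeakList] = []

    for pl in unassigned:
        candidates = list(pl.peaks)
        if not candidates:
            raise ValueError(f"empty peak list at pressure {pl.pressure}")
        pos = np.array([[c.delta_h, c.delta_n] for c in candidates])
        new_current: dict[int, Peak] = {}
        claimed: dict[int, int] = {}  # candidate index -> residue id
        for rid in sorted(current):
            ref = current[rid]
            d = np.array(
                [_delta_app(ph - ref.delta_h, pn - ref.delta_n) for ph, pn in pos]
            )
            order = np.argsort(d, kind="stable")
            best = order[0]
            if d[best] > max_step:
                continue  # residue lost at this pressure
            if len(order) > 1:
                second = order[1]
                if d[second] <= max_step and d[second] <= ambiguity_ratio * max(d[best], 1e-15):
                    raise AmbiguousMatchError(
                        f"residue {rid} at pressure {pl.pressure}: peaks at "
                        f"(H={pos[best][0]:.4f}, N={pos[best][1]:.4f}) and "
                        f"(H={pos[second][0]:.4f}, N={pos[second][1]:.4f}) are "
                        f"indistinguishable ({d[best]:.5f} vs {d[second]:.5f} ppm)"
                    )
            if best in claimed:
                raise AmbiguousMatchError(
                    f"peak (H={pos[best][0]:.4f}, N={pos[best][1]:.4f}) at pressure "
                    f"{pl.pressure} claimed by residues {claimed[best]} and {rid}"
                )
            claimed[best] = rid
            c = candidates[best]
            new_current[rid] = Peak(
                residue_id=rid,
                residue_name=ref.residue_name,
                delta_h=c.delta_h,
                delta_n=c.delta_n,
                height=c.height,
            )
        current = new_current
        tracked_lists.append(
            PeakList(
                sorted(current.values(), key=lambda p: p.residue_id),
                condition=pl.condition,
                pressure=pl.pressure,
            )
        )

    # Residues lost at any step are dropped everywhere so the series is rectangular.
    final_ids = set(current)
    rect = [
        PeakList(
            [p for p in pl.peaks if p.residue_id in final_ids],
            condition=pl.condition,
            pressure=pl.pressure,
        )
        for pl in tracked_lists
    ]
    return PressureSeries(rect, condition=reference.condition)
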