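"""Exponential-decay fitting for R₂ relaxation and H/D exchange.

Both experiments reduce to per-residue intensity decays: a CPMG-style R₂
series samples the transverse decay of each amide ¹⁵N over a handful of
relaxation delays, and an H/D exchange run watches each amide cross peak
vanish as its proton exchanges for deuterium.  Fits are mono-exponential
``I(t) = A·exp(−k·t)`` with the baseline fixed at zero.

For an aggregating sample the observed HSQC decay mixes chemical exchange
with signal loss to aggregation; the aggregation rate measured from 1D
methyl signals is removed either as a ratio ``k_obs/k_agg`` or as a
rate difference ``k_obs − k_agg`` (both provided; the mode is recorded in
the result).  Protection factors are ``P = k_int / k_ex`` with the
intrinsic (random-coil) rate predicted from the sequence by the standard
additive nearest-neighbor model, using the parameter table shipped with
the package.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from functools import lru_cache

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "DecayCurve",
    "DecayFit",
    "ExchangeResult",
    "fit_decay",
    "correct_aggregation",
    "intrinsic_rate",
    "protection_factor",
    "fit_r2_profile",
    "compute_exchange",
    "load_exchange_parameters",
]

R_GAS = 8.314  # J/(mol K)
_KCAL = 4184.0  # J per kcal


@dataclass
class DecayCurve:
    """An intensity decay series.  ``time_unit`` is 's' or 'min'."""

    times: np.ndarray
    intensities: np.ndarray
    residue_id: int | None = None
    time_unit: str = "s"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if self.time_unit not in ("s", "min"):
            raise ValueError("time_unit must be 's' or 'min'")


@dataclass
class DecayFit:
    rate: float
    amplitude: float
    rate_stderr: float | None
    amplitude_stderr: float | None
    residue_id: int | None = None


def fit_decay(curve: DecayCurve) -> DecayFit:
    """Fit ``I(t) = A exp(−k t)`` by least squares.

    Initialization is log-linear (slope of log-intensity over the points
    with positive intensity) followed by nonlinear refinement; standard
    errors come from the fit covariance.
    """
    t, y = curve.times, curve.intensities
    if len(t) < 3:
        raise ValueError("need at least 3 points to fit a decay")
    if np.allclose(y, 0.0):
        raise ValueError("all intensities are zero")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        k0 = max(-slope, 0.0)
        a0 = math.exp(intercept)
    else:
        k0, a0 = 0.0, float(y[0])

    model = lmfit.Model(lambda t, amplitude, rate: amplitude * np.exp(-rate * t))
    params = model.make_params(amplitude=a0, rate=k0)
    params["rate"].set(min=0.0)
    result = model.fit(y, params, t=t)
    if not result.success:
        raise RuntimeError(f"decay fit did not converge: {result.message}")
    return DecayFit(
        rate=float(result.params["rate"].value),
        amplitude=float(result.params["amplitude"].value),
        rate_stderr=(
            float(result.params["rate"].stderr)
            if result.params["rate"].stderr is not None
            else None
        ),
        amplitude_stderr=(
            float(result.params["amplitude"].stderr)
            if result.params["amplitude"].stderr is not None
            else None
        ),
        residue_id=curve.residue_id,
    )


def correct_aggregation(
    k_obs: float, k_agg: float | None, mode: str = "ratio"
) -> float:
    """Remove the aggregation decay channel from an observed rate.

    ``mode='ratio'`` returns ``k_obs / k_agg`` (a dimensionless rescaling);
    ``mode='difference'`` returns ``max(k_obs − k_agg, 0)``, the additive
    two-channel expectation.  ``k_agg=None`` passes ``k_obs`` through
    unchanged (the no-aggregation path).
    """
    if k_agg is None:
        return k_obs
    if mode == "ratio":
        if k_agg <= 0:
            raise ValueError("ratio mode requires k_agg > 0")
        return k_obs / k_agg
    if mode == "difference":
        return max(k_obs - k_agg, 0.0)
    raise ValueError(f"unknown aggregation mode {mode!r}")


@lru_cache(maxsize=1)
def load_exchange_parameters() -> tuple[pd.DataFrame, dict[str, float]]:
    """Shipped nearest-neighbor parameter table and reference constants."""
    ref: dict[str, float] = {}
    lines = (
        importlib.resources.files("baroshift")
        .joinpath("data/intrinsic_exchange_parameters.tsv")
        .read_text()
        .splitlines()
    )
    body = []
    for line in lines:
        if line.startswith("#REF"):
            _, key, val = line.split("\t")
            ref[key] = float(val)
        elif line.startswith("#") or not line.strip():
            continue
        else:
            body.append(line.split("\t"))
    table = pd.DataFrame(body[1:], columns=body[0]).set_index("aa").astype(float)
    return table, ref


def intrinsic_rate(
    sequence: str,
    position: int,
    pD: float,
    temperature: float = 298.15,
    units: str = "min",
) -> float:
    """Intrinsic (random-coil) amide exchange rate for one residue.

    Additive nearest-neighbor model: acid-, base- and water-catalyzed
    channels from poly-alanine reference rates, each corrected by the
    log-factors of the residue's own side chain and of the preceding
    residue, with Arrhenius temperature scaling.  ``position`` is 1-based;
    the first residue and prolines carry no exchangeable backbone amide.

    Returns a rate per minute (``units='min'``) or per second
    (``units='s'``).
    """
    seq = sequence.upper()
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside sequence of length {len(seq)}")
    aa = seq[position - 1]
    if position == 1:
        raise ValueError("the N-terminal residue has no backbone amide proton")
    if aa == "P":
        raise ValueError(f"residue {position} is proline: no amide proton")
    table, ref = load_exchange_parameters()
    prev = seq[position - 2]
    try:
        own = table.loc[aa]
        left = table.loc[prev]
    except KeyError as exc:
        raise ValueError(f"unknown amino acid {exc}") from None

    log_acid = ref["log_ka"] + own["acid_own"] + left["acid_next"] - pD
    log_base = ref["log_kb"] + own["base_own"] + left["base_next"] + pD - ref["pkd"]
    log_water = ref["log_kw"] + own["base_own"] + left["base_next"]

    t_ref = ref["t_ref_k"]
    arr = lambda ea_kcal: math.exp(
        -ea_kcal * _KCAL / R_GAS * (1.0 / temperature - 1.0 / t_ref)
    )
    k = (
        10.0**log_acid * arr(ref["ea_acid_kcal"])
        + 10.0**log_base * arr(ref["ea_base_kcal"])
        + 10.0**log_water * arr(ref["ea_water_kcal"])
    )
    if units == "min":
        return k
    if units == "s":
        return k / 60.0
    raise ValueError("units must be 'min' or 's'")


def protection_factor(k_int: float, k_ex: float) -> float:
    """Protection factor ``P = k_int / k_ex`` (rates in matching units).

    ``k_ex = 0`` means exchange was not observed at all; the protection is
    above the detection limit and reported as ``inf``.
    """
    if k_ex < 0 or k_int < 0:
        raise ValueError("rates must be non-negative")
    if k_ex == 0:
        return math.inf
    return k_int / k_ex


def fit_r2_profile(curves: list[DecayCurve]) -> pd.DataFrame:
    """Per-residue R₂ from a set of decay curves.

    A residue whose fit fails is flagged (``ok=False``, NaN rate) without
    aborting the profile.  Returns a frame sorted by residue with columns
    ``residue_id, r2, r2_stderr, amplitude, ok``.
    """
    rows = []
    for curve in curves:
        try:
            fit = fit_decay(curve)
            rows.append(
                {
                    "residue_id": curve.residue_id,
                    "r2": fit.rate,
                    "r2_stderr": fit.rate_stderr,
                    "amplitude": fit.amplitude,
                    "ok": True,
                }
            )
        except (ValueError, RuntimeError):
            rows.append(
                {
                    "residue_id": curve.residue_id,
                    "r2": np.nan,
                    "r2_stderr": np.nan,
                    "amplitude": np.nan,
                    "ok": False,
                }
            )
    return pd.DataFrame(rows).sort_values("residue_id", ignore_index=True)


@dataclass
class ExchangeResult:
    """Per-residue exchange rates and protection factors."""

    table: pd.DataFrame
    k_agg: float | None
    aggregation_mode: str
    pD: float
    temperature: float


def compute_exchange(
    curves: list[DecayCurve],
    sequence: str,
    pD: float,
    temperature: float = 298.15,
    k_agg: float | None = None,
    aggregation_mode: str = "ratio",
    k_int_table: dict[int, float] | None = None,
) -> ExchangeResult:
    """Full H/D-exchange analysis for a set of per-residue decays.

    Fits each decay, applies the aggregation correction, predicts (or
    takes from ``k_int_table``) the intrinsic rate, and forms protection
    factors.  Rates are per minute throughout.  Residues that could not be
    fit, prolines and the N-terminus appear with NaN.
    """
    rows = []
    for curve in curves:
        rid = curve.residue_id
        row: dict = {"residue_id": rid}
        try:
            fit = fit_decay(curve)
            k_obs = fit.rate if curve.time_unit == "min" else fit.rate * 60.0
            row["k_obs"] = k_obs
            row["k_ex"] = correct_aggregation(k_obs, k_agg, aggregation_mode)
            if k_int_table is not None and rid in k_int_table:
                row["k_int"] = k_int_table[rid]
            else:
                row["k_int"] = intrinsic_rate(sequence, rid, pD, temperature)
            row["protection_factor"] = protection_factor(row["k_int"], row["k_ex"])
            row["ok"] = True
        except (ValueError, RuntimeError) as exc:
            row.setdefault("k_obs", np.nan)
            row.setdefault("k_ex", np.nan)
            row.setdefault("k_int", np.nan)
            row["protection_factor"] = np.nan
            row["ok"] = False
            row["note"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("residue_id", ignore_index=True)
    return ExchangeResult(
        table=table,
        k_agg=k_agg,
        aggregation_mode=aggregation_mode if k_agg is not None else "none",
        pD=pD,
        temperature=temperature,
    )
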