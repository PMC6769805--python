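"""Sigmoidal pH-unfolding fits of tryptophan-fluorescence titrations.

Acid unfolding monitored by intrinsic fluorescence follows, to a good
approximation, a proton-linked two-state equilibrium, which motivates a
base-10 logistic in pH:

    S(pH) = S_f + (S_u − S_f) / (1 + 10^(m · (pH − pH_mid)))

``pH_mid`` is the unfolding midpoint, ``m`` a Hill-type steepness (pH⁻¹;
positive ``m`` puts the unfolded baseline ``S_u`` at low pH) and ``S_f``
the folded-state baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = ["TitrationCurve", "SigmoidFit", "sigmoid", "fit_sigmoid"]


@dataclass
class TitrationCurve:
    """pH vs. signal (arbitrary fluorescence units)."""

    ph: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ph.shape != self.signal.shape:
            raise ValueError("pH and signal arrays must have equal length")
        if self.ph.size < 5:
            raise ValueError("need at least 5 titration points")
        if np.any(np.diff(self.ph) <= 0):
            raise ValueError("pH values must be strictly increasing")


@dataclass
class SigmoidFit:
    midpoint: float
    slope: float
    s_folded: float
    s_unfolded: float
    midpoint_stderr: float | None
    slope_stderr: float | None
    midpoint_in_range: bool


def sigmoid(ph, midpoint, slope, s_folded, s_unfolded):
    """The base-10 logistic transition curve."""
    return s_folded + (s_unfolded - s_folded) / (1.0 + 10.0 ** (slope * (ph - midpoint)))


def fit_sigmoid(curve: TitrationCurve) -> SigmoidFit:
    """Least-squares fit of the base-10 logistic to a titration curve.

    The midpoint is initialized at the half-amplitude crossing of the
    data; a fitted midpoint outside the sampled pH range is flagged (with
    a warning) rather than rejected.  A flat signal cannot define a
    transition and raises.
    """
    ph, y = curve.ph, curve.signal
    span = np.ptp(y)
    if span <= 0 or span < 1e-9 * max(1.0, np.abs(y).max()):
        raise RuntimeError("signal shows no transition: sigmoid fit cannot converge")

    half = (y[0] + y[-1]) / 2.0
    mid0 = float(ph[np.argmin(np.abs(y - half))])
    # positive slope convention: high-pH baseline is the folded signal
    model = lmfit.Model(sigmoid)
    params = model.make_params(
        midpoint=mid0, slope=2.0, s_folded=float(y[-1]), s_unfolded=float(y[0])
    )
    result = model.fit(y, params, ph=ph)
    if not result.success:
        raise RuntimeError(f"sigmoid fit did not converge: {result.message}")
    mid = float(result.params["midpoint"].value)
    in_range = bool(ph.min() <= mid <= ph.max())
    if not in_range:
        warnings.warn(f"fitted midpoint {mid:.3f} lies outside the sampled pH range")
    get_err = lambda name: (
        float(result.params[name].stderr)
        if result.params[name].stderr is not None
        else None
    )
    return SigmoidFit(
        midpoint=mid,
        slope=float(result.params["slope"].value),
        s_folded=float(result.params["s_folded"].value),
        s_unfolded=float(result.params["s_unfolded"].value),
        midpoint_stderr=get_err("midpoint"),
        slope_stderr=get_err("slope"),
        midpoint_in_range=in_range,
    )
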