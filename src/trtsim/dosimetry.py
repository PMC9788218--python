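"""Tumor dosimetry: from tumor activity R2(t) to dose rate and absorbed dose.

The dose rate in the tumor is proportional to the activity residing in it,

    d(t) = k * R2(t)            [Gy/h],

with k the activity-to-dose-rate conversion constant (5.45 Gy/h per MBq
for a 1.5 g tumor, taken as a configured constant).  In the no-return
delivery model the time-integrated tumor activity has the closed form

    ∫0^∞ R2(t) dt = Q a12 / (y A),

so the total absorbed dose is k * Q * a12/(y A); with the default rate
constants and Q = 1 MBq this evaluates to 9.7 Gy.  Partial integrals are
also closed-form, which is what :func:`dose_profile` uses by default:

    D(t) = k Q (a12/B) [ (1-e^{-yt})/y - (1-e^{-At})/A ].

Multiple injections superpose linearly (the delivery ODE is linear), which
:func:`superpose_schedule` exploits for repeated-administration scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateModelError, InvalidInputError
from .pk_delivery import DeliveryRates, analytic_no_return, solve_compartments

__all__ = [
    "DoseConversion",
    "DoseProfile",
    "integrated_tumor_activity",
    "total_dose",
    "dose_profile",
    "superpose_schedule",
]


@dataclass(frozen=True)
class DoseConversion:
    """Activity-to-dose-rate conversion for the tumor.

    ``gy_per_h_per_mbq`` is the dose rate delivered per MBq of activity
    resident in the tumor (default 5.45 Gy/h/MBq for a 1.5 g tumor).
    ``tumor_mass_g`` is informational only.
    """

    gy_per_h_per_mbq: float = 5.45
    tumor_mass_g: float = 1.5

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gy_per_h_per_mbq) and self.gy_per_h_per_mbq > 0):
            raise InvalidInputError(
                f"gy_per_h_per_mbq must be positive, got {self.gy_per_h_per_mbq!r}"
            )


@dataclass(frozen=True)
class DoseProfile:
    """Dose rate d(t) [Gy/h] and cumulative dose D(t) [Gy] on a grid (hours)."""

    t: np.ndarray
    d: np.ndarray
    D: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_h": self.t, "dose_rate_gy_per_h": self.d, "cum_dose_gy": self.D}
        )


def integrated_tumor_activity(rates: DeliveryRates, Q: float) -> float:
    """Time-integrated tumor activity Q*a12/(y*A), MBq*h (no-return model)."""
    if not (np.isfinite(Q) and Q >= 0):
        raise InvalidInputError(f"Q must be a finite non-negative activity, got {Q!r}")
    if rates.y <= 0:
        raise DegenerateModelError("decay rate y must be positive: integral diverges")
    return Q * rates.a12 / (rates.y * rates.A)


def total_dose(rates: DeliveryRates, Q: float, conv: DoseConversion) -> float:
    """Total absorbed dose in the tumor, Gy (closed form, never truncated)."""
    return conv.gy_per_h_per_mbq * integrated_tumor_activity(rates, Q)


def _cumulative_analytic(rates: DeliveryRates, Q: float, conv: DoseConversion, t):
    """Closed-form running integral of the analytic dose rate, Gy."""
    A, B, y = rates.A, rates.B, rates.y
    t = np.asarray(t, dtype=float)
    return (
        conv.gy_per_h_per_mbq
        * Q
        * rates.a12
        / B
        * ((1.0 - np.exp(-y * t)) / y - (1.0 - np.exp(-A * t)) / A)
    )


def dose_profile(
    rates: DeliveryRates,
    Q: float,
    conv: DoseConversion,
    t_grid,
    *,
    method: str = "analytic",
) -> DoseProfile:
    """Dose rate and cumulative dose on ``t_grid`` (hours, starting at 0).

    ``method='analytic'`` (default) uses the no-return closed forms for both
    the rate and its running integral; ``method='numeric'`` uses the full
    numeric compartment solution (return paths included) with trapezoidal
    accumulation.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1 or t[0] != 0.0:
        raise InvalidInputError("t_grid must be 1-d and start at 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidInputError("t_grid must be strictly increasing")
    if method == "analytic":
        _, R2, _, _ = analytic_no_return(rates, Q, t)
        d = conv.gy_per_h_per_mbq * R2
        D = _cumulative_analytic(rates, Q, conv, t)
    elif method == "numeric":
        traj = solve_compartments(rates, Q, t)
        d = conv.gy_per_h_per_mbq * traj.R2
        D = np.concatenate([[0.0], np.cumsum(np.diff(t) * (d[1:] + d[:-1]) / 2.0)])
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return DoseProfile(t=t, d=d, D=D)


def superpose_schedule(
    schedule: Iterable[Sequence[float]],
    rates: DeliveryRates,
    conv: DoseConversion,
    t_grid,
) -> DoseProfile:
    """Dose profile for repeated injections, by linear superposition.

    ``schedule`` is an iterable of ``(time_h, activity_mbq)`` pairs; it is
    sorted internally.  Each injection contributes the single-injection
    profile shifted to its own time, which is exact because the delivery
    ODE is linear and time-invariant.
    """
    entries = sorted((float(ti), float(qi)) for ti, qi in schedule)
    if not entries:
        raise InvalidInputError("schedule must contain at least one injection")
    for ti, qi in entries:
        if ti < 0:
            raise InvalidInputError(f"injection time must be >= 0, got {ti}")
        if qi < 0:
            raise InvalidInputError(f"injected activity must be >= 0, got {qi}")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1 or t[0] != 0.0:
        raise InvalidInputError("t_grid must be 1-d and start at 0")
    d = np.zeros_like(t)
    D = np.zeros_like(t)
    for ti, qi in entries:
        tau = t - ti
        active = tau >= 0
        _, R2, _, _ = analytic_no_return(rates, qi, tau[active])
        d[active] += conv.gy_per_h_per_mbq * R2
        D[active] += _cumulative_analytic(rates, qi, conv, tau[active])
    return DoseProfile(t=t, d=d, D=D)
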