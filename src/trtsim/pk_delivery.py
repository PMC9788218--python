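"""Four-compartment delivery model for an intravenously injected radionuclide.

The carrier is injected into blood (compartment 1) and exchanges with the
tumor (2) and the rest of the body (3); a fourth compartment collects
excreted material.  Every compartment additionally loses activity by
physical decay at rate ``y``.  The governing linear system is

    dR1/dt = -(a12 + a13 + a14) R1 + a21 R2 + a31 R3 - y R1
    dR2/dt =  a12 R1 - a21 R2 - y R2
    dR3/dt =  a13 R1 - a31 R3 - y R3
    dR4/dt =  a14 R1 - y R4

with initial condition R1(0) = Q (the injected activity, MBq) and all
other compartments empty.  The total activity R_T = R1+R2+R3+R4 then obeys
R_T(t) = Q e^{-yt} exactly.

When the return paths a21 and a31 are dropped the system is solvable in
closed form (``analytic_no_return``), which is the variant used downstream
for dosimetry: with A = a12+a13+a14+y and B = a12+a13+a14,

    R1(t) = Q e^{-At},
    Ri(t) = Q (a1i/B) (1 - e^{-Bt}) e^{-yt},   i = 2, 3, 4.

Activities are carried in MBq throughout; the absolute number of nuclides
differs only by a constant that cancels everywhere the model is used.
Time is in hours in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DegenerateModelError, InvalidInputError

__all__ = [
    "HALF_LIFE_AT211_H",
    "DeliveryRates",
    "CompartmentTrajectory",
    "solve_compartments",
    "analytic_no_return",
    "renormalized_tumor_fraction",
]

#: Physical half-life of astatine-211, hours.
HALF_LIFE_AT211_H = 7.21


@dataclass(frozen=True)
class DeliveryRates:
    """Transfer coefficients of the four-box model, per hour.

    Defaults are the published rate constants for At-211 distribution in
    the mouse: blood→tumor 0.33, blood→body 1.0, blood→excretion 0.5,
    with return paths tumor→blood 0.1 and body→blood 0.5.  The physical
    decay rate ``y`` is derived from the half-life (7.21 h for At-211).
    """

    a12: float = 0.33
    a13: float = 1.0
    a14: float = 0.5
    a21: float = 0.1
    a31: float = 0.5
    half_life_h: float = HALF_LIFE_AT211_H

    def __post_init__(self) -> None:
        for name in ("a12", "a13", "a14", "a21", "a31"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise InvalidInputError(
                    f"{name} must be a finite non-negative rate, got {value!r}"
                )
        if not (np.isfinite(self.half_life_h) and self.half_life_h > 0):
            raise InvalidInputError(
                f"half_life_h must be positive and finite, got {self.half_life_h!r}"
            )

    @property
    def y(self) -> float:
        """Physical decay rate, per hour (ln 2 / half-life)."""
        return math.log(2.0) / self.half_life_h

    @property
    def A(self) -> float:
        """Total elimination rate from blood including decay: a12+a13+a14+y."""
        return self.a12 + self.a13 + self.a14 + self.y

    @property
    def B(self) -> float:
        """Total transfer rate out of blood excluding decay: a12+a13+a14."""
        return self.a12 + self.a13 + self.a14


@dataclass(frozen=True)
class CompartmentTrajectory:
    """Activity of each compartment on a reporting grid (hours, MBq)."""

    t: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    R3: np.ndarray
    R4: np.ndarray

    @property
    def RT(self) -> np.ndarray:
        """Total activity R1+R2+R3+R4, MBq."""
        return self.R1 + self.R2 + self.R3 + self.R4

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_h": self.t,
                "R1": self.R1,
                "R2": self.R2,
                "R3": self.R3,
                "R4": self.R4,
                "RT": self.RT,
            }
        )


def _validate_grid(t_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise InvalidInputError("t_grid must be a 1-d array with at least one point")
    if t[0] != 0.0:
        raise InvalidInputError(f"t_grid must start at 0, got {t[0]!r}")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidInputError("t_grid must be strictly increasing")
    return t


def solve_compartments(
    rates: DeliveryRates,
    Q: float,
    t_grid,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> CompartmentTrajectory:
    """Integrate the full four-box system numerically on ``t_grid`` (hours).

    Physical decay is factored out before integration: the solver works on
    S_i = R_i e^{+yt}, whose transfer matrix conserves the total exactly,
    and the decay factor is reapplied afterwards.  This keeps the relative
    error of the mass balance R_T = Q e^{-yt} at the solver tolerance even
    at times where the total activity has decayed by many orders of
    magnitude.

    Values that undershoot zero by less than ``atol`` are clamped to zero;
    a larger undershoot raises, since it indicates a solver failure rather
    than roundoff.
    """
    if not (np.isfinite(Q) and Q >= 0):
        raise InvalidInputError(f"Q must be a finite non-negative activity, got {Q!r}")
    t = _validate_grid(t_grid)

    # Transfer matrix of the decay-factored system (columns sum to zero).
    M = np.array(
        [
            [-rates.B, rates.a21, rates.a31, 0.0],
            [rates.a12, -rates.a21, 0.0, 0.0],
            [rates.a13, 0.0, -rates.a31, 0.0],
            [rates.a14, 0.0, 0.0, 0.0],
        ]
    )
    y0 = np.array([Q, 0.0, 0.0, 0.0])

    if t.size == 1 or Q == 0.0:
        S = np.tile(y0[:, None], (1, t.size))
    else:
        sol = solve_ivp(
            lambda _t, s: M @ s,
            (t[0], t[-1]),
            y0,
            method="LSODA",
            t_eval=t,
            rtol=rtol,
            atol=atol,
            jac=lambda _t, _s: M,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"compartment ODE solver failed: {sol.message}")
        S = sol.y

    if np.any(S < -atol):
        raise RuntimeError(
            f"compartment solution undershoots zero by more than atol={atol}"
        )
    S = np.clip(S, 0.0, None)
    decay = np.exp(-rates.y * t)
    R = S * decay
    return CompartmentTrajectory(t=t, R1=R[0], R2=R[1], R3=R[2], R4=R[3])


def analytic_no_return(rates: DeliveryRates, Q: float, t):
    """Closed-form compartment activities when the return paths are dropped.

    The stored ``a21``/``a31`` are ignored by construction.  Raises
    :class:`DegenerateModelError` if no transfer leaves the blood (B = 0).
    Returns ``(R1, R2, R3, R4)`` evaluated at ``t`` (scalar or array, hours).
    """
    if not (np.isfinite(Q) and Q >= 0):
        raise InvalidInputError(f"Q must be a finite non-negative activity, got {Q!r}")
    B = rates.B
    if B == 0.0:
        raise DegenerateModelError(
            "no transfer out of blood (a12+a13+a14 = 0); the no-return closed form "
            "is degenerate"
        )
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be non-negative")
    A, y = rates.A, rates.y
    R1 = Q * np.exp(-A * t)
    shape = Q / B * (1.0 - np.exp(-B * t)) * np.exp(-y * t)
    return R1, rates.a12 * shape, rates.a13 * shape, rates.a14 * shape


def renormalized_tumor_fraction(rates: DeliveryRates, t):
    """Tumor activity divided by the physical-decay curve, dimensionless.

    Equals (a12/B)(1 - e^{-Bt}) in the no-return model; the injected
    activity cancels.  Monotone non-decreasing in t, with plateau a12/B.
    """
    B = rates.B
    if B == 0.0:
        raise DegenerateModelError("a12+a13+a14 = 0: renormalized fraction undefined")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be non-negative")
    return rates.a12 / B * (1.0 - np.exp(-B * t))
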