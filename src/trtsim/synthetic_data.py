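"""Synthetic xenograft cohorts with the model's own dynamics plus noise.

No per-animal volume measurements from the original treatment experiment
are available in machine-readable form, so testable cohorts are generated
from the model itself: each animal draws an individual growth rate λ_i
(normal, mean 0.14/day, SD 0.08/day, truncated at 0.01/day) and an initial
volume V0_i (lognormal, moment-matched to mean 577 mm³ / SD 372 mm³), is
simulated under its group's dose profile, and is observed on a fixed
measurement schedule with i.i.d. multiplicative lognormal caliper noise.

Day 0 is each animal's treatment day (treatment starts when the tumor
reaches size, so cohorts are aligned on injection, not implantation).
The noise magnitude (log-SD 0.15) and the every-2-days schedule are
fixture conventions, not measured properties of any real experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .dosimetry import DoseConversion, dose_profile
from .errors import InvalidInputError
from .pk_delivery import DeliveryRates
from .tumor_response import DoseInput, TumorParams, simulate_full

__all__ = ["CohortSpec", "generate_cohort", "lam_distribution_mean"]


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort (defaults emulate the modeled study)."""

    n_per_group: int = 6
    activities: tuple[float, ...] = (0.0, 0.1, 0.4, 1.0)
    lam_mean: float = 0.14  # /day
    lam_sd: float = 0.08  # /day
    lam_min: float = 0.01  # truncation: no shrinking "control" animals
    v0_mean: float = 577.0  # mm³
    v0_sd: float = 372.0  # mm³
    noise_sigma: float = 0.15  # log-SD of multiplicative measurement noise
    schedule: tuple[float, ...] = tuple(float(d) for d in range(0, 31, 2))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise InvalidInputError("n_per_group must be >= 1")
        if min(self.lam_sd, self.v0_sd, self.noise_sigma) < 0:
            raise InvalidInputError("standard deviations must be >= 0")
        if self.v0_mean <= 0 or self.lam_mean <= 0:
            raise InvalidInputError("lam_mean and v0_mean must be positive")
        if any(q < 0 for q in self.activities):
            raise InvalidInputError("activities must be >= 0")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size < 1 or np.any(np.diff(sched) <= 0) or sched[0] < 0:
            raise InvalidInputError("schedule must be strictly increasing and >= 0")


def lam_distribution_mean(spec: CohortSpec) -> float:
    """Mean of the truncated-normal law the generator draws λ from."""
    if spec.lam_sd == 0:
        return spec.lam_mean
    a = (spec.lam_min - spec.lam_mean) / spec.lam_sd
    return float(truncnorm.mean(a, np.inf, loc=spec.lam_mean, scale=spec.lam_sd))


def _draw_lambda(spec: CohortSpec, rng: np.random.Generator) -> float:
    if spec.lam_sd == 0:
        return spec.lam_mean
    a = (spec.lam_min - spec.lam_mean) / spec.lam_sd
    return float(truncnorm.rvs(a, np.inf, loc=spec.lam_mean, scale=spec.lam_sd,
                               random_state=rng))


def _draw_v0(spec: CohortSpec, rng: np.random.Generator) -> float:
    if spec.v0_sd == 0:
        return spec.v0_mean
    # lognormal moment-matched to (mean, sd): guarantees positive volumes
    sigma2 = np.log1p((spec.v0_sd / spec.v0_mean) ** 2)
    mu = np.log(spec.v0_mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def generate_cohort(
    spec: CohortSpec,
    rates: DeliveryRates | None = None,
    conv: DoseConversion | None = None,
    p: TumorParams | None = None,
) -> pd.DataFrame:
    """Generate a long-format cohort table: animal_id, activity_mbq, day, volume_mm3.

    Each animal's trajectory is a full model run (delay and impaired
    regrowth on) under its group's dose profile; observed volumes are the
    model volumes times exp(N(0, noise_sigma)) per measurement.  Output is
    deterministic for a fixed ``spec.seed``.
    """
    rates = rates or DeliveryRates()
    conv = conv or DoseConversion()
    p = p or TumorParams()
    rng = np.random.default_rng(spec.seed)

    sched = np.asarray(spec.schedule, dtype=float)
    t_grid = np.union1d([0.0], sched)
    take = np.isin(t_grid, sched)

    doses: dict[float, DoseInput] = {}
    for q in spec.activities:
        if q == 0:
            doses[q] = DoseInput.zero()
        else:
            t_h = np.arange(0.0, 96.0 + 0.01, 0.01)
            doses[q] = DoseInput.from_profile(dose_profile(rates, q, conv, t_h))

    rows = []
    for gi, q in enumerate(spec.activities):
        for ai in range(spec.n_per_group):
            aid = f"g{gi}a{ai:03d}"
            lam_i = _draw_lambda(spec, rng)
            v0_i = _draw_v0(spec, rng)
            p_i = replace(p, lam=lam_i, V0=v0_i, v=None, Vm=None)
            traj = simulate_full(p_i, doses[q], t_grid)
            volumes = traj.V[take]
            if spec.noise_sigma > 0:
                volumes = volumes * np.exp(
                    rng.normal(0.0, spec.noise_sigma, size=volumes.size)
                )
            for day, vol in zip(sched, volumes):
                rows.append((aid, q, day, vol))
    return pd.DataFrame(rows, columns=["animal_id", "activity_mbq", "day",
                                       "volume_mm3"])
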