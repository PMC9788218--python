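"""Control-growth parameter estimation from tumor-volume time series.

During unperturbed early growth the tumor volume follows V = V0 e^{λt},
so λ and V0 are estimated per animal by ordinary least squares of ln V on
time over the early window (default first 10 days), and a cohort is
summarized by the mean and sample standard deviation of the per-animal
estimates — the procedure behind a control-cohort table of λ and V0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import InsufficientDataError, InvalidInputError

__all__ = ["GrowthFit", "CohortSummary", "fit_growth_rate", "summarize_cohort",
           "fit_cohort_table"]


@dataclass(frozen=True)
class GrowthFit:
    """Per-animal log-linear growth fit: V ≈ V0_hat · e^{lam_hat · t}."""

    animal_id: str
    lam_hat: float  # /day
    V0_hat: float  # mm³
    n_points: int
    window_days: float


@dataclass(frozen=True)
class CohortSummary:
    """Mean and sample SD (n−1 denominator) of per-animal growth fits.

    ``degenerate`` flags a single-animal cohort, for which the SDs are
    reported as 0 rather than raising.
    """

    lam_mean: float
    lam_sd: float
    V0_mean: float
    V0_sd: float
    n_animals: int
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": ["lam_per_day", "V0_mm3"],
                "mean": [self.lam_mean, self.V0_mean],
                "sd": [self.lam_sd, self.V0_sd],
            }
        )


def fit_growth_rate(
    series: Iterable[Sequence[float]] | pd.DataFrame,
    window_days: float = 10.0,
    *,
    animal_id: str = "",
) -> GrowthFit:
    """OLS of ln(volume) on day over ``[0, window_days]``.

    ``series`` is an iterable of (day, volume mm³) pairs or a DataFrame
    with ``day`` and ``volume_mm3`` columns.  Day 0 is the animal's first
    measurement.  Volumes must be positive; fewer than two usable points
    raise :class:`InsufficientDataError`.
    """
    if window_days <= 0:
        raise InvalidInputError("window_days must be positive")
    if isinstance(series, pd.DataFrame):
        arr = series[["day", "volume_mm3"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("series must be (day, volume) pairs")
    t, v = arr[:, 0], arr[:, 1]
    in_window = (t >= 0) & (t <= window_days)
    t, v = t[in_window], v[in_window]
    if np.any(v <= 0):
        raise InvalidInputError("volumes must be positive for a log-linear fit")
    if t.size < 2 or np.unique(t).size < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct time points in [0, {window_days}] days, have {t.size}"
        )
    res = linregress(t, np.log(v))
    return GrowthFit(
        animal_id=animal_id,
        lam_hat=float(res.slope),
        V0_hat=float(np.exp(res.intercept)),
        n_points=int(t.size),
        window_days=float(window_days),
    )


def summarize_cohort(fits: Sequence[GrowthFit]) -> CohortSummary:
    """Arithmetic mean and sample SD of lam_hat and V0_hat across animals."""
    fits = list(fits)
    if not fits:
        raise InsufficientDataError("cannot summarize an empty cohort")
    lam = np.array([f.lam_hat for f in fits])
    v0 = np.array([f.V0_hat for f in fits])
    degenerate = len(fits) == 1
    return CohortSummary(
        lam_mean=float(lam.mean()),
        lam_sd=0.0 if degenerate else float(lam.std(ddof=1)),
        V0_mean=float(v0.mean()),
        V0_sd=0.0 if degenerate else float(v0.std(ddof=1)),
        n_animals=len(fits),
        degenerate=degenerate,
    )


def fit_cohort_table(
    table: pd.DataFrame,
    window_days: float = 10.0,
    *,
    activity_mbq: float | None = 0.0,
) -> list[GrowthFit]:
    """Fit every animal in a long-format cohort table.

    The table needs columns ``animal_id``, ``activity_mbq``, ``day``,
    ``volume_mm3``.  By default only the control group (activity 0) is
    fitted, since the exponential-growth assumption holds only without
    treatment; pass ``activity_mbq=None`` to fit all animals.
    """
    required = {"animal_id", "activity_mbq", "day", "volume_mm3"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"cohort table missing columns: {sorted(missing)}")
    if activity_mbq is not None:
        table = table[table["activity_mbq"] == activity_mbq]
    if table.empty:
        raise InsufficientDataError("no animals in the requested group")
    fits = []
    for aid, sub in table.groupby("animal_id", sort=True):
        fits.append(fit_growth_rate(sub, window_days, animal_id=str(aid)))
    return fits
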