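"""Prey-capture accounting and feeding-rate saturation curves.

Consumption is inferred from the drop in prey density over a feeding bout,
converted to biomass at a fixed per-nauplius mass, and normalized to coral
surface area and bout duration. Feeding-rate versus prey-density curves are
fit as ``rate = a + b * ln(density)`` by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "NAUPLIUS_MASS_UG",
    "FeedingEvent",
    "CaptureResult",
    "LogCurveFit",
    "consumption_from_densities",
    "capture_table",
    "cumulative_capture",
    "fit_log_curve",
    "fit_curves_by_treatment",
]

#: mean dry mass of a single Artemia nauplius, micrograms
NAUPLIUS_MASS_UG = 3.2


@dataclass(frozen=True)
class FeedingEvent:
    """One tank x feeding bout."""

    tank_id: str
    treatment: str
    date_index: int
    density_initial: float  # nauplii per litre (tank mean of triplicate counts)
    density_final: float
    volume: float = 40.0  # litres
    duration: float = 2.0  # hours
    coral_surface_area: float = 0.0  # cm^2, summed over fragments in the tank

    def validate(self) -> None:
        if self.volume <= 0:
            raise ValidationError("volume must be positive")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.coral_surface_area <= 0:
            raise ValidationError("coral_surface_area must be positive")
        if self.density_initial < 0 or self.density_final < 0:
            raise ValidationError("densities must be non-negative")


@dataclass(frozen=True)
class CaptureResult:
    """Consumption for one feeding bout, absolute and normalized."""

    tank_id: str
    treatment: str
    date_index: int
    nauplii_consumed: float
    biomass_consumed_mg: float
    rate: float  # nauplii cm^-2 h^-1
    biomass_per_area_mg_cm2: float
    clamped: bool  # final density exceeded initial; consumption clamped to 0


def consumption_from_densities(
    event: FeedingEvent, nauplius_mass_ug: float = NAUPLIUS_MASS_UG
) -> CaptureResult:
    """Per-bout consumption from the initial/final prey-density difference.

    ``consumed = max(0, d_initial - d_final) * volume``; an apparent negative
    consumption (counting noise) is clamped to zero and flagged with a
    warning. Biomass uses the fixed per-nauplius mass (default 3.2 ug).
    """
    event.validate()
    raw = (event.density_initial - event.density_final) * event.volume
    clamped = raw < 0
    if clamped:
        warnings.warn(
            f"tank {event.tank_id} feeding {event.date_index}: final density "
            "exceeds initial; consumption clamped to 0",
            stacklevel=2,
        )
    consumed = max(0.0, raw)
    biomass_mg = consumed * nauplius_mass_ug * 1e-3
    return CaptureResult(
        tank_id=event.tank_id,
        treatment=event.treatment,
        date_index=event.date_index,
        nauplii_consumed=consumed,
        biomass_consumed_mg=biomass_mg,
        rate=consumed / event.coral_surface_area / event.duration,
        biomass_per_area_mg_cm2=biomass_mg / event.coral_surface_area,
        clamped=clamped,
    )


def capture_table(
    events: pd.DataFrame, nauplius_mass_ug: float = NAUPLIUS_MASS_UG
) -> pd.DataFrame:
    """Vectorized :func:`consumption_from_densities` over an events table.

    Expects the ``feeding_events.csv`` schema (see :mod:`mixotracer.schemas`).
    Also carries the bout's prey density through for curve fitting.
    """
    results = []
    for rec in events.itertuples(index=False):
        res = consumption_from_densities(
            FeedingEvent(
                tank_id=rec.tank_id,
                treatment=rec.treatment,
                date_index=rec.date_index,
                density_initial=rec.density_initial_per_L,
                density_final=rec.density_final_per_L,
                volume=rec.volume_L,
                duration=rec.duration_h,
                coral_surface_area=rec.coral_surface_area_cm2,
            ),
            nauplius_mass_ug=nauplius_mass_ug,
        )
        row = res.__dict__ | {"density_initial_per_L": rec.density_initial_per_L}
        results.append(row)
    return pd.DataFrame(results)


def cumulative_capture(captures: pd.DataFrame) -> pd.DataFrame:
    """Cumulative biomass capture per tank over the experiment (mg cm^-2).

    ``captures`` is the output of :func:`capture_table`; every tank must
    contribute at least one bout.
    """
    if captures.empty:
        raise ValidationError("no capture results to accumulate")
    grouped = captures.groupby(["tank_id", "treatment"], as_index=False).agg(
        cumulative_biomass_mg_cm2=("biomass_per_area_mg_cm2", "sum"),
        n_feedings=("biomass_per_area_mg_cm2", "size"),
    )
    return grouped


@dataclass(frozen=True)
class LogCurveFit:
    """OLS fit of ``rate = a + b * ln(density)``."""

    a: float
    b: float
    r_squared: float
    n_points: int
    residual_se: float

    def predict(self, density: float | np.ndarray) -> float | np.ndarray:
        """Predicted rate (nauplii cm^-2 h^-1) at a prey density (L^-1)."""
        return self.a + self.b * np.log(density)


def fit_log_curve(
    densities: Sequence[float], rates: Sequence[float]
) -> LogCurveFit:
    """Fit ``rate = a + b * ln(density)`` by ordinary least squares.

    R-squared is computed on the rate scale. A constant-rate input yields
    ``b = 0`` and ``a = mean(rate)``.
    """
    d = np.asarray(densities, dtype=float)
    r = np.asarray(rates, dtype=float)
    if d.size != r.size:
        raise ValidationError("densities and rates must be equal length")
    if d.size < 3:
        raise ValidationError("need at least 3 points to fit a curve")
    if np.any(d <= 0):
        raise ValidationError("all densities must be positive")

    x = np.log(d)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    fitted = X @ coef
    ss_res = float(((r - fitted) ** 2).sum())
    ss_tot = float(((r - r.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    dof = d.size - 2
    residual_se = float(np.sqrt(ss_res / dof)) if dof > 0 else float("nan")
    return LogCurveFit(a=a, b=b, r_squared=r2, n_points=int(d.size), residual_se=residual_se)


def fit_curves_by_treatment(
    captures: pd.DataFrame, per_tank: bool = False
) -> pd.DataFrame:
    """Per-treatment (default) or per-tank logarithmic feeding-curve fits.

    Pools bout-level observations across tanks within a treatment; tanks are
    not weighted. Treatments with fewer than 3 usable bouts are skipped.
    """
    keys = ["treatment", "tank_id"] if per_tank else ["treatment"]
    rows = []
    for key, grp in captures.groupby(keys):
        usable = grp[grp["density_initial_per_L"] > 0]
        if len(usable) < 3:
            continue
        fit = fit_log_curve(usable["density_initial_per_L"], usable["rate"])
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            a=fit.a,
            b=fit.b,
            r_squared=fit.r_squared,
            n_points=fit.n_points,
            residual_se=fit.residual_se,
        )
        rows.append(row)
    return pd.DataFrame(rows)
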