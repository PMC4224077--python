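"""Rivaroxaban pharmacokinetics overlay and schedule compliance.

A one-compartment model with first-order absorption and superposition of
once-daily oral doses.  Rivaroxaban PK is dose-proportional here; the
default parameters are literature-class values for the atrial-fibrillation
population (CL/F 6.5 L/h, V/F 55 L, ka 1.4 1/h) and can be overridden in
the run configuration.  The PK layer is presentation/decision logic only:
no clot-time calibration depends on it.

Compliance of a schedule with a safety/efficacy corridor follows the
convention of checking the day-end (trough) concentration against the
safety bound and the daily mean concentration against the efficacy bound,
both evaluated at the end of the dosing day (where the bounds are
tightest, since corridor bounds rise after warfarin discontinuation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = ["PkParams", "DoseSchedule", "pk_profile", "DayMetrics", "check_schedule"]

#: Labelled once-daily doses, mg.
ALLOWED_DOSES = (5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class PkParams:
    clearance_L_h: float = 6.5
    volume_L: float = 55.0
    ka_per_h: float = 1.4
    bioavailability: float = 1.0

    @property
    def ke_per_h(self) -> float:
        return self.clearance_L_h / self.volume_L


@dataclass(frozen=True)
class DoseSchedule:
    """Once-daily doses: (day index, dose mg); day d is dosed at d*24 h."""

    doses: tuple[tuple[int, float], ...]
    pk: PkParams = field(default_factory=PkParams)

    def __post_init__(self) -> None:
        days = [d for d, _ in self.doses]
        if len(set(days)) != len(days):
            raise ValueError("at most one dose per day (once-daily dosing)")
        for d, mg in self.doses:
            if mg not in ALLOWED_DOSES:
                raise ValueError(f"dose {mg} mg not in the labelled set {ALLOWED_DOSES}")
            if d < 0:
                raise ValueError("day index must be non-negative")

    @classmethod
    def bridging(
        cls,
        first_dose: float,
        maintenance: float,
        start_day: int = 1,
        maintenance_from_day: int | None = None,
        horizon_days: int = 7,
        pk: PkParams | None = None,
    ) -> "DoseSchedule":
        """E.g. bridging(10, 20): 10 mg on day 1, then 20 mg once daily."""
        maintenance_from_day = maintenance_from_day or start_day + 1
        doses = [(start_day, first_dose)]
        doses += [(d, maintenance) for d in range(maintenance_from_day, horizon_days + 1)]
        return cls(tuple(doses), pk or PkParams())

    @classmethod
    def flat(cls, dose: float, start_day: int = 0, horizon_days: int = 7,
             pk: PkParams | None = None) -> "DoseSchedule":
        return cls(tuple((d, dose) for d in range(start_day, horizon_days + 1)), pk or PkParams())


def concentration(schedule: DoseSchedule, t_h: np.ndarray) -> np.ndarray:
    """Plasma concentration (ug/L) at times t_h (hours) by superposition."""
    t = np.asarray(t_h, dtype=float)
    pk = schedule.pk
    ka, ke = pk.ka_per_h, pk.ke_per_h
    if ka == ke:  # pragma: no cover - degenerate flip-flop case
        ka *= 1.0 + 1e-9
    out = np.zeros_like(t)
    for day, mg in schedule.doses:
        dt = t - 24.0 * day
        mask = dt > 0
        amt = mg * 1000.0 * pk.bioavailability / pk.volume_L  # ug/L scale
        out[mask] += amt * ka / (ka - ke) * (np.exp(-ke * dt[mask]) - np.exp(-ka * dt[mask]))
    return out


@dataclass(frozen=True)
class DayMetrics:
    day: int
    cmax: float
    cmean: float
    ctrough: float


def pk_profile(
    schedule: DoseSchedule,
    horizon_h: float = 168.0,
    points_per_hour: int = 12,
) -> tuple[pd.DataFrame, list[DayMetrics]]:
    """Concentration time series plus per-day Cmax/Cmean/Ctrough.

    Cmax >= Cmean >= Ctrough within each day by construction (trough is the
    day-end value of a decaying-between-doses profile).
    """
    if not schedule.doses:
        raise ValueError("schedule is empty")
    n = int(horizon_h * points_per_hour) + 1
    t = np.linspace(0.0, horizon_h, n)
    c = concentration(schedule, t)
    series = pd.DataFrame({"time_h": t, "concentration_ugL": c})
    metrics = []
    for day in range(int(np.ceil(horizon_h / 24.0))):
        sel = (t >= 24.0 * day) & (t <= 24.0 * (day + 1))
        if not np.any(sel):
            continue
        cw, tw = c[sel], t[sel]
        metrics.append(
            DayMetrics(
                day=day,
                cmax=float(cw.max()),
                cmean=float(np.trapezoid(cw, tw) / (tw[-1] - tw[0])) if len(tw) > 1 else float(cw[0]),
                ctrough=float(concentration(schedule, np.array([24.0 * (day + 1)]))[0]),
            )
        )
    return series, metrics


def check_schedule(
    schedule: DoseSchedule,
    corridor,
    risk: Literal["high", "normal"] = "high",
) -> dict:
    """Per-day compliance of a dosing schedule with a corridor.

    For each day the day-end (trough) concentration must not exceed the
    applicable safety bound and the daily mean must not fall below the
    applicable efficacy bound; both bounds are taken at the day end.
    A zero efficacy bound means residual warfarin still covers efficacy.
    """
    if risk == "high":
        safety, efficacy = corridor.safety_high_risk, corridor.efficacy_high_risk
    elif risk == "normal":
        safety, efficacy = corridor.safety_normal, corridor.efficacy_normal
    else:
        raise ValueError("risk must be 'high' or 'normal'")
    horizon = float(corridor.times_h[-1])
    _, metrics = pk_profile(schedule, horizon_h=horizon)
    days = []
    for m in metrics:
        day_end = min(24.0 * (m.day + 1), horizon)
        safe_bound = float(np.interp(day_end, corridor.times_h, safety))
        eff_bound = float(np.interp(day_end, corridor.times_h, efficacy))
        safety_ok = m.ctrough <= safe_bound + 1e-9
        efficacy_ok = m.cmean >= eff_bound - 1e-9
        days.append(
            {
                "day": m.day,
                "cmax": m.cmax,
                "cmean": m.cmean,
                "ctrough": m.ctrough,
                "safety_bound": safe_bound,
                "efficacy_bound": eff_bound,
                "safety_ok": bool(safety_ok),
                "efficacy_ok": bool(efficacy_ok),
                "ok": bool(safety_ok and efficacy_ok),
            }
        )
    return {"risk": risk, "days": days, "pass": all(d["ok"] for d in days)}
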