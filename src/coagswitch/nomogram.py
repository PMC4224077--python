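"""Safety/efficacy exposure corridors for the warfarin-to-rivaroxaban switch.

After warfarin discontinuation the effective R-/S-warfarin levels decay and
the vitamin K-dependent factors recover on their turnover timescales.  At
each time point the residual coagulation state is combined with a candidate
rivaroxaban exposure and referenced against warfarin monotherapy:

* safety: clotting after the strong extrinsic trigger (TF 1e-11 M) must be
  faster than under warfarin at INR 4.0 (high bleeding risk) or 5.0
  (normal risk) — an upper exposure bound;
* efficacy: clotting after the weak extrinsic trigger (TF 1e-14 M) must be
  slower than under warfarin at INR 1.5 (normal thrombotic risk) or 2.0
  (high risk) — a lower exposure bound.

The four bounds over the first week form the switching nomogram; they start
narrow (residual warfarin contributes anticoagulation) and widen toward the
monotherapy window as warfarin washes out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import assay as assay_mod
from .assay import (
    AssayScenario,
    EXTRINSIC_STRONG,
    EXTRINSIC_WEAK,
    PT_TEST,
    baseline_pt,
    get_network,
    reference_clot_time,
    run_assay,
    steady_state_levels,
    titrate_profile,
)
from .populations import CAUCASIAN_MEDIAN, PopulationProfile
from .turnover import PROTEINS, RecoveryResult, WarfarinState, decay_warfarin, simulate_recovery

__all__ = [
    "SwitchScenario",
    "Corridor",
    "residual_state",
    "rivaroxaban_threshold",
    "compute_corridor",
    "monotherapy_bounds",
    "synergy_slope",
    "plot_nomogram",
]

#: (scenario, reference INR) pairs defining the four corridor bounds.
SAFETY_HIGH = (EXTRINSIC_STRONG, 4.0)
SAFETY_NORMAL = (EXTRINSIC_STRONG, 5.0)
EFFICACY_NORMAL = (EXTRINSIC_WEAK, 1.5)
EFFICACY_HIGH = (EXTRINSIC_WEAK, 2.0)


@dataclass(frozen=True)
class SwitchScenario:
    """A discontinuation scenario: start INR, population, corridor time grid."""

    start_inr: float = 2.5
    profile: PopulationProfile = CAUCASIAN_MEDIAN
    time_grid_h: tuple[float, ...] = tuple(float(h) for h in range(0, 169))

    def __post_init__(self) -> None:
        if self.start_inr < 1.0:
            raise ValueError("start INR must be >= 1")
        grid = tuple(float(t) for t in self.time_grid_h)
        if len(grid) == 0 or grid[0] != 0.0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("time grid must be sorted, unique and start at 0")
        object.__setattr__(self, "time_grid_h", grid)

    @property
    def network(self):
        return get_network(self.profile)


@lru_cache(maxsize=32)
def _recovery_for(profile: PopulationProfile, start_inr: float, horizon_s: float) -> RecoveryResult:
    network = get_network(profile)
    w0 = titrate_profile(network, start_inr)
    return simulate_recovery(w0, duration=horizon_s)


def residual_state(
    scenario: SwitchScenario, t_hours: float
) -> tuple[dict[str, float], WarfarinState]:
    """Factor levels and warfarin state `t_hours` after discontinuation.

    At t=0 the factors sit at the warfarin steady state k_i * W(w*) for the
    titrated level w*; afterwards the turnover model relaxes them toward
    baseline while R and S decay with their own half-lives.
    """
    if t_hours < 0:
        raise ValueError("time after discontinuation must be non-negative")
    horizon = max(45.0 * 24.0, t_hours * 1.25) * 3600.0
    rec = _recovery_for(scenario.profile, float(scenario.start_inr), horizon)
    levels = dict(zip(PROTEINS, rec(t_hours * 3600.0)))
    return levels, rec.warfarin_at(t_hours * 3600.0)


def rivaroxaban_threshold(
    network,
    vk_levels: Mapping[str, float] | None,
    trigger: AssayScenario,
    ct_ref: float,
    c_max: float = 2000.0,
    xtol: float = 1e-4,
) -> float:
    """Rivaroxaban concentration (ug/L) matching a reference clot time.

    Returns the exposure c* with clot_time(state, c*) = ct_ref, or 0 when
    the residual warfarin effect alone already clots slower than the
    reference (the bound is clamped at zero).  The root is located to
    near machine precision on the concentration axis, so the clot-time
    residual is limited only by the ODE solver's own tolerance (absolute
    for PT-scale references, relative ~1e-5 for the hours-long weak
    trigger references).
    """
    if ct_ref <= 0:
        raise ValueError("reference clot time must be positive")

    def gap(c: float) -> float:
        ct = run_assay(trigger, network, vk_levels=vk_levels, rivaroxaban_ugL=c).clot_time
        return (ct if np.isfinite(ct) else 1e12) - ct_ref

    if gap(0.0) >= 0.0:
        return 0.0
    if gap(c_max) < 0.0:
        raise RuntimeError(
            f"no rivaroxaban threshold below c_max={c_max} ug/L for {trigger.name} "
            f"reference {ct_ref:.1f} s"
        )
    return float(brentq(gap, 0.0, c_max, xtol=xtol))


@dataclass
class Corridor:
    """Time-indexed rivaroxaban exposure bounds (ug/L)."""

    times_h: np.ndarray
    safety_high_risk: np.ndarray
    safety_normal: np.ndarray
    efficacy_normal: np.ndarray
    efficacy_high_risk: np.ndarray
    scenario: SwitchScenario | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "safety_high_risk_ugL": self.safety_high_risk,
                "safety_normal_ugL": self.safety_normal,
                "efficacy_normal_ugL": self.efficacy_normal,
                "efficacy_high_risk_ugL": self.efficacy_high_risk,
            }
        )


def monotherapy_bounds(network) -> dict[str, float]:
    """Drug-free corridor bounds: the rivaroxaban monotherapy window."""
    out = {}
    for name, (trigger, inr_ref) in {
        "safety_high_risk": SAFETY_HIGH,
        "safety_normal": SAFETY_NORMAL,
        "efficacy_normal": EFFICACY_NORMAL,
        "efficacy_high_risk": EFFICACY_HIGH,
    }.items():
        ct_ref = reference_clot_time(network, inr_ref, trigger)
        out[name] = rivaroxaban_threshold(network, None, trigger, ct_ref)
    return out


def compute_corridor(scenario: SwitchScenario) -> Corridor:
    """The four corridor bounds on the scenario's time grid.

    Safety bounds solve the strong-trigger threshold against the INR 4.0
    (high bleeding risk) and 5.0 (normal) references; efficacy bounds solve
    the weak-trigger threshold against the INR 1.5 (normal thrombotic
    risk) and 2.0 (high) references.  Bounds widen with time toward the
    monotherapy window.
    """
    network = scenario.network
    refs = {
        "safety_high_risk": (EXTRINSIC_STRONG, reference_clot_time(network, 4.0, EXTRINSIC_STRONG)),
        "safety_normal": (EXTRINSIC_STRONG, reference_clot_time(network, 5.0, EXTRINSIC_STRONG)),
        "efficacy_normal": (EXTRINSIC_WEAK, reference_clot_time(network, 1.5, EXTRINSIC_WEAK)),
        "efficacy_high_risk": (EXTRINSIC_WEAK, reference_clot_time(network, 2.0, EXTRINSIC_WEAK)),
    }
    times = np.asarray(scenario.time_grid_h, dtype=float)
    bounds = {name: np.empty_like(times) for name in refs}
    for i, t in enumerate(times):
        levels, _ = residual_state(scenario, float(t))
        for name, (trigger, ct_ref) in refs.items():
            bounds[name][i] = rivaroxaban_threshold(network, levels, trigger, ct_ref)
    return Corridor(times_h=times, scenario=scenario, **bounds)


def plot_nomogram(corridor: Corridor, schedule=None, ax=None):
    """Render the corridor (and optionally a PK overlay) as a nomogram.

    Safety bounds are drawn in red (solid: high bleeding risk; dashed:
    normal risk), efficacy bounds in blue (solid: high thrombotic risk;
    dashed: normal risk); a dosing schedule adds its concentration curve.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    t = corridor.times_h / 24.0
    ax.plot(t, corridor.safety_high_risk, "r-", label="safety (high bleeding risk)")
    ax.plot(t, corridor.safety_normal, "r--", label="safety (normal risk)")
    ax.plot(t, corridor.efficacy_high_risk, "b-", label="efficacy (high thrombotic risk)")
    ax.plot(t, corridor.efficacy_normal, "b--", label="efficacy (normal risk)")
    if schedule is not None:
        from .pk import concentration

        tt = np.linspace(corridor.times_h[0], corridor.times_h[-1], 800)
        ax.plot(tt / 24.0, concentration(schedule, tt), "k-", lw=1,
                label="rivaroxaban PK")
    ax.set_xlabel("time after warfarin discontinuation (days)")
    ax.set_ylabel("rivaroxaban exposure (µg/L)")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def synergy_slope(
    scenario: SwitchScenario,
    t_hours: float,
    conc_grid: Sequence[float] = (0.0, 50.0, 100.0, 200.0),
) -> float:
    """Least-squares slope of PT (s) vs rivaroxaban concentration (ug/L).

    The slope measures rivaroxaban potency at the residual coagulation
    state; it is largest immediately after discontinuation (synergy with
    residual warfarin) and decays to the warfarin-free slope.
    """
    conc = np.asarray(conc_grid, dtype=float)
    if conc.size < 2 or np.allclose(conc, conc[0]):
        raise ValueError("concentration grid must contain at least two distinct points")
    network = scenario.network
    if np.isinf(t_hours):
        levels = None
    else:
        levels, _ = residual_state(scenario, t_hours)
    pts = np.array(
        [run_assay(PT_TEST, network, vk_levels=levels, rivaroxaban_ugL=c).clot_time for c in conc]
    )
    slope, _ = np.polyfit(conc, pts, 1)
    return float(slope)
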