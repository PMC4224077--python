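"""Small deterministic fixtures for fast tests and demos.

Everything here is generated from the model itself (no stored data): a
vitamin K factor state at half inhibition, a coarse 12-point corridor, and
a synthetic INR decay series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assay import PT_TEST, baseline_pt, get_network, run_assay
from .nomogram import SwitchScenario, compute_corridor, residual_state
from .populations import CAUCASIAN_MEDIAN
from .turnover import PROTEINS, TurnoverParams

__all__ = ["COARSE_GRID_H", "fixture_generator"]

#: Coarse 12-point corridor grid (hours) used by the test suite.
COARSE_GRID_H = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0, 160.0, 168.0)


def fixture_generator(kind: str):
    """Produce a named fixture: factor_state, corridor_small or inr_series."""
    if kind == "factor_state":
        params = TurnoverParams()
        return {p: params.baselines[p] * 0.5 for p in PROTEINS}
    if kind == "corridor_small":
        scenario = SwitchScenario(start_inr=2.5, profile=CAUCASIAN_MEDIAN, time_grid_h=COARSE_GRID_H)
        return compute_corridor(scenario)
    if kind == "inr_series":
        scenario = SwitchScenario(start_inr=2.5, profile=CAUCASIAN_MEDIAN)
        network = get_network(CAUCASIAN_MEDIAN)
        base = baseline_pt(network)
        rows = []
        for t in np.arange(0.0, 241.0, 24.0):
            levels, _ = residual_state(scenario, float(t))
            pt = run_assay(PT_TEST, network, vk_levels=levels).clot_time
            rows.append({"time_h": float(t), "inr": pt / base})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown fixture kind {kind!r}")
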