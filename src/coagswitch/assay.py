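"""In-silico clotting assays: PT test, strong/weak triggers, INR conversion.

Three named trigger scenarios differ only in tissue-factor concentration:
the PT test (4.0e-9 M, reagent-strength trigger), a strong extrinsic
trigger (1e-11 M, the bleeding-risk/safety scenario) and a weak extrinsic
trigger (1e-14 M, the thrombosis-risk/efficacy scenario).  Simulated PT is
converted to INR as (PT / baseline PT) ** ISI with ISI = 1.0 for the
in-silico reagent; the baseline PT is the drug-free clot time of the PT
test, computed once per population profile (the Japanese baseline is
slightly longer because of reduced Factor VII pre-activation).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np

from . import solver
from .calibration import CalibrationConstants, DEFAULT_CALIBRATION
from .network import Network, build_network
from .populations import PopulationProfile
from .turnover import TurnoverParams, WarfarinState, warfarin_prefactor, titrate_to_inr, PROTEINS

__all__ = [
    "AssayScenario",
    "PT_TEST",
    "EXTRINSIC_STRONG",
    "EXTRINSIC_WEAK",
    "SCENARIOS",
    "InrValue",
    "get_network",
    "run_assay",
    "baseline_pt",
    "pt_to_inr",
    "inr_of_state",
    "titrate_profile",
    "reference_clot_time",
]


@dataclass(frozen=True)
class AssayScenario:
    """A clotting trigger: tissue-factor concentration and detection rule.

    `drug_sensitivity` is the scenario's effective sensitivity to
    rivaroxaban relative to the in-silico PT reagent (the rivaroxaban
    analogue of the ISI): PT reagents respond only weakly to Factor Xa
    inhibitors at therapeutic exposure, whereas the near-physiological
    low-tissue-factor scenarios respond strongly.  The factors for the
    strong and weak triggers are calibrated so the drug-free corridor
    bounds reproduce the established rivaroxaban therapeutic window.
    """

    name: str
    tissue_factor: float
    max_duration: float = 7200.0
    drug_sensitivity: float = 1.0
    #: Optional override of the calibrated clot threshold (fraction of
    #: normal fibrinogen); None uses the network's calibrated rule.
    clot_threshold_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.tissue_factor <= 0:
            raise ValueError("tissue factor concentration must be positive")
        if self.max_duration <= 0:
            raise ValueError("max duration must be positive")
        if self.drug_sensitivity <= 0:
            raise ValueError("drug sensitivity must be positive")


PT_TEST = AssayScenario("pt_test", 4.0e-9, max_duration=600.0)
EXTRINSIC_STRONG = AssayScenario(
    "extrinsic_strong",
    1.0e-11,
    max_duration=14_400.0,
    drug_sensitivity=DEFAULT_CALIBRATION.strong_sensitivity,
)
EXTRINSIC_WEAK = AssayScenario(
    "extrinsic_weak",
    1.0e-14,
    max_duration=57_600.0,
    drug_sensitivity=DEFAULT_CALIBRATION.weak_sensitivity,
)

SCENARIOS: dict[str, AssayScenario] = {
    s.name: s for s in (PT_TEST, EXTRINSIC_STRONG, EXTRINSIC_WEAK)
}


@dataclass(frozen=True)
class InrValue:
    """An INR reading: (pt / baseline_pt) ** isi."""

    inr: float
    isi: float
    baseline_pt: float


@lru_cache(maxsize=None)
def get_network(profile: PopulationProfile, calibration: CalibrationConstants | None = None) -> Network:
    """Cached cascade network for a profile (compiled lazily on first use)."""
    return build_network(profile, calibration)


def run_assay(
    scenario: AssayScenario,
    network: Network,
    vk_levels: Mapping[str, float] | None = None,
    rivaroxaban_ugL: float = 0.0,
) -> solver.ClotTimeResult:
    """Run one trigger scenario and return the clot time."""
    return solver.clot_time(
        network,
        vk_levels=vk_levels,
        rivaroxaban_ugL=rivaroxaban_ugL,
        trigger=scenario,
    )


@lru_cache(maxsize=None)
def _baseline_pt_cached(profile: PopulationProfile, calibration) -> float:
    network = get_network(profile, calibration)
    result = run_assay(PT_TEST, network)
    if not result.converged:  # pragma: no cover - baseline always clots
        raise RuntimeError("drug-free PT assay did not clot within the horizon")
    return result.clot_time


def baseline_pt(network: Network) -> float:
    """Drug-free PT (s) of a profile's cascade, cached per profile."""
    return _baseline_pt_cached(network.profile, network.calibration)


def pt_to_inr(pt: float, baseline: float, isi: float = 1.0) -> InrValue:
    """Convert a PT reading to an INR value: (pt/baseline)**isi."""
    if pt <= 0 or baseline <= 0:
        raise ValueError("PT and baseline PT must be positive")
    return InrValue(inr=(pt / baseline) ** isi, isi=isi, baseline_pt=baseline)


def steady_state_levels(warfarin: WarfarinState, params: TurnoverParams | None = None) -> dict[str, float]:
    """Vitamin K-dependent factor levels at warfarin steady state, k_i * W."""
    params = params or TurnoverParams()
    w = warfarin_prefactor(warfarin)
    return {p: params.baselines[p] * w for p in PROTEINS}


def inr_of_state(network: Network, warfarin: WarfarinState, isi: float = 1.0) -> float:
    """Steady-state INR of the PT assay under a given warfarin exposure.

    If the PT assay does not clot within its horizon (extreme warfarin
    levels probed during titration bracketing), the horizon-based INR is
    returned as a finite, monotone surrogate.
    """
    levels = steady_state_levels(warfarin)
    result = run_assay(PT_TEST, network, vk_levels=levels)
    pt = result.clot_time if result.converged else result.horizon
    return pt_to_inr(pt, baseline_pt(network), isi).inr


@lru_cache(maxsize=None)
def _titrate_cached(profile: PopulationProfile, calibration, target_inr: float) -> WarfarinState:
    network = get_network(profile, calibration)
    return titrate_to_inr(
        target_inr,
        lambda st: inr_of_state(network, st),
        r_halflife=profile.r_halflife,
        s_halflife=profile.s_halflife,
    )


def titrate_profile(network: Network, target_inr: float) -> WarfarinState:
    """Racemic warfarin state reproducing `target_inr` at steady state."""
    return _titrate_cached(network.profile, network.calibration, float(target_inr))


@lru_cache(maxsize=None)
def _reference_ct_cached(profile: PopulationProfile, calibration, inr_ref: float, scenario_name: str) -> float:
    network = get_network(profile, calibration)
    scenario = SCENARIOS[scenario_name]
    if inr_ref == 1.0:
        levels = None
    else:
        levels = steady_state_levels(titrate_profile(network, inr_ref))
    result = run_assay(scenario, network, vk_levels=levels)
    if not result.converged:
        raise RuntimeError(
            f"reference scenario {scenario_name} at INR {inr_ref} did not clot "
            f"within {result.horizon} s"
        )
    return result.clot_time


def reference_clot_time(network: Network, inr_ref: float, scenario: AssayScenario) -> float:
    """Clot time of warfarin monotherapy at a reference INR under a trigger.

    Titrates warfarin to `inr_ref`, sets the factors to the corresponding
    steady state and reports the drug-free-rivaroxaban clot time; strictly
    increasing in `inr_ref`.
    """
    if not 1.0 <= inr_ref <= 6.0:
        raise ValueError("reference INR must lie in [1, 6]")
    return _reference_ct_cached(network.profile, network.calibration, float(inr_ref), scenario.name)
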