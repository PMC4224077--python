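"""Population parameterisations and the factor-abnormality sensitivity panel.

Two virtual populations are supported.  Caucasian patients use S-/R-warfarin
half-lives of 29/45 h (median), with fast (18/20 h) and slow (52/70 h)
variants spanning the observed pharmacokinetic variability, and 1.0 %
Factor VII pre-activation.  Japanese patients have a lower CYP2C9-mediated
S-warfarin clearance variability; their S-warfarin half-lives are the
Caucasian values scaled by the relative clearance 469.4/654.3 (so the
median 104,400 s becomes 74,897 s), R-warfarin and coagulation-factor
half-lives are unchanged, and Factor VII pre-activation is reduced to
0.5 %, which makes the drug-free Japanese PT slightly longer.

The abnormality panel varies the non-vitamin-K factors (fibrinogen/Factor
I, V, VIII, XI) one at a time over a wide over-/under-expression range;
these factors are independent of warfarin and probe the robustness of the
switching corridors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "PopulationProfile",
    "make_profile",
    "abnormality_panel",
    "JAPANESE_S_CLEARANCE_RATIO",
    "CAUCASIAN_MEDIAN",
    "JAPANESE_MEDIAN",
]

_H = 3600.0

#: Relative Japanese vs Caucasian S-warfarin clearance.
JAPANESE_S_CLEARANCE_RATIO = 469.4 / 654.3

#: S-/R-warfarin half-lives (s) for the Caucasian speed variants.
_S_HALFLIVES = {"fast": 18.0 * _H, "median": 29.0 * _H, "slow": 52.0 * _H}
_R_HALFLIVES = {"fast": 20.0 * _H, "median": 45.0 * _H, "slow": 70.0 * _H}

_PREACTIVATION = {"caucasian": 0.01, "japanese": 0.005}

NON_VK_FACTORS = ("factor_I", "factor_V", "factor_VIII", "factor_XI")


@dataclass(frozen=True)
class PopulationProfile:
    """Warfarin kinetics and cascade adjustments for one virtual patient."""

    name: str
    s_halflife: float
    r_halflife: float
    fvii_preactivation: float
    factor_multipliers: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.s_halflife <= 0 or self.r_halflife <= 0:
            raise ValueError("warfarin half-lives must be positive")
        if not 0 < self.fvii_preactivation < 1:
            raise ValueError("Factor VII pre-activation must be a fraction in (0, 1)")
        for factor, mult in self.factor_multipliers:
            if factor not in NON_VK_FACTORS:
                raise ValueError(f"unknown factor multiplier {factor!r}")
            if mult <= 0:
                raise ValueError(f"factor multiplier for {factor} must be positive")

    def factor_multiplier(self, factor: str) -> float:
        return dict(self.factor_multipliers).get(factor, 1.0)

    def with_multiplier(self, factor: str, mult: float, name: str | None = None) -> "PopulationProfile":
        mults = dict(self.factor_multipliers)
        mults[factor] = mult
        return replace(
            self,
            name=name or f"{self.name}_{factor}_{mult:g}x",
            factor_multipliers=tuple(sorted(mults.items())),
        )


def make_profile(population: str = "caucasian", speed: str = "median") -> PopulationProfile:
    """Build a profile for a population and warfarin elimination speed.

    The Japanese clearance scaling is applied to all three S-half-life
    variants; R-warfarin half-lives are shared between populations.
    """
    population = population.lower()
    speed = speed.lower()
    if population not in _PREACTIVATION:
        raise ValueError(f"unknown population {population!r} (expected caucasian or japanese)")
    if speed not in _S_HALFLIVES:
        raise ValueError(f"unknown warfarin speed {speed!r} (expected fast, median or slow)")
    s_half = _S_HALFLIVES[speed]
    if population == "japanese":
        s_half *= JAPANESE_S_CLEARANCE_RATIO
    return PopulationProfile(
        name=f"{population}_{speed}",
        s_halflife=s_half,
        r_halflife=_R_HALFLIVES[speed],
        fvii_preactivation=_PREACTIVATION[population],
    )


CAUCASIAN_MEDIAN = make_profile("caucasian", "median")
JAPANESE_MEDIAN = make_profile("japanese", "median")

#: One-at-a-time multipliers of the abnormality panel.
PANEL_MULTIPLIERS = {
    "factor_I": (0.15, 0.5, 0.75, 2.0, 5.0),
    "factor_V": (0.01, 0.1, 0.5, 0.75, 2.0, 5.0),
    "factor_VIII": (0.01, 0.1, 0.5, 0.75, 2.0, 5.0),
    "factor_XI": (0.01, 0.1, 0.5, 0.75, 2.0, 5.0),
}


def abnormality_panel(base: PopulationProfile | None = None) -> list[PopulationProfile]:
    """The normal patient plus 23 single-factor over/under-expression variants."""
    base = base or CAUCASIAN_MEDIAN
    panel = [replace(base, name=f"{base.name}_normal")]
    for factor, mults in PANEL_MULTIPLIERS.items():
        for mult in mults:
            panel.append(base.with_multiplier(factor, mult))
    return panel
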