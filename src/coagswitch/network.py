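"""Mass-action reaction network of the coagulation cascade.

The network covers the extrinsic pathway (TF:VIIa extrinsic tenase, TFPI
regulation), the common pathway (prothrombinase assembly, meizothrombin,
thrombin, fibrinogen conversion), thrombin feedback on Factors V, VIII and
XI, the intrinsic tenase (VIIIa:IXa), antithrombin neutralisation, a
protein C / protein S anticoagulant branch, and reversible competitive
binding of rivaroxaban to free Factor Xa and to prothrombinase-bound Xa.

The extrinsic/common core follows the stoichiometric mass-action family of
published tissue-factor-pathway models (Hockin-Mann class), extended here
with fibrin generation and the anticoagulant branch.  A small number of
scalars (clot-detection threshold, rivaroxaban inhibition constant, thrombin
feedback scaling) are calibration constants fixed against in-silico PT assay
anchors; see `coagswitch.calibration`.

Concentrations are molar and time is seconds throughout.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibration import CalibrationConstants, DEFAULT_CALIBRATION

__all__ = [
    "Role",
    "Species",
    "Reaction",
    "SpeciesIndex",
    "Network",
    "build_network",
    "RIVAROXABAN_MW",
    "rivaroxaban_molar",
    "REFERENCE_FIBRINOGEN",
]

#: Literature molecular weight of rivaroxaban, g/mol.
RIVAROXABAN_MW = 435.88

#: Normal plasma fibrinogen (Factor I), molar; the clot-detection threshold
#: is a fixed fraction of this reference value.
REFERENCE_FIBRINOGEN = 9.0e-6


def rivaroxaban_molar(concentration_ugL: float) -> float:
    """Convert a plasma rivaroxaban concentration in ug/L to molar."""
    if concentration_ugL < 0:
        raise ValueError("rivaroxaban concentration must be non-negative")
    return concentration_ugL * 1e-6 / RIVAROXABAN_MW


class Role(str, enum.Enum):
    ZYMOGEN = "zymogen"
    ENZYME = "enzyme"
    COFACTOR = "cofactor"
    COMPLEX = "complex"
    INHIBITOR = "inhibitor"
    SUBSTRATE = "substrate"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class Species:
    """One chemical species: name, mechanistic role, initial concentration (M).

    Boundary species are held constant during integration (buffered), e.g.
    the phospholipid binding sites and the clamped rivaroxaban pool.
    """

    name: str
    role: Role
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ValueError(f"negative initial concentration for {self.name}")

    @property
    def boundary(self) -> bool:
        return self.role is Role.BOUNDARY


@dataclass(frozen=True)
class Reaction:
    """A single reaction with mass-action or Michaelis-Menten kinetics.

    `constants` holds {"k": ...} (M^-n s^-1) for mass action or
    {"kcat": ..., "km": ...} for Michaelis-Menten (first reactant is the
    enzyme, second the substrate).
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: str = "mass_action"
    constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, st in (*self.reactants, *self.products):
            if st <= 0 or int(st) != st:
                raise ValueError(f"{self.name}: stoichiometry must be a positive integer")
        if self.rate_law not in ("mass_action", "michaelis_menten"):
            raise ValueError(f"{self.name}: unknown rate law {self.rate_law!r}")
        for value in self.constants.values():
            if value < 0:
                raise ValueError(f"{self.name}: rate constants must be non-negative")
        object.__setattr__(self, "constants", dict(self.constants))


class SpeciesIndex:
    """Ordered, name-unique collection of species with position lookup."""

    def __init__(self, species: Iterable[Species]):
        self.species: tuple[Species, ...] = tuple(species)
        self._pos: dict[str, int] = {}
        for i, sp in enumerate(self.species):
            if sp.name in self._pos:
                raise ValueError(f"duplicate species name {sp.name!r}")
            self._pos[sp.name] = i

    def __len__(self) -> int:
        return len(self.species)

    def __contains__(self, name: str) -> bool:
        return name in self._pos

    def __iter__(self):
        return iter(self.species)

    def index(self, name: str) -> int:
        return self._pos[name]

    def names(self) -> list[str]:
        return [sp.name for sp in self.species]

    @property
    def boundary_names(self) -> list[str]:
        return [sp.name for sp in self.species if sp.boundary]


def _r(name, reactants, products, k):
    return Reaction(name, tuple(reactants), tuple(products), "mass_action", {"k": k})


def _species_table(profile) -> list[Species]:
    """Baseline plasma composition (drug-free, unit factor multipliers)."""
    pre = profile.fvii_preactivation
    Z, E, C, X, I, S, B = (
        Role.ZYMOGEN,
        Role.ENZYME,
        Role.COFACTOR,
        Role.COMPLEX,
        Role.INHIBITOR,
        Role.SUBSTRATE,
        Role.BOUNDARY,
    )
    return [
        Species("TF", C, 0.0),
        Species("VII", Z, 1.0e-8 * (1.0 - pre)),
        Species("VIIa", E, 1.0e-8 * pre),
        Species("TF:VII", C, 0.0),
        Species("TF:VIIa", E, 0.0),
        Species("X", Z, 1.6e-7),
        Species("Xa", E, 0.0),
        Species("IX", Z, 9.0e-8),
        Species("IXa", E, 0.0),
        Species("II", Z, 1.4e-6),
        Species("mIIa", E, 0.0),
        Species("IIa", E, 0.0),
        Species("VIII", C, 7.0e-10),
        Species("VIIIa", C, 0.0),
        Species("VIIIa1L", C, 0.0),
        Species("VIIIa2", C, 0.0),
        Species("V", C, 2.0e-8),
        Species("Va", C, 0.0),
        Species("XI", Z, 3.1e-8),
        Species("XIa", E, 0.0),
        Species("Xa:II", C, 0.0),
        Species("TF:VIIa:X", C, 0.0),
        Species("TF:VIIa:Xa", C, 0.0),
        Species("IXa:VIIIa", C, 0.0),
        Species("IXa:VIIIa:X", C, 0.0),
        Species("Xa:Va", C, 0.0),
        Species("Xa:Va:II", C, 0.0),
        Species("TFPI", I, 2.5e-9),
        Species("Xa:TFPI", C, 0.0),
        Species("TF:VIIa:Xa:TFPI", C, 0.0),
        Species("AT", I, 3.4e-6),
        Species("Xa:AT", C, 0.0),
        Species("mIIa:AT", C, 0.0),
        Species("IXa:AT", C, 0.0),
        Species("IIa:AT", C, 0.0),
        Species("TF:VIIa:AT", C, 0.0),
        Species("Fg", S, REFERENCE_FIBRINOGEN),
        Species("Fn", S, 0.0),
        Species("PC", Z, 6.0e-8),
        Species("APC", E, 0.0),
        Species("PS", C, 1.4e-7),
        Species("APC:PS", C, 0.0),
        Species("Va_i", C, 0.0),
        Species("VIIIa_i", C, 0.0),
        # Protein C/S binding sites on phospholipids; in excess, buffered.
        Species("PL", B, 3.6e-6),
        # Rivaroxaban plasma pool, clamped for the duration of an assay
        # (assay timescale of seconds-minutes << PK timescale of hours).
        Species("Riv", B, 0.0),
        Species("Riv:Xa", C, 0.0),
        Species("Riv:Xa:Va", C, 0.0),
    ]


def _reaction_table(calib: CalibrationConstants) -> list[Reaction]:
    """Reaction inventory with literature-class rate constants.

    `calib.rate_scale` multiplies every rate constant (applied at the end);
    because it scales all fluxes uniformly it compresses time exactly and
    is the calibration scalar that maps the drug-free PT onto its anchor.
    `calib.riv_kon`/`riv_ki` parameterise reversible rivaroxaban binding.
    """
    fb = 1.0
    kon = calib.riv_kon
    koff = calib.riv_kon * calib.riv_ki
    rx = [
        # --- extrinsic tenase assembly and Factor VII activation ---
        _r("TF+VII_on", [("TF", 1), ("VII", 1)], [("TF:VII", 1)], 3.2e6),
        _r("TF+VII_off", [("TF:VII", 1)], [("TF", 1), ("VII", 1)], 3.1e-3),
        _r("TF+VIIa_on", [("TF", 1), ("VIIa", 1)], [("TF:VIIa", 1)], 2.3e7),
        _r("TF+VIIa_off", [("TF:VIIa", 1)], [("TF", 1), ("VIIa", 1)], 3.1e-3),
        _r("TFVIIa_act_VII", [("TF:VIIa", 1), ("VII", 1)], [("TF:VIIa", 1), ("VIIa", 1)], 4.4e5),
        _r("Xa_act_VII", [("Xa", 1), ("VII", 1)], [("Xa", 1), ("VIIa", 1)], 1.3e7),
        _r("IIa_act_VII", [("IIa", 1), ("VII", 1)], [("IIa", 1), ("VIIa", 1)], 2.3e4),
        # --- Factor X activation by extrinsic tenase ---
        _r("TFVIIa+X_on", [("TF:VIIa", 1), ("X", 1)], [("TF:VIIa:X", 1)], 2.5e7),
        _r("TFVIIa+X_off", [("TF:VIIa:X", 1)], [("TF:VIIa", 1), ("X", 1)], 1.05),
        _r("TFVIIa_X_cat", [("TF:VIIa:X", 1)], [("TF:VIIa:Xa", 1)], 6.0),
        _r("TFVIIa+Xa_on", [("TF:VIIa", 1), ("Xa", 1)], [("TF:VIIa:Xa", 1)], 2.2e7),
        _r("TFVIIa+Xa_off", [("TF:VIIa:Xa", 1)], [("TF:VIIa", 1), ("Xa", 1)], 19.0),
        # --- Factor IX activation by extrinsic tenase (via transient complex) ---
        _r("TFVIIa_act_IX", [("TF:VIIa", 1), ("IX", 1)], [("TF:VIIa", 1), ("IXa", 1)], 1.0e7 * 1.8 / (2.4 + 1.8)),
        # --- prothrombin activation by free (phospholipid-bound) Xa via an
        # explicit Michaelis complex: prothrombin occupancy of the Xa active
        # site shields Xa from rivaroxaban, so inhibition is genuinely
        # competitive with substrate (Km 0.3 uM, kcat/Km 7.5e3 /(M s)) ---
        _r("Xa+II_on", [("Xa", 1), ("II", 1)], [("Xa:II", 1)], 1.0e7),
        _r("Xa+II_off", [("Xa:II", 1)], [("Xa", 1), ("II", 1)], 2.99775),
        _r("XaII_cat", [("Xa:II", 1)], [("Xa", 1), ("IIa", 1)], 2.25e-3),
        # --- thrombin feedback on cofactors and Factor XI ---
        _r("IIa_act_VIII", [("IIa", 1), ("VIII", 1)], [("IIa", 1), ("VIIIa", 1)], 2.0e7 * fb),
        _r("IIa_act_V", [("IIa", 1), ("V", 1)], [("IIa", 1), ("Va", 1)], 2.0e7 * fb),
        _r("IIa_act_XI", [("IIa", 1), ("XI", 1)], [("IIa", 1), ("XIa", 1)], 1.0e5 * fb),
        _r("XIa_act_IX", [("XIa", 1), ("IX", 1)], [("XIa", 1), ("IXa", 1)], 1.0e7),
        # --- intrinsic tenase ---
        _r("VIIIa+IXa_on", [("VIIIa", 1), ("IXa", 1)], [("IXa:VIIIa", 1)], 1.0e7),
        _r("VIIIa+IXa_off", [("IXa:VIIIa", 1)], [("VIIIa", 1), ("IXa", 1)], 5.0e-3),
        _r("tenase+X_on", [("IXa:VIIIa", 1), ("X", 1)], [("IXa:VIIIa:X", 1)], 1.0e8),
        _r("tenase+X_off", [("IXa:VIIIa:X", 1)], [("IXa:VIIIa", 1), ("X", 1)], 1.0e-3),
        _r("tenase_X_cat", [("IXa:VIIIa:X", 1)], [("IXa:VIIIa", 1), ("Xa", 1)], 8.2),
        # --- spontaneous VIIIa dissociation (A2 subunit loss) ---
        _r("VIIIa_diss", [("VIIIa", 1)], [("VIIIa1L", 1), ("VIIIa2", 1)], 6.0e-3),
        _r("VIIIa_reass", [("VIIIa1L", 1), ("VIIIa2", 1)], [("VIIIa", 1)], 2.2e4),
        _r("tenaseX_decay", [("IXa:VIIIa:X", 1)], [("VIIIa1L", 1), ("VIIIa2", 1), ("X", 1), ("IXa", 1)], 1.0e-3),
        _r("tenase_decay", [("IXa:VIIIa", 1)], [("VIIIa1L", 1), ("VIIIa2", 1), ("IXa", 1)], 1.0e-3),
        # --- prothrombinase ---
        _r("Xa+Va_on", [("Xa", 1), ("Va", 1)], [("Xa:Va", 1)], 4.0e8),
        _r("Xa+Va_off", [("Xa:Va", 1)], [("Xa", 1), ("Va", 1)], 0.2),
        _r("protase+II_on", [("Xa:Va", 1), ("II", 1)], [("Xa:Va:II", 1)], 1.0e8),
        _r("protase+II_off", [("Xa:Va:II", 1)], [("Xa:Va", 1), ("II", 1)], 103.0),
        _r("protase_II_cat", [("Xa:Va:II", 1)], [("Xa:Va", 1), ("mIIa", 1)], 63.5),
        _r("protase_act_mIIa", [("mIIa", 1), ("Xa:Va", 1)], [("IIa", 1), ("Xa:Va", 1)], 1.5e7),
        # --- TFPI regulation (effective association rates an order of
        # magnitude above the plasma free-TFPI values, standing in for the
        # surface-localised TFPI pool) ---
        _r("Xa+TFPI_on", [("Xa", 1), ("TFPI", 1)], [("Xa:TFPI", 1)], 1.0e7),
        _r("Xa+TFPI_off", [("Xa:TFPI", 1)], [("Xa", 1), ("TFPI", 1)], 3.6e-4),
        _r("TFVIIaXa+TFPI_on", [("TF:VIIa:Xa", 1), ("TFPI", 1)], [("TF:VIIa:Xa:TFPI", 1)], 3.5e9),
        _r("TFVIIaXa+TFPI_off", [("TF:VIIa:Xa:TFPI", 1)], [("TF:VIIa:Xa", 1), ("TFPI", 1)], 1.1e-4),
        _r("TFVIIa+XaTFPI", [("TF:VIIa", 1), ("Xa:TFPI", 1)], [("TF:VIIa:Xa:TFPI", 1)], 5.5e8),
        # --- antithrombin ---
        _r("Xa+AT", [("Xa", 1), ("AT", 1)], [("Xa:AT", 1)], 1.5e3),
        _r("mIIa+AT", [("mIIa", 1), ("AT", 1)], [("mIIa:AT", 1)], 7.1e3),
        _r("IXa+AT", [("IXa", 1), ("AT", 1)], [("IXa:AT", 1)], 4.9e2),
        _r("IIa+AT", [("IIa", 1), ("AT", 1)], [("IIa:AT", 1)], 7.1e3),
        _r("TFVIIa+AT", [("TF:VIIa", 1), ("AT", 1)], [("TF:VIIa:AT", 1)], 2.3e2),
        # --- fibrinogen conversion (clot substrate) ---
        Reaction(
            "IIa_fibrinogen",
            (("IIa", 1), ("Fg", 1)),
            (("IIa", 1), ("Fn", 1)),
            "michaelis_menten",
            {"kcat": 84.0, "km": 7.2e-6},
        ),
        # --- protein C / protein S branch ---
        # Thrombin activation of protein C (thrombomodulin folded into k).
        _r("IIa_act_PC", [("IIa", 1), ("PC", 1)], [("IIa", 1), ("APC", 1)], 1.0e4),
        # APC/protein S assembly on phospholipid binding sites (sites in
        # excess at 3.6e-6 M; folded into the association constant).
        _r("APC+PS_on", [("APC", 1), ("PS", 1)], [("APC:PS", 1)], 1.0e7),
        _r("APC+PS_off", [("APC:PS", 1)], [("APC", 1), ("PS", 1)], 0.5),
        _r("APCPS_inact_Va", [("APC:PS", 1), ("Va", 1)], [("APC:PS", 1), ("Va_i", 1)], 1.0e8),
        _r("APCPS_inact_VIIIa", [("APC:PS", 1), ("VIIIa", 1)], [("APC:PS", 1), ("VIIIa_i", 1)], 1.0e8),
        # --- rivaroxaban: reversible competitive Xa binding ---
        _r("Riv+Xa_on", [("Riv", 1), ("Xa", 1)], [("Riv:Xa", 1)], kon),
        _r("Riv+Xa_off", [("Riv:Xa", 1)], [("Riv", 1), ("Xa", 1)], koff),
        _r("Riv+XaVa_on", [("Riv", 1), ("Xa:Va", 1)], [("Riv:Xa:Va", 1)], kon),
        _r("Riv+XaVa_off", [("Riv:Xa:Va", 1)], [("Riv", 1), ("Xa:Va", 1)], koff),
    ]
    if calib.rate_scale != 1.0:
        scaled = []
        for rxn in rx:
            constants = {
                key: (value * calib.rate_scale if key in ("k", "kcat") else value)
                for key, value in rxn.constants.items()
            }
            scaled.append(Reaction(rxn.name, rxn.reactants, rxn.products, rxn.rate_law, constants))
        rx = scaled
    return rx


#: Cascade species fed by the vitamin K-dependent turnover model.
VITAMIN_K_SPECIES = {
    "fII": "II",
    "fIX": "IX",
    "fX": "X",
    "protein_C": "PC",
    "protein_S": "PS",
    # fVII is split between VII and VIIa according to pre-activation.
}

#: Species scaled by the non-vitamin-K factor multipliers of a profile.
MULTIPLIER_SPECIES = {"factor_I": "Fg", "factor_V": "V", "factor_VIII": "VIII", "factor_XI": "XI"}


class Network:
    """A closed, well-mixed coagulation reaction network for one profile.

    Blood-flow exchange terms are absent (all flow parameters zero): the
    network models a static plasma assay, so every conserved moiety stays
    constant apart from boundary species, which are buffered.
    """

    def __init__(self, profile, calibration: CalibrationConstants | None = None):
        self.profile = profile
        self.calibration = calibration or DEFAULT_CALIBRATION
        self.index = SpeciesIndex(_species_table(profile))
        self.reactions: tuple[Reaction, ...] = tuple(_reaction_table(self.calibration))
        for rxn in self.reactions:
            for sp, _ in (*rxn.reactants, *rxn.products):
                if sp not in self.index:
                    raise ValueError(f"reaction {rxn.name} references unknown species {sp!r}")
        self._compiled = None

    # -- state construction -------------------------------------------------
    def baseline_state(self) -> np.ndarray:
        """Drug-free baseline concentrations with the profile's multipliers."""
        y0 = np.array([sp.initial_concentration for sp in self.index])
        for factor, species in MULTIPLIER_SPECIES.items():
            y0[self.index.index(species)] *= self.profile.factor_multiplier(factor)
        return y0

    def initial_state(
        self,
        vk_levels: Mapping[str, float] | None = None,
        tissue_factor: float = 0.0,
        rivaroxaban_ugL: float = 0.0,
    ) -> np.ndarray:
        """Assay starting state.

        `vk_levels` gives absolute molar concentrations of the six vitamin
        K-dependent proteins (turnover-model output); Factor VII is split
        between zymogen and pre-activated VIIa by the profile's
        pre-activation fraction.  Tissue factor sets the trigger and the
        rivaroxaban pool is clamped at the given plasma concentration.
        """
        y0 = self.baseline_state()
        ix = self.index.index
        if vk_levels is not None:
            y0[ix("II")] = vk_levels["fII"]
            y0[ix("IX")] = vk_levels["fIX"]
            y0[ix("X")] = vk_levels["fX"]
            y0[ix("PC")] = vk_levels["protein_C"]
            y0[ix("PS")] = vk_levels["protein_S"]
            pre = self.profile.fvii_preactivation
            y0[ix("VII")] = vk_levels["fVII"] * (1.0 - pre)
            y0[ix("VIIa")] = vk_levels["fVII"] * pre
        if tissue_factor < 0:
            raise ValueError("tissue factor concentration must be non-negative")
        y0[ix("TF")] = tissue_factor
        y0[ix("Riv")] = rivaroxaban_molar(rivaroxaban_ugL)
        return y0

    @property
    def clot_threshold(self) -> float:
        """Absolute fibrin concentration (M) that defines clot detection."""
        return self.calibration.clot_threshold_fraction * REFERENCE_FIBRINOGEN

    def compiled(self):
        if self._compiled is None:
            from .solver import CompiledNetwork

            self._compiled = CompiledNetwork(self)
        return self._compiled

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "profile": self.profile.name,
            "species": [
                {
                    "name": sp.name,
                    "role": sp.role.value,
                    "initial_concentration": sp.initial_concentration,
                    "boundary": sp.boundary,
                }
                for sp in self.index
            ],
            "reactions": [
                {
                    "name": r.name,
                    "reactants": [list(t) for t in r.reactants],
                    "products": [list(t) for t in r.products],
                    "rate_law": r.rate_law,
                    "constants": dict(r.constants),
                }
                for r in self.reactions
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_sbml(self, path) -> None:
        """Write the network as a minimal SBML Level 3 document."""
        from .sbml import write_sbml

        write_sbml(self, path)


def build_network(profile, calibration: CalibrationConstants | None = None) -> Network:
    """Assemble the cascade network for a population profile.

    Raises a ValueError naming the profile if it is not a valid
    PopulationProfile-like object.
    """
    for attr in ("name", "fvii_preactivation", "factor_multiplier"):
        if not hasattr(profile, attr):
            raise ValueError(f"unknown or invalid population profile: {profile!r}")
    return Network(profile, calibration)
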