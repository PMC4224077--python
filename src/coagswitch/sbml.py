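"""Minimal SBML Level 3 export of the cascade reaction network."""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def _sid(name: str) -> str:
    return "s_" + re.sub(r"[^A-Za-z0-9_]", "_", name)


def write_sbml(network, path) -> None:
    """Write species (with initial concentrations, boundary flags) and
    reactions (reactants, products, kinetic constants as local parameters)."""
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": "coagulation_cascade"})
    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {"id": "plasma", "size": "1", "constant": "true", "spatialDimensions": "3"},
    )
    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in network.index:
        ET.SubElement(
            species_el,
            f"{{{SBML_NS}}}species",
            {
                "id": _sid(sp.name),
                "name": sp.name,
                "compartment": "plasma",
                "initialConcentration": repr(sp.initial_concentration),
                "boundaryCondition": "true" if sp.boundary else "false",
                "constant": "false",
                "hasOnlySubstanceUnits": "false",
            },
        )
    rxns_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rxn in network.reactions:
        r_el = ET.SubElement(
            rxns_el,
            f"{{{SBML_NS}}}reaction",
            {"id": _sid(rxn.name), "name": rxn.name, "reversible": "false"},
        )
        lor = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfReactants")
        for sp, st in rxn.reactants:
            ET.SubElement(
                lor,
                f"{{{SBML_NS}}}speciesReference",
                {"species": _sid(sp), "stoichiometry": str(st), "constant": "true"},
            )
        lop = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfProducts")
        for sp, st in rxn.products:
            ET.SubElement(
                lop,
                f"{{{SBML_NS}}}speciesReference",
                {"species": _sid(sp), "stoichiometry": str(st), "constant": "true"},
            )
        kl = ET.SubElement(r_el, f"{{{SBML_NS}}}kineticLaw")
        params = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        for key, value in rxn.constants.items():
            ET.SubElement(
                params, f"{{{SBML_NS}}}localParameter", {"id": key, "value": repr(value)}
            )
    ET.ElementTree(sbml).write(path, xml_declaration=True, encoding="unicode")
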