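"""SBML Level 3 Version 2 export/import of reaction networks.

The exporter writes one SBML species per chemical species (bookkeeping
counters included, flagged via SBO term), one reaction per mass-action
Reaction with an explicit kinetic law ``k * A [* B]``, and the
compartment volume in litres.  The importer reads a document written by
this exporter back into stoichiometry form, which is what the round-trip
contract requires; it is not a general-purpose SBML reader.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import ReactionNetwork

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

#: SBO accounting terms: 247 = simple chemical, 649 = composite entity
_SBO_SPECIES = "SBO:0000247"
_SBO_COUNTER = "SBO:0000649"


def _sid(name: str) -> str:
    """SBML ids must match [A-Za-z_][A-Za-z0-9_]*."""
    return "s_" + name.replace("-", "_")


def export_sbml(network: ReactionNetwork, path: str | Path) -> None:
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(
        root, f"{{{SBML_NS}}}model",
        {"id": f"chaperone_k{network.k}", "substanceUnits": "item",
         "timeUnits": "second", "extentUnits": "item"},
    )
    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps, f"{{{SBML_NS}}}compartment",
        {"id": "lumen", "spatialDimensions": "3", "constant": "true",
         "size": repr(network.spec.params.volume_l)},
    )
    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in network.species:
        ET.SubElement(
            species_el, f"{{{SBML_NS}}}species",
            {"id": _sid(sp.name), "compartment": "lumen",
             "initialAmount": "0", "hasOnlySubstanceUnits": "true",
             "boundaryCondition": "false", "constant": "false",
             "sboTerm": _SBO_COUNTER if sp.is_counter else _SBO_SPECIES},
        )
    params_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    rxns_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for j, rxn in enumerate(network.reactions):
        rid = f"r{j:03d}"
        kid = f"k_{rid}"
        ET.SubElement(
            params_el, f"{{{SBML_NS}}}parameter",
            {"id": kid, "value": repr(rxn.rate_constant), "constant": "true"},
        )
        rxn_el = ET.SubElement(
            rxns_el, f"{{{SBML_NS}}}reaction",
            {"id": rid, "reversible": "false", "name": rxn.tag.value},
        )
        reactants_el = ET.SubElement(rxn_el, f"{{{SBML_NS}}}listOfReactants")
        for sp, n in rxn.reactants:
            ET.SubElement(
                reactants_el, f"{{{SBML_NS}}}speciesReference",
                {"species": _sid(sp.name), "stoichiometry": str(n),
                 "constant": "true"},
            )
        products_el = ET.SubElement(rxn_el, f"{{{SBML_NS}}}listOfProducts")
        for sp, n in rxn.products:
            ET.SubElement(
                products_el, f"{{{SBML_NS}}}speciesReference",
                {"species": _sid(sp.name), "stoichiometry": str(n),
                 "constant": "true"},
            )
        law = ET.SubElement(rxn_el, f"{{{SBML_NS}}}kineticLaw")
        math = ET.SubElement(law, f"{{{MATHML_NS}}}math")
        apply_el = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(apply_el, f"{{{MATHML_NS}}}times")
        ci = ET.SubElement(apply_el, f"{{{MATHML_NS}}}ci")
        ci.text = kid
        for sp, n in rxn.reactants:
            for _ in range(n):
                ci = ET.SubElement(apply_el, f"{{{MATHML_NS}}}ci")
                ci.text = _sid(sp.name)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


@dataclass(frozen=True)
class SbmlModel:
    """Bare importer result: species ids, reaction stoichiometries, rates."""

    species_ids: tuple[str, ...]
    reactions: tuple[dict, ...]
    volume_l: float

    def stoichiometry_matrix(self) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.species_ids)}
        mat = np.zeros((len(self.species_ids), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sid, n in rxn["reactants"]:
                mat[index[sid], j] -= n
            for sid, n in rxn["products"]:
                mat[index[sid], j] += n
        return mat


def import_sbml(path: str | Path) -> SbmlModel:
    tree = ET.parse(path)
    model = tree.getroot().find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValueError(f"{path}: no <model> element")
    comp = model.find(f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment")
    volume = float(comp.get("size")) if comp is not None else float("nan")
    species = tuple(
        el.get("id")
        for el in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
    )
    params = {
        el.get("id"): float(el.get("value"))
        for el in model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")
    }
    reactions = []
    for el in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        def refs(tag: str):
            return tuple(
                (ref.get("species"), float(ref.get("stoichiometry", "1")))
                for ref in el.findall(f"{{{SBML_NS}}}{tag}/{{{SBML_NS}}}speciesReference")
            )

        reactions.append(
            {
                "id": el.get("id"),
                "tag": el.get("name"),
                "reactants": refs("listOfReactants"),
                "products": refs("listOfProducts"),
                "rate_constant": params.get("k_" + el.get("id")),
            }
        )
    return SbmlModel(
        species_ids=species, reactions=tuple(reactions), volume_l=volume
    )


def network_stoichiometry(network: ReactionNetwork) -> np.ndarray:
    """Net stoichiometry matrix in the network's own species order."""
    index = {s: i for i, s in enumerate(network.species)}
    mat = np.zeros((len(network.species), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for sp, n in rxn.reactants:
            mat[index[sp], j] -= n
        for sp, n in rxn.products:
            mat[index[sp], j] += n
    return mat
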