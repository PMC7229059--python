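"""Compartmentalized metabolic network utilities.

Models are plain :class:`cobra.Model` objects; this module adds the pieces
constraint-based time-course analysis needs on top of them: chemical-formula
parsing (Hill notation), transport-reaction detection, metabolite
connectivity, elemental-balance auditing, and format-agnostic readers and
writers (SBML Level 3 + FBC, COBRA JSON).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Set, Tuple

import cobra
from cobra import Model

__all__ = [
    "FormulaError",
    "parse_formula",
    "formula_weight",
    "read_model",
    "write_model",
    "metabolite_compartment",
    "transport_reactions",
    "connectivity",
    "elemental_imbalances",
    "metabolites_without_formula",
]

# Monoisotopic-free average atomic masses (g/mol) for the elements a
# metabolic reconstruction commonly carries.
ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Cl": 35.45, "Zn": 65.38, "Cu": 63.546, "Mn": 54.938,
    "Co": 58.933, "Se": 78.971, "Mo": 95.95, "I": 126.904,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a chemical formula string cannot be parsed."""


def parse_formula(formula: str | None) -> Dict[str, int]:
    """Parse a Hill-style formula into an element → atom-count map.

    An empty or missing formula returns an empty map (pseudo-metabolites
    such as ``protein`` or ``biomass`` legitimately lack formulas and
    contribute zero atoms to any element computation).

    Parameters
    ----------
    formula
        e.g. ``"C6H12O6"`` or ``"C63H88CoN14O14P"``.

    Raises
    ------
    FormulaError
        If the string contains tokens that are not ``Element[count]``.
    """
    if formula is None or formula == "":
        return {}
    counts: Dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {formula!r}: unexpected "
                f"{formula[pos:match.start()]!r} at position {pos}"
            )
        if match.group(0) == "":
            break
        element = match.group(1)
        n = int(match.group(2)) if match.group(2) else 1
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(
            f"malformed formula {formula!r}: unexpected {formula[pos:]!r} "
            f"at position {pos}"
        )
    return counts


def formula_weight(formula: str | Dict[str, int]) -> float:
    """Molar mass in g/mol (equivalently mg/mmol) of a formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - exotic elements
        raise FormulaError(f"no atomic mass for element {exc}") from exc


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer model format from {path!r}; pass fmt=")


def read_model(path: str | Path, fmt: str | None = None) -> Model:
    """Read a model from SBML Level 3 (FBC) or COBRA-style JSON.

    The returned model must declare an objective; a model without one is
    rejected because every downstream analysis optimizes it.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "sbml":
        model = cobra.io.read_sbml_model(str(path))
    elif fmt == "json":
        model = cobra.io.load_json_model(str(path))
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    if not _objective_reactions(model):
        raise ValueError(f"model in {path} declares no objective reaction")
    return model


def write_model(model: Model, path: str | Path, fmt: str | None = None) -> None:
    """Write a model as SBML (FBC) or COBRA JSON, chosen by extension."""
    fmt = _infer_format(path, fmt)
    if fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif fmt == "json":
        cobra.io.save_json_model(model, str(path), pretty=True)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def _objective_reactions(model: Model) -> List[cobra.Reaction]:
    return [
        r for r in model.reactions
        if r.objective_coefficient not in (0, 0.0)
    ]


_SUFFIX = re.compile(r"(?:_([a-z][a-z0-9]?)|\[([a-z][a-z0-9]?)\])$")


def metabolite_compartment(met: cobra.Metabolite) -> str:
    """Compartment of a metabolite.

    The declared ``compartment`` attribute wins; an id suffix (``_c`` or
    ``[c]``) is used only as a fallback, because published reconstructions
    use inconsistent suffix dialects.
    """
    if met.compartment:
        return met.compartment
    match = _SUFFIX.search(met.id)
    if match:
        return match.group(1) or match.group(2)
    raise ValueError(f"metabolite {met.id!r} has no resolvable compartment")


def transport_reactions(model: Model) -> Set[str]:
    """Ids of reactions whose participants span at least two compartments."""
    out: Set[str] = set()
    for rxn in model.reactions:
        comps = {metabolite_compartment(m) for m in rxn.metabolites}
        if len(comps) >= 2:
            out.add(rxn.id)
    return out


def connectivity(model: Model, metabolite_id: str) -> int:
    """Number of reactions carrying the metabolite with nonzero coefficient.

    The biomass reaction counts like any other.
    """
    try:
        met = model.metabolites.get_by_id(metabolite_id)
    except KeyError as exc:
        raise KeyError(f"unknown metabolite {metabolite_id!r}") from exc
    return sum(1 for r in met.reactions if r.metabolites.get(met, 0) != 0)


def metabolites_without_formula(model: Model) -> List[str]:
    """Ids of metabolites lacking a formula (pseudo-metabolites)."""
    return [m.id for m in model.metabolites if not m.formula]


def elemental_imbalances(
    model: Model,
    elements: Iterable[str] | None = None,
    atol: float = 1e-9,
    exempt: Iterable[str] = (),
) -> Dict[str, Dict[str, float]]:
    """Audit elemental balance Σ_i γ_{i,r}·N_i^e per reaction.

    Boundary reactions (exchanges, demands, sinks), reactions listed in
    ``exempt`` (typically the biomass drain), and reactions touching a
    metabolite without a formula (pseudo-species pools) are skipped — they
    are *meant* to create or destroy mass.

    Returns
    -------
    dict
        reaction id → {element: net production} for every non-exempt
        reaction with |imbalance| > `atol` for some element.
    """
    exempt = set(exempt)
    bad: Dict[str, Dict[str, float]] = {}
    for rxn in model.reactions:
        if rxn.boundary or rxn.id in exempt:
            continue
        if any(not m.formula for m in rxn.metabolites):
            continue
        net: Dict[str, float] = {}
        for met, coeff in rxn.metabolites.items():
            for el, n in parse_formula(met.formula).items():
                net[el] = net.get(el, 0.0) + coeff * n
        if elements is not None:
            net = {e: v for e, v in net.items() if e in elements}
        imbalance = {e: v for e, v in net.items() if abs(v) > atol}
        if imbalance:
            bad[rxn.id] = imbalance
    return bad
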