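"""Compartment element loads and relative activities.

The load of element e in compartment c is the molar flux of e carried
*into* c by transport reactions:

    l_{i,c}^e = Σ_r max(v_r·γ_{i,r}, 0) · N_i^e      (per metabolite)
    L_c^e     = Σ_i l_{i,c}^e                         (per compartment)

summing over transport reactions r whose metabolite i sits in c, where
N_i^e is the number of e atoms in i.  Only net-production terms count:
under pseudo-steady state the mass balance closes, so inbound flux fully
characterizes compartment activity.  For a reversible transporter carrying
negative flux the production side follows the sign of v_r·γ_{i,r}, which
makes loads invariant to the direction convention in which a transporter
happens to be written.  Carbon and nitrogen loads are referred to as
compartment *activity*; relative activity is the ratio of activity at each
timepoint to the initial activity.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np
import pandas as pd
from cobra import Model

from .dynamic_fluxes import TimeCourseFluxes
from .fba_engine import FluxState
from .model_core import metabolite_compartment, parse_formula, transport_reactions

logger = logging.getLogger(__name__)

__all__ = ["metabolite_load", "compartment_load", "load_timecourse",
           "relative_activity", "CURRENCY_SPECIES"]

#: species commonly excluded from load reporting when the analysis focuses
#: on backbone elements rather than water/proton shuttling.
CURRENCY_SPECIES = {"h", "h2o"}


def _species_base(met_id: str, compartment: str) -> str:
    for pattern in (f"_{compartment}", f"[{compartment}]"):
        if met_id.endswith(pattern):
            return met_id[: -len(pattern)]
    return met_id


def metabolite_load(model: Model, flux_state: FluxState, reaction_id: str,
                    metabolite_id: str, compartment: str,
                    element: str) -> float:
    """Load of one element carried by one metabolite of one transporter.

    Returns max(v_r·γ_{i,r}, 0)·N_i^e if the metabolite sits in the target
    compartment, else 0.  A metabolite without a formula contributes zero
    (with a warning): pseudo-species carry no countable atoms.
    """
    rxn = model.reactions.get_by_id(reaction_id)
    met = model.metabolites.get_by_id(metabolite_id)
    if metabolite_compartment(met) != compartment:
        return 0.0
    if not met.formula:
        warnings.warn(f"metabolite {met.id} has no formula; "
                      "contributes zero load")
        return 0.0
    gamma = rxn.metabolites.get(met, 0.0)
    v = flux_state[reaction_id]
    n_atoms = parse_formula(met.formula).get(element, 0)
    return max(v * gamma, 0.0) * n_atoms


def compartment_load(model: Model, flux_state: FluxState, compartment: str,
                     element: str,
                     transports: Iterable[str] | None = None,
                     include_currency: bool = True) -> float:
    """Total load L_c^e: element influx into a compartment.

    ``include_currency=False`` drops protons and water from the sum, for
    reports restricted to backbone elements.
    """
    if compartment not in model.compartments:
        raise KeyError(f"unknown compartment {compartment!r}")
    if transports is None:
        transports = transport_reactions(model)
    total = 0.0
    for rid in transports:
        rxn = model.reactions.get_by_id(rid)
        v = flux_state[rid]
        if v == 0.0:
            continue
        for met, gamma in rxn.metabolites.items():
            if metabolite_compartment(met) != compartment:
                continue
            if not include_currency and _species_base(
                    met.id, compartment) in CURRENCY_SPECIES:
                continue
            if not met.formula:
                continue
            n_atoms = parse_formula(met.formula).get(element, 0)
            if n_atoms:
                total += max(v * gamma, 0.0) * n_atoms
    return total


def load_timecourse(model: Model, timecourse: TimeCourseFluxes,
                    compartments: Iterable[str] | None = None,
                    elements: Iterable[str] = ("C", "N"),
                    include_currency: bool = True) -> pd.DataFrame:
    """Loads for every (compartment, element) over the solved timepoints.

    Returns a tidy frame with columns compartment, element, timepoint,
    load (mmol element/gDW/h).
    """
    compartments = list(compartments) if compartments is not None \
        else sorted(model.compartments)
    transports = transport_reactions(model)
    rows = []
    for t, state in zip(timecourse.timepoints, timecourse.states):
        if not state.ok:
            continue
        for comp in compartments:
            for el in elements:
                rows.append({
                    "compartment": comp, "element": el, "timepoint": t,
                    "load": compartment_load(
                        model, state, comp, el, transports=transports,
                        include_currency=include_currency),
                })
    return pd.DataFrame(rows)


def relative_activity(loads: pd.DataFrame) -> pd.DataFrame:
    """Ratio of each (compartment, element) load to its initial load.

    Adds a ``relative_activity`` column; series whose initial load is zero
    are flagged undefined (NaN) rather than reported as infinities.
    """
    out = loads.copy()
    out["relative_activity"] = np.nan
    for (comp, el), group in loads.groupby(["compartment", "element"]):
        initial = group["load"].iloc[0]
        if initial <= 0:
            logger.warning("initial load is zero for %s/%s; "
                           "relative activity undefined", comp, el)
            continue
        out.loc[group.index, "relative_activity"] = group["load"] / initial
    return out
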