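"""Biosynthetic cost of biomass components in energy-currency units.

The cost A_i = ∂r_ATP/∂r_i of metabolite i is measured by finite
difference: growth is predicted, the biomass flux is pinned at 95% of that
optimum, the objective is switched to an ATP-hydrolysis reaction, and the
maximal hydrolysis flux is recorded before (r_base) and after (r_forced)
forcing a small demand δ (default 1e-4 mmol/gDW/h) for i.  Then

    A_i = (r_base − r_forced) / δ        [mmol ATP / mmol metabolite].

The same construction applies to NADH or NADPH oxidation as the currency.
A positive cost is energy diverted; a negative cost (a metabolite whose
synthesis yields net currency) is allowed and reported as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from cobra import Model, Reaction

from .fba_engine import solve_fba
from .model_core import formula_weight, parse_formula
from .sensitivity import CorrelationResult, correlate

logger = logging.getLogger(__name__)

__all__ = ["CostRecord", "biosynthetic_cost", "cost_report", "cost_drivers",
           "find_hydrolysis_reaction", "read_dgf_table"]

#: demand flux δ forced for the costed metabolite, mmol/gDW/h.
DEFAULT_DELTA = 1e-4
#: growth fraction at which biomass flux is pinned during costing.
GROWTH_FRACTION = 0.95

#: currency → (consumed high-energy species, produced low-energy species),
#: matched against metabolite ids without compartment suffix.
CURRENCY_COUPLES = {
    "ATP": ("atp", "adp"),
    "NADH": ("nadh", "nad"),
    "NADPH": ("nadph", "nadp"),
}


@dataclass
class CostRecord:
    """Cost of one metabolite in one currency."""

    metabolite_id: str
    currency: str
    a: float                      # mmol currency / mmol metabolite
    r_base: float                 # maximal hydrolysis flux, unforced
    r_forced: float               # maximal hydrolysis flux with demand δ
    delta: float
    mw: float | None = None       # g/mmol from the formula, if present
    n_carbon: int = 0
    n_nitrogen: int = 0
    dgf: float | None = None      # standard Gibbs energy of formation
    producible: bool = True


def find_hydrolysis_reaction(model: Model, currency: str = "ATP") -> str:
    """Locate a hydrolysis/oxidation reaction for the currency.

    A match consumes the high-energy species and produces the low-energy
    one, with no other carbon-carrying participants beyond water/protons/
    phosphate.  Raises if none exists.
    """
    try:
        high, low = CURRENCY_COUPLES[currency]
    except KeyError:
        raise ValueError(f"unknown currency {currency!r}; "
                         f"expected one of {sorted(CURRENCY_COUPLES)}")

    def base(met_id: str) -> str:
        return met_id.rsplit("_", 1)[0].rstrip("]").rsplit("[", 1)[0]

    for rxn in model.reactions:
        consumed = {base(m.id) for m, c in rxn.metabolites.items() if c < 0}
        produced = {base(m.id) for m, c in rxn.metabolites.items() if c > 0}
        allowed = {"h", "h2o", "pi", "ppi"}
        if (high in consumed and low in produced
                and consumed - {high} <= allowed
                and produced - {low} <= allowed):
            return rxn.id
    raise ValueError(f"no {currency} hydrolysis reaction found; pass "
                     "hydrolysis_id explicitly")


def biosynthetic_cost(
    model: Model,
    metabolite_id: str,
    currency: str = "ATP",
    delta: float = DEFAULT_DELTA,
    growth_fraction: float = GROWTH_FRACTION,
    hydrolysis_id: str | None = None,
    dgf: float | None = None,
) -> CostRecord:
    """Finite-difference biosynthetic cost of one metabolite.

    All modifications (biomass pinning, objective switch, temporary demand)
    happen inside a model context, so the input model is bit-identical
    before and after the call.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    met = model.metabolites.get_by_id(metabolite_id)
    if hydrolysis_id is None:
        hydrolysis_id = find_hydrolysis_reaction(model, currency)

    base_state = solve_fba(model)
    if not base_state.ok:
        raise ValueError(f"model is {base_state.status}; cannot cost")
    mu_star = base_state.objective_value
    biomass = [r for r in model.reactions if r.objective_coefficient != 0][0]

    with model:
        # pin biomass: an equality fix, because a free upper bound would
        # let the solver trade growth away for extra hydrolysis flux.
        target = growth_fraction * mu_star
        biomass.lower_bound = biomass.upper_bound = target
        model.objective = model.reactions.get_by_id(hydrolysis_id)
        r_base_state = solve_fba(model)
        if not r_base_state.ok:
            raise ValueError("hydrolysis maximization infeasible at "
                             f"{growth_fraction:.0%} growth")
        r_base = r_base_state.objective_value

        # the demand is pinned at exactly delta: Eq-3-style derivatives need
        # the forced production to be delta, not "at least delta" (a
        # metabolite with negative cost would otherwise be overproduced).
        demand = Reaction(f"DM_{metabolite_id}__cost",
                          lower_bound=delta, upper_bound=delta)
        model.add_reactions([demand])
        demand.add_metabolites({met: -1.0})
        forced_state = solve_fba(model)

    if not forced_state.ok:
        logger.warning("%s not producible at %.0f%% growth", metabolite_id,
                       100 * growth_fraction)
        return CostRecord(metabolite_id=metabolite_id, currency=currency,
                          a=float("nan"), r_base=r_base,
                          r_forced=float("nan"), delta=delta,
                          producible=False, dgf=dgf,
                          **_formula_fields(met))
    r_forced = forced_state.objective_value
    return CostRecord(metabolite_id=metabolite_id, currency=currency,
                      a=(r_base - r_forced) / delta, r_base=r_base,
                      r_forced=r_forced, delta=delta, dgf=dgf,
                      **_formula_fields(met))


def _formula_fields(met) -> Dict[str, object]:
    if not met.formula:
        return {"mw": None, "n_carbon": 0, "n_nitrogen": 0}
    counts = parse_formula(met.formula)
    return {"mw": formula_weight(counts) / 1000.0,
            "n_carbon": counts.get("C", 0),
            "n_nitrogen": counts.get("N", 0)}


def cost_report(
    model: Model,
    metabolite_ids: Sequence[str],
    currencies: Sequence[str] = ("ATP",),
    dgf_values: Mapping[str, float] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Cost records for many metabolites/currencies as a tidy table."""
    rows = []
    for currency in currencies:
        for mid in metabolite_ids:
            rec = biosynthetic_cost(
                model, mid, currency=currency,
                dgf=(dgf_values or {}).get(mid), **kwargs)
            rows.append({
                "metabolite_id": rec.metabolite_id, "currency": rec.currency,
                "cost": rec.a, "r_base": rec.r_base, "delta": rec.delta,
                "mw_g_per_mmol": rec.mw, "n_C": rec.n_carbon,
                "n_N": rec.n_nitrogen, "dgf": rec.dgf,
                "producible": rec.producible,
            })
    return pd.DataFrame(rows)


def cost_drivers(records: pd.DataFrame) -> Dict[str, CorrelationResult]:
    """What drives cost: molecular weight, N/C ratio, or free energy?

    OLS correlations of cost against each candidate driver; the ΔG_f
    correlation is skipped with a notice when no values were supplied.
    """
    usable = records[records["producible"] & records["cost"].notna()]
    if len(usable) < 3:
        raise ValueError("need at least 3 producible metabolites")
    out: Dict[str, CorrelationResult] = {}
    out["mw"] = correlate(usable["mw_g_per_mmol"], usable["cost"])
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = usable["n_N"] / usable["n_C"]
    out["n_to_c"] = correlate(nc, usable["cost"])
    if usable["dgf"].notna().sum() >= 3:
        sub = usable[usable["dgf"].notna()]
        out["dgf"] = correlate(sub["dgf"], sub["cost"])
    else:
        logger.info("ΔG_f values missing; free-energy correlation skipped")
    return out


def read_dgf_table(path) -> Dict[str, float]:
    """Read a TSV of metabolite → standard Gibbs energy of formation
    (columns ``metabolite_id``, ``dgf_kcal_per_mol``)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["metabolite_id"], df["dgf_kcal_per_mol"]))
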