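"""Build per-timepoint biomass objective functions from composition data.

A biomass objective function (BOF) is the pseudo-reaction that drains
biomass precursors in measured proportions; its flux is the growth rate μ.
Given a time-course table of mass fractions (g/gDW), this module converts
fractions to stoichiometric coefficients p_i (mmol/gDW), drops components
the model cannot produce (re-normalizing the survivors so one gram of dry
weight is still drained), and installs the resulting reaction in a model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from cobra import Model, Reaction

from .fba_engine import solve_fba

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionTable",
    "BiomassFunction",
    "GAM_STOICHIOMETRY",
    "mass_fraction_to_coefficient",
    "test_producibility",
    "build_bof",
    "install_bof",
]

#: Growth-associated maintenance: ATP + H2O -> ADP + Pi + H, per mmol ATP.
GAM_STOICHIOMETRY = {"atp": -1.0, "h2o": -1.0, "adp": 1.0, "pi": 1.0, "h": 1.0}

#: Default metabolite ids for the GAM term, cytosolic.
DEFAULT_GAM_IDS = {"atp": "atp_c", "h2o": "h2o_c", "adp": "adp_c",
                   "pi": "pi_c", "h": "h_c"}

#: FBA optimum below which a partial BOF counts as infeasible.
FEASIBILITY_EPS = 1e-9

#: number of stages a time course is aligned onto (relative time units).
N_STAGES = 6


@dataclass
class CompositionTable:
    """Timepoint × biomass-component mass fractions.

    ``data`` has one row per component with columns ``component_id``,
    ``metabolite_id``, ``class`` (AA/CB/Nuc/FA/PL/OL/...),
    ``mw_g_per_mmol`` and one fraction column per timepoint (``t1``...).
    Fractions are g per g dry weight.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"component_id", "metabolite_id", "class", "mw_g_per_mmol"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"composition table missing columns {missing}")
        if (self.data["mw_g_per_mmol"] <= 0).any():
            raise ValueError("molecular weights must be positive")
        frac = self.data[self.timepoints]
        if (frac.values < 0).any():
            raise ValueError("mass fractions must be non-negative")
        sums = frac.sum(axis=0)
        if (sums > 1 + 1e-6).any():
            raise ValueError(
                f"per-timepoint mass fractions exceed 1 g/gDW: {dict(sums)}")

    @property
    def timepoints(self) -> List[str]:
        return [c for c in self.data.columns if c.startswith("t")
                and c[1:].isdigit()]

    @property
    def components(self) -> List[str]:
        return list(self.data["component_id"])

    def fractions(self, timepoint: str) -> pd.Series:
        """Mass fractions (g/gDW) at one timepoint, indexed by component."""
        return pd.Series(self.data[timepoint].values,
                         index=self.data["component_id"], dtype=float)

    def metabolite_of(self, component_id: str) -> str:
        row = self.data.set_index("component_id")
        return str(row.loc[component_id, "metabolite_id"])

    def mw_of(self, component_id: str) -> float:
        row = self.data.set_index("component_id")
        return float(row.loc[component_id, "mw_g_per_mmol"])

    def class_of(self, component_id: str) -> str:
        row = self.data.set_index("component_id")
        return str(row.loc[component_id, "class"])

    def observed_ranges(self) -> Dict[str, Tuple[float, float]]:
        """Per-component (min, max) mass fraction across the time course."""
        frac = self.data[self.timepoints]
        return {
            comp: (float(frac.iloc[i].min()), float(frac.iloc[i].max()))
            for i, comp in enumerate(self.data["component_id"])
        }

    def align_to_stages(self, n_stages: int = N_STAGES) -> "CompositionTable":
        """Linearly interpolate the fraction columns onto `n_stages`
        equally spaced relative-time stages.

        Time courses are expressed in hypothetical time units relative to
        the total culture duration, so tables measured on any grid can be
        compared on a common six-stage axis (replete 1-2, transition 3-4,
        deplete 5-6).
        """
        old = self.timepoints
        if len(old) < 2:
            raise ValueError("need at least two timepoints to interpolate")
        x_old = np.linspace(0.0, 1.0, len(old))
        x_new = np.linspace(0.0, 1.0, n_stages)
        frac = self.data[old].values  # components × T
        interp = np.vstack([np.interp(x_new, x_old, row) for row in frac])
        out = self.data.drop(columns=old).copy()
        for k in range(n_stages):
            out[f"t{k + 1}"] = interp[:, k]
        return CompositionTable(out)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompositionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class BiomassFunction:
    """One timepoint's biomass objective function.

    ``coefficients`` maps metabolite id → p_i (mmol/gDW); ``gam`` is the
    growth-associated maintenance ATP stoichiometry (mmol ATP/gDW);
    ``excluded`` lists (metabolite_id, reason) for components dropped
    during construction.  ``mw`` carries the g/mmol weights used, so mass
    closure Σ p_i·MW_i = 1 g/gDW can be audited at any time.
    """

    coefficients: Dict[str, float]
    gam: float = 0.0
    excluded: List[Tuple[str, str]] = field(default_factory=list)
    mw: Dict[str, float] = field(default_factory=dict)

    def mass_drained(self) -> float:
        """Σ p_i·MW_i in g/gDW (1.0 when mass closure holds)."""
        return sum(p * self.mw[m] for m, p in self.coefficients.items())

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"metabolite_id": m, "p_mmol_per_gDW": p,
                 "mw_g_per_mmol": self.mw.get(m, np.nan)}
                for m, p in self.coefficients.items()]
        df = pd.DataFrame(rows)
        df["gam"] = self.gam
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BiomassFunction":
        df = pd.read_csv(path, sep="\t")
        coeffs = dict(zip(df["metabolite_id"], df["p_mmol_per_gDW"]))
        mw = dict(zip(df["metabolite_id"], df["mw_g_per_mmol"]))
        gam = float(df["gam"].iloc[0]) if len(df) else 0.0
        return cls(coefficients=coeffs, gam=gam, mw=mw)


def mass_fraction_to_coefficient(fraction: float, mw: float) -> float:
    """Convert a mass fraction (g/gDW) to a coefficient p_i (mmol/gDW).

    ``mw`` is in g/mmol, so p_i = fraction / mw.
    """
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    if fraction < 0:
        raise ValueError(f"mass fraction must be non-negative, got {fraction}")
    return fraction / mw


def test_producibility(model: Model, metabolite_id: str,
                       threshold: float = 1e-6) -> bool:
    """Can the model synthesize the metabolite at all?

    True iff a demand reaction for the metabolite can carry flux at least
    `threshold` under the model's exchange constraints.
    """
    met = model.metabolites.get_by_id(metabolite_id)
    with model:
        demand_id = f"DM_{metabolite_id}__prodtest"
        demand = Reaction(demand_id, lower_bound=0.0, upper_bound=1000.0)
        model.add_reactions([demand])
        demand.add_metabolites({met: -1.0})
        model.objective = demand
        sol = model.optimize()
        return sol.status == "optimal" and sol.objective_value >= threshold


def _set_biomass_stoichiometry(model: Model, bof: BiomassFunction,
                               biomass_id: str,
                               gam_ids: Mapping[str, str]) -> None:
    rxn = model.reactions.get_by_id(biomass_id)
    rxn.subtract_metabolites(dict(rxn.metabolites))  # clear
    stoich: Dict[str, float] = {m: -p for m, p in bof.coefficients.items()}
    if bof.gam > 0:
        for role, sign in GAM_STOICHIOMETRY.items():
            mid = gam_ids[role]
            stoich[mid] = stoich.get(mid, 0.0) + sign * bof.gam
    missing = [m for m in stoich if m not in model.metabolites]
    if missing:
        raise KeyError(f"BOF metabolites not in model: {missing}")
    rxn.add_metabolites({model.metabolites.get_by_id(m): v
                         for m, v in stoich.items() if v != 0.0})
    rxn.lower_bound, rxn.upper_bound = 0.0, 1000.0
    model.objective = rxn


def _find_biomass_reaction(model: Model, biomass_id: str | None) -> str:
    if biomass_id is not None:
        return model.reactions.get_by_id(biomass_id).id
    objective = [r for r in model.reactions if r.objective_coefficient != 0]
    if len(objective) == 1:
        return objective[0].id
    candidates = [r for r in model.reactions if "biomass" in r.id.lower()]
    if len(candidates) == 1:
        return candidates[0].id
    raise ValueError("cannot identify the biomass reaction; pass biomass_id")


def build_bof(model: Model, table: CompositionTable, timepoint: str,
              gam: float = 0.0, biomass_id: str | None = None,
              gam_ids: Mapping[str, str] = DEFAULT_GAM_IDS) -> BiomassFunction:
    """Construct the BOF for one timepoint with producibility filtering.

    Components are added one by one in order of descending mass fraction
    (the procedure is order-dependent in principle; a deterministic order
    makes runs reproducible).  Each candidate is first screened with a
    demand-reaction producibility test, then the growing BOF is installed
    and solved; any component that drives the optimum below
    ``FEASIBILITY_EPS`` (or makes the LP infeasible) is excluded with a
    reason.  Surviving mass fractions are rescaled to sum to 1 g/gDW
    before conversion to coefficients, so Σ p_i·MW_i = 1 g/gDW holds for
    every built BOF.

    GAM (the catabolic ATP requirement already set in the model) is passed
    through unchanged.
    """
    if gam < 0:
        raise ValueError("gam must be non-negative")
    biomass_id = _find_biomass_reaction(model, biomass_id)
    fractions = table.fractions(timepoint)
    fractions = fractions[fractions > 0]
    order = fractions.sort_values(ascending=False).index.tolist()

    excluded: List[Tuple[str, str]] = []
    kept: List[str] = []
    for comp in order:
        met_id = table.metabolite_of(comp)
        if met_id not in model.metabolites:
            excluded.append((met_id, "not in model"))
            continue
        if not test_producibility(model, met_id):
            excluded.append((met_id, "not producible"))
            continue
        trial = kept + [comp]
        partial = BiomassFunction(
            coefficients={
                table.metabolite_of(c): mass_fraction_to_coefficient(
                    float(fractions[c]), table.mw_of(c))
                for c in trial
            },
            gam=gam,
            mw={table.metabolite_of(c): table.mw_of(c) for c in trial},
        )
        with model:
            _set_biomass_stoichiometry(model, partial, biomass_id, gam_ids)
            state = solve_fba(model)
        if state.ok and state.objective_value > FEASIBILITY_EPS:
            kept.append(comp)
        else:
            reason = ("LP infeasible with this component" if not state.ok
                      else "growth collapses with this component")
            excluded.append((met_id, reason))
            logger.info("excluding %s at %s: %s", met_id, timepoint, reason)

    if not kept:
        raise ValueError(f"no producible biomass component at {timepoint}")

    surviving = fractions[kept]
    rescale = 1.0 / surviving.sum()
    coeffs = {
        table.metabolite_of(c): mass_fraction_to_coefficient(
            float(surviving[c]) * rescale, table.mw_of(c))
        for c in kept
    }
    return BiomassFunction(
        coefficients=coeffs, gam=gam, excluded=excluded,
        mw={table.metabolite_of(c): table.mw_of(c) for c in kept},
    )


def install_bof(model: Model, bof: BiomassFunction,
                biomass_id: str | None = None,
                gam_ids: Mapping[str, str] = DEFAULT_GAM_IDS) -> Model:
    """Return a copy of the model with the BOF installed as its objective.

    The biomass reaction's stoichiometry is replaced with −p_i per
    precursor plus the GAM hydrolysis terms; the original model is left
    untouched.  Installing the same BOF twice is idempotent.
    """
    biomass_id = _find_biomass_reaction(model, biomass_id)
    new = model.copy()
    _set_biomass_stoichiometry(new, bof, biomass_id, gam_ids)
    return new
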