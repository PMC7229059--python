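"""Linear-programming core: FBA solves, objective-fraction constraints and
loopless post-processing.

All growth-mode analyses in this package reduce to sequences of LP solves on
a :class:`cobra.Model`; this module is the single place those solves happen,
so solver configuration and tolerances are uniform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from cobra import Model
from cobra.flux_analysis.loopless import loopless_solution

logger = logging.getLogger(__name__)

__all__ = ["FluxState", "solve_fba", "loopless_fluxes", "fix_objective_fraction"]

#: optlang feasibility/optimality tolerance used for every solve.
LP_TOLERANCE = 1e-9


@dataclass
class FluxState:
    """Flux distribution at one timepoint.

    Attributes
    ----------
    fluxes : pandas.Series
        Reaction id → flux, mmol/gDW/h (h^-1 for the biomass reaction).
    objective_value : float
        Value of the model objective; growth rate μ when the objective is
        the biomass reaction.
    status : str
        ``optimal``, ``infeasible`` or ``unbounded``.
    """

    fluxes: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    objective_value: float = float("nan")
    status: str = "infeasible"

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])


def _configure(model: Model) -> None:
    model.tolerance = LP_TOLERANCE


def solve_fba(model: Model, objective_id: str | None = None,
              sense: str = "max") -> FluxState:
    """Solve the FBA problem max/min v_obj s.t. S·v = 0, lb ≤ v ≤ ub.

    Infeasibility or unboundedness is reported through ``status``; fluxes
    are never silently zeroed.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    with model:
        _configure(model)
        if objective_id is not None:
            model.objective = model.reactions.get_by_id(objective_id)
        model.objective_direction = "max" if sense == "max" else "min"
        sol = model.optimize()
        if sol.status != "optimal":
            return FluxState(status=sol.status)
        return FluxState(fluxes=sol.fluxes.copy(),
                         objective_value=float(sol.objective_value),
                         status="optimal")


def loopless_fluxes(model: Model, flux_state: FluxState) -> FluxState:
    """Remove thermodynamically infeasible internal cycles from a solution.

    CycleFreeFlux-style post-processing: a secondary LP minimizes total
    internal flux while fixing exchange fluxes and the objective value, so
    the returned state has the identical objective and exchanges but no
    internal loop carries flux.  If the secondary LP fails the input state
    is returned unchanged with a warning.
    """
    if not flux_state.ok:
        raise ValueError("loopless post-processing requires an optimal state")
    try:
        with model:
            _configure(model)
            sol = loopless_solution(model, fluxes=flux_state.fluxes.to_dict())
    except Exception as exc:  # solver hiccup: fall back, never fail the run
        warnings.warn(f"loopless post-processing failed ({exc}); "
                      "returning the input flux state")
        return flux_state
    return FluxState(fluxes=sol.fluxes.copy(),
                     objective_value=flux_state.objective_value,
                     status="optimal")


def fix_objective_fraction(model: Model, fraction: float,
                           exact: bool = False) -> Model:
    """Return a copy of the model with the objective bounded at a fraction
    of its optimum.

    With ``exact=False`` only the lower bound is set (the near-optimal
    constraint used for flux sampling, e.g. a minimum of 90% of the optimal
    solution).  With ``exact=True`` both bounds are fixed (used by the
    biosynthetic-cost algorithm, which pins biomass at 95% of the predicted
    value before re-optimizing ATP hydrolysis).

    The input model is not modified.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    base = solve_fba(model)
    if not base.ok:
        raise ValueError(f"base model is {base.status}; cannot fix fraction")
    fixed = model.copy()
    obj = [r for r in fixed.reactions if r.objective_coefficient != 0]
    if len(obj) != 1:
        raise ValueError("objective must be a single reaction")
    target = fraction * base.objective_value
    obj[0].lower_bound = target
    if exact:
        obj[0].upper_bound = target
    return fixed
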