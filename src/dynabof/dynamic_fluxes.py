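"""Per-timepoint FBA series, flux-variation Z-scores and their clustering.

The time course is driven entirely by the biomass objective: each stage's
BOF is installed in turn and solved (looplessly), nutrient-exchange
constraints being held fixed unless overridden, so composition — not a
nutrient bound — produces the dynamics.  Flux variations between stages
are standardized per reaction (Z-scores) and grouped by agglomerative
clustering with Euclidean distance and average (UPGMA) linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from cobra import Model
from scipy.cluster.hierarchy import fcluster, linkage

from .bof_builder import BiomassFunction, install_bof
from .fba_engine import FluxState, loopless_fluxes, solve_fba
from .model_core import parse_formula

logger = logging.getLogger(__name__)

__all__ = ["TimeCourseFluxes", "FluxVariationMatrix", "run_timecourse",
           "flux_variation", "zscore_and_cluster", "open_nitrogen_exchanges"]


@dataclass
class TimeCourseFluxes:
    """One loopless optimal flux state per timepoint."""

    timepoints: List[str]
    states: List[FluxState]
    bofs: List[BiomassFunction]

    def __post_init__(self) -> None:
        if not (len(self.timepoints) == len(self.states) == len(self.bofs)):
            raise ValueError("timepoints, states and bofs must align")

    @property
    def ok_timepoints(self) -> List[str]:
        return [t for t, s in zip(self.timepoints, self.states) if s.ok]

    def flux_table(self) -> pd.DataFrame:
        """Reactions × timepoints flux matrix (solved timepoints only)."""
        cols = {t: s.fluxes for t, s in zip(self.timepoints, self.states)
                if s.ok}
        return pd.DataFrame(cols)

    def growth_rates(self) -> pd.Series:
        return pd.Series(
            {t: (s.objective_value if s.ok else np.nan)
             for t, s in zip(self.timepoints, self.states)})


@dataclass
class FluxVariationMatrix:
    """Row-standardized flux-variation matrix plus its linkage tree."""

    zscores: pd.DataFrame          # reactions × variation columns
    linkage_matrix: np.ndarray     # scipy linkage encoding (n-1 merges)
    baseline_mode: str = "t0"
    dropped_constant: List[str] = field(default_factory=list)

    def flat_clusters(self, n_clusters: int) -> pd.Series:
        labels = fcluster(self.linkage_matrix, t=n_clusters,
                          criterion="maxclust")
        return pd.Series(labels, index=self.zscores.index, name="cluster")


def open_nitrogen_exchanges(model: Model, bound: float = 1000.0) -> List[str]:
    """Open (±bound) every inorganic-nitrogen exchange.

    Affects exchanges whose species contains nitrogen but no carbon
    (ammonia, nitrate and the like — the nitrogen sources proper, as
    opposed to organic carriers that double as carbon sources).  Applied
    in-place; returns the affected reaction ids.  Keeping nitrogen
    exchange unconstrained guarantees the predicted dynamics come from the
    changing biomass composition rather than from a nitrogen bound
    becoming active.
    """
    opened = []
    for rxn in model.exchanges:
        (met,) = rxn.metabolites
        counts = parse_formula(met.formula)
        if counts.get("N", 0) > 0 and counts.get("C", 0) == 0:
            rxn.lower_bound, rxn.upper_bound = -bound, bound
            opened.append(rxn.id)
    return opened


def run_timecourse(
    model: Model,
    bofs: Sequence[BiomassFunction],
    timepoints: Sequence[str] | None = None,
    uptake_constraints: Mapping[str, Mapping[str, Tuple[float, float]]] | None = None,
    open_nitrogen: bool = True,
    loopless: bool = True,
    biomass_id: str | None = None,
) -> TimeCourseFluxes:
    """Solve one FBA problem per timepoint with that timepoint's BOF.

    ``uptake_constraints`` optionally maps timepoint → {reaction: (lb, ub)}.
    Infeasible timepoints are flagged and skipped; the run only fails if
    every timepoint is infeasible.
    """
    timepoints = list(timepoints) if timepoints is not None else [
        f"t{k + 1}" for k in range(len(bofs))]
    if len(timepoints) != len(bofs):
        raise ValueError("one BOF per timepoint required")

    states: List[FluxState] = []
    for t, bof in zip(timepoints, bofs):
        staged = install_bof(model, bof, biomass_id=biomass_id)
        if open_nitrogen:
            open_nitrogen_exchanges(staged)
        if uptake_constraints and t in uptake_constraints:
            for rid, (lb, ub) in uptake_constraints[t].items():
                rxn = staged.reactions.get_by_id(rid)
                rxn.lower_bound, rxn.upper_bound = lb, ub
        state = solve_fba(staged)
        if state.ok and loopless:
            state = loopless_fluxes(staged, state)
        if not state.ok:
            logger.warning("timepoint %s: %s", t, state.status)
        states.append(state)

    if not any(s.ok for s in states):
        raise ValueError("every timepoint was infeasible")
    return TimeCourseFluxes(timepoints=timepoints, states=states,
                            bofs=list(bofs))


def flux_variation(timecourse: TimeCourseFluxes,
                   baseline_mode: str = "t0",
                   magnitude: bool = False) -> pd.DataFrame:
    """Flux differences per reaction, in absolute (not relative) units.

    ``t0`` mode: Δ_{r,t} = v_{r,t} − v_{r,t0} for every t after the
    first; ``consecutive``: Δ_{r,t} = v_{r,t} − v_{r,t−1}.  Differences
    are signed by default so that, after standardization, upregulated and
    downregulated reactions cluster apart; ``magnitude=True`` takes |Δ|
    instead when only the size of the change matters.
    """
    if baseline_mode not in ("t0", "consecutive"):
        raise ValueError("baseline_mode must be 't0' or 'consecutive'")
    table = timecourse.flux_table()
    if table.shape[1] < 2:
        raise ValueError("need at least two solved timepoints")
    cols = table.columns.tolist()
    if baseline_mode == "t0":
        deltas = {t: table[t] - table[cols[0]] for t in cols[1:]}
    else:
        deltas = {t: table[t] - table[prev]
                  for prev, t in zip(cols, cols[1:])}
    out = pd.DataFrame(deltas)
    return out.abs() if magnitude else out


def zscore_and_cluster(variation: pd.DataFrame,
                       baseline_mode: str = "t0") -> FluxVariationMatrix:
    """Row-wise Z-scores and UPGMA clustering of a variation matrix.

    Rows with zero variance (constant variation across timepoints) carry
    no trend information and are dropped rather than divided by zero.
    Standardization uses the population SD (divide by n), matching common
    clustergram practice; pairwise dissimilarity is Euclidean and linkage
    is average (UPGMA).
    """
    values = variation.values.astype(float)
    sd = values.std(axis=1)  # row-wise population SD
    keep = sd > 1e-12
    dropped = variation.index[~keep].tolist()
    kept = variation.loc[keep]
    if kept.shape[0] < 2:
        raise ValueError("need at least two non-constant rows to cluster")
    z = kept.sub(kept.mean(axis=1), axis=0).div(
        kept.std(axis=1, ddof=0), axis=0)
    lnk = linkage(z.values, method="average", metric="euclidean")
    return FluxVariationMatrix(zscores=z, linkage_matrix=lnk,
                               baseline_mode=baseline_mode,
                               dropped_constant=dropped)
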