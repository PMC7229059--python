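"""Growth sensitivity and codependence of biomass components.

The sensitivity S_i of a biomass component is the slope of predicted
growth rate against its stoichiometric coefficient p_i (μ = S_i·p_i + I,
with the intercept fitted but not reported).  Because S_i depends on the
abundance of the other precursors, the regression is repeated over many
hypothetical BOFs in which every other component is drawn uniformly from
its observed range; the reported sensitivity is the mean slope and the
codependence D_i = max(S_i) − min(S_i) measures how strongly the
background composition modulates it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from cobra import Model
from scipy import stats

from .bof_builder import (BiomassFunction, CompositionTable, DEFAULT_GAM_IDS,
                          _find_biomass_reaction, _set_biomass_stoichiometry,
                          mass_fraction_to_coefficient)
from .fba_engine import solve_fba
from .model_core import connectivity as _connectivity

logger = logging.getLogger(__name__)

__all__ = ["SensitivityRecord", "CorrelationResult", "perturb_background",
           "sensitivity_of", "sensitivity_report", "correlate"]

#: default number of hypothetical background BOFs per component.
N_BOFS = 100
#: grid points over the observed range of the swept component.
N_GRID = 10
#: minimum feasible grid points for a background's regression to count.
MIN_GRID_POINTS = 3


@dataclass
class SensitivityRecord:
    """Per-component sensitivity summary.

    ``s_samples`` holds one regression slope per hypothetical background,
    in (h^-1)/(mmol/gDW); ``s_mean`` is their mean, ``d`` the codependence
    (max − min).  ``s_mean_per_fraction`` restates the mean slope per unit
    mass fraction, i.e. s_mean / MW.
    """

    component_id: str
    metabolite_id: str
    class_label: str
    s_samples: np.ndarray
    connectivity: int
    mw_g_per_mmol: float
    n_skipped_backgrounds: int = 0
    cost: float | None = None

    @property
    def s_mean(self) -> float:
        return float(np.mean(self.s_samples))

    @property
    def d(self) -> float:
        return float(np.max(self.s_samples) - np.min(self.s_samples))

    @property
    def s_mean_per_fraction(self) -> float:
        return self.s_mean / self.mw_g_per_mmol


@dataclass
class CorrelationResult:
    r2: float
    p_value: float
    slope: float
    intercept: float


def perturb_background(
    fractions: Mapping[str, float],
    observed_ranges: Mapping[str, Tuple[float, float]],
    target: str,
    rng: np.random.Generator,
) -> Dict[str, float]:
    """Draw a hypothetical background composition.

    Every component except ``target`` is drawn uniformly from its observed
    (min, max) mass-fraction range; the full vector is then rescaled to
    mass closure (Σ fractions = 1 g/gDW).  With degenerate ranges
    (min = max for all components) the input composition is returned
    unchanged, and a fixed RNG state makes the draw reproducible.
    """
    if not observed_ranges:
        raise ValueError("observed_ranges is empty")
    out = dict(fractions)
    for comp, (lo, hi) in observed_ranges.items():
        if comp == target:
            continue
        if hi < lo:
            raise ValueError(f"invalid range for {comp}: ({lo}, {hi})")
        out[comp] = float(rng.uniform(lo, hi)) if hi > lo else lo
    total = sum(out.values())
    if total <= 0:
        raise ValueError("background composition sums to zero")
    return {c: f / total for c, f in out.items()}


def sensitivity_of(
    model: Model,
    component_id: str,
    table: CompositionTable,
    n_bofs: int = N_BOFS,
    n_grid: int = N_GRID,
    seed: int = 0,
    gam: float = 0.0,
    biomass_id: str | None = None,
    gam_ids: Mapping[str, str] = DEFAULT_GAM_IDS,
) -> SensitivityRecord:
    """Estimate S_i and D_i for one biomass component.

    For each of ``n_bofs`` random backgrounds the component's mass
    fraction sweeps ``n_grid`` evenly spaced values over its observed
    range (other components stay at their background values — no
    re-normalization during the sweep, so the slope is a clean partial
    derivative ∂μ/∂p_i), growth is predicted at each grid point, and an
    ordinary least-squares line of μ against p_i gives the slope.
    Backgrounds with fewer than three feasible grid points are skipped and
    logged.
    """
    ranges = table.observed_ranges()
    if component_id not in ranges:
        raise KeyError(f"{component_id!r} not in composition table")
    lo, hi = ranges[component_id]
    if hi <= lo:
        raise ValueError(
            f"degenerate observed range for {component_id}: ({lo}, {hi})")
    met_id = table.metabolite_of(component_id)
    mw = table.mw_of(component_id)
    biomass_rid = _find_biomass_reaction(model, biomass_id)
    base_fractions = dict(table.fractions(table.timepoints[0]))
    grid = np.linspace(lo, hi, n_grid)
    mets = {c: table.metabolite_of(c) for c in table.components}
    mws = {c: table.mw_of(c) for c in table.components}

    # one master seed; per-background substreams derived by counter so the
    # evaluation order (or parallel split) cannot change the draws.
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_bofs)

    slopes: List[float] = []
    skipped = 0
    for b in range(n_bofs):
        rng = np.random.default_rng(streams[b])
        background = perturb_background(base_fractions, ranges,
                                        component_id, rng)
        p_values: List[float] = []
        mu_values: List[float] = []
        for f_i in grid:
            fracs = dict(background)
            fracs[component_id] = float(f_i)
            coeffs = {mets[c]: mass_fraction_to_coefficient(f, mws[c])
                      for c, f in fracs.items() if f > 0}
            bof = BiomassFunction(coefficients=coeffs, gam=gam,
                                  mw={mets[c]: mws[c] for c in fracs})
            with model:
                _set_biomass_stoichiometry(model, bof, biomass_rid, gam_ids)
                state = solve_fba(model)
            if state.ok:
                p_values.append(mass_fraction_to_coefficient(float(f_i), mw))
                mu_values.append(state.objective_value)
        if len(p_values) < MIN_GRID_POINTS:
            skipped += 1
            logger.info("background %d for %s skipped: only %d feasible "
                        "grid points", b, component_id, len(p_values))
            continue
        slope, _intercept = np.polyfit(p_values, mu_values, deg=1)
        slopes.append(float(slope))

    if not slopes:
        raise ValueError(f"no background yielded a regression for "
                         f"{component_id}")
    return SensitivityRecord(
        component_id=component_id,
        metabolite_id=met_id,
        class_label=table.class_of(component_id),
        s_samples=np.asarray(slopes),
        connectivity=_connectivity(model, met_id),
        mw_g_per_mmol=mw,
        n_skipped_backgrounds=skipped,
    )


def sensitivity_report(
    model: Model,
    table: CompositionTable,
    components: Sequence[str] | None = None,
    costs: Mapping[str, float] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Sensitivity records for many components as a tidy table."""
    components = list(components) if components is not None \
        else table.components
    rows = []
    for comp in components:
        rec = sensitivity_of(model, comp, table, **kwargs)
        rows.append({
            "component_id": rec.component_id,
            "metabolite_id": rec.metabolite_id,
            "class": rec.class_label,
            "s_mean": rec.s_mean,
            "s_mean_per_fraction": rec.s_mean_per_fraction,
            "d": rec.d,
            "connectivity": rec.connectivity,
            "cost_ATP": (costs or {}).get(comp, np.nan),
            "n_backgrounds": len(rec.s_samples),
            "n_skipped": rec.n_skipped_backgrounds,
        })
    return pd.DataFrame(rows)


def correlate(x_values: Sequence[float],
              y_values: Sequence[float]) -> CorrelationResult:
    """Ordinary least-squares R², two-sided p for nonzero slope, and slope."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(r2=float(fit.rvalue ** 2),
                             p_value=float(fit.pvalue),
                             slope=float(fit.slope),
                             intercept=float(fit.intercept))
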