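"""Synthetic study system: a three-compartment toy model and a
nitrogen-starvation composition time course with closed-form ground truth.

The toy cell takes up a single nitrogen-containing substrate (a
glucosamine-like species, C6H13NO5) through the extracellular space (e)
into the cytosol (c), respires part of it in the mitochondrion (m) at a
fixed ATP yield, and polymerizes the rest into biomass precursors
(amino-acid-, lipid-, carbohydrate- and nucleotide-like pools), each with
its own substrate requirement and ATP demand.  Because the network has a
single limiting resource, growth rate, per-component growth sensitivities,
biosynthetic costs and compartment element loads all have closed forms,
which the :class:`GroundTruth` object exposes as oracles.

The default composition trend mimics nitrogen starvation: the protein-like
fraction falls while lipid- and carbohydrate-like fractions rise over six
relative-time stages, so growth slows, mitochondrial carbon and nitrogen
loads decline, lipid-synthesis flux rises and protein-synthesis flux falls
— the qualitative fingerprints the pipeline is meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .bof_builder import CompositionTable
from .model_core import formula_weight, parse_formula

__all__ = ["Precursor", "ToySpec", "GroundTruth", "make_toy_model",
           "make_timecourse_composition", "random_toy_spec", "write_toy_fixtures"]

#: substrate formula: glucosamine-like, carries both carbon and nitrogen.
SUBSTRATE_FORMULA = {"C": 6, "H": 13, "N": 1, "O": 5}

_SMALL_FORMULAS = {
    "o2": {"O": 2},
    "co2": {"C": 1, "O": 2},
    "nh3": {"N": 1, "H": 3},
    "h2o": {"H": 2, "O": 1},
    "h": {"H": 1},
    "atp": {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3},
    "adp": {"C": 10, "H": 12, "N": 5, "O": 10, "P": 2},
    "pi": {"H": 1, "O": 4, "P": 1},
}


def _fstr(counts: Mapping[str, int]) -> str:
    return "".join(f"{el}{n}" for el, n in counts.items() if n)


@dataclass(frozen=True)
class Precursor:
    """One biomass component of the toy cell.

    size
        Number of substrate units retained in the product (sets formula
        and molecular weight).
    substrate
        mmol substrate consumed per mmol product (≥ size; the excess is
        oxidized to CO2/H2O/NH3 during synthesis, the way fatty-acid
        synthesis loses carbon).
    atp
        mmol ATP hydrolyzed per mmol product.
    """

    id: str
    class_label: str
    size: int
    substrate: int
    atp: float

    def __post_init__(self) -> None:
        if self.size < 1 or self.substrate < self.size:
            raise ValueError(
                f"precursor {self.id}: need 1 <= size <= substrate")
        if self.atp <= 0:
            raise ValueError(f"precursor {self.id}: atp cost must be > 0")

    @property
    def formula(self) -> Dict[str, int]:
        return {el: n * self.size for el, n in SUBSTRATE_FORMULA.items()}

    @property
    def mw_g_per_mmol(self) -> float:
        return self.size * formula_weight(SUBSTRATE_FORMULA) / 1000.0


DEFAULT_PRECURSORS = (
    Precursor("prot", "AA", size=2, substrate=2, atp=8.0),
    Precursor("lip", "FA", size=2, substrate=4, atp=2.0),
    Precursor("carb", "CB", size=1, substrate=1, atp=1.0),
    Precursor("nuc", "Nuc", size=2, substrate=2, atp=5.0),
)

#: (start, end) mass fractions over the six stages: protein falls,
#: lipid and carbohydrate rise, nucleotides stay flat; each column sums to 1.
DEFAULT_TREND = {
    "prot": (0.55, 0.25),
    "lip": (0.10, 0.30),
    "carb": (0.25, 0.35),
    "nuc": (0.10, 0.10),
}


@dataclass
class ToySpec:
    """Parameters of the synthetic study system (units mirror the field:
    mmol/gDW/h for fluxes, g/gDW for fractions, h^-1 for growth)."""

    precursors: Tuple[Precursor, ...] = DEFAULT_PRECURSORS
    uptake_bound: float = 10.0          # U, mmol substrate/gDW/h
    atp_yield: float = 10.0             # Y, mmol ATP per mmol substrate respired
    gam: float = 0.0                    # maintenance ATP, mmol/gDW
    trend: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TREND))
    n_timepoints: int = 6
    with_futile_cycle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.uptake_bound <= 0 or self.atp_yield <= 0:
            raise ValueError("uptake_bound and atp_yield must be positive")
        if set(self.trend) != {p.id for p in self.precursors}:
            raise ValueError("trend keys must match precursor ids")
        for t in (0, 1):
            total = sum(v[t] for v in self.trend.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"trend fractions must sum to 1 at both ends, got {total}")
        if any(not (0 <= v[t] <= 1) for v in self.trend.values() for t in (0, 1)):
            raise ValueError("trend fractions must lie in [0, 1]")

    def precursor(self, pid: str) -> Precursor:
        for p in self.precursors:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def narrowed(self, scale: float) -> "ToySpec":
        """Shrink the composition trend around its per-component midpoint.

        Deviations from the midpoint are multiplied by ``scale`` (0 gives
        a constant table); per-timepoint sums stay at 1 because the
        midpoints sum to 1 and the deviations sum to 0.  Narrow trends
        make the observed ranges small, which is the regime where an OLS
        slope of μ against p_i approximates the derivative ∂μ/∂p_i.
        """
        if not 0 <= scale <= 1:
            raise ValueError("scale must lie in [0, 1]")
        trend = {}
        for pid, (lo, hi) in self.trend.items():
            mid = 0.5 * (lo + hi)
            trend[pid] = (mid + (lo - mid) * scale, mid + (hi - mid) * scale)
        return ToySpec(precursors=self.precursors,
                       uptake_bound=self.uptake_bound,
                       atp_yield=self.atp_yield, gam=self.gam, trend=trend,
                       n_timepoints=self.n_timepoints,
                       with_futile_cycle=self.with_futile_cycle,
                       seed=self.seed)


@dataclass
class GroundTruth:
    """Closed-form oracles for the toy system.

    With mass fractions f_j, coefficients p_j = f_j/MW_j, per-precursor
    total cost k_j = substrate_j + atp_j/Y and maintenance gam, growth is

        μ = U / (Σ_j p_j·k_j + gam/Y),

    sensitivities are ∂μ/∂p_i = −U·k_i / (Σ_j p_j·k_j + gam/Y)², and the
    ATP biosynthetic cost of precursor i is atp_i + Y·substrate_i (direct
    ATP demand plus the opportunity cost of the diverted substrate).
    """

    spec: ToySpec
    mu_of: Callable[[Mapping[str, float]], float]
    coefficients_of: Callable[[Mapping[str, float]], Dict[str, float]]
    s_analytic: Callable[[Mapping[str, float], str], float]
    a_analytic: Callable[[str], float]
    fluxes_of: Callable[[Mapping[str, float]], Dict[str, float]]
    loads_of: Callable[[Mapping[str, float]], Dict[Tuple[str, str], float]]


def _denominator(spec: ToySpec, fractions: Mapping[str, float]) -> float:
    total = spec.gam / spec.atp_yield
    for p in spec.precursors:
        pj = fractions.get(p.id, 0.0) / p.mw_g_per_mmol
        total += pj * (p.substrate + p.atp / spec.atp_yield)
    return total


def make_toy_model(spec: ToySpec | None = None) -> Tuple[Model, GroundTruth]:
    """Build the toy model and its ground-truth oracles.

    The biomass reaction is installed with the stage-1 composition of the
    trend so the returned model is immediately solvable; time-course
    analyses replace it per timepoint.
    """
    spec = spec or ToySpec()
    model = Model("toy_nstarve")
    model.compartments = {"e": "extracellular", "c": "cytosol",
                          "m": "mitochondrion"}

    mets: Dict[str, Metabolite] = {}

    def met(base: str, comp: str, counts: Mapping[str, int]) -> Metabolite:
        mid = f"{base}_{comp}"
        if mid not in mets:
            mets[mid] = Metabolite(mid, formula=_fstr(counts), name=base,
                                   compartment=comp)
        return mets[mid]

    s = {comp: met("s", comp, SUBSTRATE_FORMULA) for comp in "ecm"}
    small = {name: {comp: met(name, comp, counts) for comp in comps}
             for name, counts, comps in [
                 ("o2", _SMALL_FORMULAS["o2"], "ecm"),
                 ("co2", _SMALL_FORMULAS["co2"], "ecm"),
                 ("nh3", _SMALL_FORMULAS["nh3"], "ecm"),
                 ("h2o", _SMALL_FORMULAS["h2o"], "ecm"),
                 ("h", _SMALL_FORMULAS["h"], "cm"),
                 ("atp", _SMALL_FORMULAS["atp"], "cm"),
                 ("adp", _SMALL_FORMULAS["adp"], "cm"),
                 ("pi", _SMALL_FORMULAS["pi"], "cm"),
             ]}

    reactions: List[Reaction] = []

    def rxn(rid: str, stoich: Mapping[Metabolite, float],
            lb: float, ub: float, subsystem: str = "") -> Reaction:
        r = Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.subsystem = subsystem
        reactions.append(r)
        r._toy_stoich = dict(stoich)  # attached after add_reactions
        return r

    U, Y = spec.uptake_bound, spec.atp_yield

    # exchanges (single-compartment boundary reactions in e)
    rxn("EX_s", {s["e"]: -1}, -U, 1000.0, "exchange")
    rxn("EX_o2", {small["o2"]["e"]: -1}, -1000.0, 1000.0, "exchange")
    rxn("EX_co2", {small["co2"]["e"]: -1}, 0.0, 1000.0, "exchange")
    rxn("EX_nh3", {small["nh3"]["e"]: -1}, 0.0, 1000.0, "exchange")
    rxn("EX_h2o", {small["h2o"]["e"]: -1}, -1000.0, 1000.0, "exchange")

    # transporters e<->c and c<->m (all reversible, written in the
    # physiological forward direction)
    rxn("T_s_ec", {s["e"]: -1, s["c"]: 1}, -1000.0, 1000.0, "transport")
    rxn("T_s_cm", {s["c"]: -1, s["m"]: 1}, -1000.0, 1000.0, "transport")
    rxn("T_o2_ec", {small["o2"]["e"]: -1, small["o2"]["c"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("T_o2_cm", {small["o2"]["c"]: -1, small["o2"]["m"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("T_co2_mc", {small["co2"]["m"]: -1, small["co2"]["c"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("T_co2_ce", {small["co2"]["c"]: -1, small["co2"]["e"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("T_nh3_mc", {small["nh3"]["m"]: -1, small["nh3"]["c"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("T_nh3_ce", {small["nh3"]["c"]: -1, small["nh3"]["e"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("T_h2o_mc", {small["h2o"]["m"]: -1, small["h2o"]["c"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("T_h2o_ce", {small["h2o"]["c"]: -1, small["h2o"]["e"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("T_h_cm", {small["h"]["c"]: -1, small["h"]["m"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("T_pi_cm", {small["pi"]["c"]: -1, small["pi"]["m"]: 1},
        -1000.0, 1000.0, "transport")
    rxn("ANT", {small["atp"]["m"]: -1, small["adp"]["c"]: -1,
                small["atp"]["c"]: 1, small["adp"]["m"]: 1},
        -1000.0, 1000.0, "transport")

    # respiration in m: substrate combustion coupled to ATP synthesis
    rxn("RESP", {s["m"]: -1, small["o2"]["m"]: -6,
                 small["adp"]["m"]: -Y, small["pi"]["m"]: -Y,
                 small["h"]["m"]: -Y,
                 small["co2"]["m"]: 6, small["h2o"]["m"]: 5 + Y,
                 small["nh3"]["m"]: 1, small["atp"]["m"]: Y},
        0.0, 1000.0, "energy metabolism")

    # cytosolic ATP hydrolysis (maintenance / cost objective)
    rxn("ATPM", {small["atp"]["c"]: -1, small["h2o"]["c"]: -1,
                 small["adp"]["c"]: 1, small["pi"]["c"]: 1,
                 small["h"]["c"]: 1},
        0.0, 1000.0, "energy metabolism")

    # per-precursor synthesis in c
    synthesis_subsystem = {"AA": "amino acid metabolism",
                           "FA": "lipid metabolism",
                           "CB": "carbohydrate metabolism",
                           "Nuc": "nucleotide metabolism"}
    for p in spec.precursors:
        pm = met(p.id, "c", p.formula)
        waste = p.substrate - p.size
        stoich: Dict[Metabolite, float] = {
            s["c"]: -float(p.substrate),
            small["atp"]["c"]: -p.atp, small["h2o"]["c"]: -p.atp,
            pm: 1.0,
            small["adp"]["c"]: p.atp, small["pi"]["c"]: p.atp,
            small["h"]["c"]: p.atp,
        }
        if waste:
            stoich[small["o2"]["c"]] = -6.0 * waste
            stoich[small["co2"]["c"]] = 6.0 * waste
            stoich[small["h2o"]["c"]] = stoich[small["h2o"]["c"]] + 5.0 * waste
            stoich[small["nh3"]["c"]] = float(waste)
        rxn(f"SYN_{p.id}", stoich, 0.0, 1000.0,
            synthesis_subsystem.get(p.class_label, "biosynthesis"))

    if spec.with_futile_cycle:
        fut = met("fut", "c", SUBSTRATE_FORMULA)
        rxn("FUTA", {s["c"]: -1, fut: 1}, 0.0, 1000.0, "futile")
        rxn("FUTB", {fut: -1, s["c"]: 1}, 0.0, 1000.0, "futile")

    # biomass placeholder with the stage-1 composition
    start_fracs = {pid: v[0] for pid, v in spec.trend.items()}
    bio_stoich: Dict[Metabolite, float] = {}
    for p in spec.precursors:
        pj = start_fracs[p.id] / p.mw_g_per_mmol
        bio_stoich[mets[f"{p.id}_c"]] = -pj
    if spec.gam > 0:
        for role, sign in [("atp", -1), ("h2o", -1), ("adp", 1),
                           ("pi", 1), ("h", 1)]:
            m_ = small[role]["c"] if role != "h2o" else small["h2o"]["c"]
            bio_stoich[m_] = bio_stoich.get(m_, 0.0) + sign * spec.gam
    rxn("BIOMASS", bio_stoich, 0.0, 1000.0, "biomass")

    model.add_reactions(reactions)
    for r in reactions:
        r.add_metabolites(r._toy_stoich)
        del r._toy_stoich
    model.objective = "BIOMASS"

    return model, _ground_truth(spec)


def _ground_truth(spec: ToySpec) -> GroundTruth:
    U, Y = spec.uptake_bound, spec.atp_yield

    def coefficients_of(fr: Mapping[str, float]) -> Dict[str, float]:
        return {p.id: fr.get(p.id, 0.0) / p.mw_g_per_mmol
                for p in spec.precursors}

    def mu_of(fr: Mapping[str, float]) -> float:
        return U / _denominator(spec, fr)

    def s_analytic(fr: Mapping[str, float], pid: str) -> float:
        p = spec.precursor(pid)
        k = p.substrate + p.atp / Y
        return -U * k / _denominator(spec, fr) ** 2

    def a_analytic(pid: str) -> float:
        p = spec.precursor(pid)
        return p.atp + Y * p.substrate

    def fluxes_of(fr: Mapping[str, float]) -> Dict[str, float]:
        mu = mu_of(fr)
        pj = coefficients_of(fr)
        syn = {p.id: mu * pj[p.id] for p in spec.precursors}
        atp_demand = mu * (spec.gam +
                           sum(p.atp * pj[p.id] for p in spec.precursors))
        v_resp = atp_demand / Y
        waste_o2 = sum(6.0 * (p.substrate - p.size) * syn[p.id]
                       for p in spec.precursors)
        waste_co2 = waste_o2
        waste_nh3 = sum((p.substrate - p.size) * syn[p.id]
                        for p in spec.precursors)
        waste_h2o = sum(5.0 * (p.substrate - p.size) * syn[p.id]
                        for p in spec.precursors)
        uptake = v_resp + sum(p.substrate * syn[p.id] for p in spec.precursors)
        # water consumed in c: a_j per SYN_j flux plus gam per unit growth,
        # which together equal the total ATP demand rate.
        h2o_net_c = (5 + Y) * v_resp + waste_h2o - atp_demand
        fluxes = {
            "EX_s": -uptake, "EX_o2": -(6 * v_resp + waste_o2),
            "EX_co2": 6 * v_resp + waste_co2, "EX_nh3": v_resp + waste_nh3,
            "EX_h2o": h2o_net_c,
            "T_s_ec": uptake, "T_s_cm": v_resp,
            "T_o2_ec": 6 * v_resp + waste_o2, "T_o2_cm": 6 * v_resp,
            "T_co2_mc": 6 * v_resp, "T_co2_ce": 6 * v_resp + waste_co2,
            "T_nh3_mc": v_resp, "T_nh3_ce": v_resp + waste_nh3,
            "T_h2o_mc": (5 + Y) * v_resp, "T_h2o_ce": h2o_net_c,
            "T_h_cm": atp_demand, "T_pi_cm": atp_demand,
            "ANT": atp_demand, "RESP": v_resp, "ATPM": 0.0,
            "BIOMASS": mu,
        }
        for p in spec.precursors:
            fluxes[f"SYN_{p.id}"] = syn[p.id]
        if spec.with_futile_cycle:
            fluxes["FUTA"] = 0.0
            fluxes["FUTB"] = 0.0
        return fluxes

    # per-compartment inbound species for each transporter written in its
    # forward direction: (reaction, produced metabolite base, compartment)
    _inbound = [
        ("T_s_ec", "s", "c", SUBSTRATE_FORMULA),
        ("T_s_cm", "s", "m", SUBSTRATE_FORMULA),
        ("T_o2_ec", "o2", "c", _SMALL_FORMULAS["o2"]),
        ("T_o2_cm", "o2", "m", _SMALL_FORMULAS["o2"]),
        ("T_co2_mc", "co2", "c", _SMALL_FORMULAS["co2"]),
        ("T_co2_ce", "co2", "e", _SMALL_FORMULAS["co2"]),
        ("T_nh3_mc", "nh3", "c", _SMALL_FORMULAS["nh3"]),
        ("T_nh3_ce", "nh3", "e", _SMALL_FORMULAS["nh3"]),
        ("T_h2o_mc", "h2o", "c", _SMALL_FORMULAS["h2o"]),
        ("T_h2o_ce", "h2o", "e", _SMALL_FORMULAS["h2o"]),
        ("T_h_cm", "h", "m", _SMALL_FORMULAS["h"]),
        ("T_pi_cm", "pi", "m", _SMALL_FORMULAS["pi"]),
        ("ANT", "atp", "c", _SMALL_FORMULAS["atp"]),
        ("ANT", "adp", "m", _SMALL_FORMULAS["adp"]),
    ]

    def loads_of(fr: Mapping[str, float]) -> Dict[Tuple[str, str], float]:
        """(compartment, element) → inbound element load at the optimum."""
        fluxes = fluxes_of(fr)
        out: Dict[Tuple[str, str], float] = {}
        for rid, _base, comp, counts in _inbound:
            v = fluxes[rid]
            # v > 0 produces the listed species in `comp`; v < 0 produces
            # the mirror species in the opposite compartment, which is not
            # in this row's compartment.
            if v <= 0:
                continue
            for el, n in counts.items():
                out[(comp, el)] = out.get((comp, el), 0.0) + v * n
        return out

    return GroundTruth(spec=spec, mu_of=mu_of, coefficients_of=coefficients_of,
                       s_analytic=s_analytic, a_analytic=a_analytic,
                       fluxes_of=fluxes_of, loads_of=loads_of)


def make_timecourse_composition(spec: ToySpec | None = None) -> CompositionTable:
    """Six-stage composition table following the spec's starvation trend.

    Fractions interpolate linearly between the trend's start and end
    values, so each stage's fractions sum to exactly 1 g/gDW.
    """
    spec = spec or ToySpec()
    rows = []
    T = spec.n_timepoints
    for p in spec.precursors:
        lo, hi = spec.trend[p.id]
        fr = np.linspace(lo, hi, T)
        row = {"component_id": p.id, "metabolite_id": f"{p.id}_c",
               "class": p.class_label, "mw_g_per_mmol": p.mw_g_per_mmol}
        row.update({f"t{k + 1}": fr[k] for k in range(T)})
        rows.append(row)
    return CompositionTable(pd.DataFrame(rows))


def random_toy_spec(rng: np.random.Generator) -> ToySpec:
    """Draw a random but valid ToySpec (used for randomized FBA oracles)."""
    n = int(rng.integers(3, 6))
    precursors = []
    for i in range(n):
        size = int(rng.integers(1, 4))
        substrate = size + int(rng.integers(0, 3))
        atp = float(rng.uniform(0.5, 10.0))
        precursors.append(Precursor(f"p{i}", "AA" if i % 2 else "FA",
                                    size=size, substrate=substrate, atp=atp))
    start = rng.dirichlet(np.ones(n))
    end = rng.dirichlet(np.ones(n))
    trend = {p.id: (float(start[i]), float(end[i]))
             for i, p in enumerate(precursors)}
    return ToySpec(
        precursors=tuple(precursors),
        uptake_bound=float(rng.uniform(2.0, 20.0)),
        atp_yield=float(rng.uniform(4.0, 20.0)),
        gam=float(rng.uniform(0.0, 2.0)),
        trend=trend,
    )


def write_toy_fixtures(directory: str | Path,
                       spec: ToySpec | None = None) -> Dict[str, Path]:
    """Write the toy model (SBML + JSON) and composition table (TSV).

    The written files double as format-conformance fixtures for the
    readers in :mod:`dynabof.model_core`.
    """
    from .model_core import write_model

    spec = spec or ToySpec()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model, _ = make_toy_model(spec)
    paths = {
        "sbml": directory / "toy_model.xml",
        "json": directory / "toy_model.json",
        "composition": directory / "toy_composition.tsv",
    }
    write_model(model, paths["sbml"])
    write_model(model, paths["json"])
    make_timecourse_composition(spec).to_tsv(paths["composition"])
    return paths
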