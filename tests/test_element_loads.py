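"""Compartment element loads: per-metabolite terms, brute-force summation
oracle, steady-state closure and direction-convention invariance."""

import numpy as np
import pandas as pd
import pytest
from cobra import Metabolite, Model, Reaction

from dynabof.bof_builder import build_bof
from dynabof.dynamic_fluxes import run_timecourse
from dynabof.element_loads import (compartment_load, load_timecourse,
                                   metabolite_load, relative_activity)
from dynabof.fba_engine import FluxState, solve_fba
from dynabof.model_core import (metabolite_compartment, parse_formula,
                                transport_reactions)


@pytest.fixture(scope="module")
def timecourse(toy_model, composition):
    bofs = [build_bof(toy_model, composition, t)
            for t in composition.timepoints]
    return run_timecourse(toy_model, bofs)


def _glutamate_transport_model():
    """glu[c] -> glu[m] importer, for hand-checkable single terms."""
    model = Model("glu")
    gc = Metabolite("glu_c", compartment="c", formula="C5H8NO4")
    gm = Metabolite("glu_m", compartment="m", formula="C5H8NO4")
    t = Reaction("T_glu", lower_bound=-1000, upper_bound=1000)
    dm = Reaction("DM_glu_m", lower_bound=-1000, upper_bound=1000)
    sk = Reaction("SK_glu_c", lower_bound=-1000, upper_bound=1000)
    model.add_reactions([t, dm, sk])
    t.add_metabolites({gc: -1, gm: 1})
    dm.add_metabolites({gm: -1})
    sk.add_metabolites({gc: 1})
    model.objective = "DM_glu_m"
    return model


class TestMetaboliteLoad:
    def test_import_counts_carbon_atoms(self):
        model = _glutamate_transport_model()
        state = FluxState(pd.Series({"T_glu": 2.0, "DM_glu_m": 2.0,
                                     "SK_glu_c": 2.0}), 2.0, "optimal")
        # v=2 producing glu (C5) in m: l = 2 * 1 * 5
        assert metabolite_load(model, state, "T_glu", "glu_m", "m", "C") == 10

    def test_consumed_side_contributes_zero(self):
        model = _glutamate_transport_model()
        state = FluxState(pd.Series({"T_glu": 2.0, "DM_glu_m": 2.0,
                                     "SK_glu_c": 2.0}), 2.0, "optimal")
        assert metabolite_load(model, state, "T_glu", "glu_c", "c", "C") == 0

    def test_negative_flux_flips_production_side(self):
        model = _glutamate_transport_model()
        state = FluxState(pd.Series({"T_glu": -3.0}), 0.0, "optimal")
        # running m -> c: glu_c is now produced, glu_m is consumed
        assert metabolite_load(model, state, "T_glu", "glu_c", "c", "N") == 3
        assert metabolite_load(model, state, "T_glu", "glu_m", "m", "N") == 0

    def test_metabolite_without_formula_contributes_zero_with_warning(self):
        model = _glutamate_transport_model()
        model.metabolites.glu_m.formula = ""
        state = FluxState(pd.Series({"T_glu": 2.0}), 0.0, "optimal")
        with pytest.warns(UserWarning, match="no formula"):
            assert metabolite_load(model, state, "T_glu", "glu_m",
                                   "m", "C") == 0.0


class TestCompartmentLoad:
    def test_pyruvate_style_importer(self):
        # single importer of a C3 species at v=4 -> L_C = 12
        model = Model("pyr")
        pc = Metabolite("pyr_c", compartment="c", formula="C3H3O3")
        pm = Metabolite("pyr_m", compartment="m", formula="C3H3O3")
        t = Reaction("T_pyr", lower_bound=-1000, upper_bound=1000)
        sk = Reaction("SK_pyr_c", lower_bound=-1000, upper_bound=1000)
        dm = Reaction("DM_pyr_m", lower_bound=-1000, upper_bound=1000)
        model.add_reactions([t, sk, dm])
        t.add_metabolites({pc: -1, pm: 1})
        sk.add_metabolites({pc: 1})
        dm.add_metabolites({pm: -1})
        state = FluxState(pd.Series({"T_pyr": 4.0, "SK_pyr_c": 4.0,
                                     "DM_pyr_m": 4.0}), 0.0, "optimal")
        assert compartment_load(model, state, "m", "C") == 12.0

    def test_compartment_without_transporters_is_zero(self):
        model = Model("iso")
        a = Metabolite("a_x", compartment="x", formula="C2H4")
        b = Metabolite("b_c", compartment="c", formula="C2H4")
        r1 = Reaction("R_int", lower_bound=0, upper_bound=10)
        r2 = Reaction("SK_b", lower_bound=-10, upper_bound=10)
        model.add_reactions([r1, r2])
        r1.add_metabolites({a: -1, a: -1})  # degenerate self-reaction
        r2.add_metabolites({b: 1})
        state = FluxState(pd.Series({"R_int": 1.0, "SK_b": 1.0}),
                          0.0, "optimal")
        assert compartment_load(model, state, "x", "C") == 0.0

    def test_unknown_compartment_raises(self, toy_model):
        state = solve_fba(toy_model)
        with pytest.raises(KeyError):
            compartment_load(toy_model, state, "zz", "C")

    def test_matches_brute_force_double_loop(self, toy_model, timecourse):
        state = timecourse.states[0]
        transports = transport_reactions(toy_model)
        for comp in ("e", "c", "m"):
            for el in ("C", "N", "O", "P", "H"):
                total = 0.0
                for rid in transports:
                    rxn = toy_model.reactions.get_by_id(rid)
                    for met, gamma in rxn.metabolites.items():
                        if metabolite_compartment(met) != comp:
                            continue
                        n = parse_formula(met.formula).get(el, 0)
                        total += max(state[rid] * gamma, 0.0) * n
                assert compartment_load(toy_model, state, comp, el) == \
                    pytest.approx(total, abs=1e-9)

    def test_matches_closed_form_at_every_timepoint(self, toy_model,
                                                    ground_truth,
                                                    composition, timecourse):
        for t, state in zip(timecourse.timepoints, timecourse.states):
            expected = ground_truth.loads_of(dict(composition.fractions(t)))
            for (comp, el), val in expected.items():
                assert compartment_load(toy_model, state, comp, el) == \
                    pytest.approx(val, abs=1e-6)

    def test_currency_exclusion_drops_water_and_protons(self, toy_model,
                                                        timecourse):
        state = timecourse.states[0]
        with_currency = compartment_load(toy_model, state, "m", "H")
        without = compartment_load(toy_model, state, "m", "H",
                                   include_currency=False)
        assert without < with_currency  # water/proton hydrogen removed


class TestClosure:
    def test_influx_equals_efflux_plus_biomass_incorporation(
            self, toy_model, timecourse):
        """Steady state: what transport brings into a compartment leaves it
        again through transport, boundary fluxes or the biomass drain."""
        transports = transport_reactions(toy_model)
        for state in timecourse.states:
            for comp in ("c", "m", "e"):
                for el in ("C", "N", "P"):
                    influx = efflux = removal = 0.0
                    for rxn in toy_model.reactions:
                        for met, gamma in rxn.metabolites.items():
                            if metabolite_compartment(met) != comp:
                                continue
                            n = parse_formula(met.formula).get(el, 0)
                            term = state[rxn.id] * gamma * n
                            if rxn.id in transports:
                                influx += max(term, 0.0)
                                efflux += max(-term, 0.0)
                            elif rxn.id == "BIOMASS" or rxn.boundary:
                                removal += -term
                    assert influx - efflux == pytest.approx(removal,
                                                            abs=1e-6)

    def test_loads_invariant_under_transporter_mirroring(self, toy_spec,
                                                         composition):
        from dynabof.synthetic_data import make_toy_model

        model, _ = make_toy_model(toy_spec)
        mirrored, _ = make_toy_model(toy_spec)
        rxn = mirrored.reactions.T_s_cm
        stoich = {m: c for m, c in rxn.metabolites.items()}
        rxn.subtract_metabolites(stoich)
        rxn.add_metabolites({m: -c for m, c in stoich.items()})

        bof = build_bof(model, composition, "t1")
        tc_a = run_timecourse(model, [bof, bof])
        tc_b = run_timecourse(mirrored, [bof, bof])
        for comp in ("c", "m"):
            for el in ("C", "N"):
                a = compartment_load(model, tc_a.states[0], comp, el)
                b = compartment_load(mirrored, tc_b.states[0], comp, el)
                assert a == pytest.approx(b, abs=1e-6)


class TestRelativeActivity:
    def test_constant_loads_give_unit_series(self):
        loads = pd.DataFrame({
            "compartment": ["m"] * 3, "element": ["C"] * 3,
            "timepoint": ["t1", "t2", "t3"], "load": [5.0, 5.0, 5.0]})
        ra = relative_activity(loads)
        assert ra["relative_activity"].tolist() == [1.0, 1.0, 1.0]

    def test_halving_load(self):
        loads = pd.DataFrame({
            "compartment": ["m"] * 2, "element": ["C"] * 2,
            "timepoint": ["t1", "t2"], "load": [2.0, 1.0]})
        assert relative_activity(loads)["relative_activity"].tolist() == \
            [1.0, 0.5]

    def test_zero_initial_load_flagged_undefined(self):
        loads = pd.DataFrame({
            "compartment": ["m"] * 2, "element": ["C"] * 2,
            "timepoint": ["t1", "t2"], "load": [0.0, 1.0]})
        ra = relative_activity(loads)
        assert ra["relative_activity"].isna().all()

    def test_mitochondrial_activity_declines_under_starvation(
            self, toy_model, timecourse):
        loads = load_timecourse(toy_model, timecourse)
        ra = relative_activity(loads)
        for el in ("C", "N"):
            series = ra[(ra.compartment == "m")
                        & (ra.element == el)]["relative_activity"].tolist()
            assert series[0] == pytest.approx(1.0)
            assert all(a > b for a, b in zip(series, series[1:]))
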