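"""Composition → BOF conversion: unit conversion, producibility screening,
exclusion-renormalization and installation."""

import numpy as np
import pandas as pd
import pytest

from dynabof.bof_builder import (BiomassFunction, CompositionTable, build_bof,
                                 install_bof, mass_fraction_to_coefficient,
                                 test_producibility as producible)
from dynabof.fba_engine import solve_fba
from dynabof.synthetic_data import make_timecourse_composition, make_toy_model


class TestMassFractionConversion:
    def test_glucose_like_example(self):
        # 0.18 g/gDW at 0.1802 g/mmol -> 0.9989 mmol/gDW
        assert mass_fraction_to_coefficient(0.18, 0.1802) == pytest.approx(
            0.99889, abs=1e-5)

    def test_zero_fraction(self):
        assert mass_fraction_to_coefficient(0.0, 0.5) == 0.0

    @pytest.mark.parametrize("mw", [0.0, -1.0])
    def test_nonpositive_mw_rejected(self, mw):
        with pytest.raises(ValueError):
            mass_fraction_to_coefficient(0.1, mw)

    def test_full_table_matches_hand_division(self, composition):
        # independent spreadsheet-style recomputation: fraction/mw per cell
        for t in composition.timepoints:
            fr = composition.fractions(t)
            for comp in composition.components:
                expected = fr[comp] / composition.mw_of(comp)
                got = mass_fraction_to_coefficient(
                    fr[comp], composition.mw_of(comp))
                assert got == pytest.approx(expected, rel=1e-12)


class TestProducibility:
    def test_precursors_producible(self, toy_model):
        for pid in ("prot_c", "lip_c", "carb_c", "nuc_c"):
            assert producible(toy_model, pid)

    def test_metabolite_without_producer_not_producible(self, fresh_toy):
        model, _ = fresh_toy
        model.remove_reactions(["SYN_lip"])
        assert not producible(model, "lip_c")
        assert producible(model, "prot_c")

    def test_no_demand_reaction_leaks(self, toy_model):
        n = len(toy_model.reactions)
        producible(toy_model, "prot_c")
        assert len(toy_model.reactions) == n


class TestBuildBOF:
    def test_all_feasible_no_exclusions_no_rescale(self, toy_model,
                                                   composition):
        bof = build_bof(toy_model, composition, "t1")
        assert bof.excluded == []
        fr = composition.fractions("t1")
        for comp in composition.components:
            met = composition.metabolite_of(comp)
            assert bof.coefficients[met] == pytest.approx(
                fr[comp] / composition.mw_of(comp), rel=1e-12)

    def test_mass_closure_exact(self, toy_model, composition):
        for t in composition.timepoints:
            bof = build_bof(toy_model, composition, t)
            assert bof.mass_drained() == pytest.approx(1.0, abs=1e-9)

    def test_excluded_component_triggers_renormalization(self, fresh_toy,
                                                         composition):
        model, _ = fresh_toy
        model.remove_reactions(["SYN_lip"])
        bof = build_bof(model, composition, "t1")
        assert ("lip_c", "not producible") in bof.excluded
        fr = composition.fractions("t1")
        surviving = fr.drop("lip")
        rescale = 1.0 / surviving.sum()   # 1/(1 - 0.10) at t1
        assert rescale == pytest.approx(1.0 / 0.9)
        for comp in surviving.index:
            met = composition.metabolite_of(comp)
            assert bof.coefficients[met] == pytest.approx(
                fr[comp] * rescale / composition.mw_of(comp), rel=1e-9)
        assert bof.mass_drained() == pytest.approx(1.0, abs=1e-9)

    def test_protein_coefficient_decreases_along_starvation(self, toy_model,
                                                            composition):
        coeffs = [build_bof(toy_model, composition, t).coefficients["prot_c"]
                  for t in composition.timepoints]
        assert all(a > b for a, b in zip(coeffs, coeffs[1:]))

    def test_exclusion_set_is_order_independent(self, fresh_toy, composition):
        model, _ = fresh_toy
        model.remove_reactions(["SYN_lip"])
        reference = set(build_bof(model, composition, "t1").excluded)
        rng = np.random.default_rng(7)
        for _ in range(3):
            shuffled = CompositionTable(
                composition.data.sample(frac=1.0,
                                        random_state=int(rng.integers(1e6))))
            assert set(build_bof(model, shuffled, "t1").excluded) == reference

    def test_all_components_infeasible_raises(self, fresh_toy, composition):
        model, _ = fresh_toy
        model.remove_reactions([f"SYN_{p}" for p in
                                ("prot", "lip", "carb", "nuc")])
        with pytest.raises(ValueError, match="no producible"):
            build_bof(model, composition, "t1")


class TestInstallBOF:
    def test_growth_matches_closed_form(self, toy_model, ground_truth,
                                        composition):
        for t in composition.timepoints:
            bof = build_bof(toy_model, composition, t)
            staged = install_bof(toy_model, bof)
            mu = solve_fba(staged).objective_value
            assert mu == pytest.approx(
                ground_truth.mu_of(dict(composition.fractions(t))), rel=1e-9)

    def test_idempotent(self, toy_model, composition):
        bof = build_bof(toy_model, composition, "t3")
        once = install_bof(toy_model, bof)
        twice = install_bof(once, bof)
        s1 = {m.id: c for m, c in
              once.reactions.BIOMASS.metabolites.items()}
        s2 = {m.id: c for m, c in
              twice.reactions.BIOMASS.metabolites.items()}
        assert s1 == s2

    def test_excluded_component_absent_from_reaction(self, fresh_toy,
                                                     composition):
        model, _ = fresh_toy
        model.remove_reactions(["SYN_lip"])
        bof = build_bof(model, composition, "t1")
        staged = install_bof(model, bof)
        met_ids = {m.id for m in staged.reactions.BIOMASS.metabolites}
        assert "lip_c" not in met_ids

    def test_original_model_untouched(self, toy_model, composition):
        before = {m.id: c for m, c in
                  toy_model.reactions.BIOMASS.metabolites.items()}
        bof = build_bof(toy_model, composition, "t6")
        install_bof(toy_model, bof)
        after = {m.id: c for m, c in
                 toy_model.reactions.BIOMASS.metabolites.items()}
        assert before == after

    def test_unknown_metabolite_raises(self, toy_model):
        bof = BiomassFunction(coefficients={"ghost_c": 1.0},
                              mw={"ghost_c": 0.1})
        with pytest.raises(KeyError):
            install_bof(toy_model, bof)


class TestCompositionTable:
    def test_fractions_sum_to_one_each_stage(self, composition):
        for t in composition.timepoints:
            assert composition.fractions(t).sum() == pytest.approx(1.0)

    def test_align_to_stages_interpolates_preserving_endpoints(
            self, composition):
        # fabricate a 12-point version, then collapse to 6
        data = composition.data.copy()
        old = composition.timepoints
        dense = pd.DataFrame({
            "component_id": data["component_id"],
            "metabolite_id": data["metabolite_id"],
            "class": data["class"],
            "mw_g_per_mmol": data["mw_g_per_mmol"],
        })
        x_old = np.linspace(0, 1, len(old))
        x_new = np.linspace(0, 1, 12)
        for k, x in enumerate(x_new):
            dense[f"t{k+1}"] = [
                np.interp(x, x_old, data.loc[i, old].astype(float))
                for i in data.index]
        coarse = CompositionTable(dense).align_to_stages(6)
        assert coarse.timepoints == [f"t{i}" for i in range(1, 7)]
        for comp in composition.components:
            assert coarse.fractions("t1")[comp] == pytest.approx(
                composition.fractions("t1")[comp])
            assert coarse.fractions("t6")[comp] == pytest.approx(
                composition.fractions("t6")[comp])

    def test_tsv_round_trip(self, composition, tmp_path):
        path = tmp_path / "comp.tsv"
        composition.to_tsv(path)
        again = CompositionTable.from_tsv(path)
        pd.testing.assert_frame_equal(again.data, composition.data)

    def test_negative_fraction_rejected(self, composition):
        data = composition.data.copy()
        data.loc[0, "t1"] = -0.1
        with pytest.raises(ValueError):
            CompositionTable(data)

    def test_overfull_composition_rejected(self, composition):
        data = composition.data.copy()
        data.loc[0, "t1"] = 0.9  # pushes the t1 sum well over 1
        with pytest.raises(ValueError):
            CompositionTable(data)
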