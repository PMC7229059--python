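"""Compartment element loads: how much carbon and nitrogen each
compartment imports per hour, and how that activity decays under
nitrogen starvation.

The load of element e in compartment c sums v_r * gamma_i,r * N_i^e over
the production side of every transport reaction; carbon/nitrogen loads
are the compartment's "activity", reported relative to the first stage.
"""

from dynabof import (ToySpec, build_bof, load_timecourse,
                     make_timecourse_composition, make_toy_model,
                     relative_activity, run_timecourse)

spec = ToySpec()
model, _ = make_toy_model(spec)
table = make_timecourse_composition(spec)
tc = run_timecourse(model, [build_bof(model, table, t)
                            for t in table.timepoints])

loads = relative_activity(load_timecourse(model, tc))
for comp in ("c", "m"):
    for el in ("C", "N"):
        rows = loads[(loads.compartment == comp) & (loads.element == el)]
        series = " ".join(f"{x:.3f}" for x in rows["relative_activity"])
        print(f"{comp}/{el} relative activity: {series}")

print("\nMitochondrial carbon and nitrogen activity falls monotonically: "
      "as protein demand shrinks, less substrate is respired, so the "
      "mitochondrion imports less of everything.")
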