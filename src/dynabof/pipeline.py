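"""End-to-end orchestration: composition table + model → all reports.

``run_all`` executes the full analysis — BOF construction, the loopless
FBA time course, flux-variation clustering, compartment element loads,
per-component sensitivities, biosynthetic costs and sampling-based
regulation calls — writing one TSV per stage plus a JSON manifest with
parameters, seed and per-stage status.  Stages are independent where the
science allows: a failure in one is recorded and later stages that do not
need its output still run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .biosynthetic_cost import cost_report, read_dgf_table
from .bof_builder import CompositionTable, build_bof
from .dynamic_fluxes import flux_variation, run_timecourse, zscore_and_cluster
from .element_loads import load_timecourse, relative_activity
from .model_core import read_model
from .regulation_sampling import (regulation_report, regulation_test,
                                  sample_fluxes, validate_samples)
from .sensitivity import sensitivity_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full run; defaults are the study's parameters
    (100 hypothetical BOFs, 95% growth fix, δ = 1e-4, 90% optimum,
    5000 samples, α = 0.05)."""

    model_path: str
    composition_path: str
    output_dir: str
    model_format: Optional[str] = None
    gam: float = 0.0
    baseline_mode: str = "t0"
    n_clusters: int = 2
    uptake_constraints: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=dict)
    elements: Tuple[str, ...] = ("C", "N")
    n_bofs: int = 100
    n_grid: int = 10
    cost_delta: float = 1e-4
    cost_growth_fraction: float = 0.95
    currencies: Tuple[str, ...] = ("ATP",)
    dgf_path: Optional[str] = None
    sampling_fraction: float = 0.9
    n_samples: int = 5000
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("model_path", "composition_path"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if self.dgf_path and not Path(self.dgf_path).exists():
            raise FileNotFoundError(f"dgf_path: {self.dgf_path}")
        if self.baseline_mode not in ("t0", "consecutive"):
            raise ValueError("baseline_mode must be 't0' or 'consecutive'")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def run_all(config: RunConfig) -> Dict[str, object]:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }

    def stage(name: str):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
                manifest["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.perf_counter() - t0, 3)}
            except Exception as exc:
                logger.exception("stage %s failed", name)
                manifest["stages"][name] = {
                    "status": "failed", "error": str(exc),
                    "seconds": round(time.perf_counter() - t0, 3)}
        return wrap

    model = read_model(config.model_path, config.model_format)
    table = CompositionTable.from_tsv(config.composition_path)

    state: Dict[str, object] = {}

    @stage("bof")
    def _bof():
        bofs = [build_bof(model, table, t, gam=config.gam)
                for t in table.timepoints]
        state["bofs"] = bofs
        for t, bof in zip(table.timepoints, bofs):
            bof.to_tsv(out / f"bof_{t}.tsv")

    @stage("timecourse")
    def _timecourse():
        tc = run_timecourse(model, state["bofs"],
                            timepoints=table.timepoints,
                            uptake_constraints=config.uptake_constraints)
        state["tc"] = tc
        tc.flux_table().to_csv(out / "fluxes.tsv", sep="\t")
        tc.growth_rates().rename("mu").to_csv(out / "growth_rates.tsv",
                                              sep="\t")

    @stage("clustering")
    def _clustering():
        var = flux_variation(state["tc"], config.baseline_mode)
        fv = zscore_and_cluster(var, config.baseline_mode)
        var.to_csv(out / "flux_variation.tsv", sep="\t")
        fv.zscores.to_csv(out / "flux_zscores.tsv", sep="\t")
        pd.DataFrame(fv.linkage_matrix,
                     columns=["left", "right", "height", "size"]).to_csv(
            out / "linkage.tsv", sep="\t", index=False)
        clusters = fv.flat_clusters(config.n_clusters).to_frame()
        clusters["subsystem"] = [
            model.reactions.get_by_id(r).subsystem for r in clusters.index]
        clusters.to_csv(out / "clusters.tsv", sep="\t")

    @stage("loads")
    def _loads():
        loads = load_timecourse(model, state["tc"],
                                elements=config.elements)
        relative_activity(loads).to_csv(out / "element_loads.tsv",
                                        sep="\t", index=False)

    @stage("sensitivity")
    def _sensitivity():
        swept = [c for c in table.components
                 if (lambda r: r[1] > r[0])(table.observed_ranges()[c])]
        report = sensitivity_report(
            model, table, components=swept, gam=config.gam,
            n_bofs=config.n_bofs, n_grid=config.n_grid, seed=config.seed)
        report.to_csv(out / "sensitivity.tsv", sep="\t", index=False)

    @stage("cost")
    def _cost():
        dgf = read_dgf_table(config.dgf_path) if config.dgf_path else None
        mets = [table.metabolite_of(c) for c in table.components]
        report = cost_report(model, mets, currencies=config.currencies,
                             dgf_values=dgf, delta=config.cost_delta,
                             growth_fraction=config.cost_growth_fraction)
        report.to_csv(out / "cost.tsv", sep="\t", index=False)

    @stage("regulation")
    def _regulation():
        from .bof_builder import install_bof
        bofs = state["bofs"]
        first = install_bof(model, bofs[0])
        last = install_bof(model, bofs[-1])
        s0 = sample_fluxes(first, fraction=config.sampling_fraction,
                           n_samples=config.n_samples, seed=config.seed)
        sf = sample_fluxes(last, fraction=config.sampling_fraction,
                           n_samples=config.n_samples, seed=config.seed + 1)
        validate_samples(s0)
        validate_samples(sf)
        calls = regulation_test(s0, sf, alpha=config.alpha)
        regulation_report(calls, model).to_csv(out / "regulation.tsv",
                                               sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
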