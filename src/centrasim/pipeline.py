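"""End-to-end orchestration: simulate → choice sets → fit → scenarios →
burden → equity → report.

Every stage reads and writes the CSV contracts in :mod:`centrasim.io`,
so stages are independently runnable and the whole pipeline is a pure
function of the configuration and seed: identical config + seed yields
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import choice_model, choice_sets, equity, io, scenarios, synthetic

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("centrasim")

SCENARIO_BUILDERS = ("A", "B", "C")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``synthetic`` is set (the cohort is generated) or the three
    input paths point at existing CSVs — not neither.
    """

    out_dir: str
    seed: int = 0
    synthetic: synthetic.SyntheticConfig | None = None
    patients_path: str | None = None
    centers_path: str | None = None
    matrix_path: str | None = None
    max_minutes: float = 180.0
    scenario_list: tuple = ("A", "B", "C")
    volume_threshold: float = 50.0
    make_plots: bool = True

    def validate(self) -> None:
        paths = (self.patients_path, self.centers_path, self.matrix_path)
        if self.synthetic is None and not all(paths):
            raise ValueError("either a synthetic block or all three input paths "
                             "must be provided")
        for s in self.scenario_list:
            if s not in SCENARIO_BUILDERS:
                raise ValueError(f"unknown scenario {s!r}; expected A, B or C")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        raw.update(overrides)
        if "scenario_list" in raw:
            raw["scenario_list"] = tuple(raw["scenario_list"])
        cfg = cls(**raw)
        if syn is not None:
            syn.setdefault("seed", cfg.seed)
            for key in ("region_weights", "covariate_prevalences",
                        "center_attribute_prevalences", "london_center"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def _load_or_generate(config: RunConfig, out: Path, meta: dict):
    if config.synthetic is not None:
        syn = config.synthetic
        patients, centers = synthetic.generate_population(syn)
        matrix = synthetic.build_travel_matrix(patients, centers, syn)
        patients = synthetic.simulate_choices(
            patients, centers, matrix, seed=syn.seed + 1,
            max_minutes=config.max_minutes)
        n_unassigned = int(patients["chosen_center"].isna().sum())
        if n_unassigned:
            log.info("dropping %d patients with no center within %.0f min",
                     n_unassigned, config.max_minutes)
            patients = patients.dropna(subset=["chosen_center"]).reset_index(drop=True)
            matrix = matrix.loc[patients["id"]]
        io.write_patients(patients, out / "patients.csv", meta)
        io.write_centers(centers, out / "centers.csv", meta)
        io.write_matrix(matrix, out / "travel_minutes.csv", meta)
    else:
        patients = io.read_patients(config.patients_path)
        centers = io.read_centers(config.centers_path)
        matrix = io.read_matrix(config.matrix_path)
    return patients, centers, matrix


def _build_scenario(name, cohort, centers, matrix, config: RunConfig):
    if name == "A":
        return scenarios.scenario_volume(centers, config.volume_threshold)
    if name == "B":
        return scenarios.scenario_facilities(centers)
    return scenarios.scenario_capacity(cohort, matrix, centers)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a dict of artifact paths.

    With an empty scenario list the run stops after the choice-model fit
    and only data/fit artifacts are produced.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    meta = {"seed": config.seed, "config_sha256": io.config_hash(hashed)}
    artifacts: dict[str, str] = {}
    t0 = time.perf_counter()

    def _stage(name):
        log.info("stage %-12s %6.1fs", name, time.perf_counter() - t0)

    patients, centers, matrix = _load_or_generate(config, out, meta)
    for key in ("patients", "centers", "travel_minutes"):
        p = out / f"{key}.csv"
        if p.exists():
            artifacts[key] = str(p)
    _stage("data")

    all_sets = choice_sets.build_all_choice_sets(matrix, config.max_minutes)
    cohort, report = choice_sets.apply_exclusions(patients, all_sets)
    io.write_csv(report.to_frame(), out / "exclusion_report.csv", meta)
    artifacts["exclusion_report"] = str(out / "exclusion_report.csv")
    _stage("choice_sets")

    fit = choice_model.fit(cohort, all_sets, centers)
    if not fit.converged:
        raise RuntimeError(f"choice-model fit did not converge: {fit.message}")
    io.write_csv(fit.table.round(6).reset_index(), out / "fit_summary.csv",
                 {**meta, "log_likelihood": round(fit.log_likelihood, 4),
                  "n_patients": fit.n_patients,
                  "n_observations": fit.n_observations,
                  "ci": "Wald z=1.96", "p_test": "Wald"})
    with open(out / "fit.json", "w", encoding="utf-8") as fh:
        json.dump({"coefficients": dict(zip(choice_model.PARAM_NAMES,
                                            fit.params.to_array().tolist())),
                   "covariance": fit.covariance.tolist(),
                   "log_likelihood": fit.log_likelihood,
                   "n_patients": fit.n_patients,
                   "n_observations": fit.n_observations}, fh, indent=1)
    artifacts["fit_summary"] = str(out / "fit_summary.csv")
    artifacts["fit"] = str(out / "fit.json")
    _stage("fit")

    if not config.scenario_list:
        return artifacts

    all_records = []
    for name in config.scenario_list:
        scn = _build_scenario(name, cohort, centers, matrix, config)
        io.write_csv(scn.to_frame(centers), out / f"scenario_{scn.name}.csv", meta)
        affected = scenarios.affected_patients(cohort, scn)
        io.write_csv(affected[["id", "chosen_center"]],
                     out / f"affected_{scn.name}.csv", meta)
        records = burden_mod.compute_burden(cohort, all_sets, matrix, scn,
                                            fit, centers)
        io.write_csv(records, out / f"burden_{scn.name}.csv", meta)
        artifacts[f"scenario_{scn.name}"] = str(out / f"scenario_{scn.name}.csv")
        artifacts[f"burden_{scn.name}"] = str(out / f"burden_{scn.name}.csv")
        all_records.append(records)
        try:
            efit = equity.fit_equity(records, cohort, scenario=scn.name)
            io.write_csv(efit.to_frame().round(6).reset_index(),
                         out / f"equity_{scn.name}.csv",
                         {**meta, "n_patients": efit.n_patients,
                          "se": "classical"})
            artifacts[f"equity_{scn.name}"] = str(out / f"equity_{scn.name}.csv")
        except (ValueError, equity.RankDeficiencyError) as exc:
            log.warning("equity fit skipped for %s: %s", scn.name, exc)
        _stage(scn.name)

    records = pd.concat(all_records, ignore_index=True)
    summary = burden_mod.burden_summary(records)
    io.write_csv(summary.round(4), out / "burden_summary.csv", meta)
    artifacts["burden_summary"] = str(out / "burden_summary.csv")
    if config.make_plots:
        burden_mod.plot_burden(summary, out / "burden.png")
        artifacts["figure"] = str(out / "burden.png")
    _stage("report")
    return artifacts
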