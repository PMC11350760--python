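"""End-to-end analysis orchestration.

``run_full_analysis`` reproduces the study's analysis shape on any cohort
(real CSVs or the synthetic generator's output): MAP fits and diagnostics,
per-patient PK table with trough/toxicity and predicted continuous-infusion
Css, cohort attainment and %TAM tables, the per-patient counterfactual
continuous-infusion simulation, and the population Monte Carlo PTA curves.
All stages log to stderr; every output embeds the master seed and package
version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes_fit import fit_cohort, fit_diagnostics
from .crrt import FlowSettings, cl_cvvh_patient
from .io import (
    PathLike,
    diagnostics_to_json,
    fits_to_json,
    load_poppk,
    load_regimen,
    read_covariates,
    read_filter_pairs,
    read_observations,
)
from .pkpd_targets import (
    DEFAULT_MIC_GRID,
    STANDARD_TARGETS,
    PKPDTarget,
    cohort_attainment,
    trough_and_toxicity,
)
from .popmodel import DosingRegimen, PopPKParams, css_continuous, steady_state_profile
from .pta import (
    SIMULATED_REGIMENS,
    SimulationScenario,
    per_patient_regimen_sim,
    run_pta,
)

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger(__name__)

CONTINUOUS_3G = DosingRegimen(dose=3000, interval=24, infusion_duration=24)


@dataclass
class RunConfig:
    """Inputs and knobs of one full analysis run."""

    covariates_csv: PathLike
    observations_csv: PathLike
    out_dir: PathLike
    filter_pairs_csv: Optional[PathLike] = None
    pop: Union[PopPKParams, dict, PathLike, None] = None
    regimen: Union[DosingRegimen, dict, str] = "1000:8:3"
    pta_regimens: Sequence[DosingRegimen] = SIMULATED_REGIMENS
    target: PKPDTarget = PKPDTarget(100, 4)
    mic_grid: Sequence[float] = DEFAULT_MIC_GRID
    flows: FlowSettings = field(default_factory=FlowSettings.from_clinical)
    n_subjects: int = 5000
    seed: int = 0
    dt: float = 0.05
    fu: float = 1.0

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "pta_regimens" in data:
            data["pta_regimens"] = [load_regimen(r) for r in data["pta_regimens"]]
        if "target" in data:
            data["target"] = PKPDTarget(**data["target"])
        if "flows" in data:
            data["flows"] = FlowSettings(**data["flows"])
        return cls(**data)

    def resolved_pop(self) -> PopPKParams:
        if isinstance(self.pop, PopPKParams):
            return self.pop
        return load_poppk(self.pop)

    def resolved_regimen(self) -> DosingRegimen:
        if isinstance(self.regimen, DosingRegimen):
            return self.regimen
        return load_regimen(self.regimen)


def _check_inputs(config: RunConfig) -> None:
    for name in ("covariates_csv", "observations_csv", "filter_pairs_csv"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name}: {p}")


def _stamp(df: pd.DataFrame, seed: int) -> pd.DataFrame:
    df = df.copy()
    df["seed"] = seed
    df["package_version"] = __version__
    return df


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run every stage and return the paths of the written artifacts.

    Artifacts: patient_pk_table.csv, attainment_by_mic.csv,
    tam_by_mic.csv, continuous_infusion_attainment.csv, pta_curves.csv,
    diagnostics.json (plus fits.json and a config echo).
    """
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop = config.resolved_pop()
    regimen = config.resolved_regimen()
    paths: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s starting", name)
        return time.perf_counter()

    # -- stage: MAP fits ----------------------------------------------------
    t0 = stage("fit")
    covariates = read_covariates(config.covariates_csv)
    observations = read_observations(config.observations_csv, covariates,
                                     regimen)
    if not observations:
        raise RuntimeError("fit stage: no observations found")
    fits = fit_cohort(observations, pop)
    pairs_obs, pairs_pred = [], []
    for obs, fit in zip(observations, fits):
        mask = obs.fitting_mask()
        pairs_obs.extend(obs.concentrations[mask])
        pairs_pred.extend(fit.predictions)
    diag = fit_diagnostics(pairs_obs, pairs_pred)
    paths["fits"] = out / "fits.json"
    fits_to_json(fits, paths["fits"])
    paths["diagnostics"] = out / "diagnostics.json"
    diagnostics_to_json(diag, paths["diagnostics"],
                        extra={"seed": config.seed,
                               "package_version": __version__})
    log.info("stage fit done in %.2f s (%d patients)",
             time.perf_counter() - t0, len(fits))

    # -- stage: CVVH clearance ---------------------------------------------
    cl_cvvh_by_pid: dict[str, float] = {}
    if config.filter_pairs_csv is not None:
        t0 = stage("crrt")
        pairs = read_filter_pairs(config.filter_pairs_csv)
        cl_cvvh_by_pid = {
            pid: cl_cvvh_patient(ps, config.flows) for pid, ps in pairs.items()
        }
        log.info("stage crrt done in %.2f s", time.perf_counter() - t0)

    # -- stage: per-patient PK table (study-table shape) ---------------------
    t0 = stage("pk_table")
    profiles = [
        steady_state_profile(f.individual, regimen, dt=config.dt) for f in fits
    ]
    rows = []
    for fit, profile in zip(fits, profiles):
        trough, toxic = trough_and_toxicity(profile)
        rows.append(
            {
                "patient_id": fit.patient_id,
                "trough_mg_l": trough,
                "toxic": toxic,
                "predicted_css_mg_l": css_continuous(
                    CONTINUOUS_3G.daily_dose, fit.individual.cl
                ),
                "cl_total_l_h": fit.individual.cl,
                "cl_cvvh_l_h": cl_cvvh_by_pid.get(fit.patient_id, np.nan),
                "v1_l": fit.individual.v1,
                "v2_l": fit.individual.v2,
                "v_total_l": fit.individual.v_total,
            }
        )
    table = pd.DataFrame(rows)
    numeric = table.select_dtypes("number")
    summary = pd.DataFrame(
        {
            "patient_id": ["mean", "sd", "min", "max"],
            **{
                c: [numeric[c].mean(), numeric[c].std(ddof=1),
                    numeric[c].min(), numeric[c].max()]
                for c in numeric.columns
            },
        }
    )
    paths["pk_table"] = out / "patient_pk_table.csv"
    _stamp(pd.concat([table, summary], ignore_index=True),
           config.seed).to_csv(paths["pk_table"], index=False)
    log.info("stage pk_table done in %.2f s", time.perf_counter() - t0)

    # -- stage: attainment + %TAM tables -------------------------------------
    t0 = stage("attainment")
    frames = []
    for target in STANDARD_TARGETS:
        frame = cohort_attainment(profiles, target, config.mic_grid, config.fu)
        frame.insert(0, "target", target.label)
        frames.append(frame)
    attain = pd.concat(frames, ignore_index=True)
    paths["attainment"] = out / "attainment_by_mic.csv"
    _stamp(attain, config.seed).to_csv(paths["attainment"], index=False)
    tam = frames[0][["mic", "n", "tam_mean", "tam_sd"]]
    paths["tam"] = out / "tam_by_mic.csv"
    _stamp(tam, config.seed).to_csv(paths["tam"], index=False)
    log.info("stage attainment done in %.2f s", time.perf_counter() - t0)

    # -- stage: counterfactual continuous infusion ---------------------------
    t0 = stage("continuous_infusion")
    ci_table, css = per_patient_regimen_sim(
        fits, CONTINUOUS_3G, config.mic_grid, config.target,
        dt=config.dt, fu=config.fu,
    )
    ci_table["css_min_mg_l"] = css.min()
    ci_table["css_max_mg_l"] = css.max()
    paths["continuous_infusion"] = out / "continuous_infusion_attainment.csv"
    _stamp(ci_table, config.seed).to_csv(paths["continuous_infusion"],
                                         index=False)
    log.info("stage continuous_infusion done in %.2f s",
             time.perf_counter() - t0)

    # -- stage: Monte Carlo PTA ----------------------------------------------
    t0 = stage("pta")
    scenario = SimulationScenario(
        target=config.target,
        regimens=config.pta_regimens,
        mic_grid=config.mic_grid,
        pop=pop,
        n_subjects=config.n_subjects,
        seed=config.seed,
        dt=config.dt,
        fu=config.fu,
    )
    curve = run_pta(scenario)
    paths["pta"] = out / "pta_curves.csv"
    _stamp(curve.to_dataframe(), config.seed).to_csv(paths["pta"], index=False)
    log.info("stage pta done in %.2f s", time.perf_counter() - t0)

    # -- config echo ----------------------------------------------------------
    echo = dataclasses.asdict(config)
    echo["pop"] = dataclasses.asdict(pop)
    echo["regimen"] = dataclasses.asdict(regimen)
    echo["pta_regimens"] = [dataclasses.asdict(r) for r in config.pta_regimens]
    echo["package_version"] = __version__
    paths["config_echo"] = out / "config_echo.json"
    paths["config_echo"].write_text(
        json.dumps(echo, indent=1, sort_keys=True, default=str)
    )
    return paths
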