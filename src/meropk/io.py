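"""Tabular I/O: covariate, observation and filter-pair CSVs, fit JSONs,
and population-parameter profiles (YAML/JSON).

CSV dialect: comma-separated, UTF-8, header row, "." decimal separator.
Column conventions:

- covariates: patient_id, age, sex, weight_kg, scr_mg_dl, egfr_ml_min (optional)
- observations: patient_id, time_h, conc_mg_l, site
- filter pairs: patient_id, time_h, cti_mg_l, cto_mg_l
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .bayes_fit import FitDiagnostics, MapFit, ObservationSet
from .crrt import FilterSamplePair
from .popmodel import CovariateSet, DosingRegimen, PopPKParams
from .synthetic import SyntheticPatient

__all__ = [
    "load_poppk",
    "load_regimen",
    "write_cohort_csvs",
    "read_covariates",
    "read_observations",
    "read_filter_pairs",
    "fits_to_json",
    "diagnostics_to_json",
]

PathLike = Union[str, Path]


def load_poppk(source: Union[PathLike, dict, None] = None) -> PopPKParams:
    """Population parameters from a YAML/JSON file or mapping.

    ``None`` returns the packaged default profile.  Keys mirror the
    ``PopPKParams`` field names; missing keys keep their defaults.
    """
    if source is None:
        return PopPKParams()
    if isinstance(source, dict):
        return PopPKParams(**source)
    text = Path(source).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    return PopPKParams(**data)


def load_regimen(source: Union[dict, str]) -> DosingRegimen:
    """Regimen from a mapping or a compact "dose:interval:duration" string
    (mg:h:h), e.g. "1000:8:3"."""
    if isinstance(source, dict):
        return DosingRegimen(**source)
    dose, interval, duration = (float(x) for x in source.split(":"))
    return DosingRegimen(dose=dose, interval=interval,
                         infusion_duration=duration)


def write_cohort_csvs(
    patients: Sequence[SyntheticPatient], out_dir: PathLike
) -> dict[str, Path]:
    """Write covariates/observations/filter-pairs CSVs plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov_rows, obs_rows, pair_rows, truth = [], [], [], {}
    for p in patients:
        pid = p.observations.patient_id
        cov_rows.append(
            {
                "patient_id": pid,
                "age": p.covariates.age,
                "sex": p.covariates.sex,
                "weight_kg": p.covariates.weight,
                "scr_mg_dl": p.covariates.scr,
                "egfr_ml_min": p.covariates.egfr,
            }
        )
        for t, c, s in zip(p.observations.times, p.observations.concentrations,
                           p.observations.sites):
            obs_rows.append({"patient_id": pid, "time_h": t,
                             "conc_mg_l": c, "site": s})
        for pair in p.filter_pairs:
            pair_rows.append({"patient_id": pid, "time_h": pair.time,
                              "cti_mg_l": pair.cti, "cto_mg_l": pair.cto})
        truth[pid] = {
            "eta": p.true_eta.tolist(),
            "cl": p.true_params.cl,
            "q": p.true_params.q,
            "v1": p.true_params.v1,
            "v2": p.true_params.v2,
            "cl_cvvh": p.true_cl_cvvh,
        }
    paths = {
        "covariates": out / "covariates.csv",
        "observations": out / "observations.csv",
        "filter_pairs": out / "filter_pairs.csv",
        "truth": out / "truth.json",
    }
    pd.DataFrame(cov_rows).to_csv(paths["covariates"], index=False)
    pd.DataFrame(obs_rows).to_csv(paths["observations"], index=False)
    pd.DataFrame(pair_rows).to_csv(paths["filter_pairs"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def read_covariates(path: PathLike) -> dict[str, CovariateSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for _, row in df.iterrows():
        egfr = row.get("egfr_ml_min")
        out[str(row["patient_id"])] = CovariateSet(
            age=float(row["age"]),
            sex=str(row["sex"]),
            weight=float(row["weight_kg"]),
            scr=float(row["scr_mg_dl"]) if pd.notna(row.get("scr_mg_dl")) else None,
            egfr=float(egfr) if pd.notna(egfr) else None,
        )
    return out


def read_observations(
    path: PathLike,
    covariates: dict[str, CovariateSet],
    regimen: DosingRegimen,
) -> list[ObservationSet]:
    """Observation sets grouped per patient, sorted by time."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "site" not in df.columns:
        df["site"] = "systemic"
    sets = []
    for pid, grp in df.groupby("patient_id", sort=True):
        pid = str(pid)
        if pid not in covariates:
            raise KeyError(f"no covariates for patient {pid}")
        grp = grp.sort_values("time_h")
        sets.append(
            ObservationSet(
                patient_id=pid,
                times=grp["time_h"].to_numpy(float),
                concentrations=grp["conc_mg_l"].to_numpy(float),
                sites=grp["site"].to_numpy(object),
                regimen=regimen,
                covariates=covariates[pid],
            )
        )
    return sets


def read_filter_pairs(path: PathLike) -> dict[str, list[FilterSamplePair]]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, list[FilterSamplePair]] = {}
    import warnings

    for _, row in df.iterrows():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # Cto > Cti is data, not an error
            pair = FilterSamplePair(
                cti=float(row["cti_mg_l"]),
                cto=float(row["cto_mg_l"]),
                time=float(row["time_h"]),
            )
        out.setdefault(str(row["patient_id"]), []).append(pair)
    return out


def fits_to_json(fits: Sequence[MapFit], path: PathLike) -> None:
    """Per-patient fit results (eta, CL, Q, V1, V2, V_total, objective)."""
    data = {
        f.patient_id: {
            "eta": f.eta_hat.tolist(),
            "cl": f.individual.cl,
            "q": f.individual.q,
            "v1": f.individual.v1,
            "v2": f.individual.v2,
            "v_total": f.individual.v_total,
            "objective": f.objective_value,
            "converged": f.converged,
        }
        for f in fits
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def diagnostics_to_json(diag: FitDiagnostics, path: PathLike,
                        extra: Optional[dict] = None) -> None:
    data = dataclasses.asdict(diag)
    if extra:
        data.update(extra)
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))
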