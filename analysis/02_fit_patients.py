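#!/usr/bin/env python
"""MAP-fit every cohort patient and validate the predictions.

Estimates each patient's random effects from their nine plasma samples
under the population prior, writes per-patient parameters (fits.json) and
the pooled observed-vs-predicted diagnostics (R^2, RMSE, MAPE, 2-SD
coverage), and reports how well the fits recover the generator's truth.
"""

import json
from pathlib import Path

import numpy as np

from meropk import fit_cohort, fit_diagnostics
from meropk.io import (
    diagnostics_to_json,
    fits_to_json,
    load_poppk,
    load_regimen,
    read_covariates,
    read_observations,
)

COHORT = Path("results/cohort")
OUT = Path("results/fits")


def main() -> None:
    pop = load_poppk(None)
    covs = read_covariates(COHORT / "covariates.csv")
    observations = read_observations(COHORT / "observations.csv", covs,
                                     load_regimen("1000:8:3"))
    fits = fit_cohort(observations, pop)

    obs_all, pred_all = [], []
    for obs, fit in zip(observations, fits):
        obs_all.extend(obs.concentrations[obs.fitting_mask()])
        pred_all.extend(fit.predictions)
    diag = fit_diagnostics(obs_all, pred_all)

    OUT.mkdir(parents=True, exist_ok=True)
    fits_to_json(fits, OUT / "fits.json")
    diagnostics_to_json(diag, OUT / "diagnostics.json")

    truth = json.loads((COHORT / "truth.json").read_text())
    eta_err = np.array([
        np.asarray(f.eta_hat) - np.asarray(truth[f.patient_id]["eta"])
        for f in fits
    ])
    cls = np.array([f.individual.cl for f in fits])
    print(f"fitted {len(fits)} patients "
          f"({sum(f.converged for f in fits)} converged)")
    print(f"  CL_total  {cls.mean():5.2f} +/- {cls.std(ddof=1):.2f} "
          f"({cls.min():.2f}-{cls.max():.2f}) L/h")
    print(f"  R^2 {diag.r2:.3f}  RMSE {diag.rmse:.3f} mg/L  "
          f"MAPE {diag.mape:.1f} %  2SD coverage {diag.frac_within_2sd:.2f} "
          f"({diag.n_points} points)")
    print(f"  mean eta error (shrinkage bias): "
          f"{np.round(eta_err.mean(axis=0), 3).tolist()}")
    print(f"  wrote {OUT / 'fits.json'} and {OUT / 'diagnostics.json'}")


if __name__ == "__main__":
    main()
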