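"""MAP (empirical Bayes) estimation of individual PK parameters.

Each patient's random effects eta = (eta_cl, eta_v1, eta_v2) are estimated
by minimizing the standard extended-least-squares MAP objective under the
fixed population prior:

    J(eta) = sum_j [ (y_j - f_j)^2 / (sigma f_j)^2 + ln((sigma f_j)^2) ]
           + sum_k eta_k^2 / omega_k^2

with f_j the model prediction at observation time t_j under eta and a
proportional residual model whose variance uses the model prediction (not
the observation) — the convention the source population model was
estimated with.  Records at exactly 0 mg/L are excluded (the proportional
model is undefined there) and only systemic/pre-filter samples enter the
fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .popmodel import (
    CovariateSet,
    DosingRegimen,
    IndividualPKParams,
    PopPKParams,
    conc_profile,
    individual_params,
)

__all__ = [
    "ObservationSet",
    "MapFit",
    "FitDiagnostics",
    "OptimizerSettings",
    "map_objective",
    "fit_map",
    "fit_cohort",
    "fit_diagnostics",
]

log = logging.getLogger(__name__)

#: Sampling sites whose records enter the fit.
FITTABLE_SITES = ("systemic", "pre_filter")


@dataclass(frozen=True)
class ObservationSet:
    """Timed plasma concentrations for one patient under a known regimen."""

    patient_id: str
    times: np.ndarray  # h since the start of the first dose
    concentrations: np.ndarray  # mg/L
    sites: np.ndarray  # {systemic, pre_filter, post_filter}
    regimen: DosingRegimen
    covariates: CovariateSet

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        sites = np.asarray(self.sites, dtype=object)
        if not (times.shape == conc.shape == sites.shape):
            raise ValueError("times/concentrations/sites shape mismatch")
        if times.size and (np.any(times < 0) or np.any(np.diff(times) < 0)):
            raise ValueError("times must be non-negative and sorted")
        if np.any(conc < 0):
            raise ValueError("negative concentration")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "sites", sites)

    def fitting_mask(self) -> np.ndarray:
        """Records usable for estimation: fittable site and conc > 0."""
        usable = np.isin(self.sites.astype(str), FITTABLE_SITES)
        zero = self.concentrations <= 0
        if np.any(usable & zero):
            log.info(
                "patient %s: skipping %d zero-concentration record(s)",
                self.patient_id, int(np.sum(usable & zero)),
            )
        return usable & ~zero


@dataclass(frozen=True)
class MapFit:
    """Result of one patient's MAP estimation."""

    patient_id: str
    eta_hat: np.ndarray
    individual: IndividualPKParams
    objective_value: float
    predictions: np.ndarray  # mg/L at the fitted observation times
    converged: bool


@dataclass(frozen=True)
class FitDiagnostics:
    """Cohort prediction-validation metrics (observed vs predicted)."""

    r2: float
    rmse: float  # mg/L
    mape: float  # %
    frac_within_2sd: float
    n_points: int


@dataclass(frozen=True)
class OptimizerSettings:
    n_starts: int = 5  # eta = 0 plus seeded perturbations
    start_scale: float = 0.5  # perturbation SD as a multiple of omega
    seed: int = 20240811
    xatol: float = 1e-9
    fatol: float = 1e-12
    maxiter: int = 4000


def map_objective(
    eta: Sequence[float], obs: ObservationSet, pop: PopPKParams
) -> float:
    """MAP/ELS objective at ``eta`` (lower is better)."""
    eta = np.asarray(eta, dtype=float)
    mask = obs.fitting_mask()
    if not mask.any():
        raise ValueError("no usable observations")
    ind = individual_params(pop, obs.covariates, eta)
    f = conc_profile(ind, obs.regimen, obs.times[mask])
    if np.any(f <= 0):
        raise FloatingPointError("non-positive model prediction")
    y = obs.concentrations[mask]
    var = (pop.sigma_prop * f) ** 2
    data_term = float(np.sum((y - f) ** 2 / var + np.log(var)))
    prior_term = float(np.sum(eta**2 / pop.omegas**2))
    return data_term + prior_term


def fit_map(
    obs: ObservationSet,
    pop: PopPKParams,
    opts: Optional[OptimizerSettings] = None,
) -> MapFit:
    """Minimize the MAP objective from eta = 0 with seeded multistart.

    With an empty observation set the prior mode (eta = 0, typical
    parameters) is returned.  Non-convergence of the optimizer is flagged
    on the result, not raised; an observation set whose records are all
    unusable raises.
    """
    opts = opts or OptimizerSettings()
    if obs.times.size == 0:
        ind = individual_params(pop, obs.covariates, np.zeros(3))
        return MapFit(obs.patient_id, np.zeros(3), ind, 0.0,
                      np.array([]), True)
    mask = obs.fitting_mask()
    if not mask.any():
        raise ValueError(f"patient {obs.patient_id}: no usable observations")

    def objective(eta: np.ndarray) -> float:
        try:
            return map_objective(eta, obs, pop)
        except FloatingPointError:
            return np.inf

    rng = np.random.default_rng(opts.seed)
    starts = [np.zeros(3)]
    starts += [
        rng.normal(0.0, opts.start_scale * pop.omegas)
        for _ in range(opts.n_starts - 1)
    ]
    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": opts.xatol, "fatol": opts.fatol,
                     "maxiter": opts.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    eta_hat = np.asarray(best.x, dtype=float)
    ind = individual_params(pop, obs.covariates, eta_hat)
    preds = conc_profile(ind, obs.regimen, obs.times[mask])
    return MapFit(
        patient_id=obs.patient_id,
        eta_hat=eta_hat,
        individual=ind,
        objective_value=float(best.fun),
        predictions=preds,
        converged=bool(best.success),
    )


def fit_cohort(
    observations: Sequence[ObservationSet],
    pop: PopPKParams,
    opts: Optional[OptimizerSettings] = None,
) -> list[MapFit]:
    """MAP fits for every patient in a cohort."""
    return [fit_map(obs, pop, opts) for obs in observations]


def fit_diagnostics(
    observed: Sequence[float], predicted: Sequence[float]
) -> FitDiagnostics:
    """Prediction-validation metrics on pooled (observed, predicted) pairs.

    R^2 is computed against the identity line (1 - SS_res/SS_tot of
    observed vs predicted), RMSE is the root-mean-squared error, MAPE the
    mean absolute percentage error relative to the observation, and the
    2-SD coverage counts prediction-minus-observation differences within
    their own mean +/- 2 SD.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need >= 2 matched (observed, predicted) pairs")
    if np.any(obs <= 0):
        raise ValueError("observed concentrations must be positive")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mape = float(np.mean(np.abs(resid) / obs) * 100.0)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    diff = pred - obs
    sd = float(diff.std(ddof=1))
    within = np.abs(diff - diff.mean()) <= 2.0 * sd
    return FitDiagnostics(
        r2=r2,
        rmse=rmse,
        mape=mape,
        frac_within_2sd=float(within.mean()),
        n_points=int(obs.size),
    )
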