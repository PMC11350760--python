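"""Two-compartment population pharmacokinetic model of meropenem on CRRT.

Structural model: two compartments, zero-order (infusion) input into the
central compartment, first-order elimination from it.  Total clearance is
tied to renal function through a power covariate model,

    CL_total = theta_cl_ref * (eGFR / egfr_ref) ** cl_exponent,

with log-normal inter-individual variability on CL, V1 and V2
(parameter = typical * exp(eta), eta ~ Normal(0, omega^2)) and a
proportional residual-error model on observed concentrations.
Inter-compartmental clearance Q carries no variability and is fixed
across subjects.

All internal units: clearances in L/h, volumes in L, concentrations in
mg/L, times in h, eGFR in mL/min, doses in mg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "PopPKParams",
    "CovariateSet",
    "IndividualPKParams",
    "DosingRegimen",
    "ConcentrationProfile",
    "DEFAULT_POPPK",
    "egfr_from_covariates",
    "typical_clearance",
    "individual_params",
    "conc_profile",
    "steady_state_profile",
    "steady_state_conc_matrix",
    "window_profile",
    "css_continuous",
]

# Japanese 3-variable eGFR equation coefficients (mL/min/1.73 m^2 by
# convention; used unindexed here as the covariate the clearance model
# expects — see docs/methods.md).
_EGFR_COEF = 194.0
_EGFR_SCR_EXP = -1.094
_EGFR_AGE_EXP = -0.287
_EGFR_FEMALE_FACTOR = 0.739

#: Relative eigenvalue gap below which the biexponential solution is
#: replaced by its repeated-root limit form.
_DEGENERATE_TOL = 1e-10


@dataclass(frozen=True)
class PopPKParams:
    """Fixed effects, random-effect SDs and residual SD of the population model.

    Defaults are the meropenem CRRT population values used throughout:
    CL 4.22 L/h at the reference eGFR of 26.1 mL/min with exponent 0.25,
    Q 7.84 L/h, V1 14.82 L, V2 11.75 L, omegas (0.2675, 0.2733, 0.5705)
    and 18.39 % proportional residual error.
    """

    theta_cl_ref: float = 4.22
    egfr_ref: float = 26.1
    cl_exponent: float = 0.25
    q: float = 7.84
    v1: float = 14.82
    v2: float = 11.75
    omega_cl: float = 0.2675
    omega_v1: float = 0.2733
    omega_v2: float = 0.5705
    sigma_prop: float = 0.1839

    def __post_init__(self) -> None:
        for name in ("theta_cl_ref", "egfr_ref", "q", "v1", "v2",
                     "omega_cl", "omega_v1", "omega_v2", "sigma_prop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cl_exponent < 0:
            raise ValueError("cl_exponent must be non-negative")
        for name in ("omega_cl", "omega_v1", "omega_v2", "sigma_prop"):
            if getattr(self, name) >= 1:
                raise ValueError(f"{name} must be < 1 (log-scale SD)")

    @property
    def omegas(self) -> np.ndarray:
        """SDs of the (eta_cl, eta_v1, eta_v2) random effects."""
        return np.array([self.omega_cl, self.omega_v1, self.omega_v2])


DEFAULT_POPPK = PopPKParams()


@dataclass(frozen=True)
class CovariateSet:
    """Per-patient covariates feeding the clearance model.

    ``egfr`` overrides the creatinine-based estimate when supplied, which
    insulates downstream results from the eGFR-equation convention.
    Weight is carried for cohort description but enters no model term.
    """

    age: float
    sex: Literal["male", "female"]
    weight: float
    scr: Optional[float] = None
    egfr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.egfr is None:
            if self.scr is None or self.scr <= 0:
                raise ValueError("scr must be positive when egfr is absent")
        elif self.egfr <= 0:
            raise ValueError("egfr override must be positive")


@dataclass(frozen=True)
class IndividualPKParams:
    """One subject's disposition parameters after covariates and eta."""

    cl: float
    q: float
    v1: float
    v2: float
    eta: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if min(self.cl, self.q, self.v1, self.v2) <= 0:
            raise ValueError("all PK parameters must be positive")
        object.__setattr__(self, "eta", np.asarray(self.eta, dtype=float))

    @property
    def v_total(self) -> float:
        return self.v1 + self.v2


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated zero-order infusion schedule.

    ``n_doses=None`` marks an open-ended (steady-state) regimen.  A
    continuous infusion is encoded as ``infusion_duration == interval`` so
    the same event machinery covers it.
    """

    dose: float  # mg per administration
    interval: float  # h
    infusion_duration: float  # h
    n_doses: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if not (0 < self.infusion_duration <= self.interval):
            raise ValueError("need 0 < infusion_duration <= interval")
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def rate(self) -> float:
        """Infusion rate while running, mg/h."""
        return self.dose / self.infusion_duration

    @property
    def daily_dose(self) -> float:
        return self.dose * 24.0 / self.interval

    @property
    def is_continuous(self) -> bool:
        return math.isclose(self.infusion_duration, self.interval)

    @property
    def label(self) -> str:
        if self.is_continuous:
            return f"{self.daily_dose / 1000:g} g continuous over 24 h"
        return (f"{self.dose / 1000:g} g q{self.interval:g}h "
                f"over {self.infusion_duration:g} h")

    def infusion_starts(self, t_max: float) -> Iterator[float]:
        """Dose start times (first dose at t = 0) strictly before ``t_max``."""
        k = 0
        while True:
            start = k * self.interval
            if start >= t_max:
                return
            if self.n_doses is not None and k >= self.n_doses:
                return
            yield start
            k += 1


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration-time grid over one steady-state dosing interval."""

    times: np.ndarray  # h, strictly increasing, relative to dose start
    concentrations: np.ndarray  # mg/L
    regimen: DosingRegimen

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.size == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("negative concentration")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)

    @property
    def trough(self) -> float:
        """Concentration at the end of the interval (pre-dose)."""
        return float(self.concentrations[-1])


# ---------------------------------------------------------------------------
# covariate model


def egfr_from_covariates(cov: CovariateSet) -> float:
    """Estimated GFR in mL/min.

    Returns the direct override when present, else the Japanese 3-variable
    creatinine equation 194 * SCr^-1.094 * age^-0.287 (x 0.739 if female).
    """
    if cov.egfr is not None:
        return float(cov.egfr)
    egfr = _EGFR_COEF * cov.scr ** _EGFR_SCR_EXP * cov.age ** _EGFR_AGE_EXP
    if cov.sex == "female":
        egfr *= _EGFR_FEMALE_FACTOR
    return float(egfr)


def typical_clearance(egfr: float, pop: PopPKParams = DEFAULT_POPPK) -> float:
    """Population-typical total clearance (L/h) at the given eGFR."""
    if egfr <= 0:
        raise ValueError("egfr must be positive")
    return pop.theta_cl_ref * (egfr / pop.egfr_ref) ** pop.cl_exponent


def individual_params(
    pop: PopPKParams,
    cov: CovariateSet,
    eta: Sequence[float] = (0.0, 0.0, 0.0),
) -> IndividualPKParams:
    """Individual parameters: typical values scaled by exp(eta) on CL/V1/V2."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 3-vector")
    egfr = egfr_from_covariates(cov)
    return IndividualPKParams(
        cl=typical_clearance(egfr, pop) * math.exp(eta[0]),
        q=pop.q,
        v1=pop.v1 * math.exp(eta[1]),
        v2=pop.v2 * math.exp(eta[2]),
        eta=eta,
    )


# ---------------------------------------------------------------------------
# analytic two-compartment solution


def _eigen(cl, q, v1, v2):
    """Hybrid rate constants (lam1 > lam2) and k21; array-safe."""
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    return lam1, lam2, k21


def _unit_on(t: np.ndarray, lam1: float, lam2: float, k21: float) -> np.ndarray:
    """V1*C/rate for an infusion switched on at t=0 and still running, t >= 0.

    Handles the (measure-zero) repeated-eigenvalue case by the analytic
    limit form rather than a numerical nudge.
    """
    if lam1 - lam2 < _DEGENERATE_TOL * lam1:
        lam = 0.5 * (lam1 + lam2)
        g = -np.expm1(-lam * t) / lam
        gp = (t * np.exp(-lam * t) + np.expm1(-lam * t) / lam) / lam
        return g + (lam - k21) * gp
    g1 = -np.expm1(-lam1 * t) / lam1
    g2 = -np.expm1(-lam2 * t) / lam2
    return ((lam1 - k21) * g1 - (lam2 - k21) * g2) / (lam1 - lam2)


def conc_profile(
    ind: IndividualPKParams,
    regimen: DosingRegimen,
    times: Sequence[float],
) -> np.ndarray:
    """Central-compartment concentration (mg/L) at the requested times.

    Exact analytic solution: superposition over all infusion events, each
    event contributing an infusion-on response at its start minus one at
    its end.  Times are hours since the start of the first dose.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    lam1, lam2, k21 = _eigen(ind.cl, ind.q, ind.v1, ind.v2)
    out = np.zeros(times.shape, dtype=float)
    t_max = float(times.max()) if times.size else 0.0
    for start in regimen.infusion_starts(t_max):
        dt_on = times - start
        mask = dt_on > 0
        if mask.any():
            out[mask] += _unit_on(dt_on[mask], lam1, lam2, k21)
        dt_off = dt_on - regimen.infusion_duration
        mask = dt_off > 0
        if mask.any():
            out[mask] -= _unit_on(dt_off[mask], lam1, lam2, k21)
    return regimen.rate / ind.v1 * out


def _interval_grid(interval: float, dt: float) -> np.ndarray:
    """Uniform grid over [0, interval] with spacing <= dt, endpoints included."""
    m = max(1, int(math.ceil(interval / dt - 1e-9)))
    return np.linspace(0.0, interval, m + 1)


def steady_state_conc_matrix(
    cl: np.ndarray,
    q: np.ndarray,
    v1: np.ndarray,
    v2: np.ndarray,
    regimen: DosingRegimen,
    times: np.ndarray,
) -> np.ndarray:
    """Closed-form steady-state concentrations for many subjects at once.

    Parameters are 1-D arrays over subjects (``q`` may be scalar), ``times``
    the within-interval grid; returns shape (n_subjects, n_times).  Uses the
    geometric-series accumulation of the per-dose biexponential response;
    the repeated-eigenvalue limit is not special-cased here because random
    log-normal parameter draws hit it with probability zero.
    """
    cl, v1, v2 = (np.asarray(a, float).reshape(-1, 1) for a in (cl, v1, v2))
    q = np.broadcast_to(np.asarray(q, float), cl.shape[:1]).reshape(-1, 1)
    times = np.asarray(times, float)
    tau = regimen.interval
    t_inf = regimen.infusion_duration
    lam1, lam2, k21 = _eigen(cl, q, v1, v2)

    def branch(lam: np.ndarray) -> np.ndarray:
        # current-dose kernel: rising limb during the infusion, paired
        # decaying exponentials after it
        current = np.where(
            times < t_inf,
            -np.expm1(-lam * times),
            np.exp(-lam * (times - t_inf)) - np.exp(-lam * times),
        )
        # accumulated tail of all earlier doses (geometric series)
        tail = (
            np.exp(-lam * (times + tau - t_inf)) - np.exp(-lam * (times + tau))
        ) / (-np.expm1(-lam * tau))
        return (current + tail) / lam

    kern = ((lam1 - k21) * branch(lam1) - (lam2 - k21) * branch(lam2)) / (lam1 - lam2)
    return regimen.rate / v1 * kern


def steady_state_profile(
    ind: IndividualPKParams,
    regimen: DosingRegimen,
    dt: float = 0.05,
    method: Literal["closed_form", "simulate"] = "closed_form",
) -> ConcentrationProfile:
    """One dosing interval at steady state on a grid of spacing <= ``dt``.

    ``closed_form`` sums the dose superposition as a geometric series;
    ``simulate`` runs >= 10 terminal half-lives of doses and takes the last
    interval.  The two routes agree to well within 0.1 % and the simulation
    route doubles as the fallback for (near-)degenerate eigenvalues.
    """
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 h")
    times = _interval_grid(regimen.interval, dt)
    lam1, lam2, _ = _eigen(ind.cl, ind.q, ind.v1, ind.v2)
    if method == "closed_form" and lam1 - lam2 < _DEGENERATE_TOL * lam1:
        method = "simulate"
    if method == "closed_form":
        conc = steady_state_conc_matrix(
            np.array([ind.cl]), np.array([ind.q]), np.array([ind.v1]),
            np.array([ind.v2]), regimen, times,
        )[0]
    elif method == "simulate":
        n_doses = int(math.ceil(10.0 * math.log(2.0) / lam2 / regimen.interval)) + 1
        t0 = (n_doses - 1) * regimen.interval
        run = DosingRegimen(regimen.dose, regimen.interval,
                            regimen.infusion_duration, n_doses=n_doses)
        conc = conc_profile(ind, run, t0 + times)
    else:
        raise ValueError(f"unknown method {method!r}")
    conc = np.maximum(conc, 0.0)  # clip float dust at the trough
    return ConcentrationProfile(times=times, concentrations=conc, regimen=regimen)


def window_profile(
    ind: IndividualPKParams,
    regimen: DosingRegimen,
    t_start: float = 0.0,
    t_end: float = 24.0,
    dt: float = 0.05,
) -> ConcentrationProfile:
    """Transient (from first dose) profile over [t_start, t_end]."""
    if not 0 <= t_start < t_end:
        raise ValueError("need 0 <= t_start < t_end")
    m = max(1, int(math.ceil((t_end - t_start) / dt - 1e-9)))
    times = np.linspace(t_start, t_end, m + 1)
    conc = np.maximum(conc_profile(ind, regimen, times), 0.0)
    return ConcentrationProfile(times=times, concentrations=conc, regimen=regimen)


def css_continuous(daily_dose: float, cl: float) -> float:
    """Steady-state concentration (mg/L) of a continuous infusion.

    Mass balance: Css = (daily dose / 24 h) / CL.
    """
    if cl <= 0:
        raise ValueError("cl must be positive")
    return (daily_dose / 24.0) / cl
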