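"""Shared fixtures and the independent ODE oracle for the PK solution."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from meropk import (
    CovariateSet,
    DosingRegimen,
    IndividualPKParams,
    PopPKParams,
    individual_params,
)

NINE_POINT_SCHEDULE = np.array([3.0, 5, 8, 11, 13, 16, 19, 21, 24])


@pytest.fixture(scope="session")
def pop() -> PopPKParams:
    return PopPKParams()


@pytest.fixture(scope="session")
def template_cov() -> CovariateSet:
    """Cohort-mean covariates (age 63, weight 70.2 kg, SCr 3.4, male)."""
    return CovariateSet(age=63.0, sex="male", weight=70.2, scr=3.4)


@pytest.fixture(scope="session")
def typical_individual(pop, template_cov) -> IndividualPKParams:
    return individual_params(pop, template_cov, np.zeros(3))


@pytest.fixture(scope="session")
def regimen_q8h() -> DosingRegimen:
    return DosingRegimen(dose=1000, interval=8, infusion_duration=3)


@pytest.fixture(scope="session")
def regimen_q12h() -> DosingRegimen:
    return DosingRegimen(dose=1000, interval=12, infusion_duration=0.5)


@pytest.fixture(scope="session")
def regimen_continuous() -> DosingRegimen:
    return DosingRegimen(dose=3000, interval=24, infusion_duration=24)


def ode_conc(
    ind: IndividualPKParams, regimen: DosingRegimen, times: np.ndarray
) -> np.ndarray:
    """Numerically integrate the two-compartment system (independent oracle).

    Piecewise integration between infusion on/off breakpoints with a
    constant input rate on each piece, so the integrator never steps over
    a discontinuity.
    """
    times = np.asarray(times, float)
    t_max = float(times.max())
    k10 = ind.cl / ind.v1
    k12 = ind.q / ind.v1
    k21 = ind.q / ind.v2

    events = []
    for start in regimen.infusion_starts(t_max):
        events.append((start, regimen.rate))
        events.append((start + regimen.infusion_duration, -regimen.rate))
    breaks = sorted({0.0, t_max, *(t for t, _ in events if t < t_max)})

    def rate_at(t: float) -> float:
        return sum(r for t0, r in events if t0 <= t)

    out = np.zeros_like(times)
    state = np.zeros(2)  # amounts (mg) in central, peripheral
    for a, b in zip(breaks[:-1], breaks[1:]):
        rate = rate_at(0.5 * (a + b))

        def rhs(t, y, rate=rate):
            a1, a2 = y
            return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

        sol = solve_ivp(
            rhs, (a, b), state, rtol=1e-10, atol=1e-12,
            method="LSODA", dense_output=True,
        )
        mask = (times > a) & (times <= b)
        if mask.any():
            out[mask] = sol.sol(times[mask])[0]
        state = sol.y[:, -1]
    return out / ind.v1


def random_individual(rng: np.random.Generator) -> IndividualPKParams:
    """Physiologically broad random parameter draw for property tests."""
    return IndividualPKParams(
        cl=float(rng.uniform(1.0, 15.0)),
        q=float(rng.uniform(2.0, 15.0)),
        v1=float(rng.uniform(5.0, 30.0)),
        v2=float(rng.uniform(4.0, 30.0)),
    )


def random_regimen(rng: np.random.Generator) -> DosingRegimen:
    interval = float(rng.choice([6.0, 8.0, 12.0, 24.0]))
    duration = float(rng.uniform(0.25, interval))
    return DosingRegimen(
        dose=float(rng.uniform(250, 3000)),
        interval=interval,
        infusion_duration=duration,
    )
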