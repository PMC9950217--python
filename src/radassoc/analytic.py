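"""Deterministic reference computations.

Two independent analytic routes live here:

1. The phenomenological excess-relative-risk (ERR) model for LSS breast
   cancer.  The hazard is ``h(D, a) = h0(a) * (1 + ERR(D, a))`` with
   ``ERR(D, a) = 1.06 * D * exp(-1.92 * ln(a/70))`` and a log-quadratic
   baseline hazard with knots at ages 70 and 51.  Expected first-cancer case
   counts in an age window follow by quadrature with survival depletion.

2. The analytic hazard of the two-stage clonal expansion (TSCE) model.  For
   a clone started from one initiated cell at age ``s``, the probability
   ``u(s, t)`` of no malignant transformation by age ``t`` obeys the backward
   Riccati equation

       du/ds = -(alpha * u^2 - (alpha + beta(s) + mu) * u + beta(s)),
       u(t, t) = 1,

   and the person-level cancer-free survival of first transformation is
   ``S(t) = exp(-int_0^t N*nu(s) * (1 - u(s, t)) ds)``.  This is used to
   validate the Monte Carlo engine's marginal incidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, solve_ivp

from .params import ModelSpec, Scenario, effective_rates

__all__ = [
    "ERRModelSpec",
    "baseline_hazard",
    "excess_relative_risk",
    "err_hazard",
    "err_expected_cases",
    "no_transform_prob_const",
    "tsce_transform_survival",
    "tsce_hazard",
    "tsce_expected_window_cases",
    "HazardCurve",
]


@dataclass(frozen=True)
class ERRModelSpec:
    """Coefficients of the phenomenological ERR model (LSS breast cancer)."""

    err_per_gy: float = 1.06
    err_age_power: float = -1.92
    b0: float = -8.07
    b1: float = -3.37
    b2: float = -7.29
    b3: float = 8.87
    pivot_age: float = 70.0
    knot_age: float = 51.0
    lag_start_age: float = 35.0  # exposure age + lag; risk active from here

    def with_scenario(self, scenario: Scenario) -> "ERRModelSpec":
        """Risk becomes active one lag time after the exposure starts."""
        return ERRModelSpec(
            self.err_per_gy, self.err_age_power, self.b0, self.b1, self.b2,
            self.b3, self.pivot_age, self.knot_age,
            lag_start_age=scenario.exposure_start_age + scenario.t_lag,
        )


def baseline_hazard(age, spec: ERRModelSpec = ERRModelSpec()):
    """Baseline (unexposed) breast-cancer hazard h0(age) per year."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    la = np.log(age / spec.pivot_age)
    lk = np.maximum(0.0, np.log(age / spec.knot_age))
    return np.exp(spec.b0 + spec.b1 * la + spec.b2 * la * la + spec.b3 * lk * lk)


def excess_relative_risk(dose: float, age, spec: ERRModelSpec = ERRModelSpec()):
    """ERR(D_tot, age) = 1.06 * D_tot * exp(-1.92 * ln(age/70))."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    return spec.err_per_gy * dose * np.exp(
        spec.err_age_power * np.log(age / spec.pivot_age)
    )


def err_hazard(spec: ERRModelSpec, dose: float, age):
    """Full hazard h0(age) * (1 + ERR) with ERR active from lag_start_age."""
    age = np.asarray(age, dtype=float)
    h0 = baseline_hazard(age, spec)
    active = age >= spec.lag_start_age
    return h0 * (1.0 + np.where(active, excess_relative_risk(dose, age, spec), 0.0))


def _cumhaz0(a: float, spec: ERRModelSpec) -> float:
    if a <= 0:
        return 0.0
    val, _ = quad(lambda x: baseline_hazard(x, spec), 0.0, a,
                  points=[spec.knot_age] if 0 < spec.knot_age < a else None,
                  limit=200, epsrel=1e-10, epsabs=1e-14)
    return val


def _cumhaz_excess(a: float, dose: float, spec: ERRModelSpec) -> float:
    s = spec.lag_start_age
    if a <= s or dose == 0.0:
        return 0.0
    val, _ = quad(
        lambda x: baseline_hazard(x, spec) * excess_relative_risk(dose, x, spec),
        s, a, limit=200, epsrel=1e-10, epsabs=1e-14,
    )
    return val


def err_expected_cases(
    spec: ERRModelSpec,
    scenario: Scenario,
    n_persons: int | None = None,
    depletion: bool = False,
) -> dict:
    """Expected cancer case counts in the scoring window under the ERR model.

    By default the counts are plain hazard integrals over the window,
    ``n * int_w h(a) da`` — the rate-times-person-years convention of
    phenomenological risk models, where depletion of the at-risk population
    by earlier cancers is neglected (cumulative hazard to age 60 is below
    0.03, so the correction would be ~1-3%).  With ``depletion=True`` the
    counts are first-cancer counts ``n * [S(w_lo) - S(w_hi)]`` instead.

    Returns a dict with ``spo`` (unexposed), ``tot`` (exposed), ``exc``,
    the interval ``ERR = exc/spo`` and ``AS = exc/tot``.
    """
    spec = spec.with_scenario(scenario)
    n = scenario.n_persons if n_persons is None else n_persons
    w_lo, w_hi = scenario.window
    dose = scenario.dose_total

    if depletion:
        S0 = {a: math.exp(-_cumhaz0(a, spec)) for a in (w_lo, w_hi)}
        S = {
            a: math.exp(-(_cumhaz0(a, spec) + _cumhaz_excess(a, dose, spec)))
            for a in (w_lo, w_hi)
        }
        spo = n * (S0[w_lo] - S0[w_hi])
        tot = n * (S[w_lo] - S[w_hi])
    else:
        spo = n * (_cumhaz0(w_hi, spec) - _cumhaz0(w_lo, spec))
        tot = spo + n * (
            _cumhaz_excess(w_hi, dose, spec) - _cumhaz_excess(w_lo, dose, spec)
        )
    exc = tot - spo
    return {
        "spo": spo,
        "tot": tot,
        "exc": exc,
        "ERR": exc / spo if spo > 0 else math.nan,
        "AS": exc / tot if tot > 0 else math.nan,
    }


# ---------------------------------------------------------------------------
# TSCE analytic hazard
# ---------------------------------------------------------------------------


def no_transform_prob_const(
    alpha: float, beta: float, mu: float, tau: float
) -> float:
    """Closed-form P(no transformation within tau) for a clone started from
    one cell under constant rates (constant-coefficient Riccati solution).

    With r1 < 1 < r2 the roots of ``alpha x^2 - (alpha+beta+mu) x + beta``,
    ``u(tau) = (r1 - r2 W) / (1 - W)`` where
    ``W = ((1-r1)/(1-r2)) * exp(alpha (r1-r2) tau)``.
    """
    if tau <= 0:
        return 1.0
    s = alpha + beta + mu
    disc = math.sqrt(s * s - 4.0 * alpha * beta)
    r1 = (s - disc) / (2.0 * alpha)
    r2 = (s + disc) / (2.0 * alpha)
    w = (1.0 - r1) / (1.0 - r2) * math.exp(alpha * (r1 - r2) * tau)
    return (r1 - r2 * w) / (1.0 - w)


def _segment_breaks(scenario: Scenario, t: float) -> list[float]:
    pts = {0.0, t}
    for b in (scenario.exposure_start_age, scenario.exposure_end_age):
        if 0.0 < b < t:
            pts.add(b)
    return sorted(pts)


def _cancer_prob_and_cumhaz(
    model: ModelSpec, scenario: Scenario, t: float, exposed: bool
) -> float:
    """Cumulative transformation hazard Lambda(t) = -ln S(t).

    Solves the backward Riccati equation for u(s, t) jointly with the
    initiation integral, piecewise over the constant-rate (or smoothly
    ramping) segments.
    """
    if t <= 0:
        return 0.0
    alpha = model.alpha0
    mu = model.mu0

    def rates(s: float) -> tuple[float, float]:
        r = effective_rates(model, scenario, min(s, scenario.follow_up_end))
        if exposed:
            return r.nu_rate, r.beta_rad
        return model.N_nu0, r.beta_spont

    def rhs(s, y):
        u = y[0]
        nu, beta = rates(s)
        du = -(alpha * u * u - (alpha + beta + mu) * u + beta)
        dlam = -nu * (1.0 - u)
        return [du, dlam]

    y = [1.0, 0.0]
    breaks = _segment_breaks(scenario, t)
    # integrate s downwards from t to 0, stopping at rate breakpoints
    for lo, hi in zip(breaks[-2::-1], breaks[::-1]):
        sol = solve_ivp(
            rhs, (hi, lo), y, method="RK45", rtol=1e-9, atol=1e-12,
            dense_output=False,
        )
        if not sol.success:  # pragma: no cover - diagnostics path
            raise RuntimeError(f"Riccati integration failed: {sol.message}")
        y = [sol.y[0][-1], sol.y[1][-1]]
    return max(y[1], 0.0)


@dataclass(frozen=True)
class HazardCurve:
    """Analytic transformation hazard/survival evaluated on an age grid."""

    age: np.ndarray  # transformation ages, years
    hazard: np.ndarray  # per year
    survival: np.ndarray  # P(no transformation by age)

    def to_frame(self):
        """Tabular view (age, hazard, survival) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {"age": self.age, "hazard": self.hazard,
             "survival": self.survival}
        )


def tsce_transform_survival(
    model: ModelSpec, scenario: Scenario, ages, exposed: bool = False
) -> np.ndarray:
    """P(no malignant transformation by each age) for one person."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    lam = np.array(
        [_cancer_prob_and_cumhaz(model, scenario, t, exposed) for t in ages]
    )
    return np.exp(-lam)


def tsce_hazard(
    model: ModelSpec, scenario: Scenario, ages, exposed: bool = False
) -> HazardCurve:
    """Analytic TSCE transformation hazard on a grid.

    Survival values are accurate to the ODE tolerance; the hazard is obtained
    by central differences of the cumulative hazard on the supplied grid.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    lam = np.array(
        [_cancer_prob_and_cumhaz(model, scenario, t, exposed) for t in ages]
    )
    hazard = np.gradient(lam, ages) if ages.size > 1 else np.zeros_like(lam)
    return HazardCurve(age=ages, hazard=hazard, survival=np.exp(-lam))


def tsce_expected_window_cases(
    model: ModelSpec,
    scenario: Scenario,
    exposed: bool = False,
    window: tuple[float, float] | None = None,
    n_persons: int | None = None,
) -> float:
    """Expected first cancers in a cancer-age window per cohort.

    Cancer age = transformation age + t_lag, so the window is shifted back by
    the lag before evaluating the transformation survival.
    """
    w_lo, w_hi = window if window is not None else scenario.window
    n = scenario.n_persons if n_persons is None else n_persons
    s = tsce_transform_survival(
        model, scenario,
        [w_lo - scenario.t_lag, w_hi - scenario.t_lag],
        exposed=exposed,
    )
    return float(n * (s[0] - s[1]))
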