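"""Model parameterizations, exposure scenarios and effective-rate evaluation.

The two-stage clonal expansion (TSCE) model describes carcinogenesis as
initiation of healthy stem cells (pool rate ``N*nu``), clonal expansion of
initiated cells by symmetric division (rate ``alpha``) versus
differentiation/inactivation (rate ``beta``), and malignant transformation
(rate ``mu`` per initiated cell).  Cancer becomes observable ``t_lag`` years
after the first malignant cell.  All rates are per year; ages are continuous
years.

Three named parameter sets are shipped, all calibrated to LSS breast-cancer
incidence, differing only in how radiation acts:

``M_I``
    instantaneous effect on initiation, ``nu = nu0 * (1 + 52.4 * d)`` with
    dose rate ``d`` in Gy/year, active only while the exposure lasts.
``M_P``
    instantaneous effect on promotion, ``beta = beta0 - 2.3 * d`` during
    exposure (raising the net clonal expansion rate ``gamma = alpha - beta``).
``M_P-ll``
    lifelong effect on promotion, ``beta = beta0 - 0.112/yr * D_tot`` with
    ``D_tot`` the dose accumulated so far; the reduction persists after the
    exposure has ended.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import yaml

__all__ = [
    "RadiationEffect",
    "ModelSpec",
    "Scenario",
    "EffectiveRates",
    "MODEL_PRESETS",
    "MODEL_INDEX",
    "DEFAULT_SCENARIO",
    "get_model",
    "effective_rates",
    "accumulated_dose",
    "check_step_criterion",
    "load_config",
]

#: Stable integer id per model, used for seeding independent random streams.
MODEL_INDEX = {"M_I": 0, "M_P": 1, "M_P-ll": 2}

#: The step criterion: (any rate) * dt must stay below 1/25.
MAX_RATE_DT = 1.0 / 25.0


@dataclass(frozen=True)
class RadiationEffect:
    """How radiation modifies the TSCE rates.

    ``slope`` is per Gy/year of dose rate for instantaneous effects and per
    (Gy * year) of accumulated dose for lifelong effects.
    """

    target: str  # "initiation" | "promotion"
    persistence: str  # "instantaneous" | "lifelong"
    slope: float

    def __post_init__(self) -> None:
        if self.target not in ("initiation", "promotion"):
            raise ValueError(f"unknown radiation target {self.target!r}")
        if self.persistence not in ("instantaneous", "lifelong"):
            raise ValueError(f"unknown persistence {self.persistence!r}")
        if self.slope < 0:
            raise ValueError("radiation-effect slope must be non-negative")


@dataclass(frozen=True)
class ModelSpec:
    """One TSCE parameterization: baseline rates plus the radiation effect.

    Parameters
    ----------
    N_nu0
        Spontaneous initiation rate of the whole stem-cell pool
        (new clones per year).
    alpha0
        Symmetric division rate per initiated cell per year.
    beta0
        Differentiation/inactivation rate per initiated cell per year.
        Supercriticality ``alpha0 > beta0`` is required; the effective clonal
        expansion rate is ``gamma = alpha0 - beta0``.
    mu0
        Malignant transformation rate per initiated cell per year.
    """

    name: str
    N_nu0: float
    alpha0: float
    beta0: float
    mu0: float
    effect: RadiationEffect

    def __post_init__(self) -> None:
        if not (self.N_nu0 >= 0):
            raise ValueError("N_nu0 must be non-negative")
        for attr in ("alpha0", "beta0", "mu0"):
            if not (getattr(self, attr) > 0):
                raise ValueError(f"{attr} must be strictly positive")
        if not self.alpha0 > self.beta0:
            raise ValueError(
                "alpha0 must exceed beta0 (supercritical clonal expansion)"
            )
        if not self.mu0 < 1e-3:
            raise ValueError("mu0 implausibly large; transformation is rare")

    @property
    def gamma0(self) -> float:
        """Baseline effective clonal expansion rate alpha0 - beta0."""
        return self.alpha0 - self.beta0


#: The three shipped TSCE parameter sets (LSS breast cancer calibration).
MODEL_PRESETS: dict[str, ModelSpec] = {
    "M_I": ModelSpec(
        name="M_I",
        N_nu0=0.054,
        alpha0=12.0,
        beta0=11.837,
        mu0=3.83e-6,
        effect=RadiationEffect("initiation", "instantaneous", 52.4),
    ),
    "M_P": ModelSpec(
        name="M_P",
        N_nu0=0.177,
        alpha0=12.0,
        beta0=11.913,
        mu0=4.64e-6,
        effect=RadiationEffect("promotion", "instantaneous", 2.3),
    ),
    "M_P-ll": ModelSpec(
        name="M_P-ll",
        N_nu0=0.076,
        alpha0=12.0,
        beta0=11.867,
        mu0=4.30e-6,
        effect=RadiationEffect("promotion", "lifelong", 0.112),
    ),
}

_ALIASES = {
    "MI": "M_I",
    "M_I": "M_I",
    "MP": "M_P",
    "M_P": "M_P",
    "MPLL": "M_P-ll",
    "M_PLL": "M_P-ll",
    "M_P-LL": "M_P-ll",
}


def get_model(name: str) -> ModelSpec:
    """Look up a shipped model preset by name (aliases MI/MP/MPll accepted)."""
    key = _ALIASES.get(name.upper().replace("-", "-"))
    if key is None:
        key = _ALIASES.get(name.upper().replace("-", "_"))
    if key is None:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_PRESETS)}"
        )
    return MODEL_PRESETS[key]


@dataclass(frozen=True)
class Scenario:
    """Exposure timing, scoring window and simulation controls.

    The default reproduces the reference scenario: a single 1-year exposure
    delivering 1 Gy to breast tissue at age 30, a fixed 5-year lag from
    malignant transformation to observable cancer, follow-up to age 80 and
    scoring of cancers in the half-open age window [60, 61).
    """

    dose_total: float = 1.0  # Gy
    exposure_start_age: float = 30.0  # years
    exposure_duration: float = 1.0  # years
    t_lag: float = 5.0  # years
    follow_up_end: float = 80.0  # years
    window: tuple[float, float] = (60.0, 61.0)
    n_persons: int = 1_000_000
    n_runs: int = 10
    base_seed: int = 1
    dt: float = 1.0 / 365.0  # years

    def __post_init__(self) -> None:
        w_lo, w_hi = self.window
        if not w_lo < w_hi:
            raise ValueError("window must be a non-empty half-open interval")
        if self.exposure_start_age + self.exposure_duration > w_lo:
            raise ValueError("exposure must end before the scoring window")
        if w_hi > self.follow_up_end:
            raise ValueError("scoring window must lie within follow-up")
        if self.dose_total < 0:
            raise ValueError("dose must be non-negative")
        if self.exposure_duration <= 0:
            raise ValueError("exposure duration must be positive")
        if self.t_lag < 0:
            raise ValueError("lag time must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_persons < 0 or self.n_runs < 0:
            raise ValueError("cohort size and run count must be non-negative")

    @property
    def dose_rate(self) -> float:
        """Constant dose rate during exposure, Gy/year."""
        return self.dose_total / self.exposure_duration

    @property
    def exposure_end_age(self) -> float:
        return self.exposure_start_age + self.exposure_duration

    @property
    def t_sim_end(self) -> float:
        """Latest transformation age that can still produce an observable
        cancer within follow-up (= follow_up_end - t_lag)."""
        return self.follow_up_end - self.t_lag

    def replace(self, **kwargs) -> "Scenario":
        return dataclasses.replace(self, **kwargs)


DEFAULT_SCENARIO = Scenario()


def accumulated_dose(scenario: Scenario, age: float) -> float:
    """Dose in Gy accumulated up to ``age`` (linear ramp during exposure)."""
    elapsed = age - scenario.exposure_start_age
    if elapsed <= 0:
        return 0.0
    return scenario.dose_rate * min(elapsed, scenario.exposure_duration)


class EffectiveRates(NamedTuple):
    """Per-year rates at one age: exposed-world initiation rate of the pool,
    division rate, spontaneous and radiation-modified inactivation rates, and
    the transformation rate."""

    nu_rate: float
    alpha: float
    beta_spont: float
    beta_rad: float
    mu: float


def effective_rates(model: ModelSpec, scenario: Scenario, age: float) -> EffectiveRates:
    """Evaluate spontaneous and radiation-modified rates at a given age.

    For the initiation model the pool initiation rate ``N*nu`` is elevated
    during exposure only.  For instantaneous promotion, ``beta`` is reduced
    proportionally to the dose rate during exposure.  For lifelong promotion,
    ``beta`` is reduced proportionally to the dose accumulated so far and
    stays reduced for the rest of life.
    """
    if not (0.0 <= age <= scenario.follow_up_end):
        raise ValueError(f"age {age} outside [0, {scenario.follow_up_end}]")
    in_exposure = scenario.exposure_start_age <= age < scenario.exposure_end_age
    d = scenario.dose_rate if in_exposure else 0.0

    nu_rate = model.N_nu0
    beta_rad = model.beta0
    eff = model.effect
    if eff.target == "initiation":
        if in_exposure:
            nu_rate = model.N_nu0 * (1.0 + eff.slope * scenario.dose_rate)
    else:  # promotion
        if eff.persistence == "instantaneous":
            beta_rad = model.beta0 - eff.slope * d
        else:  # lifelong: proportional to accumulated dose, permanent
            beta_rad = model.beta0 - eff.slope * accumulated_dose(scenario, age)
    if beta_rad < 0 or nu_rate < 0:
        raise ValueError(
            "radiation-modified rate became negative; "
            "model and scenario are incompatible"
        )
    return EffectiveRates(nu_rate, model.alpha0, model.beta0, beta_rad, model.mu0)


def check_step_criterion(model: ModelSpec, scenario: Scenario) -> None:
    """Validate dt against the largest effective rate (rate * dt < 1/25)."""
    nu_max = model.N_nu0
    if model.effect.target == "initiation":
        nu_max = model.N_nu0 * (1.0 + model.effect.slope * scenario.dose_rate)
    biggest = max(model.alpha0, model.beta0, model.mu0, nu_max)
    if biggest * scenario.dt >= MAX_RATE_DT:
        raise ValueError(
            f"time step dt={scenario.dt:g} violates the step criterion: "
            f"max rate {biggest:g}/yr * dt = {biggest * scenario.dt:.4f} "
            f">= {MAX_RATE_DT:g}; reduce dt"
        )


_SCENARIO_KEYS = {
    "dose_total",
    "exposure_start_age",
    "exposure_duration",
    "t_lag",
    "follow_up_end",
    "n_persons",
    "n_runs",
    "base_seed",
    "dt",
}


def load_config(path) -> tuple[ModelSpec, Scenario]:
    """Read a YAML config file and resolve (model, scenario).

    Recognized keys: ``model`` (required; one of MI/MP/MPll or the full
    names), the Scenario field names, and ``window_lo``/``window_hi``.
    Unknown keys raise, so typos do not silently fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of key: value pairs")
    if "model" not in raw:
        raise KeyError("config is missing the required key 'model'")
    model = get_model(str(raw.pop("model")))
    window = list(DEFAULT_SCENARIO.window)
    if "window_lo" in raw:
        window[0] = float(raw.pop("window_lo"))
    if "window_hi" in raw:
        window[1] = float(raw.pop("window_hi"))
    kwargs = {}
    for key in list(raw):
        if key not in _SCENARIO_KEYS:
            raise KeyError(f"unknown config key {key!r}")
        kwargs[key] = raw.pop(key)
    for int_key in ("n_persons", "n_runs", "base_seed"):
        if int_key in kwargs:
            kwargs[int_key] = int(kwargs[int_key])
    scenario = Scenario(window=(window[0], window[1]), **kwargs)
    check_step_criterion(model, scenario)
    return model, scenario
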