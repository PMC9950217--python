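"""Whole-person and cohort simulation.

Each person is simulated from birth to the end of follow-up in two worlds at
once: the counterfactual unexposed world and the exposed world.  Clones are
initiated spontaneously in both worlds; radiation adds excess
radiation-associated clones (initiation models) or couples/forks existing
clones (promotion models, see :mod:`radassoc.clones`).  Per person only two
events matter and both are always recorded: the first cancer on the
spontaneous side and the first radiation-associated cancer.  Growth stopping
is label-stratified — a spontaneous-lineage cancer stops only
spontaneous-lineage clones and vice versa — which is exactly equivalent to
recording the earliest transformation of each label.

A transformation at age ``t`` becomes an observable cancer at ``t + t_lag``;
transformations later than ``follow_up_end - t_lag`` can never be observed
and are not simulated.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .params import (
    MODEL_INDEX,
    ModelSpec,
    Scenario,
    check_step_criterion,
)

__all__ = ["PersonOutcome", "RunResult", "simulate_person", "simulate_cohort"]

logger = logging.getLogger(__name__)

_KIND = {
    ("initiation", "instantaneous"): _engine.KIND_INITIATION,
    ("promotion", "instantaneous"): _engine.KIND_PROMO_INST,
    ("promotion", "lifelong"): _engine.KIND_PROMO_LL,
}
_SCHEME = {"thinning": _engine.THINNING, "independent": _engine.INDEPENDENT}


@dataclass(frozen=True)
class PersonOutcome:
    """First-cancer ages of one person in the two worlds.

    ``None`` means no cancer within follow-up.  If the exposed-world cancer
    is not radiation-associated it is the same cancer (same age) that occurs
    in the counterfactual world.
    """

    spont_cancer_age: float | None
    exposed_cancer_age: float | None
    exposed_cancer_rad_associated: bool


@dataclass
class RunResult:
    """Vectorized outcomes of one cohort run.

    ``spont_age`` and ``exposed_age`` are cancer ages (transformation age
    plus lag) with NaN for "no cancer within follow-up"; ``exposed_rad``
    flags whether the exposed-world first cancer came from a
    radiation-associated lineage.
    """

    spont_age: np.ndarray
    exposed_age: np.ndarray
    exposed_rad: np.ndarray
    model: ModelSpec
    scenario: Scenario
    run_index: int

    @property
    def n_persons(self) -> int:
        return self.spont_age.shape[0]

    def outcome(self, i: int) -> PersonOutcome:
        s = self.spont_age[i]
        e = self.exposed_age[i]
        return PersonOutcome(
            None if np.isnan(s) else float(s),
            None if np.isnan(e) else float(e),
            bool(self.exposed_rad[i]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": np.arange(self.n_persons),
                "spont_age": self.spont_age,
                "exposed_age": self.exposed_age,
                "rad_label": self.exposed_rad.astype(int),
            }
        )


def _person_seeds(scenario: Scenario, model: ModelSpec, run_index: int,
                  n: int) -> np.ndarray:
    """Independent 32-bit seeds per person, reproducible and
    order-independent: f(base_seed, model, run_index, person_index)."""
    model_key = MODEL_INDEX.get(
        model.name, zlib.crc32(model.name.encode()) & 0x7FFFFFFF
    )
    ss = np.random.SeedSequence(
        [int(scenario.base_seed), model_key, int(run_index)]
    )
    return ss.generate_state(n, dtype=np.uint32)


def _engine_args(model: ModelSpec, scenario: Scenario, coupling: str):
    kind = _KIND[(model.effect.target, model.effect.persistence)]
    return (
        kind,
        model.N_nu0,
        model.alpha0,
        model.beta0,
        model.mu0,
        model.effect.slope,
        scenario.dose_rate,
        scenario.dose_total,
        scenario.exposure_start_age,
        scenario.exposure_end_age,
        scenario.t_sim_end,
        scenario.dt,
        _SCHEME[coupling],
    )


def simulate_cohort(
    model: ModelSpec,
    scenario: Scenario,
    run_index: int = 0,
    coupling: str = "independent",
    chunk_size: int = 20_000,
) -> RunResult:
    """Simulate ``scenario.n_persons`` independent persons.

    Per-person seeding makes the result bit-reproducible for a given
    (base_seed, model, run_index) regardless of chunking.
    """
    check_step_criterion(model, scenario)
    if coupling not in _SCHEME:
        raise ValueError(f"unknown coupling scheme {coupling!r}")
    n = scenario.n_persons
    seeds = _person_seeds(scenario, model, run_index, n)
    t_shared = np.empty(n)
    t_sp = np.empty(n)
    t_rad = np.empty(n)
    args = _engine_args(model, scenario, coupling)
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        _engine.simulate_chunk(
            seeds[lo:hi], *args, t_shared[lo:hi], t_sp[lo:hi], t_rad[lo:hi]
        )
        if hi % 100_000 == 0 or hi == n:
            logger.info(
                "%s run %d: %d / %d persons", model.name, run_index, hi, n
            )

    lag = scenario.t_lag
    spont_t = np.minimum(t_shared, t_sp)
    exposed_t = np.minimum(t_shared, t_rad)
    # ties between a shared and a radiation-associated transformation in the
    # same step are broken toward the spontaneous label
    exposed_rad = t_rad < t_shared

    spont_age = np.where(np.isfinite(spont_t), spont_t + lag, np.nan)
    exposed_age = np.where(np.isfinite(exposed_t), exposed_t + lag, np.nan)
    return RunResult(
        spont_age=spont_age,
        exposed_age=exposed_age,
        exposed_rad=exposed_rad,
        model=model,
        scenario=scenario,
        run_index=run_index,
    )


def simulate_person(
    model: ModelSpec,
    scenario: Scenario,
    run_index: int = 0,
    person_index: int = 0,
    coupling: str = "independent",
) -> PersonOutcome:
    """Simulate a single person (person ``person_index`` of the cohort)."""
    check_step_criterion(model, scenario)
    seeds = _person_seeds(
        model=model, scenario=scenario, run_index=run_index,
        n=person_index + 1,
    )[person_index : person_index + 1]
    out = tuple(np.empty(1) for _ in range(3))
    _engine.simulate_chunk(seeds, *_engine_args(model, scenario, coupling), *out)
    t_shared, t_sp, t_rad = (float(a[0]) for a in out)
    lag = scenario.t_lag
    spont_t = min(t_shared, t_sp)
    exposed_t = min(t_shared, t_rad)
    return PersonOutcome(
        spont_cancer_age=spont_t + lag if np.isfinite(spont_t) else None,
        exposed_cancer_age=exposed_t + lag if np.isfinite(exposed_t) else None,
        exposed_cancer_rad_associated=bool(t_rad < t_shared),
    )
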