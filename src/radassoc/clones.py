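"""Per-time-step stochastic evolution of clones of initiated cells.

A clone is a lineage descending from a single initiated cell.  Within one
time step of length ``dt`` each of its ``m`` cells independently divides
(probability ``alpha*dt``), differentiates/dies (``beta*dt``), transforms
malignantly (``mu*dt``) or stays.  Per clone and step this is one multinomial
draw over (divide, die, transform, stay) — equivalent to per-cell draws but
O(1) per clone per step.

While a promotion-type radiation action is active the clone is evolved
*coupled*: each step is computed separately with and without the radiation
action.  Under the default ``independent`` scheme the two worlds draw their
step outcomes independently; if the outcomes agree, radiation is assumed to
have had no influence and the clone remains one lineage, and on the first
disagreement the lineages *fork* — the intuition being that a
radiation-induced size change alters the clone's microenvironment and
decorrelates subsequent cell fates.  From the fork on the two copies evolve
independently and the radiation copy is marked radiation-associated.  The
alternative ``thinning`` scheme is a maximal coupling: divisions and
transformations are shared, deaths are drawn at the higher spontaneous rate
``beta0`` and each death is accepted for the radiation lineage with
probability ``beta_rad/beta0``, so the worlds stay in lockstep exactly until
a death is thinned away.  Thinning forks far more rarely (and only with the
radiation copy larger), which suppresses retarded cases; it is kept as a
sensitivity variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Clone", "StepOutcome", "sample_new_clones", "step_clone",
           "step_clone_coupled"]

_clone_ids = itertools.count()


@dataclass
class Clone:
    """A lineage of initiated cells."""

    size: int
    birth_age: float
    rad_associated: bool = False
    world: str = "spontaneous"  # "spontaneous" | "exposed"
    forked_from: int | None = None
    id: int = field(default_factory=lambda: next(_clone_ids))

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("clone size must be non-negative")

    @property
    def extinct(self) -> bool:
        return self.size == 0


@dataclass(frozen=True)
class StepOutcome:
    """Result of evolving one clone over one time step."""

    new_size: int
    transformed: bool
    transform_age: float | None = None


def sample_new_clones(rate: float, dt: float, rng: np.random.Generator) -> int:
    """Number of clones newly initiated in one step, Poisson(rate * dt).

    Each new clone starts from a single initiated cell at the current age.
    """
    if rate < 0:
        raise ValueError("initiation rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rate == 0.0:
        return 0
    return int(rng.poisson(rate * dt))


def _step_counts(
    size: int, alpha: float, beta: float, mu: float, dt: float,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """One multinomial step: (divisions, deaths, transformations)."""
    pa, pb, pm = alpha * dt, beta * dt, mu * dt
    p_stay = 1.0 - pa - pb - pm
    if p_stay <= 0.0:
        raise ValueError(
            "per-cell event probabilities sum to >= 1; reduce dt"
        )
    n_div, n_die, n_tr, _ = rng.multinomial(size, [pa, pb, pm, p_stay])
    return int(n_div), int(n_die), int(n_tr)


def step_clone(
    size: int, alpha: float, beta: float, mu: float, dt: float,
    rng: np.random.Generator, age: float = 0.0,
) -> StepOutcome:
    """Evolve a clone of ``size`` cells over one time step.

    A transforming cell is recorded as a malignant event; at ``mu`` about six
    orders of magnitude below ``alpha`` it is irrelevant whether the
    transformed cell leaves the initiated pool, so it is kept in it.
    """
    if size < 1:
        raise ValueError("step_clone requires a live clone (size >= 1)")
    n_div, n_die, n_tr = _step_counts(size, alpha, beta, mu, dt, rng)
    return StepOutcome(
        new_size=size + n_div - n_die,
        transformed=n_tr > 0,
        transform_age=age + dt if n_tr > 0 else None,
    )


def step_clone_coupled(
    clone: Clone,
    rates_spont: tuple[float, float, float],
    rates_rad: tuple[float, float, float],
    dt: float,
    rng: np.random.Generator,
    scheme: str = "independent",
    age: float = 0.0,
) -> tuple[StepOutcome, StepOutcome, bool]:
    """Evolve an unforked clone one step in both worlds simultaneously.

    ``rates_spont``/``rates_rad`` are (alpha, beta, mu) tuples.  Returns the
    spontaneous-world outcome, the exposed-world outcome and whether the
    lineages forked this step (their sizes now differ, or — under the
    independent scheme — their event histories diverged).
    """
    if clone.forked_from is not None:
        raise ValueError(
            "clone already forked; step its lineages independently"
        )
    if clone.size < 1:
        raise ValueError("cannot step an extinct clone")
    a_s, b_s, m_s = rates_spont
    a_r, b_r, m_r = rates_rad

    if scheme == "thinning":
        if not (a_r == a_s and m_r == m_s):
            raise ValueError(
                "thinning couples promotion effects only (alpha, mu shared)"
            )
        if b_r > b_s:
            raise ValueError("thinning requires beta_rad <= beta_spont")
        n_div, n_die, n_tr = _step_counts(clone.size, a_s, b_s, m_s, dt, rng)
        # each spontaneous-world death survives in the radiation lineage
        # with probability 1 - beta_rad/beta_spont
        n_acc = int(rng.binomial(n_die, b_r / b_s)) if n_die and b_s > 0 else n_die
        out_s = StepOutcome(clone.size + n_div - n_die, n_tr > 0,
                            age + dt if n_tr > 0 else None)
        out_r = StepOutcome(clone.size + n_div - n_acc, n_tr > 0,
                            age + dt if n_tr > 0 else None)
        return out_s, out_r, n_die > n_acc
    if scheme == "independent":
        out_s = step_clone(clone.size, a_s, b_s, m_s, dt, rng, age)
        out_r = step_clone(clone.size, a_r, b_r, m_r, dt, rng, age)
        forked = (out_s.new_size != out_r.new_size) or (
            out_s.transformed != out_r.transformed
        )
        return out_s, out_r, forked
    raise ValueError(f"unknown coupling scheme {scheme!r}")
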