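"""Counterfactual case classification and association measures.

Each exposed person's cancer in the scoring window is compared against the
same person's counterfactual unexposed world:

* ``unaffected`` — the window cancer is not radiation-associated (the same
  cancer occurs at the same age without the exposure);
* ``new`` — radiation-associated, and no spontaneous cancer occurs before
  the end of follow-up;
* ``accelerated`` — radiation-associated, and the spontaneous cancer would
  have occurred after the window;
* ``retarded`` — radiation-associated, and the spontaneous cancer would
  have occurred before the window (the exposure delayed it into the window
  through the stochasticity of clonal growth).

From the cohort tallies the population-level assigned share
``AS = (tot - spo)/tot`` and the mechanism-level association measures are
derived: PA = (new+acc+ret)/tot, PH = (new+acc)/tot, PEH = (new+acc-ret)/tot,
PR = ret/tot and HRR = (new+acc)/ret.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .person import PersonOutcome, RunResult

__all__ = [
    "CaseClass",
    "CohortTally",
    "AssociationMeasures",
    "AccelerationHistogram",
    "classify_codes",
    "classify_person",
    "tally",
    "measures",
    "acceleration_histogram",
    "followup_invariance_check",
]


class CaseClass(enum.IntEnum):
    """Classification of one person's exposed-world window cancer."""

    NONE = 0  # no exposed-world cancer in the window
    UNAFFECTED = 1
    NEW = 2
    ACCELERATED = 3
    RETARDED = 4


def classify_codes(
    spont_age: np.ndarray,
    exposed_age: np.ndarray,
    exposed_rad: np.ndarray,
    window: tuple[float, float],
    follow_up_end: float,
) -> np.ndarray:
    """Vectorized classification; NaN ages mean "no cancer in follow-up".

    A spontaneous cancer age beyond ``follow_up_end`` counts as none, which
    makes the same outcomes reusable under a truncated follow-up.  The edge
    case of both cancers falling inside the window is resolved by the sign
    of the age shift (earlier exposed-world cancer: accelerated; later:
    retarded; identical age: unaffected).
    """
    w_lo, w_hi = window
    spont = np.asarray(spont_age, dtype=float)
    exposed = np.asarray(exposed_age, dtype=float)
    rad = np.asarray(exposed_rad, dtype=bool)

    cls = np.full(spont.shape, CaseClass.NONE, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        in_win = (exposed >= w_lo) & (exposed < w_hi)
        spont_seen = ~np.isnan(spont) & (spont <= follow_up_end)
        cls[in_win & ~rad] = CaseClass.UNAFFECTED
        rad_win = in_win & rad
        cls[rad_win & ~spont_seen] = CaseClass.NEW
        cls[rad_win & spont_seen & (spont >= w_hi)] = CaseClass.ACCELERATED
        cls[rad_win & spont_seen & (spont < w_lo)] = CaseClass.RETARDED
        both_in = rad_win & spont_seen & (spont >= w_lo) & (spont < w_hi)
        cls[both_in & (spont > exposed)] = CaseClass.ACCELERATED
        cls[both_in & (spont < exposed)] = CaseClass.RETARDED
        cls[both_in & (spont == exposed)] = CaseClass.UNAFFECTED
    return cls


def classify_person(
    outcome: PersonOutcome,
    window: tuple[float, float],
    follow_up_end: float,
) -> CaseClass:
    """Classify a single person's outcome."""
    code = classify_codes(
        np.array([math.nan if outcome.spont_cancer_age is None
                  else outcome.spont_cancer_age]),
        np.array([math.nan if outcome.exposed_cancer_age is None
                  else outcome.exposed_cancer_age]),
        np.array([outcome.exposed_cancer_rad_associated]),
        window,
        follow_up_end,
    )[0]
    return CaseClass(code)


@dataclass(frozen=True)
class CohortTally:
    """Classified window-case counts of one cohort run.

    ``spo`` counts counterfactual spontaneous window cancers, ``tot`` the
    exposed-world window cancers; ``tot = unaff + acc + ret + new`` always.
    """

    spo: int
    tot: int
    unaff: int
    acc: int
    ret: int
    new: int

    def __post_init__(self) -> None:
        if min(self.spo, self.tot, self.unaff, self.acc, self.ret, self.new) < 0:
            raise ValueError("counts must be non-negative")
        if self.tot != self.unaff + self.acc + self.ret + self.new:
            raise AssertionError(
                "tally invariant violated: tot != unaff + acc + ret + new "
                f"({self.tot} != {self.unaff}+{self.acc}+{self.ret}+{self.new})"
            )

    @property
    def exc(self) -> int:
        return self.tot - self.spo

    def __add__(self, other: "CohortTally") -> "CohortTally":
        return CohortTally(
            self.spo + other.spo, self.tot + other.tot,
            self.unaff + other.unaff, self.acc + other.acc,
            self.ret + other.ret, self.new + other.new,
        )


def tally(
    run: RunResult,
    window: tuple[float, float] | None = None,
    follow_up_end: float | None = None,
) -> CohortTally:
    """Count classified window cases of one cohort run."""
    window = run.scenario.window if window is None else window
    follow_up_end = (
        run.scenario.follow_up_end if follow_up_end is None else follow_up_end
    )
    w_lo, w_hi = window
    cls = classify_codes(
        run.spont_age, run.exposed_age, run.exposed_rad, window, follow_up_end
    )
    with np.errstate(invalid="ignore"):
        spo = int(np.sum((run.spont_age >= w_lo) & (run.spont_age < w_hi)))
    counts = np.bincount(cls, minlength=5)
    return CohortTally(
        spo=spo,
        tot=int(counts[1:].sum()),
        unaff=int(counts[CaseClass.UNAFFECTED]),
        acc=int(counts[CaseClass.ACCELERATED]),
        ret=int(counts[CaseClass.RETARDED]),
        new=int(counts[CaseClass.NEW]),
    )


@dataclass(frozen=True)
class AssociationMeasures:
    """Population- and mechanism-level association measures.

    ``HRR`` is ``inf`` when there are no retarded cases (harm/retardation
    ratio undefined).
    """

    ERR: float
    AS: float
    PA: float
    PH: float
    PEH: float
    PR: float
    HRR: float


def measures(t: CohortTally) -> AssociationMeasures:
    """Derive the association measures from a tally (requires tot > 0)."""
    if t.tot <= 0:
        raise ValueError("no exposed-world cases in window; measures undefined")
    harm = t.new + t.acc
    return AssociationMeasures(
        ERR=t.exc / t.spo if t.spo > 0 else math.inf,
        AS=t.exc / t.tot,
        PA=(harm + t.ret) / t.tot,
        PH=harm / t.tot,
        PEH=(harm - t.ret) / t.tot,
        PR=t.ret / t.tot,
        HRR=harm / t.ret if t.ret > 0 else math.inf,
    )


@dataclass(frozen=True)
class AccelerationHistogram:
    """Distribution of accelerated cases over the spontaneous cancer age.

    One-year bins cover (w_hi, follow_up_end]; the mean acceleration time is
    the average of (spontaneous age - exposed age) over accelerated cases,
    NaN when there are none.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mean_acceleration: float

    @property
    def n_accelerated(self) -> int:
        return int(self.counts.sum())


def acceleration_histogram(
    run: RunResult,
    window: tuple[float, float] | None = None,
    follow_up_end: float | None = None,
) -> AccelerationHistogram:
    """Histogram of spontaneous-cancer ages of the accelerated cases."""
    window = run.scenario.window if window is None else window
    follow_up_end = (
        run.scenario.follow_up_end if follow_up_end is None else follow_up_end
    )
    cls = classify_codes(
        run.spont_age, run.exposed_age, run.exposed_rad, window, follow_up_end
    )
    acc = cls == CaseClass.ACCELERATED
    edges = np.arange(math.floor(window[1]), math.ceil(follow_up_end) + 1.0)
    counts, _ = np.histogram(run.spont_age[acc], bins=edges)
    shifts = run.spont_age[acc] - run.exposed_age[acc]
    mean = float(np.mean(shifts)) if shifts.size else math.nan
    return AccelerationHistogram(
        bin_edges=edges, counts=counts, mean_acceleration=mean
    )


def followup_invariance_check(
    run: RunResult,
    window: tuple[float, float] | None = None,
    alt_follow_up: float = 70.0,
) -> tuple[int, int]:
    """Recount new + accelerated under a truncated follow-up.

    Shortening the follow-up turns accelerated cases whose spontaneous
    cancer falls beyond the new horizon into new cases, so the sum
    new + accelerated is exactly invariant.  Returns the sum under the
    original and the truncated follow-up.
    """
    window = run.scenario.window if window is None else window
    if not (window[1] <= alt_follow_up <= run.scenario.follow_up_end):
        raise ValueError(
            "alternative follow-up must lie between the window end and the "
            "original follow-up"
        )
    t_orig = tally(run, window)
    t_alt = tally(run, window, follow_up_end=alt_follow_up)
    return t_orig.new + t_orig.acc, t_alt.new + t_alt.acc
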