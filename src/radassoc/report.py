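"""Summary report across repeated cohort runs.

Aggregates per-run tallies and measures into the standard presentation:
a phenomenological block (spo, tot, exc, ERR, AS), a mechanistic block
(unaff, acc, ret, new) and the association-measure block (PA, PH, PEH, PR,
HRR), each as mean and standard deviation over runs.  Counts are reported
rounded back to integers, measures at three decimals.
"""

from __future__ import annotations

import math
from dataclasses import asdict

import numpy as np
import pandas as pd

from .classify import CohortTally, measures

__all__ = ["summary_table", "pooled_tally"]

_COUNT_ROWS = ["spo", "tot", "exc", "unaff", "acc", "ret", "new"]
_MEASURE_ROWS = ["ERR", "AS", "PA", "PH", "PEH", "PR", "HRR"]


def pooled_tally(tallies: list[CohortTally]) -> CohortTally:
    """Sum of per-run tallies (one pooled cohort of n_runs * n_persons)."""
    if not tallies:
        raise ValueError("no tallies to pool")
    out = tallies[0]
    for t in tallies[1:]:
        out = out + t
    return out


def summary_table(tallies: list[CohortTally]) -> pd.DataFrame:
    """Mean/SD-over-runs table of counts and measures.

    HRR is NaN-masked for runs without retarded cases (its value is
    infinite there); the ``n_runs`` column reports how many runs entered
    each row's statistics.
    """
    rows = []
    per_run: dict[str, list[float]] = {k: [] for k in _COUNT_ROWS + _MEASURE_ROWS}
    for t in tallies:
        d = asdict(t)
        d["exc"] = t.exc
        m = asdict(measures(t)) if t.tot > 0 else {k: math.nan for k in _MEASURE_ROWS}
        for k in _COUNT_ROWS:
            per_run[k].append(float(d[k]))
        for k in _MEASURE_ROWS:
            v = m[k]
            per_run[k].append(float(v) if math.isfinite(v) else math.nan)
    for k in _COUNT_ROWS + _MEASURE_ROWS:
        vals = np.asarray(per_run[k], dtype=float)
        ok = np.isfinite(vals)
        mean = float(np.mean(vals[ok])) if ok.any() else math.nan
        sd = float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else math.nan
        if k in _COUNT_ROWS:
            mean = round(mean) if ok.any() else mean
            sd = round(sd) if ok.sum() > 1 else sd
        else:
            mean = round(mean, 3) if ok.any() else mean
            sd = round(sd, 3) if ok.sum() > 1 else sd
        rows.append({"quantity": k, "mean": mean, "sd": sd, "n_runs": int(ok.sum())})
    return pd.DataFrame(rows)
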