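import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radassoc.classify import (
    AccelerationHistogram,
    CaseClass,
    CohortTally,
    acceleration_histogram,
    classify_codes,
    classify_person,
    followup_invariance_check,
    measures,
    tally,
)
from radassoc.params import DEFAULT_SCENARIO, MODEL_PRESETS
from radassoc.person import PersonOutcome, RunResult

WINDOW = (60.0, 61.0)
FU = 80.0


def _run_from(spont, exposed, rad):
    return RunResult(
        spont_age=np.asarray(spont, dtype=float),
        exposed_age=np.asarray(exposed, dtype=float),
        exposed_rad=np.asarray(rad, dtype=bool),
        model=MODEL_PRESETS["M_P"],
        scenario=DEFAULT_SCENARIO,
        run_index=0,
    )


class TestClassifyPerson:
    @pytest.mark.parametrize(
        "spont,exposed,rad,expected",
        [
            # no exposed-world window cancer
            (None, None, False, CaseClass.NONE),
            (60.5, 59.0, True, CaseClass.NONE),
            (60.5, 70.0, False, CaseClass.NONE),
            # a window cancer from a non-radiation-associated clone
            (60.4, 60.4, False, CaseClass.UNAFFECTED),
            # radiation-associated, no spontaneous cancer within follow-up
            (None, 60.4, True, CaseClass.NEW),
            # spontaneous cancer would only occur beyond follow-up: also new
            (85.0, 60.4, True, CaseClass.NEW),
            # spontaneous cancer later (61-80): accelerated into the window
            (70.2, 60.4, True, CaseClass.ACCELERATED),
            # spontaneous cancer earlier (<60): retarded into the window
            (58.9, 60.4, True, CaseClass.RETARDED),
            # both inside the window: sign of the shift decides
            (60.8, 60.2, True, CaseClass.ACCELERATED),
            (60.2, 60.8, True, CaseClass.RETARDED),
            (60.5, 60.5, True, CaseClass.UNAFFECTED),
        ],
    )
    def test_scoring_rules(self, spont, exposed, rad, expected):
        outcome = PersonOutcome(spont, exposed, rad)
        assert classify_person(outcome, WINDOW, FU) is expected

    def test_truncated_followup_reclassifies_accelerated_as_new(self):
        outcome = PersonOutcome(75.0, 60.5, True)
        assert classify_person(outcome, WINDOW, 80.0) is CaseClass.ACCELERATED
        assert classify_person(outcome, WINDOW, 70.0) is CaseClass.NEW


class TestTally:
    def test_all_none_outcomes(self):
        run = _run_from([np.nan] * 5, [np.nan] * 5, [False] * 5)
        t = tally(run)
        assert (t.spo, t.tot, t.unaff, t.acc, t.ret, t.new) == (0,) * 6

    def test_schematic_cohort(self):
        # six persons covering every scoring outcome:
        # 1: spontaneous window cancer, untouched by radiation
        # 2: all clones die out, no cancer anywhere
        # 3: new radiation-induced cancer, no spontaneous counterpart
        # 4: spontaneous cancer after follow-up -> counts as new
        # 5: spontaneous cancer 61-80 accelerated into the window
        # 6: spontaneous cancer < 60 retarded into the window
        spont = [60.3, np.nan, np.nan, 85.0, 70.2, 58.9]
        exposed = [60.3, np.nan, 60.6, 60.4, 60.5, 60.7]
        rad = [False, False, True, True, True, True]
        t = tally(_run_from(spont, exposed, rad))
        assert t.spo == 1  # only person 1 has a spontaneous window cancer
        assert t.tot == 5
        assert (t.unaff, t.new, t.acc, t.ret) == (1, 2, 1, 1)
        assert t.tot == t.unaff + t.acc + t.ret + t.new

    def test_sum_invariant_enforced(self):
        with pytest.raises(AssertionError):
            CohortTally(spo=1, tot=5, unaff=1, acc=1, ret=1, new=1)

    @given(
        st.lists(
            st.tuples(
                st.one_of(st.none(), st.floats(30.0, 90.0)),
                st.one_of(st.none(), st.floats(30.0, 90.0)),
                st.booleans(),
            ),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_partition_property(self, raw):
        """Every exposed-world window cancer lands in exactly one class."""
        spont = [np.nan if s is None else s for s, _, _ in raw]
        exposed = [np.nan if e is None else e for _, e, _ in raw]
        rad = [r for _, _, r in raw]
        run = _run_from(spont, exposed, rad)
        t = tally(run)  # constructor asserts tot == unaff+acc+ret+new
        with np.errstate(invalid="ignore"):
            expected_tot = int(
                np.sum((run.exposed_age >= 60.0) & (run.exposed_age < 61.0))
            )
        assert t.tot == expected_tot


class TestMeasures:
    def test_schematic_worked_example(self):
        # 100 spontaneous cases double to 200 after exposure; 80 newly
        # induced and 50 accelerated cases among them
        t = CohortTally(spo=100, tot=200, unaff=70, acc=50, ret=0, new=80)
        m = measures(t)
        assert m.AS == pytest.approx(0.5)
        assert m.PA == pytest.approx(0.65)
        assert m.PH == pytest.approx(0.65)
        assert m.PEH == pytest.approx(0.65)
        assert m.PR == 0.0
        assert math.isinf(m.HRR)

    def test_promotion_scale_example(self):
        t = CohortTally(spo=654, tot=1277, unaff=80, acc=253, ret=95, new=849)
        m = measures(t)
        assert m.PA == pytest.approx(1197 / 1277)
        assert m.PH == pytest.approx(1102 / 1277)
        assert m.PEH == pytest.approx(1007 / 1277)
        assert m.PR == pytest.approx(95 / 1277)
        assert m.HRR == pytest.approx(11.6, abs=0.05)
        assert m.ERR == pytest.approx(623 / 654)

    def test_no_association(self):
        t = CohortTally(spo=50, tot=50, unaff=50, acc=0, ret=0, new=0)
        m = measures(t)
        assert m.AS == 0.0 and m.PA == 0.0

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            measures(CohortTally(spo=0, tot=0, unaff=0, acc=0, ret=0, new=0))

    @given(
        spo=st.integers(0, 10_000),
        unaff=st.integers(0, 10_000),
        acc=st.integers(0, 10_000),
        ret=st.integers(0, 10_000),
        new=st.integers(0, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_measure_identities(self, spo, unaff, acc, ret, new):
        tot = unaff + acc + ret + new
        if tot == 0:
            return
        m = measures(CohortTally(spo, tot, unaff, acc, ret, new))
        assert 0.0 <= m.PH <= m.PA <= 1.0
        assert m.PEH <= m.PH
        assert m.PA == pytest.approx(m.PH + m.PR)
        assert m.PEH == pytest.approx(m.PH - m.PR)


class TestAccelerationHistogram:
    def test_single_case(self):
        run = _run_from([70.5], [60.5], [True])
        h = acceleration_histogram(run)
        assert h.mean_acceleration == pytest.approx(10.0)
        assert h.counts.sum() == 1
        lo = h.bin_edges[:-1][h.counts > 0]
        assert lo[0] == 70.0

    def test_counts_match_accelerated_class(self):
        spont = [70.2, 62.0, 58.0, np.nan, 79.9]
        exposed = [60.5, 60.1, 60.9, 60.2, 60.8]
        rad = [True, True, True, True, True]
        run = _run_from(spont, exposed, rad)
        h = acceleration_histogram(run)
        t = tally(run)
        assert h.n_accelerated == t.acc == 3
        assert h.mean_acceleration == pytest.approx(
            np.mean([70.2 - 60.5, 62.0 - 60.1, 79.9 - 60.8])
        )

    def test_empty(self):
        run = _run_from([np.nan], [np.nan], [False])
        h = acceleration_histogram(run)
        assert isinstance(h, AccelerationHistogram)
        assert h.n_accelerated == 0
        assert math.isnan(h.mean_acceleration)


class TestFollowupInvariance:
    def test_truncation_preserves_new_plus_accelerated(self):
        # spontaneous ages straddle the truncated horizon 70
        spont = [np.nan, 65.0, 72.0, 79.0, 85.0, 58.0]
        exposed = [60.1, 60.2, 60.3, 60.4, 60.5, 60.6]
        rad = [True] * 6
        run = _run_from(spont, exposed, rad)
        orig, alt = followup_invariance_check(run, alt_follow_up=70.0)
        assert orig == alt
        t80 = tally(run)
        t70 = tally(run, follow_up_end=70.0)
        assert t70.acc < t80.acc
        assert t70.new - t80.new == t80.acc - t70.acc

    def test_identity_at_full_followup(self):
        run = _run_from([72.0], [60.5], [True])
        orig, alt = followup_invariance_check(run, alt_follow_up=80.0)
        assert orig == alt == 1

    def test_no_radiation_cases(self):
        run = _run_from([60.5, np.nan], [60.5, np.nan], [False, False])
        assert followup_invariance_check(run, alt_follow_up=70.0) == (0, 0)

    def test_invalid_horizon_rejected(self):
        run = _run_from([np.nan], [np.nan], [False])
        with pytest.raises(ValueError):
            followup_invariance_check(run, alt_follow_up=30.0)
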