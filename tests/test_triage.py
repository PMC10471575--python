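"""Decision-tree semantics: branch cutoffs, MDE rule, full-record triage.

The independent oracle here is a literal nested-conditional transcription
of the published flow diagram, written without reference to the package
internals; triage_record must agree with it on every enumerable input.
"""

import itertools

import pytest

from depscreen import (
    Category,
    MDEAssessment,
    ProtocolSpec,
    ScreeningRecord,
    classify_bdi,
    classify_bhs,
    evaluate_mde,
    get_protocol,
    triage_record,
)
from depscreen.instruments import BDI9Response, BHSResponse
from depscreen.triage import (
    Action,
    BDIBranch,
    BHSBranch,
    IncompleteAssessmentError,
    MDESubresult,
    PROTOCOLS,
)

PROTOCOL_NAMES = ("P1", "P2", "P3")


def bhs_items(total):
    """Deterministic 4-item composition reaching ``total`` (0..12)."""
    items = []
    for _ in range(4):
        v = min(3, total)
        items.append(v)
        total -= v
    return tuple(items)


def bdi_items(total):
    """Deterministic 9-item composition reaching ``total`` (9..36)."""
    items = [1] * 9
    extra = total - 9
    for i in range(9):
        bump = min(3, extra)
        items[i] += bump
        extra -= bump
    return tuple(items)


def make_record(prior=False, bhs_total=None, bdi_total=None, mde=None, rid="r"):
    return ScreeningRecord(
        record_id=rid,
        prior_psychiatric_diagnosis=prior,
        bhs=None if bhs_total is None else BHSResponse(bhs_items(bhs_total)),
        bdi=None if bdi_total is None else BDI9Response(bdi_items(bdi_total)),
        mde=mde,
    )


def oracle_category(prior, bhs_total, bdi_total, stop_max):
    """Brute-force truth table of the flow diagram (independent of triage)."""
    if prior:
        return Category.EXCLUDED_PRIOR_PSYCHIATRIC
    if bhs_total is None:
        return Category.MISSING_BHS
    if bhs_total <= stop_max:
        return Category.NO_FURTHER_EVALUATION
    if bhs_total >= 6:
        return Category.IMMEDIATE_REFERRAL_BHS
    if bdi_total is None:
        return Category.BDI_MISSING
    if bdi_total < 19:
        return Category.BDI_BELOW_ASSESS
    if bdi_total >= 25:
        return Category.IMMEDIATE_REFERRAL_BDI
    return Category.MDE_ASSESSMENT_INDICATED


# ---------------------------------------------------------------------------
# stage classifiers


@pytest.mark.parametrize(
    "total, protocol_name, branch",
    [
        (0, "P1", BHSBranch.STOP),
        (1, "P1", BHSBranch.STOP),
        (2, "P1", BHSBranch.BDI_INDICATED),
        (2, "P2", BHSBranch.STOP),
        (3, "P2", BHSBranch.BDI_INDICATED),
        (3, "P3", BHSBranch.STOP),
        (4, "P3", BHSBranch.BDI_INDICATED),
        (5, "P1", BHSBranch.BDI_INDICATED),
        (6, "P1", BHSBranch.REFER),
        (6, "P2", BHSBranch.REFER),
        (6, "P3", BHSBranch.REFER),
        (12, "P3", BHSBranch.REFER),
    ],
)
def test_bhs_zones_per_protocol(total, protocol_name, branch):
    assert classify_bhs(total, get_protocol(protocol_name)) is branch


@pytest.mark.parametrize(
    "total, branch",
    [
        (9, BDIBranch.STOP),
        (18, BDIBranch.STOP),
        (19, BDIBranch.ASSESS_MDE),
        (22, BDIBranch.ASSESS_MDE),
        (24, BDIBranch.ASSESS_MDE),
        (25, BDIBranch.REFER),
        (36, BDIBranch.REFER),
    ],
)
def test_bdi_zones(total, branch):
    assert classify_bdi(total) is branch


@pytest.mark.parametrize("bad", [-1, 13, 100])
def test_classify_bhs_range_error(bad):
    with pytest.raises(ValueError):
        classify_bhs(bad, get_protocol("P1"))


@pytest.mark.parametrize("bad", [8, 37])
def test_classify_bdi_range_error(bad):
    with pytest.raises(ValueError):
        classify_bdi(bad)


def test_bhs_zones_partition_total_range():
    """For each protocol the three zones cover 0..12 exactly once."""
    for name in PROTOCOL_NAMES:
        protocol = get_protocol(name)
        seen = [classify_bhs(t, protocol) for t in range(13)]
        assert seen == sorted(seen, key=[BHSBranch.STOP, BHSBranch.BDI_INDICATED,
                                         BHSBranch.REFER].index)
        lo, hi = protocol.bdi_indicated_range
        assert [t for t in range(13) if seen[t] is BHSBranch.BDI_INDICATED] == list(
            range(lo, hi + 1)
        )


def test_protocol_spec_rejects_inverted_cutoffs():
    with pytest.raises(ValueError):
        ProtocolSpec(name="bad", bhs_stop_max=7, bhs_refer_min=6)


# ---------------------------------------------------------------------------
# MDE rule


@pytest.mark.parametrize(
    "core, others, suicidality, expected",
    [
        ((True, False), 4, {}, MDESubresult.MDE_NON_SUICIDAL_GP_TREATABLE),
        ((False, False), 7, {}, MDESubresult.NOT_MDE_CONSIDER_REFERRAL),
        ((True, True), 5, {"prior_attempt": True}, MDESubresult.MDE_SUICIDAL_PSYCHIATRIST),
        ((True, False), 3, {}, MDESubresult.NOT_MDE_CONSIDER_REFERRAL),
        ((False, True), 4, {"suicidal_ideation": True}, MDESubresult.MDE_SUICIDAL_PSYCHIATRIST),
        ((False, True), 4, {"suicide_plan": True}, MDESubresult.MDE_SUICIDAL_PSYCHIATRIST),
    ],
)
def test_mde_rule(core, others, suicidality, expected):
    flags = dict(suicidal_ideation=False, suicide_plan=False, prior_attempt=False)
    flags.update(suicidality)
    assessment = MDEAssessment(
        depressed_mood=core[0], loss_of_interest=core[1], other_symptoms=others, **flags
    )
    assert evaluate_mde(assessment) is expected


def test_mde_exhaustive_against_rule():
    """Enumerate every flag combination: MDE iff >=1 core and >=4 others."""
    for c1, c2, others, ide, plan, att in itertools.product(
        (False, True), (False, True), range(8), (False, True), (False, True), (False, True)
    ):
        sub = evaluate_mde(
            MDEAssessment(c1, c2, others, ide, plan, att)
        )
        mde = (c1 or c2) and others >= 4
        if not mde:
            assert sub is MDESubresult.NOT_MDE_CONSIDER_REFERRAL
        elif ide or plan or att:
            assert sub is MDESubresult.MDE_SUICIDAL_PSYCHIATRIST
        else:
            assert sub is MDESubresult.MDE_NON_SUICIDAL_GP_TREATABLE


def test_incomplete_assessment_signalled():
    with pytest.raises(IncompleteAssessmentError):
        evaluate_mde(MDEAssessment(depressed_mood=True))


def test_other_symptom_count_range_checked():
    with pytest.raises(ValueError):
        MDEAssessment(other_symptoms=8)


# ---------------------------------------------------------------------------
# full-record triage


@pytest.mark.parametrize(
    "kwargs, category",
    [
        (dict(prior=True, bhs_total=12), Category.EXCLUDED_PRIOR_PSYCHIATRIC),
        (dict(bhs_total=0), Category.NO_FURTHER_EVALUATION),
        (dict(bhs_total=4, bdi_total=27), Category.IMMEDIATE_REFERRAL_BDI),
        (dict(bhs_total=4), Category.BDI_MISSING),
        (dict(), Category.MISSING_BHS),
        (dict(bhs_total=7), Category.IMMEDIATE_REFERRAL_BHS),
        (dict(bhs_total=3, bdi_total=12), Category.BDI_BELOW_ASSESS),
        (dict(bhs_total=3, bdi_total=21), Category.MDE_ASSESSMENT_INDICATED),
    ],
)
def test_triage_examples_p1(kwargs, category):
    assert triage_record(make_record(**kwargs), get_protocol("P1")).category is category


def test_partially_missing_bhs_counts_as_missing():
    record = ScreeningRecord(
        record_id="r", prior_psychiatric_diagnosis=False,
        bhs=BHSResponse((2, 1, None, 1)),
    )
    assert triage_record(record, get_protocol("P1")).category is Category.MISSING_BHS


def test_very_high_risk_annotation():
    p1 = get_protocol("P1")
    assert triage_record(make_record(bhs_total=9), p1).very_high_risk
    assert not triage_record(make_record(bhs_total=8), p1).very_high_risk
    assert triage_record(make_record(bhs_total=8), p1).category is (
        Category.IMMEDIATE_REFERRAL_BHS
    )


def test_mde_subresult_attached_only_with_complete_flags():
    p1 = get_protocol("P1")
    full = MDEAssessment(True, False, 4, False, False, False)
    out = triage_record(make_record(bhs_total=3, bdi_total=21, mde=full), p1)
    assert out.mde_subresult is MDESubresult.MDE_NON_SUICIDAL_GP_TREATABLE
    assert out.action is Action.GP_TREATMENT
    partial = MDEAssessment(depressed_mood=True)
    out = triage_record(make_record(bhs_total=3, bdi_total=21, mde=partial), p1)
    assert out.category is Category.MDE_ASSESSMENT_INDICATED
    assert out.mde_subresult is None


def test_triage_agrees_with_truth_table_everywhere():
    """Exhaustive oracle equivalence over prior x BHS x BDI x protocol."""
    for name in PROTOCOL_NAMES:
        protocol = get_protocol(name)
        for prior in (False, True):
            for bhs_total in (None, *range(13)):
                for bdi_total in (None, *range(9, 37)):
                    record = make_record(prior=prior, bhs_total=bhs_total,
                                         bdi_total=bdi_total)
                    expected = oracle_category(
                        prior, bhs_total, bdi_total, protocol.bhs_stop_max
                    )
                    assert triage_record(record, protocol).category is expected


def test_protocol_monotonicity_of_categories():
    """P1 -> P2 -> P3 moves records only into NO_FURTHER_EVALUATION; the
    BHS-referral set never changes."""
    specs = [get_protocol(n) for n in PROTOCOL_NAMES]
    for bhs_total in range(13):
        for bdi_total in (None, *range(9, 37)):
            cats = [
                triage_record(
                    make_record(bhs_total=bhs_total, bdi_total=bdi_total), s
                ).category
                for s in specs
            ]
            refer = [c is Category.IMMEDIATE_REFERRAL_BHS for c in cats]
            assert len(set(refer)) == 1
            for earlier, later in zip(cats, cats[1:]):
                if later is not earlier:
                    assert later is Category.NO_FURTHER_EVALUATION


def test_validation_error_carries_record_id():
    # corrupt response smuggled past construction-time validation
    bad_bhs = object.__new__(BHSResponse)
    object.__setattr__(bad_bhs, "items", (5, 5, 5, 5))
    record = ScreeningRecord(record_id="R0042", prior_psychiatric_diagnosis=False,
                             bhs=bad_bhs)
    with pytest.raises(ValueError, match="R0042"):
        triage_record(record, get_protocol("P1"))


def test_shipped_protocols_mapping():
    assert set(PROTOCOL_NAMES) <= set(PROTOCOLS.keys())
    assert PROTOCOLS["P1"].bhs_stop_max == 1
    assert PROTOCOLS["P2"].bhs_stop_max == 2
    assert PROTOCOLS["P3"].bhs_stop_max == 3
    for name in PROTOCOL_NAMES:
        assert PROTOCOLS[name].bhs_refer_min == 6
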