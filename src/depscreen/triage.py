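"""The staged screening decision tree and its cutoff variants.

Screening proceeds in fixed order for each respondent:

1. **Prior psychiatric diagnosis** — already under specialist care;
   excluded before screening (screening cannot be implemented for them).
2. **BHS-4** — totals up to the protocol's stop cutoff end screening;
   totals ≥ 6 mean immediate psychiatric referral without completing the
   BDI-9; the zone in between triggers BDI-9 completion.
3. **BDI-9** — totals < 19 end screening; 19–24 indicate a DSM-5
   major-depressive-episode (MDE) assessment; ≥ 25 mean immediate
   referral.
4. **MDE assessment** (when symptom data exist) — MDE is present when at
   least one core symptom (depressed mood, loss of interest) and at
   least four additional DSM-5 symptoms are present.  A suicidality
   qualifier (current ideation, a plan, or a previous attempt) routes an
   MDE case to a psychiatrist; non-suicidal MDE can be treated in the
   general medical practice; non-MDE cases are considered for referral
   or re-screened after three months.

The three shipped protocols P1/P2/P3 differ only in the BHS stop cutoff
(0–1, 0–2, 0–3); the referral cutoff (≥6) is shared.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from functools import lru_cache
from typing import TYPE_CHECKING, Optional

import yaml

from .instruments import score_bhs, score_bdi9, BHS_TOTAL_RANGE, BDI9_TOTAL_RANGE

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import ScreeningRecord

__all__ = [
    "ProtocolSpec",
    "MDEAssessment",
    "TriageOutcome",
    "Category",
    "Action",
    "MDESubresult",
    "BHSBranch",
    "BDIBranch",
    "classify_bhs",
    "classify_bdi",
    "evaluate_mde",
    "triage_record",
    "get_protocol",
    "PROTOCOLS",
    "IncompleteAssessmentError",
    "VERY_HIGH_RISK_MIN",
]

#: BHS total at or above which the referral carries a "very high risk"
#: annotation (consultation/psychiatric admission); same REFER branch.
VERY_HIGH_RISK_MIN = 9


class Category(str, enum.Enum):
    """Terminal care-need categories; every record lands in exactly one."""

    EXCLUDED_PRIOR_PSYCHIATRIC = "EXCLUDED_PRIOR_PSYCHIATRIC"
    MISSING_BHS = "MISSING_BHS"
    NO_FURTHER_EVALUATION = "NO_FURTHER_EVALUATION"
    BDI_MISSING = "BDI_MISSING"
    BDI_BELOW_ASSESS = "BDI_BELOW_ASSESS"
    MDE_ASSESSMENT_INDICATED = "MDE_ASSESSMENT_INDICATED"
    IMMEDIATE_REFERRAL_BHS = "IMMEDIATE_REFERRAL_BHS"
    IMMEDIATE_REFERRAL_BDI = "IMMEDIATE_REFERRAL_BDI"


class Action(str, enum.Enum):
    NONE = "none"
    REFER_PSYCHIATRIST = "refer-psychiatrist"
    ASSESS_MDE = "assess-MDE"
    GP_TREATMENT = "GP-treatment"
    PSYCHIATRIST_TREATMENT = "psychiatrist-treatment"
    MONITOR_3_MONTHS = "monitor-3-months"


class MDESubresult(str, enum.Enum):
    MDE_NON_SUICIDAL_GP_TREATABLE = "MDE_NON_SUICIDAL_GP_TREATABLE"
    MDE_SUICIDAL_PSYCHIATRIST = "MDE_SUICIDAL_PSYCHIATRIST"
    NOT_MDE_CONSIDER_REFERRAL = "NOT_MDE_CONSIDER_REFERRAL"


class BHSBranch(str, enum.Enum):
    STOP = "STOP"
    BDI_INDICATED = "BDI_INDICATED"
    REFER = "REFER"


class BDIBranch(str, enum.Enum):
    STOP = "STOP"
    ASSESS_MDE = "ASSESS_MDE"
    REFER = "REFER"


_CATEGORY_ACTION = {
    Category.EXCLUDED_PRIOR_PSYCHIATRIC: Action.NONE,
    Category.MISSING_BHS: Action.NONE,
    Category.NO_FURTHER_EVALUATION: Action.NONE,
    Category.BDI_MISSING: Action.NONE,
    Category.BDI_BELOW_ASSESS: Action.NONE,
    Category.MDE_ASSESSMENT_INDICATED: Action.ASSESS_MDE,
    Category.IMMEDIATE_REFERRAL_BHS: Action.REFER_PSYCHIATRIST,
    Category.IMMEDIATE_REFERRAL_BDI: Action.REFER_PSYCHIATRIST,
}

_SUBRESULT_ACTION = {
    MDESubresult.MDE_NON_SUICIDAL_GP_TREATABLE: Action.GP_TREATMENT,
    MDESubresult.MDE_SUICIDAL_PSYCHIATRIST: Action.PSYCHIATRIST_TREATMENT,
    MDESubresult.NOT_MDE_CONSIDER_REFERRAL: Action.MONITOR_3_MONTHS,
}


class IncompleteAssessmentError(ValueError):
    """Raised when evaluate_mde is called with required flags missing."""


@dataclass(frozen=True)
class ProtocolSpec:
    """A cutoff configuration for the decision tree.

    The three BHS zones — stop (≤ ``bhs_stop_max``), BDI-indicated
    (``bhs_stop_max``+1 .. ``bhs_refer_min``−1) and refer
    (≥ ``bhs_refer_min``) — partition the 0–12 total range.
    """

    name: str
    bhs_stop_max: int
    bhs_refer_min: int = 6
    bdi_assess_lo: int = 19
    bdi_assess_hi: int = 24
    bdi_refer_min: int = 25

    def __post_init__(self) -> None:
        if not self.bhs_stop_max < self.bhs_refer_min:
            raise ValueError(
                f"protocol {self.name}: stop cutoff {self.bhs_stop_max} must lie "
                f"below the referral cutoff {self.bhs_refer_min}"
            )
        lo, hi = BHS_TOTAL_RANGE
        if not (lo <= self.bhs_stop_max and self.bhs_refer_min <= hi):
            raise ValueError(f"protocol {self.name}: BHS cutoffs outside {lo}..{hi}")
        if not self.bdi_assess_lo <= self.bdi_assess_hi < self.bdi_refer_min:
            raise ValueError(f"protocol {self.name}: BDI cutoffs are not ordered")

    @property
    def bdi_indicated_range(self) -> tuple[int, int]:
        """Closed interval of BHS totals that trigger BDI-9 completion."""
        return (self.bhs_stop_max + 1, self.bhs_refer_min - 1)


@lru_cache(maxsize=1)
def _shipped_protocols() -> dict[str, ProtocolSpec]:
    text = resources.files("depscreen.data").joinpath("protocols.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: ProtocolSpec(name=name, **cfg) for name, cfg in raw["protocols"].items()}


def get_protocol(name: str) -> ProtocolSpec:
    """Look up a shipped protocol (P1, P2 or P3) by name."""
    protocols = _shipped_protocols()
    try:
        return protocols[name]
    except KeyError:
        raise KeyError(f"unknown protocol {name!r}; shipped: {sorted(protocols)}") from None


#: The shipped protocols, keyed by name.
PROTOCOLS: dict[str, ProtocolSpec] = _shipped_protocols()


@dataclass(frozen=True)
class MDEAssessment:
    """DSM-5 MDE symptom flags plus suicidality qualifiers.

    ``other_symptoms`` counts the additional (non-core) DSM-5 symptoms
    present, 0..7.  Any flag may be ``None`` (not assessed).
    """

    depressed_mood: Optional[bool] = None
    loss_of_interest: Optional[bool] = None
    other_symptoms: Optional[int] = None
    suicidal_ideation: Optional[bool] = None
    suicide_plan: Optional[bool] = None
    prior_attempt: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.other_symptoms is not None and not 0 <= self.other_symptoms <= 7:
            raise ValueError(f"other_symptoms {self.other_symptoms} outside 0..7")

    @property
    def complete(self) -> bool:
        return None not in (
            self.depressed_mood,
            self.loss_of_interest,
            self.other_symptoms,
            self.suicidal_ideation,
            self.suicide_plan,
            self.prior_attempt,
        )


@dataclass(frozen=True)
class TriageOutcome:
    """Terminal category plus recommended action for one record.

    ``very_high_risk`` annotates BHS totals ≥ 9 within the referral
    branch (consultation with a psychiatrist or psychiatric admission);
    it is a severity note, not a separate category.
    """

    category: Category
    action: Action
    mde_subresult: Optional[MDESubresult] = None
    very_high_risk: bool = False

    def __post_init__(self) -> None:
        if self.mde_subresult is not None and self.category is not Category.MDE_ASSESSMENT_INDICATED:
            raise ValueError("mde_subresult only applies to MDE_ASSESSMENT_INDICATED outcomes")


def classify_bhs(bhs_total: int, protocol: ProtocolSpec) -> BHSBranch:
    """Assign a complete BHS total to one of the three protocol zones."""
    lo, hi = BHS_TOTAL_RANGE
    if not isinstance(bhs_total, int) or not lo <= bhs_total <= hi:
        raise ValueError(f"BHS total {bhs_total!r} outside {lo}..{hi}")
    if bhs_total <= protocol.bhs_stop_max:
        return BHSBranch.STOP
    if bhs_total >= protocol.bhs_refer_min:
        return BHSBranch.REFER
    return BHSBranch.BDI_INDICATED


def classify_bdi(bdi_total: int) -> BDIBranch:
    """Assign a complete BDI-9 total to stop / assess-MDE / refer."""
    lo, hi = BDI9_TOTAL_RANGE
    if not isinstance(bdi_total, int) or not lo <= bdi_total <= hi:
        raise ValueError(f"BDI-9 total {bdi_total!r} outside {lo}..{hi}")
    if bdi_total >= 25:
        return BDIBranch.REFER
    if bdi_total >= 19:
        return BDIBranch.ASSESS_MDE
    return BDIBranch.STOP


def evaluate_mde(assessment: MDEAssessment) -> MDESubresult:
    """Apply the DSM-5 MDE rule and the suicidality qualifier.

    MDE is present iff at least one core symptom (depressed mood or loss
    of interest) and at least four additional symptoms are present.
    Among MDE cases, any of ideation / plan / previous attempt routes to
    psychiatrist treatment; otherwise treatment can start in the general
    medical practice.  Non-MDE cases are flagged for considered referral
    (or re-screening after three months).
    """
    if not assessment.complete:
        raise IncompleteAssessmentError("MDE assessment has missing flags")
    core = assessment.depressed_mood or assessment.loss_of_interest
    mde = bool(core) and assessment.other_symptoms >= 4  # type: ignore[operator]
    if not mde:
        return MDESubresult.NOT_MDE_CONSIDER_REFERRAL
    suicidal = (
        assessment.suicidal_ideation or assessment.suicide_plan or assessment.prior_attempt
    )
    if suicidal:
        return MDESubresult.MDE_SUICIDAL_PSYCHIATRIST
    return MDESubresult.MDE_NON_SUICIDAL_GP_TREATABLE


def _outcome(category: Category, *, subresult: Optional[MDESubresult] = None,
             very_high_risk: bool = False) -> TriageOutcome:
    action = _SUBRESULT_ACTION[subresult] if subresult is not None else _CATEGORY_ACTION[category]
    return TriageOutcome(category=category, action=action,
                         mde_subresult=subresult, very_high_risk=very_high_risk)


def triage_record(record: "ScreeningRecord", protocol: ProtocolSpec) -> TriageOutcome:
    """Run one respondent through the decision tree of ``protocol``.

    Evaluation order is fixed: prior-diagnosis exclusion, BHS
    missingness, BHS zones, BDI missingness, BDI zones, and — only when
    the DSM-5 flags are all present — the MDE sub-classification.
    Deterministic; exactly one terminal category.
    """
    try:
        if record.prior_psychiatric_diagnosis:
            return _outcome(Category.EXCLUDED_PRIOR_PSYCHIATRIC)
        bhs_total = None if record.bhs is None else score_bhs(record.bhs)
        if bhs_total is None:
            return _outcome(Category.MISSING_BHS)
        branch = classify_bhs(bhs_total, protocol)
        if branch is BHSBranch.STOP:
            return _outcome(Category.NO_FURTHER_EVALUATION)
        if branch is BHSBranch.REFER:
            return _outcome(
                Category.IMMEDIATE_REFERRAL_BHS,
                very_high_risk=bhs_total >= VERY_HIGH_RISK_MIN,
            )
        bdi_total = None if record.bdi is None else score_bdi9(record.bdi)
        if bdi_total is None:
            return _outcome(Category.BDI_MISSING)
        bdi_branch = classify_bdi(bdi_total)
        if bdi_branch is BDIBranch.STOP:
            return _outcome(Category.BDI_BELOW_ASSESS)
        if bdi_branch is BDIBranch.REFER:
            return _outcome(Category.IMMEDIATE_REFERRAL_BDI)
        if record.mde is not None and record.mde.complete:
            return _outcome(Category.MDE_ASSESSMENT_INDICATED,
                            subresult=evaluate_mde(record.mde))
        return _outcome(Category.MDE_ASSESSMENT_INDICATED)
    except (ValueError, TypeError) as exc:
        raise type(exc)(f"record {record.record_id!r}: {exc}") from exc
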