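"""Cohort containers, CSV schema and per-protocol tabulation.

A cohort is one row per respondent.  ``tabulate`` triages every record
under one protocol and counts terminal categories against the *full*
cohort denominator N — excluded and instrument-missing respondents stay
in the denominator, so prevalences are fractions of the whole sample,
exactly as survey tabulations report them.

CSV schema (missing cells empty)::

    id, prior_dx, bhs1..bhs4, bdi1..bdi9,
    mde_core1, mde_core2, mde_other_count, ideation, plan, prior_attempt,
    sex, age
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .instruments import BHSResponse, BDI9Response
from .triage import (
    Category,
    MDEAssessment,
    MDESubresult,
    ProtocolSpec,
    triage_record,
)

__all__ = [
    "ScreeningRecord",
    "CohortTable",
    "tabulate",
    "definitive_and_potential",
    "read_cohort_csv",
    "write_cohort_csv",
    "frame_to_records",
    "records_to_frame",
    "CohortSchemaError",
    "COHORT_COLUMNS",
]

BHS_COLS = [f"bhs{i}" for i in range(1, 5)]
BDI_COLS = [f"bdi{i}" for i in range(1, 10)]
MDE_FLAG_COLS = ["mde_core1", "mde_core2", "mde_other_count", "ideation", "plan", "prior_attempt"]
COHORT_COLUMNS = ["id", "prior_dx", *BHS_COLS, *BDI_COLS, *MDE_FLAG_COLS, "sex", "age"]


class CohortSchemaError(ValueError):
    """Cohort CSV violates the schema; message carries line numbers."""


@dataclass(frozen=True)
class ScreeningRecord:
    """One respondent: instrument answers, exclusion flag, optional MDE data.

    ``sex`` and ``age`` are carried through for reporting; triage never
    reads them.
    """

    record_id: str
    prior_psychiatric_diagnosis: bool
    bhs: Optional[BHSResponse] = None
    bdi: Optional[BDI9Response] = None
    mde: Optional[MDEAssessment] = None
    sex: Optional[str] = None
    age: Optional[int] = None


def round_pct(x: float) -> float:
    """Round a percentage to 2 decimals, half away from zero."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


#: Categories produced by the BDI-9 stage; together with
#: NO_FURTHER_EVALUATION and the fixed top categories they partition a cohort.
BDI_STAGE_CATEGORIES = (
    Category.BDI_MISSING,
    Category.BDI_BELOW_ASSESS,
    Category.MDE_ASSESSMENT_INDICATED,
    Category.IMMEDIATE_REFERRAL_BDI,
)


@dataclass(frozen=True)
class CohortTable:
    """Category counts for one protocol over one cohort.

    The denominator is the full cohort size N; prevalence is count/N.
    ``mde_split`` sub-divides MDE_ASSESSMENT_INDICATED when DSM-5 flags
    were present (it never replaces the headline count).
    """

    protocol: str
    denominator: int
    counts: Mapping[Category, int]
    mde_split: Mapping[MDESubresult, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.denominator:
            raise ValueError(
                f"category counts sum to {total}, not the denominator {self.denominator}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative category count")

    def count(self, category: Category) -> int:
        return int(self.counts.get(category, 0))

    def prevalence(self, category: Category) -> float:
        """Raw prevalence in percent (unrounded)."""
        return 100.0 * self.count(category) / self.denominator

    def prevalence_pct(self, category: Category) -> float:
        """Presentation prevalence: percent, 2 decimals, half away from zero."""
        return round_pct(self.prevalence(category))

    @property
    def bdi_indicated_count(self) -> int:
        """Respondents whose BHS total put them in the BDI-completion zone."""
        return sum(self.count(c) for c in BDI_STAGE_CATEGORIES)

    @property
    def definitive_care_count(self) -> int:
        """Immediate psychiatric referrals (BHS ≥ 6 or BDI-9 ≥ 25)."""
        return self.count(Category.IMMEDIATE_REFERRAL_BHS) + self.count(
            Category.IMMEDIATE_REFERRAL_BDI
        )

    @property
    def potential_care_count(self) -> int:
        """The BDI-9 19–24 group awaiting MDE assessment."""
        return self.count(Category.MDE_ASSESSMENT_INDICATED)


Cohort = Union[pd.DataFrame, Sequence[ScreeningRecord], Iterable[ScreeningRecord]]


def tabulate(cohort: Cohort, protocol: ProtocolSpec) -> CohortTable:
    """Triage every record under ``protocol`` and tally categories.

    Accepts either a schema-conformant DataFrame or ScreeningRecord
    objects.  Every record lands in exactly one category; the counts sum
    to N by construction.
    """
    if isinstance(cohort, pd.DataFrame):
        records: Sequence[ScreeningRecord] = frame_to_records(cohort)
    else:
        records = list(cohort)
    if not records:
        raise ValueError("empty cohort")
    seen: dict[str, int] = {}
    for r in records:
        seen[r.record_id] = seen.get(r.record_id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate record ids: {dupes[:10]}")

    counts = {category: 0 for category in Category}
    mde_split = {sub: 0 for sub in MDESubresult}
    for record in records:
        outcome = triage_record(record, protocol)
        counts[outcome.category] += 1
        if outcome.mde_subresult is not None:
            mde_split[outcome.mde_subresult] += 1
    mde_split = {sub: n for sub, n in mde_split.items() if n}
    return CohortTable(
        protocol=protocol.name,
        denominator=len(records),
        counts=counts,
        mde_split=mde_split,
    )


def definitive_and_potential(table: CohortTable) -> tuple[int, int]:
    """(definitive, potential) care-need counts for one protocol table.

    Definitive = both immediate-referral categories; potential = the
    BDI-9 19–24 group.  The BDI 19–24 group counts as potential need
    whether or not DSM-5 flags were collected.
    """
    return table.definitive_care_count, table.potential_care_count


# ---------------------------------------------------------------------------
# CSV I/O


def _check_int_column(df: pd.DataFrame, col: str, lo: int, hi: int, errors: list[str]) -> None:
    bad = df.index[df[col].notna() & ~df[col].between(lo, hi)]
    for idx in bad[:5]:
        # +2: header line plus 1-based data rows
        errors.append(f"line {idx + 2}: column {col} value {df.at[idx, col]} outside {lo}..{hi}")


def validate_cohort_frame(df: pd.DataFrame) -> None:
    """Strict schema validation with line-number diagnostics."""
    errors: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if missing:
        errors.append(f"missing columns: {missing}")
    if extra:
        errors.append(f"unexpected columns: {extra}")
    if not errors:
        if df["id"].isna().any():
            first = int(df.index[df["id"].isna()][0])
            errors.append(f"line {first + 2}: empty id")
        dup = df["id"][df["id"].duplicated()]
        if not dup.empty:
            errors.append(f"duplicate ids: {sorted(dup.unique())[:10]}")
        _check_int_column(df, "prior_dx", 0, 1, errors)
        if df["prior_dx"].isna().any():
            first = int(df.index[df["prior_dx"].isna()][0])
            errors.append(f"line {first + 2}: prior_dx must be 0 or 1, not empty")
        for col in BHS_COLS:
            _check_int_column(df, col, 0, 3, errors)
        for col in BDI_COLS:
            _check_int_column(df, col, 1, 4, errors)
        for col in ("mde_core1", "mde_core2", "ideation", "plan", "prior_attempt"):
            _check_int_column(df, col, 0, 1, errors)
        _check_int_column(df, "mde_other_count", 0, 7, errors)
    if errors:
        raise CohortSchemaError("; ".join(errors))


_INT_COLS = ["prior_dx", *BHS_COLS, *BDI_COLS, *MDE_FLAG_COLS, "age"]


def read_cohort_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises CohortSchemaError on violation."""
    try:
        df = pd.read_csv(
            path,
            dtype={"id": "string", "sex": "string"},
        )
    except ValueError as exc:
        raise CohortSchemaError(f"{path}: {exc}") from exc
    for col in df.columns:
        if col in _INT_COLS:
            try:
                df[col] = df[col].astype("Int64")
            except (ValueError, TypeError) as exc:
                raise CohortSchemaError(f"column {col}: non-integer value ({exc})") from exc
    validate_cohort_frame(df)
    return df


def write_cohort_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False)


def _opt_int(value) -> Optional[int]:
    return None if pd.isna(value) else int(value)


def _opt_bool(value) -> Optional[bool]:
    return None if pd.isna(value) else bool(int(value))


def frame_to_records(df: pd.DataFrame) -> list[ScreeningRecord]:
    """Materialise ScreeningRecord objects from a schema-conformant frame."""
    validate_cohort_frame(df)
    records: list[ScreeningRecord] = []
    cols = {name: df[name].to_numpy(dtype=object) for name in COHORT_COLUMNS}
    n = len(df)
    for i in range(n):
        bhs_items = tuple(_opt_int(cols[c][i]) for c in BHS_COLS)
        bdi_items = tuple(_opt_int(cols[c][i]) for c in BDI_COLS)
        bhs = None if all(v is None for v in bhs_items) else BHSResponse(bhs_items)
        bdi = None if all(v is None for v in bdi_items) else BDI9Response(bdi_items)
        mde_raw = [cols[c][i] for c in MDE_FLAG_COLS]
        if all(pd.isna(v) for v in mde_raw):
            mde = None
        else:
            mde = MDEAssessment(
                depressed_mood=_opt_bool(cols["mde_core1"][i]),
                loss_of_interest=_opt_bool(cols["mde_core2"][i]),
                other_symptoms=_opt_int(cols["mde_other_count"][i]),
                suicidal_ideation=_opt_bool(cols["ideation"][i]),
                suicide_plan=_opt_bool(cols["plan"][i]),
                prior_attempt=_opt_bool(cols["prior_attempt"][i]),
            )
        sex = cols["sex"][i]
        records.append(
            ScreeningRecord(
                record_id=str(cols["id"][i]),
                prior_psychiatric_diagnosis=bool(int(cols["prior_dx"][i])),
                bhs=bhs,
                bdi=bdi,
                mde=mde,
                sex=None if pd.isna(sex) else str(sex),
                age=_opt_int(cols["age"][i]),
            )
        )
    return records


def _flag(value: Optional[bool]) -> Optional[int]:
    return None if value is None else int(value)


def records_to_frame(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    """Inverse of frame_to_records (for writing cohorts built in memory)."""
    rows = []
    for r in records:
        row: dict = {"id": r.record_id, "prior_dx": int(r.prior_psychiatric_diagnosis)}
        bhs_items = r.bhs.items if r.bhs is not None else (None,) * 4
        bdi_items = r.bdi.items if r.bdi is not None else (None,) * 9
        row.update(dict(zip(BHS_COLS, bhs_items)))
        row.update(dict(zip(BDI_COLS, bdi_items)))
        if r.mde is not None:
            row.update(
                mde_core1=_flag(r.mde.depressed_mood),
                mde_core2=_flag(r.mde.loss_of_interest),
                mde_other_count=r.mde.other_symptoms,
                ideation=_flag(r.mde.suicidal_ideation),
                plan=_flag(r.mde.suicide_plan),
                prior_attempt=_flag(r.mde.prior_attempt),
            )
        row.update(sex=r.sex, age=r.age)
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    for col in _INT_COLS:
        df[col] = df[col].astype("Int64")
    df["id"] = df["id"].astype("string")
    df["sex"] = df["sex"].astype("string")
    return df
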