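"""Item-level representation and scoring of the two screening instruments.

Two short self-report scales drive the triage algorithm:

* **BHS-4** — the four-item short form of the Beck Hopelessness Scale.
  Each item is answered on a 0–3 Likert scale (0 "not typical" … 3 "very
  typical"), so the total ranges 0–12.  Totals of 6–8 indicate suicide
  risk; 9 or more indicate very high risk.  Hopelessness is an
  independent, strong predictor of suicide risk, which is why this scale
  is administered first.

* **BDI-9** — the Hungarian nine-item short form of the Beck Depression
  Inventory.  Each item is answered on a 1–4 intensity scale, so the
  total ranges 9–36.  Severity bands: 9–13 no depression, 14–18 mild,
  19–24 moderate, ≥25 severe.  The raw 1–4 coding is kept as published
  (not rebased to 0–3) so the band boundaries apply verbatim.

A response with *any* absent item is treated as missing at the
instrument level: no prorating or imputation is applied, matching how
whole-instrument missingness is accounted for in survey tabulations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache
from typing import Optional

import yaml

__all__ = [
    "BHSResponse",
    "BDI9Response",
    "SeverityBand",
    "SeverityLabel",
    "BDI9_BANDS",
    "score_bhs",
    "score_bdi9",
    "bdi9_severity",
    "load_instrument_definitions",
    "InstrumentValidationError",
]

BHS_N_ITEMS = 4
BHS_ITEM_RANGE = (0, 3)
BHS_TOTAL_RANGE = (0, 12)

BDI9_N_ITEMS = 9
BDI9_ITEM_RANGE = (1, 4)
BDI9_TOTAL_RANGE = (9, 36)


class InstrumentValidationError(ValueError):
    """An item score is absent where forbidden or outside its legal range."""


class SeverityLabel(str, enum.Enum):
    NO_DEPRESSION = "NO_DEPRESSION"
    MILD = "MILD"
    MODERATE = "MODERATE"
    SEVERE = "SEVERE"


@dataclass(frozen=True)
class SeverityBand:
    """One BDI-9 severity band: a closed interval of total scores.

    ``upper is None`` means the band is unbounded above (the "severe"
    band, ≥25).
    """

    label: SeverityLabel
    lower: int
    upper: Optional[int]

    def contains(self, total: int) -> bool:
        return total >= self.lower and (self.upper is None or total <= self.upper)


#: The published BDI-9 severity bands; they partition 9..36 exactly.
BDI9_BANDS: tuple[SeverityBand, ...] = (
    SeverityBand(SeverityLabel.NO_DEPRESSION, 9, 13),
    SeverityBand(SeverityLabel.MILD, 14, 18),
    SeverityBand(SeverityLabel.MODERATE, 19, 24),
    SeverityBand(SeverityLabel.SEVERE, 25, None),
)


def _validate_items(
    items: tuple[Optional[int], ...],
    n_items: int,
    lo: int,
    hi: int,
    instrument: str,
) -> None:
    if len(items) != n_items:
        raise InstrumentValidationError(
            f"{instrument}: expected {n_items} item slots, got {len(items)}"
        )
    for idx, value in enumerate(items, start=1):
        if value is None:
            continue
        if not isinstance(value, int) or isinstance(value, bool):
            raise InstrumentValidationError(
                f"{instrument} item {idx}: non-integer score {value!r}"
            )
        if not lo <= value <= hi:
            raise InstrumentValidationError(
                f"{instrument} item {idx}: score {value} outside {lo}..{hi}"
            )


@dataclass(frozen=True)
class BHSResponse:
    """One respondent's BHS-4 answers, item by item (``None`` = absent).

    Item identity is preserved in storage (each item has clinical
    meaning) even though the total is order-invariant.
    """

    items: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        _validate_items(self.items, BHS_N_ITEMS, *BHS_ITEM_RANGE, instrument="BHS4")

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.items)


@dataclass(frozen=True)
class BDI9Response:
    """One respondent's BDI-9 answers, item by item (``None`` = absent)."""

    items: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        _validate_items(self.items, BDI9_N_ITEMS, *BDI9_ITEM_RANGE, instrument="BDI9")

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.items)


def score_bhs(response: BHSResponse) -> Optional[int]:
    """Total BHS-4 score (0–12), or ``None`` when any item is absent."""
    if not response.complete:
        return None
    return sum(response.items)  # type: ignore[arg-type]


def score_bdi9(response: BDI9Response) -> Optional[int]:
    """Total BDI-9 score (9–36), or ``None`` when any item is absent."""
    if not response.complete:
        return None
    return sum(response.items)  # type: ignore[arg-type]


def bdi9_severity(total: int) -> SeverityBand:
    """Map a complete BDI-9 total to its severity band.

    Raises
    ------
    ValueError
        If ``total`` lies outside 9..36 (an unscored or corrupt input —
        a complete BDI-9 response cannot produce such a total).
    """
    lo, hi = BDI9_TOTAL_RANGE
    if not isinstance(total, int) or not lo <= total <= hi:
        raise ValueError(f"BDI-9 total {total!r} outside {lo}..{hi}")
    for band in BDI9_BANDS:
        if band.contains(total):
            return band
    raise AssertionError("unreachable: bands partition 9..36")


@lru_cache(maxsize=1)
def load_instrument_definitions() -> dict:
    """Load the versioned instrument metadata (item texts, ranges, bands).

    Shipped as human-readable YAML so reports can render item wording and
    protocols can reference instruments by name ("BHS4", "BDI9").
    """
    text = resources.files("depscreen.data").joinpath("instruments.yaml").read_text()
    return yaml.safe_load(text)
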