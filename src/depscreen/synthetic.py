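"""Seedable synthetic cohorts calibrated to published survey marginals.

The survey that motivates this package (Hungarostudy 2002, N = 12,668)
is not publicly deposited.  What *is* published is the complete set of
branch counts of the screening tree under all three protocols, which
pins down most of the joint distribution of (prior diagnosis, BHS zone,
BDI band, instrument missingness).  A :class:`CohortBlueprint` stores
exact counts for these calibration cells; :func:`generate` materialises
item-level records cell by cell, so tabulating the generated cohort
reproduces every published count identically, for every seed.

Cells not pinned by published numbers (the BDI band split inside BHS
zone 2, and how the 491 BDI-incomplete respondents distribute across
BHS zones 2/3/4–5) are filled by a fixed, documented allocation rule —
proportional allocation with remainders by the largest-remainder
method — and flagged ``free`` in the cell metadata.

Exact-count generation is the default because the published analysis is
a census of the sample, not a sampling experiment.
:func:`sample_stochastic` draws cell sizes multinomially instead, for
robustness/power experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import BHS_COLS, BDI_COLS, COHORT_COLUMNS, _INT_COLS

__all__ = [
    "CellSpec",
    "CohortBlueprint",
    "default_blueprint",
    "generate",
    "sample_stochastic",
    "blueprint_to_yaml",
    "blueprint_from_yaml",
    "HUNGAROSTUDY_MARGINALS",
]

#: Published marginal counts of the Hungarostudy 2002 screening analysis.
#: These are the calibration anchors; everything else is derived.
HUNGAROSTUDY_MARGINALS = {
    "total_n": 12_668,
    "prior_psychiatric": 805,
    "bhs_missing": 658,
    "bhs_ge6": 1_097,
    "bhs_0_1": 6_992,       # stop zone, protocol 1
    "bhs_0_2": 8_169,       # stop zone, protocol 2
    "bhs_0_3": 8_996,       # stop zone, protocol 3
    "bdi_missing_total": 491,  # BDI incomplete among BHS completers
    "bhs_3_5_bdi_19_24": 235,
    "bhs_3_5_bdi_ge25": 178,
    "bhs_4_5_bdi_19_24": 190,
    "bhs_4_5_bdi_ge25": 137,
}

# BDI band labels used by cells
_BDI_BANDS = {
    "lt19": (9, 18),
    "19_24": (19, 24),
    "ge25": (25, 36),
    "any": (9, 36),
}


@dataclass(frozen=True)
class CellSpec:
    """One calibration cell: a count plus the score ranges it must hit.

    ``bhs_range is None`` means the BHS instrument is missing for the
    cell; ``bdi_band == "missing"`` likewise for the BDI-9.  ``free``
    marks cells whose count is fixed by the allocation rule rather than
    by a published number.
    """

    name: str
    count: int
    prior_dx: bool = False
    bhs_range: Optional[tuple[int, int]] = None
    bdi_band: str = "missing"
    free: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"cell {self.name}: negative count")
        if self.bdi_band not in (*_BDI_BANDS, "missing"):
            raise ValueError(f"cell {self.name}: unknown BDI band {self.bdi_band!r}")
        if self.bhs_range is not None:
            lo, hi = self.bhs_range
            if not (0 <= lo <= hi <= 12):
                raise ValueError(f"cell {self.name}: BHS range {self.bhs_range} invalid")


@dataclass(frozen=True)
class CohortBlueprint:
    """Exact cell counts for a synthetic cohort."""

    total_n: int
    cells: tuple[CellSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        total = sum(c.count for c in self.cells)
        if total != self.total_n:
            raise ValueError(f"cell counts sum to {total}, not total_n {self.total_n}")
        names = [c.name for c in self.cells]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell names")

    def cell(self, name: str) -> CellSpec:
        for c in self.cells:
            if c.name == name:
                return c
        raise KeyError(name)

    def zone_sum(self, bhs_lo: int, bhs_hi: int) -> int:
        """Total count of screening cells whose BHS range lies in [lo, hi]."""
        return sum(
            c.count
            for c in self.cells
            if not c.prior_dx
            and c.bhs_range is not None
            and bhs_lo <= c.bhs_range[0]
            and c.bhs_range[1] <= bhs_hi
        )


def largest_remainder(total: int, weights: Sequence[int]) -> list[int]:
    """Split ``total`` proportionally to ``weights``, remainders to the
    largest fractional parts (ties to the earlier index)."""
    if total < 0 or any(w < 0 for w in weights):
        raise ValueError("negative input")
    wsum = sum(weights)
    if wsum == 0:
        raise ValueError("all weights zero")
    floors = [total * w // wsum for w in weights]
    fracs = [total * w % wsum for w in weights]
    short = total - sum(floors)
    order = sorted(range(len(weights)), key=lambda i: (-fracs[i], i))
    for i in order[:short]:
        floors[i] += 1
    return floors


def default_blueprint() -> CohortBlueprint:
    """The Hungarostudy-2002-calibrated blueprint (N = 12,668).

    Derivation from the published marginals:

    * BHS zones: 0–1 = 6,992; zone 2 = 8,169 − 6,992; zone 3 =
      8,996 − 8,169; zone 4–5 = remainder of the 2–5 zone; ≥6 = 1,097.
    * BDI bands inside zones 3 and 4–5 follow from the published 3–5 and
      4–5 band counts by subtraction.
    * The 491 BDI-incomplete respondents are allocated inside the BHS
      2–5 zone, split across zones 2/3/4–5 proportionally (largest
      remainder) — a free choice, flagged on the cells.
    * The BDI band split inside zone 2 (unpublished; only protocol 1's
      unprinted sub-branches depend on it) is proportional to the
      BDI-complete band distribution observed in zones 3–5.
    """
    m = HUNGAROSTUDY_MARGINALS
    zone2 = m["bhs_0_2"] - m["bhs_0_1"]
    zone3 = m["bhs_0_3"] - m["bhs_0_2"]
    completers = m["total_n"] - m["prior_psychiatric"] - m["bhs_missing"]
    zone2_5 = completers - m["bhs_0_1"] - m["bhs_ge6"]
    zone45 = zone2_5 - zone2 - zone3

    miss2, miss3, miss45 = largest_remainder(m["bdi_missing_total"], [zone2, zone3, zone45])

    z3_assess = m["bhs_3_5_bdi_19_24"] - m["bhs_4_5_bdi_19_24"]
    z3_refer = m["bhs_3_5_bdi_ge25"] - m["bhs_4_5_bdi_ge25"]
    z3_lt19 = zone3 - z3_assess - z3_refer - miss3
    z45_lt19 = zone45 - m["bhs_4_5_bdi_19_24"] - m["bhs_4_5_bdi_ge25"] - miss45

    # zone-2 BDI bands: proportional to the BDI-complete distribution in 3-5
    z35_complete = [z3_lt19 + z45_lt19,
                    m["bhs_3_5_bdi_19_24"],
                    m["bhs_3_5_bdi_ge25"]]
    z2_complete = zone2 - miss2
    z2_lt19, z2_assess, z2_refer = largest_remainder(z2_complete, z35_complete)

    cells = (
        CellSpec("prior_dx", m["prior_psychiatric"], prior_dx=True,
                 bhs_range=(0, 12), bdi_band="any", free=True),
        CellSpec("bhs_missing", m["bhs_missing"], bhs_range=None, bdi_band="missing"),
        CellSpec("bhs01", m["bhs_0_1"], bhs_range=(0, 1), bdi_band="any", free=True),
        CellSpec("bhs2_bdi_lt19", z2_lt19, bhs_range=(2, 2), bdi_band="lt19", free=True),
        CellSpec("bhs2_bdi_19_24", z2_assess, bhs_range=(2, 2), bdi_band="19_24", free=True),
        CellSpec("bhs2_bdi_ge25", z2_refer, bhs_range=(2, 2), bdi_band="ge25", free=True),
        CellSpec("bhs2_bdi_missing", miss2, bhs_range=(2, 2), bdi_band="missing", free=True),
        CellSpec("bhs3_bdi_lt19", z3_lt19, bhs_range=(3, 3), bdi_band="lt19", free=True),
        CellSpec("bhs3_bdi_19_24", z3_assess, bhs_range=(3, 3), bdi_band="19_24"),
        CellSpec("bhs3_bdi_ge25", z3_refer, bhs_range=(3, 3), bdi_band="ge25"),
        CellSpec("bhs3_bdi_missing", miss3, bhs_range=(3, 3), bdi_band="missing", free=True),
        CellSpec("bhs45_bdi_lt19", z45_lt19, bhs_range=(4, 5), bdi_band="lt19", free=True),
        CellSpec("bhs45_bdi_19_24", m["bhs_4_5_bdi_19_24"], bhs_range=(4, 5), bdi_band="19_24"),
        CellSpec("bhs45_bdi_ge25", m["bhs_4_5_bdi_ge25"], bhs_range=(4, 5), bdi_band="ge25"),
        CellSpec("bhs45_bdi_missing", miss45, bhs_range=(4, 5), bdi_band="missing", free=True),
        CellSpec("bhs_ge6", m["bhs_ge6"], bhs_range=(6, 12), bdi_band="any", free=True),
    )
    return CohortBlueprint(total_n=m["total_n"], cells=cells)


# ---------------------------------------------------------------------------
# item-composition machinery


@lru_cache(maxsize=None)
def _compositions(n_items: int, item_lo: int, item_hi: int) -> tuple[np.ndarray, np.ndarray]:
    """All item-score vectors and their totals (int16)."""
    n_levels = item_hi - item_lo + 1
    grid = (
        np.indices((n_levels,) * n_items)
        .reshape(n_items, -1)
        .T.astype(np.int16)
        + item_lo
    )
    return grid, grid.sum(axis=1)


def _sample_items(
    rng: np.random.Generator, n: int, n_items: int, item_lo: int, item_hi: int,
    total_lo: int, total_hi: int, cell_name: str,
) -> np.ndarray:
    """Sample n item vectors uniformly over compositions with total in range."""
    grid, totals = _compositions(n_items, item_lo, item_hi)
    mask = (totals >= total_lo) & (totals <= total_hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            f"cell {cell_name!r}: no {n_items}-item composition reaches total "
            f"{total_lo}..{total_hi}"
        )
    return grid[rng.choice(idx, size=n)]


def _materialise(
    cell_sizes: Sequence[tuple[CellSpec, int]],
    rng: np.random.Generator,
    mde_rate: Optional[float],
    suicidality_rate: float,
) -> pd.DataFrame:
    parts: list[pd.DataFrame] = []
    for cell, n in cell_sizes:
        if n == 0:
            continue
        block = pd.DataFrame(index=range(n), columns=COHORT_COLUMNS, dtype=object)
        block["prior_dx"] = int(cell.prior_dx)
        if cell.bhs_range is not None:
            lo, hi = cell.bhs_range
            items = _sample_items(rng, n, 4, 0, 3, lo, hi, cell.name)
            for j, col in enumerate(BHS_COLS):
                block[col] = items[:, j]
        if cell.bdi_band != "missing":
            lo, hi = _BDI_BANDS[cell.bdi_band]
            items = _sample_items(rng, n, 9, 1, 4, lo, hi, cell.name)
            for j, col in enumerate(BDI_COLS):
                block[col] = items[:, j]
        block["_cell"] = cell.name
        parts.append(block)
    df = pd.concat(parts, ignore_index=True)
    # shuffle, then assign ids in the shuffled order
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df["id"] = [f"R{i + 1:06d}" for i in range(len(df))]

    # demographics: uniform placeholders, deliberately non-calibrated
    df["sex"] = rng.choice(["F", "M"], size=len(df))
    df["age"] = rng.integers(18, 90, size=len(df))

    if mde_rate is not None:
        _attach_mde_flags(df, rng, mde_rate, suicidality_rate)

    cells = df.pop("_cell")
    df = df[COHORT_COLUMNS].copy()
    for col in _INT_COLS:
        df[col] = df[col].astype("Int64")
    df["id"] = df["id"].astype("string")
    df["sex"] = df["sex"].astype("string")
    df.attrs["cells"] = cells.tolist()
    return df


def _attach_mde_flags(
    df: pd.DataFrame, rng: np.random.Generator, mde_rate: float, suicidality_rate: float
) -> None:
    """Give DSM-5 flags to the BDI 19-24 band (screened records only).

    With probability ``mde_rate`` a record meets the MDE rule (one or
    both core symptoms plus 4-7 other symptoms); among MDE cases a
    suicidality qualifier is present with ``suicidality_rate``.
    """
    bdi_total = df[BDI_COLS].apply(pd.to_numeric).sum(axis=1, min_count=9)
    eligible = (
        (df["prior_dx"] == 0)
        & bdi_total.between(19, 24)
    )
    idx = df.index[eligible]
    n = len(idx)
    if n == 0:
        return
    is_mde = rng.random(n) < mde_rate
    core1 = np.where(is_mde, rng.random(n) < 0.8, rng.random(n) < 0.3)
    # guarantee >=1 core symptom for MDE cases, allow both patterns otherwise
    core2 = np.where(is_mde & ~core1, True, rng.random(n) < 0.5)
    others = np.where(is_mde, rng.integers(4, 8, size=n), rng.integers(0, 4, size=n))
    # non-MDE records without any core symptom may still carry many "other" symptoms
    no_core = ~(core1 | core2)
    others = np.where(~is_mde & no_core, rng.integers(0, 8, size=n), others)
    suicidal = is_mde & (rng.random(n) < suicidality_rate)
    ideation = suicidal & (rng.random(n) < 0.9)
    plan = suicidal & (rng.random(n) < 0.4)
    attempt = suicidal & ~(ideation | plan)  # qualifier guaranteed via history
    df.loc[idx, "mde_core1"] = core1.astype(int)
    df.loc[idx, "mde_core2"] = core2.astype(int)
    df.loc[idx, "mde_other_count"] = others
    df.loc[idx, "ideation"] = ideation.astype(int)
    df.loc[idx, "plan"] = plan.astype(int)
    df.loc[idx, "prior_attempt"] = attempt.astype(int)


def generate(
    blueprint: CohortBlueprint,
    seed: int,
    mde_rate: Optional[float] = None,
    suicidality_rate: float = 0.3,
) -> pd.DataFrame:
    """Materialise exactly ``blueprint``-many records per cell.

    Item scores are drawn uniformly from the compositions consistent
    with each cell's total-score range; deterministic given ``seed``
    (cell counts are blueprint-determined, only item values and record
    order vary with the seed).  DSM-5 symptom flags are generated only
    when ``mde_rate`` is given, for the BDI 19–24 band.
    """
    rng = np.random.default_rng(seed)
    return _materialise(
        [(c, c.count) for c in blueprint.cells], rng, mde_rate, suicidality_rate
    )


def sample_stochastic(
    blueprint: CohortBlueprint,
    n: int,
    seed: int,
    mde_rate: Optional[float] = None,
    suicidality_rate: float = 0.3,
) -> pd.DataFrame:
    """Draw ``n`` records with cell sizes multinomial(blueprint proportions).

    Unlike :func:`generate`, cell counts fluctuate around n x p; use this
    for sampling experiments, not for reproducing the published census.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    p = np.array([c.count for c in blueprint.cells], dtype=float)
    p /= p.sum()
    sizes = rng.multinomial(n, p)
    return _materialise(
        list(zip(blueprint.cells, (int(s) for s in sizes))), rng, mde_rate, suicidality_rate
    )


# ---------------------------------------------------------------------------
# blueprint serialisation


def blueprint_to_yaml(blueprint: CohortBlueprint, path: Union[str, Path]) -> None:
    payload = {
        "total_n": blueprint.total_n,
        "cells": [
            {**asdict(c), "bhs_range": list(c.bhs_range) if c.bhs_range else None}
            for c in blueprint.cells
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def blueprint_from_yaml(path: Union[str, Path]) -> CohortBlueprint:
    raw = yaml.safe_load(Path(path).read_text())
    cells = tuple(
        CellSpec(
            name=c["name"],
            count=int(c["count"]),
            prior_dx=bool(c.get("prior_dx", False)),
            bhs_range=tuple(c["bhs_range"]) if c.get("bhs_range") else None,
            bdi_band=c.get("bdi_band", "missing"),
            free=bool(c.get("free", False)),
        )
        for c in raw["cells"]
    )
    return CohortBlueprint(total_n=int(raw["total_n"]), cells=cells)
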