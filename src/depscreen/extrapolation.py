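"""Rescaling cohort counts to target populations.

An observed proportion count/N is applied to a target population of
``target_size`` people and rounded to the nearest integer, halves away
from zero.  The arithmetic is exact (integer, not floating point), so
rounding behaviour is bit-reproducible for any operand sizes.

Aggregates (definitive / potential care) are extrapolated from their raw
summed counts — not by summing the rounded per-category estimates — but
the component-wise sums are recorded too, so reports can show either
convention and flag any discrepancy between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .cohort import CohortTable
from .triage import Category

__all__ = [
    "PopulationTarget",
    "PopulationEstimate",
    "extrapolate_count",
    "extrapolate_table",
    "GMP_TARGET",
    "NATIONAL_25PLUS_TARGET",
]


@dataclass(frozen=True)
class PopulationTarget:
    """A population to which cohort proportions are extrapolated."""

    name: str
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"target size must be >= 1, got {self.size}")


#: An average Hungarian general medical practice: 1,600 registered adults.
GMP_TARGET = PopulationTarget("gmp", 1600)
#: The Hungarian population aged 25+ in 2018.
NATIONAL_25PLUS_TARGET = PopulationTarget("national", 7_288_433)


def extrapolate_count(count: int, denominator: int, target_size: int) -> int:
    """round-half-away-from-zero(count * target_size / denominator).

    Exact integer arithmetic: q + (1 if the remainder is at least half
    the denominator).  0 maps to 0 and count == denominator maps to
    target_size.
    """
    if denominator < 1 or target_size < 1:
        raise ValueError("denominator and target_size must be >= 1")
    if not 0 <= count <= denominator:
        raise ValueError(f"count {count} outside 0..{denominator}")
    q, r = divmod(count * target_size, denominator)
    return q + (1 if 2 * r >= denominator else 0)


@dataclass(frozen=True)
class PopulationEstimate:
    """A CohortTable rescaled to one target population.

    ``definitive_componentwise`` sums the already-rounded referral
    estimates; it can differ from ``definitive_estimate`` (rounded from
    the raw summed count) by at most 1 per component.
    """

    protocol: str
    target: PopulationTarget
    denominator: int
    estimates: Mapping[Category, int]
    definitive_estimate: int
    potential_estimate: int
    bdi_indicated_estimate: int
    definitive_componentwise: int

    def estimate(self, category: Category) -> int:
        return int(self.estimates.get(category, 0))

    @property
    def sum_discrepancy(self) -> int:
        """Rounded-total vs summed-rounded-categories mismatch (people)."""
        return sum(self.estimates.values()) - self.target.size


def extrapolate_table(table: CohortTable, target: PopulationTarget) -> PopulationEstimate:
    """Extrapolate every category and aggregate of ``table`` to ``target``."""
    n = table.denominator
    estimates = {
        category: extrapolate_count(table.count(category), n, target.size)
        for category in Category
    }
    return PopulationEstimate(
        protocol=table.protocol,
        target=target,
        denominator=n,
        estimates=estimates,
        definitive_estimate=extrapolate_count(table.definitive_care_count, n, target.size),
        potential_estimate=extrapolate_count(table.potential_care_count, n, target.size),
        bdi_indicated_estimate=extrapolate_count(table.bdi_indicated_count, n, target.size),
        definitive_componentwise=(
            estimates[Category.IMMEDIATE_REFERRAL_BHS]
            + estimates[Category.IMMEDIATE_REFERRAL_BDI]
        ),
    )
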