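"""Release-period assignment for recipient cultivars.

Periods are a step function of year of release with two cut points
(defaults 1920 and 1970): period 1 is ``year <= cut1``, period 2 is
``cut1 < year <= cut2``, period 3 is ``year > cut2``.  The left-inclusive
convention (1920 -> period 1, 1970 -> period 2) is configurable via
``PeriodBounds``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from haplopaint.data_model.types import SampleMetadata, ValidationError

EARLIEST_YEAR = 1788


@dataclass(frozen=True)
class PeriodBounds:
    cut1: int = 1920
    cut2: int = 1970

    def __post_init__(self) -> None:
        if not self.cut1 < self.cut2:
            raise ValidationError("PeriodBounds requires cut1 < cut2")


def assign_period(year: int, bounds: PeriodBounds = PeriodBounds()) -> int:
    """Map a year of release to period 1, 2 or 3."""
    year = int(year)
    if year < EARLIEST_YEAR:
        raise ValidationError(f"year {year} predates {EARLIEST_YEAR}")
    if year <= bounds.cut1:
        return 1
    if year <= bounds.cut2:
        return 2
    return 3


def assign_periods(
    metadata: SampleMetadata, bounds: PeriodBounds = PeriodBounds()
) -> SampleMetadata:
    """Return metadata with the ``period`` column filled from ``year``.

    Samples with no year keep a missing period and are excluded from
    period-based analyses; a warning reports how many.
    """
    t = metadata.table.copy()
    known = t["year"].notna()
    n_missing = int((~known & (t["role"] == "recipient")).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} recipient sample(s) lack year_of_release; "
            "excluded from period analyses",
            stacklevel=2,
        )
    t["period"] = pd.array(
        [assign_period(y, bounds) if pd.notna(y) else pd.NA for y in t["year"]],
        dtype="Int64",
    )
    return SampleMetadata(t)
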