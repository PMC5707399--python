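"""Small shared helpers: seeding, season parsing, errors."""

from __future__ import annotations

import zlib

import numpy as np

MONTH_INITIALS = "JFMAMJJASOND"

#: season name (e.g. "SON") -> tuple of calendar month indices, January = 0
SEASONS = {
    "".join(MONTH_INITIALS[(m + k) % 12] for k in range(3)): tuple((m + k) % 12 for k in range(3))
    for m in range(12)
}


class GEFAError(ValueError):
    """Raised when an input violates an estimator precondition."""


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed deterministically from a run seed.

    Stages seeded this way are independently reproducible: rerunning a single
    stage with the same run seed regenerates the same stream.
    """
    return (zlib.crc32(stage.encode("utf8")) ^ (int(seed) * 1000003)) % (2**31)


def parse_season(season) -> tuple[int, int, int]:
    """Normalize a season spec to three consecutive calendar month indices.

    Accepts a name built from month initials ("SON", "JAS", ...) or a sequence
    of three consecutive month indices (January = 0, wrapping at December).
    """
    if isinstance(season, str):
        key = season.upper()
        if key not in SEASONS:
            raise GEFAError(f"unknown season name {season!r}; expected e.g. 'SON', 'JAS'")
        return SEASONS[key]
    months = tuple(int(m) for m in season)
    if len(months) != 3:
        raise GEFAError(f"a season is 3 consecutive calendar months, got {season!r}")
    for a, b in zip(months, months[1:]):
        if (a + 1) % 12 != b:
            raise GEFAError(f"season months must be consecutive, got {season!r}")
    if not all(0 <= m < 12 for m in months):
        raise GEFAError(f"month indices must be in 0..11, got {season!r}")
    return months


def calendar_months(n_months: int, start_month: int = 0) -> np.ndarray:
    """Calendar month index (0..11) for each step of a monthly record."""
    return (np.arange(n_months) + start_month) % 12
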