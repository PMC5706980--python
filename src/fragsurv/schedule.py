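"""Geometric contour-fragmentation schedule for the build-up paradigm.

At presentation ``x`` (1-based) of ``n`` the stimulus shows
``100 * alpha**(n - x)`` percent of the object outline, so the contour grows
geometrically and reaches the intact outline (100%) on the last presentation.
With the study default ``alpha = 0.77`` over 10 presentations the schedule is
10, 12, 16, 21, 27, 35, 46, 59, 77, 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["FragmentationSchedule", "fragment_percentages"]


@dataclass(frozen=True)
class FragmentationSchedule:
    """Percent contour shown per presentation level."""

    alpha: float
    n_levels: int
    percentages: tuple[int, ...]

    def __post_init__(self):
        if list(self.percentages) != sorted(set(self.percentages)):
            raise ValueError("percentages must be strictly increasing")
        if self.percentages[-1] != 100:
            raise ValueError("final presentation must show the intact outline (100%)")
        if len(self.percentages) != self.n_levels:
            raise ValueError("length of percentages must equal n_levels")


def fragment_percentages(alpha: float, n_levels: int) -> FragmentationSchedule:
    """Integer percent contour per level, ``round_half_up(100 * alpha**(n-x))``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    pct = tuple(
        int(math.floor(100.0 * alpha ** (n_levels - x) + 0.5)) for x in range(1, n_levels + 1)
    )
    return FragmentationSchedule(alpha=alpha, n_levels=n_levels, percentages=pct)
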