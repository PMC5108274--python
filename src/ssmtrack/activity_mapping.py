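"""Mapping of ancillary tag proportions to activity-state probabilities.

The third ("activity") behavioral state is informed by tag data that can
be expressed as a per-interval proportion: time hauled out, or time
spent diving.  This module converts such a series into the per-interval
probability ``pr_A`` of being in the activity state and the binary
status ``a_status`` (1 = activity state, 2 = not) that the model
formulations consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "AncillarySeries",
    "ActivityProbability",
    "haulout_status",
    "inactive_prob_from_diving",
    "STATUS_ACTIVITY",
    "STATUS_OTHER",
    "STATUS_UNFORCED",
]

STATUS_ACTIVITY = 1
STATUS_OTHER = 2
STATUS_UNFORCED = 0


@dataclass
class AncillarySeries:
    """Per-interval ancillary proportion aligned with a regular grid.

    ``values`` holds fractions in [0, 1]; ``missing`` is a boolean mask
    of intervals with no usable record (None means nothing is missing,
    as for haulout aggregation where absence of a record reads as 0).
    """

    animal_id: str
    values: np.ndarray
    kind: str  # "haulout" | "diving"
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask and values length mismatch")
        present = self.values if self.missing is None else self.values[~self.missing]
        if present.size and (np.nanmin(present) < 0 or np.nanmax(present) > 1):
            raise ValueError("ancillary proportions must lie in [0, 1]")

    @property
    def missing_mask(self) -> np.ndarray:
        if self.missing is None:
            return np.zeros(self.values.shape, dtype=bool)
        return self.missing


@dataclass
class ActivityProbability:
    """Activity-state probability and forcing status per interval."""

    pr_A: np.ndarray
    a_status: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pr_A = np.asarray(self.pr_A, dtype=float)
        if np.any((self.pr_A < 0) | (self.pr_A > 1)):
            raise ValueError("pr_A must lie in [0, 1]")
        if self.a_status is None:
            self.a_status = np.full(self.pr_A.shape, STATUS_UNFORCED, dtype=np.int8)
        self.a_status = np.asarray(self.a_status, dtype=np.int8)


def haulout_status(series: AncillarySeries, threshold: float = 0.5) -> ActivityProbability:
    """Map haulout proportions to ``pr_A`` / ``a_status``.

    ``pr_A`` is the observed proportion itself; the interval is treated
    as hauled out (status 1) only where the proportion strictly exceeds
    the threshold.  A proportion of exactly 0.5 is *not* hauled out —
    the movement-informed states win ties.  Missing intervals read as
    not hauled out with ``pr_A = 0``.
    """
    if series.kind != "haulout":
        raise ValueError(f"expected a haulout series, got kind={series.kind!r}")
    pr = series.values.copy()
    pr[series.missing_mask] = 0.0
    status = np.where(pr > threshold, STATUS_ACTIVITY, STATUS_OTHER).astype(np.int8)
    return ActivityProbability(pr_A=pr, a_status=status)


def inactive_prob_from_diving(
    series: AncillarySeries,
    rescale: Callable[[np.ndarray, float], np.ndarray] | None = None,
    missing_value: float = 0.5,
) -> ActivityProbability:
    """Map dive proportions d to the probability of being inactive.

    ``pr_A = 1`` only where no diving at all was recorded (d = 0).  Any
    diving rescales ``pr_A`` strictly below 0.5, reaching ~0 at the
    animal's maximum observed dive proportion ``d_max``.  The default
    rescale is linear, ``0.5 * (1 - d / d_max)``; an alternative can be
    injected as ``rescale(d, d_max)``.  Missing bins are uninformative
    (``pr_A = 0.5``).

    ``a_status`` is 1 where pr_A > 0.5, 2 where pr_A < 0.5, and
    unforced (0) at exactly 0.5.
    """
    if series.kind != "diving":
        raise ValueError(f"expected a diving series, got kind={series.kind!r}")
    d = series.values.astype(float).copy()
    miss = series.missing_mask | np.isnan(d)
    observed = d[~miss]
    d_max = float(observed.max()) if observed.size else 0.0
    if d_max == 0.0:
        warnings.warn(
            "all observed dive proportions are zero: d_max undefined, "
            "every observed interval maps to pr_A = 1",
            stacklevel=2,
        )
        pr = np.full(d.shape, 1.0)
    else:
        if rescale is None:
            scaled = 0.5 * (1.0 - d / d_max)
        else:
            scaled = np.asarray(rescale(d, d_max), dtype=float)
        pr = np.where(d == 0.0, 1.0, scaled)
    pr = np.where(miss, missing_value, pr)
    pr = np.clip(pr, 0.0, 1.0)
    status = np.full(pr.shape, STATUS_UNFORCED, dtype=np.int8)
    status[pr > 0.5] = STATUS_ACTIVITY
    status[pr < 0.5] = STATUS_OTHER
    return ActivityProbability(pr_A=pr, a_status=status)
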