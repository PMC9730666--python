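"""Knee detection on sorted end-contact values.

Sorted in descending order, end-pair contact values fall steeply through the
adjacent-pair (signal) regime and then flatten into the non-adjacent
background (noise); the knee of that curve is a natural basic cutoff.  Both
axes are min-max normalized so the curve runs from (0, 1) to (1, 0), and the
curve is rotated 45 degrees anticlockwise so the endpoint chord becomes
horizontal; the lowest rotated point — equivalently argmin(x + y) — is the
turning point.  Because the knee tends to sit in the upper part of the noise
values, graph cutoffs are taken as small multiples of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

__all__ = ["TurningPoint", "TurningPointError", "find_turning_point", "derive_cutoffs"]


class TurningPointError(ValueError):
    """Degenerate value distribution; choose a cutoff manually."""


@dataclass(frozen=True)
class TurningPoint:
    sorted_rank: int  # index in the descending-sorted value vector
    value: float      # the basic cutoff T


def find_turning_point(values: Sequence[float]) -> TurningPoint:
    """Locate the knee of the descending-sorted value curve.

    Ranks and values are min-max normalized to [0, 1]; the point minimizing
    the rotated ordinate (x + y, up to scale) is returned.  Ties go to the
    smaller rank, i.e. the larger contact value.
    """
    vals = np.sort(np.asarray(values, dtype=float))[::-1]
    if len(vals) < 3:
        raise TurningPointError(
            "need at least 3 contact values to locate a turning point; "
            "set a manual cutoff"
        )
    vmax, vmin = vals[0], vals[-1]
    if vmax == vmin:
        raise TurningPointError(
            "all contact values are equal; set a manual cutoff"
        )
    x = np.arange(len(vals)) / (len(vals) - 1)
    y = (vals - vmin) / (vmax - vmin)
    rank = int(np.argmin(x + y))  # argmin returns the first (smallest) rank
    return TurningPoint(sorted_rank=rank, value=float(vals[rank]))


def derive_cutoffs(tp: TurningPoint, multipliers: Sequence[float]) -> List[float]:
    """Contact cutoffs as multiples of the basic cutoff, order preserved."""
    if any(m <= 0 for m in multipliers):
        raise ValueError("multipliers must be positive")
    return [m * tp.value for m in multipliers]
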