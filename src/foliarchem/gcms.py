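"""GC-MS identification support: Kovats retention indices.

Under a temperature-programmed GC run, retention indices interpolate
linearly between the bracketing n-alkanes (van den Dool & Kratz):
``RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n))``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InputError, RangeError

__all__ = ["kovats_ri"]


def kovats_ri(rt: float, alkane_ladder: Sequence[tuple[int, float]]) -> float:
    """Kovats retention index of a peak at ``rt`` minutes.

    ``alkane_ladder`` lists (carbon_number, retention_time) anchors, strictly
    increasing in both fields, with at least two entries; ``rt`` must fall
    within the ladder range.  An alkane's own retention time maps to 100 x
    its carbon number.
    """
    if len(alkane_ladder) < 2:
        raise InputError("alkane ladder needs at least 2 entries")
    carbons = np.array([c for c, _ in alkane_ladder], dtype=float)
    times = np.array([t for _, t in alkane_ladder], dtype=float)
    if np.any(np.diff(carbons) <= 0) or np.any(np.diff(times) <= 0):
        raise InputError("alkane ladder must be strictly increasing in carbon number and time")
    if rt < times[0] or rt > times[-1]:
        raise RangeError(
            f"retention time {rt} outside ladder range [{times[0]}, {times[-1]}]")
    k = int(np.searchsorted(times, rt, side="right")) - 1
    k = min(k, len(times) - 2)
    frac = (rt - times[k]) / (times[k + 1] - times[k])
    return 100.0 * (carbons[k] + frac * (carbons[k + 1] - carbons[k]))
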