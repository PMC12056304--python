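"""Behavior metrics: novel-object discrimination index and open-field
time-in-center.

The discrimination index comes in two conventional forms — the fraction of
exploration time spent on the novel object, t_n/(t_n+t_f), at chance 0.5, and
the signed index (t_n−t_f)/(t_n+t_f), at chance 0. Both are reported; which
one a given study prints is a matter of convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import MeasurementError, UsageError


@dataclass
class DiscriminationIndex:
    fraction: float  # t_n / (t_n + t_f), chance 0.5
    signed: float  # (t_n - t_f) / (t_n + t_f), chance 0.0


def discrimination_index(t_novel_s: float, t_familiar_s: float) -> DiscriminationIndex:
    """Novel-object preference from exploration times (seconds)."""
    if t_novel_s < 0 or t_familiar_s < 0:
        raise UsageError("exploration times must be non-negative")
    total = t_novel_s + t_familiar_s
    if total <= 0:
        raise MeasurementError(
            "discrimination index undefined: zero total exploration time"
        )
    return DiscriminationIndex(
        fraction=t_novel_s / total, signed=(t_novel_s - t_familiar_s) / total
    )


def time_in_center(
    positions: np.ndarray,
    center_zone: tuple[float, float, float, float],
    frame_interval_s: float,
) -> float:
    """Seconds spent inside a rectangular center zone.

    ``positions`` is (n_frames, 2) as (x, y); ``center_zone`` is
    (x_min, y_min, x_max, y_max), boundary inclusive. Occupancy is counted
    per frame and multiplied by the frame interval.
    """
    if frame_interval_s <= 0:
        raise UsageError("frame_interval_s must be positive")
    x0, y0, x1, y1 = center_zone
    if not (x0 < x1 and y0 < y1):
        raise UsageError("center_zone must be (x_min, y_min, x_max, y_max)")
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        warnings.warn("empty track: time in center is 0 s", stacklevel=2)
        return 0.0
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise UsageError("positions must be an (n_frames, 2) array")
    inside = (
        (pos[:, 0] >= x0) & (pos[:, 0] <= x1) & (pos[:, 1] >= y0) & (pos[:, 1] <= y1)
    )
    return float(inside.sum()) * frame_interval_s
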