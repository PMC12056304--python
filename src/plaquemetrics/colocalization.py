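"""Two-channel Aβ40/Aβ42 quantification and fibrillar-fraction ratios.

The colocalization statistic is the Manders-style overlap coefficient

    R = Σ(A_i · B_i) / sqrt(Σ A_i² · Σ B_i²)

computed over pixels supra-threshold in either channel, with sub-threshold
values zeroed. R is bounded in [0, 1] (Cauchy–Schwarz), symmetric, and
invariant under positive rescaling of either channel. A set-overlap
alternative |A∩B| / |A∪B| on the thresholded supports is available via
``method="area"``. Channel thresholds default to Otsu per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import MeasurementError, UsageError


@dataclass
class ColocResult:
    """Channel areas (µm²), the Aβ40/Aβ42 area ratio (%), overlap coefficient."""

    area_ab40_um2: float
    area_ab42_um2: float
    ratio_40_42_percent: float
    overlap_coefficient: float
    threshold_ab40: float
    threshold_ab42: float


def channel_area(channel: np.ndarray, threshold: float, pixel_size_um: float) -> float:
    """Supra-threshold area in µm² (pixels with value ≥ threshold)."""
    if threshold < 0:
        raise UsageError("threshold must be >= 0")
    return float(np.count_nonzero(np.asarray(channel) >= threshold)) * pixel_size_um**2


def area_ratio_40_42(area40: float, area42: float) -> float:
    """100 × area(Aβ40) / area(Aβ42); undefined for zero Aβ42 area."""
    if area42 <= 0:
        raise MeasurementError("Aβ40/Aβ42 ratio undefined: Aβ42 area is zero")
    return 100.0 * area40 / area42


def overlap_coefficient(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
    method: str = "manders",
) -> float:
    """Two-color overlap coefficient of two equally shaped channels.

    Thresholds default to Otsu per channel; sub-threshold pixels are zeroed
    and the statistic runs over pixels supra-threshold in either channel.
    """
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    if a.shape != b.shape:
        raise UsageError("channels must have the same shape")
    if method not in ("manders", "area"):
        raise UsageError(f"unknown overlap method {method!r}")
    if threshold_a is None:
        threshold_a = float(threshold_otsu(a))
    if threshold_b is None:
        threshold_b = float(threshold_otsu(b))
    sup_a = a >= threshold_a
    sup_b = b >= threshold_b
    if not sup_a.any() or not sup_b.any():
        raise MeasurementError("overlap undefined: a channel has no supra-threshold pixels")
    if method == "area":
        return float(np.count_nonzero(sup_a & sup_b) / np.count_nonzero(sup_a | sup_b))
    either = sup_a | sup_b
    av = np.where(sup_a, a, 0.0)[either]
    bv = np.where(sup_b, b, 0.0)[either]
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        raise MeasurementError("overlap undefined: zero channel energy")
    return float((av * bv).sum() / denom)


def measure_colocalization(
    ch_ab40: np.ndarray,
    ch_ab42: np.ndarray,
    pixel_size_um: float,
    threshold_ab40: float | None = None,
    threshold_ab42: float | None = None,
    method: str = "manders",
) -> ColocResult:
    """Areas, area ratio and overlap coefficient for one two-channel field."""
    a = np.asarray(ch_ab40, dtype=float)
    b = np.asarray(ch_ab42, dtype=float)
    if threshold_ab40 is None:
        threshold_ab40 = float(threshold_otsu(a))
    if threshold_ab42 is None:
        threshold_ab42 = float(threshold_otsu(b))
    area40 = channel_area(a, threshold_ab40, pixel_size_um)
    area42 = channel_area(b, threshold_ab42, pixel_size_um)
    return ColocResult(
        area_ab40_um2=area40,
        area_ab42_um2=area42,
        ratio_40_42_percent=area_ratio_40_42(area40, area42),
        overlap_coefficient=overlap_coefficient(
            a, b, threshold_ab40, threshold_ab42, method
        ),
        threshold_ab40=threshold_ab40,
        threshold_ab42=threshold_ab42,
    )


def ths_to_ihc_ratio(ths_area_per_mm2: float, ihc_area_per_mm2: float) -> float:
    """Fibrillar fraction: 100 × ThS-positive area / immunostained area.

    Computed at the region-per-animal level (consecutive sections of the same
    region); undefined when the immunostained area is zero.
    """
    if ihc_area_per_mm2 <= 0:
        raise MeasurementError("ThS/IHC ratio undefined: zero immunostained area")
    return 100.0 * ths_area_per_mm2 / ihc_area_per_mm2
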