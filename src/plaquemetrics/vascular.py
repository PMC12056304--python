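"""Plaque–vessel spatial statistics.

Distances are edge-to-edge at pixel-center precision: the nearest-vessel
distance of a plaque is the minimum, over its pixels, of the Euclidean
distance transform of the vessel mask, scaled by the pixel size. A vessel
running through or in direct contact with a deposit (overlap or 8-adjacency,
i.e. minimum distance ≤ √2 px) is scored as a 0 µm distance with the contact
flag set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import MeasurementError, UsageError
from . import stats as _stats

#: Contact rule: overlap or 8-adjacency at raster precision.
CONTACT_RADIUS_PX = float(np.sqrt(2.0))


def nearest_vessel_distance(
    plaque_mask: np.ndarray, vessel_mask: np.ndarray, pixel_size_um: float
) -> tuple[float, bool]:
    """(distance µm, contact flag) for one plaque against the vessel mask.

    Raises when the vessel mask is empty (the distance is undefined; exclude
    the record downstream).
    """
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not plaque_mask.any():
        raise MeasurementError("empty plaque mask")
    if not vessel_mask.any():
        raise MeasurementError("empty vessel mask: nearest-vessel distance undefined")
    vdist = ndi.distance_transform_edt(~vessel_mask)
    dmin_px = float(vdist[plaque_mask].min())
    if dmin_px <= CONTACT_RADIUS_PX:
        return 0.0, True
    return dmin_px * pixel_size_um, False


def vessel_distances(
    plaque_masks: list[np.ndarray], vessel_mask: np.ndarray, pixel_size_um: float
) -> pd.DataFrame:
    """Batch form: one distance-transform pass shared across all plaques."""
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    recs = []
    vdist = (
        ndi.distance_transform_edt(~vessel_mask) if vessel_mask.any() else None
    )
    for i, pm in enumerate(plaque_masks, start=1):
        pm = np.asarray(pm, dtype=bool)
        if vdist is None:
            recs.append(dict(plaque_id=i, nearest_vessel_distance_um=np.nan, contact=False))
            continue
        dmin_px = float(vdist[pm].min())
        contact = dmin_px <= CONTACT_RADIUS_PX
        recs.append(
            dict(
                plaque_id=i,
                nearest_vessel_distance_um=0.0 if contact else dmin_px * pixel_size_um,
                contact=contact,
            )
        )
    return pd.DataFrame.from_records(
        recs, columns=["plaque_id", "nearest_vessel_distance_um", "contact"]
    )


def association_frequency(records: pd.DataFrame) -> float:
    """Percentage of plaques in contact with (or containing) a vessel."""
    if len(records) == 0:
        raise MeasurementError("association frequency undefined for no records")
    return 100.0 * float(records["contact"].sum()) / len(records)


def mean_noncontact_distance(records: pd.DataFrame) -> float:
    """Mean nearest-vessel distance over non-contact plaques only (µm)."""
    non = records.loc[~records["contact"], "nearest_vessel_distance_um"].dropna()
    if len(non) == 0:
        raise MeasurementError(
            "all plaques are vessel-contacting; non-contact mean distance undefined"
        )
    return float(non.mean())


def diameter_distance_correlation(
    records: pd.DataFrame, include_contacts: bool = True
) -> tuple[float, int, float]:
    """Pearson correlation of plaque diameter against nearest-vessel distance.

    Pooled at the plaque level; `include_contacts=False` drops 0-distance
    (contact) plaques first. Returns (r, n, two-sided p).
    """
    required = {"max_diameter_um", "nearest_vessel_distance_um", "contact"}
    if len(records) < 4 or not required.issubset(records.columns):
        raise UsageError("need at least 4 records with diameter/distance/contact fields")
    sub = records if include_contacts else records.loc[~records["contact"]]
    sub = sub.dropna(subset=["max_diameter_um", "nearest_vessel_distance_um"])
    if len(sub) < 4:
        raise UsageError("need at least 4 records for a correlation")
    r, p = _stats.pearson(
        sub["max_diameter_um"].to_numpy(), sub["nearest_vessel_distance_um"].to_numpy()
    )
    return r, len(sub), p


def brute_force_min_distance(
    plaque_mask: np.ndarray, vessel_mask: np.ndarray, pixel_size_um: float
) -> float:
    """O(|P|·|V|) oracle: minimum pairwise pixel-center distance, in µm."""
    pr, pc = np.nonzero(np.asarray(plaque_mask, dtype=bool))
    vr, vc = np.nonzero(np.asarray(vessel_mask, dtype=bool))
    if pr.size == 0 or vr.size == 0:
        raise MeasurementError("brute-force distance needs non-empty masks")
    d2 = (pr[:, None] - vr[None, :]) ** 2 + (pc[:, None] - vc[None, :]) ** 2
    return float(np.sqrt(d2.min())) * pixel_size_um
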