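"""Per-plaque morphometry: area, maximum diameter, IOD, fractal dimension.

Definitions follow standard histomorphometric practice:

* area — foreground pixel count × pixel area (µm²);
* maximum diameter — the maximum Feret diameter, i.e. the largest pairwise
  Euclidean distance between foreground pixel centers (µm);
* IOD (integrated optical density) — ROI area × mean stain intensity, which
  equals the sum of per-pixel OD × pixel area exactly; the intensity used is
  the deconvolved DAB optical density (stain-linear), with a raw-inverted-gray
  variant available via the ``intensity`` argument;
* FD — box-counting fractal dimension: the OLS slope of log N(s) against
  log(1/s) over dyadic box sizes on a grid anchored at the mask's bounding
  box, N(s) counting boxes holding at least one foreground pixel. Expected
  in [1, 2] for planar deposit masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MeasurementError
from .io import RegionLabelMap


@dataclass
class PlaqueROI:
    """One segmented deposit and its measurements."""

    id: int
    mask: np.ndarray  # full-frame boolean mask
    centroid: tuple[float, float]
    region: str
    area_um2: float
    max_diameter_um: float
    iod: float
    fd: float  # NaN when the ROI is too small for a box-count


def max_feret_diameter(mask: np.ndarray, pixel_size_um: float) -> float:
    """Maximum pairwise distance between foreground pixel centers, in µm.

    Computed on the convex hull for non-degenerate masks (the diameter of a
    point set is attained at hull vertices); single-pixel masks measure 0.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise MeasurementError("max_feret_diameter of an empty mask is undefined")
    if rows.size == 1:
        return 0.0
    pts = np.column_stack([rows, cols]).astype(float)
    if len(pts) > 8:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear point sets have no 2D hull
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max()) * pixel_size_um


def integrated_optical_density(
    mask: np.ndarray, intensity: np.ndarray, pixel_size_um: float
) -> float:
    """IOD = area (µm²) × mean intensity over the ROI.

    Identical to the sum form Σ intensity × pixel area; `intensity` is
    normally the deconvolved DAB OD raster.
    """
    npx = int(np.count_nonzero(mask))
    if npx == 0:
        raise MeasurementError("IOD of an empty mask is undefined")
    area = npx * pixel_size_um**2
    return float(area * np.asarray(intensity)[mask].mean())


def box_counting_fd(mask: np.ndarray, min_sizes: int = 3) -> float:
    """Box-counting fractal dimension of a binary mask.

    The mask's bounding box is padded to the next power of two; box sizes run
    s = 2, 4, …, side/2 (grid anchored at the bounding-box origin, single
    offset). Requires at least ``min_sizes`` usable box sizes — tiny ROIs
    (padded side < 2**(min_sizes+1)) raise and should simply be skipped.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise MeasurementError("box_counting_fd of an empty mask is undefined")
    crop = mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    side = 2 ** int(np.ceil(np.log2(max(crop.shape))))
    sizes = [2**k for k in range(1, int(np.log2(side)))]  # 2 .. side/2
    if len(sizes) < min_sizes:
        raise MeasurementError(
            f"ROI too small for a box count ({len(sizes)} usable box sizes, "
            f"need {min_sizes}); skip FD for this ROI"
        )
    padded = np.zeros((side, side), dtype=bool)
    padded[: crop.shape[0], : crop.shape[1]] = crop
    counts = []
    for s in sizes:
        blocks = padded.reshape(side // s, s, side // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)
    return float(np.round(slope, 12))  # suppress sub-1e-12 log-arithmetic slop


def measure_plaques(
    roi_masks: list[np.ndarray],
    dab_od: np.ndarray,
    pixel_size_um: float,
    region_map: RegionLabelMap | None = None,
) -> list[PlaqueROI]:
    """Measure each ROI mask; FD is NaN for ROIs too small to box-count.

    ROIs are assigned to the region holding the majority of their pixels;
    all-background ROIs are excluded.
    """
    rois = []
    for i, mask in enumerate(roi_masks, start=1):
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            continue
        region = "cortex"
        if region_map is not None:
            labs = region_map.labels[rows, cols]
            counts = np.bincount(labs)
            lab = int(counts.argmax())
            if lab == 0:
                nz = counts.copy()
                nz[0] = 0
                if nz.sum() == 0:
                    continue  # entirely on background: excluded
                lab = int(nz.argmax())
            region = region_map.names[lab]
        try:
            fd = box_counting_fd(mask)
        except MeasurementError:
            fd = float("nan")
        rois.append(
            PlaqueROI(
                id=i,
                mask=mask,
                centroid=(float(rows.mean()), float(cols.mean())),
                region=region,
                area_um2=float(rows.size) * pixel_size_um**2,
                max_diameter_um=max_feret_diameter(mask, pixel_size_um),
                iod=integrated_optical_density(mask, dab_od, pixel_size_um),
                fd=fd,
            )
        )
    return rois


def rois_to_table(rois: list[PlaqueROI]) -> pd.DataFrame:
    cols = ["id", "region", "centroid_row", "centroid_col", "area_um2",
            "max_diameter_um", "iod", "fd"]
    recs = [
        dict(
            id=r.id,
            region=r.region,
            centroid_row=r.centroid[0],
            centroid_col=r.centroid[1],
            area_um2=r.area_um2,
            max_diameter_um=r.max_diameter_um,
            iod=r.iod,
            fd=r.fd,
        )
        for r in rois
    ]
    return pd.DataFrame.from_records(recs, columns=cols)


def region_densities(
    rois: list[PlaqueROI], region_map: RegionLabelMap
) -> pd.DataFrame:
    """Per-region burden table.

    Densities are normalized by the *region* area: total plaque area in
    µm²/mm², plaque count /mm², plus total (cumulated) IOD, mean per-plaque
    IOD, mean diameter and mean FD (NaN-FD ROIs excluded from the FD mean).
    """
    rows = []
    table = rois_to_table(rois)
    for lab, name in sorted(region_map.names.items()):
        area_mm2 = region_map.region_area_mm2(lab)
        if area_mm2 <= 0:
            continue
        sub = table[table["region"] == name]
        rows.append(
            dict(
                region=name,
                region_area_mm2=area_mm2,
                n_plaques=len(sub),
                plaque_area_um2_per_mm2=sub["area_um2"].sum() / area_mm2,
                plaque_count_per_mm2=len(sub) / area_mm2,
                total_iod=sub["iod"].sum(),
                mean_iod=sub["iod"].mean() if len(sub) else 0.0,
                mean_diameter_um=sub["max_diameter_um"].mean() if len(sub) else 0.0,
                mean_fd=float(sub["fd"].dropna().mean()) if sub["fd"].notna().any() else float("nan"),
            )
        )
    return pd.DataFrame(rows)
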