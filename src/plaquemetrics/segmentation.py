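"""Stain separation and mask extraction.

The brightfield double stain is unmixed by Beer–Lambert optical-density
projection: per-pixel OD ``= -log10((I + 1) / white_level)`` per RGB channel,
solved against the 3×3 stain matrix (hematoxylin, DAB, Fast Red) and clipped
at zero. Plaques, vessels and ThS-positive deposits are then fixed-threshold
segmentations of the relevant density/intensity map — the same threshold
pattern applied to every image, which is what makes the measurements
comparable across animals and groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .errors import ConfigError, DataError
from .io import ImagePlane
from .synthetic import StainProfile, default_stain_profile

#: 8-connectivity structuring element for component labelling.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class StainMaps:
    """Per-stain optical-density rasters (same shape as the source image)."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    fast_red: np.ndarray


@dataclass
class SegmentationParams:
    """The fixed threshold pattern applied to all images.

    Defaults (DAB OD 0.15, Fast Red OD 0.20, ThS intensity 60, minimum plaque
    area 20 µm², closing radius 1 px) are configuration, not constants of
    nature — expose and record them with every run.
    """

    dab_od_threshold: float = 0.15
    red_od_threshold: float = 0.20
    ths_intensity_threshold: int = 60
    min_plaque_area_um2: float = 20.0
    closing_radius_px: int = 1

    def validate(self) -> None:
        if self.dab_od_threshold <= 0 or self.red_od_threshold <= 0:
            raise ConfigError("OD thresholds must be positive")
        if self.min_plaque_area_um2 <= 0:
            raise ConfigError("min_plaque_area_um2 must be positive")
        if self.closing_radius_px < 0:
            raise ConfigError("closing_radius_px must be non-negative")


def separate_stains(image: ImagePlane, profile: StainProfile | None = None) -> StainMaps:
    """Unmix an RGB brightfield image into per-stain OD maps.

    16-bit renders are assumed to sit on a 256×finer transmitted-light scale
    than 8-bit ones (see the synthetic renderer); negative projected densities
    are clipped to zero.
    """
    profile = profile or default_stain_profile()
    if image.n_channels != 3:
        raise DataError("stain separation needs a 3-channel RGB image")
    m = profile.matrix
    if abs(np.linalg.det(m)) < 1e-6:
        raise ConfigError("singular stain matrix; vectors are not independent")
    white = profile.white_level
    if image.data.dtype == np.uint16:
        white = white * 256.0
    od = -np.log10((image.data.astype(float) + 1.0) / white)
    od = np.maximum(od, 0.0)
    dens = od @ np.linalg.inv(m)
    dens = np.maximum(dens, 0.0)
    return StainMaps(
        hematoxylin=dens[..., 0], dab=dens[..., 1], fast_red=dens[..., 2]
    )


def _components(mask: np.ndarray, min_area_px: float) -> list[np.ndarray]:
    """8-connected components at or above a minimum pixel area, as bool masks."""
    labels, n = ndi.label(mask, structure=_STRUCT8)
    out = []
    for sl, idx in zip(ndi.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == idx
        if comp.sum() >= min_area_px:
            full = np.zeros_like(mask)
            full[sl] = comp
            out.append(full)
    return out


def segment_plaques(
    dab_od: np.ndarray, params: SegmentationParams, pixel_size_um: float
) -> list[np.ndarray]:
    """Threshold the DAB OD map into per-plaque ROI masks.

    Morphological closing merges a dense core with its corona, holes are
    filled so pale plaque centers measure as part of the deposit, and
    components under the minimum area are discarded.
    """
    params.validate()
    mask = dab_od >= params.dab_od_threshold
    if params.closing_radius_px > 0:
        mask = morphology.closing(mask, morphology.disk(params.closing_radius_px))
    mask = ndi.binary_fill_holes(mask)
    min_area_px = params.min_plaque_area_um2 / pixel_size_um**2
    return _components(mask, min_area_px)


def segment_vessels(fast_red_od: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Threshold the Fast Red OD map into a single vessel mask."""
    params.validate()
    return fast_red_od >= params.red_od_threshold


def segment_ths(
    green: np.ndarray, params: SegmentationParams, pixel_size_um: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Threshold a ThS intensity frame; same component logic as plaques."""
    params.validate()
    mask = np.asarray(green) >= params.ths_intensity_threshold
    min_area_px = params.min_plaque_area_um2 / pixel_size_um**2
    return mask, _components(mask, min_area_px)
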