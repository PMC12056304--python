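"""Ground-truthed synthetic histology.

This module fabricates the kinds of images the quantification pipeline is
built for — sagittal-section brightfield double stains (DAB on amyloid
plaques, Fast Red on vessel endothelium, hematoxylin counterstain), two-channel
Aβ40/Aβ42 immunofluorescence, and single-channel thioflavin-S frames — together
with a per-object ground-truth table, so every downstream measurement can be
validated against known geometry.

Brightfield rendering uses Beer–Lambert optical-density mixing: the per-pixel
stain densities are projected through unit optical-density colour vectors and
converted to transmitted light, ``T_c = white * 10**(-sum_s D_s * V_s[c])``.
Stored 8-bit codes follow the convention ``code = round(T) - 1`` on a
``white_level = 256`` scale, so the downstream conversion
``OD = -log10((code + 1) / white_level)`` is unbiased to half a count.

Plaque archetypes:

* ``diffuse`` — irregular blob with a soft radial density profile;
* ``dense`` — steeper, near-plateau radial profile;
* ``dense_core`` — compact high-density core (default 0.3 × plaque radius)
  surrounded by a pale corona.

A configurable fraction of dense/dense-core plaques carries a fibrillar
(thioflavin-S-positive) core subregion. Vessels are smoothed random-walk
centerlines dilated to a physical radius. The Aβ40 channel support is
constructed per plaque so that the noiseless Manders overlap coefficient with
the Aβ42 channel equals the requested level exactly (see
:func:`build_ab40_mask`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb_from_hed, rgb_from_rbd

from .errors import DataError, UsageError
from .io import ImagePlane, RegionLabelMap

PLAQUE_TYPES = ("diffuse", "dense", "dense_core")

#: Density (OD units) every plaque pixel carries at minimum; safely above the
#: default DAB segmentation threshold of 0.15 even under 8-bit quantization.
_BASE_PLAQUE_DENSITY = 0.35
#: Dense-core core radius as a fraction of the plaque radius.
CORE_RADIUS_FRACTION = 0.3
#: Fibrillar (ThS-positive) core radius as a fraction of the plaque radius.
THS_CORE_FRACTION = 0.45


# --------------------------------------------------------------------------
# stain profile
# --------------------------------------------------------------------------


@dataclass
class StainProfile:
    """Unit optical-density colour vectors for the brightfield stains.

    The defaults are the published Ruifrok–Johnston vectors for hematoxylin
    and DAB and the published Fast Red vector; all three are overridable.
    ``white_level`` is the transmitted-light full scale (256 for 8-bit codes
    under the ``code = T - 1`` convention).
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    fast_red: np.ndarray
    white_level: float = 256.0

    def __post_init__(self) -> None:
        for name in ("hematoxylin", "dab", "fast_red"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise DataError(f"stain vector {name} must be a 3-vector")
            if (v < 0).any():
                raise DataError(f"stain vector {name} must be non-negative")
            n = np.linalg.norm(v)
            if abs(n - 1.0) > 1e-6:
                raise DataError(f"stain vector {name} must have unit norm (got {n:.6f})")
            setattr(self, name, v)
        if not self.white_level > 0:
            raise DataError("white_level must be positive")
        if abs(np.linalg.det(self.matrix)) < 1e-6:
            raise DataError("stain vectors are linearly dependent; cannot unmix")

    @property
    def matrix(self) -> np.ndarray:
        """3×3 matrix, rows = (hematoxylin, dab, fast_red) OD vectors."""
        return np.stack([self.hematoxylin, self.dab, self.fast_red])


def default_stain_profile() -> StainProfile:
    """Hematoxylin + DAB + Fast Red profile from the standard published vectors."""

    def unit(v):
        v = np.asarray(v, dtype=float)
        return v / np.linalg.norm(v)

    return StainProfile(
        hematoxylin=unit(rgb_from_hed[0]),
        dab=unit(rgb_from_rbd[2]),
        fast_red=unit(rgb_from_rbd[0]),
    )


# --------------------------------------------------------------------------
# scene specification
# --------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Parameters of one synthetic tissue field.

    Defaults emulate a ~1 mm² cortical field of a plaque-bearing transgenic
    mouse: plaque diameters spanning the 14–36 µm range around the ~20–25 µm
    regional means reported for such models, three vessels per mm², and a
    constructed Aβ40/Aβ42 overlap of 0.6 (the upper end of the 0.43–0.62
    range typical of untreated animals).
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.0
    n_plaques: int = 25
    plaque_type_mix: dict = field(
        default_factory=lambda: {"diffuse": 0.40, "dense": 0.35, "dense_core": 0.25}
    )
    diameter_range_um: tuple[float, float] = (14.0, 36.0)
    vessel_count: int = 3
    vessel_radius_um: float = 5.0
    fibrillar_core_fraction: float = 0.5
    ab40_ab42_overlap: float = 0.6
    ab40_area_fraction: float = 1.0
    vessel_contact_fraction: float = 0.25
    diameter_distance_rho: float = -0.2
    noise_sd: float = 2.0
    seed: int = 0
    region_layout: str = "single"  # "single" (all cortex) or "quadrants"

    def validate(self) -> None:
        h, w = self.field_size_px
        if h <= 0 or w <= 0:
            raise DataError("field_size_px must be positive")
        if not self.pixel_size_um > 0:
            raise DataError("pixel_size_um must be > 0")
        if self.n_plaques < 0 or self.vessel_count < 0:
            raise DataError("counts must be non-negative")
        mix = self.plaque_type_mix
        if set(mix) - set(PLAQUE_TYPES):
            raise DataError(f"unknown plaque types {set(mix) - set(PLAQUE_TYPES)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise DataError("plaque_type_mix proportions must sum to 1")
        lo, hi = self.diameter_range_um
        if not (0 < lo <= hi):
            raise DataError("diameter_range_um must be a non-empty positive interval")
        max_d_px = hi / self.pixel_size_um
        if 1.6 * max_d_px + 4 > min(h, w):
            raise DataError(
                f"field too small: max diameter {hi} µm needs "
                f">= {int(1.6 * max_d_px + 4)} px, field is {min(h, w)} px"
            )
        for name in (
            "fibrillar_core_fraction",
            "ab40_ab42_overlap",
            "vessel_contact_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.ab40_area_fraction < self.ab40_ab42_overlap**2:
            raise DataError(
                "ab40_area_fraction must be >= ab40_ab42_overlap**2 "
                "for the overlap level to be constructible"
            )
        if self.noise_sd < 0:
            raise DataError("noise_sd must be non-negative")
        if self.region_layout not in ("single", "quadrants"):
            raise DataError(f"unknown region_layout {self.region_layout!r}")


@dataclass
class Scene:
    """Rasterized synthetic tissue: density maps, label masks, region map."""

    spec: SceneSpec
    plaque_labels: np.ndarray  # int32, 0 background, ids 1..n
    dab_density: np.ndarray
    hematoxylin_density: np.ndarray
    fastred_density: np.ndarray
    vessel_mask: np.ndarray
    fibrillar_core_mask: np.ndarray
    region_map: RegionLabelMap
    ab40_mask: np.ndarray | None = None  # built lazily (see get_ab40_mask)


@dataclass
class GroundTruth:
    """Per-plaque truth table plus scene-level channel truth."""

    plaques: pd.DataFrame
    ab40_ab42_area_ratio_percent: float
    overlap_level: float


GT_COLUMNS = [
    "id",
    "type",
    "centroid_row",
    "centroid_col",
    "area_um2",
    "max_diameter_um",
    "has_fibrillar_core",
    "nearest_vessel_distance_um",
    "contact",
    "region",
]

_REGION_NAMES = {1: "cortex", 2: "hippocampus", 3: "striatum", 4: "thalamus"}


def _make_region_map(spec: SceneSpec) -> RegionLabelMap:
    h, w = spec.field_size_px
    labels = np.ones((h, w), dtype=np.int32)
    if spec.region_layout == "quadrants":
        labels[: h // 2, w // 2 :] = 2
        labels[h // 2 :, : w // 2] = 3
        labels[h // 2 :, w // 2 :] = 4
        names = dict(_REGION_NAMES)
    else:
        names = {1: "cortex"}
    return RegionLabelMap(labels=labels, names=names, pixel_size_um=spec.pixel_size_um)


def _draw_vessels(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random-walk centerlines dilated to the vessel radius."""
    h, w = spec.field_size_px
    center = np.zeros((h, w), dtype=bool)
    for _ in range(spec.vessel_count):
        edge = rng.integers(0, 4)
        if edge == 0:
            r, c, heading = 0.0, rng.uniform(0, w - 1), np.pi / 2
        elif edge == 1:
            r, c, heading = h - 1.0, rng.uniform(0, w - 1), -np.pi / 2
        elif edge == 2:
            r, c, heading = rng.uniform(0, h - 1), 0.0, 0.0
        else:
            r, c, heading = rng.uniform(0, h - 1), w - 1.0, np.pi
        for _ in range(2 * (h + w)):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w):
                break
            center[ri, ci] = True
            heading += rng.normal(0.0, 0.12)
            r += 1.5 * np.sin(heading)
            c += 1.5 * np.cos(heading)
    if not center.any():
        return center
    radius_px = spec.vessel_radius_um / spec.pixel_size_um
    return ndi.distance_transform_edt(~center) <= radius_px


def _plaque_boundary_radius(
    r_px: float, theta: np.ndarray, ptype: str, rng: np.random.Generator
) -> np.ndarray:
    """Angularly modulated boundary radius; diffuse plaques are most irregular."""
    amp = {"diffuse": 0.14, "dense": 0.07, "dense_core": 0.05}[ptype]
    rb = np.full_like(theta, r_px)
    for k in range(2, 6):
        a = rng.uniform(0.3, 1.0) * amp / (k - 1)
        phi = rng.uniform(0, 2 * np.pi)
        rb = rb + r_px * a * np.cos(k * theta + phi)
    return np.clip(rb, 0.4 * r_px, 1.3 * r_px)


def _radial_density(rho: np.ndarray, rb: np.ndarray, ptype: str) -> np.ndarray:
    """DAB density profile inside the plaque support (OD units)."""
    rel = np.divide(rho, np.maximum(rb, 1e-9))
    if ptype == "diffuse":
        extra = 0.25 * np.exp(-((rel / 0.6) ** 2))
    elif ptype == "dense":
        extra = 0.55 * np.exp(-((rel / 0.8) ** 4))
    else:  # dense_core: compact core plus pale corona
        extra = 0.15 + 0.65 * (rel <= CORE_RADIUS_FRACTION)
    return _BASE_PLAQUE_DENSITY + extra


def generate_scene(spec: SceneSpec) -> tuple[Scene, GroundTruth]:
    """Generate one ground-truthed scene; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    px = spec.pixel_size_um

    region_map = _make_region_map(spec)
    vessel_mask = _draw_vessels(spec, rng)
    have_vessels = bool(vessel_mask.any())
    # distance (px) from every pixel to the nearest vessel pixel
    vdist = (
        ndi.distance_transform_edt(~vessel_mask)
        if have_vessels
        else np.full((h, w), np.inf)
    )

    n = spec.n_plaques
    types = list(spec.plaque_type_mix)
    probs = np.array([spec.plaque_type_mix[t] for t in types])
    ptypes = rng.choice(types, size=n, p=probs) if n else np.array([], dtype=object)
    diameters = rng.uniform(*spec.diameter_range_um, size=n)
    want_contact = rng.random(n) < spec.vessel_contact_fraction if have_vessels else np.zeros(n, bool)

    # diameter-coupled target boundary distances (Gaussian copula, negative rho)
    rho = spec.diameter_distance_rho
    if n:
        z_d = (diameters - diameters.mean()) / (diameters.std() or 1.0)
        z = rho * z_d + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
        target_um = np.clip(60.0 + 25.0 * z, 8.0, None)
    else:
        target_um = np.zeros(0)

    order = np.argsort(-diameters)  # place large plaques first
    labels = np.zeros((h, w), dtype=np.int32)
    dab = np.zeros((h, w))
    fib_mask = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []  # row, col, radius_px
    records: list[dict] = []

    # fibrillar cores go to the stated fraction of dense/dense_core plaques
    fib_candidates = [i for i in range(n) if ptypes[i] in ("dense", "dense_core")]
    n_fib = int(round(spec.fibrillar_core_fraction * len(fib_candidates)))
    fib_ids = set(
        rng.choice(fib_candidates, size=n_fib, replace=False) if n_fib else []
    )

    yy_all, xx_all = np.mgrid[0:h, 0:w]
    for idx in order:
        r_px = diameters[idx] / 2.0 / px
        margin = int(np.ceil(1.3 * r_px)) + 2
        valid = np.zeros((h, w), dtype=bool)
        valid[margin : h - margin, margin : w - margin] = True

        if want_contact[idx]:
            cand = valid & (vdist <= 0.8 * r_px)
        elif have_vessels:
            t_px = target_um[idx] / px
            tol = 2.0
            cand = np.zeros_like(valid)
            while not cand.any() and tol < max(h, w):
                lo, hi_ = 1.3 * r_px + t_px - tol, 1.3 * r_px + t_px + tol
                cand = valid & (vdist >= max(lo, 1.3 * r_px + 3)) & (vdist <= hi_)
                tol *= 2.0
            if not cand.any():
                cand = valid & (vdist >= 1.3 * r_px + 3)
        else:
            cand = valid
        if not cand.any():
            cand = valid
        rows, cols = np.nonzero(cand)
        if rows.size == 0:
            raise DataError("field too small to place requested plaques")
        ok = None
        for _ in range(400):
            j = rng.integers(rows.size)
            cr, cc = float(rows[j]), float(cols[j])
            if all(
                np.hypot(cr - pr, cc - pc) > 1.3 * (r_px + prad) + 5 for pr, pc, prad in placed
            ):
                ok = (cr, cc)
                break
        if ok is None:
            # exhaustive fallback: scan the candidate band, then (dropping the
            # distance/contact target) every valid center, before giving up
            for pool in (cand, valid):
                prow, pcol = np.nonzero(pool)
                free = np.ones(prow.size, dtype=bool)
                for pr, pc, prad in placed:
                    free &= np.hypot(prow - pr, pcol - pc) > 1.3 * (r_px + prad) + 5
                if free.any():
                    fr, fc = prow[free], pcol[free]
                    j = rng.integers(fr.size)
                    ok = (float(fr[j]), float(fc[j]))
                    break
            if ok is None:
                raise DataError(
                    "field too small: could not place plaque without overlap "
                    f"(placed {len(placed)} of {n})"
                )
        cr, cc = ok
        placed.append((cr, cc, r_px))

        # rasterize on a local window (boundary radius is clipped to 1.3·r)
        half = margin
        r0, r1 = int(cr) - half, int(cr) + half + 1
        c0, c1 = int(cc) - half, int(cc) + half + 1
        yy = yy_all[r0:r1, c0:c1] - cr
        xx = xx_all[r0:r1, c0:c1] - cc
        rho_px = np.hypot(yy, xx)
        theta = np.arctan2(yy, xx)
        rb = _plaque_boundary_radius(r_px, theta, ptypes[idx], rng)
        support = rho_px <= rb
        labels[r0:r1, c0:c1][support] = idx + 1
        dens = _radial_density(rho_px, rb, ptypes[idx])
        dab[r0:r1, c0:c1][support] = np.maximum(
            dab[r0:r1, c0:c1][support], dens[support]
        )
        if idx in fib_ids:
            fib_mask[r0:r1, c0:c1] |= support & (rho_px <= THS_CORE_FRACTION * rb)

        # ground truth from the realized geometry
        sup_rows, sup_cols = np.nonzero(support)
        g_rows, g_cols = sup_rows + r0, sup_cols + c0
        area_um2 = sup_rows.size * px**2
        dmax_um = _mask_max_diameter_px(sup_rows, sup_cols) * px
        if have_vessels:
            dmin_px = float(vdist[g_rows, g_cols].min())
            contact = dmin_px <= np.sqrt(2.0)
            dist_um = 0.0 if contact else dmin_px * px
        else:
            contact, dist_um = False, np.nan
        reg_labels = region_map.labels[g_rows, g_cols]
        reg = int(np.bincount(reg_labels).argmax())
        records.append(
            dict(
                id=idx + 1,
                type=str(ptypes[idx]),
                centroid_row=float(g_rows.mean()),
                centroid_col=float(g_cols.mean()),
                area_um2=float(area_um2),
                max_diameter_um=float(dmax_um),
                has_fibrillar_core=bool(idx in fib_ids),
                nearest_vessel_distance_um=float(dist_um),
                contact=bool(contact),
                region=region_map.names.get(reg, "background"),
            )
        )

    records.sort(key=lambda r: r["id"])
    gt_df = pd.DataFrame.from_records(records, columns=GT_COLUMNS)

    # hematoxylin: smooth tissue background
    hema = 0.2 + 0.05 * ndi.gaussian_filter(rng.normal(size=(h, w)), 12.0)
    hema = np.clip(hema, 0.0, None)
    fastred = np.where(vessel_mask, 0.9, 0.0)

    scene = Scene(
        spec=spec,
        plaque_labels=labels,
        dab_density=dab,
        hematoxylin_density=hema,
        fastred_density=fastred,
        vessel_mask=vessel_mask,
        fibrillar_core_mask=fib_mask,
        region_map=region_map,
    )
    gt = GroundTruth(
        plaques=gt_df,
        ab40_ab42_area_ratio_percent=100.0 * spec.ab40_area_fraction,
        overlap_level=spec.ab40_ab42_overlap,
    )
    return scene, gt


def _mask_max_diameter_px(rows: np.ndarray, cols: np.ndarray) -> float:
    """Max pairwise pixel-center distance via the convex hull (brute on tiny sets)."""
    pts = np.column_stack([rows, cols]).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 8:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear / degenerate point sets
            pass
    d = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).max())


# --------------------------------------------------------------------------
# Aβ40 support construction
# --------------------------------------------------------------------------


def get_ab40_mask(scene: Scene) -> np.ndarray:
    """The scene's Aβ40 support at its configured overlap level (cached)."""
    if scene.ab40_mask is None:
        scene.ab40_mask = build_ab40_mask(
            scene, scene.spec.ab40_ab42_overlap, scene.spec.ab40_area_fraction
        )
    return scene.ab40_mask


def build_ab40_mask(scene: Scene, overlap: float, area_fraction: float = 1.0) -> np.ndarray:
    """Construct the Aβ40 support so the noiseless overlap coefficient is exact.

    With equal-intensity binary channels the Manders overlap coefficient is
    ``|A∩B| / sqrt(|A|·|B|)``. Per plaque we give Aβ40 a support of
    ``q·m`` pixels (``m`` = plaque pixels, ``q`` = area_fraction): the
    ``rho·sqrt(q)·m`` pixels closest to the centroid sit inside the plaque
    (Aβ40 is core-tropic) and the remainder form a halo just outside it, so
    the scene-level coefficient equals ``overlap`` up to rounding.
    """
    if not 0.0 <= overlap <= 1.0:
        raise UsageError("overlap must be in [0, 1]")
    if area_fraction < overlap**2:
        raise UsageError("area_fraction must be >= overlap**2")
    labels = scene.plaque_labels
    a_mask = np.zeros(labels.shape, dtype=bool)
    forbidden = labels > 0
    inside_frac = overlap * np.sqrt(area_fraction)
    for pid in np.unique(labels):
        if pid == 0:
            continue
        rows, cols = np.nonzero(labels == pid)
        m = rows.size
        n_total = int(round(area_fraction * m))
        n_inside = min(int(round(inside_frac * m)), n_total, m)
        n_outside = n_total - n_inside
        cr, cc = rows.mean(), cols.mean()
        rho = np.hypot(rows - cr, cols - cc)
        take = np.lexsort((cols, rows, rho))[:n_inside]
        a_mask[rows[take], cols[take]] = True
        if n_outside > 0:
            sel = _halo_pixels(labels == pid, forbidden | a_mask, n_outside)
            a_mask |= sel
    return a_mask


def _halo_pixels(support: np.ndarray, forbidden: np.ndarray, count: int) -> np.ndarray:
    """The `count` free pixels nearest (but outside) a plaque support."""
    dist = ndi.distance_transform_edt(~support)
    cand = (~support) & (~forbidden)
    rows, cols = np.nonzero(cand)
    if rows.size < count:
        raise DataError("not enough free pixels around plaque for Aβ40 halo")
    order = np.lexsort((cols, rows, dist[rows, cols]))[:count]
    out = np.zeros_like(support)
    out[rows[order], cols[order]] = True
    return out


# --------------------------------------------------------------------------
# renderers
# --------------------------------------------------------------------------


def render_brightfield(
    scene: Scene,
    profile: StainProfile | None = None,
    noise_sd: float | None = None,
    bit_depth: int = 8,
) -> ImagePlane:
    """Render the DAB + Fast Red + hematoxylin double stain as RGB.

    Transmitted intensity per channel is ``white · 10^(−Σ_s density_s ·
    vector_s[channel])`` with additive Gaussian noise (sd in 8-bit counts),
    stored as ``round(T) − 1`` and clipped to the code range. ``bit_depth``
    16 renders on a 256×finer scale for quantitative roundtrips.
    """
    profile = profile or default_stain_profile()
    noise_sd = scene.spec.noise_sd if noise_sd is None else noise_sd
    if bit_depth not in (8, 16):
        raise UsageError("bit_depth must be 8 or 16")
    scale = 1.0 if bit_depth == 8 else 256.0
    white = profile.white_level * scale
    dens = np.stack(
        [scene.hematoxylin_density, scene.dab_density, scene.fastred_density], axis=-1
    )
    od = dens @ profile.matrix
    t = white * 10.0 ** (-od)
    if noise_sd > 0:
        rng = np.random.default_rng([scene.spec.seed, 1])
        t = t + rng.normal(0.0, noise_sd * scale, size=t.shape)
    code_max = 2**bit_depth - 1
    codes = np.clip(np.round(t) - 1, 0, code_max)
    data = codes.astype(np.uint8 if bit_depth == 8 else np.uint16)
    return ImagePlane(
        data=data,
        pixel_size_um=scene.spec.pixel_size_um,
        modality="brightfield",
        channel_names=["R", "G", "B"],
    )


_FLUOR_FG = 180
_FLUOR_BG = 4


def render_fluorescence(
    scene: Scene, overlap: float | None = None, noise_sd: float | None = None
) -> ImagePlane:
    """Two-channel Aβ40/Aβ42 immunofluorescence render (uint8).

    Channel ``ab42`` covers every plaque; channel ``ab40`` uses the
    constructed support whose noiseless overlap coefficient with ``ab42``
    equals ``overlap`` (defaults to the scene's configured level).
    """
    spec = scene.spec
    noise_sd = spec.noise_sd if noise_sd is None else noise_sd
    if overlap is None or overlap == spec.ab40_ab42_overlap:
        a_mask = get_ab40_mask(scene)
    else:
        a_mask = build_ab40_mask(scene, overlap, spec.ab40_area_fraction)
    b_mask = scene.plaque_labels > 0
    chans = np.stack(
        [
            np.where(a_mask, _FLUOR_FG, _FLUOR_BG),
            np.where(b_mask, _FLUOR_FG, _FLUOR_BG),
        ],
        axis=-1,
    ).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 2])
        chans = chans + rng.normal(0.0, noise_sd, size=chans.shape)
    data = np.clip(np.round(chans), 0, 255).astype(np.uint8)
    return ImagePlane(
        data=data,
        pixel_size_um=spec.pixel_size_um,
        modality="fluorescence",
        channel_names=["ab40", "ab42"],
    )


def render_ths(scene: Scene, noise_sd: float | None = None) -> ImagePlane:
    """Single-channel thioflavin-S render: fibrillar cores bright on dark."""
    spec = scene.spec
    noise_sd = spec.noise_sd if noise_sd is None else noise_sd
    img = np.where(scene.fibrillar_core_mask, 200.0, 6.0)
    if noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 3])
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    data = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImagePlane(
        data=data,
        pixel_size_um=spec.pixel_size_um,
        modality="fluorescence",
        channel_names=["ths"],
    )


# --------------------------------------------------------------------------
# analytic fractal fixtures
# --------------------------------------------------------------------------


def generate_fractal_mask(kind: str, size_or_depth: int) -> np.ndarray:
    """Exact deterministic masks with known box-counting dimension.

    ``line`` (FD 1) and ``filled_square`` (FD 2) take a pixel size;
    ``sierpinski_triangle`` (FD log2 3 ≈ 1.585) and ``sierpinski_carpet``
    (FD log3 8 ≈ 1.893) take a recursion depth ≥ 4.
    """
    if kind == "line":
        return np.ones((1, int(size_or_depth)), dtype=bool)
    if kind == "filled_square":
        s = int(size_or_depth)
        return np.ones((s, s), dtype=bool)
    if kind == "sierpinski_triangle":
        d = int(size_or_depth)
        if d < 4:
            raise UsageError("fractal kinds need depth >= 4")
        n = 2**d
        i, j = np.ogrid[0:n, 0:n]
        return (i & j) == 0
    if kind == "sierpinski_carpet":
        d = int(size_or_depth)
        if d < 4:
            raise UsageError("fractal kinds need depth >= 4")
        n = 3**d
        idx = np.arange(n)
        mask = np.ones((n, n), dtype=bool)
        for k in range(d):
            digit = (idx // 3**k) % 3 == 1
            mask &= ~(digit[:, None] & digit[None, :])
        return mask
    raise UsageError(f"unknown fractal kind {kind!r}")


# --------------------------------------------------------------------------
# record-level simulation for the correlation machinery
# --------------------------------------------------------------------------


def simulate_plaque_vessel_records(
    n: int,
    rho: float,
    seed: int,
    diameter_mean: float = 24.0,
    diameter_sd: float = 5.0,
    distance_mean: float = 50.0,
    distance_sd: float = 15.0,
) -> pd.DataFrame:
    """Pooled plaque records with a known diameter–distance correlation.

    Draws a bivariate normal with correlation ``rho`` and maps it affinely to
    diameter/distance scales (affine maps preserve the Pearson correlation);
    the distance mean sits far enough from zero that truncation is negligible.
    """
    if not -1.0 <= rho <= 1.0:
        raise UsageError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
    return pd.DataFrame(
        {
            "plaque_id": np.arange(1, n + 1),
            "max_diameter_um": diameter_mean + diameter_sd * z1,
            "nearest_vessel_distance_um": np.clip(
                distance_mean + distance_sd * z2, 0.0, None
            ),
            "contact": np.zeros(n, dtype=bool),
        }
    )
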