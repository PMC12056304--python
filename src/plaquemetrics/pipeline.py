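"""End-to-end orchestration: simulate → segment → measure → vascular →
coloc → stats, as one reproducible, seed-deterministic run.

Each virtual animal contributes one synthetic tissue field. The treatment
arms differ in expected plaque load (``burden_multiplier`` × the base plaque
count, with a lognormal per-animal effect) and in the planted plaque–vessel
contact fraction. All measurements then flow through the same image pipeline
a real study would use: stain unmixing, fixed-threshold segmentation,
per-ROI morphometry, vessel distances, colocalization, and
animal-then-group statistics.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import colocalization as coloc
from . import morphometry, segmentation, stats, synthetic, vascular
from .config import RunConfig
from .errors import MeasurementError, PlaquemetricsError, UsageError
from .io import RunLog, write_image, write_table

#: metrics carried per animal × region; all are animal-region scalars, so the
#: group aggregation step averages them over animals (IOD is already the
#: per-animal-region cumulated total at this point).
REGION_METRICS = [
    "burden_um2_per_mm2",
    "count_per_mm2",
    "total_iod",
    "mean_iod",
    "mean_diameter_um",
    "mean_fd",
    "pct_vessel_associated",
    "mean_noncontact_distance_um",
    "ab40_ab42_ratio_percent",
    "overlap_coefficient",
    "ths_area_um2_per_mm2",
    "ths_count_per_mm2",
    "ths_ihc_percent",
]


def analyze_scene(
    scene: synthetic.Scene,
    params: segmentation.SegmentationParams,
    profile: synthetic.StainProfile | None = None,
    coloc_method: str = "manders",
) -> tuple[list[dict], pd.DataFrame]:
    """Run the full measurement pipeline on one rendered field.

    Returns per-region metric rows and the plaque-level record table
    (diameter, nearest-vessel distance, contact, region).
    """
    profile = profile or synthetic.default_stain_profile()
    px = scene.spec.pixel_size_um
    bf = synthetic.render_brightfield(scene, profile)
    maps = segmentation.separate_stains(bf, profile)
    roi_masks = segmentation.segment_plaques(maps.dab, params, px)
    vessel_mask = segmentation.segment_vessels(maps.fast_red, params)
    rois = morphometry.measure_plaques(roi_masks, maps.dab, px, scene.region_map)
    region_table = morphometry.region_densities(rois, scene.region_map)

    dist = vascular.vessel_distances([r.mask for r in rois], vessel_mask, px)
    roi_table = morphometry.rois_to_table(rois)
    plaques = roi_table.merge(dist, left_on="id", right_on="plaque_id", how="left")

    fluor = synthetic.render_fluorescence(scene)
    ths_img = synthetic.render_ths(scene)
    _, ths_rois = segmentation.segment_ths(ths_img.data, params, px)

    rows = []
    for _, reg in region_table.iterrows():
        name = reg["region"]
        area_mm2 = reg["region_area_mm2"]
        reg_mask = scene.region_map.labels == _label_of(scene.region_map, name)
        sub = plaques[plaques["region"] == name]
        row = dict(
            region=name,
            burden_um2_per_mm2=reg["plaque_area_um2_per_mm2"],
            count_per_mm2=reg["plaque_count_per_mm2"],
            total_iod=reg["total_iod"],
            mean_iod=reg["mean_iod"],
            mean_diameter_um=reg["mean_diameter_um"],
            mean_fd=reg["mean_fd"],
        )
        with_dist = sub.dropna(subset=["nearest_vessel_distance_um"])
        row["pct_vessel_associated"] = (
            vascular.association_frequency(with_dist) if len(with_dist) else np.nan
        )
        non = with_dist.loc[~with_dist["contact"], "nearest_vessel_distance_um"]
        row["mean_noncontact_distance_um"] = float(non.mean()) if len(non) else np.nan

        a = fluor.channel("ab40")[reg_mask].astype(float)
        b = fluor.channel("ab42")[reg_mask].astype(float)
        try:
            res = coloc.measure_colocalization(a, b, px, method=coloc_method)
            row["ab40_ab42_ratio_percent"] = res.ratio_40_42_percent
            row["overlap_coefficient"] = res.overlap_coefficient
        except (MeasurementError, ValueError):
            row["ab40_ab42_ratio_percent"] = np.nan
            row["overlap_coefficient"] = np.nan

        ths_in_region = [
            m for m in ths_rois if reg_mask[tuple(np.argwhere(m)[0])]
        ]
        ths_area = sum(int(m.sum()) for m in ths_in_region) * px**2
        row["ths_area_um2_per_mm2"] = ths_area / area_mm2
        row["ths_count_per_mm2"] = len(ths_in_region) / area_mm2
        try:
            row["ths_ihc_percent"] = coloc.ths_to_ihc_ratio(
                row["ths_area_um2_per_mm2"], row["burden_um2_per_mm2"]
            )
        except MeasurementError:
            row["ths_ihc_percent"] = np.nan
        rows.append(row)
    return rows, plaques


def _label_of(region_map, name: str) -> int:
    for lab, nm in region_map.names.items():
        if nm == name:
            return lab
    raise MeasurementError(f"no region named {name!r}")


def simulate_animal(
    config: RunConfig, group: str, animal_index: int
) -> tuple[synthetic.Scene, synthetic.GroundTruth]:
    """One virtual animal's tissue field under its group's parameters."""
    gcfg = config.groups[group]
    g_idx = sorted(config.groups).index(group)
    rng = np.random.default_rng([config.seed, g_idx, animal_index])
    effect = float(np.exp(rng.normal(0.0, config.animal_effect_sd)))
    lam = config.base_n_plaques * gcfg["burden_multiplier"] * effect
    n_plaques = int(max(0, rng.poisson(lam)))
    spec = config.scene_spec(
        n_plaques=n_plaques,
        vessel_contact_fraction=gcfg["contact_fraction"],
        seed=int(rng.integers(2**31)),
    )
    return synthetic.generate_scene(spec)


def run_pipeline(config: RunConfig, write_images: bool = False) -> dict:
    """Full multi-group run; writes CSV tables and ``summary.json``.

    Deterministic for a fixed config (the seed drives every random draw);
    any stage failure halts with the stage named, preserving partial outputs.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    log = RunLog(os.path.join(outdir, "run.log"))
    log.info(f"resolved config hash {config.config_hash}")
    log.info(json.dumps(config.to_dict(), sort_keys=True))

    stage = "simulate"
    try:
        animal_rows: list[dict] = []
        plaque_records: list[pd.DataFrame] = []
        for group in sorted(config.groups):
            for a in range(config.groups[group]["n_animals"]):
                animal = f"{group}_{a + 1:02d}"
                scene, gt = simulate_animal(config, group, a)
                if write_images:
                    bf = synthetic.render_brightfield(scene)
                    write_image(bf, os.path.join(outdir, f"{animal}_brightfield.tiff"))
                stage = "analyze"
                rows, plaques = analyze_scene(
                    scene,
                    config.segmentation,
                    coloc_method=config.coloc_method,
                )
                for r in rows:
                    r.update(group=group, animal=animal)
                    animal_rows.append(r)
                plaques = plaques.assign(group=group, animal=animal)
                plaque_records.append(plaques)
                log.info(f"analyzed {animal}: {len(plaques)} plaques")
                stage = "simulate"

        stage = "aggregate"
        records = pd.DataFrame(animal_rows)
        per_animal, summaries = stats.aggregate(
            records, {m: "mean" for m in REGION_METRICS}
        )
        summary_table = stats.summaries_to_table(summaries)

        stage = "stats"
        anova_rows, anova_json = [], {}
        group_names = sorted(config.groups)
        for region in sorted(per_animal["region"].unique()):
            anova_json[region] = {}
            for metric in REGION_METRICS:
                vals = [
                    per_animal.loc[
                        (per_animal["group"] == g) & (per_animal["region"] == region),
                        metric,
                    ]
                    .dropna()
                    .to_numpy()
                    for g in group_names
                ]
                if any(v.size < 2 for v in vals):
                    continue
                try:
                    res = stats.anova_lsd(vals, group_names)
                except (UsageError, MeasurementError) as exc:
                    anova_json[region][metric] = {"degenerate": str(exc)}
                    continue
                entry = {
                    "F": res.f,
                    "df": [res.df_between, res.df_within],
                    "p": res.p_omnibus,
                    "pairwise": res.pairwise.to_dict("records")
                    if len(res.pairwise)
                    else [],
                }
                anova_json[region][metric] = entry
                for pw in entry["pairwise"]:
                    anova_rows.append(dict(region=region, metric=metric, **pw))

        corr_json: dict = {"diameter_distance": {}, "fisher_z": []}
        pooled = (
            pd.concat(plaque_records, ignore_index=True)
            if plaque_records
            else pd.DataFrame()
        )
        group_corr: dict[str, tuple[float, int, float]] = {}
        for g in group_names:
            sub = pooled[pooled["group"] == g] if len(pooled) else pd.DataFrame()
            try:
                r, n, p = vascular.diameter_distance_correlation(sub)
                r_nc, n_nc, p_nc = vascular.diameter_distance_correlation(
                    sub, include_contacts=False
                )
            except (UsageError, MeasurementError):
                continue
            group_corr[g] = (r, n, p)
            corr_json["diameter_distance"][g] = {
                "r": r,
                "n": n,
                "p": p,
                "r_excluding_contacts": r_nc,
                "n_excluding_contacts": n_nc,
                "p_excluding_contacts": p_nc,
            }
        for g1, g2 in [("facilitator", "control"), ("facilitator", "inhibitor"), ("control", "inhibitor")]:
            if g1 in group_corr and g2 in group_corr:
                r1, n1, _ = group_corr[g1]
                r2, n2, _ = group_corr[g2]
                try:
                    fz = stats.fisher_z_independent(r1, n1, r2, n2, tail="greater")
                except UsageError:
                    continue
                corr_json["fisher_z"].append(
                    dict(group_1=g1, group_2=g2, r1=r1, n1=n1, r2=r2, n2=n2, z=fz.z, p=fz.p, tail=fz.tail)
                )

        stage = "write"
        write_table(records, os.path.join(outdir, "animal_region_metrics.csv"))
        if len(pooled):
            write_table(
                pooled.drop(columns=["plaque_id"]),
                os.path.join(outdir, "plaque_vessel.csv"),
            )
        write_table(summary_table, os.path.join(outdir, "group_summaries.csv"))
        write_table(
            pd.DataFrame(anova_rows), os.path.join(outdir, "anova_lsd.csv")
        )
        summary = {
            "seed": config.seed,
            "config_hash": config.config_hash,
            "groups": {
                g: {"n_animals": config.groups[g]["n_animals"]} for g in group_names
            },
            "metrics": _nest_summaries(summary_table),
            "anova": anova_json,
            "correlations": corr_json,
        }
        summary = _jsonable(summary)
        with open(os.path.join(outdir, "summary.json"), "w", encoding="utf-8") as fh:
            json.dump(summary, fh, sort_keys=True, indent=1)
        log.info("run complete")
        return summary
    except PlaquemetricsError as exc:
        log.info(f"stage {stage!r} failed: {exc}")
        raise PlaquemetricsError(f"stage {stage!r} failed: {exc}") from exc


def _nest_summaries(table: pd.DataFrame) -> dict:
    out: dict = {}
    for _, row in table.iterrows():
        out.setdefault(row["region"], {}).setdefault(row["metric"], {})[row["group"]] = {
            "mean": row["mean"],
            "sem": row["sem"],
            "n": int(row["n_animals"]),
        }
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# --------------------------------------------------------------------------
# scaled-down parameter-recovery replicate
# --------------------------------------------------------------------------


def burden_recovery_replicate(
    seed: int,
    n_animals: int = 15,
    field_px: int = 192,
    base_n_plaques: int = 10,
    max_n_plaques: int = 24,
    burden_multipliers: dict | None = None,
    contact_fractions: dict | None = None,
    animal_effect_sd: float = 0.22,
) -> dict[tuple[str, str], float]:
    """One replicate of the three-group burden recovery study.

    Simulates a reduced-size field per virtual animal under planted burden
    ratios (default facilitator:control:inhibitor = 0.4:1:1.4) and contact
    fractions, runs the real image pipeline, and returns the LSD p-values
    for each cortical burden contrast.
    """
    mult = burden_multipliers or {"control": 1.0, "facilitator": 0.4, "inhibitor": 1.4}
    contact = contact_fractions or {
        "control": 0.279,
        "facilitator": 0.178,
        "inhibitor": 0.256,
    }
    params = segmentation.SegmentationParams()
    burdens: dict[str, list[float]] = {g: [] for g in mult}
    for g_idx, g in enumerate(sorted(mult)):
        for a in range(n_animals):
            rng = np.random.default_rng([seed, g_idx, a])
            effect = float(np.exp(rng.normal(0.0, animal_effect_sd)))
            # truncated Poisson: the reduced field holds ~max_n_plaques deposits
            n_plq = min(int(rng.poisson(base_n_plaques * mult[g] * effect)), max_n_plaques)
            spec = synthetic.SceneSpec(
                field_size_px=(field_px, field_px),
                n_plaques=n_plq,
                diameter_range_um=(10.0, 24.0),
                vessel_count=1,
                vessel_contact_fraction=contact[g],
                noise_sd=2.0,
                seed=int(rng.integers(2**31)),
            )
            scene, _ = synthetic.generate_scene(spec)
            bf = synthetic.render_brightfield(scene)
            maps = segmentation.separate_stains(bf)
            roi_masks = segmentation.segment_plaques(
                maps.dab, params, spec.pixel_size_um
            )
            area_um2 = sum(int(m.sum()) for m in roi_masks) * spec.pixel_size_um**2
            field_mm2 = (field_px * spec.pixel_size_um) ** 2 / 1e6
            burdens[g].append(area_um2 / field_mm2)
    names = sorted(mult)
    res = stats.anova_lsd([np.asarray(burdens[g]) for g in names], names)
    out = {}
    for _, row in res.pairwise.iterrows():
        out[(row["group_1"], row["group_2"])] = float(row["p"])
    return out
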