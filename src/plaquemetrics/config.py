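"""Run configuration: YAML-backed, strictly validated before any compute.

Unknown keys, bad units and unresolvable values are all collected and
reported in one ConfigError rather than failing one at a time. The resolved
configuration (defaults filled) is echoed into the run log and hashed into
``summary.json`` so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .segmentation import SegmentationParams
from .synthetic import SceneSpec

#: Demo cohort emulating the three-arm design: untreated controls, an
#: AQP4-facilitator arm with a ~0.4× cortical burden and lower vessel-contact
#: frequency, and an AQP4-inhibitor arm with a ~1.4× burden.
DEFAULT_GROUPS = {
    "control": {"n_animals": 3, "burden_multiplier": 1.0, "contact_fraction": 0.279},
    "facilitator": {"n_animals": 3, "burden_multiplier": 0.4, "contact_fraction": 0.178},
    "inhibitor": {"n_animals": 3, "burden_multiplier": 1.4, "contact_fraction": 0.256},
}

_SCENE_KEYS = {f.name for f in dataclasses.fields(SceneSpec)} - {"seed"}
_SEG_KEYS = {f.name for f in dataclasses.fields(SegmentationParams)}
_GROUP_KEYS = {"n_animals", "burden_multiplier", "contact_fraction"}
_TOP_KEYS = {
    "outdir",
    "seed",
    "base_n_plaques",
    "animal_effect_sd",
    "scene",
    "segmentation",
    "groups",
    "coloc_method",
    "log_level",
}


@dataclass
class RunConfig:
    """Validated, normalized configuration for one pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    base_n_plaques: int = 20
    animal_effect_sd: float = 0.22  # lognormal sd of the per-animal burden effect
    scene: dict = field(default_factory=dict)  # SceneSpec overrides
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    groups: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUPS.items()})
    coloc_method: str = "manders"
    log_level: str = "info"

    def scene_spec(self, **overrides) -> SceneSpec:
        kwargs = dict(self.scene)
        kwargs.update(overrides)
        return SceneSpec(**kwargs)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "base_n_plaques": self.base_n_plaques,
            "animal_effect_sd": self.animal_effect_sd,
            "scene": dict(self.scene),
            "segmentation": dataclasses.asdict(self.segmentation),
            "groups": {g: dict(v) for g, v in self.groups.items()},
            "coloc_method": self.coloc_method,
            "log_level": self.log_level,
        }

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded)."""
        payload = self.to_dict()
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(raw: dict | None) -> RunConfig:
    """Normalize a raw mapping into a RunConfig, listing all violations."""
    raw = dict(raw or {})
    problems: list[str] = []

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")

    scene = dict(raw.get("scene") or {})
    bad_scene = set(scene) - _SCENE_KEYS
    if bad_scene:
        problems.append(f"unknown scene keys: {sorted(bad_scene)}")
    for tup_key in ("field_size_px", "diameter_range_um"):
        if tup_key in scene and isinstance(scene[tup_key], list):
            scene[tup_key] = tuple(scene[tup_key])
    if "pixel_size_um" in scene and not (
        isinstance(scene["pixel_size_um"], (int, float)) and scene["pixel_size_um"] > 0
    ):
        problems.append(f"scene.pixel_size_um must be > 0, got {scene['pixel_size_um']!r}")

    seg_raw = dict(raw.get("segmentation") or {})
    bad_seg = set(seg_raw) - _SEG_KEYS
    if bad_seg:
        problems.append(f"unknown segmentation keys: {sorted(bad_seg)}")
    seg = SegmentationParams(**{k: v for k, v in seg_raw.items() if k in _SEG_KEYS})
    try:
        seg.validate()
    except ConfigError as exc:
        problems.append(str(exc))

    groups_raw = raw.get("groups")
    groups = {k: dict(v) for k, v in (groups_raw or DEFAULT_GROUPS).items()}
    for gname, gcfg in groups.items():
        bad = set(gcfg) - _GROUP_KEYS
        if bad:
            problems.append(f"unknown keys in group {gname!r}: {sorted(bad)}")
        full = dict(DEFAULT_GROUPS.get(gname, DEFAULT_GROUPS["control"]))
        full.update(gcfg)
        if not (isinstance(full["n_animals"], int) and full["n_animals"] >= 1):
            problems.append(f"group {gname!r}: n_animals must be a positive integer")
        if full["burden_multiplier"] <= 0:
            problems.append(f"group {gname!r}: burden_multiplier must be > 0")
        if not 0.0 <= full["contact_fraction"] <= 1.0:
            problems.append(f"group {gname!r}: contact_fraction must be in [0, 1]")
        groups[gname] = full

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")
    base_n = raw.get("base_n_plaques", 20)
    if not (isinstance(base_n, int) and base_n >= 0):
        problems.append("base_n_plaques must be a non-negative integer")
    eff_sd = raw.get("animal_effect_sd", 0.22)
    if not (isinstance(eff_sd, (int, float)) and eff_sd >= 0):
        problems.append("animal_effect_sd must be non-negative")
    method = raw.get("coloc_method", "manders")
    if method not in ("manders", "area"):
        problems.append(f"coloc_method must be 'manders' or 'area', got {method!r}")

    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))

    cfg = RunConfig(
        outdir=str(raw.get("outdir", "pipeline_out")),
        seed=seed,
        base_n_plaques=base_n,
        animal_effect_sd=float(eff_sd),
        scene=scene,
        segmentation=seg,
        groups=groups,
        coloc_method=method,
        log_level=str(raw.get("log_level", "info")),
    )
    # eagerly validate the scene overrides against SceneSpec's own invariants
    try:
        cfg.scene_spec(seed=0).validate()
    except Exception as exc:
        raise ConfigError(f"invalid scene configuration: {exc}") from exc
    return cfg


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Read a YAML config file (or use all defaults when path is None)."""
    if path is None:
        return validate_config({})
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return validate_config(raw)
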