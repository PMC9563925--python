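"""Run configuration: defaults for every named threshold, YAML round-trip."""

from __future__ import annotations

from pathlib import Path

import yaml


def default_config() -> dict:
    """All tunable parameters with their defaults, grouped by stage."""
    return {
        "protocol": "Landscape",  # "Landscape" | "CDX2" | "both"
        "seed": 0,
        "n_patients": 2,
        "frames_per_slide": 8,
        "rare_scale": 1.0,
        "segmentation": {
            "dapi_floor_nmads": 3.0,
            "marker_floor_nmads": 4.0,
            "min_nucleus_area_um2": 6.0,
            "split_min_distance_um": 3.0,
            "cytoplasm_max_expand_um": 5.0,
            "dapi_neg_area_bounds_um2": (2.0, 120.0),
        },
        "morphometrics": {
            "positivity_nmads": 5.0,
            "diffuse_max_contrast": 0.20,
            "filamentous_min_orientation": 0.55,
        },
        "detection": {
            "variance_explained": 0.95,
            "n_clusters": 10,
            "common_fraction": 0.20,
            "min_bulk_distance": 4.0,
            "min_events": 5,
        },
        "classification": {
            "oncosome_min_circularity": 0.85,
            "oncosome_max_diameter_um": 12.0,
            "clear_nucleus_min_area_um2": 20.0,
            "clear_nucleus_min_solidity": 0.90,
            "mega_area_factor": 2.0,
            "clustered_distance_factor": 1.5,
        },
    }


def validate_config(config: dict) -> None:
    """Fail fast on structurally invalid configs, before any compute."""
    if config.get("protocol") not in ("Landscape", "CDX2", "both"):
        raise ValueError(
            "config must set protocol to 'Landscape', 'CDX2' or 'both'"
        )
    for key in ("seed", "n_patients", "frames_per_slide"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Defaults, optionally updated from a YAML file, then from kwargs."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    cfg.update(overrides)
    return cfg


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
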