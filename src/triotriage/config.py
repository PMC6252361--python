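"""Shared YAML configuration: filter thresholds and annotation key names."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .filters import FilterConfig
from .variant_io import AnnotationKeys


def load_config(path: str | Path) -> tuple[FilterConfig, AnnotationKeys]:
    """Read a config file with optional ``filters`` / ``annotation_keys`` sections."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - {"filters", "annotation_keys"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg = FilterConfig.from_mapping(data.get("filters", {}) or {})
    keys = AnnotationKeys.from_mapping(data.get("annotation_keys", {}) or {})
    return cfg, keys


def dump_config(cfg: FilterConfig, keys: AnnotationKeys, path: str | Path) -> None:
    data = {
        "filters": {
            "af_standard_max": cfg.af_standard_max,
            "af_permissive_max": cfg.af_permissive_max,
            "splice_window_bp": cfg.splice_window_bp,
            "deleterious_consequences": sorted(
                c.value for c in cfg.deleterious_consequences
            ),
            "min_gq": cfg.min_gq,
            "min_depth": cfg.min_depth,
            "allow_unresolved_phase": cfg.allow_unresolved_phase,
            "par_regions": [list(r) for r in cfg.par_regions],
        },
        "annotation_keys": asdict(keys),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
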