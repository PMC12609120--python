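"""Readers, writers, configuration and provenance.

Conventions: pixel-space origin is the top-left corner, x rightward
(columns), y downward (rows), half-open pixel intervals; exported
coordinates are in μm via the microns-per-pixel scale.  CSVs are UTF-8,
comma-delimited, "." decimal.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stains import StainModel

__all__ = [
    "RunConfig",
    "read_eo_table",
    "write_eo_table",
    "read_geojson_annotations",
    "write_geojson_annotations",
    "read_stain_model",
    "write_stain_model",
    "write_provenance",
]

logger = logging.getLogger("eoquant")

EO_TABLE_REQUIRED = ["object_id", "area_um2", "ins_area_um2", "gluc_area_um2"]
_NUMERIC = ["area_um2", "ins_area_um2", "gluc_area_um2"]


@dataclass
class RunConfig:
    """Run-level settings; defaults are the published thresholds."""

    stain_model_path: str | None = None
    microns_per_px: float = 0.5
    min_object_area_um2: float = 170.0
    positivity_area_um2: float = 40.0
    seed: int = 0
    out_dir: str = "."
    test_plan: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_object_area_um2 != 170.0:
            logger.warning("min object area overridden to %.1f μm²",
                           self.min_object_area_um2)
        if self.positivity_area_um2 != 40.0:
            logger.warning("positivity threshold overridden to %.1f μm²",
                           self.positivity_area_um2)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "stain_model_path": self.stain_model_path,
            "microns_per_px": self.microns_per_px,
            "min_object_area_um2": self.min_object_area_um2,
            "positivity_area_um2": self.positivity_area_um2,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "test_plan": self.test_plan,
        }


def read_eo_table(path) -> pd.DataFrame:
    """Read a per-object CSV, validating required numeric columns.

    Required columns: ``object_id, area_um2, ins_area_um2,
    gluc_area_um2``.  Unknown columns pass through untouched.  A
    non-numeric area raises, citing the 1-based data row.
    """
    df = pd.read_csv(path, dtype={"object_id": str})
    missing = [c for c in EO_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in "
                f"column {col!r} at data row {row}")
        df[col] = coerced
    return df


def write_eo_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON


def _close_ring(ring: list, where: str) -> list:
    if ring and ring[0] != ring[-1]:
        warnings.warn(f"{where}: unclosed ring auto-closed")
        ring = list(ring) + [ring[0]]
    return ring


def read_geojson_annotations(path) -> list[dict]:
    """Polygons with properties from a GeoJSON FeatureCollection.

    Returns dicts ``{"id", "ring" (Nx2 array), "properties"}``.  Rings
    are closed (auto-closed with a warning when needed); MultiPolygons
    are split into one entry per part with ``/part<k>`` id suffixes.
    """
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection")
    out = []
    for k, feat in enumerate(data.get("features", [])):
        geom = feat.get("geometry") or {}
        fid = str(feat.get("id", feat.get("properties", {}).get("id", k)))
        props = feat.get("properties", {}) or {}
        gtype = geom.get("type")
        if gtype == "Polygon":
            ring = _close_ring(geom["coordinates"][0], f"feature {fid}")
            out.append({"id": fid, "ring": np.asarray(ring, float),
                        "properties": props})
        elif gtype == "MultiPolygon":
            logger.warning("feature %s: MultiPolygon split into %d parts",
                           fid, len(geom["coordinates"]))
            for p, part in enumerate(geom["coordinates"]):
                ring = _close_ring(part[0], f"feature {fid}/part{p}")
                out.append({"id": f"{fid}/part{p}",
                            "ring": np.asarray(ring, float),
                            "properties": props})
        else:
            raise ValueError(
                f"{path}: feature {fid} has unsupported geometry {gtype!r}")
    return out


def write_geojson_annotations(annotations: list[dict], path) -> None:
    """Inverse of :func:`read_geojson_annotations`."""
    features = []
    for ann in annotations:
        ring = [[float(x), float(y)] for x, y in np.asarray(ann["ring"])]
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append({
            "type": "Feature",
            "id": ann.get("id"),
            "properties": ann.get("properties", {}),
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# stain model YAML


def read_stain_model(path) -> StainModel:
    """Stain model from YAML: unit RGB OD vectors + thresholds."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return StainModel(
        stain_vectors={k: np.asarray(v, float)
                       for k, v in data["stain_vectors"].items()},
        od_threshold={k: float(v) for k, v in data["od_threshold"].items()},
        background_intensity=tuple(data.get("background_intensity",
                                            (255.0, 255.0, 255.0))),
        od_floor=float(data.get("od_floor", 0.10)),
    )


def write_stain_model(model: StainModel, path) -> None:
    data = {
        "stain_vectors": {k: [float(x) for x in v]
                          for k, v in model.stain_vectors.items()},
        "od_threshold": {k: float(v) for k, v in model.od_threshold.items()},
        "background_intensity": [float(x) for x in model.background_intensity],
        "od_floor": float(model.od_floor),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# provenance


def write_provenance(out_dir, config: dict, seed: int | None = None) -> Path:
    """Machine-readable provenance: config hash, versions, seed."""
    import eoquant

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "eoquant": eoquant.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    return path
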