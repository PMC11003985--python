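"""Reading and writing the package's plain-text exchange formats.

* Whisker arrays: CSV with one row per polyline point
  (``whisker_id, point_index, x, y, z``) plus a JSON header holding the
  eye position, head frame and per-whisker identity/angles.
* Visual-space polygons: CSV with ``azimuth, elevation`` columns.
* Cell tables: CSV with ``x, y`` (optionally ``z``, ``layer``, ``animal``).
* Barrel maps: plain-text integer matrix plus JSON metadata.
* Configuration: YAML or JSON with blocks mirroring the dataclass fields
  (``network``, ``protocol``, generator blocks, ...).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from whiskvis.exceptions import ConfigError
from whiskvis.geometry import VisualSpaceMap, Whisker, WhiskerArray
from whiskvis.network import NetworkParams, StimulusProtocol
from whiskvis.spatial import BarrelMap

__all__ = [
    "save_whisker_array", "load_whisker_array",
    "save_visual_space", "load_visual_space",
    "save_cells", "load_cells",
    "save_barrel_map", "load_barrel_map",
    "load_config", "network_params_from_config",
    "protocol_from_config", "dump_json",
]


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# whisker arrays
# ---------------------------------------------------------------------------

def save_whisker_array(array: WhiskerArray, csv_path: str | Path,
                       header_path: str | Path | None = None) -> None:
    csv_path = Path(csv_path)
    rows = []
    for w in array.whiskers:
        for i, p in enumerate(w.polyline):
            rows.append((w.label, i, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=["whisker_id", "point_index", "x", "y", "z"]) \
        .to_csv(csv_path, index=False, float_format="%.17g")
    header = {
        "eye": array.eye.tolist(),
        "head_frame": array.head_frame.tolist(),
        "whiskers": {w.label: {"row": w.row, "arc": w.arc,
                               "phi_w": w.phi_w, "theta_w": w.theta_w,
                               "zeta_w": w.zeta_w, "length": w.length}
                     for w in array.whiskers},
    }
    header_path = header_path or csv_path.with_suffix(".json")
    dump_json(header, header_path)


def load_whisker_array(csv_path: str | Path,
                       header_path: str | Path | None = None) -> WhiskerArray:
    csv_path = Path(csv_path)
    header_path = header_path or csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    header = json.loads(Path(header_path).read_text())
    whiskers = []
    for label, meta in header["whiskers"].items():
        sub = df[df["whisker_id"] == label].sort_values("point_index")
        poly = sub[["x", "y", "z"]].to_numpy()
        whiskers.append(Whisker(row=meta["row"], arc=meta["arc"],
                                basepoint=poly[0], phi_w=meta["phi_w"],
                                theta_w=meta["theta_w"],
                                zeta_w=meta["zeta_w"],
                                length=meta["length"], polyline=poly))
    return WhiskerArray(whiskers=whiskers,
                        eye=np.asarray(header["eye"]),
                        head_frame=np.asarray(header["head_frame"]))


# ---------------------------------------------------------------------------
# visual space, cells, barrel maps
# ---------------------------------------------------------------------------

def save_visual_space(vmap: VisualSpaceMap, path: str | Path) -> None:
    pd.DataFrame(vmap.vertices, columns=["azimuth", "elevation"]) \
        .to_csv(path, index=False, float_format="%.17g")


def load_visual_space(path: str | Path, dilation: float = 0.0
                      ) -> VisualSpaceMap:
    df = pd.read_csv(path)
    return VisualSpaceMap(vertices=df[["azimuth", "elevation"]].to_numpy(),
                          dilation=dilation)


def save_cells(cells: Mapping[str, np.ndarray], path: str | Path) -> None:
    frames = []
    for layer, xy in cells.items():
        xy = np.asarray(xy).reshape(-1, 2)
        frames.append(pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1],
                                    "layer": layer}))
    pd.concat(frames, ignore_index=True) \
        .to_csv(path, index=False, float_format="%.17g")


def load_cells(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    if "layer" not in df.columns:
        df["layer"] = "all"
    return {layer: sub[["x", "y"]].to_numpy()
            for layer, sub in df.groupby("layer")}


def save_barrel_map(barrel_map: BarrelMap, path: str | Path,
                    meta_path: str | Path | None = None) -> None:
    path = Path(path)
    np.savetxt(path, barrel_map.raster, fmt="%d")
    meta_path = meta_path or path.with_suffix(".json")
    dump_json({"pixel_area": barrel_map.pixel_area,
               "shape": list(barrel_map.raster.shape)}, meta_path)


def load_barrel_map(path: str | Path,
                    meta_path: str | Path | None = None) -> BarrelMap:
    path = Path(path)
    raster = np.loadtxt(path, dtype=np.int64)
    meta_path = meta_path or path.with_suffix(".json")
    pixel_area = 1.0
    if Path(meta_path).exists():
        pixel_area = json.loads(Path(meta_path).read_text()) \
            .get("pixel_area", 1.0)
    return BarrelMap(raster=raster, pixel_area=pixel_area)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def _from_block(cls, block: Mapping[str, Any], name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(
            f"unknown field(s) in '{name}' block: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' block: {exc}") from exc


def network_params_from_config(cfg: Mapping[str, Any]) -> NetworkParams:
    return _from_block(NetworkParams, cfg.get("network", {}), "network")


def protocol_from_config(cfg: Mapping[str, Any]) -> StimulusProtocol:
    return _from_block(StimulusProtocol, cfg.get("protocol", {}), "protocol")
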