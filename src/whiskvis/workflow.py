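"""End-to-end orchestration: reproducible multi-stage runs with a manifest.

A run executes the requested stages in order — synthetic-data generation,
network simulation and sweeps, whisker/visual-space overlap, spatial
statistics — writing all outputs under one directory together with a
``manifest.json`` recording the config hash, seeds, stage list, file paths,
package version and timestamps.  All randomness flows from the manifest
seed; deterministic stages reproduce bit-identical CSV output given the
same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import whiskvis
from whiskvis import io as wio
from whiskvis.exceptions import ConfigError
from whiskvis.geometry import tips_in_space, whisk_scenario
from whiskvis.network import (
    StimulusProtocol, classify_regime, measure_steady_states, simulate,
    steady_state_analytic, suppression_analytic, sweep,
)
from whiskvis.spatial import (
    barrel_permutation_test, density_map, parcellate, pca_axes,
)
from whiskvis import synth

log = logging.getLogger("whiskvis")

ALL_STAGES = ("generate", "network", "overlap", "spatial")

__all__ = ["RunManifest", "run_pipeline", "ALL_STAGES"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    outputs: dict[str, list[str]] = field(default_factory=dict)
    package_version: str = whiskvis.__version__
    started: str = ""
    finished: str = ""


def _hash_config(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _validate(cfg: dict) -> list[str]:
    stages = cfg.get("stages", list(ALL_STAGES))
    if not isinstance(stages, list) or not stages:
        raise ConfigError("'stages' must be a non-empty list")
    for s in stages:
        if s not in ALL_STAGES:
            raise ConfigError(
                f"unknown stage {s!r} in 'stages' "
                f"(valid: {', '.join(ALL_STAGES)})")
    # force block validation early so bad configs fail before any stage runs
    wio.network_params_from_config(cfg)
    wio.protocol_from_config(cfg)
    return stages


def run_pipeline(config: dict, seed: int, out_dir: str | Path) -> RunManifest:
    """Execute the configured stages and write outputs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _validate(config)
    manifest = RunManifest(config_hash=_hash_config(config), seed=seed,
                           stages=stages,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    artifacts: dict[str, object] = {}
    for stage in stages:
        t0 = time.time()
        log.info("stage %s: starting (seed=%d)", stage, seed)
        paths = _STAGE_FUNCS[stage](config, seed, out, artifacts)
        manifest.outputs[stage] = [str(p) for p in paths]
        log.info("stage %s: done in %.2f s", stage, time.time() - t0)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    wio.dump_json(dataclasses.asdict(manifest), out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_generate(cfg: dict, seed: int, out: Path, art: dict) -> list[Path]:
    paths = []
    array, side_w = synth.gen_whisker_array(seed=seed)
    vmap, side_v = synth.gen_visual_space(seed=seed)
    barrel_map, cells, side_b = synth.gen_barrel_map(seed=seed)
    cloud, side_c = synth.gen_cell_cloud(seed=seed)
    art.update(array=array, vmap=vmap, barrel_map=barrel_map,
               cells=cells, cloud=cloud)

    wio.save_whisker_array(array, out / "whiskers.csv")
    wio.save_visual_space(vmap, out / "visual_space.csv")
    wio.save_barrel_map(barrel_map, out / "barrels.txt")
    wio.save_cells(cells, out / "barrel_cells.csv")
    pd.DataFrame(cloud.points, columns=["x", "y", "z"]) \
        .assign(layer=cloud.labels) \
        .to_csv(out / "cloud.csv", index=False, float_format="%.17g")
    for name, side in (("whiskers", side_w), ("visual_space", side_v),
                       ("barrels", side_b), ("cloud", side_c)):
        wio.dump_json(side, out / f"{name}.truth.json")
        paths.append(out / f"{name}.truth.json")
    paths += [out / "whiskers.csv", out / "visual_space.csv",
              out / "barrels.txt", out / "barrel_cells.csv",
              out / "cloud.csv"]
    return paths


def _stage_network(cfg: dict, seed: int, out: Path, art: dict) -> list[Path]:
    params = wio.network_params_from_config(cfg)
    protocol = wio.protocol_from_config(cfg)
    traj = simulate(params, protocol)
    pd.DataFrame({"time": traj.times, "A_P": traj.A_P, "A_F": traj.A_F}) \
        .to_csv(out / "trajectory.csv", index=False, float_format="%.17g")
    (pre, post) = measure_steady_states(traj, protocol)
    sidecar = {
        "steady_state_v": dataclasses.asdict(steady_state_analytic(params, "v")),
        "steady_state_vw": dataclasses.asdict(steady_state_analytic(params, "v+w")),
        "suppression": dataclasses.asdict(suppression_analytic(params)),
        "regime": dataclasses.asdict(classify_regime(params)),
        "simulated_pre_cm": pre, "simulated_post_cm": post,
    }
    wio.dump_json(sidecar, out / "network.json")

    sweep_cfg = cfg.get("sweep", {"axes": {"I_cm": [0.0, 2.0, 41]}})
    axes = {name: np.linspace(*spec[:2], int(spec[2]))
            for name, spec in sweep_cfg.get("axes", {}).items()}
    if axes:
        sweep(params, axes).to_csv(out / "sweep.csv", index=False,
                                   float_format="%.17g")
    return [out / "trajectory.csv", out / "network.json", out / "sweep.csv"]


def _stage_overlap(cfg: dict, seed: int, out: Path, art: dict) -> list[Path]:
    array = art.get("array") or synth.gen_whisker_array(seed=seed)[0]
    vmap = art.get("vmap") or synth.gen_visual_space(seed=seed)[0]
    scen_cfg = cfg.get("overlap", {})
    angles = scen_cfg.get("angles", [-40.0, 0.0, 40.0])
    incline = scen_cfg.get("plane_incline", 0.0)
    roll = scen_cfg.get("roll_scale", 0.0)
    dil = 20.0 if scen_cfg.get("eye_movements", False) else 0.0
    report = {}
    for ang in angles:
        posed = whisk_scenario(array, ang, incline, roll)
        res = tips_in_space(posed, vmap.dilated(dil) if dil else vmap)
        report[f"{ang:+g}deg"] = {"fraction": res.fraction,
                                  "inside": res.inside}
    wio.dump_json(report, out / "overlap.json")
    return [out / "overlap.json"]


def _stage_spatial(cfg: dict, seed: int, out: Path, art: dict) -> list[Path]:
    cloud = art.get("cloud") or synth.gen_cell_cloud(seed=seed)[0]
    barrel_map, cells = (art.get("barrel_map"), art.get("cells"))
    if barrel_map is None or cells is None:
        barrel_map, cells, _ = synth.gen_barrel_map(seed=seed)
    sp_cfg = cfg.get("spatial", {})

    pts = cloud.points2d
    pc1, pc2, explained = pca_axes(pts)
    parc = parcellate(pts, (pc1, pc2), sp_cfg.get("spacing", 200.0),
                      cross=sp_cfg.get("cross", False))
    dm = density_map(pts, sp_cfg.get("grid_step", 58.0))
    perm = barrel_permutation_test(
        cells, barrel_map,
        n_shuffles=sp_cfg.get("n_shuffles", 2500),
        alpha=sp_cfg.get("alpha", 0.001), seed=seed,
        method=sp_cfg.get("method", "per-barrel"))

    wio.dump_json({
        "pc1": pc1, "pc2": pc2, "explained": explained,
        "section_lines": parc.section_lines,
        "per_parcel_fraction": {f"{i},{j}": v for (i, j), v
                                in parc.per_parcel_fraction.items()},
        "density_argmax": dm.argmax,
    }, out / "spatial.json")
    pd.DataFrame({
        "barrel": perm.barrel_ids,
        **{f"fr_{lay}": perm.fr_obs[lay] for lay in perm.layers},
        **{f"p_{lay}": perm.p[lay] for lay in perm.layers},
        **{f"significant_{lay}": perm.significant[lay]
           for lay in perm.layers},
    }).to_csv(out / "barrel_test.csv", index=False, float_format="%.17g")
    return [out / "spatial.json", out / "barrel_test.csv"]


_STAGE_FUNCS = {"generate": _stage_generate, "network": _stage_network,
                "overlap": _stage_overlap, "spatial": _stage_spatial}
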