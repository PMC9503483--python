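"""Container and config I/O.

Slow-time cubes travel in an HDF5 container (complex dataset plus JSON
radar-config and ground-truth attributes); scene/run parameters come from a
YAML config; ground truth per recording is logged to a CSV sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cube import SlowTimeCube
from .errors import ConfigurationError
from .scene import ChestMotion, Reflector, Scene, make_scene
from .simulate import RadarConfig

__all__ = [
    "save_cube",
    "load_cube",
    "scene_to_dict",
    "scene_from_dict",
    "config_to_dict",
    "config_from_dict",
    "load_run_config",
    "write_grid_config",
    "write_truth_csv",
]


def config_to_dict(config: RadarConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(data: dict) -> RadarConfig:
    return RadarConfig(**data)


def scene_to_dict(scene: Scene) -> dict:
    data = dataclasses.asdict(scene)
    data["clutter"] = [list(dataclasses.astuple(c)) for c in scene.clutter]
    return data


def scene_from_dict(data: dict) -> Scene:
    data = dict(data)
    if "motion" in data and isinstance(data["motion"], dict):
        motion = dict(data["motion"])
        motion["harmonics"] = tuple(tuple(h) for h in motion.get("harmonics", ()))
        data["motion"] = ChestMotion(**motion)
    data["clutter"] = tuple(Reflector(*c) for c in data.get("clutter", ()))
    return Scene(**data)


def save_cube(path, slow: SlowTimeCube, scene: Scene | None = None) -> None:
    """Write a slow-time cube (and optional ground-truth scene) to HDF5."""
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("slow_time", data=slow.values)
        dset.attrs["frame_rate"] = slow.frame_rate
        if slow.bin_spacing is not None:
            dset.attrs["bin_spacing"] = slow.bin_spacing
        if slow.config is not None:
            dset.attrs["radar_config"] = json.dumps(config_to_dict(slow.config))
        if scene is not None:
            dset.attrs["scene"] = json.dumps(scene_to_dict(scene))


def load_cube(path) -> tuple[SlowTimeCube, Scene | None]:
    """Read a slow-time cube container written by :func:`save_cube`."""
    with h5py.File(path, "r") as f:
        dset = f["slow_time"]
        values = dset[()]
        attrs = dict(dset.attrs)
    config = None
    if "radar_config" in attrs:
        config = config_from_dict(json.loads(attrs["radar_config"]))
    scene = None
    if "scene" in attrs:
        scene = scene_from_dict(json.loads(attrs["scene"]))
    slow = SlowTimeCube(
        values=np.asarray(values),
        frame_rate=float(attrs["frame_rate"]),
        bin_spacing=float(attrs["bin_spacing"]) if "bin_spacing" in attrs else None,
        config=config,
    )
    return slow, scene


def load_run_config(path) -> dict:
    """Parse a YAML run config into radar/scene/recording objects.

    Layout::

        radar: {fc: 6.0e10, ...}          # optional, defaults otherwise
        recording: {duration: 60, seed: 1}
        scenes:
          - {distance: 1.2, angle: 20, noise_std: 0.0, seed: 1, ...}
    """
    with open(path) as f:
        raw = yaml.safe_load(f)
    if not isinstance(raw, dict) or "scenes" not in raw:
        raise ConfigurationError("run config must contain a 'scenes' list")
    config = config_from_dict(raw.get("radar", {}))
    recording = dict(raw.get("recording", {}))
    scenes = []
    for entry in raw["scenes"]:
        entry = dict(entry)
        motion = entry.pop("motion", None)
        if motion is not None:
            motion = ChestMotion(**motion)
        scenes.append(
            make_scene(
                entry.pop("distance"),
                entry.pop("angle"),
                motion=motion,
                **entry,
            )
        )
    return {"radar": config, "scenes": scenes, "recording": recording}


def write_grid_config(
    path,
    *,
    duration: float = 60.0,
    noise_std: float = 0.0,
    seed: int = 0,
    radar: RadarConfig | None = None,
) -> None:
    """Emit the canonical 15-point grid as a YAML run config."""
    from .evaluate import grid_points

    doc = {
        "radar": config_to_dict(radar) if radar is not None else {},
        "recording": {"duration": duration, "seed": seed},
        "scenes": [
            {
                "distance": p.distance,
                "angle": p.angle,
                "noise_std": noise_std,
                "seed": seed,
            }
            for p in grid_points()
        ],
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def write_truth_csv(path, scenes) -> None:
    """CSV sidecar with ground-truth BR/HR/range/angle per recording."""
    rows = [
        {
            "recording": i,
            "br_bpm": s.motion.br_bpm,
            "hr_bpm": s.motion.hr_bpm,
            "r0_m": s.r0,
            "theta_deg": s.theta,
        }
        for i, s in enumerate(scenes)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, config: RadarConfig, seeds, extra=None) -> None:
    """JSON run manifest: package/library versions, config hash, seeds."""
    import hashlib
    from importlib.metadata import version

    import scipy

    from . import __version__

    config_hash = hashlib.sha256(
        json.dumps(config_to_dict(config), sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "radarvitals": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "click": version("click"),
        "config_sha256": config_hash,
        "seeds": list(seeds),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
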