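"""Checkpointing, run manifests, and tabular/graphical export.

Snapshots go to HDF5 (one file per snapshot: field datasets + time/frame
attributes + the JSON-encoded run manifest); time series to CSV; quick-look
maps to PNG.  A manifest records the configuration hash, code version and
seed so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass

import h5py
import numpy as np

from . import __version__
from .grids import FieldState2D, FieldState3D

__all__ = ["make_manifest", "config_hash", "save_snapshot", "load_snapshot",
           "write_csv", "save_orientation_png", "save_composition_png"]

FORMAT_VERSION = 1


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config) -> str:
    """Stable SHA-256 of a configuration (dataclass or dict)."""
    payload = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def make_manifest(config, seed: int, extra: dict | None = None) -> dict:
    m = {
        "format_version": FORMAT_VERSION,
        "code_version": __version__,
        "seed": int(seed),
        "config": _jsonable(config),
        "config_hash": config_hash(config),
    }
    if extra:
        m.update(_jsonable(extra))
    return m


def save_snapshot(state, manifest: dict, path) -> None:
    """Write a field state plus manifest; round-trips bit-exactly."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["code_version"] = __version__
        f.attrs["t"] = state.t
        f.attrs["frame_offset"] = state.frame_offset
        f.attrs["manifest"] = json.dumps(manifest, sort_keys=True)
        if isinstance(state, FieldState2D):
            f.attrs["kind"] = "2d"
            for name in ("phi", "c", "theta"):
                f.create_dataset(name, data=getattr(state, name),
                                 compression="gzip", compression_opts=4)
        elif isinstance(state, FieldState3D):
            f.attrs["kind"] = "3d"
            f.create_dataset("phi", data=state.phi, compression="gzip",
                             compression_opts=4)
            f.create_dataset("comp", data=state.comp, compression="gzip",
                             compression_opts=4)
        else:
            raise TypeError(f"unsupported state type {type(state)!r}")


def load_snapshot(path):
    """Read a snapshot; returns (state, manifest).

    Raises a clean error on truncated/invalid files and on format-version
    mismatch (reporting both versions); no partial state escapes.
    """
    try:
        with h5py.File(path, "r") as f:
            ver = int(f.attrs.get("format_version", -1))
            if ver != FORMAT_VERSION:
                raise ValueError(
                    f"snapshot format version {ver} != supported {FORMAT_VERSION}")
            manifest = json.loads(f.attrs["manifest"])
            kind = f.attrs["kind"]
            t = float(f.attrs["t"])
            off = int(f.attrs["frame_offset"])
            if kind == "2d":
                state = FieldState2D(f["phi"][...], f["c"][...], f["theta"][...],
                                     t=t, frame_offset=off)
            elif kind == "3d":
                state = FieldState3D(f["phi"][...], f["comp"][...],
                                     t=t, frame_offset=off)
            else:
                raise ValueError(f"unknown snapshot kind {kind!r}")
    except OSError as exc:
        raise OSError(f"cannot read snapshot {path}: {exc}") from exc
    return state, manifest


def write_csv(path, columns: dict) -> None:
    """Write named 1D arrays as a simple CSV (header = keys)."""
    keys = list(columns)
    arrs = [np.asarray(columns[k]) for k in keys]
    n = len(arrs[0])
    with open(path, "w") as fh:
        fh.write(",".join(keys) + "\n")
        for i in range(n):
            fh.write(",".join(repr(a[i].item()) for a in arrs) + "\n")


def save_orientation_png(state: FieldState2D, path, solid_level: float = 0.5) -> None:
    """Orientation map with cyclic colormap, mother phase in black."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    img = plt.get_cmap("hsv")(state.theta % 1.0)
    img[state.phi <= solid_level] = (0, 0, 0, 1)
    plt.imsave(path, img[::-1])


def save_composition_png(state: FieldState2D, path, c_alpha: float = 1 / 3,
                         c_beta: float = 2 / 3, solid_level: float = 0.5) -> None:
    """Three-tone composition map: mother phase gray, organic-rich yellow,
    mineral-rich blue."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    mid = 0.5 * (c_alpha + c_beta)
    img = np.zeros(state.phi.shape + (4,))
    img[...] = (0.6, 0.6, 0.6, 1.0)
    solid = state.phi > solid_level
    img[solid & (state.c >= mid)] = (0.9, 0.8, 0.1, 1.0)
    img[solid & (state.c < mid)] = (0.1, 0.3, 0.8, 1.0)
    plt.imsave(path, img[::-1])
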