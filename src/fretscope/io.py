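"""TIFF stack I/O, metadata sidecars and scene serialization.

Multi-page TIFF is the only required image dialect.  Acquisition metadata
(pixel size, frame interval) is read from a YAML or JSON sidecar next to the
stack (``<stem>.yaml`` / ``<stem>.json``); when absent, documented defaults
of 0.2 µm/px and 0.5 min/frame are used with a logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import DataError
from .fret import FRETFrameSet

log = logging.getLogger("fretscope")

DEFAULT_PIXEL_SIZE_UM = 0.2
DEFAULT_FRAME_INTERVAL_MIN = 0.5

__all__ = [
    "read_stack",
    "write_stack",
    "read_frameset",
    "write_scene",
    "load_scene_config",
]


def _sidecar_metadata(path: Path) -> dict:
    for suffix, loader in ((".yaml", yaml.safe_load), (".yml", yaml.safe_load),
                           (".json", json.load)):
        side = path.with_suffix(suffix)
        if side.exists():
            with open(side) as fh:
                return loader(fh) or {}
    return {}


def read_stack(path, expected_channel: str | None = None):
    """Read a single-channel multi-page TIFF as a float (T, H, W) array.

    Returns ``(stack, metadata)`` where metadata holds ``pixel_size_um`` and
    ``frame_interval_min`` from the sidecar file or the documented defaults.
    RGB/multi-sample TIFFs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            if tif.pages[0].samplesperpixel != 1:
                raise DataError(f"{path}: single-channel TIFF expected "
                                f"({expected_channel or 'any channel'})")
            arr = tif.asarray()
    except tifffile.TiffFileError as exc:
        raise DataError(f"unreadable TIFF {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataError(f"{path}: expected T×H×W pages, got shape {arr.shape}")
    meta = _sidecar_metadata(path)
    if "pixel_size_um" not in meta or "frame_interval_min" not in meta:
        log.warning("%s: no metadata sidecar; assuming %.2g µm/px, "
                    "%.2g min/frame", path, DEFAULT_PIXEL_SIZE_UM,
                    DEFAULT_FRAME_INTERVAL_MIN)
    meta.setdefault("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)
    meta.setdefault("frame_interval_min", DEFAULT_FRAME_INTERVAL_MIN)
    return arr, meta


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (T, H, W) array as a float32 multi-page TIFF."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(Path(path), arr.astype(np.float32),
                     photometric="minisblack")


def read_frameset(donor_path, fret_path, acceptor_path) -> FRETFrameSet:
    """Assemble a three-channel frame set from per-channel TIFFs."""
    donor, meta = read_stack(donor_path, "donor")
    fret, _ = read_stack(fret_path, "fret")
    acceptor, _ = read_stack(acceptor_path, "acceptor")
    return FRETFrameSet(donor=donor, fret=fret, acceptor=acceptor,
                        pixel_size_um=meta["pixel_size_um"],
                        frame_interval_min=meta["frame_interval_min"])


def write_scene(out_dir, frames: FRETFrameSet, truth=None, config=None,
                stem: str = "scene") -> dict:
    """Write a generated scene: per-channel TIFFs, truth arrays, config YAML.

    Channels go to ``<stem>_donor.tif`` / ``_fret.tif`` / ``_acceptor.tif``
    with a shared metadata sidecar; ground truth (when given) to
    ``<stem>_truth.npz`` with a JSON sidecar describing its fields.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, data in (("donor", frames.donor), ("fret", frames.fret),
                       ("acceptor", frames.acceptor)):
        p = out / f"{stem}_{name}.tif"
        write_stack(p, data)
        paths[name] = str(p)
    meta = {"pixel_size_um": frames.pixel_size_um,
            "frame_interval_min": frames.frame_interval_min}
    for p in paths.values():
        with open(Path(p).with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)
    if truth is not None:
        np.savez_compressed(out / f"{stem}_truth.npz",
                            activity_field=truth.activity_field,
                            mask_truth=truth.mask_truth,
                            sensitized_truth=truth.sensitized_truth,
                            boundary_radius_series=truth.boundary_radius_series)
        with open(out / f"{stem}_truth.json", "w") as fh:
            json.dump({"fields": ["activity_field", "mask_truth",
                                  "sensitized_truth",
                                  "boundary_radius_series"],
                       "center": list(truth.center)}, fh, indent=2)
        paths["truth"] = str(out / f"{stem}_truth.npz")
    if config is not None:
        from dataclasses import asdict
        cfg = asdict(config)
        cfg["image_shape"] = list(cfg["image_shape"])
        cfg["shape_harmonics"] = [list(h) for h in cfg["shape_harmonics"]]
        cfg["drift_quadratic_coeffs"] = list(cfg["drift_quadratic_coeffs"])
        with open(out / f"{stem}_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
        paths["config"] = str(out / f"{stem}_config.yaml")
    return paths


def load_scene_config(path):
    """Load a SceneConfig from YAML (tuples restored from lists)."""
    from .synthetic import SceneConfig
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("image_shape", "drift_quadratic_coeffs"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "shape_harmonics" in raw:
        raw["shape_harmonics"] = tuple(tuple(h) for h in raw["shape_harmonics"])
    return SceneConfig(**raw)
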