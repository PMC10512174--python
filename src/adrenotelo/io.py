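"""File I/O: per-channel TIFF triplets, RGB TIFFs, YAML configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .qfish import QFISHImage

__all__ = [
    "save_qfish_tiffs",
    "load_qfish_tiffs",
    "save_rgb_tiff",
    "load_rgb_image",
    "dump_config_yaml",
]

CHANNEL_SUFFIXES = ("dapi", "cy3", "fitc")


def save_qfish_tiffs(image: QFISHImage, out_dir: str | Path, prefix: str) -> list[Path]:
    """Write 16-bit grayscale TIFFs ``<prefix>_dapi/_cy3/_fitc.tif``."""
    base = Path(out_dir)
    base.mkdir(parents=True, exist_ok=True)
    paths = []
    for suffix in CHANNEL_SUFFIXES:
        plane = getattr(image, suffix)
        data = np.clip(np.round(plane), 0, 65535).astype(np.uint16)
        path = base / f"{prefix}_{suffix}.tif"
        tifffile.imwrite(path, data)
        paths.append(path)
    return paths


def load_qfish_tiffs(
    in_dir: str | Path, prefix: str, slide_id: str | None = None
) -> QFISHImage:
    """Read a ``<prefix>_dapi/_cy3/_fitc.tif`` triplet."""
    base = Path(in_dir)
    planes = {}
    for suffix in CHANNEL_SUFFIXES:
        path = base / f"{prefix}_{suffix}.tif"
        if not path.is_file():
            raise FileNotFoundError(f"missing channel file: {path}")
        planes[suffix] = tifffile.imread(path).astype(float)
    return QFISHImage(slide_id=slide_id or prefix, **planes)


def save_rgb_tiff(rgb: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(rgb, dtype=np.uint8))
    return path


def load_rgb_image(path: str | Path) -> np.ndarray:
    img = tifffile.imread(Path(path))
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {img.shape}")
    return img


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def dump_config_yaml(config, path: str | Path) -> Path:
    """Serialize a (dataclass) config into the output directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_plain(config), sort_keys=False))
    return path
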