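"""Readers/writers for images, masks, saliency maps and manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Grayscale or RGB uint8 PNG."""
    iio.imwrite(str(path), np.asarray(image, dtype=np.uint8))


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(str(path)))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Binary mask as 0/255 PNG."""
    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr >= 128


def save_saliency(path: str | Path, values: np.ndarray, sidecar: Mapping) -> None:
    """Saliency map as 16-bit PNG plus a JSON sidecar of provenance."""
    v = np.asarray(values, dtype=np.float64)
    if v.min() < 0 or v.max() > 1:
        raise ConfigurationError("saliency values must be in [0, 1]")
    iio.imwrite(str(path), np.rint(v * 65535).astype(np.uint16))
    Path(str(path) + ".json").write_text(json.dumps(dict(sidecar), indent=1))


def load_saliency(path: str | Path) -> tuple[np.ndarray, dict]:
    arr = iio.imread(str(path)).astype(np.float64) / 65535.0
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    return arr, sidecar


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())


def save_case_volume(outdir: str | Path, volume) -> dict:
    """Per-slice PNGs plus truth masks; returns the per-case manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    slice_files = []
    for i in range(volume.n_slices):
        f = f"{volume.case_id}_z{i:03d}.png"
        save_image(outdir / f, volume.slices[i])
        slice_files.append(f)
        if volume.truth_masks[i].any():
            save_mask(outdir / f"{volume.case_id}_z{i:03d}_truth.png",
                      volume.truth_masks[i])
    return {"case_id": volume.case_id, "label": volume.label,
            "n_slices": volume.n_slices, "slices": slice_files}
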