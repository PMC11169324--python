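"""Concatenated-slice montages: the 2D model input embedding 3D context.

A montage takes equally spaced slices of a case volume and tiles them into
one 2D image so a plain 2D classifier sees information from several
transverse planes at once.  Conventions used throughout the package:
row-major, 0-based, origin top-left, (row, col) order.

``orientation="vertical"`` fills columns top-to-bottom (consecutive slices
are stacked vertically), ``"horizontal"`` fills rows left-to-right.  The
mapping is exactly invertible: :func:`split_montage` recovers the source
slices bit-identically, and :func:`project_mask` places per-slice masks at
the same coordinates as the image tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .errors import AlignmentError, RangeError, ShapeError

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import CaseVolume


@dataclass
class Montage:
    image: np.ndarray  # 2D uint8 (raw intensities)
    layout: tuple[int, int]  # (rows, cols) of tiles
    source: tuple[int, ...]  # slice indices, strictly increasing, equal step
    case_id: str
    label: int
    orientation: str = "vertical"
    montage_id: str = ""

    def __post_init__(self) -> None:
        rows, cols = self.layout
        if self.image.ndim != 2:
            raise ShapeError("montage image must be 2D")
        if len(self.source) != rows * cols:
            raise ShapeError("len(source) must equal rows*cols")
        if self.image.shape[0] % rows or self.image.shape[1] % cols:
            raise ShapeError("image dimensions must be multiples of the layout")
        steps = np.diff(self.source)
        if len(steps) and (steps.min() <= 0 or steps.min() != steps.max()):
            raise ShapeError("source indices must increase with a constant step")
        if not self.montage_id:
            self.montage_id = f"{self.case_id}-o{self.source[0]}"

    @property
    def tile_shape(self) -> tuple[int, int]:
        return (self.image.shape[0] // self.layout[0],
                self.image.shape[1] // self.layout[1])


def select_slices(volume: "CaseVolume", count: int, interval: int,
                  offset: int = 0) -> list[int]:
    """Indices ``offset, offset+interval, ...`` of length ``count``."""
    if count < 1 or interval < 1 or offset < 0:
        raise RangeError("count and interval must be >= 1, offset >= 0")
    needed = offset + (count - 1) * interval + 1
    if needed > volume.n_slices:
        raise RangeError(
            f"need {needed} slices (offset {offset}, count {count}, "
            f"interval {interval}) but volume has {volume.n_slices}"
        )
    return [offset + i * interval for i in range(count)]


def _tile_origin(i: int, layout: tuple[int, int], orientation: str) -> tuple[int, int]:
    rows, cols = layout
    if orientation == "vertical":
        return i % rows, i // rows
    if orientation == "horizontal":
        return i // cols, i % cols
    raise ShapeError(f"unknown orientation {orientation!r}")


def _assemble(planes: Sequence[np.ndarray], layout: tuple[int, int],
              orientation: str) -> np.ndarray:
    rows, cols = layout
    h, w = planes[0].shape
    out = np.zeros((rows * h, cols * w), dtype=planes[0].dtype)
    for i, p in enumerate(planes):
        if p.shape != (h, w):
            raise ShapeError("all slices must share identical dimensions")
        r, c = _tile_origin(i, layout, orientation)
        out[r * h:(r + 1) * h, c * w:(c + 1) * w] = p
    return out


def build_montage(volume: "CaseVolume", indices: Sequence[int],
                  layout: tuple[int, int], orientation: str = "vertical") -> Montage:
    """Tile the selected slices into a single 2D image."""
    rows, cols = layout
    if rows * cols != len(indices):
        raise ShapeError(f"layout {layout} incompatible with {len(indices)} indices")
    planes = [volume.slices[i] for i in indices]
    image = _assemble(planes, layout, orientation)
    return Montage(image=image, layout=(rows, cols), source=tuple(int(i) for i in indices),
                   case_id=volume.case_id, label=volume.label, orientation=orientation)


def split_montage(image: np.ndarray, layout: tuple[int, int],
                  orientation: str = "vertical") -> list[np.ndarray]:
    """Inverse of :func:`build_montage`: recover the tiles in slice order."""
    rows, cols = layout
    if image.shape[0] % rows or image.shape[1] % cols:
        raise ShapeError("image dimensions must be multiples of the layout")
    h, w = image.shape[0] // rows, image.shape[1] // cols
    out = []
    for i in range(rows * cols):
        r, c = _tile_origin(i, layout, orientation)
        out.append(image[r * h:(r + 1) * h, c * w:(c + 1) * w].copy())
    return out


def project_mask(masks: np.ndarray | Mapping[int, np.ndarray],
                 indices: Sequence[int], layout: tuple[int, int],
                 orientation: str = "vertical") -> np.ndarray:
    """Tile per-slice binary masks with the same geometry as the montage."""
    planes = []
    for i in indices:
        if isinstance(masks, Mapping):
            if i not in masks:
                raise AlignmentError(f"no mask for selected slice {i}")
            planes.append(np.asarray(masks[i], dtype=bool))
        else:
            if i >= masks.shape[0]:
                raise AlignmentError(f"no mask for selected slice {i}")
            planes.append(masks[i].astype(bool))
    rows, cols = layout
    if rows * cols != len(indices):
        raise ShapeError(f"layout {layout} incompatible with {len(indices)} indices")
    return _assemble(planes, layout, orientation)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-montage min-max normalization to [0, 1]; constant images -> zeros."""
    x = image.astype(np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)
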