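"""Cell-mask container shared by detection, registration and matching."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CellMask:
    """A single cell's binary spatial footprint in one imaging plane.

    ``pixels`` is an (n, 2) integer array of (row, col) coordinates.
    """

    pixels: np.ndarray
    plane_index: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)

    @property
    def area_px2(self) -> int:
        return len(self.pixels)

    @property
    def centroid_px(self) -> tuple[float, float]:
        """(row, col) centroid."""
        if len(self.pixels) == 0:
            return (float("nan"), float("nan"))
        return tuple(self.pixels.mean(axis=0))

    def to_image(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        inside = ((self.pixels[:, 0] >= 0) & (self.pixels[:, 0] < shape[0]) &
                  (self.pixels[:, 1] >= 0) & (self.pixels[:, 1] < shape[1]))
        px = self.pixels[inside]
        out[px[:, 0], px[:, 1]] = True
        return out

    @classmethod
    def from_image(cls, image: np.ndarray, plane_index: int = 0) -> "CellMask":
        return cls(pixels=np.argwhere(image), plane_index=plane_index)
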