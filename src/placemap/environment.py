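"""Geometry of the discretized open-field arena.

The spatial environment is a rectangular box (default 1 x 1 m) discretized
into an ``nx`` x ``ny`` grid of location bins.  The animal's position is the
one-hot vector over these bins, so every firing field in the model is a
vector of length ``nx * ny``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["Environment", "make_environment"]


@dataclass(frozen=True)
class Environment:
    """A discretized 2D box.

    Locations are indexed row-major: ``index = iy * nx + ix`` where ``ix``
    runs along the x axis and ``iy`` along the y axis.  Bin centers sit at
    ``((ix + 0.5) * width / nx, (iy + 0.5) * height / ny)`` so every center
    lies strictly inside the box.
    """

    width_cm: float = 100.0
    height_cm: float = 100.0
    nx: int = 32
    ny: int = 32

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError(
                f"box dimensions must be positive, got "
                f"{self.width_cm} x {self.height_cm} cm"
            )
        if self.nx < 1 or self.ny < 1:
            raise ValueError(f"grid shape must be positive, got {self.nx} x {self.ny}")

    @property
    def n_locations(self) -> int:
        return self.nx * self.ny

    @property
    def dx_cm(self) -> float:
        return self.width_cm / self.nx

    @property
    def dy_cm(self) -> float:
        return self.height_cm / self.ny

    @cached_property
    def centers_cm(self) -> np.ndarray:
        """(n_locations, 2) array of bin-center coordinates in cm."""
        xs = (np.arange(self.nx) + 0.5) * self.dx_cm
        ys = (np.arange(self.ny) + 0.5) * self.dy_cm
        gx, gy = np.meshgrid(xs, ys)  # row-major: y varies over rows
        return np.column_stack([gx.ravel(), gy.ravel()])

    def index_to_xy(self, index: int) -> tuple[float, float]:
        if not 0 <= index < self.n_locations:
            raise IndexError(f"location index {index} out of range [0, {self.n_locations})")
        x, y = self.centers_cm[index]
        return float(x), float(y)

    def xy_to_index(self, x_cm: float, y_cm: float) -> int:
        """Index of the bin containing (clipping to the box) a point."""
        ix = int(np.clip(np.floor(x_cm / self.dx_cm), 0, self.nx - 1))
        iy = int(np.clip(np.floor(y_cm / self.dy_cm), 0, self.ny - 1))
        return iy * self.nx + ix

    def xy_to_indices(self, points_cm: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`xy_to_index` for an (n, 2) array of points."""
        pts = np.asarray(points_cm, dtype=float)
        ix = np.clip(np.floor(pts[:, 0] / self.dx_cm), 0, self.nx - 1).astype(np.int64)
        iy = np.clip(np.floor(pts[:, 1] / self.dy_cm), 0, self.ny - 1).astype(np.int64)
        return iy * self.nx + ix

    def to_grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape a location vector into an (ny, nx) rate map."""
        v = np.asarray(values)
        if v.shape[-1] != self.n_locations:
            raise ValueError(f"expected {self.n_locations} locations, got {v.shape[-1]}")
        return v.reshape(*v.shape[:-1], self.ny, self.nx)

    def one_hot(self, index: int) -> np.ndarray:
        r = np.zeros(self.n_locations)
        r[index] = 1.0
        return r

    def to_dict(self) -> dict:
        return {
            "width_cm": self.width_cm,
            "height_cm": self.height_cm,
            "nx": self.nx,
            "ny": self.ny,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        return cls(**d)


def make_environment(
    width_cm: float = 100.0, height_cm: float = 100.0, nx: int = 32, ny: int = 32
) -> Environment:
    """Build the discretized arena (default: 1 x 1 m box on a 32 x 32 grid)."""
    return Environment(width_cm=width_cm, height_cm=height_cm, nx=nx, ny=ny)
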