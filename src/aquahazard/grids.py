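"""Regular raster grids of parameter values (~2-km cells by default)."""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np


class InterpMethod(str, enum.Enum):
    ORDINARY_KRIGING = "ordinary_kriging"
    IDW = "idw"


@dataclass(frozen=True)
class GridSpec:
    """A regular grid of square cells over a planar rectangle (km)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    cell_size: float = 2.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("empty grid extent")

    @property
    def n_cols(self) -> int:
        return math.ceil((self.x_max - self.x_min) / self.cell_size)

    @property
    def n_rows(self) -> int:
        return math.ceil((self.y_max - self.y_min) / self.cell_size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of cell centres; row 0 is the southernmost
        row, so ``values[i, j]`` sits at ``(xs[j], ys[i])``."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_min + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def center_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened meshgrid of all cell-centre coordinates (row-major)."""
        xs, ys = self.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()


@dataclass
class ParameterGrid:
    """An interpolated (or simulated) raster of one parameter.

    ``values[i, j]`` is the concentration at the cell centre in row ``i``
    (south to north), column ``j`` (west to east).  ``variance`` carries
    kriging variances where the method provides them.
    """

    parameter: str
    spec: GridSpec
    values: np.ndarray
    method: InterpMethod | None = None
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
            if self.variance.shape != self.spec.shape:
                raise ValueError("variance shape mismatch")
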