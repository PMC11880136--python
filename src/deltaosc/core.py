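"""Shared domain types: observation window, detected-cell table, errors.

All coordinates are continuous 2D positions in micrometres (µm).  Images use
pixel-centre coordinates with 0-based indices; conversion between the two goes
through the image's pixel size (µm/px).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Window",
    "CellTable",
    "CELLTABLE_COLUMNS",
    "SchemaError",
    "PlacementError",
    "DegenerateSeriesError",
]


class SchemaError(ValueError):
    """A tabular input does not match the expected column schema."""


class PlacementError(RuntimeError):
    """Random object placement failed after the retry budget was exhausted."""


class DegenerateSeriesError(ValueError):
    """A time series has no variance and the requested statistic is undefined."""


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window, in µm.

    The study window of a slice is the bounding box spanned by the minimal
    X/Y coordinate ranges of its cells; :meth:`from_points` builds that box.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: x [{self.x_min}, {self.x_max}], "
                f"y [{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def span(self) -> float:
        """Smaller of the two side lengths (sets the radius grid)."""
        return min(self.width, self.height)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (
            (pts[:, 0] >= self.x_min)
            & (pts[:, 0] <= self.x_max)
            & (pts[:, 1] >= self.y_min)
            & (pts[:, 1] <= self.y_max)
        )

    @classmethod
    def from_points(cls, points: np.ndarray) -> "Window":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError("need at least two points to span a window")
        return cls(
            x_min=float(pts[:, 0].min()),
            x_max=float(pts[:, 0].max()),
            y_min=float(pts[:, 1].min()),
            y_max=float(pts[:, 1].max()),
        )


CELLTABLE_COLUMNS = [
    "cell_id",
    "x_um",
    "y_um",
    "radius_um",
    "delta_intensity",
    "dapi_intensity",
    "ratio",
    "positive",
]


@dataclass
class CellTable:
    """Table of detected cells with per-channel intensities and positive calls.

    Thin wrapper around a :class:`pandas.DataFrame` with a fixed schema
    (``CELLTABLE_COLUMNS``).  ``ratio`` is the Delta/DAPI intensity ratio used
    to rectify staining variability before thresholding positives; columns that
    have not been measured yet hold NaN.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CELLTABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cell table is missing columns: {missing}")
        self.df = self.df[CELLTABLE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"CellTable(n_cells={len(self)}, n_positive={self.n_positive})"

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of cell positions in µm."""
        return self.df[["x_um", "y_um"]].to_numpy(dtype=float)

    @property
    def positive_mask(self) -> np.ndarray:
        return self.df["positive"].to_numpy() == 1

    @property
    def positive_points(self) -> np.ndarray:
        return self.points[self.positive_mask]

    @property
    def n_positive(self) -> int:
        return int(self.positive_mask.sum())

    @classmethod
    def from_arrays(
        cls,
        points: np.ndarray,
        radius_um: float | np.ndarray = np.nan,
        positive: np.ndarray | None = None,
    ) -> "CellTable":
        pts = np.asarray(points, dtype=float)
        n = len(pts)
        pos = np.zeros(n, dtype=int) if positive is None else np.asarray(positive, dtype=int)
        df = pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "x_um": pts[:, 0],
                "y_um": pts[:, 1],
                "radius_um": np.broadcast_to(np.asarray(radius_um, dtype=float), (n,)).copy(),
                "delta_intensity": np.nan,
                "dapi_intensity": np.nan,
                "ratio": np.nan,
                "positive": pos,
            }
        )
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CellTable":
        df = pd.read_csv(path)
        missing = [c for c in CELLTABLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        return cls(df)
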