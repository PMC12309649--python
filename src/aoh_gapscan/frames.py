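"""Planar equal-area coordinate frames shared by raster and vector layers.

The analysis world is a flat equal-area plane measured in kilometres, the
abstraction of an equal-area cylindrical projection: every raster cell has
the identical area ``cell_km ** 2`` and polygon areas are planar (shoelace)
areas.  A :class:`Frame` is an invertible 2-D affine map from a layer's local
coordinates to world coordinates; rasters use a frame whose local axes are
(column, row) with y *increasing upward* in world space (row 0 is the top of
the grid), so raster and vector layers share one frame convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry


class FrameError(ValueError):
    """Layer frame metadata missing or incompatible."""


@dataclass(frozen=True)
class Frame:
    """Affine map ``(u, v) -> (x, y) = (a*u + b*v + c, d*u + e*v + f)``.

    For a raster frame, ``u`` is the (fractional) column index and ``v`` the
    row index; cell ``(row, col)`` has its center at ``(col + 0.5, row + 0.5)``
    in local coordinates.
    """

    name: str = "world"
    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 1.0
    f: float = 0.0

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    @property
    def is_equal_area(self) -> bool:
        return bool(np.isclose(abs(self.determinant), abs(self.a * self.e - self.b * self.d)))

    def to_world(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        return self.a * u + self.b * v + self.c, self.d * u + self.e * v + self.f

    def from_world(self, x, y):
        det = self.determinant
        if det == 0:
            raise FrameError(f"frame {self.name!r} is singular")
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        return (self.e * x - self.b * y) / det, (-self.d * x + self.a * y) / det

    def inverse(self) -> "Frame":
        det = self.determinant
        if det == 0:
            raise FrameError(f"frame {self.name!r} is singular")
        return Frame(
            name=f"{self.name}^-1",
            a=self.e / det,
            b=-self.b / det,
            c=(self.b * self.f - self.e * self.c) / det,
            d=-self.d / det,
            e=self.a / det,
            f=(self.d * self.c - self.a * self.f) / det,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "affine": [self.a, self.b, self.c, self.d, self.e, self.f],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Frame":
        a, b, c, d_, e, f = d["affine"]
        return cls(name=d.get("name", "world"), a=a, b=b, c=c, d=d_, e=e, f=f)


#: The shared world frame (identity; km units, y up).
WORLD = Frame("world")


def raster_frame(rows: int, cell_km: float, *, x0: float = 0.0, y_top: float | None = None,
                 name: str = "raster") -> Frame:
    """Frame for a north-up raster: col/row -> km, y increasing upward.

    Row 0 sits at the top edge ``y_top`` (default ``rows * cell_km`` so the
    grid's bottom-left corner is the world origin).
    """
    if y_top is None:
        y_top = rows * cell_km
    return Frame(name=name, a=cell_km, b=0.0, c=x0, d=0.0, e=-cell_km, f=y_top)


def cell_centers(rows_idx, cols_idx, frame: Frame):
    """World coordinates of cell centers for parallel row/col index arrays."""
    return frame.to_world(np.asarray(cols_idx) + 0.5, np.asarray(rows_idx) + 0.5)


def transform_geometry(geom: BaseGeometry, source: Frame, target: Frame) -> BaseGeometry:
    """Re-express a geometry given in ``source`` frame in ``target`` frame."""
    if source is None or target is None:
        raise FrameError("both source and target frames are required")

    def _f(coords: np.ndarray) -> np.ndarray:
        x, y = source.to_world(coords[:, 0], coords[:, 1])
        u, v = target.from_world(x, y)
        return np.column_stack([u, v])

    return shapely.transform(geom, _f)
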