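"""Planar geometry and hex-lattice primitives for spatial proximity rules.

All coordinates are continuous micrometres in the image convention: origin
top-left, y increasing downward.  Areas are reported in mm².  Two geometry
backbones live here:

* :class:`RegionPolygon` — a lesion / tissue region boundary (shapely-backed)
  with signed distances and band partitions used for rules like "within
  250 μm of the invasive edge".
* :class:`HexLattice` — the hexagonally packed spot array (100 μm
  centre-to-centre, even-parity ``(row, col)`` occupancy) with breadth-first
  neighbourhood expansion used for "within 2 spots of a boundary".
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

UM2_PER_MM2 = 1e6

#: lattice step offsets that define hex adjacency on the even-parity array
HEX_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class RegionPolygon:
    """A simple polygon region with a class label.

    Parameters
    ----------
    region_id:
        Unique identifier within a :class:`RegionSet`.
    region_class:
        Lesion class label, e.g. ``"normal"``, ``"PanIN"``, ``"PDAC"``, ``"CP"``.
    vertices:
        ``(n, 2)`` array-like of exterior vertices in μm, in order.
    """

    region_id: str
    region_class: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValueError(
                f"region {self.region_id!r}: polygon needs >= 3 vertices"
            )
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"region {self.region_id!r}: polygon is not simple")
        if poly.area <= 0:
            raise ValueError(f"region {self.region_id!r}: area must be > 0")
        self._poly = poly

    @classmethod
    def from_rectangle(
        cls, region_id: str, region_class: str, rect: Sequence[float]
    ) -> "RegionPolygon":
        """Build from ``(x0, y0, x1, y1)`` μm bounds."""
        x0, y0, x1, y1 = map(float, rect)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("rectangle must have positive extent")
        verts = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
        return cls(region_id, region_class, np.asarray(verts))

    @property
    def polygon(self) -> Polygon:
        return self._poly

    @property
    def area_mm2(self) -> float:
        """Polygon area in mm² (shoelace, via shapely)."""
        return self._poly.area / UM2_PER_MM2

    def contains(self, x: float, y: float) -> bool:
        """True if the point is inside or on the boundary."""
        return bool(shapely.covers(self._poly, Point(x, y)))


@dataclass
class RegionSet:
    """An ordered collection of :class:`RegionPolygon` with unique ids."""

    regions: list[RegionPolygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids must be unique")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, region_id: str) -> RegionPolygon:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    @property
    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def of_class(self, *classes: str) -> list[RegionPolygon]:
        return [r for r in self.regions if r.region_class in classes]


def signed_boundary_distance(point: Sequence[float], polygon: RegionPolygon) -> float:
    """Signed Euclidean distance (μm) from a point to a polygon boundary.

    Negative inside, positive outside, zero on the boundary; the magnitude
    is the distance to the nearest boundary segment.
    """
    p = Point(float(point[0]), float(point[1]))
    d = p.distance(polygon.polygon.exterior)
    if shapely.covers(polygon.polygon, p):
        return -d
    return d


def signed_boundary_distances(
    xy: np.ndarray, polygon: RegionPolygon
) -> np.ndarray:
    """Vectorised :func:`signed_boundary_distance` over an ``(n, 2)`` array."""
    xy = np.asarray(xy, dtype=float)
    pts = shapely.points(xy)
    d = shapely.distance(pts, polygon.polygon.exterior)
    inside = shapely.covers(polygon.polygon, pts)
    return np.where(inside, -d, d)


def proximity_band(
    cells: pd.DataFrame, polygon: RegionPolygon, band_um: float
) -> pd.Series:
    """Partition cells into ``inside`` / ``band`` / ``outside`` a boundary.

    ``inside`` ⇔ signed distance ≤ 0; ``band`` ⇔ 0 < distance ≤ ``band_um``;
    ``outside`` otherwise.  The partition is exhaustive and exclusive.

    Parameters
    ----------
    cells:
        Cell table with ``x_um`` / ``y_um`` columns.
    band_um:
        Band width in μm beyond the boundary, ≥ 0 (the analysis default for
        lesion-adjacent bands is 250 μm).
    """
    if band_um < 0:
        raise ValueError("band_um must be >= 0")
    d = signed_boundary_distances(cells[["x_um", "y_um"]].to_numpy(), polygon)
    labels = np.where(d <= 0, "inside", np.where(d <= band_um, "band", "outside"))
    return pd.Series(labels, index=cells.index, name="band")


@dataclass(frozen=True)
class HexLattice:
    """Hexagonally packed spot array in array coordinates.

    Occupied positions are the ``(row, col)`` pairs with ``row + col`` even,
    ``0 <= row < n_rows``, ``0 <= col < n_cols``.  Neighbouring spots differ
    by ``(0, ±2)`` or ``(±1, ±1)``; an interior spot therefore has exactly 6
    neighbours.  Physical spacing is centre-to-centre between adjacent spots.
    """

    n_rows: int
    n_cols: int
    spacing_um: float = 100.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be > 0")

    def is_occupied(self, row: int, col: int) -> bool:
        return (
            0 <= row < self.n_rows
            and 0 <= col < self.n_cols
            and (row + col) % 2 == 0
        )

    def spots(self) -> list[tuple[int, int]]:
        """All occupied ``(row, col)`` positions in row-major order."""
        return [
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if (r + c) % 2 == 0
        ]

    def xy_um(self, row: int, col: int) -> tuple[float, float]:
        """Physical centre of a spot.

        Columns advance by half the spot pitch (adjacent same-row spots are
        two columns apart); rows advance by the hex row height.
        """
        x = col * self.spacing_um / 2.0
        y = row * self.spacing_um * np.sqrt(3.0) / 2.0
        return (x, y)

    def positions(self) -> pd.DataFrame:
        """Tidy table of all occupied spots with physical coordinates."""
        rows = self.spots()
        xy = np.array([self.xy_um(r, c) for r, c in rows])
        return pd.DataFrame(
            {
                "array_row": [r for r, _ in rows],
                "array_col": [c for _, c in rows],
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
            }
        )

    def adjacent(self, row: int, col: int) -> list[tuple[int, int]]:
        """Occupied lattice neighbours of a spot (≤ 6)."""
        return [
            (row + dr, col + dc)
            for dr, dc in HEX_OFFSETS
            if self.is_occupied(row + dr, col + dc)
        ]


def spot_neighbors(
    lattice: HexLattice,
    seed_spots: Iterable[tuple[int, int]],
    depth: int,
) -> set[tuple[int, int]]:
    """Breadth-first hex expansion around a seed set, excluding the seeds.

    Returns every occupied spot reachable from a seed in ≤ ``depth`` lattice
    steps that is not itself a seed.  Deterministic by construction.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    seeds = set(tuple(s) for s in seed_spots)
    for r, c in seeds:
        if not lattice.is_occupied(r, c):
            raise ValueError(f"seed spot {(r, c)} is not on the lattice")
    frontier = deque((s, 0) for s in seeds)
    seen = set(seeds)
    out: set[tuple[int, int]] = set()
    while frontier:
        (r, c), d = frontier.popleft()
        if d == depth:
            continue
        for nb in lattice.adjacent(r, c):
            if nb not in seen:
                seen.add(nb)
                out.add(nb)
                frontier.append((nb, d + 1))
    return out
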