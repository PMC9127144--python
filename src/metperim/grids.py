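"""Binocular visual-field test grids.

Defines the two built-in suprathreshold screening grids — the classic
120-point Esterman pattern (inferior-weighted, used for disability and
driving assessment) and the 160-point modified-Esterman (mET) pattern
(even spread with two planes of symmetry, extended to 60 degrees
superiorly) — together with the Goldmann stimulus-size geometry.

Coordinates are degrees of visual angle with the origin at fixation:
x positive toward the subject's right, y positive superior.

The mET layout is generated deterministically by :func:`generate_met_grid`
(an offset rectangular lattice clipped to an elliptical field boundary)
and shipped as a versioned CSV fixture.  The Esterman layout is a
hardcoded structural reconstruction of the published pattern (the exact
published coordinates are not tabulated here); see
``data/esterman_grid_synthetic.csv``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridPoint",
    "FieldBoundary",
    "TestGrid",
    "StimulusSpec",
    "goldmann_area_mm2",
    "goldmann_angular_diameter",
    "generate_met_grid",
    "load_grid",
    "strip_superior_rows",
    "grid_to_csv",
    "grid_from_csv",
    "registered_grids",
]

#: Default Goldmann perimeter bowl radius in millimetres.
DEFAULT_BOWL_RADIUS_MM = 300.0

#: Suprathreshold presentation level shared by both paradigms (dB attenuation).
DEFAULT_LEVEL_DB = 10.0

#: Default full-field boundary semi-axes (degrees).
DEFAULT_SEMI_AXIS_X = 85.0
DEFAULT_SEMI_AXIS_Y = 60.0

_GRID_CSV_HEADER = ["index", "x_deg", "y_deg"]


class GridError(ValueError):
    """Invalid grid construction or lookup."""


@dataclass(frozen=True)
class GridPoint:
    """A single test location in degrees of visual angle."""

    index: int
    x: float
    y: float

    @property
    def eccentricity(self) -> float:
        """Radial distance from fixation in degrees."""
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class FieldBoundary:
    """Axis-aligned elliptical boundary of the testable binocular field.

    The superior semi-axis may differ from the inferior one: normal
    binocular fields reach further inferiorly and temporally than
    superiorly, and the physiological superior limit is about 63 degrees.
    """

    semi_axis_x: float = DEFAULT_SEMI_AXIS_X
    semi_axis_y_sup: float = DEFAULT_SEMI_AXIS_Y
    semi_axis_y_inf: float = DEFAULT_SEMI_AXIS_Y

    def __post_init__(self) -> None:
        if min(self.semi_axis_x, self.semi_axis_y_sup, self.semi_axis_y_inf) <= 0:
            raise GridError("boundary semi-axes must be positive")
        if self.semi_axis_y_sup > 63.0:
            raise GridError(
                "superior semi-axis exceeds the 63 degree physiological limit"
            )

    def contains(self, x: float, y: float) -> bool:
        ay = self.semi_axis_y_sup if y >= 0 else self.semi_axis_y_inf
        return (x / self.semi_axis_x) ** 2 + (y / ay) ** 2 <= 1.0

    def polygon_vertices(self, n: int = 720) -> np.ndarray:
        """Polygonal approximation of the boundary, counter-clockwise."""
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        ay = np.where(np.sin(theta) >= 0, self.semi_axis_y_sup, self.semi_axis_y_inf)
        return np.column_stack(
            [self.semi_axis_x * np.cos(theta), ay * np.sin(theta)]
        )

    def area(self) -> float:
        """Exact area of the (possibly asymmetric) ellipse in square degrees."""
        return 0.5 * math.pi * self.semi_axis_x * (
            self.semi_axis_y_sup + self.semi_axis_y_inf
        )


@dataclass(frozen=True)
class TestGrid:
    """An ordered set of binocular field locations with identity metadata."""

    __test__ = False  # not a pytest class despite the clinical name

    name: str
    points: tuple[GridPoint, ...]
    boundary: FieldBoundary = field(default_factory=FieldBoundary)
    notes: str = ""

    def __post_init__(self) -> None:
        indices = [p.index for p in self.points]
        if len(set(indices)) != len(indices):
            raise GridError("point indices must be unique within a grid")
        for p in self.points:
            if abs(p.x) > 90 or abs(p.y) > 60:
                raise GridError(
                    f"point {p.index} at ({p.x}, {p.y}) outside |x|<=90, |y|<=60"
                )

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of point coordinates in grid order."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    def point_by_index(self, index: int) -> GridPoint:
        for p in self.points:
            if p.index == index:
                return p
        raise GridError(f"no point with index {index} in grid {self.name!r}")

    def nearest_neighbour_distances(self) -> np.ndarray:
        from scipy.spatial import cKDTree

        xy = self.coordinates()
        dist, _ = cKDTree(xy).query(xy, k=2)
        return dist[:, 1]


@dataclass(frozen=True)
class StimulusSpec:
    """A single stimulus presentation: Goldmann size, level and location.

    Goldmann stimuli double in diameter per size step, so the area
    quadruples: size III is 4 mm² and size V is 64 mm².
    """

    goldmann_size: int
    level_db: float
    location: GridPoint | None

    def __post_init__(self) -> None:
        if not 1 <= self.goldmann_size <= 5:
            raise GridError("goldmann_size must be an integer in 1..5")
        if self.level_db < 0:
            raise GridError("level_db must be non-negative")

    @property
    def area_mm2(self) -> float:
        return goldmann_area_mm2(self.goldmann_size)

    @property
    def is_catch(self) -> bool:
        return self.location is None


def goldmann_area_mm2(goldmann_size: int) -> float:
    """Stimulus area for a Goldmann size (1..5): 4^(size-3) × 4 mm²."""
    if not 1 <= int(goldmann_size) <= 5:
        raise GridError("goldmann_size must be an integer in 1..5")
    return 4.0 ** (int(goldmann_size) - 3) * 4.0


def goldmann_angular_diameter(
    area_mm2: float, bowl_radius_mm: float = DEFAULT_BOWL_RADIUS_MM
) -> float:
    """Angular subtense, in degrees, of a circular stimulus on the bowl.

    A circle of area *A* has diameter d = 2·sqrt(A/π); at viewing distance
    *R* it subtends 2·atan(d / 2R).  At the standard 300 mm bowl the
    Goldmann V stimulus (64 mm²) subtends 1.72 degrees and the Goldmann
    III stimulus (4 mm²) subtends 0.43 degrees.
    """
    if area_mm2 < 0:
        raise GridError("stimulus area must be non-negative")
    if bowl_radius_mm <= 0:
        raise GridError("bowl radius must be positive")
    diameter = 2.0 * math.sqrt(area_mm2 / math.pi)
    return math.degrees(2.0 * math.atan(diameter / (2.0 * bowl_radius_mm)))


# ---------------------------------------------------------------------------
# Grid generation
# ---------------------------------------------------------------------------

#: Lattice spacing of the shipped 160-point mET fixture (degrees).  The
#: automated search below returns this value for the default boundary.
MET_SPACING_DEG = 10.0


def generate_met_grid(
    spacing: float | None = None,
    boundary: FieldBoundary | None = None,
    name: str = "met",
) -> TestGrid:
    """Generate an evenly spread, doubly symmetric offset-lattice grid.

    Points sit at (±(i+½)·s, ±(j+½)·s) for i, j ≥ 0, clipped to the
    elliptical *boundary*; the construction is closed under reflection in
    both the x and y axes, so the point count is always divisible by 4.
    With the default boundary and spacing the result is the canonical
    160-point mET pattern reaching 55 degrees superiorly.

    When *spacing* is None a deterministic scan over [10°, 16°] in 0.05°
    steps picks the first spacing whose clipped lattice has exactly 160
    points with the maximal row at y ≥ 55°.
    """
    boundary = boundary or FieldBoundary()
    if spacing is None:
        spacing = _find_met_spacing(boundary)
    if spacing <= 0:
        raise GridError("spacing must be positive")
    quadrant: list[tuple[float, float]] = []
    i = 0
    while (i + 0.5) * spacing <= boundary.semi_axis_x:
        j = 0
        while (j + 0.5) * spacing <= max(
            boundary.semi_axis_y_sup, boundary.semi_axis_y_inf
        ):
            x = (i + 0.5) * spacing
            y = (j + 0.5) * spacing
            if boundary.contains(x, y):
                quadrant.append((x, y))
            j += 1
        i += 1
    pts: list[GridPoint] = []
    # quadrant order NE, NW, SE, SW within each (i, j) shell keeps the
    # numbering stable under regeneration
    coords = []
    for x, y in sorted(quadrant, key=lambda q: (q[1], q[0])):
        coords.extend([(x, y), (-x, y), (x, -y), (-x, -y)])
    # asymmetric boundaries can clip a reflected point; re-check membership
    coords = [(x, y) for x, y in coords if boundary.contains(x, y)]
    pts = [GridPoint(index=k, x=x, y=y) for k, (x, y) in enumerate(coords)]
    return TestGrid(
        name=name,
        points=tuple(pts),
        boundary=boundary,
        notes=f"offset lattice, spacing {spacing} deg",
    )


def _find_met_spacing(boundary: FieldBoundary) -> float:
    for s in np.arange(10.0, 16.0 + 1e-9, 0.05):
        s = round(float(s), 2)
        grid = generate_met_grid(spacing=s, boundary=boundary, name="_scan")
        ys = [p.y for p in grid.points]
        if len(grid) == 160 and ys and max(ys) >= 55.0:
            return s
    raise GridError("no spacing in [10, 16] yields a 160-point grid")


def _esterman_rows() -> list[tuple[float, list[float]]]:
    """Row layout of the 120-point binocular Esterman reconstruction.

    Synthetic stand-in: the published pattern is reproduced structurally
    (120 points over a 150-degree horizontal span, only two points above
    20 degrees superior, 78 inferior vs 42 superior points, density
    increasing toward the centre and the inferior field) rather than
    coordinate-for-coordinate.
    """
    half = {
        30.0: [15.0],
        15.0: [10.0, 25.0, 40.0, 55.0],
        8.0: [6.0, 12.0, 19.0, 28.0, 40.0, 55.0, 70.0],
        3.0: [2.0, 7.0, 13.0, 20.0, 29.0, 39.0, 50.0, 62.0, 75.0],
        -3.0: [2.0, 7.0, 13.0, 20.0, 29.0, 39.0, 50.0, 62.0, 75.0],
        -8.0: [6.0, 12.0, 19.0, 28.0, 40.0, 55.0, 70.0],
        -15.0: [5.0, 12.0, 21.0, 32.0, 45.0, 60.0, 70.0],
        -25.0: [7.0, 16.0, 27.0, 40.0, 55.0, 65.0],
        -35.0: [8.0, 18.0, 30.0, 45.0, 58.0],
        -45.0: [10.0, 22.0, 35.0],
        -55.0: [7.0, 20.0],
    }
    return [(y, sorted({-x for x in xs} | set(xs))) for y, xs in half.items()]


def _build_esterman_grid() -> TestGrid:
    pts: list[GridPoint] = []
    k = 0
    for y, xs in sorted(_esterman_rows(), key=lambda r: -r[0]):
        for x in xs:
            pts.append(GridPoint(index=k, x=x, y=y))
            k += 1
    return TestGrid(
        name="esterman",
        points=tuple(pts),
        boundary=FieldBoundary(),
        notes="synthetic structural reconstruction of the binocular Esterman layout",
    )


# ---------------------------------------------------------------------------
# Fixture registry and CSV interchange
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "met": "met_grid.csv",
    "esterman": "esterman_grid_synthetic.csv",
}


def registered_grids() -> list[str]:
    return sorted(_FIXTURE_FILES)


def load_grid(name: str) -> TestGrid:
    """Load a canonical built-in grid fixture ("met" or "esterman")."""
    if name not in _FIXTURE_FILES:
        raise GridError(
            f"unknown grid {name!r}; registered grids: {', '.join(registered_grids())}"
        )
    ref = resources.files("metperim.data") / _FIXTURE_FILES[name]
    with resources.as_file(ref) as path:
        grid = grid_from_csv(path, name=name)
    return grid


def grid_to_csv(grid: TestGrid, path: str | Path) -> None:
    """Write a grid as `index,x_deg,y_deg` CSV (LF endings, decimal point)."""
    with open(path, "w", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_GRID_CSV_HEADER)
        for p in grid.points:
            writer.writerow([p.index, _fmt(p.x), _fmt(p.y)])


def grid_from_csv(
    path: str | Path, name: str = "custom", boundary: FieldBoundary | None = None
) -> TestGrid:
    points: list[GridPoint] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _GRID_CSV_HEADER:
            raise GridError(f"bad grid CSV header {header!r} in {path}")
        for row_no, row in enumerate(reader, start=2):
            try:
                points.append(
                    GridPoint(index=int(row[0]), x=float(row[1]), y=float(row[2]))
                )
            except (IndexError, ValueError) as exc:
                raise GridError(f"{path}: malformed row {row_no}: {row!r}") from exc
    return TestGrid(name=name, points=tuple(points), boundary=boundary or FieldBoundary())


def _fmt(value: float) -> str:
    return f"{value:.6g}"


# ---------------------------------------------------------------------------
# Grid editing
# ---------------------------------------------------------------------------

def strip_superior_rows(grid: TestGrid, n_rows: int) -> TestGrid:
    """Remove the *n_rows* most superior rows (largest distinct y values).

    The top rows of the mET pattern fall under the upper eyelid in many
    subjects and can be removed without losing information; doing so
    intentionally breaks the grid's symmetry about the x axis, which is
    recorded in the grid metadata.
    """
    distinct_y = sorted({p.y for p in grid.points}, reverse=True)
    if not 0 <= n_rows < len(distinct_y):
        raise GridError(
            f"n_rows must be in [0, {len(distinct_y) - 1}] for this grid"
        )
    if n_rows == 0:
        return grid
    cut = distinct_y[n_rows - 1]
    kept = tuple(p for p in grid.points if p.y < cut)
    return replace(
        grid,
        points=kept,
        notes=(grid.notes + f"; top {n_rows} row(s) removed, x-axis symmetry broken").strip("; "),
    )
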