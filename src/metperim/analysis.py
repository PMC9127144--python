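"""Field analysis: Voronoi tessellation, scoring and severity grading.

The test grid is tessellated into Voronoi cells clipped to the elliptical
field boundary; every point of the field then belongs to the cell of its
nearest test location, so a cell's fill colour reports that location's
outcome directly with no interpolation.  Cell adjacency (shared edges)
defines what counts as a "cluster" of defective locations, and a
four-level ordinal severity grade is derived from the defect map:

* normal — no defective locations;
* mild — some defects, but neither rule below holds;
* moderate — at least two adjacency-connected clusters of at least three
  defects each, with under half the locations missed;
* severe — at least half of the locations missed.

The precedence is severe > moderate > mild, making the classes
exhaustive and mutually exclusive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from .engine import Outcome, TestResult
from .grids import FieldBoundary, TestGrid

__all__ = [
    "VoronoiPartition",
    "DefectCluster",
    "Severity",
    "SeverityGrade",
    "voronoi_partition",
    "percent_seen",
    "find_clusters",
    "classify_severity",
    "grade_averaged",
    "consensus_defects",
    "render_field",
    "estimate_central_scotoma_radius",
]

#: Defect fraction at or above which a field is graded severe.
SEVERE_DEFECT_FRACTION = 0.5
#: Cluster requirements for the moderate grade.
MODERATE_MIN_CLUSTERS = 2
MODERATE_MIN_CLUSTER_SIZE = 3


class AnalysisError(ValueError):
    """Invalid analysis input (degenerate grid, grid/partition mismatch)."""


@dataclass(frozen=True)
class DefectCluster:
    members: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.members)


class Severity(enum.IntEnum):
    """Ordinal disease-severity grade."""

    NORMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Severity":
        return cls[label.upper()]


@dataclass(frozen=True)
class SeverityGrade:
    """A grade together with the evidence it rests on."""

    severity: Severity
    defect_count: int
    percent_seen: float
    cluster_sizes: tuple[int, ...]

    @property
    def label(self) -> str:
        return self.severity.label


@dataclass(frozen=True)
class VoronoiPartition:
    """One clipped polygon per grid point, plus shared-edge adjacency."""

    grid_name: str
    point_indices: tuple[int, ...]
    cells: dict[int, Polygon]  # grid point index → clipped cell
    adjacency: frozenset[frozenset[int]]  # pairs sharing an edge
    boundary: FieldBoundary

    def neighbours(self, index: int) -> set[int]:
        out: set[int] = set()
        for pair in self.adjacency:
            if index in pair:
                out |= pair - {index}
        return out

    def total_area(self) -> float:
        return sum(c.area for c in self.cells.values())


# distance (degrees) of the ghost-point ring used to bound outer cells;
# far enough that ghost ridges never intersect the field boundary
_GHOST_RADIUS = 1e4


def voronoi_partition(
    grid: TestGrid, boundary: FieldBoundary | None = None
) -> VoronoiPartition:
    """Voronoi tessellation of *grid*, clipped to the field boundary.

    A distant ring of ghost generators bounds the outer cells so that
    every real cell is a finite polygon before clipping; two cells are
    adjacent when their clipped polygons share a boundary segment of
    positive length.
    """
    boundary = boundary or grid.boundary
    xy = grid.coordinates()
    if len(xy) < 4:
        raise AnalysisError("Voronoi partition needs at least 4 points")
    if len(np.unique(xy.round(9), axis=0)) != len(xy):
        raise AnalysisError("duplicate grid points are degenerate")
    rank = np.linalg.matrix_rank(xy - xy.mean(axis=0))
    if rank < 2:
        raise AnalysisError("collinear grid points are degenerate")

    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    ghosts = _GHOST_RADIUS * np.column_stack([np.cos(theta), np.sin(theta)])
    vor = Voronoi(np.vstack([xy, ghosts]))

    clip = Polygon(boundary.polygon_vertices())
    cells: dict[int, Polygon] = {}
    for k, point in enumerate(grid.points):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or not region:  # pragma: no cover - ghosts prevent this
            raise AnalysisError(f"unbounded cell for point {point.index}")
        poly = Polygon(vor.vertices[region]).intersection(clip)
        cells[point.index] = poly

    pairs: set[frozenset[int]] = set()
    for (a, b) in vor.ridge_points:
        if a < len(xy) and b < len(xy):
            ia = grid.points[a].index
            ib = grid.points[b].index
            shared = cells[ia].intersection(cells[ib])
            if shared.length > 1e-9:
                pairs.add(frozenset((ia, ib)))
    return VoronoiPartition(
        grid_name=grid.name,
        point_indices=tuple(p.index for p in grid.points),
        cells=cells,
        adjacency=frozenset(pairs),
        boundary=boundary,
    )


def percent_seen(result: TestResult) -> float:
    """Percent of test locations seen (on either presentation)."""
    _require_complete(result)
    return result.percent_seen()


def find_clusters(
    result: TestResult, partition: VoronoiPartition
) -> list[DefectCluster]:
    """Connected components of the defect set under cell adjacency.

    Clusters are returned largest first (ties broken by smallest member
    index) so reports are deterministic.
    """
    _check_match(result, partition)
    defects = result.defect_indices()
    graph = nx.Graph()
    graph.add_nodes_from(defects)
    for pair in partition.adjacency:
        a, b = tuple(pair)
        if a in defects and b in defects:
            graph.add_edge(a, b)
    clusters = [DefectCluster(frozenset(c)) for c in nx.connected_components(graph)]
    return sorted(clusters, key=lambda c: (-c.size, min(c.members)))


def classify_severity(
    result: TestResult, partition: VoronoiPartition
) -> SeverityGrade:
    """Grade a completed run on the four-level ordinal scale."""
    _require_complete(result)
    _check_match(result, partition)
    n = len(result.grid_indices)
    defects = result.defect_indices()
    clusters = find_clusters(result, partition)
    sizes = tuple(c.size for c in clusters)
    pct_seen = 100.0 * (n - len(defects)) / n
    if len(defects) / n >= SEVERE_DEFECT_FRACTION:
        sev = Severity.SEVERE
    elif sum(1 for s in sizes if s >= MODERATE_MIN_CLUSTER_SIZE) >= MODERATE_MIN_CLUSTERS:
        sev = Severity.MODERATE
    elif defects:
        sev = Severity.MILD
    else:
        sev = Severity.NORMAL
    return SeverityGrade(
        severity=sev,
        defect_count=len(defects),
        percent_seen=pct_seen,
        cluster_sizes=sizes,
    )


def consensus_defects(run1: TestResult, run2: TestResult) -> TestResult:
    """Per-location consensus of two runs on the same grid.

    Each location's defect indicator (defect = 1, seen = 0) is averaged
    over the two runs and the location is counted defective when the mean
    is at least one half — i.e. a tie (defective in exactly one run) is
    resolved defective, the conservative choice for safety monitoring.
    """
    if run1.grid_name != run2.grid_name or run1.grid_indices != run2.grid_indices:
        raise AnalysisError("runs are on different grids")
    _require_complete(run1)
    _require_complete(run2)
    d1, d2 = run1.defect_indices(), run2.defect_indices()
    outcomes = {
        i: (Outcome.DEFECT if (int(i in d1) + int(i in d2)) / 2 >= 0.5
            else Outcome.SEEN_FIRST)
        for i in run1.grid_indices
    }
    return TestResult(
        grid_name=run1.grid_name,
        grid_indices=run1.grid_indices,
        outcomes=outcomes,
        presentations=(),
        catch_trials=run1.catch_trials + run2.catch_trials,
        false_positive_responses=run1.false_positive_responses
        + run2.false_positive_responses,
        completed=True,
        seed=run1.seed,
    )


def grade_averaged(
    run1: TestResult, run2: TestResult, partition: VoronoiPartition
) -> SeverityGrade:
    """Grade the consensus of a test–retest pair (averaging the two runs
    absorbs a possible learning effect between them)."""
    return classify_severity(consensus_defects(run1, run2), partition)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def estimate_central_scotoma_radius(result: TestResult, grid: TestGrid) -> float:
    """Estimate a central scotoma's radius from the defect map.

    For a noise-free observer the defect set of a central scotoma of
    radius r is exactly the locations with eccentricity below r; the
    radius is estimated as the midpoint between the outermost defective
    eccentricity and the innermost seen eccentricity, which is within one
    grid spacing of the truth.  Returns 0 when there are no defects.
    """
    _require_complete(result)
    if result.grid_name != grid.name:
        raise AnalysisError("result/grid mismatch")
    defects = result.defect_indices()
    if not defects:
        return 0.0
    ecc = {p.index: p.eccentricity for p in grid.points}
    max_defect = max(ecc[i] for i in defects)
    seen_beyond = [e for i, e in ecc.items() if i not in defects and e > max_defect]
    if not seen_beyond:
        return max_defect
    return 0.5 * (max_defect + min(seen_beyond))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

#: Completed-test palette: light grey seen-first, dark grey seen-on-retest,
#: black defect.  Live palette: green seen, red missed.
FINAL_COLOURS = {
    Outcome.SEEN_FIRST: "#d9d9d9",
    Outcome.SEEN_RETEST: "#7f7f7f",
    Outcome.DEFECT: "#000000",
}
LIVE_COLOURS = {
    Outcome.SEEN_FIRST: "#2ca02c",
    Outcome.SEEN_RETEST: "#2ca02c",
    Outcome.DEFECT: "#d62728",
}


def render_field(
    result: TestResult,
    partition: VoronoiPartition,
    style: str = "final",
    ax=None,
):
    """Draw the outcome map as filled Voronoi cells.

    ``style="final"`` uses the grey-scale completed-test palette;
    ``style="live"`` the green/red in-test palette.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    _require_complete(result)
    _check_match(result, partition)
    palette = FINAL_COLOURS if style == "final" else LIVE_COLOURS
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    for idx in partition.point_indices:
        poly = partition.cells[idx]
        colour = palette[result.outcomes[idx]]
        xs, ys = poly.exterior.xy
        ax.fill(xs, ys, facecolor=colour, edgecolor="white", linewidth=0.5)
    bx = partition.boundary.polygon_vertices()
    ax.plot(
        np.append(bx[:, 0], bx[0, 0]), np.append(bx[:, 1], bx[0, 1]),
        color="black", linewidth=1.0,
    )
    ax.set_aspect("equal")
    ax.set_xlabel("eccentricity (deg), temporal →")
    ax.set_ylabel("eccentricity (deg), superior ↑")
    ax.set_title(f"{result.grid_name} — {result.percent_seen():.1f}% seen")
    return ax


# ---------------------------------------------------------------------------
# Internal checks
# ---------------------------------------------------------------------------

def _require_complete(result: TestResult) -> None:
    if not result.completed or result.missing_indices():
        raise AnalysisError("analysis requires a completed test result")


def _check_match(result: TestResult, partition: VoronoiPartition) -> None:
    if (
        result.grid_name != partition.grid_name
        or tuple(sorted(result.grid_indices)) != tuple(sorted(partition.point_indices))
    ):
        raise AnalysisError(
            f"partition for grid {partition.grid_name!r} does not match "
            f"result on grid {result.grid_name!r}"
        )
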