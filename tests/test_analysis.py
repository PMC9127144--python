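import numpy as np
import pytest

from conftest import grow_cluster, make_result
from metperim.analysis import (
    AnalysisError,
    Severity,
    classify_severity,
    consensus_defects,
    estimate_central_scotoma_radius,
    find_clusters,
    grade_averaged,
    percent_seen,
    render_field,
    voronoi_partition,
)
from metperim.engine import EngineConfig, run_screening
from metperim.grids import FieldBoundary, GridPoint, TestGrid


def bfs_components(defects, adjacency):
    """Independent breadth-first-search oracle for connected components."""
    defects = set(defects)
    adj = {d: set() for d in defects}
    for pair in adjacency:
        a, b = tuple(pair)
        if a in defects and b in defects:
            adj[a].add(b)
            adj[b].add(a)
    components = []
    todo = set(defects)
    while todo:
        start = todo.pop()
        comp = {start}
        queue = [start]
        while queue:
            cur = queue.pop(0)
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        todo -= comp
        components.append(frozenset(comp))
    return set(components)


class TestVoronoiPartition:
    def test_symmetric_four_point_grid(self):
        """Four points at (±10, ±10) split the ellipse into four congruent
        quarter cells, each containing its generator."""
        pts = tuple(
            GridPoint(index=i, x=x, y=y)
            for i, (x, y) in enumerate([(10, 10), (-10, 10), (10, -10), (-10, -10)])
        )
        grid = TestGrid(name="square4", points=pts)
        from shapely.geometry import Point

        part = voronoi_partition(grid)
        areas = [part.cells[i].area for i in range(4)]
        assert areas == pytest.approx([grid.boundary.area() / 4] * 4, rel=1e-3)
        for p in pts:
            assert part.cells[p.index].contains(Point(p.x, p.y))

    def test_cells_contain_generators(self, met_grid, met_partition):
        from shapely.geometry import Point

        for p in met_grid:
            assert met_partition.cells[p.index].distance(Point(p.x, p.y)) == 0.0

    def test_nearest_generator_oracle(self, met_grid, met_partition):
        """Random probe locations land in the cell of their brute-force
        nearest grid point."""
        rng = np.random.default_rng(123)
        xy = met_grid.coordinates()
        from shapely.geometry import Point

        n_checked = 0
        while n_checked < 2000:
            x = rng.uniform(-85, 85)
            y = rng.uniform(-60, 60)
            if not met_grid.boundary.contains(x, y):
                continue
            d = np.hypot(xy[:, 0] - x, xy[:, 1] - y)
            order = np.argsort(d)
            if d[order[1]] - d[order[0]] < 1e-6:  # skip exact bisector ties
                continue
            nearest = met_grid.points[order[0]].index
            assert met_partition.cells[nearest].distance(Point(x, y)) == 0.0
            n_checked += 1

    def test_areas_sum_to_boundary_area(self, met_partition, esterman_partition):
        for part in (met_partition, esterman_partition):
            assert part.total_area() == pytest.approx(
                part.boundary.area(), rel=1e-3
            )

    def test_cell_interiors_disjoint(self, met_partition):
        cells = list(met_partition.cells.values())
        total = sum(c.area for c in cells)
        from shapely.ops import unary_union

        assert unary_union(cells).area == pytest.approx(total, rel=1e-6)

    def test_adjacency_is_shared_edge(self, met_partition):
        for pair in list(met_partition.adjacency)[:50]:
            a, b = tuple(pair)
            shared = met_partition.cells[a].intersection(met_partition.cells[b])
            assert shared.length > 0

    def test_degenerate_grids_rejected(self):
        line = TestGrid(
            name="line",
            points=tuple(GridPoint(index=i, x=5.0 * i - 20, y=0.0) for i in range(5)),
        )
        with pytest.raises(AnalysisError):
            voronoi_partition(line)
        few = TestGrid(
            name="few", points=tuple(GridPoint(index=i, x=i * 10.0, y=i * 5.0) for i in range(3))
        )
        with pytest.raises(AnalysisError):
            voronoi_partition(few)


class TestScoring:
    def test_percent_seen_values(self, met_grid):
        assert percent_seen(make_result(met_grid, [])) == 100.0
        assert percent_seen(make_result(met_grid, range(40))) == 75.0
        assert percent_seen(make_result(met_grid, range(160))) == 0.0

    def test_retest_counts_as_seen(self, met_grid):
        result = make_result(met_grid, [], seen_retest_indices=range(20))
        assert percent_seen(result) == 100.0

    def test_percent_seen_complements_defect_fraction(self, met_grid):
        result = make_result(met_grid, range(37))
        assert percent_seen(result) + 100.0 * 37 / 160 == 100.0


class TestClusters:
    def test_no_defects_no_clusters(self, met_grid, met_partition):
        assert find_clusters(make_result(met_grid, []), met_partition) == []

    def test_three_adjacent_defects_one_cluster(self, met_grid, met_partition):
        members = grow_cluster(met_partition, met_grid.points[0].index, 3)
        clusters = find_clusters(make_result(met_grid, members), met_partition)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(members)

    @pytest.mark.parametrize("seed", range(15))
    def test_components_match_bfs_oracle(self, met_grid, met_partition, seed):
        rng = np.random.default_rng(seed)
        defects = {
            p.index for p in met_grid if rng.random() < rng.uniform(0.05, 0.5)
        }
        clusters = find_clusters(make_result(met_grid, defects), met_partition)
        assert {c.members for c in clusters} == bfs_components(
            defects, met_partition.adjacency
        )
        assert sum(c.size for c in clusters) == len(defects)
        # clusters pairwise non-adjacent
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                for pair in met_partition.adjacency:
                    x, y = tuple(pair)
                    assert not (
                        (x in a.members and y in b.members)
                        or (y in a.members and x in b.members)
                    )

    def test_partition_mismatch_rejected(self, esterman_grid, met_partition):
        with pytest.raises(AnalysisError, match="does not match"):
            find_clusters(make_result(esterman_grid, []), met_partition)


class TestSeverityClassification:
    def test_no_defects_normal(self, met_grid, met_partition):
        grade = classify_severity(make_result(met_grid, []), met_partition)
        assert grade.severity is Severity.NORMAL

    def test_half_missed_is_severe(self, met_grid, met_partition):
        defects = grow_cluster(met_partition, met_grid.points[0].index, 80)
        grade = classify_severity(make_result(met_grid, defects), met_partition)
        assert grade.severity is Severity.SEVERE

    def test_two_clusters_of_three_is_moderate(self, met_grid, met_partition):
        left = {p.index for p in met_grid if p.x < -20}
        right = {p.index for p in met_grid if p.x > 20}
        seed_l = min(left, key=lambda i: met_grid.point_by_index(i).x)
        seed_r = max(right, key=lambda i: met_grid.point_by_index(i).x)
        a = grow_cluster(met_partition, seed_l, 3, allowed=left)
        b = grow_cluster(met_partition, seed_r, 3, allowed=right)
        grade = classify_severity(make_result(met_grid, a | b), met_partition)
        assert grade.severity is Severity.MODERATE
        assert sorted(grade.cluster_sizes) == [3, 3]

    def test_cluster_sizes_three_and_two_is_mild(self, met_grid, met_partition):
        left = {p.index for p in met_grid if p.x < -20}
        right = {p.index for p in met_grid if p.x > 20}
        seed_l = min(left, key=lambda i: met_grid.point_by_index(i).x)
        seed_r = max(right, key=lambda i: met_grid.point_by_index(i).x)
        a = grow_cluster(met_partition, seed_l, 3, allowed=left)
        b = grow_cluster(met_partition, seed_r, 2, allowed=right)
        grade = classify_severity(make_result(met_grid, a | b), met_partition)
        assert grade.severity is Severity.MILD

    def test_scattered_single_defect_is_mild(self, met_grid, met_partition):
        grade = classify_severity(make_result(met_grid, [5]), met_partition)
        assert grade.severity is Severity.MILD

    def test_severe_takes_precedence_over_clusters(self, met_grid, met_partition):
        # 80+ defects always severe no matter the cluster structure
        defects = {p.index for p in met_grid if p.y < 0} | {
            p.index for p in met_grid if p.y > 40
        }
        assert len(defects) >= 80
        grade = classify_severity(make_result(met_grid, defects), met_partition)
        assert grade.severity is Severity.SEVERE

    @pytest.mark.parametrize("seed", range(10))
    def test_adding_a_defect_never_lowers_grade(self, met_grid, met_partition, seed):
        rng = np.random.default_rng(seed)
        indices = [p.index for p in met_grid]
        rng.shuffle(indices)
        defects: set[int] = set()
        prev = Severity.NORMAL
        for idx in indices[:100]:
            defects.add(idx)
            grade = classify_severity(
                make_result(met_grid, defects), met_partition
            ).severity
            assert grade >= prev
            prev = grade


class TestConsensusGrading:
    def test_identical_runs_same_grade(self, met_grid, met_partition):
        defects = grow_cluster(met_partition, met_grid.points[0].index, 10)
        run = make_result(met_grid, defects)
        assert (
            grade_averaged(run, run, met_partition).severity
            is classify_severity(run, met_partition).severity
        )

    def test_two_clean_runs_normal(self, met_grid, met_partition):
        clean = make_result(met_grid, [])
        assert grade_averaged(clean, clean, met_partition).severity is Severity.NORMAL

    def test_tie_resolves_defective(self, met_grid):
        run1 = make_result(met_grid, [7])
        run2 = make_result(met_grid, [])
        consensus = consensus_defects(run1, run2)
        assert consensus.defect_indices() == {7}

    def test_grid_mismatch_rejected(self, met_grid, esterman_grid):
        with pytest.raises(AnalysisError):
            consensus_defects(make_result(met_grid, []), make_result(esterman_grid, []))


class TestScotomaRadiusRecovery:
    @pytest.mark.parametrize("radius", [8.0, 16.0, 24.0, 33.0, 41.0])
    def test_recovery_within_one_grid_spacing(self, met_grid, radius):
        from metperim.responder import FieldModel, ScotomaSpec

        model = FieldModel(scotomata=(ScotomaSpec(kind="central", outer_radius=radius),))

        class Det:
            def respond(self, stim):
                return (not stim.is_catch) and model.sensitivity(
                    stim.location.x, stim.location.y
                ) > stim.level_db

        result = run_screening(met_grid, Det(), EngineConfig(seed=1))
        estimate = estimate_central_scotoma_radius(result, met_grid)
        assert abs(estimate - radius) <= 10.0  # one lattice spacing

    def test_no_defects_zero_radius(self, met_grid):
        assert estimate_central_scotoma_radius(make_result(met_grid, []), met_grid) == 0.0


class TestRendering:
    def test_cell_colours_match_outcome_multiset(self, met_grid, met_partition):
        import matplotlib

        matplotlib.use("Agg")
        from matplotlib.colors import to_hex

        defects = set(range(10))
        retests = set(range(20, 35))
        result = make_result(met_grid, defects, seen_retest_indices=retests)
        ax = render_field(result, met_partition)
        fills = [
            to_hex(patch.get_facecolor()) for patch in ax.patches
        ]
        assert fills.count("#000000") == 10
        assert fills.count("#7f7f7f") == 15
        assert fills.count("#d9d9d9") == 160 - 25
        import matplotlib.pyplot as plt

        plt.close(ax.figure)

    def test_rendering_deterministic(self, met_grid, met_partition, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        result = make_result(met_grid, range(30))
        paths = []
        for name in ("a.png", "b.png"):
            ax = render_field(result, met_partition)
            p = tmp_path / name
            ax.figure.savefig(p, dpi=60)
            plt.close(ax.figure)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
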