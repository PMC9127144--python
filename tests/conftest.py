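import pytest

from metperim.analysis import voronoi_partition
from metperim.engine import Outcome, TestResult
from metperim.grids import load_grid


@pytest.fixture(scope="session")
def met_grid():
    return load_grid("met")


@pytest.fixture(scope="session")
def esterman_grid():
    return load_grid("esterman")


@pytest.fixture(scope="session")
def met_partition(met_grid):
    return voronoi_partition(met_grid)


@pytest.fixture(scope="session")
def esterman_partition(esterman_grid):
    return voronoi_partition(esterman_grid)


def make_result(grid, defect_indices, seen_retest_indices=()):
    """Synthetic completed TestResult with a prescribed outcome map."""
    defect_indices = set(defect_indices)
    seen_retest_indices = set(seen_retest_indices)
    outcomes = {}
    for p in grid.points:
        if p.index in defect_indices:
            outcomes[p.index] = Outcome.DEFECT
        elif p.index in seen_retest_indices:
            outcomes[p.index] = Outcome.SEEN_RETEST
        else:
            outcomes[p.index] = Outcome.SEEN_FIRST
    return TestResult(
        grid_name=grid.name,
        grid_indices=tuple(p.index for p in grid.points),
        outcomes=outcomes,
        presentations=(),
        catch_trials=0,
        false_positive_responses=0,
        completed=True,
        seed=0,
    )


def grow_cluster(partition, start_index, size, allowed=None):
    """Deterministic BFS-ordered connected defect set of a given size."""
    allowed = set(partition.point_indices) if allowed is None else set(allowed)
    members = [start_index]
    seen = {start_index}
    frontier = [start_index]
    while len(members) < size and frontier:
        current = frontier.pop(0)
        for nb in sorted(partition.neighbours(current)):
            if nb in allowed and nb not in seen:
                seen.add(nb)
                members.append(nb)
                frontier.append(nb)
                if len(members) == size:
                    break
    if len(members) < size:
        raise AssertionError(f"could not grow a cluster of size {size}")
    return set(members)
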