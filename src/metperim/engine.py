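"""The suprathreshold screening algorithm.

Both paradigms share one loop: every grid location is presented once at a
fixed 10 dB suprathreshold level in seeded-random order with catch trials
interleaved; locations missed on the first pass are re-presented (again
in seeded-random order), and a location is recorded as a defect only if
the retest is also missed.  Seen-on-retest is kept as a distinct outcome
so a location seen once and missed once is reported as such.

The engine is responder-agnostic: anything with a
``respond(stim: StimulusSpec) -> bool`` method can sit behind it, which
is the hook point a hardware driver would implement.  A responder may
raise :class:`ResponderInterrupt` to pause or cancel mid-test, yielding a
partial result with ``completed=False``.

All randomness (presentation order, catch-trial positions) comes from a
single seeded generator, so a run is fully reproducible given the seed
and a deterministic responder.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Protocol

import numpy as np

from .grids import DEFAULT_LEVEL_DB, GridPoint, StimulusSpec, TestGrid

__all__ = [
    "Outcome",
    "EngineConfig",
    "PresentationRecord",
    "TestResult",
    "SummaryCounts",
    "ResponderInterrupt",
    "run_screening",
    "event_stream",
    "summarise",
    "default_goldmann_size",
]

#: Catch trials per scheduled stimulus presentation.
CATCH_TRIAL_FREQUENCY = 0.1


class ResponderInterrupt(RuntimeError):
    """Raised by a responder to pause or cancel the examination."""


class Responder(Protocol):
    def respond(self, stim: StimulusSpec) -> bool: ...


class Outcome(enum.Enum):
    """Per-location three-state outcome of a completed screening run."""

    SEEN_FIRST = "seen_first"
    SEEN_RETEST = "seen_retest"
    DEFECT = "defect"


def default_goldmann_size(grid_name: str) -> int:
    """Paradigm convention: Esterman uses Goldmann III, mET Goldmann V."""
    return 3 if grid_name == "esterman" else 5


@dataclass(frozen=True)
class EngineConfig:
    level_db: float = DEFAULT_LEVEL_DB
    goldmann_size: int | None = None  # None → paradigm default for the grid
    seed: int = 0
    catch_frequency: float = CATCH_TRIAL_FREQUENCY

    def __post_init__(self) -> None:
        if not 0.0 <= self.catch_frequency < 1.0:
            raise ValueError("catch_frequency must lie in [0, 1)")


@dataclass(frozen=True)
class PresentationRecord:
    """One row of the examination log."""

    order: int
    location: GridPoint | None
    level_db: float
    goldmann_size: int
    seen: bool
    is_catch: bool
    pass_number: int

    def __post_init__(self) -> None:
        if self.is_catch and self.location is not None:
            raise ValueError("catch trials carry no location")


@dataclass(frozen=True)
class TestResult:
    """Outcome map plus the full presentation log for one run."""

    __test__ = False  # not a pytest class despite the clinical name

    grid_name: str
    grid_indices: tuple[int, ...]  # every location the run was to test
    outcomes: dict[int, Outcome]  # grid point index → outcome
    presentations: tuple[PresentationRecord, ...]
    catch_trials: int
    false_positive_responses: int
    completed: bool
    seed: int

    @property
    def false_positive_rate(self) -> float:
        if self.catch_trials == 0:
            return 0.0
        return self.false_positive_responses / self.catch_trials

    @property
    def flagged_unreliable(self) -> bool:
        """True when the catch-trial false-positive rate exceeds 20%."""
        return self.false_positive_rate > 0.20

    def defect_indices(self) -> set[int]:
        return {i for i, o in self.outcomes.items() if o is Outcome.DEFECT}

    def missing_indices(self) -> list[int]:
        return sorted(set(self.grid_indices) - set(self.outcomes))

    def percent_seen(self) -> float:
        seen = sum(1 for o in self.outcomes.values() if o is not Outcome.DEFECT)
        return 100.0 * seen / len(self.grid_indices)


class SummaryCounts(NamedTuple):
    failed_false_positives: int
    seen_first: int
    seen_retest: int
    defects: int


def _interleave_catches(
    n_stimuli: int, frequency: float, rng: np.random.Generator
) -> list[bool]:
    """Schedule: True = catch trial, at `frequency` per scheduled stimulus,
    positions seeded-random within the pass."""
    n_catch = int(round(n_stimuli * frequency))
    flags = [False] * n_stimuli + [True] * n_catch
    rng.shuffle(flags)
    return flags


def run_screening(
    grid: TestGrid, responder: Responder, cfg: EngineConfig | None = None
) -> TestResult:
    """Run the two-pass suprathreshold screening test.

    Pass 1 presents every location exactly once; pass 2 re-presents only
    the locations missed on pass 1, after pass 1 completes, in an
    independently shuffled order.  Catch trials (no stimulus) are
    interleaved in both passes; a "seen" answer to one counts as a false
    positive.  A :class:`ResponderInterrupt` anywhere yields a partial
    result with the outcomes accumulated so far and ``completed=False``.
    """
    cfg = cfg or EngineConfig()
    size = (
        cfg.goldmann_size
        if cfg.goldmann_size is not None
        else default_goldmann_size(grid.name)
    )
    rng = np.random.default_rng(cfg.seed)

    outcomes: dict[int, Outcome] = {}
    records: list[PresentationRecord] = []
    catch_trials = 0
    false_positives = 0
    order = 0
    completed = True

    def present(point: GridPoint | None, pass_number: int) -> bool:
        nonlocal order, catch_trials, false_positives
        stim = StimulusSpec(goldmann_size=size, level_db=cfg.level_db, location=point)
        seen = bool(responder.respond(stim))
        records.append(
            PresentationRecord(
                order=order,
                location=point,
                level_db=cfg.level_db,
                goldmann_size=size,
                seen=seen,
                is_catch=point is None,
                pass_number=pass_number,
            )
        )
        order += 1
        if point is None:
            catch_trials += 1
            if seen:
                false_positives += 1
        return seen

    first_pass = list(grid.points)
    rng.shuffle(first_pass)
    missed: list[GridPoint] = []
    try:
        schedule = iter(first_pass)
        for is_catch in _interleave_catches(len(first_pass), cfg.catch_frequency, rng):
            if is_catch:
                present(None, 1)
            else:
                point = next(schedule)
                if present(point, 1):
                    outcomes[point.index] = Outcome.SEEN_FIRST
                else:
                    missed.append(point)

        retest = list(missed)
        rng.shuffle(retest)
        schedule = iter(retest)
        for is_catch in _interleave_catches(len(retest), cfg.catch_frequency, rng):
            if is_catch:
                present(None, 2)
            else:
                point = next(schedule)
                outcomes[point.index] = (
                    Outcome.SEEN_RETEST if present(point, 2) else Outcome.DEFECT
                )
    except ResponderInterrupt:
        completed = False

    return TestResult(
        grid_name=grid.name,
        grid_indices=tuple(p.index for p in grid.points),
        outcomes=outcomes,
        presentations=tuple(records),
        catch_trials=catch_trials,
        false_positive_responses=false_positives,
        completed=completed,
        seed=cfg.seed,
    )


def event_stream(result: TestResult) -> Iterator[tuple[str, object]]:
    """Replay a run as an ordered event stream.

    Yields ``("stimulus", record)`` or ``("catch", record)`` per
    presentation in log order, with a ``("pass-complete", n)`` marker
    after each pass; consumers (live renderer, log writer) each receive
    every presentation record exactly once, in order.
    """
    current_pass = None
    for rec in result.presentations:
        if current_pass is not None and rec.pass_number != current_pass:
            yield ("pass-complete", current_pass)
        current_pass = rec.pass_number
        yield (("catch" if rec.is_catch else "stimulus"), rec)
    if current_pass is not None:
        yield ("pass-complete", current_pass)


def summarise(result: TestResult) -> SummaryCounts:
    """Summary counts for a completed run.

    Returns (failed false positives, seen first try, seen on retest,
    defects); the last three always sum to the grid size.
    """
    if not result.completed or result.missing_indices():
        missing = result.missing_indices()
        raise ValueError(
            f"cannot summarise an incomplete run; missing locations "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    counts = {o: 0 for o in Outcome}
    for o in result.outcomes.values():
        counts[o] += 1
    return SummaryCounts(
        failed_false_positives=result.false_positive_responses,
        seen_first=counts[Outcome.SEEN_FIRST],
        seen_retest=counts[Outcome.SEEN_RETEST],
        defects=counts[Outcome.DEFECT],
    )
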