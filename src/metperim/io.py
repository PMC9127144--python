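"""File formats and configuration.

A completed run is persisted as a :class:`RunBundle`: a per-presentation
log CSV (`order,x_deg,y_deg,goldmann_size,level_db,is_catch,pass,seen`,
catch rows with empty coordinates), a one-row summary CSV
(`failed_false_positives,seen_first,seen_retest,defects`), a field-map
image, and a JSON snapshot of the configuration and seed.  Reading the
log back reconstructs a :class:`~metperim.engine.TestResult` identical
to the in-memory one, and writers are byte-stable for fixed inputs
(fixed float format, LF endings, sorted JSON keys).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field

from .engine import (
    Outcome,
    PresentationRecord,
    SummaryCounts,
    TestResult,
    summarise,
)
from .grids import GridError, TestGrid

__all__ = [
    "RunBundle",
    "RunConfig",
    "write_run",
    "read_run",
    "read_log",
    "write_log",
    "write_summary",
    "read_summary",
    "load_config",
    "FormatError",
]

logger = logging.getLogger("metperim")

LOG_HEADER = ["order", "x_deg", "y_deg", "goldmann_size", "level_db", "is_catch", "pass", "seen"]
SUMMARY_HEADER = ["failed_false_positives", "seen_first", "seen_retest", "defects"]
FORMAT_VERSION = 1


class FormatError(ValueError):
    """Malformed file content."""


# ---------------------------------------------------------------------------
# Configuration (CLI flag > config file > built-in default)
# ---------------------------------------------------------------------------

class GridConfig(BaseModel):
    name: str = "met"
    strip_superior_rows: int = 0


class ResponderSettings(BaseModel):
    fp_rate: float = 0.03
    fn_rate: float = 0.03
    slope_db: float = 2.0


class CohortConfig(BaseModel):
    seed: int = 0
    counts: dict[str, dict[str, int]] | None = None


class RunConfig(BaseModel):
    """Structured configuration accepted by every CLI workflow."""

    grid: GridConfig = Field(default_factory=GridConfig)
    responder: ResponderSettings = Field(default_factory=ResponderSettings)
    cohort: CohortConfig = Field(default_factory=CohortConfig)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; None yields built-in defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


# ---------------------------------------------------------------------------
# Log / summary CSV
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    return f"{value:.6g}"


def write_log(result: TestResult, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LOG_HEADER)
        for rec in result.presentations:
            writer.writerow(
                [
                    rec.order,
                    "" if rec.is_catch else _fmt(rec.location.x),
                    "" if rec.is_catch else _fmt(rec.location.y),
                    rec.goldmann_size,
                    _fmt(rec.level_db),
                    int(rec.is_catch),
                    rec.pass_number,
                    int(rec.seen),
                ]
            )


def read_log(path: str | Path, grid: TestGrid) -> TestResult:
    """Rebuild a TestResult from a log CSV and the grid it was run on.

    Locations are matched to grid points by coordinates; outcomes are
    re-derived from the pass-1/pass-2 seen flags, so read∘write is the
    identity on the outcome map, presentations and catch statistics.
    """
    by_coord = {(round(p.x, 4), round(p.y, 4)): p for p in grid.points}
    records: list[PresentationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != LOG_HEADER:
            raise FormatError(f"bad log header {header!r} in {path}")
        for row_no, row in enumerate(reader, start=2):
            try:
                is_catch = bool(int(row[5]))
                if is_catch:
                    location = None
                else:
                    key = (round(float(row[1]), 4), round(float(row[2]), 4))
                    location = by_coord.get(key)
                    if location is None:
                        raise FormatError(
                            f"{path}: row {row_no}: location {key} not in grid "
                            f"{grid.name!r}"
                        )
                records.append(
                    PresentationRecord(
                        order=int(row[0]),
                        location=location,
                        goldmann_size=int(row[3]),
                        level_db=float(row[4]),
                        is_catch=is_catch,
                        pass_number=int(row[6]),
                        seen=bool(int(row[7])),
                    )
                )
            except FormatError:
                raise
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed row {row_no}: {row!r}") from exc

    outcomes: dict[int, Outcome] = {}
    for rec in records:
        if rec.is_catch:
            continue
        idx = rec.location.index
        if rec.pass_number == 1:
            if rec.seen:
                outcomes[idx] = Outcome.SEEN_FIRST
        else:
            outcomes[idx] = Outcome.SEEN_RETEST if rec.seen else Outcome.DEFECT
    catch = sum(1 for r in records if r.is_catch)
    fps = sum(1 for r in records if r.is_catch and r.seen)
    grid_indices = tuple(p.index for p in grid.points)
    return TestResult(
        grid_name=grid.name,
        grid_indices=grid_indices,
        outcomes=outcomes,
        presentations=tuple(records),
        catch_trials=catch,
        false_positive_responses=fps,
        completed=len(outcomes) == len(grid_indices),
        seed=-1,  # unknown from the log alone; restored from the bundle config
    )


def write_summary(result: TestResult, path: str | Path) -> None:
    counts = summarise(result)
    with open(path, "w", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SUMMARY_HEADER)
        writer.writerow(list(counts))


def read_summary(path: str | Path) -> SummaryCounts:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != SUMMARY_HEADER:
            raise FormatError(f"bad summary header {header!r} in {path}")
        row = next(reader, None)
        if row is None:
            raise FormatError(f"{path}: missing summary row")
        try:
            return SummaryCounts(*(int(v) for v in row))
        except ValueError as exc:
            raise FormatError(f"{path}: malformed summary row {row!r}") from exc


# ---------------------------------------------------------------------------
# Run bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunBundle:
    log_path: Path
    summary_path: Path
    image_path: Path | None
    config_path: Path
    seed: int


def write_run(
    result: TestResult,
    out_dir: str | Path,
    grid: TestGrid,
    config: dict[str, Any] | None = None,
    image: bool = True,
    image_format: str = "png",
) -> RunBundle:
    """Persist a completed run: log CSV, summary CSV, field map, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{result.grid_name}_seed{result.seed}"
    log_path = out / f"{stem}_log.csv"
    summary_path = out / f"{stem}_summary.csv"
    config_path = out / f"{stem}_config.json"
    write_log(result, log_path)
    write_summary(result, summary_path)
    snapshot = {
        "format_version": FORMAT_VERSION,
        "grid": result.grid_name,
        "seed": result.seed,
        "config": config or {},
    }
    config_path.write_text(json.dumps(snapshot, sort_keys=True, indent=2) + "\n")

    image_path: Path | None = None
    if image:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .analysis import render_field, voronoi_partition

        image_path = out / f"{stem}_field.{image_format}"
        ax = render_field(result, voronoi_partition(grid))
        ax.figure.savefig(image_path, dpi=120)
        plt.close(ax.figure)
    logger.info("wrote run bundle to %s", out)
    return RunBundle(
        log_path=log_path,
        summary_path=summary_path,
        image_path=image_path,
        config_path=config_path,
        seed=result.seed,
    )


def read_run(bundle: RunBundle | str | Path, grid: TestGrid) -> TestResult:
    """Reconstruct the TestResult from a bundle (or a log CSV path)."""
    if isinstance(bundle, RunBundle):
        log_path = bundle.log_path
        seed = bundle.seed
        snapshot = json.loads(Path(bundle.config_path).read_text())
        if snapshot.get("format_version") != FORMAT_VERSION:
            logger.warning(
                "bundle format version %s differs from current %s",
                snapshot.get("format_version"),
                FORMAT_VERSION,
            )
    else:
        log_path = Path(bundle)
        seed = -1
    result = read_log(log_path, grid)
    return TestResult(
        grid_name=result.grid_name,
        grid_indices=result.grid_indices,
        outcomes=result.outcomes,
        presentations=result.presentations,
        catch_trials=result.catch_trials,
        false_positive_responses=result.false_positive_responses,
        completed=result.completed,
        seed=seed,
    )
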