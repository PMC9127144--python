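"""Simulated observers for suprathreshold perimetry.

A :class:`FieldModel` describes a subject's binocular sensitivity surface
in dB: a "hill of vision" (peak at fixation falling off linearly with
eccentricity) on which scotomata and an optional superior eyelid artifact
are superimposed.  :class:`SimulatedResponder` turns that surface into
seen/not-seen answers through a frequency-of-seeing psychometric function
(cumulative Gaussian on the dB axis) contaminated by false-positive and
false-negative response noise.

Disease phenotypes mirror the two inherited retinal dystrophies the test
was designed around: choroideremia (rod-cone dystrophy; progressive
peripheral loss with a preserved central island) and Stargardt disease
(cone-rod dystrophy; central scotoma).  :func:`generate_cohort` builds a
seeded synthetic study population whose default composition is 19
choroideremia, 17 Stargardt and 26 control subjects (62 in total) with
the severity splits 6/8/5 and 3/8/6.

dB here is attenuation relative to an abstract instrument maximum;
nothing in the screening algorithm needs luminance units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grids import GridPoint, StimulusSpec


def _phi(z: float) -> float:
    """Standard normal CDF (scalar, via erf: cheap in the response loop)."""
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))

__all__ = [
    "ScotomaSpec",
    "FieldModel",
    "ResponderConfig",
    "SimulatedResponder",
    "AlwaysSeenResponder",
    "NeverSeenResponder",
    "Subject",
    "sensitivity_at",
    "make_phenotype",
    "generate_cohort",
    "DEFAULT_COHORT_COUNTS",
    "SEVERITY_RADIUS_RANGES",
]


class PhenotypeError(ValueError):
    """Invalid phenotype or responder configuration."""


@dataclass(frozen=True)
class ScotomaSpec:
    """A rotationally defined region of reduced or absent sensitivity.

    kind "central" covers eccentricities below ``outer_radius``;
    "peripheral_ring" covers eccentricities between ``inner_radius`` and
    ``outer_radius`` (use ``math.inf`` for an unbounded ring, i.e. loss of
    everything outside a preserved central island); "sector" restricts a
    ring to a wedge of polar angles.  ``depth_db = math.inf`` models an
    absolute scotoma.
    """

    kind: str
    inner_radius: float = 0.0
    outer_radius: float = math.inf
    depth_db: float = math.inf
    angle_start_deg: float = 0.0
    angle_end_deg: float = 360.0

    def __post_init__(self) -> None:
        if self.kind not in ("central", "peripheral_ring", "sector"):
            raise PhenotypeError(f"unknown scotoma kind {self.kind!r}")
        if self.inner_radius > self.outer_radius:
            raise PhenotypeError("inner_radius must not exceed outer_radius")
        if self.depth_db < 0:
            raise PhenotypeError("depth_db must be non-negative")

    def covers(self, x: float, y: float) -> bool:
        ecc = math.hypot(x, y)
        if self.kind == "central":
            return ecc <= self.outer_radius
        if not self.inner_radius <= ecc <= self.outer_radius:
            return False
        if self.kind == "peripheral_ring":
            return True
        angle = math.degrees(math.atan2(y, x)) % 360.0
        lo = self.angle_start_deg % 360.0
        hi = self.angle_end_deg % 360.0
        if lo <= hi:
            return lo <= angle <= hi
        return angle >= lo or angle <= hi


@dataclass(frozen=True)
class FieldModel:
    """A sensitivity surface (dB) over the binocular field.

    Baseline sensitivity is ``max(0, peak − slope·eccentricity)``; the
    deepest scotoma covering a location is then subtracted, and locations
    above ``eyelid_cut_y`` (a ptosis/lid artifact) are fully masked.
    """

    baseline_peak_db: float = 30.0
    eccentricity_slope_db_per_deg: float = 0.1
    scotomata: tuple[ScotomaSpec, ...] = ()
    eyelid_cut_y: float | None = None
    label: str = ""

    def sensitivity(self, x: float, y: float) -> float:
        base = max(
            0.0,
            self.baseline_peak_db
            - self.eccentricity_slope_db_per_deg * math.hypot(x, y),
        )
        depth = max(
            (s.depth_db for s in self.scotomata if s.covers(x, y)), default=0.0
        )
        sens = 0.0 if math.isinf(depth) else max(0.0, base - depth)
        if self.eyelid_cut_y is not None and y > self.eyelid_cut_y:
            sens = 0.0
        return sens


def sensitivity_at(model: FieldModel, point: GridPoint) -> float:
    """Sensitivity in dB of *model* at a grid location."""
    return model.sensitivity(point.x, point.y)


@dataclass(frozen=True)
class ResponderConfig:
    """Response-noise parameters of a simulated observer.

    ``psychometric_slope_db`` is the spread of the cumulative-Gaussian
    frequency-of-seeing curve; small slopes approach a deterministic
    threshold observer.
    """

    fp_rate: float = 0.03
    fn_rate: float = 0.03
    psychometric_slope_db: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp_rate <= 1.0 and 0.0 <= self.fn_rate <= 1.0):
            raise PhenotypeError("fp_rate and fn_rate must lie in [0, 1]")
        if self.fp_rate + self.fn_rate >= 1.0:
            raise PhenotypeError("fp_rate + fn_rate must be < 1")
        if self.psychometric_slope_db <= 0:
            raise PhenotypeError("psychometric slope must be positive")


class SimulatedResponder:
    """Answers stimulus presentations from a field model.

    P(seen) = fp + (1 − fp − fn) · Φ((sensitivity − level) / slope);
    a catch trial (no stimulus) is answered "seen" with probability fp.
    Draws come from a private seeded stream, so a fixed (model, config,
    presentation sequence) triple reproduces the identical response
    sequence.
    """

    def __init__(self, model: FieldModel, cfg: ResponderConfig | None = None):
        self.model = model
        self.cfg = cfg or ResponderConfig()
        self._rng = np.random.default_rng(self.cfg.seed)

    def p_seen(self, stim: StimulusSpec) -> float:
        cfg = self.cfg
        if stim.is_catch:
            return cfg.fp_rate
        sens = sensitivity_at(self.model, stim.location)
        z = (sens - stim.level_db) / cfg.psychometric_slope_db
        return cfg.fp_rate + (1.0 - cfg.fp_rate - cfg.fn_rate) * _phi(z)

    def respond(self, stim: StimulusSpec) -> bool:
        return bool(self._rng.random() < self.p_seen(stim))


class AlwaysSeenResponder:
    """Perfect observer: sees every stimulus, never a false positive."""

    def respond(self, stim: StimulusSpec) -> bool:
        return not stim.is_catch


class NeverSeenResponder:
    """Blind observer: sees nothing, never a false positive."""

    def respond(self, stim: StimulusSpec) -> bool:
        return False


# ---------------------------------------------------------------------------
# Phenotypes and cohorts
# ---------------------------------------------------------------------------

#: Severity → radius range (degrees) for the defining scotoma of each
#: disease group.  For choroideremia the radius is the preserved central
#: island (smaller island = worse disease); for Stargardt it is the
#: central scotoma (larger scotoma = worse disease).  Calibration
#: constants for internally consistent grading, not anatomical claims.
SEVERITY_RADIUS_RANGES: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "choroideremia": {"mild": (45.0, 58.0), "moderate": (25.0, 40.0), "severe": (5.0, 15.0)},
    "stargardt": {"mild": (5.0, 17.0), "moderate": (20.0, 35.0), "severe": (40.0, 60.0)},
}

#: Default study composition: 62 subjects.
DEFAULT_COHORT_COUNTS: Mapping[str, Mapping[str, int]] = {
    "choroideremia": {"mild": 6, "moderate": 8, "severe": 5},
    "stargardt": {"mild": 3, "moderate": 8, "severe": 6},
    "control": {"normal": 26},
}

#: QC bound on the catch-trial false-positive rate.
MAX_FP_RATE = 0.20


def make_phenotype(group: str, severity: str, seed: int) -> FieldModel:
    """Build a seeded sensitivity surface for a study group and severity.

    choroideremia → absolute peripheral-ring scotoma outside a preserved
    central island whose radius is drawn from a severity-dependent range;
    stargardt → absolute central scotoma with a severity-dependent radius;
    control → no scotomata (severity must be "normal").
    """
    rng = np.random.default_rng(seed)
    if group == "control":
        if severity != "normal":
            raise PhenotypeError("control subjects only take severity 'normal'")
        return FieldModel(label=f"control/normal/{seed}")
    try:
        lo, hi = SEVERITY_RADIUS_RANGES[group][severity]
    except KeyError:
        raise PhenotypeError(
            f"invalid group/severity combination {group!r}/{severity!r}"
        ) from None
    radius = float(rng.uniform(lo, hi))
    if group == "choroideremia":
        scotoma = ScotomaSpec(kind="peripheral_ring", inner_radius=radius)
    else:
        scotoma = ScotomaSpec(kind="central", outer_radius=radius)
    return FieldModel(scotomata=(scotoma,), label=f"{group}/{severity}/{seed}")


@dataclass(frozen=True)
class Subject:
    """One simulated participant: identity, phenotype and response noise."""

    subject_id: str
    group: str
    severity: str
    model: FieldModel
    responder_cfg: ResponderConfig

    def responder(self) -> SimulatedResponder:
        return SimulatedResponder(self.model, self.responder_cfg)


def generate_cohort(
    counts: Mapping[str, Mapping[str, int]] | None = None,
    seed: int = 0,
    fp_rate: float = 0.03,
    fn_rate: float = 0.03,
    psychometric_slope_db: float = 2.0,
) -> list[Subject]:
    """Generate a reproducible synthetic cohort.

    Per-subject seeds are spawned from the master *seed* via
    ``numpy.random.SeedSequence`` so any sub-cohort is stable under
    changes elsewhere in the composition mapping.  Configurations whose
    false-positive rate exceeds the 20% QC bound are rejected, mirroring
    the compliance screen applied to real participants.
    """
    counts = counts if counts is not None else DEFAULT_COHORT_COUNTS
    if fp_rate > MAX_FP_RATE:
        raise PhenotypeError(
            f"false-positive rate {fp_rate} exceeds the QC bound {MAX_FP_RATE}"
        )
    total = sum(int(n) for sev in counts.values() for n in sev.values())
    if any(int(n) < 0 for sev in counts.values() for n in sev.values()):
        raise PhenotypeError("cohort counts must be non-negative")
    children = np.random.SeedSequence(seed).spawn(max(total, 1))
    subjects: list[Subject] = []
    k = 0
    for group in sorted(counts):
        for severity in sorted(counts[group]):
            for _ in range(int(counts[group][severity])):
                sub_seed = int(children[k].generate_state(1)[0] % (2**31))
                model = make_phenotype(group, severity, sub_seed)
                cfg = ResponderConfig(
                    fp_rate=fp_rate,
                    fn_rate=fn_rate,
                    psychometric_slope_db=psychometric_slope_db,
                    seed=sub_seed,
                )
                subjects.append(
                    Subject(
                        subject_id=f"{group[:3]}-{severity[:3]}-{k:03d}",
                        group=group,
                        severity=severity,
                        model=model,
                        responder_cfg=cfg,
                    )
                )
                k += 1
    return subjects
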