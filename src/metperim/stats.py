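"""Agreement and repeatability statistics.

Three standard biostatistical tools compare two graded or scored tests:

* **Weighted kappa** — chance-corrected agreement for ordinal grades,
  κ_w = 1 − Σ w_ij·p_ij / Σ w_ij·e_ij with disagreement weights
  w_ij = |i−j|/(k−1) (linear, default) or (|i−j|/(k−1))² (quadratic) and
  expected proportions e_ij from the marginal products.  The 95% CI uses
  the large-sample (Fleiss–Cohen–Everitt) standard error, with a seeded
  bootstrap available as an alternative.
* **Bland–Altman** — mean difference (bias) and 1.96·SD limits of
  agreement on paired percent-seen scores, restricted to pairs whose
  mean lies inside a band (default 20–80%), since scores pile up at the
  floor and ceiling where differences are structurally compressed.
* **Repeatability coefficient** — 1.96·√2·s_w with s_w² = Σd_i²/(2n) for
  test–retest differences d_i: the value below which 95% of absolute
  test–retest differences are expected to fall.

The difference sign convention is Esterman − mET throughout, so a
positive bias means the even-coverage mET paradigm records more field
loss (a lower percent seen) than the inferior-weighted Esterman.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .analysis import Severity

__all__ = [
    "KappaResult",
    "BlandAltmanResult",
    "RepeatabilityResult",
    "weighted_kappa",
    "kappa_interpretation",
    "bland_altman",
    "repeatability_coefficient",
    "paired_defect_excess",
    "DefectExcessSummary",
]

DEFAULT_BAND = (20.0, 80.0)


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass(frozen=True)
class KappaResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    weights: str
    degenerate: bool = False  # single category with zero expected disagreement

    @property
    def interpretation(self) -> str:
        return kappa_interpretation(self.estimate)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_included: int
    n_excluded: int
    band: tuple[float, float]


@dataclass(frozen=True)
class RepeatabilityResult:
    coefficient: float
    within_subject_sd: float
    n: int


def kappa_interpretation(estimate: float) -> str:
    """Conventional verbal banding of a kappa estimate."""
    if estimate < 0.0:
        return "poor"
    if estimate <= 0.20:
        return "poor"
    if estimate <= 0.40:
        return "fair"
    if estimate <= 0.60:
        return "moderate"
    if estimate <= 0.80:
        return "substantial"
    return "almost perfect"


def _as_levels(ratings: Sequence) -> np.ndarray:
    out = []
    for r in ratings:
        if isinstance(r, Severity):
            out.append(int(r))
        elif isinstance(r, str):
            out.append(int(Severity.from_label(r)))
        else:
            out.append(int(r))
    arr = np.asarray(out, dtype=int)
    if arr.min() < 0 or arr.max() > 3:
        raise StatsError("grades must lie on the 4-level ordinal scale 0..3")
    return arr


def weighted_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    weights: str = "linear",
    ci_method: str = "asymptotic",
    n_boot: int = 2000,
    seed: int = 0,
    n_categories: int = 4,
) -> KappaResult:
    """Weighted kappa between two raters of ordinal severity grades.

    Ratings may be :class:`~metperim.analysis.Severity` values, their
    lower-case labels, or integer levels 0..3.  ``ci_method`` is
    "asymptotic" (default) or "bootstrap" (seeded percentile bootstrap).
    """
    a = _as_levels(ratings_a)
    b = _as_levels(ratings_b)
    if len(a) != len(b):
        raise StatsError("rating vectors must have equal length")
    if len(a) < 2:
        raise StatsError("need at least 2 rating pairs")
    if weights not in ("linear", "quadratic"):
        raise StatsError("weights must be 'linear' or 'quadratic'")

    k = n_categories
    n = len(a)
    table = np.zeros((k, k))
    np.add.at(table, (a, b), 1.0)
    p = table / n
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    ij = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    w_dis = ij if weights == "linear" else ij**2  # disagreement weights
    e = np.outer(pa, pb)

    expected_dis = float((w_dis * e).sum())
    observed_dis = float((w_dis * p).sum())
    if expected_dis == 0.0:
        # both raters used a single category: agreement is perfect but
        # chance correction is undefined; report κ=1 with a degenerate CI
        return KappaResult(1.0, 1.0, 1.0, n, weights, degenerate=True)
    kappa = 1.0 - observed_dis / expected_dis

    if ci_method == "asymptotic":
        se = _kappa_asymptotic_se(p, pa, pb, 1.0 - w_dis, n)
        z = norm.ppf(0.975)
        lo, hi = kappa - z * se, kappa + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for r in range(n_boot):
            idx = rng.integers(0, n, n)
            reps[r] = weighted_kappa(
                a[idx], b[idx], weights=weights, ci_method="none"
            ).estimate
        lo, hi = np.quantile(reps, [0.025, 0.975])
    elif ci_method == "none":
        lo = hi = kappa
    else:
        raise StatsError("ci_method must be 'asymptotic', 'bootstrap' or 'none'")
    lo = min(max(lo, -1.0), kappa)
    hi = max(min(hi, 1.0), kappa)
    return KappaResult(kappa, float(lo), float(hi), n, weights)


def _kappa_asymptotic_se(
    p: np.ndarray, pa: np.ndarray, pb: np.ndarray, w: np.ndarray, n: int
) -> float:
    """Large-sample SE of weighted kappa (agreement weights *w*)."""
    po = float((w * p).sum())
    pe = float((w * np.outer(pa, pb)).sum())
    if pe >= 1.0:
        return 0.0
    wbar_i = (w * pb[np.newaxis, :]).sum(axis=1)  # row averages vs rater B margins
    wbar_j = (w * pa[:, np.newaxis]).sum(axis=0)
    kappa = (po - pe) / (1.0 - pe)
    term = (
        w - (wbar_i[:, np.newaxis] + wbar_j[np.newaxis, :]) * (1.0 - kappa)
    ) ** 2
    var = ((p * term).sum() - (kappa - pe * (1.0 - kappa)) ** 2) / (
        n * (1.0 - pe) ** 2
    )
    return math.sqrt(max(var, 0.0))


def bland_altman(
    percent_a: Sequence[float],
    percent_b: Sequence[float],
    band: tuple[float, float] = DEFAULT_BAND,
) -> BlandAltmanResult:
    """Bland–Altman agreement between paired percentage scores.

    ``percent_a`` is the Esterman percent seen and ``percent_b`` the mET
    percent seen; differences are a − b, so positive bias means the mET
    recorded more loss.  Pairs whose mean falls outside ``band`` are
    excluded before computing the bias and limits of agreement.
    """
    a = np.asarray(percent_a, dtype=float)
    b = np.asarray(percent_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("paired vectors must be 1-D and of equal length")
    lo, hi = band
    if lo > hi:
        raise StatsError(f"invalid band ({lo}, {hi})")
    means = (a + b) / 2.0
    keep = (means >= lo) & (means <= hi)
    if keep.sum() < 2:
        raise StatsError(
            f"fewer than 2 pairs have mean percent seen inside the "
            f"[{lo}, {hi}] band ({int(keep.sum())} included of {len(a)})"
        )
    diff = a[keep] - b[keep]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n_included=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        band=(float(lo), float(hi)),
    )


def repeatability_coefficient(
    test1: Sequence[float], test2: Sequence[float]
) -> RepeatabilityResult:
    """Repeatability coefficient of paired test–retest scores.

    RC = 1.96·√2·s_w with the two-replicate within-subject SD
    s_w = sqrt(Σ d_i² / 2n); symmetric in the two replicates.
    """
    t1 = np.asarray(test1, dtype=float)
    t2 = np.asarray(test2, dtype=float)
    if t1.shape != t2.shape or t1.ndim != 1:
        raise StatsError("paired vectors must be 1-D and of equal length")
    if len(t1) < 2:
        raise StatsError("need at least 2 test-retest pairs")
    d = t1 - t2
    sw = math.sqrt(float((d**2).sum()) / (2 * len(d)))
    return RepeatabilityResult(
        coefficient=1.96 * math.sqrt(2.0) * sw,
        within_subject_sd=sw,
        n=len(d),
    )


# ---------------------------------------------------------------------------
# Paradigm comparison on a simulated cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DefectExcessSummary:
    """How much more loss the mET records than the Esterman."""

    bias_by_group: Mapping[str, float | None]  # Esterman − mET percent seen
    overall: "BlandAltmanResult | None"
    superior_defects_esterman: int
    superior_defects_met: int


def paired_defect_excess(
    subject_groups: Sequence[str],
    esterman_pct: Sequence[float],
    met_pct: Sequence[float],
    esterman_superior_defects: Iterable[int] = (),
    met_superior_defects: Iterable[int] = (),
    band: tuple[float, float] = DEFAULT_BAND,
) -> DefectExcessSummary:
    """Summarise the excess field loss recorded by mET over Esterman.

    Per-group and overall Bland–Altman biases of percent seen
    (Esterman − mET, band-filtered); groups with too few in-band pairs
    report None.  Superior-region defect counts are summed per paradigm.
    """
    groups = list(subject_groups)
    a = np.asarray(esterman_pct, dtype=float)
    b = np.asarray(met_pct, dtype=float)
    if not (len(groups) == len(a) == len(b)):
        raise StatsError("groups and paired vectors must align")
    bias_by_group: dict[str, float | None] = {}
    for g in sorted(set(groups)):
        mask = np.array([x == g for x in groups])
        try:
            bias_by_group[g] = bland_altman(a[mask], b[mask], band=band).bias
        except StatsError:
            bias_by_group[g] = None
    try:
        overall = bland_altman(a, b, band=band)
    except StatsError:
        overall = None
    return DefectExcessSummary(
        bias_by_group=bias_by_group,
        overall=overall,
        superior_defects_esterman=int(sum(esterman_superior_defects)),
        superior_defects_met=int(sum(met_superior_defects)),
    )
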