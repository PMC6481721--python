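"""Population statistics: gating, rank tests, dose response, QC.

Deformability across a cell population is log-normally distributed, so all
between-sample comparisons use the (nonparametric) Mann-Whitney U test at a
0.01 significance level, reported with the conventional tier ladder

    ns (p > 0.01), * (p < 0.01), ** (p < 0.001), *** (p < 0.0001),
    **** (p < 0.00001)

(the most extreme applicable tier wins; the ``*`` rung is an extension to
make the ladder total, since published captions skip it).

Analysis is restricted by a confinement gate 0.85 < Dc/Dh < 0.95: below it
cells barely deform, above it the cell surface risks wall contact.

Dose-response: each dose arm is compared with the untreated control by the
more significant of the two one-tailed tests, Bonferroni-corrected within
the pair (detection must catch either an increase or a decrease in DI).
Cmin is the smallest dose that passes; the trend over higher doses is
classified against successive-dose tests in the same way.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from skimage.measure import find_contours

from .summarize import SamplePopulation

__all__ = [
    "ComparisonResult",
    "DoseResponseResult",
    "PressureFit",
    "QCChannel",
    "QCReport",
    "significance_tier",
    "confinement_gate",
    "mann_whitney_one_tailed",
    "dose_response_cmin",
    "pressure_response_fit",
    "density_contour",
    "manifold_qc",
    "boxplot_summary",
]

log = logging.getLogger(__name__)

SOFTENING = "DI increases (softening)"
STIFFENING = "DI decreases (stiffening)"


def significance_tier(p: float) -> str:
    """Map a p-value to the star-tier ladder (alpha = 0.01)."""
    if p < 1e-5:
        return "****"
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return "ns"


@dataclasses.dataclass
class ComparisonResult:
    u_statistic: float
    p_value: float
    tier: str
    n1: int
    n2: int
    direction: str  # the one-tailed alternative that was tested


def confinement_gate(
    pop: SamplePopulation, lo: float = 0.85, hi: float = 0.95
) -> SamplePopulation:
    """Retain accepted records with lo < Dc/Dh < hi (strict open interval)."""
    if not (0.0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    kept = [r for r in pop.accepted if lo < r.confinement < hi]
    meta = dict(pop.metadata)
    meta["confinement_gate"] = (lo, hi)
    return SamplePopulation(sample_id=pop.sample_id, records=kept, metadata=meta)


def _as_array(sample) -> np.ndarray:
    if isinstance(sample, SamplePopulation):
        return sample.di_values()
    return np.asarray(sample, dtype=float)


def mann_whitney_one_tailed(
    a, b, alternative: str = "greater"
) -> ComparisonResult:
    """One-tailed Mann-Whitney U test of sample ``a`` against sample ``b``.

    ``alternative`` follows the usual convention for the first sample:
    "greater" tests whether values in ``a`` tend to exceed those in ``b``.
    The U statistic is the rank-sum statistic of ``a`` (midranks for ties).
    The p-value is exact (full enumeration of the null permutation
    distribution) when n1*n2 <= 400 and the pooled data are tie-free,
    otherwise the normal approximation with tie and continuity corrections
    is used.
    """
    x = _as_array(a)
    y = _as_array(b)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) * len(y) <= 400 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    p = float(res.pvalue)
    return ComparisonResult(
        u_statistic=float(res.statistic),
        p_value=p,
        tier=significance_tier(p),
        n1=len(x),
        n2=len(y),
        direction=alternative,
    )


def _two_sided_detect(
    treated, control, alpha: float
) -> Tuple[bool, str, ComparisonResult]:
    """Detect a DI change in either direction (paired one-tailed tests,
    Bonferroni within the pair): significant iff 2*min(p) < alpha."""
    up = mann_whitney_one_tailed(treated, control, "greater")
    down = mann_whitney_one_tailed(treated, control, "less")
    win, label = (up, SOFTENING) if up.p_value <= down.p_value else (down, STIFFENING)
    return (2.0 * win.p_value < alpha), label, win


@dataclasses.dataclass
class DoseResponseResult:
    cmin: Optional[float]
    direction: str  # change at Cmin ("No change" when cmin is None)
    pattern: str  # behaviour over doses above Cmin
    comparisons: List[Tuple[float, ComparisonResult]]  # winning tail per dose
    significant: List[Tuple[float, bool]]


def dose_response_cmin(
    control: SamplePopulation,
    doses: Sequence[Tuple[float, SamplePopulation]],
    alpha: float = 0.01,
) -> DoseResponseResult:
    """Minimum effective concentration from gated dose arms vs control.

    ``doses`` must be sorted ascending by concentration.  Cmin is the
    smallest dose whose DI distribution differs from control in either
    direction at level ``alpha``.  The pattern over higher doses is
    "No change" if no successive step is significant, "Monotonic
    increase"/"Monotonic decrease" if every significant step agrees with the
    direction at Cmin, and "Non-monotonic" otherwise.
    """
    if len(doses) < 1:
        raise ValueError("need at least one dose arm")
    dose_vals = [d for d, _ in doses]
    if sorted(dose_vals) != dose_vals:
        raise ValueError("doses must be sorted ascending")
    comparisons = []
    flags = []
    cmin = None
    cmin_idx = None
    direction = "No change"
    for i, (dose, pop) in enumerate(doses):
        sig, label, res = _two_sided_detect(pop, control, alpha)
        comparisons.append((dose, res))
        flags.append((dose, sig))
        if sig and cmin is None:
            cmin, cmin_idx, direction = dose, i, label
    if cmin is None:
        return DoseResponseResult(None, "No change", "No change", comparisons, flags)
    # trend over doses above Cmin: successive-dose tests, same detection rule
    steps = []
    arms = doses[cmin_idx:]
    for (d1, p1), (d2, p2) in zip(arms[:-1], arms[1:]):
        sig, label, _ = _two_sided_detect(p2, p1, alpha)
        if sig:
            steps.append(label)
    if not steps:
        pattern = "No change"
    elif all(s == direction for s in steps):
        pattern = (
            "Monotonic increase" if direction == SOFTENING else "Monotonic decrease"
        )
    else:
        pattern = "Non-monotonic"
    return DoseResponseResult(cmin, direction, pattern, comparisons, flags)


@dataclasses.dataclass
class PressureFit:
    slope: float
    intercept: float
    r_squared: float


def pressure_response_fit(points: Sequence[Tuple[float, float]]) -> PressureFit:
    """OLS fit of mean gated DI against driving pressure (kPa)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (pressure_kpa, mean_di) pairs")
    if len(np.unique(pts[:, 0])) < 3:
        raise ValueError("need at least 3 distinct pressures")
    res = sps.linregress(pts[:, 0], pts[:, 1])
    return PressureFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def density_contour(
    points: np.ndarray, level_fraction: float = 0.5, grid: int = 128
) -> List[np.ndarray]:
    """Iso-density contour(s) of the (confinement, DI) event cloud.

    A 2-D Gaussian KDE (Scott bandwidth) is evaluated on a regular grid and
    the contour at ``level_fraction`` times the peak density is traced.
    Returns a list of closed (k, 2) polylines in data coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 50:
        raise ValueError("need an (n>=50, 2) point array")
    if not (0.0 < level_fraction < 1.0):
        raise ValueError("level_fraction must be in (0, 1)")
    if np.allclose(pts.std(axis=0), 0):
        raise ValueError("degenerate point cloud (zero variance)")
    try:
        kde = sps.gaussian_kde(pts.T)
    except np.linalg.LinAlgError as exc:  # singular covariance
        raise ValueError("degenerate point cloud (singular covariance)") from exc
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    pad = 0.25 * (hi - lo + 1e-12)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid, grid)
    level = level_fraction * dens.max()
    cell_area = (xs[1] - xs[0]) * (ys[1] - ys[0])
    out = []
    for c in find_contours(dens, level):
        # grid indices -> data coordinates
        cx = np.interp(c[:, 0], np.arange(grid), xs)
        cy = np.interp(c[:, 1], np.arange(grid), ys)
        ring = np.column_stack([cx, cy])
        # discard sub-grid-cell artifacts (aliasing on razor-thin ridges)
        enclosed = 0.5 * abs(
            np.sum(cx * np.roll(cy, -1) - np.roll(cx, -1) * cy)
        )
        if enclosed >= 4 * cell_area:
            out.append(ring)
    return out


@dataclasses.dataclass
class QCChannel:
    channel: str
    n: int
    mean_mps: float
    sd_mps: float
    rel_deviation: float
    coverage_ok: bool


@dataclasses.dataclass
class QCReport:
    channels: List[QCChannel]
    grand_mean_mps: float
    max_rel_deviation: float
    tolerance: float
    passed: bool


def manifold_qc(
    per_channel_velocities: Dict[str, Sequence[float]],
    tolerance_fraction: float = 0.03,
) -> QCReport:
    """Verify that a shared pressure source drives all channels equally.

    Rigid-bead mean velocities per channel must deviate from the grand mean
    by at most ``tolerance_fraction`` (default 3%).  Channels with fewer
    than 20 beads are flagged with a warning; channels with zero beads are
    reported as failed coverage (and fail the report) rather than crashing.
    """
    if len(per_channel_velocities) < 2:
        raise ValueError("need at least 2 channels for manifold QC")
    prelim = []
    for ch, v in per_channel_velocities.items():
        arr = np.asarray(list(v), dtype=float)
        if arr.size and arr.size < 20:
            warnings.warn(
                f"channel {ch}: only {arr.size} beads (<20); velocity mean is noisy",
                stacklevel=2,
            )
        prelim.append((str(ch), arr))
    covered = [(ch, a) for ch, a in prelim if a.size > 0]
    if not covered:
        raise ValueError("no channel has any beads")
    grand = float(np.mean([a.mean() for _, a in covered]))
    channels = []
    for ch, a in prelim:
        if a.size == 0:
            channels.append(QCChannel(ch, 0, float("nan"), float("nan"), float("nan"), False))
            continue
        m = float(a.mean())
        channels.append(
            QCChannel(
                channel=ch,
                n=int(a.size),
                mean_mps=m,
                sd_mps=float(a.std(ddof=1)) if a.size > 1 else 0.0,
                rel_deviation=abs(m - grand) / grand,
                coverage_ok=True,
            )
        )
    max_dev = float(max(c.rel_deviation for c in channels if c.coverage_ok))
    passed = all(c.coverage_ok for c in channels) and max_dev <= tolerance_fraction
    return QCReport(
        channels=channels,
        grand_mean_mps=grand,
        max_rel_deviation=max_dev,
        tolerance=tolerance_fraction,
        passed=passed,
    )


def boxplot_summary(pop) -> Dict[str, float]:
    """Median, quartiles and 10/90 whiskers (linear-interpolation quantiles).

    Accepts a :class:`SamplePopulation` (gated DI values) or an array.
    Warns when n < 100, the floor used for publication-grade boxplots.
    """
    values = _as_array(pop)
    if values.size == 0:
        raise ValueError("empty sample")
    if values.size < 100:
        warnings.warn(
            f"boxplot summary over n={values.size} < 100 cells", stacklevel=2
        )
    q10, q25, q50, q75, q90 = np.quantile(values, [0.1, 0.25, 0.5, 0.75, 0.9])
    return {
        "median": float(q50),
        "q25": float(q25),
        "q75": float(q75),
        "p10": float(q10),
        "p90": float(q90),
        "n": int(values.size),
    }
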