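"""Deformation index and derived per-frame shape quantities.

The central readout is the deformation index

    DI = 1 - 2 sqrt(pi A) / p

where A is the projected area and p the perimeter of the cell contour.
DI is zero for a perfect circle (isoperimetric equality) and grows as the
contour elongates; it is computed from area and perimeter only, never from a
fitted ellipse.  Equivalently DI = 1 - sqrt(circularity) with
circularity = 4 pi A / p^2.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "deformation_index",
    "polygon_measure",
    "di_profile",
    "moving_average_profile",
]

#: negative-DI slack attributed to floating-point roundoff; anything worse
#: indicates a broken perimeter estimator (p^2 < 4 pi A is impossible for a
#: genuine closed contour).
_ISOPERIMETRIC_SLACK = 1e-9


def deformation_index(area: float, perimeter: float) -> float:
    """DI = 1 - 2 sqrt(pi * area) / perimeter.

    Parameters are in consistent units (area in L^2, perimeter in L); the
    result is dimensionless and scale-invariant.  Tiny negative values from
    roundoff are clamped to 0; violations of the isoperimetric inequality
    beyond the numeric slack raise, since no closed contour can produce them.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    di = 1.0 - 2.0 * np.sqrt(np.pi * area) / perimeter
    if di < 0.0:
        if di < -_ISOPERIMETRIC_SLACK:
            raise ValueError(
                f"non-physical contour: DI={di:.3e} (p^2 < 4*pi*A beyond slack)"
            )
        di = 0.0
    return float(di)


def polygon_measure(vertices: np.ndarray) -> Tuple[float, float, Tuple[float, float]]:
    """Exact area, perimeter and centroid of a closed polygon.

    ``vertices`` is an (n, 2) array of (x, y) points describing the boundary
    once, without repeating the first vertex.  Area by the shoelace formula
    (sign-independent), perimeter by polygonal arc length, centroid by the
    polygon first moments (falls back to the vertex mean for degenerate,
    zero-area rings).
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("vertices must be an (n>=3, 2) array")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area2 = cross.sum()
    area = abs(area2) / 2.0
    perimeter = float(np.hypot(xn - x, yn - y).sum())
    if area > 0:
        cx = float(((x + xn) * cross).sum() / (3.0 * area2))
        cy = float(((y + yn) * cross).sum() / (3.0 * area2))
    else:
        cx, cy = float(x.mean()), float(y.mean())
    return float(area), perimeter, (cx, cy)


def di_profile(track) -> List[Tuple[float, float]]:
    """Raw (x_um, DI) profile of one track, ordered by x.

    Uses only usable observations: non-coincident and not truncated by the
    image border.  No smoothing is applied here; pooled smoothing lives in
    :func:`moving_average_profile`.
    """
    pts = []
    coincident = getattr(track, "coincident_frames", set())
    for obs in track.observations:
        if obs.touches_border or obs.frame_index in coincident:
            continue
        di = deformation_index(obs.area_um2, obs.perimeter_um)
        pts.append((obs.x_um, di))
    pts.sort(key=lambda t: t[0])
    return pts


def moving_average_profile(
    profiles: Iterable[Sequence[Tuple[float, float]]],
    window: int = 3,
    bin_width_um: float = 10.0,
    x_range: Tuple[float, float] | None = None,
) -> List[Tuple[float, float]]:
    """Pooled, binned and moving-averaged DI(x) across many cells.

    All (x, DI) points from all profiles are pooled, binned by x with the
    given bin width, averaged per bin, and the sequence of occupied-bin means
    is smoothed with a centred ``window``-point moving average (endpoint bins
    use shrunken windows).  ``window`` must be odd; ``window=1`` returns the
    per-bin means unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    xs: List[float] = []
    dis: List[float] = []
    for prof in profiles:
        for x, di in prof:
            xs.append(x)
            dis.append(di)
    if not xs:
        return []
    x_arr = np.asarray(xs)
    di_arr = np.asarray(dis)
    lo, hi = x_range if x_range is not None else (x_arr.min(), x_arr.max())
    n_bins = int(np.floor((hi - lo) / bin_width_um)) + 1
    edges = lo + bin_width_um * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(x_arr, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=di_arr, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = np.nonzero(counts)[0]
    means = sums[occupied] / counts[occupied]
    centers = (edges[occupied] + edges[occupied + 1]) / 2.0
    half = window // 2
    out = []
    for i in range(len(means)):
        a, b = max(0, i - half), min(len(means), i + half + 1)
        out.append((float(centers[i]), float(means[a:b].mean())))
    return out
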