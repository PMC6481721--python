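"""Frame-to-frame linking of observations into per-cell tracks.

Greedy nearest-neighbour assignment with a velocity gate: a next-frame
candidate must lie downstream of the track head by between ``v_min * dt``
and ``v_max * dt`` (flow is unidirectional, so upstream motion beyond one
pixel of noise is forbidden).  New IDs are minted only in the upstream entry
zone — a cell is tagged when it first appears in the ROI — which keeps
segmentation flicker mid-channel from creating phantom cells.  Frames in
which two or more tracks occupy the test section simultaneously are flagged
as coincident and excluded from all downstream DI readouts (hydrodynamic
interaction between neighbouring cells corrupts their deformation).

At the occupancies this assay analyses (about one cell in the test section
at a time) greedy matching is equivalent to global assignment and far easier
to audit; crowded frames are removed by the coincidence rule regardless.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, NamedTuple, Sequence, Set

import numpy as np

from .config import AcquisitionConfig, ChannelGeometry
from .segment import FrameObservation

__all__ = [
    "CellTrack",
    "TrackingParams",
    "LinkResult",
    "link_tracks",
    "flag_coincidence",
    "track_velocity",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class TrackingParams:
    nominal_velocity_mps: float = 0.3
    v_max_factor: float = 2.0  # v_max = factor * nominal
    v_min_mps: float = 0.0
    max_gap_frames: int = 2
    #: candidates whose distances differ by less than this are ties,
    #: resolved by smallest area difference, then smallest ID
    tie_tolerance_um: float = 1.0
    #: maximum lateral jump between consecutive observations
    dy_max_um: float = 6.0
    #: upstream-noise allowance on the monotone-x rule (about one pixel)
    backstep_tolerance_um: float = 1.0
    #: fraction of the ROI length, from the upstream edge, where new IDs start
    entry_zone_fraction: float = 0.25


@dataclasses.dataclass
class CellTrack:
    cell_id: int
    observations: List[FrameObservation]
    coincident_frames: Set[int] = dataclasses.field(default_factory=set)
    entered_roi: bool = False
    exited_roi: bool = False
    valid: bool = False

    def usable_observations(self, lo_x: float | None = None, hi_x: float | None = None):
        """Non-border, non-coincident observations, optionally x-windowed."""
        out = []
        for o in self.observations:
            if o.touches_border or o.frame_index in self.coincident_frames:
                continue
            if lo_x is not None and o.x_um < lo_x:
                continue
            if hi_x is not None and o.x_um > hi_x:
                continue
            out.append(o)
        return out


class LinkResult(NamedTuple):
    tracks: List[CellTrack]
    dropped: List[FrameObservation]


def _update_validity(track: CellTrack, geom: ChannelGeometry) -> None:
    L = geom.test_length_um
    xs = [o.x_um for o in track.observations]
    track.entered_roi = bool(xs) and min(xs) < 0.0
    track.exited_roi = bool(xs) and max(xs) > L
    pre = track.usable_observations(hi_x=-1e-12)
    pre = [o for o in pre if o.x_um < 0]
    insection = [o for o in track.usable_observations(0.0, L)]
    track.valid = (
        track.entered_roi and track.exited_roi and len(pre) >= 1 and len(insection) >= 1
    )


def link_tracks(
    observations: Sequence[FrameObservation],
    acq: AcquisitionConfig,
    geom: ChannelGeometry,
    params: TrackingParams | None = None,
) -> LinkResult:
    """Link per-frame observations into tracks (greedy NN, velocity-gated).

    Returns the tracks together with the observations that could be
    attributed to no track, so callers can verify conservation:
    every input observation ends up in exactly one track or in ``dropped``.
    """
    params = params or TrackingParams()
    by_frame: Dict[int, List[FrameObservation]] = {}
    for o in observations:
        by_frame.setdefault(o.frame_index, []).append(o)
    frames = sorted(by_frame)
    dt0 = 1.0 / acq.frame_rate_fps
    v_max_um = params.v_max_factor * params.nominal_velocity_mps * 1e6
    v_min_um = params.v_min_mps * 1e6
    entry_x_max = geom.roi_start_um + params.entry_zone_fraction * geom.roi_length_um

    open_tracks: List[CellTrack] = []
    closed_tracks: List[CellTrack] = []
    dropped: List[FrameObservation] = []
    next_id = 0

    for f in frames:
        obs = by_frame[f]
        # retire stale tracks
        still_open = []
        for t in open_tracks:
            if f - t.observations[-1].frame_index > params.max_gap_frames:
                closed_tracks.append(t)
            else:
                still_open.append(t)
        open_tracks = still_open

        # candidate (track, obs) pairs within the velocity gate
        pairs = []
        for ti, t in enumerate(open_tracks):
            last = t.observations[-1]
            dt = (f - last.frame_index) * dt0
            lo = v_min_um * dt - params.backstep_tolerance_um
            hi = v_max_um * dt + params.backstep_tolerance_um
            for oi, o in enumerate(obs):
                dx = o.x_um - last.x_um
                dy = abs(o.y_um - last.y_um)
                if lo <= dx <= hi and dy <= params.dy_max_um:
                    dist = float(np.hypot(dx, o.y_um - last.y_um))
                    darea = abs(o.area_um2 - last.area_um2)
                    pairs.append((dist, darea, t.cell_id, ti, oi))
        # greedy with tie resolution: quantising distance by the tie
        # tolerance makes (area difference, ID) decide within a tie band
        pairs.sort(
            key=lambda p: (round(p[0] / params.tie_tolerance_um), p[1], p[2])
        )
        used_t: Set[int] = set()
        used_o: Set[int] = set()
        for dist, darea, cid, ti, oi in pairs:
            if ti in used_t or oi in used_o:
                continue
            open_tracks[ti].observations.append(obs[oi])
            used_t.add(ti)
            used_o.add(oi)

        for oi, o in enumerate(obs):
            if oi in used_o:
                continue
            if o.x_um <= entry_x_max:
                open_tracks.append(CellTrack(cell_id=next_id, observations=[o]))
                next_id += 1
            else:
                # mid-channel orphan: try the nearest open track that did not
                # receive a match this frame and is velocity-compatible
                best = None
                for ti, t in enumerate(open_tracks):
                    if ti in used_t:
                        continue
                    last = t.observations[-1]
                    if last.frame_index >= f:
                        continue
                    dt = (f - last.frame_index) * dt0
                    dx = o.x_um - last.x_um
                    if (
                        v_min_um * dt - params.backstep_tolerance_um
                        <= dx
                        <= v_max_um * dt + params.backstep_tolerance_um
                    ):
                        d = abs(dx)
                        if best is None or d < best[0]:
                            best = (d, ti)
                if best is not None:
                    open_tracks[best[1]].observations.append(o)
                    used_t.add(best[1])
                else:
                    dropped.append(o)
                    log.debug("dropped mid-channel orphan at x=%.1f um frame %d", o.x_um, f)

    closed_tracks.extend(open_tracks)
    closed_tracks.sort(key=lambda t: t.cell_id)
    for t in closed_tracks:
        _update_validity(t, geom)
    return LinkResult(tracks=closed_tracks, dropped=dropped)


def flag_coincidence(tracks: List[CellTrack], geom: ChannelGeometry) -> List[CellTrack]:
    """Flag every frame where >=2 tracks occupy the test section (0 <= x <= L).

    The flagged observations stay in the raw output but are excluded from
    all DI summaries.  Cells upstream (x < 0) or downstream (x > L) of the
    test section never trigger the rule.
    """
    L = geom.test_length_um
    per_frame: Dict[int, List[CellTrack]] = {}
    for t in tracks:
        for o in t.observations:
            if 0.0 <= o.x_um <= L:
                per_frame.setdefault(o.frame_index, []).append(t)
    for f, ts in per_frame.items():
        if len({t.cell_id for t in ts}) >= 2:
            for t in ts:
                t.coincident_frames.add(f)
    for t in tracks:
        _update_validity(t, geom)
    return tracks


def track_velocity(track: CellTrack, acq: AcquisitionConfig, geom: ChannelGeometry | None = None) -> float | None:
    """Mean transit speed (m/s) from a least-squares fit of x against time.

    Uses non-coincident, non-border observations inside the test section
    when a geometry is given (otherwise all usable observations).  With two
    points the fit degenerates to the endpoint difference.  Returns None if
    fewer than two usable observations exist.
    """
    if geom is not None:
        usable = track.usable_observations(0.0, geom.test_length_um)
        if len(usable) < 2:
            usable = track.usable_observations()
    else:
        usable = track.usable_observations()
    if len(usable) < 2:
        return None
    t = np.array([o.frame_index for o in usable], dtype=float) / acq.frame_rate_fps
    x = np.array([o.x_um for o in usable], dtype=float) * 1e-6
    slope = np.polyfit(t, x, 1)[0]
    return float(slope)
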