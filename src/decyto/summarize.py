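"""Per-cell readouts: undeformed diameter, confinement, maximum DI.

Each valid track collapses to one :class:`CellRecord`:

* ``dc_um`` — undeformed diameter from the mean projected area over all
  usable *pre-entry* observations (x < 0).  In-channel frames never
  contribute: the cell is already deformed there.
* ``confinement`` — dc divided by the channel hydraulic diameter.
* ``di_max`` — the maximum DI over usable in-test-section observations
  (0 <= x <= L, non-coincident, non-border); the cell's deformability
  readout, since deformation peaks before the exit plane.

Rejected cells are first-class outputs carrying a reason, because the
accept/reject accounting is the pipeline's main QC surface.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AcquisitionConfig, ChannelGeometry
from .metrics import deformation_index
from .segment import equivalent_diameter
from .track import CellTrack, track_velocity

__all__ = [
    "CellRecord",
    "SamplePopulation",
    "summarize_cell",
    "summarize_tracks",
    "assemble_population",
    "records_from_event_table",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class CellRecord:
    cell_id: int
    sample_id: str
    dc_um: float = float("nan")
    confinement: float = float("nan")
    di_max: float = float("nan")
    velocity_mps: float = float("nan")
    n_frames_used: int = 0
    reject_reason: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None


@dataclasses.dataclass
class SamplePopulation:
    """Gated or ungated collection of per-cell records for one sample."""

    sample_id: str
    records: List[CellRecord]
    metadata: Dict = dataclasses.field(default_factory=dict)

    @property
    def accepted(self) -> List[CellRecord]:
        return [r for r in self.records if r.accepted]

    @property
    def n(self) -> int:
        return len(self.accepted)

    def di_values(self) -> np.ndarray:
        return np.array([r.di_max for r in self.accepted])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": r.sample_id,
                "cell_id": r.cell_id,
                "dc_um": r.dc_um,
                "confinement": r.confinement,
                "di_max": r.di_max,
                "velocity_mps": r.velocity_mps,
                "n_frames_used": r.n_frames_used,
                "reject_reason": r.reject_reason or "",
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "cell_id",
                "dc_um",
                "confinement",
                "di_max",
                "velocity_mps",
                "n_frames_used",
                "reject_reason",
            ],
        )


def summarize_cell(
    track: CellTrack,
    geom: ChannelGeometry,
    acq: AcquisitionConfig,
    sample_id: str = "",
) -> CellRecord:
    """Collapse one track to its per-cell readouts (or a rejection record)."""
    rec = CellRecord(cell_id=track.cell_id, sample_id=sample_id)
    L = geom.test_length_um
    pre = [o for o in track.usable_observations() if o.x_um < 0.0]
    insection = track.usable_observations(0.0, L)
    if not (track.entered_roi and track.exited_roi):
        rec.reject_reason = "partial_transit"
        return rec
    if not pre:
        rec.reject_reason = "no_pre_entry"
        return rec
    if not insection:
        any_insection = [o for o in track.observations if 0.0 <= o.x_um <= L]
        rec.reject_reason = "coincidence" if any_insection else "no_in_section"
        return rec
    area = float(np.mean([o.area_um2 for o in pre]))
    rec.dc_um = equivalent_diameter(area)
    rec.confinement = rec.dc_um / geom.hydraulic_diameter_um
    rec.di_max = max(deformation_index(o.area_um2, o.perimeter_um) for o in insection)
    v = track_velocity(track, acq, geom)
    rec.velocity_mps = float("nan") if v is None else v
    rec.n_frames_used = len(pre) + len(insection)
    return rec


def summarize_tracks(
    tracks: Sequence[CellTrack],
    geom: ChannelGeometry,
    acq: AcquisitionConfig,
    sample_id: str = "",
) -> List[CellRecord]:
    return [summarize_cell(t, geom, acq, sample_id) for t in tracks]


def assemble_population(
    records: Sequence[CellRecord], metadata: Dict | None = None
) -> SamplePopulation:
    """Bundle records sharing one sample_id into a population.

    Records from replicate channels of the same sample merge here (the
    acquisition protocol runs two channels per sample).  Mixed sample_ids
    raise.  Empty populations are allowed but logged.
    """
    records = list(records)
    ids = {r.sample_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"mixed sample_ids in one population: {sorted(ids)}")
    sample_id = ids.pop() if ids else (metadata or {}).get("sample_id", "")
    n_acc = sum(1 for r in records if r.accepted)
    n_rej = len(records) - n_acc
    if not records:
        log.warning("assembling empty population for sample %r", sample_id)
    else:
        log.info(
            "sample %r: %d accepted, %d rejected cells", sample_id, n_acc, n_rej
        )
    return SamplePopulation(
        sample_id=sample_id, records=records, metadata=dict(metadata or {})
    )


def records_from_event_table(
    events: pd.DataFrame,
    geom: ChannelGeometry,
    acq: AcquisitionConfig,
    sample_id: str = "",
) -> List[CellRecord]:
    """Per-cell records straight from an analytic event table.

    The table has one row per (cell, frame) with columns cell_id, frame,
    x_um, area_um2, perimeter_um (a ``di`` column is accepted and ignored;
    DI is recomputed from area and perimeter).  The same pre-entry /
    in-section rules apply as for imaged tracks; there is no border or
    coincidence information in an analytic table, so none is assumed.
    """
    out: List[CellRecord] = []
    L = geom.test_length_um
    for cid, grp in events.groupby("cell_id"):
        grp = grp.sort_values("frame")
        rec = CellRecord(cell_id=int(cid), sample_id=sample_id)
        pre = grp[grp["x_um"] < 0.0]
        ins = grp[(grp["x_um"] >= 0.0) & (grp["x_um"] <= L)]
        if pre.empty:
            rec.reject_reason = "no_pre_entry"
            out.append(rec)
            continue
        if ins.empty:
            rec.reject_reason = "no_in_section"
            out.append(rec)
            continue
        rec.dc_um = equivalent_diameter(float(pre["area_um2"].mean()))
        rec.confinement = rec.dc_um / geom.hydraulic_diameter_um
        rec.di_max = float(
            max(
                deformation_index(a, p)
                for a, p in zip(ins["area_um2"], ins["perimeter_um"])
            )
        )
        t = ins["frame"].to_numpy(dtype=float) / acq.frame_rate_fps
        x = ins["x_um"].to_numpy(dtype=float) * 1e-6
        rec.velocity_mps = float(np.polyfit(t, x, 1)[0]) if len(ins) >= 2 else float("nan")
        rec.n_frames_used = len(pre) + len(ins)
        out.append(rec)
    return out
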