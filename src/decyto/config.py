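"""Channel geometry, optics and acquisition parameters.

Every other stage consumes these two models plus the :class:`CoordinateFrame`
they define.  The coordinate frame puts the flow axis ``x`` in micrometres
with ``x = 0`` at the entrance plane of the constricted test section and
``x = L`` at its exit plane; the imaged region of interest (ROI) extends a
configurable number of channel-widths upstream and downstream of the test
section.  Lateral position ``y`` is measured from the channel centreline.

Defaults correspond to a linear-microchannel deformability cytometer:
an 18 x 19.8 um test section of length 230 um, imaged at 0.97 um/px and
15 000 frames/s with a 464 x 504 px sensor crop, driven at 15 kPa.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ChannelGeometry",
    "AcquisitionConfig",
    "CoordinateFrame",
    "hydraulic_diameter",
    "coordinate_frame",
    "load_config",
    "save_config",
]


class ChannelGeometry(BaseModel):
    """Test-section dimensions and ROI margins (all lengths in um)."""

    model_config = {"frozen": True}

    width_um: float = Field(default=18.0, gt=0)
    height_um: float = Field(default=19.8, gt=0)
    test_length_um: float = Field(default=230.0, gt=0)
    #: number of channel-widths of ROI before and after the test section
    roi_margin_widths: float = Field(default=5.0, ge=0)

    @property
    def hydraulic_diameter_um(self) -> float:
        """2WH/(W+H) for a rectangular duct; derived, never stored."""
        w, h = self.width_um, self.height_um
        return 2.0 * w * h / (w + h)

    @property
    def roi_start_um(self) -> float:
        """x of the upstream ROI edge (negative: upstream of the entrance)."""
        return -self.roi_margin_widths * self.width_um

    @property
    def roi_end_um(self) -> float:
        return self.test_length_um + self.roi_margin_widths * self.width_um

    @property
    def roi_length_um(self) -> float:
        return self.roi_end_um - self.roi_start_um


class AcquisitionConfig(BaseModel):
    """Optics and camera parameters for one recording."""

    model_config = {"frozen": True}

    pixel_size_um: float = Field(default=0.97, gt=0)
    frame_rate_fps: float = Field(default=15000.0, gt=0)
    driving_pressure_kpa: float = Field(default=15.0, ge=0)
    exposure_us: float = Field(default=1.0, gt=0)
    image_shape_px: Tuple[int, int] = (464, 504)

    @model_validator(mode="after")
    def _check_shape(self) -> "AcquisitionConfig":
        rows, cols = self.image_shape_px
        if rows <= 0 or cols <= 0:
            raise ValueError("image_shape_px entries must be positive")
        return self


def hydraulic_diameter(geom: ChannelGeometry) -> float:
    """Hydraulic diameter 2WH/(W+H) of the rectangular test section, in um."""
    return geom.hydraulic_diameter_um


class CoordinateFrame:
    """Affine mapping between pixel indices and physical (y, x) in um.

    Pixel centres sit at half-integer continuous pixel coordinates: column
    index ``i`` covers the continuous interval ``[i, i+1)`` and its centre
    maps to ``x = roi_start + (i + 0.5) * pixel_size``.  Row 0 is the top of
    the image; ``y`` increases downward with ``y = 0`` at the image mid-height
    (the channel centreline).  x is continuous so subpixel centroids are
    representable exactly.
    """

    def __init__(self, geom: ChannelGeometry, acq: AcquisitionConfig):
        rows, cols = acq.image_shape_px
        extent = cols * acq.pixel_size_um
        if geom.roi_length_um > extent + 1e-9:
            raise ValueError(
                f"ROI length {geom.roi_length_um:.1f} um exceeds image extent "
                f"{extent:.1f} um at {acq.pixel_size_um} um/px"
            )
        self.geom = geom
        self.acq = acq
        self.x0_um = geom.roi_start_um
        self.y_center_px = rows / 2.0

    @property
    def pixel_size_um(self) -> float:
        return self.acq.pixel_size_um

    def pixel_to_physical(self, row: float, col: float) -> Tuple[float, float]:
        """(row, col) pixel-centre coordinates -> physical (y_um, x_um)."""
        px = self.acq.pixel_size_um
        x = self.x0_um + (col + 0.5) * px
        y = (row + 0.5 - self.y_center_px) * px
        return y, x

    def physical_to_pixel(self, y_um: float, x_um: float) -> Tuple[float, float]:
        """Physical (y_um, x_um) -> continuous (row, col); exact inverse."""
        px = self.acq.pixel_size_um
        col = (x_um - self.x0_um) / px - 0.5
        row = y_um / px + self.y_center_px - 0.5
        return row, col


def coordinate_frame(geom: ChannelGeometry, acq: AcquisitionConfig) -> CoordinateFrame:
    """Build the shared pixel<->physical coordinate frame for a recording."""
    return CoordinateFrame(geom, acq)


def load_config(path: str | Path) -> Tuple[ChannelGeometry, AcquisitionConfig]:
    """Read a JSON or YAML config with ``geometry`` and ``acquisition`` keys."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    geom = ChannelGeometry(**data.get("geometry", {}))
    acq_raw = dict(data.get("acquisition", {}))
    if "image_shape_px" in acq_raw:
        acq_raw["image_shape_px"] = tuple(acq_raw["image_shape_px"])
    acq = AcquisitionConfig(**acq_raw)
    return geom, acq


def save_config(path: str | Path, geom: ChannelGeometry, acq: AcquisitionConfig) -> None:
    path = Path(path)
    data = {
        "geometry": geom.model_dump(),
        "acquisition": {**acq.model_dump(), "image_shape_px": list(acq.image_shape_px)},
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
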