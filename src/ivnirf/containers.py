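"""Data containers for co-registered NIRF/geometry pullbacks.

A pullback is a helical scan: the catheter rotates while being withdrawn, one
rotation producing one cross-sectional frame of ``n_angles`` angular samples.
Each angular sample carries a NIRF intensity plus geometry measured on the
co-registered ultrasound frame: the water path from the sensor to the outer
sheath wall (``ds``), the distance from the sheath wall to the labeled target
(``d_out``), and a label telling whether that angle sees the guidewire
reference, tissue, or background.

All distances are millimetres; intensities are arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError, SchemaError

LABEL_BACKGROUND = 0
LABEL_GUIDEWIRE = 1
LABEL_TISSUE = 2

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_GUIDEWIRE: "guidewire",
    LABEL_TISSUE: "tissue",
}


def frame_count(length_mm: float, pullback_speed_mm_s: float, rpm: float) -> int:
    """Number of cross-sectional frames of a helical pullback.

    One frame per catheter rotation: ``floor(length / speed * rpm / 60)``.

    Parameters
    ----------
    length_mm : float
        Total pullback length in mm.
    pullback_speed_mm_s : float
        Linear withdrawal speed in mm/s.
    rpm : float
        Rotation speed in revolutions per minute.
    """
    for name, value in (
        ("length_mm", length_mm),
        ("pullback_speed_mm_s", pullback_speed_mm_s),
        ("rpm", rpm),
    ):
        if not np.isfinite(value) or value <= 0:
            raise DomainError(f"{name} must be positive and finite, got {value!r}")
    return int(math.floor(length_mm / pullback_speed_mm_s * rpm / 60.0))


@dataclass(frozen=True)
class Kinematics:
    """Pullback kinematics: length (mm), speed (mm/s) and rotation (rpm)."""

    length_mm: float
    pullback_speed_mm_s: float
    rpm: float

    @property
    def n_frames(self) -> int:
        return frame_count(self.length_mm, self.pullback_speed_mm_s, self.rpm)

    @property
    def frame_positions(self) -> np.ndarray:
        """Pullback position (mm) of each frame, starting at 0."""
        step = self.pullback_speed_mm_s * 60.0 / self.rpm
        return np.arange(self.n_frames) * step

    def to_dict(self) -> dict:
        return {
            "length_mm": self.length_mm,
            "pullback_speed_mm_s": self.pullback_speed_mm_s,
            "rpm": self.rpm,
        }


@dataclass
class NirfFrame:
    """One cross-sectional frame of angular NIRF intensities."""

    intensities: np.ndarray
    frame_index: int
    position: float


@dataclass
class FrameGeometry:
    """Per-angle geometry of one frame.

    ``ds``: sensor -> outer sheath wall water path (mm).
    ``d_out``: outer sheath wall -> target distance (mm).
    ``label``: one of LABEL_BACKGROUND / LABEL_GUIDEWIRE / LABEL_TISSUE.
    """

    ds: np.ndarray
    d_out: np.ndarray
    label: np.ndarray

    def validate(self) -> None:
        if not (self.ds.shape == self.d_out.shape == self.label.shape):
            raise SchemaError("geometry arrays must share one shape")
        if np.any(self.ds < 0):
            raise DomainError("ds must be non-negative everywhere")
        labeled = self.label != LABEL_BACKGROUND
        if np.any(~np.isfinite(self.d_out[labeled])) or np.any(self.d_out[labeled] < 0):
            raise DomainError("d_out must be finite and >= 0 wherever labeled")


@dataclass
class Truth:
    """Generating ground truth carried by simulated pullbacks (pre-noise)."""

    source: np.ndarray         # (F, A) unattenuated source intensity
    concentration: np.ndarray  # (F, A) fluorophore concentration, uM
    cb: np.ndarray             # (F,) generating medium coefficient per frame


@dataclass
class Pullback:
    """Ordered, co-registered NIRF + geometry frames of one pullback."""

    nirf: np.ndarray       # (F, A)
    ds: np.ndarray         # (F, A)
    d_out: np.ndarray      # (F, A)
    labels: np.ndarray     # (F, A) int
    positions: np.ndarray  # (F,)
    kinematics: Kinematics
    medium: str = "water"
    meta: dict = field(default_factory=dict)
    truth: Optional[Truth] = None

    @property
    def n_frames(self) -> int:
        return self.nirf.shape[0]

    @property
    def n_angles(self) -> int:
        return self.nirf.shape[1]

    def frame(self, i: int) -> tuple[NirfFrame, FrameGeometry]:
        return (
            NirfFrame(self.nirf[i], i, float(self.positions[i])),
            FrameGeometry(self.ds[i], self.d_out[i], self.labels[i]),
        )

    def validate(self) -> "Pullback":
        if self.nirf.ndim != 2:
            raise SchemaError("nirf must be a (frames, angles) array")
        shape = self.nirf.shape
        for name in ("ds", "d_out", "labels"):
            if getattr(self, name).shape != shape:
                raise SchemaError(
                    f"{name} shape {getattr(self, name).shape} != nirf shape {shape}"
                )
        if self.positions.shape != (shape[0],):
            raise SchemaError("positions length must equal frame count")
        if np.any(self.nirf < 0):
            raise DomainError("NIRF intensities must be non-negative")
        if not np.isin(self.labels, list(LABEL_NAMES)).all():
            raise SchemaError("labels must be in {0, 1, 2}")
        FrameGeometry(self.ds, self.d_out, self.labels).validate()
        expected = self.kinematics.n_frames
        if shape[0] != expected:
            raise SchemaError(
                f"frame count {shape[0]} inconsistent with kinematics ({expected})"
            )
        return self
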