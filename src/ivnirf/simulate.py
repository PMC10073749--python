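"""Synthetic pullback generator: co-registered NIRF/geometry frames for the
three experiment scenes (slanted-guidewire water calibration, four-capillary
target phantom, blood-perfused artery), with configurable media, noise and
seeds.

Scenes are generative descriptions; :func:`simulate_scene` renders them into
:class:`~ivnirf.containers.Pullback` objects carrying the pre-noise ground
truth.  Source intensity is proportional to fluorophore concentration
(``i0_per_uM``); self-quenching is ignored because all scenes stay at or
below the coating concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .containers import (
    LABEL_BACKGROUND,
    LABEL_GUIDEWIRE,
    LABEL_TISSUE,
    Kinematics,
    Pullback,
    Truth,
    frame_count,
)
from .errors import DomainError
from .model import forward_attenuate
from .pipeline import COATING_CONCENTRATION_UM

__all__ = [
    "frame_count",
    "TargetSpec",
    "PhantomScene",
    "calibration_scene",
    "capillary_scene",
    "reference_validation_scene",
    "artery_scene",
    "simulate_scene",
    "simulate_calibration_phantom",
    "simulate_capillary_phantom",
    "simulate_artery_pullback",
    "add_noise",
]

# Coefficients as printed (per mm); multiply by a unit scale of 1000 for the
# per-um reading.
CW_WATER = 0.0009
CB_BLOOD_50 = 0.0028
CB_BLOOD_75 = 0.0034
CB_BLOOD_75_FIT = 0.0033

#: Capillary-phantom target concentrations, uM (T1, T2, T3, reference).
CAPILLARY_CONCENTRATIONS = {"T1": 6.8, "T2": 27.0, "T3": 13.0, "R": 27.0}

#: Peak injected tissue concentration of the artery scene, uM.
ARTERY_PEAK_CONCENTRATION = 38.0

DEFAULT_KINEMATICS = Kinematics(length_mm=20.0, pullback_speed_mm_s=0.25, rpm=60.0)
DEFAULT_N_ANGLES = 256
DEFAULT_DS_RANGE = (0.1, 0.6)  # sinusoidal per-angle sensor-sheath path, mm


@dataclass
class TargetSpec:
    """One fluorescent object occupying an angular sector over all frames."""

    name: str
    label: int                     # LABEL_GUIDEWIRE or LABEL_TISSUE
    sector: tuple[int, int]        # (first angle index, width in angles)
    distance_mm: np.ndarray        # (F,) sheath -> target distance per frame
    concentration_uM: np.ndarray   # (F,) fluorophore concentration per frame
    ds_mm: Optional[float] = None  # per-sector constant sensor-sheath path


@dataclass
class PhantomScene:
    """Generative description of one simulated pullback experiment."""

    kind: str                      # calibration | capillary | artery
    targets: list[TargetSpec]
    medium: str = "water"          # water | blood
    cw_true: float = CW_WATER
    cb_true: np.ndarray | float = CB_BLOOD_75   # scalar or (F,) profile
    i0_per_uM: float = 100.0       # source intensity per uM, a.u.
    kinematics: Kinematics = DEFAULT_KINEMATICS
    n_angles: int = DEFAULT_N_ANGLES
    ds_range: tuple[float, float] = DEFAULT_DS_RANGE
    ds_constant: Optional[float] = None  # overrides the sinusoidal profile
    noise_sigma: float = 0.0
    noise_floor: float = 0.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return self.kinematics.n_frames

    def medium_coefficient(self) -> np.ndarray:
        """(F,) attenuation coefficient of the luminal medium per frame."""
        F = self.n_frames
        if self.medium == "water":
            return np.full(F, float(self.cw_true))
        if self.medium == "blood":
            return np.broadcast_to(np.asarray(self.cb_true, float), (F,)).copy()
        raise DomainError(f"unknown medium {self.medium!r}")

    def validate(self) -> "PhantomScene":
        F = self.n_frames
        claimed = np.zeros(self.n_angles, dtype=bool)
        for t in self.targets:
            start, width = t.sector
            if width < 1 or start < 0 or start + width > self.n_angles:
                raise DomainError(f"target {t.name}: sector {t.sector} out of range")
            if claimed[start:start + width].any():
                raise DomainError(f"target {t.name}: overlapping angular sector")
            claimed[start:start + width] = True
            for arr_name in ("distance_mm", "concentration_uM"):
                arr = getattr(t, arr_name)
                if arr.shape != (F,):
                    raise DomainError(f"target {t.name}: {arr_name} must be (F,)")
            if np.any(t.distance_mm < 0) or np.any(t.distance_mm > 5):
                raise DomainError(f"target {t.name}: distances must lie in [0, 5] mm")
            if np.any(t.concentration_uM < 0):
                raise DomainError(f"target {t.name}: concentrations must be >= 0")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        return self


def _smooth_span(F: int, lo: float, hi: float, phase: float = 0.0) -> np.ndarray:
    """Smooth profile covering [lo, hi] exactly over F frames (half-cosine)."""
    if F == 1:
        return np.array([(lo + hi) / 2.0])
    x = np.linspace(0.0, 2.0 * np.pi, F) + phase
    return lo + (hi - lo) * (1.0 - np.cos(x)) / 2.0


def calibration_scene(
    *,
    concentration_uM: float = COATING_CONCENTRATION_UM,
    d_range: tuple[float, float] = (0.1, 1.0),
    cw_true: float = CW_WATER,
    unit_scale: float = 1.0,
    kinematics: Kinematics = DEFAULT_KINEMATICS,
    n_angles: int = DEFAULT_N_ANGLES,
    i0_per_uM: float = 100.0,
    noise_sigma: float = 0.0,
    noise_floor: float = 0.0,
    seed: int = 0,
) -> PhantomScene:
    """Slanted-guidewire water phantom: the guidewire distance ramps linearly
    across the pullback (default 0.1 -> 1.0 mm)."""
    F = kinematics.n_frames
    gw = TargetSpec(
        name="GW",
        label=LABEL_GUIDEWIRE,
        sector=(n_angles // 8, max(8, n_angles // 8)),
        distance_mm=np.linspace(d_range[0], d_range[1], F),
        concentration_uM=np.full(F, float(concentration_uM)),
    )
    return PhantomScene(
        kind="calibration",
        targets=[gw],
        medium="water",
        cw_true=cw_true * unit_scale,
        i0_per_uM=i0_per_uM,
        kinematics=kinematics,
        n_angles=n_angles,
        noise_sigma=noise_sigma,
        noise_floor=noise_floor,
        seed=seed,
    ).validate()


def capillary_scene(
    *,
    medium: str = "blood",
    cb_true: float | np.ndarray = CB_BLOOD_75,
    cw_true: float = CW_WATER,
    unit_scale: float = 1.0,
    concentrations: Optional[dict[str, float]] = None,
    target_d_range: tuple[float, float] = (0.55, 1.0),
    reference_d_band: tuple[float, float] = (0.43, 0.53),
    kinematics: Kinematics = DEFAULT_KINEMATICS,
    n_angles: int = DEFAULT_N_ANGLES,
    i0_per_uM: float = 100.0,
    noise_sigma: float = 0.0,
    noise_floor: float = 0.0,
    seed: int = 0,
) -> PhantomScene:
    """Four-capillary target phantom.

    A reference capillary (guidewire surrogate, 27 uM) sits near 0.45 mm with
    a smooth jitter inside the given band; three slanted target capillaries
    (6.8 / 27 / 13 uM) span ``target_d_range`` over the pullback.  Each
    sector gets its own constant sensor-sheath path (T3 < T1 < T2, with a
    small reference path), enabling the sheath-correction impact experiment.
    """
    F = kinematics.n_frames
    conc = dict(CAPILLARY_CONCENTRATIONS)
    if concentrations:
        conc.update(concentrations)
    lo, hi = target_d_range
    width = max(8, n_angles // 10)
    step = n_angles // 4
    ds_per_sector = {"R": 0.05, "T1": 0.30, "T2": 0.50, "T3": 0.15}
    targets = [
        TargetSpec(
            name="R",
            label=LABEL_GUIDEWIRE,
            sector=(step * 0 + 8, width),
            distance_mm=_smooth_span(F, reference_d_band[0], reference_d_band[1]),
            concentration_uM=np.full(F, conc["R"]),
            ds_mm=ds_per_sector["R"],
        )
    ]
    for j, name in enumerate(("T1", "T2", "T3"), start=1):
        targets.append(
            TargetSpec(
                name=name,
                label=LABEL_TISSUE,
                sector=(step * j + 8, width),
                distance_mm=np.linspace(lo, hi, F),
                concentration_uM=np.full(F, conc[name]),
                ds_mm=ds_per_sector[name],
            )
        )
    return PhantomScene(
        kind="capillary",
        targets=targets,
        medium=medium,
        cw_true=cw_true * unit_scale,
        cb_true=np.asarray(cb_true, float) * unit_scale,
        i0_per_uM=i0_per_uM,
        kinematics=kinematics,
        n_angles=n_angles,
        noise_sigma=noise_sigma,
        noise_floor=noise_floor,
        seed=seed,
    ).validate()


def reference_validation_scene(
    *,
    medium: str = "blood",
    cb_true: float | np.ndarray = CB_BLOOD_75,
    cw_true: float = CW_WATER,
    unit_scale: float = 1.0,
    concentration_uM: float = CAPILLARY_CONCENTRATIONS["R"],
    d_range: tuple[float, float] = (0.5, 1.6),
    kinematics: Kinematics = DEFAULT_KINEMATICS,
    n_angles: int = DEFAULT_N_ANGLES,
    i0_per_uM: float = 100.0,
    noise_sigma: float = 0.0,
    noise_floor: float = 0.0,
    seed: int = 0,
) -> PhantomScene:
    """Single slanted reference capillary spanning a wide distance range,
    used to fit the medium coefficient globally and validate the frame-wise
    estimates against it."""
    F = kinematics.n_frames
    ref = TargetSpec(
        name="R",
        label=LABEL_GUIDEWIRE,
        sector=(n_angles // 8, max(8, n_angles // 8)),
        distance_mm=np.linspace(d_range[0], d_range[1], F),
        concentration_uM=np.full(F, float(concentration_uM)),
    )
    return PhantomScene(
        kind="capillary",
        targets=[ref],
        medium=medium,
        cw_true=cw_true * unit_scale,
        cb_true=np.asarray(cb_true, float) * unit_scale,
        i0_per_uM=i0_per_uM,
        kinematics=kinematics,
        n_angles=n_angles,
        noise_sigma=noise_sigma,
        noise_floor=noise_floor,
        seed=seed,
    ).validate()


def artery_scene(
    *,
    medium: str = "blood",
    cb_true: float | np.ndarray = CB_BLOOD_75,
    cw_true: float = CW_WATER,
    unit_scale: float = 1.0,
    gw_d_range: tuple[float, float] = (0.5, 0.85),
    tissue_d_range: tuple[float, float] = (0.09, 0.4),
    peak_concentration_uM: float = ARTERY_PEAK_CONCENTRATION,
    kinematics: Kinematics = DEFAULT_KINEMATICS,
    n_angles: int = DEFAULT_N_ANGLES,
    i0_per_uM: float = 100.0,
    noise_sigma: float = 0.0,
    noise_floor: float = 0.0,
    seed: int = 0,
) -> PhantomScene:
    """Blood-perfused artery with an injected fluorophore bolus.

    The guidewire distance varies smoothly over 0.5-0.85 mm, the tissue
    distance over 0.09-0.4 mm, and the tissue concentration follows a
    Gaussian bump along the pullback peaking at 38 uM mid-pullback.  A paired
    control pullback is obtained by re-rendering the same scene with
    ``medium="water"``.
    """
    F = kinematics.n_frames
    frames = np.arange(F)
    # peak centered on a frame so the generating maximum is attained exactly
    bump = peak_concentration_uM * np.exp(
        -(((frames - (F - 1) // 2) / (0.35 * max(F, 2))) ** 2)
    )
    gw = TargetSpec(
        name="GW",
        label=LABEL_GUIDEWIRE,
        sector=(n_angles // 12, max(8, n_angles // 8)),
        distance_mm=_smooth_span(F, gw_d_range[0], gw_d_range[1]),
        concentration_uM=np.full(F, COATING_CONCENTRATION_UM),
    )
    tissue = TargetSpec(
        name="tissue",
        label=LABEL_TISSUE,
        sector=(n_angles // 2, max(8, n_angles // 4)),
        distance_mm=_smooth_span(F, tissue_d_range[0], tissue_d_range[1], phase=np.pi / 3),
        concentration_uM=bump,
    )
    return PhantomScene(
        kind="artery",
        targets=[gw, tissue],
        medium=medium,
        cw_true=cw_true * unit_scale,
        cb_true=np.asarray(cb_true, float) * unit_scale,
        i0_per_uM=i0_per_uM,
        kinematics=kinematics,
        n_angles=n_angles,
        noise_sigma=noise_sigma,
        noise_floor=noise_floor,
        seed=seed,
    ).validate()


def _render(scene: PhantomScene) -> Pullback:
    scene.validate()
    F, A = scene.n_frames, scene.n_angles
    if scene.ds_constant is not None:
        ds_profile = np.full(A, float(scene.ds_constant))
    else:
        lo, hi = scene.ds_range
        angles = np.arange(A) * 2.0 * np.pi / A
        ds_profile = lo + (hi - lo) * (1.0 + np.sin(angles)) / 2.0
    ds = np.tile(ds_profile, (F, 1))
    d_out = np.zeros((F, A))
    labels = np.full((F, A), LABEL_BACKGROUND, dtype=np.int8)
    source = np.zeros((F, A))
    concentration = np.zeros((F, A))
    c_med = scene.medium_coefficient()
    for t in scene.targets:
        start, width = t.sector
        cols = slice(start, start + width)
        if t.ds_mm is not None:
            ds[:, cols] = t.ds_mm
        d_out[:, cols] = t.distance_mm[:, None]
        labels[:, cols] = t.label
        concentration[:, cols] = t.concentration_uM[:, None]
        source[:, cols] = scene.i0_per_uM * t.concentration_uM[:, None]
    nirf = forward_attenuate(source, scene.cw_true, ds, c_med[:, None], d_out)
    pullback = Pullback(
        nirf=nirf,
        ds=ds,
        d_out=d_out,
        labels=labels,
        positions=scene.kinematics.frame_positions,
        kinematics=scene.kinematics,
        medium=scene.medium,
        meta={"scene_kind": scene.kind, "seed": scene.seed,
              "i0_per_uM": scene.i0_per_uM, "cw_true": scene.cw_true},
        truth=Truth(source=source, concentration=concentration, cb=c_med),
    ).validate()
    if scene.noise_sigma > 0 or scene.noise_floor > 0:
        pullback = add_noise(pullback, scene.noise_sigma, scene.noise_floor, scene.seed)
    return pullback


def simulate_scene(scene: PhantomScene) -> Pullback:
    """Render any scene kind."""
    dispatch = {
        "calibration": simulate_calibration_phantom,
        "capillary": simulate_capillary_phantom,
        "artery": simulate_artery_pullback,
    }
    if scene.kind not in dispatch:
        raise DomainError(f"unknown scene kind {scene.kind!r}")
    return dispatch[scene.kind](scene)


def simulate_calibration_phantom(scene: PhantomScene) -> Pullback:
    """Render a water calibration scene (guidewire at ramped distance)."""
    if scene.kind != "calibration":
        raise DomainError(f"expected a calibration scene, got {scene.kind!r}")
    if scene.medium != "water":
        raise DomainError("calibration scenes must be rendered through water")
    return _render(scene)


def simulate_capillary_phantom(scene: PhantomScene) -> Pullback:
    if scene.kind != "capillary":
        raise DomainError(f"expected a capillary scene, got {scene.kind!r}")
    return _render(scene)


def simulate_artery_pullback(scene: PhantomScene) -> Pullback:
    if scene.kind != "artery":
        raise DomainError(f"expected an artery scene, got {scene.kind!r}")
    return _render(scene)


def paired_control(scene: PhantomScene) -> PhantomScene:
    """Control (water-medium) variant of a scene with identical geometry."""
    return replace(scene, medium="water")


def add_noise(pullback: Pullback, sigma: float, floor: float, seed: int) -> Pullback:
    """Seeded measurement noise: each intensity is multiplied by a lognormal
    factor with median 1 and log-sd ``sigma``, then a non-negative
    (half-normal, scale ``floor``) background is added."""
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    if floor < 0:
        raise DomainError("floor must be >= 0")
    if sigma == 0 and floor == 0:
        return pullback
    rng = np.random.default_rng(seed)
    nirf = pullback.nirf.copy()
    if sigma > 0:
        nirf *= np.exp(rng.normal(0.0, sigma, size=nirf.shape))
    if floor > 0:
        nirf += np.abs(rng.normal(0.0, floor, size=nirf.shape))
    return replace_nirf(pullback, nirf)


def replace_nirf(pullback: Pullback, nirf: np.ndarray) -> Pullback:
    out = Pullback(
        nirf=nirf,
        ds=pullback.ds,
        d_out=pullback.d_out,
        labels=pullback.labels,
        positions=pullback.positions,
        kinematics=pullback.kinematics,
        medium=pullback.medium,
        meta=dict(pullback.meta),
        truth=pullback.truth,
    )
    return out.validate()
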