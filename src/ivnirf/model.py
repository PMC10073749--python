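"""Two-media exponential attenuation model and its inverse operations.

The optical path is split at the outer sheath wall: light first crosses the
water-filled gap inside the sheath (path ``ds``, coefficient ``cw``), then the
luminal medium (path ``d_out``, coefficient ``c_medium`` — water in control
runs, blood otherwise).  All coefficients are effective single-term exponential
coefficients over the combined excitation + emission path.

Sign convention (self-consistent, round-trip exact): the forward model
multiplies by ``exp(-c*d)`` per medium segment; every correction multiplies by
``exp(+c*d)`` to undo it.  ``cb`` is the *total* coefficient of the luminal
medium, not the excess over water; with that choice, blood correction exactly
cancels the forward blood term and a water medium yields ``cb == cw``.
Calibration look-ups are referenced at the outer sheath wall.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DomainError,
    NegativeCoefficientWarning,
    SuperUnityTransmissionWarning,
)

#: Intensities are floored at this value before any logarithm.
EPS_INTENSITY = 1e-12


@dataclass(frozen=True)
class OpticalPathModel:
    """Fitted single-medium model: incident intensity at the sheath wall plus
    the water coefficient.  Any object exposing ``i0`` and ``cw`` (e.g. a
    :class:`~ivnirf.calibration.CalibrationResult`) is accepted wherever this
    type is."""

    cw: float  # water attenuation coefficient, 1/mm
    i0: float  # incident intensity at the sheath-wall reference plane, a.u.

    def __post_init__(self):
        if not np.isfinite(self.cw) or self.cw < 0:
            raise DomainError(f"cw must be finite and >= 0, got {self.cw!r}")
        if not np.isfinite(self.i0) or self.i0 <= 0:
            raise DomainError(f"i0 must be finite and > 0, got {self.i0!r}")


def _check_nonneg(**kwargs) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise DomainError(f"{name} must be finite")
        if np.any(arr < 0):
            raise DomainError(f"{name} must be non-negative")


def forward_attenuate(i_source, cw, ds, c_medium, d_out):
    """Attenuate a source intensity through the in-sheath water path and the
    luminal medium: ``i_source * exp(-cw*ds) * exp(-c_medium*d_out)``.

    Array inputs broadcast; scalars return floats.
    """
    _check_nonneg(i_source=i_source, cw=cw, ds=ds, c_medium=c_medium, d_out=d_out)
    out = np.asarray(i_source, dtype=float) * np.exp(
        -(np.asarray(cw, dtype=float) * np.asarray(ds, dtype=float)
          + np.asarray(c_medium, dtype=float) * np.asarray(d_out, dtype=float))
    )
    return float(out) if np.ndim(out) == 0 else out


def water_correct_to_sheath(i_meas, cw, ds):
    """Undo the in-sheath water loss: ``i_meas * exp(+cw*ds)``.

    References the measured intensity to the outer sheath wall; the result is
    never smaller than the input (``cw, ds >= 0``).
    """
    _check_nonneg(i_meas=i_meas, cw=cw, ds=ds)
    out = np.asarray(i_meas, dtype=float) * np.exp(
        np.asarray(cw, dtype=float) * np.asarray(ds, dtype=float)
    )
    return float(out) if np.ndim(out) == 0 else out


def estimate_cb_frame(igw_star, calib, d, *, clamp_negative: bool = False) -> float:
    """Estimate the frame's total luminal attenuation coefficient from the
    sheath-referenced guidewire intensity ``igw_star`` against the water
    calibration look-up at the same sheath-to-guidewire distance ``d``.

    ``cb = ln(lookup(d) / igw_star) / d + cw`` where
    ``lookup(d) = i0 * exp(-cw*d)``; on noiseless model data this returns the
    generating coefficient exactly.  Assumes equal incident intensities
    between the calibration and the measurement.

    A negative estimate (possible under noise) is returned as-is with a
    warning unless ``clamp_negative`` is set.
    """
    igw_star = float(igw_star)
    d = float(d)
    if not math.isfinite(igw_star) or igw_star <= 0:
        raise DomainError(f"igw_star must be > 0, got {igw_star!r}")
    if not math.isfinite(d) or d <= 0:
        raise DomainError(f"distance must be > 0, got {d!r}")
    i0, cw = float(calib.i0), float(calib.cw)
    if igw_star > i0:
        warnings.warn(
            f"reference intensity {igw_star:.6g} exceeds calibrated incident "
            f"intensity {i0:.6g} (super-unity transmission)",
            SuperUnityTransmissionWarning,
            stacklevel=2,
        )
    reference = i0 * math.exp(-cw * d)
    cb = math.log(reference / max(igw_star, EPS_INTENSITY)) / d + cw
    if cb < 0:
        warnings.warn(
            f"estimated coefficient is negative ({cb:.6g} 1/mm)",
            NegativeCoefficientWarning,
            stacklevel=2,
        )
        if clamp_negative:
            cb = 0.0
    return cb


def blood_correct(it_star, cb, d_t):
    """Undo luminal-medium attenuation: ``it_star * exp(+cb*d_t)``.

    ``cb`` may be negative (noisy estimate passed through un-clamped), in
    which case the "correction" attenuates.
    """
    _check_nonneg(it_star=it_star, d_t=d_t)
    cb_arr = np.asarray(cb, dtype=float)
    if not np.all(np.isfinite(cb_arr)):
        raise DomainError("cb must be finite")
    out = np.asarray(it_star, dtype=float) * np.exp(cb_arr * np.asarray(d_t, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def ground_truth_correct(it_water, cw, ds, d_t):
    """Remove all water attenuation from a control (water-medium) sample:
    ``it_water * exp(+cw*(ds + d_t))`` — a noiseless control pullback then
    yields the unattenuated source intensity."""
    _check_nonneg(it_water=it_water, cw=cw, ds=ds, d_t=d_t)
    out = np.asarray(it_water, dtype=float) * np.exp(
        np.asarray(cw, dtype=float)
        * (np.asarray(ds, dtype=float) + np.asarray(d_t, dtype=float))
    )
    return float(out) if np.ndim(out) == 0 else out


def to_concentration(i_corrected, i_ref_corrected, c_ref):
    """Linear intensity-to-concentration map against the reference coating:
    ``c_ref * i_corrected / i_ref_corrected`` (uM).

    ``i_ref_corrected`` must already be propagated to the zero-distance plane
    (i.e. it is the unattenuated reference source intensity).
    """
    i_ref_corrected = float(i_ref_corrected)
    c_ref = float(c_ref)
    if not math.isfinite(i_ref_corrected) or i_ref_corrected <= 0:
        raise DomainError(f"reference intensity must be > 0, got {i_ref_corrected!r}")
    if not math.isfinite(c_ref) or c_ref <= 0:
        raise DomainError(f"reference concentration must be > 0, got {c_ref!r}")
    out = c_ref * np.asarray(i_corrected, dtype=float) / i_ref_corrected
    return float(out) if np.ndim(out) == 0 else out
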