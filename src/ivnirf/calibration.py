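"""Water-phantom calibration: fit the one-term exponential model to guidewire
signals measured at varying distance in water and expose the fitted
distance -> reference-intensity look-up.

The fit is an ordinary least-squares line on log-intensity versus distance
(exactly solvable, unique); the look-up evaluates the fitted model
analytically rather than interpolating the raw table, so reference values are
available at any distance.  The raw per-frame table is retained for
diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import LABEL_GUIDEWIRE, Pullback
from .errors import DomainError, FitError, IvnirfWarning, MissingGuidewireError
from .model import EPS_INTENSITY

DEFAULT_TOP_K = 5  # highest five angular values averaged per frame


@dataclass
class CalibrationResult:
    """Fitted single-medium model plus fit diagnostics.

    ``i0`` is referenced at the outer sheath wall, so look-up values are
    directly comparable to sheath-referenced (water-corrected) measurements.
    ``table`` holds (sheath-to-guidewire distance, sheath-referenced top-k
    mean intensity) pairs, one per usable frame.
    """

    i0: float
    cw: float
    r2: float
    table: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        if not np.isfinite(self.i0) or self.i0 <= 0:
            raise DomainError(f"i0 must be > 0, got {self.i0!r}")
        if self.r2 > 1 + 1e-12:
            raise DomainError(f"r2 cannot exceed 1, got {self.r2!r}")


def top_k_mean(values, k: int = DEFAULT_TOP_K) -> float:
    """Mean of the ``k`` largest values (order-independent).

    With fewer than ``k`` values, the mean of all of them is returned with a
    warning.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise DomainError("top_k_mean requires a non-empty sequence")
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k!r}")
    if arr.size < k:
        warnings.warn(
            f"only {arr.size} values available for top-{k} mean; using all",
            IvnirfWarning,
            stacklevel=2,
        )
        return float(arr.mean())
    return float(np.partition(arr, arr.size - k)[arr.size - k:].mean())


def fit_exponential(distances, intensities) -> CalibrationResult:
    """Fit ``I = i0 * exp(-c * d)`` by OLS on log-intensity vs distance.

    Non-positive intensities are excluded with a warning; at least two
    distinct distances must remain.  ``r2`` is the coefficient of
    determination on the log scale (defined as 1.0 for constant data).
    """
    d = np.asarray(distances, dtype=float).ravel()
    i = np.asarray(intensities, dtype=float).ravel()
    if d.shape != i.shape:
        raise DomainError("distances and intensities must have equal length")
    keep = i > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} non-positive intensities from fit",
            IvnirfWarning,
            stacklevel=2,
        )
        d, i = d[keep], i[keep]
    if np.unique(d).size < 2:
        raise FitError("fit requires at least 2 distinct distances")
    y = np.log(np.maximum(i, EPS_INTENSITY))
    slope, intercept = np.polyfit(d, y, 1)
    residuals = y - (slope * d + intercept)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationResult(
        i0=float(np.exp(intercept)),
        cw=float(-slope),
        r2=min(r2, 1.0),
        table=np.column_stack([d, i]),
    )


def lookup_reference(calib: CalibrationResult, d) -> float:
    """Reference intensity expected at sheath-to-guidewire distance ``d`` in
    water: ``i0 * exp(-cw*d)``, evaluated from the fitted model."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0) or not np.all(np.isfinite(d_arr)):
        raise DomainError("look-up distance must be finite and >= 0")
    out = calib.i0 * np.exp(-calib.cw * d_arr)
    return float(out) if np.ndim(out) == 0 else out


def run_calibration(pullback: Pullback, k: int = DEFAULT_TOP_K) -> CalibrationResult:
    """Extract per-frame guidewire signals from a water pullback and fit the
    exponential model.

    Per frame, the ``k`` brightest guidewire-labeled samples are reduced to a
    single point: their log-mean intensity paired with their mean *total*
    water path (``ds + d_out``).  Fitting against the total path makes the
    intercept the sheath-wall-referenced incident intensity without needing
    the (yet unknown) water coefficient for in-sheath pre-correction, and is
    exactly log-linear on noiseless model data.

    The returned ``table`` stores, per frame, the sheath-to-guidewire
    distance and the arithmetic top-k mean referenced to the sheath wall with
    the fitted coefficient.
    """
    total_paths = np.empty(pullback.n_frames)
    log_means = np.empty(pullback.n_frames)
    d_gw = np.empty(pullback.n_frames)
    ds_gw = np.empty(pullback.n_frames)
    tkm = np.empty(pullback.n_frames)
    for f in range(pullback.n_frames):
        gw = np.flatnonzero(pullback.labels[f] == LABEL_GUIDEWIRE)
        if gw.size == 0:
            raise MissingGuidewireError(f"no guidewire samples in frame {f}")
        vals = pullback.nirf[f, gw]
        kk = min(k, vals.size)
        if vals.size < k:
            warnings.warn(
                f"frame {f}: only {vals.size} guidewire samples for top-{k}",
                IvnirfWarning,
                stacklevel=2,
            )
        top = np.argpartition(vals, vals.size - kk)[vals.size - kk:]
        sel = gw[top]
        log_means[f] = np.mean(np.log(np.maximum(pullback.nirf[f, sel], EPS_INTENSITY)))
        total_paths[f] = np.mean(pullback.ds[f, sel] + pullback.d_out[f, sel])
        d_gw[f] = np.mean(pullback.d_out[f, sel])
        ds_gw[f] = np.mean(pullback.ds[f, sel])
        tkm[f] = np.mean(pullback.nirf[f, sel])
    result = fit_exponential(total_paths, np.exp(log_means))
    result.table = np.column_stack([d_gw, tkm * np.exp(result.cw * ds_gw)])
    return result
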