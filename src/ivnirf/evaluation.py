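"""Quantitative evaluation: accuracy/variance metrics, fold improvement over
uncorrected signals, fit-based validation of frame-wise coefficients, the
agreement metric, and the distance-error sensitivity analysis.

Metric definitions (stated here because only the resulting numbers, not the
formulas, are conventionally reported): per-sample accuracy is
``100 * (1 - |x - truth| / truth)`` clamped at 0; "variance" is the
population variance of the per-sample accuracies in percent squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .calibration import DEFAULT_TOP_K, CalibrationResult, fit_exponential
from .containers import LABEL_BACKGROUND, LABEL_GUIDEWIRE, LABEL_TISSUE, Pullback
from .errors import DomainError, IvnirfWarning
from .model import estimate_cb_frame, water_correct_to_sheath
from .pipeline import correct_pullback
from .simulate import PhantomScene, simulate_scene

#: Default distance perturbations for the sensitivity analysis, micrometres.
DEFAULT_DELTAS_UM = (-100.0, -50.0, 0.0, 50.0, 100.0)

#: Marker returned by fold_improvement when the corrected error is zero.
INFINITE_IMPROVEMENT = float("inf")


def accuracy(corrected, truth) -> tuple[float, float]:
    """Mean per-sample accuracy (%) and population variance of the
    per-sample accuracies (%^2)."""
    c = np.asarray(corrected, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if c.size == 0 or t.size == 0:
        raise DomainError("accuracy requires non-empty inputs")
    if c.shape != t.shape:
        raise DomainError("corrected and truth must have equal length")
    if np.any(t <= 0):
        raise DomainError("truth values must be > 0")
    per_sample = np.clip(100.0 * (1.0 - np.abs(c - t) / t), 0.0, None)
    return float(per_sample.mean()), float(per_sample.var())


def fold_improvement(uncorrected, corrected, truth) -> float:
    """Ratio of mean relative errors: uncorrected over corrected.

    Uncorrected (and, for scale fairness, corrected) values are first put on
    the truth scale with a single least-squares gain, making the metric
    insensitive to the arbitrary intensity units of the raw signal.  A zero
    corrected error returns ``inf``.
    """
    u = np.asarray(uncorrected, dtype=float).ravel()
    c = np.asarray(corrected, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if not (u.shape == c.shape == t.shape) or t.size == 0:
        raise DomainError("all inputs must be non-empty and of equal length")
    if np.any(t <= 0):
        raise DomainError("truth values must be > 0")

    def gain_error(x: np.ndarray) -> float:
        denom = float(np.dot(x, x))
        g = float(np.dot(x, t)) / denom if denom > 0 else 1.0
        return float(np.mean(np.abs(g * x - t) / t))

    err_c = gain_error(c)
    err_u = gain_error(u)
    if err_c == 0.0:
        return INFINITE_IMPROVEMENT
    return err_u / err_c


def agreement_metric(calculated, fitted) -> float:
    """Agreement between frame-calculated and fit-extracted coefficients:
    ``100 * (1 - mean(|calculated - fitted| / calculated))``."""
    c = np.asarray(calculated, dtype=float).ravel()
    f = np.asarray(fitted, dtype=float).ravel()
    if c.shape != f.shape:
        raise DomainError("sequences must have equal length")
    if c.size == 0:
        raise DomainError("sequences must be non-empty")
    if np.any(c <= 0):
        raise DomainError("calculated coefficients must be > 0")
    return float(100.0 * (1.0 - np.mean(np.abs(c - f) / c)))


@dataclass
class SensitivityReport:
    """Accuracy versus simulated distance-measurement error."""

    deltas_um: np.ndarray           # evaluated perturbations
    accuracy_per_delta: np.ndarray  # mean accuracy (%) at each delta
    mean_accuracy: float            # mean over the nonzero deltas (%)


def sensitivity_analysis(
    scene: PhantomScene,
    calib: CalibrationResult,
    deltas_um=DEFAULT_DELTAS_UM,
    *,
    c_ref: float | None = None,
) -> SensitivityReport:
    """Perturb the sheath-to-guidewire and sheath-to-tissue distances fed to
    the correction jointly by each signed delta (geometry truth unchanged),
    rerun the correction, and score concentration accuracy against the
    generating truth.

    Deltas that would drive any labeled distance non-positive are skipped
    with a warning.  The summary figure is the mean accuracy over the
    *nonzero* evaluated deltas.
    """
    scene = replace(scene, noise_sigma=0.0, noise_floor=0.0)
    pullback = simulate_scene(scene)
    if pullback.truth is None:
        raise DomainError("sensitivity analysis needs a simulated scene with truth")
    if c_ref is None:
        gw_targets = [t for t in scene.targets if t.label == LABEL_GUIDEWIRE]
        c_ref = float(gw_targets[0].concentration_uM[0])
    tissue_mask = pullback.labels == LABEL_TISSUE
    truth_conc = pullback.truth.concentration[tissue_mask]

    kept, acc = [], []
    for delta_um in np.asarray(deltas_um, dtype=float):
        delta_mm = delta_um / 1000.0
        labeled = pullback.labels != LABEL_BACKGROUND
        d_out = pullback.d_out.copy()
        d_out[labeled] += delta_mm
        if np.any(d_out[labeled] <= 0):
            warnings.warn(
                f"delta {delta_um:+g} um drives a distance non-positive; skipped",
                IvnirfWarning,
                stacklevel=2,
            )
            continue
        perturbed = Pullback(
            nirf=pullback.nirf,
            ds=pullback.ds,
            d_out=d_out,
            labels=pullback.labels,
            positions=pullback.positions,
            kinematics=pullback.kinematics,
            medium=pullback.medium,
            meta=dict(pullback.meta),
        )
        series = correct_pullback(perturbed, calib, c_ref)
        mean_acc, _ = accuracy(series.concentration_map[tissue_mask], truth_conc)
        kept.append(delta_um)
        acc.append(mean_acc)
    kept_arr = np.asarray(kept)
    acc_arr = np.asarray(acc)
    nonzero = kept_arr != 0
    if not nonzero.any():
        raise DomainError("no nonzero delta could be evaluated")
    return SensitivityReport(
        deltas_um=kept_arr,
        accuracy_per_delta=acc_arr,
        mean_accuracy=float(acc_arr[nonzero].mean()),
    )


def validate_cb_fit(
    pullback: Pullback,
    calib: CalibrationResult,
    *,
    k: int = DEFAULT_TOP_K,
) -> tuple[float, np.ndarray]:
    """Fit the one-term model globally to the sheath-referenced reference
    intensities versus distance of a blood pullback whose reference target
    spans a distance range, and return (fitted coefficient, per-frame
    calculated coefficients) for comparison.

    A distance span below 0.2 mm makes the global fit poorly conditioned and
    triggers a warning; the fit is still returned.
    """
    F = pullback.n_frames
    igw_star = np.empty(F)
    d_gw = np.empty(F)
    cb_calc = np.empty(F)
    for f in range(F):
        gw = np.flatnonzero(pullback.labels[f] == LABEL_GUIDEWIRE)
        if gw.size == 0:
            raise DomainError(f"frame {f} has no reference samples")
        vals = np.asarray(
            water_correct_to_sheath(pullback.nirf[f, gw], calib.cw, pullback.ds[f, gw]),
            float,
        )
        kk = min(k, vals.size)
        top = np.argpartition(vals, vals.size - kk)[vals.size - kk:]
        igw_star[f] = vals[top].mean()
        d_gw[f] = pullback.d_out[f, gw[top]].mean()
        cb_calc[f] = estimate_cb_frame(igw_star[f], calib, d_gw[f])
    span = float(d_gw.max() - d_gw.min())
    if span < 0.2:
        warnings.warn(
            f"reference distance span {span:.3f} mm < 0.2 mm; global fit is "
            "poorly conditioned",
            IvnirfWarning,
            stacklevel=2,
        )
    fit = fit_exponential(d_gw, igw_star)
    return float(fit.cw), cb_calc
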