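"""Time-series conditioning before dynamic-connectivity analysis.

Operations, in their canonical pipeline order: discard of initial volumes,
optional nuisance regression against motion/trend regressors, despiking, and
zero-phase Butterworth band-pass filtering.  Framewise displacement is
computed from rigid-body motion parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

#: Robust-scale factor relating MAD to Gaussian sigma.
_MAD_TO_SD = 1.4826


@dataclass
class ComponentTimecourses:
    """One subject's T x C matrix of component signals.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        Either ``"patient"`` or ``"control"``.
    data : ndarray of shape (T, C)
        Component amplitudes, one column per component.
    tr_seconds : float
        Repetition time of the acquisition in seconds.
    """

    subject_id: str
    group: str
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-course data must be a 2-D T x C matrix")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 components")
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in time courses")
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionParams:
    """Six rigid-body realignment parameter traces (6 x T).

    Rows 0-2 are translations in mm, rows 3-5 rotations in radians.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 6:
            raise ValueError("motion parameters must be a 6 x T matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite motion parameters")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class FDSeries:
    """Per-volume framewise displacement in mm."""

    values: np.ndarray
    mean_fd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values[0] != 0:
            raise ValueError("framewise displacement must start at 0")
        if (self.values < 0).any():
            raise ValueError("framewise displacement must be non-negative")
        self.mean_fd = float(self.values.mean())


def discard_initial_volumes(tc: ComponentTimecourses, n_discard: int = 3) -> ComponentTimecourses:
    """Drop the first ``n_discard`` volumes (T1-disequilibrium settling)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= tc.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {tc.n_volumes} volumes for subject {tc.subject_id}"
        )
    return replace(tc, data=tc.data[n_discard:].copy())


def build_motion_regressors(mp: MotionParams) -> np.ndarray:
    """T x 12 design: the six parameters and their backward first differences.

    The first row of each derivative column is zero.
    """
    params = mp.data.T  # T x 6
    deriv = np.zeros_like(params)
    deriv[1:] = np.diff(params, axis=0)
    return np.hstack([params, deriv])


def regress_nuisance(tc: ComponentTimecourses, regressors: np.ndarray | None) -> ComponentTimecourses:
    """Residualize every component on [intercept | regressors] by least squares.

    With no regressors this reduces to column-mean removal.  Raises if the
    design (including the intercept) is rank-deficient, naming the collinear
    columns.
    """
    t = tc.n_volumes
    if regressors is None or (hasattr(regressors, "size") and regressors.size == 0):
        design = np.ones((t, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != t:
            raise ValueError(
                f"regressor rows ({regressors.shape[0]}) != time points ({t})"
            )
        design = np.hstack([np.ones((t, 1)), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, tc.data, rcond=None)
    resid = tc.data - design @ beta
    return replace(tc, data=resid)


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Greedy scan for columns linearly dependent on the preceding ones."""
    bad = []
    for j in range(1, design.shape[1]):
        sub = design[:, : j + 1]
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            bad.append(j)
    return bad


def framewise_displacement(mp: MotionParams, sphere_radius_mm: float = 50.0) -> FDSeries:
    """Sum of absolute frame-to-frame parameter changes, rotations scaled to mm.

    ``FD(t) = sum |d trans_i| + radius * sum |d rot_j|`` with ``FD(0) = 0``.
    Rotations (radians) are converted to arc length on a sphere of the given
    radius.
    """
    diffs = np.abs(np.diff(mp.data, axis=1))  # 6 x (T-1)
    fd = np.zeros(mp.n_volumes)
    fd[1:] = diffs[:3].sum(axis=0) + sphere_radius_mm * diffs[3:].sum(axis=0)
    return FDSeries(values=fd)


def despike(series: np.ndarray, mad_threshold: float = 4.0, median_window: int = 11) -> np.ndarray:
    """Shrink outliers toward a running median with a smooth squashing.

    Samples whose robust z-score (deviation from a running median, scaled by
    1.4826 * MAD of those deviations) exceeds ``mad_threshold`` are replaced by
    ``median + sign * sigma * (threshold + tanh(|z| - threshold))``, bounding
    the post-despike robust z-score below ``mad_threshold + 1``.  All other
    samples pass through unchanged; constant series are returned as-is.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("despike operates on 1-D series")
    if series.size < 5:
        raise ValueError("series too short to despike (need >= 5 samples)")
    run_med = ndimage.median_filter(series, size=median_window, mode="nearest")
    resid = series - run_med
    mad = np.median(np.abs(resid))
    if mad == 0:
        return series.copy()
    sigma = _MAD_TO_SD * mad
    z = resid / sigma
    out = series.copy()
    hot = np.abs(z) > mad_threshold
    if hot.any():
        zh = z[hot]
        out[hot] = run_med[hot] + np.sign(zh) * sigma * (
            mad_threshold + np.tanh(np.abs(zh) - mad_threshold)
        )
    return out


def despike_timecourses(tc: ComponentTimecourses, mad_threshold: float = 4.0) -> ComponentTimecourses:
    """Apply :func:`despike` to every component column."""
    cols = [despike(tc.data[:, j], mad_threshold=mad_threshold) for j in range(tc.n_components)]
    return replace(tc, data=np.column_stack(cols))


def bandpass(
    series: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass filter.

    The effective magnitude response is the squared single-pass response, so
    the effective order doubles; no phase shift is introduced.
    """
    series = np.asarray(series, dtype=float)
    nyquist = 0.5 / tr_seconds
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz ({high_hz}) must be below Nyquist ({nyquist})")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos")
    return signal.sosfiltfilt(sos, series, axis=0)


def bandpass_timecourses(
    tc: ComponentTimecourses,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
    order: int = 5,
) -> ComponentTimecourses:
    """Band-pass every component column (zero-phase)."""
    filtered = bandpass(tc.data, tc.tr_seconds, low_hz=low_hz, high_hz=high_hz, order=order)
    return replace(tc, data=filtered)


def preprocess(
    tc: ComponentTimecourses,
    n_discard: int = 3,
    motion: MotionParams | None = None,
    regress_motion: bool = False,
    mad_threshold: float = 4.0,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
    order: int = 5,
) -> ComponentTimecourses:
    """Canonical conditioning chain: discard -> (nuisance) -> despike -> band-pass.

    Nuisance regression (motion parameters + derivatives + linear/quadratic/
    cubic trends) is optional and off by default: component time courses from
    a cleaned decomposition arrive already orthogonalized.
    """
    logger.info(
        "preprocess subject=%s discard=%d regress_motion=%s band=(%g,%g) order=%d",
        tc.subject_id, n_discard, regress_motion, low_hz, high_hz, order,
    )
    out = discard_initial_volumes(tc, n_discard)
    if regress_motion:
        if motion is None:
            raise ValueError("regress_motion=True requires motion parameters")
        mp = MotionParams(motion.data[:, n_discard:])
        t = out.n_volumes
        trend = np.arange(t, dtype=float)
        regs = np.hstack([
            build_motion_regressors(mp),
            np.column_stack([trend, trend**2, trend**3]),
        ])
        out = regress_nuisance(out, regs)
    out = despike_timecourses(out, mad_threshold=mad_threshold)
    out = bandpass_timecourses(out, low_hz=low_hz, high_hz=high_hz, order=order)
    return out
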