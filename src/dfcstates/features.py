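"""Windowed connectivity features.

Sliding-window Pearson correlations (SWC), their boxcar averages (ASWC) with
first-order derivatives, per-subject block z-scoring, cohort concatenation,
and full-length static connectivity.

Window-count convention: with step 1 a T-volume series yields ``W = T - L``
windows of length ``L`` (the final window ending exactly at T is not formed),
so 222 volumes -> 200 SWC windows -> 175 aligned ASWC+derivative windows with
the default lengths 22 and 25.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .prep import ComponentTimecourses

logger = logging.getLogger(__name__)


def vectorize_pairs(n_components: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle pair order (i < j); length C(C-1)/2."""
    if n_components < 2:
        raise ValueError("need at least 2 components to form pairs")
    return [(i, j) for i in range(n_components) for j in range(i + 1, n_components)]


@dataclass
class SWCSeries:
    """Per-subject sliding-window correlations: W windows x P component pairs."""

    subject_id: str
    windows: np.ndarray
    window_size_tr: int = 22
    step_tr: int = 1
    pair_index: list[tuple[int, int]] | None = None

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.windows.shape[1]


@dataclass
class DfcFeatureSet:
    """Aligned ASWC and derivative blocks: W' windows x 2P features.

    Column ``j < P`` is pair j's ASWC; column ``P + j`` is the same pair's
    derivative.
    """

    subject_id: str
    aswc: np.ndarray
    derivatives: np.ndarray
    aswc_window: int = 25
    zscored: bool = False

    @property
    def features(self) -> np.ndarray:
        return np.hstack([self.aswc, self.derivatives])

    @property
    def n_windows(self) -> int:
        return self.aswc.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.aswc.shape[1]


@dataclass
class StaticFC:
    """Full-length correlation matrix over a component subset."""

    matrix: np.ndarray
    subset: np.ndarray


@dataclass
class CohortFeatures:
    """Cohort-concatenated feature matrix with a (subject, window) row index."""

    matrix: np.ndarray
    index: pd.DataFrame  # columns: subject_id, window

    def subject_rows(self, subject_id: str) -> np.ndarray:
        return np.flatnonzero((self.index["subject_id"] == subject_id).to_numpy())


def sliding_window_correlations(
    tc: ComponentTimecourses, window_size_tr: int = 22, step_tr: int = 1
) -> SWCSeries:
    """Pearson correlation of every component pair in each sliding window.

    Window ``w`` covers TRs ``[w * step, w * step + L)`` (0-based half-open);
    ``W = floor((T - L) / step)``.  A zero-variance component inside a window
    sets its pairs' correlations to 0 with a warning (keeps clustering total).
    """
    t, c = tc.data.shape
    if t < window_size_tr:
        raise ValueError(f"need T >= window length ({window_size_tr}), got {t}")
    # W = (T - L) // step; a full-length window (T == L) degenerates to W = 1
    n_windows = max((t - window_size_tr) // step_tr, 1)
    view = sliding_window_view(tc.data, window_size_tr, axis=0)  # (T-L+1, C, L)
    view = view[: n_windows * step_tr : step_tr]
    centered = view - view.mean(axis=2, keepdims=True)
    cov = np.einsum("wct,wdt->wcd", centered, centered)
    sd = np.sqrt(np.einsum("wcc->wc", cov))
    degenerate = sd == 0
    if degenerate.any():
        nwin = int(degenerate.any(axis=1).sum())
        warnings.warn(
            f"subject {tc.subject_id}: zero-variance component in {nwin} window(s); "
            "affected correlations set to 0",
            stacklevel=2,
        )
        sd[degenerate] = 1.0
    corr = cov / (sd[:, :, None] * sd[:, None, :])
    if degenerate.any():
        corr[degenerate[:, :, None] | degenerate[:, None, :]] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    iu = np.triu_indices(c, k=1)
    return SWCSeries(
        subject_id=tc.subject_id,
        windows=corr[:, iu[0], iu[1]],
        window_size_tr=window_size_tr,
        step_tr=step_tr,
        pair_index=vectorize_pairs(c),
    )


def aswc_and_derivatives(
    swc: SWCSeries, aswc_window: int = 25, drop: str = "last"
) -> DfcFeatureSet:
    """Boxcar-average the SWC series and take aligned first differences.

    ``ASWC_raw(t)`` averages SWC windows ``[t, t + A)``; the derivative is
    ``ASWC_raw(t+1) - ASWC_raw(t)``.  One raw average is dropped so both
    blocks share indices, leaving ``W' = W - A`` aligned windows; ``drop``
    selects whether the last (default) or first raw window is discarded.
    """
    w = swc.n_windows
    if w < aswc_window + 1:
        raise ValueError(f"need at least {aswc_window + 1} SWC windows, got {w}")
    if drop not in ("last", "first"):
        raise ValueError("drop must be 'last' or 'first'")
    raw = sliding_window_view(swc.windows, aswc_window, axis=0).mean(axis=2)  # (W-A+1, P)
    deriv = np.diff(raw, axis=0)  # (W-A, P)
    return DfcFeatureSet(
        subject_id=swc.subject_id,
        aswc=raw[:-1] if drop == "last" else raw[1:],
        derivatives=deriv,
        aswc_window=aswc_window,
    )


def zscore_feature_blocks(fs: DfcFeatureSet, per_feature: bool = False) -> DfcFeatureSet:
    """Standardize the ASWC and derivative blocks separately (per subject).

    By default each block is centered and scaled over all its entries to grand
    mean 0 and grand (population) SD 1; ``per_feature=True`` standardizes each
    column of a block instead.
    """
    if fs.zscored:
        return fs

    def _z(block: np.ndarray, name: str) -> np.ndarray:
        axis = 0 if per_feature else None
        sd = block.std(axis=axis)
        if np.any(sd <= 1e-12 * (np.abs(block.mean(axis=axis)) + 1)):
            raise ValueError(f"subject {fs.subject_id}: {name} block is constant")
        return (block - block.mean(axis=axis)) / sd

    return replace(
        fs,
        aswc=_z(fs.aswc, "ASWC"),
        derivatives=_z(fs.derivatives, "derivative"),
        zscored=True,
    )


def concatenate_cohort(feature_sets: list[DfcFeatureSet]) -> CohortFeatures:
    """Stack subjects' feature matrices in manifest order with a row index."""
    if not feature_sets:
        raise ValueError("no feature sets to concatenate")
    ref = feature_sets[0]
    for fs in feature_sets[1:]:
        if fs.aswc.shape != ref.aswc.shape:
            raise ValueError(
                f"subject {fs.subject_id}: feature shape {fs.features.shape} "
                f"differs from {ref.subject_id}'s {ref.features.shape}"
            )
    matrix = np.vstack([fs.features for fs in feature_sets])
    index = pd.DataFrame(
        {
            "subject_id": np.repeat([fs.subject_id for fs in feature_sets], ref.n_windows),
            "window": np.tile(np.arange(ref.n_windows), len(feature_sets)),
        }
    )
    logger.info("concatenated cohort matrix: %d x %d", *matrix.shape)
    return CohortFeatures(matrix=matrix, index=index)


def static_fc(tc: ComponentTimecourses, subset: np.ndarray | list[int] | None = None) -> StaticFC:
    """Full-length Pearson correlation matrix over a component subset."""
    subset = np.arange(tc.n_components) if subset is None else np.asarray(subset, dtype=int)
    if subset.size < 2:
        raise ValueError("subset must contain at least 2 components")
    if subset.min() < 0 or subset.max() >= tc.n_components:
        raise ValueError("subset indices out of range")
    data = tc.data[:, subset]
    if (data.std(axis=0) == 0).any():
        bad = subset[data.std(axis=0) == 0]
        raise ValueError(f"zero-variance component(s) {bad.tolist()} in static FC")
    return StaticFC(matrix=np.corrcoef(data, rowvar=False), subset=subset)
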