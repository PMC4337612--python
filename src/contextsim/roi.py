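"""ROI hygiene: temporal-SNR voxel filtering, pattern extraction, outliers.

ROI masks are filtered to drop voxels whose mean temporal SNR (across all
functional runs) falls more than one standard deviation below the ROI mean;
trial patterns are extracted as column subsets of the beta series; trials
with outlying global signal are flagged by the run-wise mean of absolute
standardized voxel values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, EmptyInputError
from .glm import BetaSeries


def compute_tsnr(runs: list[np.ndarray]) -> np.ndarray:
    """Per-voxel temporal SNR (mean/SD over time), averaged across runs.

    Each run is (n_voxels, n_scans). Zero-variance voxels get +inf.
    """

    if not runs:
        raise EmptyInputError("no runs supplied")
    per_run = []
    for Y in runs:
        Y = np.asarray(Y, dtype=float)
        sd = Y.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = Y.mean(axis=1) / sd
        t[sd == 0.0] = np.inf
        per_run.append(t)
    return np.mean(per_run, axis=0)


@dataclass
class ROIMask:
    """A named boolean mask on the functional grid, with optional tSNR."""

    label: str
    voxels: np.ndarray  # boolean, grid-shaped
    tsnr: np.ndarray | None = None  # full-grid per-voxel tSNR

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.voxels.ravel())


def filter_low_snr_voxels(mask: ROIMask, n_sd: float = 1.0) -> ROIMask:
    """Drop voxels with tSNR below (ROI mean - n_sd x ROI SD).

    Statistics are computed within the mask; re-filtering recomputes them on
    the already-filtered set (the operation is not idempotent by design).
    """

    if mask.tsnr is None:
        raise ConfigurationError("mask has no tSNR; run compute_tsnr first")
    flat = mask.voxels.ravel()
    vals = np.asarray(mask.tsnr).ravel()[flat]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise EmptyInputError(f"ROI {mask.label!r} has no finite-tSNR voxels")
    cut = finite.mean() - n_sd * finite.std()
    keep = flat.copy()
    keep[flat] = np.isfinite(vals) & (vals >= cut)
    if not keep.any():
        raise EmptyInputError(f"tSNR filter emptied ROI {mask.label!r}")
    return ROIMask(
        label=mask.label, voxels=keep.reshape(mask.voxels.shape), tsnr=mask.tsnr
    )


def extract_patterns(beta_series: BetaSeries, mask: ROIMask) -> BetaSeries:
    """Column subset of a full-grid beta series by an ROI mask."""

    idx = mask.flat_indices()
    if beta_series.matrix.shape[1] <= idx.max():
        raise ConfigurationError(
            f"mask {mask.label!r} indexes voxel {idx.max()} but the beta "
            f"series has {beta_series.matrix.shape[1]} columns"
        )
    return BetaSeries(matrix=beta_series.matrix[:, idx], meta=beta_series.meta)


def flag_outlier_trials(
    beta_series: BetaSeries, threshold_sd: float = 3.0
) -> np.ndarray:
    """Boolean flags for trials with outlying global signal.

    Per run, voxel values are standardized across trials; each trial's score
    is the mean absolute standardized value over voxels, and trials whose
    score exceeds the run mean by more than ``threshold_sd`` run-SDs are
    flagged.
    """

    flags = np.zeros(beta_series.n_trials, dtype=bool)
    runs = beta_series.meta["run"].to_numpy()
    for run in np.unique(runs):
        rows = np.flatnonzero(runs == run)
        B = beta_series.matrix[rows]
        sd = B.std(axis=0)
        sd[sd == 0.0] = 1.0
        z = (B - B.mean(axis=0)) / sd
        score = np.abs(z).mean(axis=1)
        s_sd = score.std()
        if s_sd == 0.0 or not np.isfinite(threshold_sd):
            continue
        flags[rows[score > score.mean() + threshold_sd * s_sd]] = True
    return flags
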