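"""GLM estimation: design matrices, condition contrasts, and LSS betas.

Implements the two models run on the item-recognition runs: a nine-condition
event model (recollection/familiarity/forgotten by delay, plus correct
rejections, false alarms, and no-response trials) for univariate contrasts,
and least-squares-separate (LSS) single-trial models in which each trial is
estimated by its own GLM with one regressor for the target trial and one
pooling every other trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special
from scipy.linalg import cho_factor as _cho, cho_solve as _cho_solve

from .config import (
    CONDITIONS_9,
    TR_S,
    ConfigurationError,
    EmptyInputError,
    EstimationError,
    SchedulingError,
)

# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (s), peak-normalized.

    Positive gamma peaking ~5 s post-stimulus minus a later undershoot at
    one-sixth amplitude; the default of mainstream GLM toolchains.
    """

    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x, shape, scale):
        return (
            x ** (shape - 1)
            * np.exp(-x / scale)
            / (scale**shape * special.gamma(shape))
        )

    out[pos] = gpdf(tp, peak_delay / peak_disp, peak_disp) - gpdf(
        tp, undershoot_delay / undershoot_disp, undershoot_disp
    ) / ratio
    peak = out.max()
    if peak > 0:
        out = out / peak
    return out


@lru_cache(maxsize=4)
def _hrf_table(length_s: float, dt_s: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(0.0, length_s + dt_s, dt_s)
    return t, double_gamma_hrf(t)


def hrf_regressors(
    onsets: np.ndarray,
    n_scans: int,
    tr_s: float = TR_S,
    *,
    length_s: float = 32.0,
    dt_s: float = 0.01,
) -> np.ndarray:
    """(n_scans, n_onsets) matrix of HRF responses to zero-duration sticks.

    Because each event is a single stick, its regressor is the HRF shifted
    to the event onset and sampled at scan times.
    """

    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    t_h, h = _hrf_table(length_s, dt_s)
    scan_times = np.arange(n_scans) * tr_s
    lags = scan_times[:, None] - onsets[None, :]
    return np.interp(lags, t_h, h, left=0.0, right=0.0)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def condition_labels(trial_table: pd.DataFrame) -> pd.Series:
    """Map each trial to one of the nine event-model conditions."""

    status = trial_table["memory_status"]
    lists = trial_table["list"]
    labels = status.copy().astype(object)
    old = status.isin(("recollection", "familiarity", "forgotten"))
    labels[old] = lists[old] + "_" + status[old]
    bad = ~labels.isin(CONDITIONS_9)
    if bad.any():
        raise ConfigurationError(
            f"conditions outside the nine-condition set: {sorted(labels[bad].unique())}"
        )
    return labels


def legendre_drift(n_scans: int, order: int) -> np.ndarray:
    """(n_scans, order+1) Legendre polynomial drift basis incl. intercept."""

    t = np.linspace(-1.0, 1.0, n_scans)
    return np.stack([special.eval_legendre(k, t) for k in range(order + 1)], axis=1)


def _nuisance_block(
    n_scans: int,
    motion: np.ndarray | None,
    spike_scans,
    drift_order: int | None,
) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_scans:
            raise SchedulingError("motion trace not aligned to scans")
        cols.append(motion)
        names += [f"motion{k}" for k in range(motion.shape[1])]
    if spike_scans is not None:
        for s in sorted(set(int(s) for s in spike_scans)):
            if not 0 <= s < n_scans:
                raise SchedulingError(f"spike scan {s} outside run")
            col = np.zeros((n_scans, 1))
            col[s] = 1.0
            cols.append(col)
            names.append(f"spike{s}")
    if drift_order is not None:
        cols.append(legendre_drift(n_scans, drift_order))
        names += [f"drift{k}" for k in range(drift_order + 1)]
    if not cols:
        return np.empty((n_scans, 0)), []
    return np.hstack(cols), names


def build_design_matrix(
    trial_table: pd.DataFrame,
    n_scans: int,
    tr_s: float = TR_S,
    *,
    condition_col: str = "condition",
    motion: np.ndarray | None = None,
    spike_scans=None,
    drift_order: int | None = 2,
    hrf_length_s: float = 32.0,
) -> pd.DataFrame:
    """Condition-level design matrix: HRF-convolved sticks plus nuisance.

    ``trial_table`` needs ``onset`` and a condition column (if absent, one
    is derived from memory status and list). Raises a scheduling error for
    onsets beyond the run and refuses all-zero regressors.
    """

    table = trial_table.copy()
    if condition_col not in table:
        table[condition_col] = condition_labels(table)
    onsets = table["onset"].to_numpy(dtype=float)
    if np.any(onsets < 0) or np.any(onsets >= n_scans * tr_s):
        raise SchedulingError("event onset outside run duration")

    R = hrf_regressors(onsets, n_scans, tr_s, length_s=hrf_length_s)
    cols: dict[str, np.ndarray] = {}
    for cond in pd.unique(table[condition_col]):
        cols[str(cond)] = R[:, (table[condition_col] == cond).to_numpy()].sum(axis=1)

    nuis, nuis_names = _nuisance_block(n_scans, motion, spike_scans, drift_order)
    for name, col in zip(nuis_names, nuis.T):
        cols[name] = col

    dm = pd.DataFrame(cols)
    zero = dm.columns[(dm.abs().sum(axis=0) == 0.0)]
    if len(zero):
        raise ConfigurationError(f"all-zero regressors: {list(zero)}")
    return dm


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns loading on the smallest singular directions
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        bad = vt[rank:].__abs__().sum(axis=0)
        guilty = [names[i] for i in np.argsort(bad)[::-1][: X.shape[1] - rank + 1]]
        raise EstimationError(f"design matrix rank deficient; collinear: {guilty}")


@dataclass
class ConditionGLMResult:
    """OLS condition betas per voxel, with the design column names."""

    betas: pd.DataFrame  # index: regressor names, columns: voxel index

    def contrast(self, plus: str, minus: str) -> np.ndarray:
        return (self.betas.loc[plus] - self.betas.loc[minus]).to_numpy()

    def recollection_contrasts(self) -> dict[str, np.ndarray]:
        """Recollection-minus-familiarity per delay and their delay difference."""

        out = {}
        for delay in ("immediate", "delayed"):
            out[delay] = self.contrast(f"{delay}_recollection", f"{delay}_familiarity")
        out["delay_difference"] = out["immediate"] - out["delayed"]
        return out


def fit_condition_glm(Y: np.ndarray, dm: pd.DataFrame) -> ConditionGLMResult:
    """Fit the condition model by OLS to every voxel.

    ``Y`` is (n_scans, n_voxels); returns betas for every design column.
    """

    Y = np.asarray(Y, dtype=float)
    X = dm.to_numpy(dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise SchedulingError("data and design matrix row counts differ")
    _check_rank(X, list(dm.columns))
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return ConditionGLMResult(betas=pd.DataFrame(betas, index=dm.columns))


@dataclass
class BetaSeries:
    """Single-trial beta estimates with aligned trial metadata."""

    matrix: np.ndarray  # (n_trials, n_voxels)
    meta: pd.DataFrame  # aligned trial rows, incl. run / trial / onset

    def __post_init__(self):
        if len(self.meta) != self.matrix.shape[0]:
            raise ConfigurationError("beta matrix and metadata misaligned")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]


def fit_lss(
    Y: np.ndarray,
    trial_table: pd.DataFrame,
    tr_s: float = TR_S,
    *,
    motion: np.ndarray | None = None,
    spike_scans=None,
    drift_order: int | None = 2,
    hrf_length_s: float = 32.0,
) -> BetaSeries:
    """Least-squares-separate single-trial betas for one run.

    For each trial, an OLS model with (1) the target trial's HRF-convolved
    stick, (2) a single regressor pooling all other trials, and (3) the
    nuisance block. The target regressor's estimate is the trial beta.
    """

    Y = np.asarray(Y, dtype=float)
    onsets = trial_table["onset"].to_numpy(dtype=float)
    n_trials = len(onsets)
    if n_trials < 2:
        raise EmptyInputError("LSS needs at least 2 trials per run")
    n_scans = Y.shape[0]
    if np.any(onsets >= n_scans * tr_s):
        raise SchedulingError("trial onset beyond run duration")

    R = hrf_regressors(onsets, n_scans, tr_s, length_s=hrf_length_s)
    total = R.sum(axis=1)
    nuis, nuis_names = _nuisance_block(n_scans, motion, spike_scans, drift_order)

    betas = np.empty((n_trials, Y.shape[1]))
    for j in range(n_trials):
        X = np.column_stack([R[:, j], total - R[:, j], nuis])
        try:
            # normal equations with Cholesky; falls back to a rank check
            # plus lstsq for (near-)singular designs
            gram = X.T @ X
            c, low = _cho(gram)
            coef = _cho_solve((c, low), X.T @ Y)
        except np.linalg.LinAlgError:
            _check_rank(X, ["target", "others", *nuis_names])
            coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        betas[j] = coef[0]
    return BetaSeries(matrix=betas, meta=trial_table.reset_index(drop=True))


def concat_beta_series(parts: list[BetaSeries]) -> BetaSeries:
    """Stack per-run beta series into one subject-level series."""

    if not parts:
        raise EmptyInputError("no beta series to concatenate")
    return BetaSeries(
        matrix=np.vstack([p.matrix for p in parts]),
        meta=pd.concat([p.meta for p in parts], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Artifact flagging
# ---------------------------------------------------------------------------


def framewise_displacement(motion: np.ndarray, radius_mm: float = 50.0) -> np.ndarray:
    """ART-style composite FD: |d translations| + radius x |d rotations|.

    ``motion`` is (n_scans, 6): three translations (mm), three rotations
    (radians). The first scan has FD 0.
    """

    motion = np.asarray(motion, dtype=float)
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def flag_suspect_timepoints(
    motion: np.ndarray,
    global_signal: np.ndarray,
    *,
    fd_threshold_mm: float = 0.3,
    gs_threshold_pct: float = 1.3,
    radius_mm: float = 50.0,
) -> np.ndarray:
    """Scan indices with > 0.3 mm movement or > 1.3% global signal change.

    Global signal change is the scan-to-scan difference expressed as a
    percentage of the run-mean global signal.
    """

    motion = np.asarray(motion, dtype=float)
    gs = np.asarray(global_signal, dtype=float)
    if motion.shape[0] != gs.shape[0]:
        raise SchedulingError("motion and global signal traces not aligned")
    fd = framewise_displacement(motion, radius_mm)
    gs_change = np.concatenate([[0.0], np.abs(np.diff(gs))]) / gs.mean() * 100.0
    return np.flatnonzero((fd > fd_threshold_mm) | (gs_change > gs_threshold_pct))
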