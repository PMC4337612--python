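"""Group-level inference: within-subject factorial tests, trial matching,
brain-behavior correlation, conjunction thresholding.

The 2x2 within-subject ANOVA (memory status x delay, or pair type x delay)
is computed through difference scores, which is exact for two-level
factors: each effect's F equals the squared paired t of its contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .behavior import round_half_up
from .config import (
    ConfigurationError,
    ContextSimError,
    EmptyInputError,
    UndefinedEstimateError,
)


class SubjectExcludedError(ContextSimError):
    """A subject falls below the minimum trial-count floor."""


# ---------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA via difference scores
# ---------------------------------------------------------------------------


@dataclass
class EffectTest:
    F: float
    p: float
    df: tuple[int, int]


def rm_anova_2x2(cell_means: np.ndarray) -> dict[str, EffectTest]:
    """Within-subject 2x2 ANOVA from per-subject cell means.

    ``cell_means`` is (n_subjects, 4), columns ordered (a1b1, a1b2, a2b1,
    a2b2). Each effect is a paired t-test on the corresponding difference
    score; F = t^2 with df (1, n-1). Subjects with any missing cell are
    dropped listwise.
    """

    cells = np.asarray(cell_means, dtype=float)
    if cells.ndim != 2 or cells.shape[1] != 4:
        raise ConfigurationError("cell_means must be (n_subjects, 4)")
    complete = ~np.isnan(cells).any(axis=1)
    cells = cells[complete]
    n = cells.shape[0]
    if n < 3:
        raise EmptyInputError("need >= 3 complete subjects for the 2x2 ANOVA")

    contrasts = {
        "A": np.array([1.0, 1.0, -1.0, -1.0]) / 2.0,
        "B": np.array([1.0, -1.0, 1.0, -1.0]) / 2.0,
        "AxB": np.array([1.0, -1.0, -1.0, 1.0]),
    }
    out = {}
    for name, c in contrasts.items():
        d = cells @ c
        sd = d.std(ddof=1)
        if sd == 0.0:
            F = 0.0 if np.isclose(d.mean(), 0.0) else np.inf
        else:
            t = d.mean() / (sd / np.sqrt(n))
            F = t**2
        p = float(stats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
        out[name] = EffectTest(F=float(F), p=p, df=(1, n - 1))
    return out


# ---------------------------------------------------------------------------
# Trial-count matching
# ---------------------------------------------------------------------------

_MATCH_CELLS = [
    ("recollection", "immediate"),
    ("recollection", "delayed"),
    ("familiarity", "immediate"),
    ("familiarity", "delayed"),
]


def match_trial_counts(
    trial_table: pd.DataFrame,
    seed: int = 0,
    n_resamples: int = 1,
    *,
    floor: int = 9,
) -> list[np.ndarray]:
    """Equalize recollection/familiarity trial counts across delays.

    Returns ``n_resamples`` boolean masks over the trial table in which
    each of the four memory x delay cells is randomly subsampled (without
    replacement) to the minimum cell count; trials outside those cells are
    kept. Subjects whose minimum count falls below ``floor`` are excluded.
    """

    rng = np.random.default_rng(seed)
    status = trial_table["memory_status"].to_numpy()
    lists = trial_table["list"].to_numpy()
    cell_rows = [
        np.flatnonzero((status == st) & (lists == delay))
        for st, delay in _MATCH_CELLS
    ]
    m = min(len(rows) for rows in cell_rows)
    if m < floor:
        raise SubjectExcludedError(
            f"minimum cell count {m} below the floor of {floor} trials"
        )
    masks = []
    for _ in range(n_resamples):
        mask = np.ones(len(trial_table), dtype=bool)
        for rows in cell_rows:
            drop = rng.permutation(rows)[m:]
            mask[drop] = False
        masks.append(mask)
    return masks


# ---------------------------------------------------------------------------
# Brain-behavior correlation
# ---------------------------------------------------------------------------


@dataclass
class BrainBehaviorResult:
    r: float
    t: float
    p: float
    n: int
    partial_slope: float | None = None
    partial_slope_t: float | None = None
    partial_slope_p: float | None = None


def brain_behavior_correlation(
    context_sim: np.ndarray,
    assoc_dprime: np.ndarray,
    covariate: np.ndarray | None = None,
) -> BrainBehaviorResult:
    """Pearson correlation between context similarity and associative d'.

    Also fits similarity ~ d' + covariate by OLS to verify the relationship
    survives controlling for, e.g., the number of recollection trials.
    """

    y = np.asarray(context_sim, dtype=float)
    x = np.asarray(assoc_dprime, dtype=float)
    if y.size != x.size or y.size < 4:
        raise EmptyInputError("need >= 4 paired subjects")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedEstimateError("zero variance in correlation input")
    n = y.size
    r = float(np.corrcoef(x, y)[0, 1])
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt((n - 2) / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))

    slope = slope_t = slope_p = None
    if covariate is not None:
        X = sm.add_constant(
            np.column_stack([x, np.asarray(covariate, float)]), has_constant="add"
        )
        fit = sm.OLS(y, X).fit()
        slope = float(fit.params[1])
        slope_t, slope_p = float(fit.tvalues[1]), float(fit.pvalues[1])
    return BrainBehaviorResult(
        r=r,
        t=float(t),
        p=p,
        n=n,
        partial_slope=slope,
        partial_slope_t=slope_t,
        partial_slope_p=slope_p,
    )


# ---------------------------------------------------------------------------
# Small scalar tests
# ---------------------------------------------------------------------------


def conjunction_threshold(joint_p: float, ndigits: int | None = None) -> float:
    """Per-map threshold so two independent one-sided maps jointly meet joint_p.

    Both maps must individually pass sqrt(joint_p).
    """

    if not 0.0 < joint_p < 1.0:
        raise ConfigurationError("joint_p must lie in (0, 1)")
    per_map = float(np.sqrt(joint_p))
    return round_half_up(per_map, ndigits) if ndigits is not None else per_map


def directional_t(values: np.ndarray) -> tuple[float, float]:
    """One-sample t against 0, upper-tailed (directional hypothesis)."""

    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise EmptyInputError("need >= 2 subjects for a t-test")
    if v.std(ddof=1) == 0.0:
        # degenerate spread: t defined by the sign of the (exact) mean
        m = v.mean()
        if np.isclose(m, 0.0):
            return 0.0, 0.5
        return (np.inf, 0.0) if m > 0 else (-np.inf, 1.0)
    res = stats.ttest_1samp(v, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)
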