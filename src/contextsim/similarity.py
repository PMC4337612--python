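"""Context similarity: same-room vs different-room pattern correlation.

The statistic of interest is the difference in Fisher-z pattern similarity
between pairs of recollection trials whose items were studied in the same
room and pairs studied in different rooms. Pairs are restricted to the same
encoding list and memory status, within run, at least two presentation
positions apart; different-room pairs whose rooms were grouped into the
same house after encoding are excluded, as are pairs containing trials with
outlying global signal. Same-room and different-room similarity are
averaged within each run and then across runs; the statistic is their
difference. A stratified room-label randomization test provides the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    ConfigurationError,
    DegenerateStrataError,
    EmptyInputError,
)

_STUDIED_LISTS = ("immediate", "delayed")


def pairwise_similarity(patterns: np.ndarray, *, cocktail_blank: bool = False) -> np.ndarray:
    """Trial-by-trial Pearson correlation matrix of voxel patterns.

    Rows are trials, columns voxels. Zero-variance trials yield NaN rows
    (their pairs are invalid downstream). ``cocktail_blank`` removes the
    mean pattern across trials before correlating.
    """

    P = np.asarray(patterns, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ConfigurationError("patterns must be trials x voxels with >= 2 voxels")
    if cocktail_blank:
        P = P - P.mean(axis=0, keepdims=True)
    centered = P - P.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = centered / sd[:, None]
    Z[sd == 0.0] = np.nan
    return (Z @ Z.T) / P.shape[1]


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing arctanh, clipped away from |r| = 1."""

    return np.arctanh(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12))


@dataclass
class PairSet:
    """Selected trial pairs with their strata and pair types."""

    i: np.ndarray  # row indices into the trial metadata
    j: np.ndarray
    run: np.ndarray
    list_label: np.ndarray
    pair_type: np.ndarray  # 'same' | 'different'
    n_candidates: int = 0

    def __len__(self) -> int:
        return len(self.i)

    def counts(self) -> pd.DataFrame:
        return (
            pd.DataFrame(
                {"run": self.run, "list": self.list_label, "pair_type": self.pair_type}
            )
            .value_counts()
            .rename("n_pairs")
            .reset_index()
        )


def select_pairs(
    meta: pd.DataFrame,
    house_grouping: dict[str, str],
    *,
    status: str = "recollection",
    flags: np.ndarray | None = None,
    min_lag: int = 2,
) -> PairSet:
    """Enforce all pair-selection rules and assign pair types.

    Pairs are formed within run among trials of the requested memory status
    and the same studied list, at presentation lag >= ``min_lag``, skipping
    flagged trials; 'different' pairs from rooms sharing a house are
    dropped.
    """

    required = {"run", "trial", "list", "room", "memory_status"}
    if not required.issubset(meta.columns):
        raise ConfigurationError(f"metadata missing columns {required - set(meta.columns)}")
    flags = np.zeros(len(meta), dtype=bool) if flags is None else np.asarray(flags)

    runs = meta["run"].to_numpy()
    pos = meta["trial"].to_numpy()
    lists = meta["list"].to_numpy()
    rooms = meta["room"].to_numpy()
    stat = meta["memory_status"].to_numpy()

    ii, jj = [], []
    n_candidates = 0
    for run in np.unique(runs):
        for lst in _STUDIED_LISTS:
            rows = np.flatnonzero(
                (runs == run) & (lists == lst) & (stat == status) & ~flags
            )
            if len(rows) < 2:
                continue
            a, b = np.triu_indices(len(rows), k=1)
            keep = np.abs(pos[rows[a]] - pos[rows[b]]) >= min_lag
            n_candidates += keep.sum()
            ii.append(rows[a[keep]])
            jj.append(rows[b[keep]])
    if not ii:
        return PairSet(
            i=np.empty(0, int),
            j=np.empty(0, int),
            run=np.empty(0, int),
            list_label=np.empty(0, object),
            pair_type=np.empty(0, object),
        )
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    same = rooms[i] == rooms[j]
    house = np.vectorize(house_grouping.__getitem__)
    grouped = ~same & (house(rooms[i]) == house(rooms[j]))
    keep = same | ~grouped
    i, j, same = i[keep], j[keep], same[keep]
    return PairSet(
        i=i,
        j=j,
        run=runs[i],
        list_label=lists[i],
        pair_type=np.where(same, "same", "different"),
        n_candidates=int(n_candidates),
    )


@dataclass
class ContextSimilarityResult:
    """Run-wise and pooled same/different similarity and their difference."""

    same_mean: float
    diff_mean: float
    context_similarity: float
    per_run: pd.DataFrame
    n_same: int
    n_diff: int
    roi: str | None = None
    delay: str | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.context_similarity)


def context_similarity(
    corr: np.ndarray,
    pairs: PairSet,
    *,
    list_label: str | None = None,
    roi: str | None = None,
) -> ContextSimilarityResult:
    """Average Fisher-z similarity within run, across runs, then difference.

    Runs missing either a same-room or different-room cell are omitted from
    the cross-run average. The result is NaN if no run has both cells.
    """

    sel = np.ones(len(pairs), dtype=bool)
    if list_label is not None:
        sel &= pairs.list_label == list_label
    z = fisher_z(corr[pairs.i[sel], pairs.j[sel]])
    same = pairs.pair_type[sel] == "same"
    run = pairs.run[sel]
    valid = np.isfinite(z)

    rows = []
    for r in np.unique(run):
        m_same = valid & same & (run == r)
        m_diff = valid & ~same & (run == r)
        rows.append(
            {
                "run": int(r),
                "same_mean": z[m_same].mean() if m_same.any() else np.nan,
                "diff_mean": z[m_diff].mean() if m_diff.any() else np.nan,
                "n_same": int(m_same.sum()),
                "n_diff": int(m_diff.sum()),
            }
        )
    per_run = pd.DataFrame(
        rows, columns=["run", "same_mean", "diff_mean", "n_same", "n_diff"]
    )
    complete = per_run.dropna(subset=["same_mean", "diff_mean"])
    if len(complete) == 0:
        same_mean = diff_mean = stat = np.nan
    else:
        same_mean = float(complete["same_mean"].mean())
        diff_mean = float(complete["diff_mean"].mean())
        stat = same_mean - diff_mean
    return ContextSimilarityResult(
        same_mean=same_mean,
        diff_mean=diff_mean,
        context_similarity=stat,
        per_run=per_run,
        n_same=int(per_run["n_same"].sum()),
        n_diff=int(per_run["n_diff"].sum()),
        roi=roi,
        delay=list_label,
    )


# ---------------------------------------------------------------------------
# Randomization test
# ---------------------------------------------------------------------------


@dataclass
class RandomizationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int


def _context_stat_fast(
    z: np.ndarray,
    run: np.ndarray,
    same: np.ndarray,
    grouped: np.ndarray,
    run_values: np.ndarray,
) -> float:
    """Statistic over a fixed candidate pair set given pair-type masks."""

    keep = same | ~grouped
    same_tot, diff_tot, n_runs = [], [], 0
    for r in run_values:
        m = keep & (run == r)
        ms = m & same
        md = m & ~same
        ns, nd = ms.sum(), md.sum()
        if ns == 0 or nd == 0:
            continue
        same_tot.append(z[ms].sum() / ns)
        diff_tot.append(z[md].sum() / nd)
        n_runs += 1
    if n_runs == 0:
        return np.nan
    return (np.sum(same_tot) - np.sum(diff_tot)) / n_runs


def randomization_test(
    patterns: np.ndarray,
    meta: pd.DataFrame,
    house_grouping: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
    *,
    status: str = "recollection",
    list_label: str | None = None,
    flags: np.ndarray | None = None,
    min_lag: int = 2,
    cocktail_blank: bool = False,
) -> RandomizationResult:
    """Stratified room-label randomization test of the context statistic.

    Room labels are shuffled across trials within run x list x memory-status
    strata (preserving per-room counts); the full pair-selection and
    averaging pipeline is re-run on each permutation, including the house
    exclusion re-derived from the permuted labels. One-sided
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """

    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    corr = pairwise_similarity(patterns, cocktail_blank=cocktail_blank)
    flags = np.zeros(len(meta), dtype=bool) if flags is None else np.asarray(flags)

    runs = meta["run"].to_numpy()
    lists = meta["list"].to_numpy()
    stat_col = meta["memory_status"].to_numpy()
    rooms = meta["room"].to_numpy(dtype=object)

    analyzed_lists = _STUDIED_LISTS if list_label is None else (list_label,)
    strata = []
    any_exchangeable = False
    for run in np.unique(runs):
        for lst in analyzed_lists:
            rows = np.flatnonzero(
                (runs == run) & (lists == lst) & (stat_col == status) & ~flags
            )
            if len(rows) >= 2:
                strata.append(rows)
                if len(np.unique(rooms[rows])) >= 2:
                    any_exchangeable = True
    if not strata or not any_exchangeable:
        raise DegenerateStrataError(
            "no stratum carries more than one room label; nothing to permute"
        )

    # candidate pairs are independent of room labels
    pairs = _candidate_pairs(meta, status=status, flags=flags, min_lag=min_lag)
    sel = np.ones(len(pairs["i"]), dtype=bool)
    if list_label is not None:
        sel = pairs["list"] == list_label
    i, j, run_of_pair = pairs["i"][sel], pairs["j"][sel], pairs["run"][sel]
    if len(i) == 0:
        raise EmptyInputError("no candidate pairs for the requested cell")
    z = fisher_z(corr[i, j])
    ok = np.isfinite(z)
    i, j, run_of_pair, z = i[ok], j[ok], run_of_pair[ok], z[ok]
    run_values = np.unique(run_of_pair)

    # integer room/house codes so each permutation is pure array work
    studied_rooms = sorted(house_grouping)
    room_code = {room: k for k, room in enumerate(studied_rooms)}
    houses = sorted({house_grouping[r] for r in studied_rooms})
    house_of = np.array(
        [houses.index(house_grouping[r]) for r in studied_rooms], dtype=int
    )
    codes = np.array([room_code.get(r, -1) for r in rooms], dtype=int)

    def stat_for(labels: np.ndarray) -> float:
        ri, rj = labels[i], labels[j]
        same = ri == rj
        grouped = ~same & (house_of[ri] == house_of[rj])
        return _context_stat_fast(z, run_of_pair, same, grouped, run_values)

    observed = stat_for(codes)
    if not np.isfinite(observed):
        raise EmptyInputError("observed context similarity undefined")

    null = np.empty(n_perm)
    labels = codes.copy()
    for p in range(n_perm):
        labels[:] = codes
        for rows in strata:
            labels[rows] = codes[rows][rng.permutation(len(rows))]
        null[p] = stat_for(labels)
    valid = np.isfinite(null)
    p_value = (1.0 + np.sum(null[valid] >= observed)) / (1.0 + valid.sum())
    return RandomizationResult(
        observed=float(observed), null=null, p_value=float(p_value), n_perm=n_perm
    )


def _candidate_pairs(
    meta: pd.DataFrame,
    *,
    status: str,
    flags: np.ndarray,
    min_lag: int,
) -> dict[str, np.ndarray]:
    """Label-independent pair candidates (run, list, status, lag, flags)."""

    runs = meta["run"].to_numpy()
    pos = meta["trial"].to_numpy()
    lists = meta["list"].to_numpy()
    stat = meta["memory_status"].to_numpy()
    ii, jj = [], []
    for run in np.unique(runs):
        for lst in _STUDIED_LISTS:
            rows = np.flatnonzero(
                (runs == run) & (lists == lst) & (stat == status) & ~flags
            )
            if len(rows) < 2:
                continue
            a, b = np.triu_indices(len(rows), k=1)
            keep = np.abs(pos[rows[a]] - pos[rows[b]]) >= min_lag
            ii.append(rows[a[keep]])
            jj.append(rows[b[keep]])
    if not ii:
        return {
            "i": np.empty(0, int),
            "j": np.empty(0, int),
            "run": np.empty(0, int),
            "list": np.empty(0, object),
        }
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    return {"i": i, "j": j, "run": runs[i], "list": lists[i]}
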