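"""Behavioral measures: dual-process estimates, d-prime, source accuracy.

Recognition responses on the modified 6-point remember/know scale are
summarized into 'remember' (R) and confident-old (F) rates per list, from
which the corrected dual-process estimates are computed:

    recollection = (R_old - R_new) / (1 - R_new)
    familiarity  = F_old / (1 - R_old) - F_new / (1 - F_new)

where R_old/R_new are 'remember' rates to old/new items and F_old/F_new are
'definitely old' + 'probably old' rates. The familiarity correction term
F_new/(1 - F_new) is the study's printed form; the conventional
independence-RK term F_new/(1 - R_new) is available as a variant. Item and
associative discriminability use d' = z(hit) - z(false alarm).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import EmptyInputError, UndefinedEstimateError

#: Group-mean response rates of the reference two-day study (worked example
#: inputs): 'R' and confident-old rates per list, and associative 'intact'
#: rates for intact/recombined sentences per delay.
REFERENCE_GROUP_RATES = {
    "R_old": {"immediate": 0.46, "delayed": 0.25},
    "R_new": 0.04,
    "F_old": {"immediate": 0.40, "delayed": 0.43},
    "F_new": 0.23,
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (how printed tables are rounded)."""

    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Estimators on rates
# ---------------------------------------------------------------------------


def estimate_recollection(r_old: float, r_new: float) -> float:
    """Corrected recollection estimate (R_old - R_new) / (1 - R_new)."""

    if not (0 <= r_old <= 1 and 0 <= r_new <= 1):
        raise UndefinedEstimateError("rates must lie in [0, 1]")
    if r_new >= 1.0:
        raise UndefinedEstimateError("R_new = 1 leaves recollection undefined")
    return (r_old - r_new) / (1.0 - r_new)


def estimate_familiarity(
    f_old: float,
    r_old: float,
    f_new: float,
    variant: str = "as_printed",
    r_new: float | None = None,
) -> float:
    """Corrected familiarity estimate.

    ``as_printed``:   F_old/(1 - R_old) - F_new/(1 - F_new)
    ``conventional``: F_old/(1 - R_old) - F_new/(1 - R_new)  (needs r_new)
    """

    if r_old >= 1.0:
        raise UndefinedEstimateError("R_old = 1 leaves familiarity undefined")
    first = f_old / (1.0 - r_old)
    if variant == "as_printed":
        if f_new >= 1.0:
            raise UndefinedEstimateError("F_new = 1 leaves familiarity undefined")
        return first - f_new / (1.0 - f_new)
    if variant == "conventional":
        if r_new is None:
            raise UndefinedEstimateError("conventional variant needs r_new")
        if r_new >= 1.0:
            raise UndefinedEstimateError("R_new = 1 leaves familiarity undefined")
        return first - f_new / (1.0 - r_new)
    raise UndefinedEstimateError(f"unknown variant {variant!r}")


def dprime(
    hit_rate: float,
    fa_rate: float,
    *,
    n_signal: int | None = None,
    n_noise: int | None = None,
) -> float:
    """Signal-detection discriminability z(hit) - z(fa).

    Extreme rates (0 or 1) are corrected by the 1/(2N) rule when trial
    counts are supplied; without counts, extreme rates raise.
    """

    def correct(p: float, n: int | None) -> float:
        if 0.0 < p < 1.0:
            return p
        if n is None:
            raise UndefinedEstimateError(
                f"extreme rate {p} needs a trial count for the 1/(2N) correction"
            )
        return 1.0 - 1.0 / (2 * n) if p >= 1.0 else 1.0 / (2 * n)

    h = correct(hit_rate, n_signal)
    f = correct(fa_rate, n_noise)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


# ---------------------------------------------------------------------------
# Rates from a trial table
# ---------------------------------------------------------------------------

_OLD_RESPONSES = (4, 5, 6)  # probably old, definitely old, remember


@dataclass
class RateSummary:
    """Response rates per list (no-response trials excluded from denominators)."""

    R_old: dict[str, float]
    F_old: dict[str, float]
    hit_rate: dict[str, float]
    R_new: float
    F_new: float
    fa_rate: float
    n_old: dict[str, int]
    n_new: int


def summarize_rates(trials: pd.DataFrame) -> RateSummary:
    """Compute R, F, and old-response rates per list from a trial table."""

    if len(trials) == 0:
        raise EmptyInputError("empty trial table")
    answered = trials[trials["response"] > 0]
    if len(answered) == 0:
        raise EmptyInputError("no answered trials")

    def rates(sub: pd.DataFrame) -> tuple[float, float, float, int]:
        n = len(sub)
        if n == 0:
            raise EmptyInputError("empty response cell")
        resp = sub["response"].to_numpy()
        return (
            float((resp == 6).mean()),
            float(np.isin(resp, (4, 5)).mean()),
            float(np.isin(resp, _OLD_RESPONSES).mean()),
            n,
        )

    R_old, F_old, hit, n_old = {}, {}, {}, {}
    for lst in ("immediate", "delayed"):
        sub = answered[answered["list"] == lst]
        R_old[lst], F_old[lst], hit[lst], n_old[lst] = rates(sub)
    lure = answered[answered["list"] == "lure"]
    r_new, f_new, fa, n_new = rates(lure)
    return RateSummary(
        R_old=R_old,
        F_old=F_old,
        hit_rate=hit,
        R_new=r_new,
        F_new=f_new,
        fa_rate=fa,
        n_old=n_old,
        n_new=n_new,
    )


@dataclass
class DualProcessEstimates:
    recollection: dict[str, float]
    familiarity: dict[str, float]
    dprime_item: dict[str, float]


def dual_process_estimates(
    rates: RateSummary, variant: str = "as_printed"
) -> DualProcessEstimates:
    """Recollection, familiarity, and item d' per list from a rate summary."""

    rec, fam, dp = {}, {}, {}
    for lst in ("immediate", "delayed"):
        rec[lst] = estimate_recollection(rates.R_old[lst], rates.R_new)
        fam[lst] = estimate_familiarity(
            rates.F_old[lst], rates.R_old[lst], rates.F_new, variant, rates.R_new
        )
        dp[lst] = dprime(
            rates.hit_rate[lst],
            rates.fa_rate,
            n_signal=rates.n_old[lst],
            n_noise=rates.n_new,
        )
    return DualProcessEstimates(recollection=rec, familiarity=fam, dprime_item=dp)


def score_trial_table(
    trials: pd.DataFrame, variant: str = "as_printed"
) -> DualProcessEstimates:
    """Convenience: rates then dual-process estimates from one trial table."""

    return dual_process_estimates(summarize_rates(trials), variant)


# ---------------------------------------------------------------------------
# Associative recognition
# ---------------------------------------------------------------------------


def associative_dprime(assoc_trials: pd.DataFrame) -> dict[str, float]:
    """d' between intact and recombined sentences, per delay list."""

    out = {}
    for lst in ("immediate", "delayed"):
        sub = assoc_trials[assoc_trials["list"] == lst]
        if len(sub) == 0:
            raise EmptyInputError(f"no associative trials for list {lst!r}")
        intact = sub[sub["sentence_type"] == "intact"]
        recomb = sub[sub["sentence_type"] == "recombined"]
        hit = float((intact["response"] == "intact").mean())
        fa = float((recomb["response"] == "intact").mean())
        out[lst] = dprime(hit, fa, n_signal=len(intact), n_noise=len(recomb))
    return out


def conditional_source_accuracy(
    item_trials: pd.DataFrame,
    assoc_trials: pd.DataFrame,
    *,
    include_recombined: bool = False,
) -> pd.DataFrame:
    """Associative accuracy conditioned on prior item-memory status.

    For each memory-status bin of the item test, the proportion of correct
    associative responses among that bin's items. By default only intact
    sentences are scored; with ``include_recombined`` the sentence is binned
    by its item word's status (item-word convention). Empty bins are
    reported as NaN, never zero.
    """

    status_by_item = dict(zip(item_trials["item"], item_trials["memory_status"]))
    sub = assoc_trials
    if not include_recombined:
        sub = sub[sub["sentence_type"] == "intact"]
    rows = []
    for lst in ("immediate", "delayed"):
        for status in ("recollection", "familiarity", "forgotten"):
            cell = sub[
                (sub["list"] == lst)
                & (sub["item"].map(status_by_item) == status)
            ]
            rows.append(
                {
                    "list": lst,
                    "memory_status": status,
                    "n": len(cell),
                    "accuracy": float(cell["correct"].mean()) if len(cell) else np.nan,
                }
            )
    return pd.DataFrame(rows)
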