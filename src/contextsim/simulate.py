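"""Synthetic data generation for the two-day item-context experiment.

Generates, with known ground truth: the experimental design (list, room,
and house assignments plus per-phase trial schedules), remember/know
behavior from a dual-process generative model, and ROI-structured BOLD
time series in which recollection trials carry a shared room-specific
pattern component whose strength is set by a context gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .config import (
    TR_S,
    BehavioralParams,
    ConfigurationError,
    DesignParams,
    NeuralParams,
    SchedulingError,
)

# ---------------------------------------------------------------------------
# Seed fan-out
# ---------------------------------------------------------------------------

_STAGES = ("design", "behavior", "neural", "bold", "patterns", "associative")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive an independent generator for a named pipeline stage.

    One master seed fans out to per-stage streams so that, e.g., changing
    the behavioral draw does not perturb the neural realization.
    """

    if stage not in _STAGES:
        raise ConfigurationError(f"unknown RNG stage {stage!r}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Jittered onsets
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _truncexp_scale(target_mean: float, upper: float) -> float:
    """Scale of an exponential truncated to [0, upper] with the given mean."""

    def mean_of(scale: float) -> float:
        z = upper / scale
        return scale - upper * np.exp(-z) / (1.0 - np.exp(-z))

    return float(optimize.brentq(lambda s: mean_of(s) - target_mean, 1e-3, 1e3))


def generate_jittered_onsets(
    n_trials: int,
    duration_s: float,
    seed: int | np.random.Generator,
    *,
    mean_gap_s: float = 4.0,
    gap_range_s: tuple[float, float] = (2.0, 10.0),
    step_s: float = 0.5,
    start_s: float = 0.0,
) -> np.ndarray:
    """Strictly increasing onsets separated by jittered fixation gaps.

    Gaps follow a shifted exponential truncated to ``gap_range_s`` with the
    requested mean, discretized to ``step_s`` increments (a standard
    rapid event-related jitter scheme).
    """

    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = gap_range_s
    scale = _truncexp_scale(mean_gap_s - lo, hi - lo)
    u = rng.random(n_trials - 1)
    # inverse-CDF sampling of the truncated exponential
    z = (hi - lo) / scale
    x = -scale * np.log1p(-u * (1.0 - np.exp(-z)))
    gaps = lo + np.round(x / step_s) * step_s
    gaps = np.clip(gaps, lo, hi)
    onsets = start_s + np.concatenate([[0.0], np.cumsum(gaps + duration_s)])
    return onsets


# ---------------------------------------------------------------------------
# Experimental design
# ---------------------------------------------------------------------------


@dataclass
class ExperimentDesign:
    """Item, context, and schedule structure for one simulated subject."""

    items: list[str]
    #: item -> 'immediate' | 'delayed' | 'lure'
    list_assignment: dict[str, str]
    #: studied item -> room name
    room_assignment: dict[str, str]
    #: day -> list of its four rooms ('day1' holds the delayed list's rooms)
    day_rooms: dict[str, list[str]]
    #: room -> house label; rooms grouped after encoding, two per house
    house_grouping: dict[str, str]
    #: day -> DataFrame(onset, duration, item, room)
    encoding_schedule: dict[str, pd.DataFrame]
    #: DataFrame(run, trial, onset, duration, item, list, room)
    recognition_schedule: pd.DataFrame
    #: DataFrame(run, trial, onset, duration, item, room, sentence_type, list)
    associative_schedule: pd.DataFrame
    params: DesignParams = field(default_factory=DesignParams)

    @property
    def n_runs(self) -> int:
        return int(self.recognition_schedule["run"].max()) + 1


_LIST_DAY = {"delayed": "day1", "immediate": "day2"}


def generate_design(seed: int, config: DesignParams | None = None) -> ExperimentDesign:
    """Generate one subject's full experimental design.

    Deterministic given ``seed``. Honors the study structure: three equal
    item lists, four rooms per study day with equal items per room, equal
    per-room trial counts in each recognition run, and per day 28 intact
    plus 56 recombined associative sentences recombined within day only.
    """

    config = config or DesignParams()
    config.validate()
    rng = stage_rng(seed, "design")

    n_list = config.items_per_list
    items = [f"item{i:03d}" for i in range(config.n_items)]
    shuffled = list(rng.permutation(items))
    lists = {
        "delayed": shuffled[:n_list],
        "immediate": shuffled[n_list : 2 * n_list],
        "lure": shuffled[2 * n_list :],
    }
    list_assignment = {it: name for name, its in lists.items() for it in its}

    from .config import ROOMS

    if config.n_rooms > len(ROOMS):
        room_names = [f"room{i}" for i in range(config.n_rooms)]
    else:
        room_names = list(ROOMS[: config.n_rooms])
    room_order = list(rng.permutation(room_names))
    day_rooms = {
        "day1": room_order[: config.rooms_per_day],
        "day2": room_order[config.rooms_per_day :],
    }

    items_per_room = n_list // config.rooms_per_day
    room_assignment: dict[str, str] = {}
    room_items: dict[str, list[str]] = {}
    for lst in ("delayed", "immediate"):
        day = _LIST_DAY[lst]
        perm = list(rng.permutation(lists[lst]))
        for r, room in enumerate(day_rooms[day]):
            members = perm[r * items_per_room : (r + 1) * items_per_room]
            room_items[room] = members
            for it in members:
                room_assignment[it] = room

    house_grouping: dict[str, str] = {}
    for day in ("day1", "day2"):
        paired = list(rng.permutation(day_rooms[day]))
        half = len(paired) // 2
        for h in range(half):
            for room in paired[2 * h : 2 * h + 2]:
                house_grouping[room] = f"{day}_house{h + 1}"

    encoding_schedule = {}
    for day in ("day1", "day2"):
        lst = "delayed" if day == "day1" else "immediate"
        order = list(rng.permutation(lists[lst]))
        onsets = generate_jittered_onsets(
            len(order),
            config.encoding_duration_s,
            rng,
            mean_gap_s=config.jitter_mean_s,
            gap_range_s=config.jitter_range_s,
            step_s=config.jitter_step_s,
        )
        encoding_schedule[day] = pd.DataFrame(
            {
                "onset": onsets,
                "duration": config.encoding_duration_s,
                "item": order,
                "room": [room_assignment[i] for i in order],
            }
        )

    # --- item recognition: per room, split its items evenly across runs ---
    per_run_items: list[list[str]] = [[] for _ in range(config.n_runs)]
    per_room_per_run = items_per_room // config.n_runs
    for room, members in room_items.items():
        perm = list(rng.permutation(members))
        for run in range(config.n_runs):
            per_run_items[run].extend(
                perm[run * per_room_per_run : (run + 1) * per_room_per_run]
            )
    lures_per_run = n_list // config.n_runs
    lure_perm = list(rng.permutation(lists["lure"]))
    for run in range(config.n_runs):
        per_run_items[run].extend(
            lure_perm[run * lures_per_run : (run + 1) * lures_per_run]
        )

    rec_rows = []
    for run in range(config.n_runs):
        order = list(rng.permutation(per_run_items[run]))
        onsets = generate_jittered_onsets(
            len(order),
            config.recognition_duration_s,
            rng,
            mean_gap_s=config.jitter_mean_s,
            gap_range_s=config.jitter_range_s,
            step_s=config.jitter_step_s,
        )
        for t, (item, onset) in enumerate(zip(order, onsets)):
            rec_rows.append(
                {
                    "run": run,
                    "trial": t,
                    "onset": onset,
                    "duration": config.recognition_duration_s,
                    "item": item,
                    "list": list_assignment[item],
                    "room": room_assignment.get(item, "n/a"),
                }
            )
    recognition_schedule = pd.DataFrame(rec_rows)

    # --- associative recognition: intact vs recombined, within day only ---
    assoc_sentences = []
    for lst in ("delayed", "immediate"):
        day = _LIST_DAY[lst]
        perm = list(rng.permutation(lists[lst]))
        intact = perm[: config.n_intact_per_day]
        recombined = perm[config.n_intact_per_day :]
        for it in intact:
            assoc_sentences.append((it, room_assignment[it], "intact", lst))
        rooms = day_rooms[day]
        for it in recombined:
            own = room_assignment[it]
            other = [r for r in rooms if r != own]
            new_room = other[rng.integers(len(other))]
            assoc_sentences.append((it, new_room, "recombined", lst))

    # even split of each day-list's sentences across runs
    assoc_rows = []
    by_list: dict[str, list] = {"delayed": [], "immediate": []}
    for sent in assoc_sentences:
        by_list[sent[3]].append(sent)
    per_list_per_run = n_list // config.n_runs
    run_sentences: list[list] = [[] for _ in range(config.n_runs)]
    for lst, sents in by_list.items():
        order = [sents[k] for k in rng.permutation(len(sents))]
        for run in range(config.n_runs):
            run_sentences[run].extend(
                order[run * per_list_per_run : (run + 1) * per_list_per_run]
            )
    for run in range(config.n_runs):
        order = [run_sentences[run][k] for k in rng.permutation(len(run_sentences[run]))]
        onsets = generate_jittered_onsets(
            len(order),
            config.associative_duration_s,
            rng,
            mean_gap_s=config.jitter_mean_s,
            gap_range_s=config.jitter_range_s,
            step_s=config.jitter_step_s,
        )
        for t, ((item, room, kind, lst), onset) in enumerate(zip(order, onsets)):
            assoc_rows.append(
                {
                    "run": run,
                    "trial": t,
                    "onset": onset,
                    "duration": config.associative_duration_s,
                    "item": item,
                    "room": room,
                    "sentence_type": kind,
                    "list": lst,
                }
            )
    associative_schedule = pd.DataFrame(assoc_rows)

    return ExperimentDesign(
        items=items,
        list_assignment=list_assignment,
        room_assignment=room_assignment,
        day_rooms=day_rooms,
        house_grouping=house_grouping,
        encoding_schedule=encoding_schedule,
        recognition_schedule=recognition_schedule,
        associative_schedule=associative_schedule,
        params=config,
    )


# ---------------------------------------------------------------------------
# Behavioral simulation
# ---------------------------------------------------------------------------


def _classify_status(is_old: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Memory status from response codes (6='remember', 4/5 confident old)."""

    status = np.full(is_old.shape, "no_response", dtype=object)
    answered = response > 0
    old = is_old & answered
    new = ~is_old & answered
    status[old & (response == 6)] = "recollection"
    status[old & np.isin(response, (4, 5))] = "familiarity"
    status[old & np.isin(response, (1, 2, 3))] = "forgotten"
    status[new & np.isin(response, (4, 5, 6))] = "false_alarm"
    status[new & np.isin(response, (1, 2, 3))] = "correct_rejection"
    return status


def simulate_behavior(
    design: ExperimentDesign,
    params: BehavioralParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate item-recognition responses on the 6-point remember/know scale.

    Returns the trial table: one row per recognition trial with the response
    code (1-6, 0 for no response), response time, and derived memory status.
    """

    params = params or BehavioralParams()
    params.validate()
    rng = stage_rng(seed, "behavior")

    table = design.recognition_schedule.copy()
    n = len(table)
    lists = table["list"].to_numpy()
    is_old = lists != "lure"

    rho = np.zeros(n)
    rho[lists == "immediate"] = params.rho_immediate
    rho[lists == "delayed"] = params.rho_delayed
    recollected = (rng.random(n) < rho) & is_old

    spurious = rng.random(n) < params.spurious_remember_rate
    mu = np.full(n, params.familiarity_mu["lure"])
    for lst in ("immediate", "delayed"):
        mu[lists == lst] = params.familiarity_mu[lst]
    strength = rng.normal(mu, 1.0)
    graded = np.searchsorted(np.asarray(params.criteria), strength) + 1

    response = np.where(recollected | spurious, 6, graded)
    no_resp = rng.random(n) < params.no_response_rate
    response = np.where(no_resp, 0, response)

    status = _classify_status(is_old, response)

    rt = np.empty(n)
    delay = np.where(is_old, lists, "none")
    for i in range(n):
        key = f"{status[i]}_{delay[i]}"
        mean, sd = params.rt_params.get(key, params.rt_params["default"])
        rt[i] = max(0.2, rng.normal(mean, sd))
    rt[no_resp] = np.nan

    table["response"] = response
    table["rt"] = rt
    table["memory_status"] = status
    table["recollected_truth"] = recollected
    return table


def simulate_associative(
    design: ExperimentDesign,
    item_trials: pd.DataFrame,
    params: BehavioralParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate intact/recombined judgments of the associative test.

    Accuracy on intact sentences depends on the item's memory status from
    the item test (recollected items retain their room association best);
    'intact' responses to recombined sentences occur at a per-delay rate.
    """

    params = params or BehavioralParams()
    rng = stage_rng(seed, "associative")

    status_by_item = dict(zip(item_trials["item"], item_trials["memory_status"]))
    table = design.associative_schedule.copy()
    n = len(table)
    resp_intact = np.zeros(n, dtype=bool)
    for i, row in enumerate(table.itertuples()):
        delay = row.list
        if row.sentence_type == "intact":
            st = status_by_item.get(row.item, "forgotten")
            acc = {
                "recollection": params.assoc_accuracy_given_R[delay],
                "familiarity": params.assoc_accuracy_given_F[delay],
            }.get(st, params.assoc_accuracy_given_forgotten[delay])
            resp_intact[i] = rng.random() < acc
        else:
            resp_intact[i] = rng.random() < params.assoc_intact_rate_recombined[delay]
    table["response"] = np.where(resp_intact, "intact", "recombined")
    table["correct"] = table["response"] == table["sentence_type"]
    return table


# ---------------------------------------------------------------------------
# Neural realization and BOLD simulation
# ---------------------------------------------------------------------------


@dataclass
class NeuralRealization:
    """Masks, prototypes, and voxel baselines drawn for one subject."""

    params: NeuralParams
    #: roi -> boolean 3D array on the functional grid
    masks: dict[str, np.ndarray]
    #: roi -> {room: pattern vector over the ROI's voxels}
    prototypes: dict[str, dict[str, np.ndarray]]
    #: roi -> static per-voxel responsiveness pattern
    baselines: dict[str, np.ndarray]

    def flat_indices(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.masks[roi].ravel())


def realize_neural(
    params: NeuralParams, seed: int, rooms: list[str] | None = None
) -> NeuralRealization:
    """Draw the subject-level neural structure (deterministic given seed).

    ROI masks are disjoint random voxel sets on the grid; room prototypes
    are i.i.d. standard-normal per voxel (independent across rooms, so a
    zero context gain leaves room labels exchangeable).
    """

    from .config import ROOMS

    params.validate()
    rng = stage_rng(seed, "neural")
    rooms = list(rooms) if rooms is not None else list(ROOMS)

    n_grid = int(np.prod(params.grid_shape))
    order = rng.permutation(n_grid)
    masks: dict[str, np.ndarray] = {}
    cursor = 0
    for roi, count in params.roi_spec.items():
        flat = np.zeros(n_grid, dtype=bool)
        flat[order[cursor : cursor + count]] = True
        cursor += count
        masks[roi] = flat.reshape(params.grid_shape)

    prototypes: dict[str, dict[str, np.ndarray]] = {}
    baselines: dict[str, np.ndarray] = {}
    for roi, count in params.roi_spec.items():
        prototypes[roi] = {room: rng.standard_normal(count) for room in rooms}
        baselines[roi] = params.event_amplitude + params.voxel_baseline_sd * (
            rng.standard_normal(count)
        )
    return NeuralRealization(params, masks, prototypes, baselines)


def generate_roi_masks(
    params: NeuralParams | None = None, seed: int = 0
) -> dict[str, np.ndarray]:
    """Named disjoint boolean ROI volumes on the functional grid."""

    params = params or NeuralParams()
    return realize_neural(params, seed).masks


def trial_amplitude_patterns(
    realization: NeuralRealization,
    trial_table: pd.DataFrame,
    seed: int,
) -> dict[str, np.ndarray]:
    """Ground-truth per-trial voxel patterns for every ROI.

    Pattern of trial t = baseline pattern + recollection gain (on
    recollection trials) + context gain x room prototype (on recollection
    trials) + i.i.d. pattern noise. These are the expected single-trial
    betas; estimating them from the BOLD series adds GLM noise on top.
    """

    params = realization.params
    rng = stage_rng(seed, "patterns")
    status = trial_table["memory_status"].to_numpy()
    lists = trial_table["list"].to_numpy()
    rooms = trial_table["room"].to_numpy()
    n = len(trial_table)

    out: dict[str, np.ndarray] = {}
    for roi in params.roi_spec:
        v = len(realization.baselines[roi])
        pat = np.tile(realization.baselines[roi], (n, 1))
        pat += params.pattern_noise_sd * rng.standard_normal((n, v))
        for t in range(n):
            if status[t] == "recollection":
                delay = lists[t]
                pat[t] += params.recollection_gain.get(roi, {}).get(delay, 0.0)
                c = params.context_gain.get(roi, {}).get(delay, 0.0)
                if c > 0.0:
                    pat[t] += c * realization.prototypes[roi][rooms[t]]
        out[roi] = pat
    return out


def simulate_trial_patterns(
    design: ExperimentDesign,
    trial_table: pd.DataFrame,
    params: NeuralParams | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], NeuralRealization]:
    """Convenience path: ground-truth trial patterns without BOLD synthesis.

    Equivalent to the expected output of the full simulate -> GLM route and
    used for large calibration studies where the time-series stage would
    only add estimation noise.
    """

    params = params or NeuralParams()
    realization = realize_neural(params, seed)
    return trial_amplitude_patterns(realization, trial_table, seed), realization


@dataclass
class RunData:
    """One functional run: 4D data plus nuisance traces and ground truth."""

    data: np.ndarray  # (nx, ny, nz, n_scans)
    tr_s: float
    motion: np.ndarray  # (n_scans, 6)
    global_signal: np.ndarray  # (n_scans,)
    onsets: np.ndarray
    trial_index: np.ndarray  # indices into the subject trial table

    @property
    def n_scans(self) -> int:
        return self.data.shape[-1]

    def flat(self) -> np.ndarray:
        """(n_voxels, n_scans) view of the grid data."""
        return self.data.reshape(-1, self.data.shape[-1])


@dataclass
class BOLDDataset:
    runs: list[RunData]
    realization: NeuralRealization
    #: roi -> (n_trials_total, n_voxels) generating patterns
    ground_truth: dict[str, np.ndarray]
    trial_table: pd.DataFrame


def _ar1_noise(rng, phi: float, sd: float, shape: tuple[int, int]) -> np.ndarray:
    white = rng.standard_normal(shape)
    if phi == 0.0:
        return sd * white
    out = signal.lfilter([1.0], [1.0, -phi], white, axis=-1)
    return sd * np.sqrt(1.0 - phi**2) * out


def simulate_bold(
    design: ExperimentDesign,
    trial_table: pd.DataFrame,
    params: NeuralParams | None = None,
    seed: int = 0,
    *,
    pad_s: float = 20.0,
) -> BOLDDataset:
    """Synthesize the three recognition runs of 4D BOLD data.

    Each trial's stick function, scaled per voxel by its generating pattern,
    is convolved with a canonical double-gamma HRF; AR(1) noise, polynomial
    drift, and motion-coupled artifacts are added on top of a constant
    scanner baseline. Ground-truth patterns are stored alongside.
    """

    from .glm import hrf_regressors

    params = params or NeuralParams()
    realization = realize_neural(params, seed)
    patterns = trial_amplitude_patterns(realization, trial_table, seed)
    rng = stage_rng(seed, "bold")

    n_grid = int(np.prod(params.grid_shape))
    roi_flat = {roi: realization.flat_indices(roi) for roi in params.roi_spec}

    runs: list[RunData] = []
    for run in sorted(trial_table["run"].unique()):
        rows = trial_table.index[trial_table["run"] == run].to_numpy()
        onsets = trial_table.loc[rows, "onset"].to_numpy()
        n_scans = int(np.ceil((onsets.max() + pad_s) / params.tr_s))
        if onsets.max() >= n_scans * params.tr_s:
            raise SchedulingError("trial onset beyond run duration")
        # (n_scans, n_trials) single-stick regressors
        X = hrf_regressors(onsets, n_scans, params.tr_s, length_s=params.hrf_length_s)

        data = np.zeros((n_grid, n_scans))
        for roi, flat in roi_flat.items():
            data[flat] = (X @ patterns[roi][rows]).T

        # non-ROI background voxels: mean event response, no pattern structure
        bg = np.ones(n_grid, dtype=bool)
        for flat in roi_flat.values():
            bg[flat] = False
        data[bg] = np.outer(
            params.event_amplitude * np.ones(bg.sum()), X.sum(axis=1)
        )

        # nuisance structure
        t = np.linspace(-1.0, 1.0, n_scans)
        drift_basis = np.stack([t, 0.5 * (3 * t**2 - 1)], axis=1)
        drift_coef = params.drift_amplitude * rng.standard_normal((n_grid, 2))
        data += drift_coef @ drift_basis.T

        data += _ar1_noise(rng, params.ar1_phi, params.noise_sd, (n_grid, n_scans))

        steps = rng.normal(
            0.0,
            [params.motion_step_sd_mm] * 3 + [params.motion_step_sd_rad] * 3,
            size=(n_scans, 6),
        )
        jumps = rng.random(n_scans) < params.motion_spike_rate
        steps[jumps, 0] += params.motion_spike_mm * rng.choice([-1, 1], jumps.sum())
        motion = np.cumsum(steps, axis=0)
        fd_proxy = np.concatenate([[0.0], np.abs(np.diff(motion[:, :3], axis=0)).sum(1)])
        if params.motion_coupling > 0.0:
            art_pattern = rng.standard_normal(n_grid)
            data += params.motion_coupling * np.outer(art_pattern, fd_proxy)

        data += params.baseline_signal
        runs.append(
            RunData(
                data=data.reshape(*params.grid_shape, n_scans),
                tr_s=params.tr_s,
                motion=motion,
                global_signal=data.mean(axis=0),
                onsets=onsets,
                trial_index=rows,
            )
        )

    return BOLDDataset(
        runs=runs,
        realization=realization,
        ground_truth=patterns,
        trial_table=trial_table,
    )
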