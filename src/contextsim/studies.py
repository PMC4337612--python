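"""Simulation studies: null calibration, oracle checks, parameter recovery.

These are the package's validation experiments, run at fixed problem sizes:

* ``null_calibration`` — with zero context gain the room-label
  randomization test must reject at the nominal rate.
* ``lss_noiseless_max_error`` — on noiseless, well-separated trials the
  LSS betas must equal the generating amplitudes.
* ``monotonicity_study`` — the context-similarity statistic must increase
  with the generative context gain.
* ``recovery_study`` — cohorts generated with a delay-reduced posterior-HF
  recollection gain and an ability-linked anterior-HF context gain must
  reproduce the qualitative group-level result (posterior-HF memory x
  delay interaction; positive delayed anterior-HF brain-behavior
  correlation).
"""

from __future__ import annotations

import numpy as np

from .config import NeuralParams, PipelineConfig, small_mtl_params
from .glm import fit_lss, hrf_regressors
from .pipeline import simulate_cohort
from .similarity import (
    context_similarity,
    pairwise_similarity,
    randomization_test,
    select_pairs,
)
from .simulate import generate_design, simulate_behavior, simulate_trial_patterns


def _spawn_seeds(seed: int, n: int, tag: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed, spawn_key=(tag,))
    return ss.generate_state(n) % (2**31)


def _single_roi_params(context_gain: float, n_voxels: int = 45) -> NeuralParams:
    return NeuralParams(
        grid_shape=(5, 5, 2),
        roi_spec={"left_ant_hf": n_voxels},
        recollection_gain={"left_ant_hf": {"immediate": 0.4, "delayed": 0.4}},
        context_gain={
            "left_ant_hf": {"immediate": context_gain, "delayed": context_gain}
        },
    )


def null_calibration(
    n_subjects: int = 500,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the randomization test under zero context gain.

    Each simulated subject has exchangeable room labels (context gain 0);
    the room-label randomization p-value should be uniform, so the
    rejection rate at ``alpha`` should match ``alpha``.
    """

    seeds = _spawn_seeds(seed, n_subjects, tag=1)
    params = _single_roi_params(0.0)
    p_values = np.empty(n_subjects)
    for k, s in enumerate(seeds):
        s = int(s)
        design = generate_design(s)
        trials = simulate_behavior(design, seed=s)
        patterns, _ = simulate_trial_patterns(design, trials, params, seed=s)
        meta = trials[["run", "trial", "list", "room", "memory_status"]]
        res = randomization_test(
            patterns["left_ant_hf"],
            meta,
            design.house_grouping,
            n_perm=n_perm,
            seed=s,
        )
        p_values[k] = res.p_value
    return {
        "rejection_rate": float(np.mean(p_values <= alpha)),
        "p_values": p_values,
        "n_subjects": n_subjects,
        "n_perm": n_perm,
    }


def lss_noiseless_max_error(
    n_trials: int = 8, separation_s: float = 36.0, seed: int = 0
) -> float:
    """Max |LSS beta - generating amplitude| on noiseless separated trials."""

    import pandas as pd

    rng = np.random.default_rng(seed)
    tr = 1.22
    onsets = 5.0 + np.arange(n_trials) * separation_s
    n_scans = int((onsets[-1] + 40.0) / tr)
    amps = rng.uniform(0.5, 2.0, size=(n_trials, 6))
    Y = hrf_regressors(onsets, n_scans, tr) @ amps
    table = pd.DataFrame({"onset": onsets, "run": 0})
    betas = fit_lss(Y, table, tr, drift_order=None).matrix
    return float(np.max(np.abs(betas - amps)))


def monotonicity_study(
    gains: tuple[float, ...] = (0.0, 0.5, 1.0),
    n_seeds: int = 50,
    seed: int = 0,
) -> dict:
    """Mean context-similarity statistic at each generative context gain."""

    seeds = _spawn_seeds(seed, n_seeds, tag=2)
    means = []
    for c in gains:
        params = _single_roi_params(c)
        vals = []
        for s in seeds:
            s = int(s)
            design = generate_design(s)
            trials = simulate_behavior(design, seed=s)
            patterns, _ = simulate_trial_patterns(design, trials, params, seed=s)
            meta = trials[["run", "trial", "list", "room", "memory_status"]]
            pairs = select_pairs(meta, design.house_grouping)
            vals.append(
                context_similarity(
                    pairwise_similarity(patterns["left_ant_hf"]), pairs
                ).context_similarity
            )
        means.append(float(np.nanmean(vals)))
    return {"gains": list(gains), "mean_statistic": means, "n_seeds": n_seeds}


def recovery_study(
    n_cohorts: int = 50,
    n_subjects: int = 19,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of simulated cohorts reproducing the qualitative pattern.

    Success requires, within a cohort: (1) a significant posterior-HF
    memory x delay interaction with the recollection effect larger
    immediately than after the delay, and (2) a positive, significant
    correlation between delayed anterior-HF context similarity and delayed
    associative d'.
    """

    seeds = _spawn_seeds(seed, n_cohorts, tag=3)
    int_ok = np.zeros(n_cohorts, dtype=bool)
    bb_ok = np.zeros(n_cohorts, dtype=bool)
    rs = np.full(n_cohorts, np.nan)
    for k, s in enumerate(seeds):
        config = PipelineConfig(
            seed=int(s), n_subjects=n_subjects, neural=small_mtl_params()
        )
        results, group = simulate_cohort(config, route="bold")
        anova = group.get("activation_anova", {}).get("left_post_hf", {})
        inter = anova.get("memory_x_delay", {})
        # direction: immediate recollection effect exceeds delayed
        included = [
            r for r in results
            if min(r.n_trials.values()) >= config.analysis.min_trials_per_condition
        ]
        diffs = []
        for r in included:
            m = r.condition_means["left_post_hf"]
            diffs.append(
                (m["immediate_recollection"] - m["immediate_familiarity"])
                - (m["delayed_recollection"] - m["delayed_familiarity"])
            )
        right_direction = np.mean(diffs) > 0 if diffs else False
        int_ok[k] = inter.get("p", 1.0) < alpha and right_direction
        bb = group.get("brain_behavior") or {}
        rs[k] = bb.get("r", np.nan)
        bb_ok[k] = bb.get("r", 0.0) > 0.0 and bb.get("p", 1.0) < alpha
    both = int_ok & bb_ok
    return {
        "n_cohorts": n_cohorts,
        "interaction_rate": float(int_ok.mean()),
        "brain_behavior_rate": float(bb_ok.mean()),
        "joint_rate": float(both.mean()),
        "mean_r": float(np.nanmean(rs)),
    }
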