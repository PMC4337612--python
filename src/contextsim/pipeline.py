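"""End-to-end orchestration: simulate -> score -> GLM -> ROI -> similarity
-> group statistics, plus cohort-level simulation studies.

Two subject-level routes are provided. The ``bold`` route synthesizes full
time series and estimates single-trial betas with LSS (the faithful
pipeline). The ``patterns`` route takes the generator's ground-truth trial
patterns directly, which is the expected output of the BOLD+LSS route and
is used for large calibration studies of the similarity statistic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import glm, roi, similarity
from .config import (
    AnalysisParams,
    BehavioralParams,
    NeuralParams,
    PipelineConfig,
    config_hash,
    to_dict,
)
from .inference import brain_behavior_correlation, directional_t, rm_anova_2x2
from .simulate import (
    generate_design,
    realize_neural,
    simulate_associative,
    simulate_behavior,
    simulate_bold,
    simulate_trial_patterns,
)

log = logging.getLogger("contextsim")

_CELLS = [
    ("recollection", "immediate"),
    ("familiarity", "immediate"),
    ("recollection", "delayed"),
    ("familiarity", "delayed"),
]


# ---------------------------------------------------------------------------
# Subject-level heterogeneity
# ---------------------------------------------------------------------------


def draw_subject_params(
    config: PipelineConfig, rng: np.random.Generator
) -> tuple[BehavioralParams, NeuralParams, float]:
    """Draw one subject's parameters around the cohort means.

    A latent ability ``a ~ N(0, 1)`` couples the delayed anterior-HF
    context gain to delayed associative accuracy (the generative analogue
    of the brain-behavior relationship); ROI gains additionally receive
    independent between-subject jitter.
    """

    a = float(rng.standard_normal())
    b = config.behavior
    n = config.neural

    def clip01(p):
        return float(np.clip(p, 0.02, 0.98))

    behav = replace(
        b,
        rho_immediate=clip01(b.rho_immediate + config.rho_subject_sd * rng.standard_normal()),
        rho_delayed=clip01(b.rho_delayed + config.rho_subject_sd * rng.standard_normal()),
        assoc_accuracy_given_R={
            "immediate": clip01(b.assoc_accuracy_given_R["immediate"]),
            "delayed": clip01(
                b.assoc_accuracy_given_R["delayed"] + config.ability_assoc_slope * a
            ),
        },
        assoc_accuracy_given_F={
            "immediate": clip01(b.assoc_accuracy_given_F["immediate"]),
            "delayed": clip01(
                b.assoc_accuracy_given_F["delayed"] + config.ability_assoc_slope * a
            ),
        },
        assoc_intact_rate_recombined={
            "immediate": clip01(b.assoc_intact_rate_recombined["immediate"]),
            "delayed": clip01(
                b.assoc_intact_rate_recombined["delayed"]
                - config.ability_recombined_slope * a
            ),
        },
    )

    rec_gain = {}
    for roi_name, by_delay in n.recollection_gain.items():
        rec_gain[roi_name] = {
            d: g + config.subject_gain_sd * rng.standard_normal()
            for d, g in by_delay.items()
        }
    ctx_gain = {}
    for roi_name, by_delay in n.context_gain.items():
        ctx_gain[roi_name] = {
            d: max(0.0, g + 0.05 * rng.standard_normal()) for d, g in by_delay.items()
        }
    if "left_ant_hf" in ctx_gain:
        base = n.context_gain["left_ant_hf"]["delayed"]
        ctx_gain["left_ant_hf"]["delayed"] = max(
            0.0, base + config.ability_context_slope * a
        )
    neural = replace(n, recollection_gain=rec_gain, context_gain=ctx_gain)
    return behav, neural, a


# ---------------------------------------------------------------------------
# Subject-level pipeline
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class SubjectResult:
    """Everything the group stage needs from one simulated subject."""

    subject_id: int
    ability: float
    trial_table: pd.DataFrame
    assoc_table: pd.DataFrame
    rates: bhv.RateSummary
    estimates: bhv.DualProcessEstimates
    assoc_dprime: dict[str, float]
    n_trials: dict[tuple[str, str], int]
    #: roi -> condition -> ROI-mean activation estimate
    condition_means: dict[str, dict[str, float]]
    #: (roi, delay) -> context-similarity result
    context: dict[tuple[str, str], similarity.ContextSimilarityResult]
    n_outlier_trials: int = 0
    n_spike_scans: int = 0

    def cell_means(self, roi_name: str) -> list[float]:
        means = self.condition_means[roi_name]
        return [means.get(f"{d}_{s}", np.nan) for s, d in _CELLS]


def _trial_counts(trials: pd.DataFrame) -> dict[tuple[str, str], int]:
    out = {}
    for status, delay in _CELLS:
        out[(status, delay)] = int(
            ((trials["memory_status"] == status) & (trials["list"] == delay)).sum()
        )
    return out


def _similarity_stage(
    roi_patterns: dict[str, np.ndarray],
    meta: pd.DataFrame,
    house_grouping: dict[str, str],
    analysis: AnalysisParams,
    flags: np.ndarray,
) -> dict[tuple[str, str], similarity.ContextSimilarityResult]:
    out = {}
    for roi_name, P in roi_patterns.items():
        corr = similarity.pairwise_similarity(P, cocktail_blank=analysis.cocktail_blank)
        pairs = similarity.select_pairs(
            meta,
            house_grouping,
            status=analysis.similarity_status,
            flags=flags,
            min_lag=analysis.min_lag,
        )
        for delay in ("immediate", "delayed"):
            out[(roi_name, delay)] = similarity.context_similarity(
                corr, pairs, list_label=delay, roi=roi_name
            )
    return out


def simulate_subject(
    subject_id: int,
    config: PipelineConfig,
    *,
    behav: BehavioralParams | None = None,
    neural: NeuralParams | None = None,
    ability: float = 0.0,
    route: str = "bold",
) -> SubjectResult:
    """Simulate and fully analyze one subject.

    ``route='bold'`` synthesizes time series and estimates betas with LSS;
    ``route='patterns'`` analyzes the generator's ground-truth patterns.
    """

    behav = behav if behav is not None else config.behavior
    neural = neural if neural is not None else config.neural
    analysis = config.analysis
    seed = int(
        np.random.SeedSequence(config.seed, spawn_key=(1000 + subject_id,)).generate_state(1)[0]
        % (2**31)
    )

    design = generate_design(seed, config.design)
    trials = simulate_behavior(design, behav, seed)
    assoc = simulate_associative(design, trials, behav, seed)

    meta = trials[["run", "trial", "onset", "item", "list", "room", "memory_status"]]

    if route == "patterns":
        patterns, realization = simulate_trial_patterns(design, trials, neural, seed)
        all_cols = np.hstack([patterns[r] for r in patterns])
        flags = roi.flag_outlier_trials(
            glm.BetaSeries(matrix=all_cols, meta=meta.reset_index(drop=True)),
            threshold_sd=analysis.outlier_threshold_sd,
        )
        cond_means = {
            r: _condition_means_from_patterns(patterns[r], trials) for r in patterns
        }
        context = _similarity_stage(
            patterns, meta, design.house_grouping, analysis, flags
        )
        n_spikes = 0
    elif route == "bold":
        bold = simulate_bold(design, trials, neural, seed)
        beta_parts, spike_total = [], 0
        cond_betas_runs = []
        for run_data in bold.runs:
            Y = run_data.flat().T  # scans x voxels
            spikes = glm.flag_suspect_timepoints(
                run_data.motion,
                run_data.global_signal,
                fd_threshold_mm=analysis.fd_threshold_mm,
                gs_threshold_pct=analysis.gs_threshold_pct,
                radius_mm=analysis.rotation_radius_mm,
            )
            spike_total += len(spikes)
            run_trials = trials.loc[run_data.trial_index]
            beta_parts.append(
                glm.fit_lss(
                    Y,
                    run_trials,
                    neural.tr_s,
                    motion=run_data.motion,
                    spike_scans=spikes,
                    drift_order=analysis.drift_order,
                )
            )
            dm = glm.build_design_matrix(
                run_trials,
                Y.shape[0],
                neural.tr_s,
                motion=run_data.motion,
                spike_scans=spikes,
                drift_order=analysis.drift_order,
            )
            cond_betas_runs.append(glm.fit_condition_glm(Y, dm).betas)
        beta_series = glm.concat_beta_series(beta_parts)
        flags = roi.flag_outlier_trials(
            beta_series, threshold_sd=analysis.outlier_threshold_sd
        )

        tsnr = roi.compute_tsnr([r.flat() for r in bold.runs])
        roi_patterns = {}
        cond_means = {}
        for roi_name, mask_arr in bold.realization.masks.items():
            mask = roi.ROIMask(label=roi_name, voxels=mask_arr, tsnr=tsnr)
            if analysis.tsnr_filter:
                mask = roi.filter_low_snr_voxels(mask)
            roi_patterns[roi_name] = roi.extract_patterns(beta_series, mask).matrix
            cond_means[roi_name] = _condition_means_from_glm(
                cond_betas_runs, mask.flat_indices()
            )
        meta = beta_series.meta[
            ["run", "trial", "onset", "item", "list", "room", "memory_status"]
        ]
        context = _similarity_stage(
            roi_patterns, meta, design.house_grouping, analysis, flags
        )
        n_spikes = spike_total
    else:
        raise ValueError(f"unknown route {route!r}")

    rates = bhv.summarize_rates(trials)
    estimates = bhv.dual_process_estimates(rates)
    return SubjectResult(
        subject_id=subject_id,
        ability=ability,
        trial_table=trials,
        assoc_table=assoc,
        rates=rates,
        estimates=estimates,
        assoc_dprime=bhv.associative_dprime(assoc),
        n_trials=_trial_counts(trials),
        condition_means=cond_means,
        context=context,
        n_outlier_trials=int(np.sum(flags)),
        n_spike_scans=n_spikes,
    )


def _condition_means_from_patterns(
    patterns: np.ndarray, trials: pd.DataFrame
) -> dict[str, float]:
    labels = glm.condition_labels(trials)
    roi_amp = patterns.mean(axis=1)
    return {
        cond: float(roi_amp[(labels == cond).to_numpy()].mean())
        for cond in labels.unique()
    }


def _condition_means_from_glm(
    cond_betas_runs: list[pd.DataFrame], voxels: np.ndarray
) -> dict[str, float]:
    """Average per-run condition betas over runs, then over ROI voxels."""

    acc: dict[str, list[float]] = {}
    for betas in cond_betas_runs:
        for cond in betas.index:
            if cond.startswith(("motion", "drift", "spike")):
                continue
            acc.setdefault(cond, []).append(float(betas.loc[cond].iloc[voxels].mean()))
    return {cond: float(np.mean(v)) for cond, v in acc.items()}


# ---------------------------------------------------------------------------
# Group stage
# ---------------------------------------------------------------------------


def group_analysis(results: list[SubjectResult], config: PipelineConfig) -> dict:
    """Group statistics over a cohort of analyzed subjects.

    Applies the trial-count exclusion floor, runs memory x delay ANOVAs on
    ROI activation means, directional t-tests and pair-type x delay ANOVAs
    on context similarity, the anterior/posterior HF ROI x delay
    interaction, and the delayed brain-behavior regression (excluding
    below-chance associative performers).
    """

    floor = config.analysis.min_trials_per_condition
    included = [r for r in results if min(r.n_trials.values()) >= floor]
    included_ids = {r.subject_id for r in included}
    excluded = [r.subject_id for r in results if r.subject_id not in included_ids]
    if excluded:
        log.info("excluded subjects below %d-trial floor: %s", floor, excluded)
    out: dict = {
        "n_subjects": len(results),
        "n_included": len(included),
        "excluded_subjects": excluded,
    }
    if len(included) < 4:
        out["error"] = "too few subjects after exclusions"
        return out

    rois = list(included[0].condition_means)
    anova = {}
    for roi_name in rois:
        cells = np.array([r.cell_means(roi_name) for r in included])
        # order for rm_anova_2x2: (R,imm), (R,del), (F,imm), (F,del)
        reordered = cells[:, [0, 2, 1, 3]]
        eff = rm_anova_2x2(reordered)
        anova[roi_name] = {
            "memory": {"F": eff["A"].F, "p": eff["A"].p},
            "delay": {"F": eff["B"].F, "p": eff["B"].p},
            "memory_x_delay": {"F": eff["AxB"].F, "p": eff["AxB"].p},
            "df": eff["A"].df,
        }
    out["activation_anova"] = anova

    context_tests = {}
    pairtype_anova = {}
    for roi_name in rois:
        for delay in ("immediate", "delayed"):
            vals = np.array(
                [r.context[(roi_name, delay)].context_similarity for r in included]
            )
            vals = vals[np.isfinite(vals)]
            if len(vals) >= 2:
                t, p = directional_t(vals)
                context_tests[f"{roi_name}_{delay}"] = {
                    "t": t, "p": p, "n": int(len(vals)),
                    "mean": float(vals.mean()),
                }
        cells = np.array(
            [
                [
                    r.context[(roi_name, "immediate")].same_mean,
                    r.context[(roi_name, "delayed")].same_mean,
                    r.context[(roi_name, "immediate")].diff_mean,
                    r.context[(roi_name, "delayed")].diff_mean,
                ]
                for r in included
            ]
        )
        try:
            eff = rm_anova_2x2(cells)
            pairtype_anova[roi_name] = {
                "pair_type": {"F": eff["A"].F, "p": eff["A"].p},
                "delay": {"F": eff["B"].F, "p": eff["B"].p},
                "pair_type_x_delay": {"F": eff["AxB"].F, "p": eff["AxB"].p},
            }
        except Exception as exc:  # incomplete cells
            pairtype_anova[roi_name] = {"error": str(exc)}
    out["context_similarity_tests"] = context_tests
    out["pairtype_anova"] = pairtype_anova

    # anterior vs posterior HF: ROI x delay on recollection-minus-familiarity
    if {"left_ant_hf", "left_post_hf"} <= set(rois):
        cells = []
        for r in included:
            ant = r.condition_means["left_ant_hf"]
            post = r.condition_means["left_post_hf"]

            def rmf(m, d):
                return m.get(f"{d}_recollection", np.nan) - m.get(
                    f"{d}_familiarity", np.nan
                )

            cells.append(
                [rmf(ant, "immediate"), rmf(ant, "delayed"),
                 rmf(post, "immediate"), rmf(post, "delayed")]
            )
        eff = rm_anova_2x2(np.array(cells))
        out["hf_axis_by_delay"] = {
            "roi_x_delay_F": eff["AxB"].F,
            "roi_x_delay_p": eff["AxB"].p,
        }

    # delayed brain-behavior relationship in the left anterior HF
    roi_bb = "left_ant_hf" if "left_ant_hf" in rois else rois[0]
    rows = []
    for r in included:
        sim = r.context[(roi_bb, "delayed")].context_similarity
        dpa = r.assoc_dprime["delayed"]
        if np.isfinite(sim) and dpa > 0.0:  # below-chance performers excluded
            rows.append((sim, dpa, r.n_trials[("recollection", "delayed")]))
    if len(rows) >= 4:
        sims, dps, nrec = map(np.array, zip(*rows))
        try:
            bb = brain_behavior_correlation(sims, dps, covariate=nrec)
            out["brain_behavior"] = {
                "roi": roi_bb,
                "r": bb.r,
                "t": bb.t,
                "p": bb.p,
                "n": bb.n,
                "partial_slope_t": bb.partial_slope_t,
                "partial_slope_p": bb.partial_slope_p,
            }
        except Exception as exc:
            out["brain_behavior"] = {"error": str(exc)}
    return out


def simulate_cohort(
    config: PipelineConfig, *, route: str = "bold"
) -> tuple[list[SubjectResult], dict]:
    """Simulate and analyze a full cohort; returns subjects + group stats."""

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(7,)))
    results = []
    for sid in range(config.n_subjects):
        behav, neural, ability = draw_subject_params(config, rng)
        results.append(
            simulate_subject(
                sid, config, behav=behav, neural=neural, ability=ability, route=route
            )
        )
    return results, group_analysis(results, config)


# ---------------------------------------------------------------------------
# Run directory
# ---------------------------------------------------------------------------


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    *,
    route: str = "bold",
    write_volumes: bool = False,
) -> dict:
    """Execute the full pipeline and write every stage's artifacts.

    Writes per-subject events TSVs, the subject summary CSV, group
    statistics, a config snapshot with its hash, and a machine-readable
    ``results.json``. Deterministic given the config (same seed ->
    byte-identical results).
    """

    from . import io as cio

    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    cio.save_config(config, out / "config.yaml")

    stage = "simulate+analyze"
    try:
        results, group = simulate_cohort(config, route=route)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed (config {chash}): {exc}") from exc

    events_dir = out / "events"
    events_dir.mkdir(exist_ok=True)
    for r in results:
        cio.write_events_tsv(
            r.trial_table[
                ["run", "trial", "onset", "duration", "item", "list", "room",
                 "response", "rt", "memory_status"]
            ],
            events_dir / f"sub-{r.subject_id:02d}_task-recognition_events.tsv",
        )

    if write_volumes:
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        masks = realize_neural(config.neural, config.seed).masks
        for name, mask in masks.items():
            cio.write_nifti(mask.astype(float), vol_dir / f"mask-{name}.nii.gz")

    summary_rows = []
    for r in results:
        row = {
            "subject": r.subject_id,
            "ability": r.ability,
            "recollection_immediate": r.estimates.recollection["immediate"],
            "recollection_delayed": r.estimates.recollection["delayed"],
            "familiarity_immediate": r.estimates.familiarity["immediate"],
            "familiarity_delayed": r.estimates.familiarity["delayed"],
            "dprime_item_immediate": r.estimates.dprime_item["immediate"],
            "dprime_item_delayed": r.estimates.dprime_item["delayed"],
            "dprime_assoc_immediate": r.assoc_dprime["immediate"],
            "dprime_assoc_delayed": r.assoc_dprime["delayed"],
            "n_recollection_delayed": r.n_trials[("recollection", "delayed")],
            "n_outlier_trials": r.n_outlier_trials,
            "n_spike_scans": r.n_spike_scans,
        }
        for (roi_name, delay), res in r.context.items():
            row[f"context_{roi_name}_{delay}"] = res.context_similarity
        summary_rows.append(row)
    pd.DataFrame(summary_rows).to_csv(out / "subject_summary.csv", index=False)

    results_payload = {
        "config_hash": chash,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "group": group,
    }
    (out / "results.json").write_text(
        json.dumps(_jsonable(results_payload), indent=2, sort_keys=True)
    )
    return results_payload


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
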