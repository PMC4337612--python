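"""Parameters, defaults, and error types for the context-similarity pipeline.

The defaults encode the study conditions this package emulates: a two-day
item-context experiment in which 252 object nouns are split into three
84-item lists (immediate, delayed, lure), studied items are paired with one
of eight rooms (four per study day), and recognition is tested in the
scanner across three functional runs at TR = 1.22 s.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class ContextSimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ContextSimError):
    """A configuration value violates a structural constraint."""


class SchedulingError(ContextSimError):
    """An event falls outside the run it is assigned to."""


class EstimationError(ContextSimError):
    """A model fit cannot be computed (e.g. rank deficiency)."""


class UndefinedEstimateError(ContextSimError):
    """A behavioral estimator is undefined for the given rates."""


class EmptyInputError(ContextSimError):
    """An operation received an empty table or mask."""


class DegenerateStrataError(ContextSimError):
    """Randomization strata carry no exchangeable room labels."""


class ParseError(ContextSimError):
    """A text table could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# Fixed study constants
# ---------------------------------------------------------------------------

TR_S = 1.22
ROOMS = (
    "bathroom",
    "bedroom",
    "den",
    "dining_room",
    "kitchen",
    "living_room",
    "office",
    "patio",
)
LISTS = ("immediate", "delayed", "lure")
DELAYS = ("immediate", "delayed")

#: The nine event conditions of the item-recognition GLM.
CONDITIONS_9 = (
    "immediate_recollection",
    "immediate_familiarity",
    "immediate_forgotten",
    "delayed_recollection",
    "delayed_familiarity",
    "delayed_forgotten",
    "correct_rejection",
    "false_alarm",
    "no_response",
)

#: 6-point item-recognition scale. 1..5 are confidence responses
#: (definitely new .. definitely old); 6 is 'remember'.
RESPONSE_LABELS = {
    1: "definitely_new",
    2: "probably_new",
    3: "not_sure",
    4: "probably_old",
    5: "definitely_old",
    6: "remember",
}

#: Left-hemisphere medial temporal lobe ROIs used in the main analyses.
MTL_ROIS = (
    "left_ant_hf",
    "left_post_hf",
    "left_prc",
    "left_phc",
    "right_ant_hf",
    "right_post_hf",
    "right_prc",
    "right_phc",
)
CORTICAL_ROIS = (
    "left_rsc",
    "left_pcc",
    "left_precuneus",
    "left_angular",
    "left_mpfc",
)


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class DesignParams:
    """Structural parameters of the two-day experiment."""

    n_items: int = 252
    n_rooms: int = 8
    n_runs: int = 3
    encoding_duration_s: float = 5.0
    recognition_duration_s: float = 2.0
    associative_duration_s: float = 3.0
    n_intact_per_day: int = 28
    jitter_mean_s: float = 4.0
    jitter_range_s: tuple[float, float] = (2.0, 10.0)
    jitter_step_s: float = 0.5

    @property
    def items_per_list(self) -> int:
        return self.n_items // 3

    @property
    def rooms_per_day(self) -> int:
        return self.n_rooms // 2

    def validate(self) -> None:
        if self.n_items % 3 != 0:
            raise ConfigurationError(
                f"n_items={self.n_items} must be divisible by 3 lists"
            )
        if self.n_rooms % 2 != 0:
            raise ConfigurationError(
                f"n_rooms={self.n_rooms} must be divisible by 2 study days"
            )
        if self.items_per_list % self.rooms_per_day != 0:
            raise ConfigurationError(
                f"items per list ({self.items_per_list}) must be divisible by "
                f"rooms per day ({self.rooms_per_day})"
            )
        items_per_room = self.items_per_list // self.rooms_per_day
        if items_per_room % self.n_runs != 0:
            raise ConfigurationError(
                f"items per room ({items_per_room}) must divide evenly across "
                f"{self.n_runs} runs"
            )
        if self.items_per_list % self.n_runs != 0:
            raise ConfigurationError(
                f"items per list ({self.items_per_list}) must divide evenly "
                f"across {self.n_runs} runs"
            )
        if not 0 < self.n_intact_per_day < self.items_per_list:
            raise ConfigurationError("n_intact_per_day out of range")
        lo, hi = self.jitter_range_s
        if not lo < self.jitter_mean_s < hi:
            raise ConfigurationError("jitter mean must lie inside jitter range")


@dataclass
class BehavioralParams:
    """Generative dual-process parameters for the recognition tests.

    Old items are recollected with probability ``rho_<list>``; recollected
    items produce a 'remember' response. Non-recollected trials (old or
    lure) produce a spurious 'remember' with probability
    ``spurious_remember_rate`` (independent of strength, so the corrected
    recollection estimator is consistent); otherwise a familiarity strength
    ~ Normal(mu, 1) is mapped onto responses 1-5 by four ordered criteria.
    """

    rho_immediate: float = 0.44
    rho_delayed: float = 0.22
    spurious_remember_rate: float = 0.04
    familiarity_mu: dict[str, float] = field(
        default_factory=lambda: {"immediate": 1.38, "delayed": 0.92, "lure": 0.0}
    )
    criteria: tuple[float, ...] = (0.0, 0.4, 0.74, 1.4)
    #: P(correct | intact sentence) by the item's prior memory status.
    #: Chosen so the aggregate 'intact' hit rates and the per-status percent
    #: correct over all sentences match the reference study's levels.
    assoc_accuracy_given_R: dict[str, float] = field(
        default_factory=lambda: {"immediate": 0.87, "delayed": 0.78}
    )
    assoc_accuracy_given_F: dict[str, float] = field(
        default_factory=lambda: {"immediate": 0.73, "delayed": 0.66}
    )
    assoc_accuracy_given_forgotten: dict[str, float] = field(
        default_factory=lambda: {"immediate": 0.55, "delayed": 0.51}
    )
    #: P('intact' response) to recombined sentences, per delay.
    assoc_intact_rate_recombined: dict[str, float] = field(
        default_factory=lambda: {"immediate": 0.34, "delayed": 0.43}
    )
    no_response_rate: float = 0.02
    #: (mean, sd) of response times in seconds, keyed by memory status x delay.
    rt_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "recollection_immediate": (1.35, 0.23),
            "recollection_delayed": (1.40, 0.24),
            "familiarity_immediate": (1.64, 0.35),
            "familiarity_delayed": (1.70, 0.29),
            "default": (1.60, 0.35),
        }
    )

    def validate(self) -> None:
        probs = [
            self.rho_immediate,
            self.rho_delayed,
            self.spurious_remember_rate,
            self.no_response_rate,
            *self.assoc_accuracy_given_R.values(),
            *self.assoc_accuracy_given_F.values(),
            *self.assoc_accuracy_given_forgotten.values(),
            *self.assoc_intact_rate_recombined.values(),
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        crit = np.asarray(self.criteria, dtype=float)
        if crit.size < 1 or np.any(np.diff(crit) <= 0):
            raise ConfigurationError("criteria must be strictly increasing")


def _default_roi_spec() -> dict[str, int]:
    spec = {name: 45 for name in MTL_ROIS}
    spec.update({name: 48 for name in CORTICAL_ROIS})
    return spec


def _gain_table(rois, immediate: float, delayed: float) -> dict:
    return {r: {"immediate": immediate, "delayed": delayed} for r in rois}


def _default_recollection_gain() -> dict[str, dict[str, float]]:
    # Recollection-related amplitude boost (in arbitrary beta units) is
    # stable over the delay everywhere except the posterior hippocampus,
    # where it drops after one day.
    gains = _gain_table(MTL_ROIS + CORTICAL_ROIS, 0.4, 0.4)
    for roi in ("left_post_hf", "right_post_hf"):
        gains[roi] = {"immediate": 0.5, "delayed": 0.1}
    return gains


def _default_context_gain() -> dict[str, dict[str, float]]:
    # Room-prototype reactivation on recollection trials: present in the
    # left anterior hippocampus and (weaker) left perirhinal cortex.
    gains = _gain_table(MTL_ROIS + CORTICAL_ROIS, 0.0, 0.0)
    gains["left_ant_hf"] = {"immediate": 0.35, "delayed": 0.65}
    gains["left_prc"] = {"immediate": 0.25, "delayed": 0.25}
    return gains


@dataclass
class NeuralParams:
    """Generative parameters of the synthetic ROI-structured BOLD data."""

    grid_shape: tuple[int, int, int] = (14, 14, 8)
    roi_spec: dict[str, int] = field(default_factory=_default_roi_spec)
    #: Amplitude of every event relative to baseline (beta units).
    event_amplitude: float = 1.0
    #: SD of the static per-voxel responsiveness pattern shared by all trials.
    voxel_baseline_sd: float = 0.5
    #: Univariate recollection-minus-familiarity amplitude, per ROI x delay.
    recollection_gain: dict[str, dict[str, float]] = field(
        default_factory=_default_recollection_gain
    )
    #: Weight of the room prototype on recollection trials, per ROI x delay.
    context_gain: dict[str, dict[str, float]] = field(
        default_factory=_default_context_gain
    )
    #: SD of i.i.d. per-trial, per-voxel idiosyncratic pattern noise.
    pattern_noise_sd: float = 1.0
    #: SD of the AR(1) scan noise added to the time series.
    noise_sd: float = 1.0
    ar1_phi: float = 0.3
    drift_amplitude: float = 1.0
    #: Scanner baseline intensity (arbitrary units).
    baseline_signal: float = 100.0
    motion_step_sd_mm: float = 0.02
    motion_step_sd_rad: float = 2e-4
    #: Rate and size of abrupt head movements (per scan).
    motion_spike_rate: float = 0.005
    motion_spike_mm: float = 0.6
    #: Scale of motion-coupled signal artifacts.
    motion_coupling: float = 0.5
    tr_s: float = TR_S
    hrf_length_s: float = 32.0

    def rois(self) -> tuple[str, ...]:
        return tuple(self.roi_spec)

    def validate(self) -> None:
        n_grid = int(np.prod(self.grid_shape))
        n_roi = sum(self.roi_spec.values())
        if n_roi > n_grid:
            raise ConfigurationError(
                f"roi_spec requests {n_roi} voxels but the grid has {n_grid}"
            )
        if any(n <= 1 for n in self.roi_spec.values()):
            raise ConfigurationError("each ROI needs at least 2 voxels")
        for table in (self.recollection_gain, self.context_gain):
            for roi, by_delay in table.items():
                if roi not in self.roi_spec:
                    raise ConfigurationError(f"gain for unknown ROI {roi!r}")
                if any(c < 0 for c in by_delay.values()) and table is self.context_gain:
                    raise ConfigurationError("context_gain must be >= 0")


def small_mtl_params(**overrides: Any) -> NeuralParams:
    """Compact configuration restricted to the four left MTL ROIs.

    Used for cohort-scale simulation studies where only the left-hemisphere
    MTL results are interrogated; identical generative model, smaller grid.
    """

    base = NeuralParams()
    rois = ("left_ant_hf", "left_post_hf", "left_prc", "left_phc")
    params = NeuralParams(
        grid_shape=(10, 10, 4),
        roi_spec={r: 60 for r in rois},
        recollection_gain={r: dict(base.recollection_gain[r]) for r in rois},
        context_gain={r: dict(base.context_gain[r]) for r in rois},
    )
    for key, value in overrides.items():
        setattr(params, key, value)
    return params


@dataclass
class AnalysisParams:
    """Options of the estimation and similarity stages."""

    drift_order: int | None = 2
    hrf_dt_s: float = 0.01
    fd_threshold_mm: float = 0.3
    gs_threshold_pct: float = 1.3
    rotation_radius_mm: float = 50.0
    tsnr_filter: bool = True
    outlier_threshold_sd: float = 3.0
    min_lag: int = 2
    #: Memory status whose trials enter the similarity analysis.
    similarity_status: str = "recollection"
    #: Remove the ROI-mean pattern from each trial before correlating.
    cocktail_blank: bool = False
    #: Exclusion floor on per-delay recollection/familiarity trial counts.
    min_trials_per_condition: int = 9


@dataclass
class PipelineConfig:
    """Full configuration of one reproducible pipeline run."""

    seed: int = 0
    n_subjects: int = 19
    design: DesignParams = field(default_factory=DesignParams)
    behavior: BehavioralParams = field(default_factory=BehavioralParams)
    neural: NeuralParams = field(default_factory=NeuralParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    #: Between-subject SD of the ROI gain parameters.
    subject_gain_sd: float = 0.2
    #: Slope linking a subject's latent ability to the delayed anterior-HF
    #: context gain and to delayed associative accuracy.
    ability_context_slope: float = 0.8
    ability_assoc_slope: float = 0.14
    ability_recombined_slope: float = 0.06
    rho_subject_sd: float = 0.04

    def validate(self) -> None:
        self.design.validate()
        self.behavior.validate()
        self.neural.validate()
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")


def to_dict(obj: Any) -> Any:
    """Recursively convert a parameter dataclass to plain JSON-able types."""

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_dict(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of a configuration (for provenance stamping)."""

    payload = json.dumps(to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Rebuild a :class:`PipelineConfig` from a plain dict (YAML/JSON)."""

    def build(cls, payload):
        kwargs = {}
        names = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in payload.items():
            if key not in names:
                raise ConfigurationError(f"unknown config field {key!r}")
            f = names[key]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "design",
                "behavior",
                "neural",
                "analysis",
            ):
                sub = {
                    "design": DesignParams,
                    "behavior": BehavioralParams,
                    "neural": NeuralParams,
                    "analysis": AnalysisParams,
                }[f.name]
                kwargs[key] = build(sub, value)
            else:
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[key] = value
        return cls(**kwargs)

    return build(PipelineConfig, data)
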