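"""HRF construction, design matrices, condition GLM, LSS, artifact flags."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import contextsim as cs
from contextsim.config import EstimationError, SchedulingError
from contextsim.glm import (
    build_design_matrix,
    double_gamma_hrf,
    fit_condition_glm,
    fit_lss,
    hrf_regressors,
)
from contextsim.simulate import realize_neural, trial_amplitude_patterns

from conftest import noiseless

TR = 1.22


def _trial_frame(onsets, conditions=None):
    df = pd.DataFrame({"onset": np.asarray(onsets, float)})
    df["condition"] = conditions if conditions is not None else "immediate_recollection"
    return df


class TestHRF:
    def test_matches_spm_reference_shape(self):
        """Cross-check against nilearn's SPM HRF implementation."""

        nilearn_glm = pytest.importorskip("nilearn.glm.first_level")
        t = np.arange(0, 32.0, 0.1)
        ours = double_gamma_hrf(t)
        theirs = nilearn_glm.spm_hrf(0.1, oversampling=1, time_length=32.0)
        n = min(len(ours), len(theirs))
        r = np.corrcoef(ours[:n], theirs[:n])[0, 1]
        assert r > 0.999

    def test_peak_and_undershoot(self):
        t = np.arange(0, 32, 0.01)
        h = double_gamma_hrf(t)
        assert 4.0 < t[h.argmax()] < 6.5
        assert h.min() < 0  # undershoot present
        assert abs(h.min()) < 0.5 * h.max()

    def test_single_event_regressor_peaks_after_onset(self):
        R = hrf_regressors([10.0], n_scans=40, tr_s=TR)
        peak_time = R[:, 0].argmax() * TR - 10.0
        assert 4.0 < peak_time < 6.5
        assert R[: int(10 / TR), 0].max() == 0.0


class TestDesignMatrix:
    def test_column_sums_track_trial_counts(self):
        onsets = np.arange(10) * 40.0 + 10.0
        conds = ["a"] * 7 + ["b"] * 3
        dm = build_design_matrix(
            _trial_frame(onsets, conds), n_scans=400, tr_s=TR, drift_order=None
        )
        # far from run edges, each stick contributes ~the same HRF mass
        # (up to sampling phase relative to the scan grid)
        assert dm["a"].sum() / dm["b"].sum() == pytest.approx(7 / 3, rel=1e-2)

    def test_spike_column_one_hot(self):
        dm = build_design_matrix(
            _trial_frame([5.0, 30.0]), n_scans=60, tr_s=TR, spike_scans=[10]
        )
        col = dm["spike10"].to_numpy()
        assert col.sum() == 1.0 and col[10] == 1.0

    def test_onset_beyond_run_raises(self):
        with pytest.raises(SchedulingError):
            build_design_matrix(_trial_frame([999.0]), n_scans=100, tr_s=TR)

    def test_nine_condition_labels_derived(self, trials):
        labels = cs.condition_labels(trials)
        assert set(labels) <= set(cs.config.CONDITIONS_9)


class TestConditionGLM:
    def _noiseless_run(self, tiny_neural, design, trials):
        params = noiseless(tiny_neural)
        params = replace(
            params,
            context_gain={"left_ant_hf": {"immediate": 0.0, "delayed": 0.0}},
        )
        bold = cs.simulate_bold(design, trials, params, seed=0)
        return params, bold

    def test_noiseless_recovery_of_recollection_gain(
        self, tiny_neural, design, trials
    ):
        """Recollection-minus-familiarity contrast recovers the true gain."""

        params, bold = self._noiseless_run(tiny_neural, design, trials)
        run = bold.runs[0]
        run_trials = trials.loc[run.trial_index]
        dm = build_design_matrix(run_trials, run.n_scans, TR, drift_order=2)
        res = fit_condition_glm(run.flat().T, dm)
        con = res.recollection_contrasts()
        roi = bold.realization.flat_indices("left_ant_hf")
        assert np.allclose(con["immediate"][roi], 0.5, atol=1e-3)
        assert np.allclose(con["delayed"][roi], 0.1, atol=1e-3)
        assert np.allclose(con["delay_difference"][roi], 0.4, atol=2e-3)

    def test_zero_data_zero_betas(self):
        dm = build_design_matrix(_trial_frame([5.0, 40.0]), 80, TR, drift_order=None)
        res = fit_condition_glm(np.zeros((80, 4)), dm)
        assert np.allclose(res.betas.to_numpy(), 0.0)

    def test_voxel_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((80, 6))
        dm = build_design_matrix(_trial_frame([5.0, 40.0]), 80, TR)
        perm = rng.permutation(6)
        b1 = fit_condition_glm(Y, dm).betas.to_numpy()
        b2 = fit_condition_glm(Y[:, perm], dm).betas.to_numpy()
        assert np.allclose(b1[:, perm], b2)

    def test_collinear_columns_named(self):
        dm = build_design_matrix(_trial_frame([5.0, 40.0]), 80, TR, drift_order=0)
        dm["dup"] = dm["immediate_recollection"]
        with pytest.raises(EstimationError, match="collinear"):
            fit_condition_glm(np.zeros((80, 2)), dm)


class TestLSS:
    def _separated_data(self, n_trials=6, sep=36.0, n_vox=5, seed=0):
        rng = np.random.default_rng(seed)
        onsets = 5.0 + np.arange(n_trials) * sep
        n_scans = int((onsets[-1] + 40) / TR)
        amps = rng.uniform(0.5, 2.0, size=(n_trials, n_vox))
        R = hrf_regressors(onsets, n_scans, TR)
        Y = R @ amps
        table = _trial_frame(onsets)
        table["run"] = 0
        return Y, table, amps

    def test_noiseless_recovery_to_1e6(self):
        """Well-separated noiseless trials: betas equal generating amplitudes."""

        Y, table, amps = self._separated_data()
        bs = fit_lss(Y, table, TR, drift_order=None)
        assert np.max(np.abs(bs.matrix - amps)) < 1e-6

    def test_linearity_in_amplitude(self):
        Y, table, amps = self._separated_data()
        Y2 = Y.copy()
        # double trial 2's contribution
        R = hrf_regressors(table["onset"].to_numpy(), Y.shape[0], TR)
        Y2 += np.outer(R[:, 2], amps[2])
        b1 = fit_lss(Y, table, TR, drift_order=None).matrix
        b2 = fit_lss(Y2, table, TR, drift_order=None).matrix
        assert np.allclose(b2[2], 2 * b1[2], atol=1e-8)

    def test_equivalence_with_condition_glm_one_trial_per_condition(self):
        """With one trial per condition and no noise, LSS = condition GLM."""

        onsets = [5.0, 45.0, 85.0]
        conds = ["a", "b", "c"]
        n_scans = 120
        R = hrf_regressors(onsets, n_scans, TR)
        amps = np.array([[1.0], [2.0], [0.5]])
        Y = R @ amps
        table = _trial_frame(onsets, conds)
        table["run"] = 0
        lss = fit_lss(Y, table, TR, drift_order=None).matrix
        dm = build_design_matrix(table, n_scans, TR, drift_order=None)
        cond = fit_condition_glm(Y, dm).betas
        for k, c in enumerate(conds):
            assert lss[k, 0] == pytest.approx(cond.loc[c, 0], abs=1e-8)

    def test_default_design_yields_252_betas(self, design, trials, tiny_neural):
        bold = cs.simulate_bold(design, trials, tiny_neural, seed=0)
        parts = []
        for run in bold.runs:
            idx = bold.realization.flat_indices("left_ant_hf")
            parts.append(
                fit_lss(run.flat()[idx].T, trials.loc[run.trial_index], TR,
                        motion=run.motion, drift_order=2)
            )
        bs = cs.concat_beta_series(parts)
        assert bs.n_trials == 252
        assert bs.matrix.shape == (252, 20)

    @pytest.mark.parametrize("noise_sd,floor", [(1.0, 0.75), (0.3, 0.9)])
    def test_beta_recovery_correlation(self, design, trials, tiny_neural, noise_sd, floor):
        """LSS betas track generating patterns; > 0.9 at low scan noise.

        At the default scan noise (CNR ~ 1 per event) the truth-estimate
        correlation settles near 0.78; quieter noise recovers > 0.9.
        """

        params = replace(tiny_neural, noise_sd=noise_sd)
        rs = []
        for seed in range(5):
            t = cs.simulate_behavior(design, seed=seed)
            bold = cs.simulate_bold(design, t, params, seed=seed)
            run = bold.runs[0]
            idx = bold.realization.flat_indices("left_ant_hf")
            bs = fit_lss(
                run.flat()[idx].T, t.loc[run.trial_index], TR,
                motion=run.motion, drift_order=2,
            )
            truth = bold.ground_truth["left_ant_hf"][run.trial_index]
            rs.append(np.corrcoef(bs.matrix.ravel(), truth.ravel())[0, 1])
        assert np.mean(rs) > floor


class TestArtifactFlags:
    def test_still_subject_flat_signal(self):
        flags = cs.flag_suspect_timepoints(np.zeros((50, 6)), np.full(50, 100.0))
        assert len(flags) == 0

    def test_motion_jump_flagged(self):
        motion = np.zeros((50, 6))
        motion[20:, 0] = 0.5  # 0.5 mm translation jump at scan 20
        flags = cs.flag_suspect_timepoints(motion, np.full(50, 100.0))
        assert flags.tolist() == [20]

    def test_subthreshold_signal_change_not_flagged(self):
        gs = np.full(60, 100.0)
        gs[30] = 101.0  # 1.0% change, below the 1.3% cut
        flags = cs.flag_suspect_timepoints(np.zeros((60, 6)), gs)
        assert len(flags) == 0
        gs[30] = 101.5  # 1.5% change -> flagged (both edges)
        flags = cs.flag_suspect_timepoints(np.zeros((60, 6)), gs)
        assert 30 in flags.tolist()

    def test_rotation_contributes_via_radius(self):
        motion = np.zeros((10, 6))
        motion[5:, 3] = 0.008  # rad; x50 mm = 0.4 mm displacement
        flags = cs.flag_suspect_timepoints(motion, np.full(10, 100.0))
        assert 5 in flags.tolist()

    def test_spike_column_isolates_flagged_scan(self):
        """Betas are invariant to the data value at a spike-modeled scan."""

        onsets = [5.0, 40.0]
        n_scans = 80
        R = hrf_regressors(onsets, n_scans, TR)
        Y = R @ np.array([[1.0], [2.0]])
        Y2 = Y.copy()
        Y2[10] += 50.0
        table = _trial_frame(onsets)
        dm_kwargs = dict(n_scans=n_scans, tr_s=TR, spike_scans=[10], drift_order=1)
        b1 = fit_condition_glm(Y, build_design_matrix(_trial_frame(onsets), **dm_kwargs)).betas
        b2 = fit_condition_glm(Y2, build_design_matrix(_trial_frame(onsets), **dm_kwargs)).betas
        keep = [r for r in b1.index if not r.startswith("spike")]
        assert np.allclose(b1.loc[keep].to_numpy(), b2.loc[keep].to_numpy(), atol=1e-9)
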