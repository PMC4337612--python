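"""Pairwise similarity, pair-selection rules, the context statistic, and
its room-label randomization null."""

import numpy as np
import pandas as pd
import pytest

import contextsim as cs
from contextsim.config import DegenerateStrataError
from contextsim.similarity import (
    PairSet,
    context_similarity,
    fisher_z,
    pairwise_similarity,
    randomization_test,
    select_pairs,
)
from contextsim.simulate import realize_neural, trial_amplitude_patterns


def _meta(rows):
    """rows: (run, trial, list, room, status)"""

    return pd.DataFrame(
        rows, columns=["run", "trial", "list", "room", "memory_status"]
    ).assign(item="x", onset=0.0)


HOUSES = {
    "bedroom": "day2_house1",
    "kitchen": "day2_house1",
    "office": "day2_house2",
    "patio": "day2_house2",
}


class TestPairwiseSimilarity:
    def test_self_correlation_is_one(self):
        P = np.random.default_rng(0).normal(size=(4, 30))
        C = pairwise_similarity(P)
        assert np.allclose(np.diag(C), 1.0)

    def test_symmetry(self):
        P = np.random.default_rng(1).normal(size=(6, 12))
        C = pairwise_similarity(P)
        assert np.allclose(C, C.T)

    def test_orthogonal_patterns(self):
        P = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        C = pairwise_similarity(P)
        assert abs(C[0, 1]) < 1e-12

    def test_zero_variance_trial_invalid(self):
        P = np.vstack([np.ones(10), np.random.default_rng(2).normal(size=10)])
        C = pairwise_similarity(P)
        assert np.isnan(C[0, 1])

    def test_cocktail_blank_removes_common_pattern(self):
        rng = np.random.default_rng(3)
        common = rng.normal(size=40)
        P = common + 0.1 * rng.normal(size=(6, 40))
        raw = pairwise_similarity(P)
        blanked = pairwise_similarity(P, cocktail_blank=True)
        off = ~np.eye(6, dtype=bool)
        assert raw[off].mean() > 0.9
        assert abs(blanked[off].mean()) < 0.5


class TestSelectPairs:
    def test_adjacent_trials_excluded(self):
        meta = _meta(
            [
                (0, 0, "immediate", "bedroom", "recollection"),
                (0, 1, "immediate", "bedroom", "recollection"),
                (0, 3, "immediate", "bedroom", "recollection"),
            ]
        )
        ps = select_pairs(meta, HOUSES)
        got = {(meta.loc[a, "trial"], meta.loc[b, "trial"]) for a, b in zip(ps.i, ps.j)}
        assert got == {(0, 3), (1, 3)}  # lag-1 pair (0,1) excluded

    def test_same_room_pair_included(self):
        meta = _meta(
            [
                (0, 0, "immediate", "bedroom", "recollection"),
                (0, 5, "immediate", "bedroom", "recollection"),
            ]
        )
        ps = select_pairs(meta, HOUSES)
        assert len(ps) == 1 and ps.pair_type[0] == "same"

    def test_house_grouped_different_rooms_excluded(self):
        meta = _meta(
            [
                (0, 0, "immediate", "bedroom", "recollection"),
                (0, 5, "immediate", "kitchen", "recollection"),  # same house
                (0, 9, "immediate", "office", "recollection"),  # other house
            ]
        )
        ps = select_pairs(meta, HOUSES)
        kinds = sorted(
            (meta.loc[a, "room"], meta.loc[b, "room"]) for a, b in zip(ps.i, ps.j)
        )
        assert ("bedroom", "kitchen") not in kinds
        assert ("bedroom", "office") in kinds
        assert ("kitchen", "office") in kinds

    def test_lists_and_status_not_mixed(self):
        meta = _meta(
            [
                (0, 0, "immediate", "bedroom", "recollection"),
                (0, 4, "delayed", "bedroom", "recollection"),
                (0, 8, "immediate", "bedroom", "familiarity"),
            ]
        )
        assert len(select_pairs(meta, HOUSES)) == 0

    def test_no_cross_run_pairs(self):
        meta = _meta(
            [
                (0, 0, "immediate", "bedroom", "recollection"),
                (1, 5, "immediate", "bedroom", "recollection"),
            ]
        )
        assert len(select_pairs(meta, HOUSES)) == 0

    def test_flagged_trials_excluded(self):
        meta = _meta(
            [
                (0, 0, "immediate", "bedroom", "recollection"),
                (0, 5, "immediate", "bedroom", "recollection"),
            ]
        )
        flags = np.array([False, True])
        assert len(select_pairs(meta, HOUSES, flags=flags)) == 0


class TestContextSimilarity:
    def _pairset(self, i, j, runs, types):
        n = len(i)
        return PairSet(
            i=np.asarray(i),
            j=np.asarray(j),
            run=np.asarray(runs),
            list_label=np.array(["immediate"] * n, dtype=object),
            pair_type=np.array(types, dtype=object),
        )

    def test_identical_cells_give_zero(self):
        C = np.full((4, 4), np.tanh(0.25))
        ps = self._pairset([0, 0], [1, 2], [0, 0], ["same", "different"])
        res = context_similarity(C, ps)
        assert res.context_similarity == pytest.approx(0.0)

    def test_arithmetic_oracle(self):
        """same z-mean 0.30, different z-mean 0.10 in every run -> 0.20."""

        C = np.zeros((6, 6))
        pairs_i = [0, 0, 2, 2, 4, 4]
        pairs_j = [1, 1, 3, 3, 5, 5]
        # one same and one different pair per run; encode z targets via tanh
        C[0, 1] = C[1, 0] = np.tanh(0.30)
        C[2, 3] = C[3, 2] = np.tanh(0.30)
        C[4, 5] = C[5, 4] = np.tanh(0.30)
        Cd = np.tanh(0.10)
        C[0, 2] = C[2, 0] = Cd
        C[1, 3] = C[3, 1] = Cd
        C[4, 0] = C[0, 4] = Cd
        ps = self._pairset(
            [0, 0, 2, 1, 4, 4],
            [1, 2, 3, 3, 5, 0],
            [0, 0, 1, 1, 2, 2],
            ["same", "different"] * 3,
        )
        res = context_similarity(C, ps)
        assert res.same_mean == pytest.approx(0.30)
        assert res.diff_mean == pytest.approx(0.10)
        assert res.context_similarity == pytest.approx(0.20)

    def test_run_missing_cell_omitted(self):
        C = np.zeros((4, 4))
        C[0, 1] = C[1, 0] = np.tanh(0.5)
        C[2, 3] = C[3, 2] = np.tanh(0.2)
        ps = self._pairset([0, 2], [1, 3], [0, 1], ["same", "different"])
        res = context_similarity(C, ps)  # neither run has both cells
        assert not res.defined

    def test_invariant_to_reordering(self, design, trials, tiny_neural):
        """Permuting trial rows (with metadata) leaves the statistic fixed."""

        pats, _ = cs.simulate_trial_patterns(design, trials, tiny_neural, seed=0)
        P = pats["left_ant_hf"]
        meta = trials[["run", "trial", "list", "room", "memory_status"]].copy()
        perm = np.random.default_rng(0).permutation(len(meta))
        stat0 = context_similarity(
            pairwise_similarity(P),
            select_pairs(meta, design.house_grouping),
            list_label="immediate",
        ).context_similarity
        meta_p = meta.iloc[perm].reset_index(drop=True)
        stat1 = context_similarity(
            pairwise_similarity(P[perm]),
            select_pairs(meta_p, design.house_grouping),
            list_label="immediate",
        ).context_similarity
        assert stat1 == pytest.approx(stat0, abs=1e-12)


class TestRandomization:
    def _subject(self, seed, context=0.0):
        d = cs.generate_design(seed)
        t = cs.simulate_behavior(d, seed=seed)
        params = cs.NeuralParams(
            grid_shape=(4, 4, 2),
            roi_spec={"left_ant_hf": 20},
            recollection_gain={"left_ant_hf": {"immediate": 0.4, "delayed": 0.4}},
            context_gain={"left_ant_hf": {"immediate": context, "delayed": context}},
        )
        pats, _ = cs.simulate_trial_patterns(d, t, params, seed=seed)
        meta = t[["run", "trial", "onset", "item", "list", "room", "memory_status"]]
        return pats["left_ant_hf"], meta, d.house_grouping

    def test_p_value_bounds_and_support(self):
        P, meta, houses = self._subject(0, context=1.0)
        res = randomization_test(P, meta, houses, n_perm=199, seed=1)
        assert 1 / 200 <= res.p_value <= 1.0
        assert res.n_perm == 199
        assert len(res.null) == 199

    def test_strong_context_gain_detected(self):
        P, meta, houses = self._subject(3, context=1.5)
        res = randomization_test(P, meta, houses, n_perm=199, seed=1)
        assert res.p_value <= 0.01

    def test_null_mean_zero_under_shuffles(self):
        """Room-label shuffles of a c>0 subject center the statistic on 0."""

        P, meta, houses = self._subject(5, context=1.0)
        res = randomization_test(P, meta, houses, n_perm=200, seed=2)
        se = res.null.std(ddof=1) / np.sqrt(len(res.null))
        assert abs(res.null.mean()) < 3 * se + 1e-3

    def test_min_permutations_enforced(self):
        P, meta, houses = self._subject(0)
        with pytest.raises(cs.ConfigurationError):
            randomization_test(P, meta, houses, n_perm=50, seed=0)

    def test_degenerate_strata_raise(self):
        P, meta, houses = self._subject(0)
        meta = meta.copy()
        meta["room"] = np.where(meta["list"] == "lure", meta["room"], "bedroom")
        with pytest.raises(DegenerateStrataError):
            randomization_test(P, meta, houses, n_perm=100, seed=0)

    def test_familiarity_trials_carry_no_context_signal(self):
        """Context injected only on recollection: familiarity stat ~ 0."""

        stats_f, stats_r = [], []
        for seed in range(25):
            d = cs.generate_design(seed)
            t = cs.simulate_behavior(d, seed=seed)
            params = cs.NeuralParams(
                grid_shape=(4, 4, 2),
                roi_spec={"left_ant_hf": 20},
                recollection_gain={"left_ant_hf": {"immediate": 0.4, "delayed": 0.4}},
                context_gain={"left_ant_hf": {"immediate": 0.8, "delayed": 0.8}},
            )
            pats, _ = cs.simulate_trial_patterns(d, t, params, seed=seed)
            meta = t[["run", "trial", "list", "room", "memory_status"]]
            C = pairwise_similarity(pats["left_ant_hf"])
            for status, acc in (("familiarity", stats_f), ("recollection", stats_r)):
                ps = select_pairs(meta, d.house_grouping, status=status)
                acc.append(context_similarity(C, ps).context_similarity)
        tf, pf = cs.directional_t(np.array(stats_f))
        tr, pr = cs.directional_t(np.array(stats_r))
        assert pr < 1e-4  # recollection pairs show the effect
        assert abs(np.nanmean(stats_f)) < 0.02
        assert abs(tf) < 2.5


class TestMonotonicity:
    def test_statistic_increases_with_context_gain(self):
        """Mean statistic rises across c in {0, 0.5, 1.0} (module property)."""

        means = []
        for c in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(15):
                d = cs.generate_design(seed)
                t = cs.simulate_behavior(d, seed=seed)
                params = cs.NeuralParams(
                    grid_shape=(4, 4, 2),
                    roi_spec={"left_ant_hf": 20},
                    recollection_gain={
                        "left_ant_hf": {"immediate": 0.4, "delayed": 0.4}
                    },
                    context_gain={"left_ant_hf": {"immediate": c, "delayed": c}},
                )
                pats, _ = cs.simulate_trial_patterns(d, t, params, seed=seed)
                meta = t[["run", "trial", "list", "room", "memory_status"]]
                ps = select_pairs(meta, d.house_grouping)
                vals.append(
                    context_similarity(
                        pairwise_similarity(pats["left_ant_hf"]), ps
                    ).context_similarity
                )
            means.append(np.nanmean(vals))
        assert means[0] < means[1] < means[2]
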