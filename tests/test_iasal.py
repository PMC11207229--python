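"""Adjacent-slice scoring, selection, the simulated doctor, and workload accounting."""

import numpy as np
import pytest

from swsal.annotations import dice
from swsal.iasal import (
    AnnotationState,
    BBOX_ONLY,
    CORRECTED,
    IasalSchedule,
    SEG_LABELED,
    adjacent_dice_scores,
    equivalent_workload,
    equivalent_workload_exact,
    oracle_correct,
    select_slices,
)


def _random_stack(rng, n=6, shape=(8, 8)):
    return [(rng.random(shape) > 0.5).astype(np.uint8) for _ in range(n)]


class TestAdjacentDiceScores:
    def test_identical_predictions_score_one(self):
        m = np.zeros((5, 5), np.uint8)
        m[1:3, 1:3] = 1
        assert adjacent_dice_scores([m, m.copy(), m.copy()]) == [1.0, 1.0, 1.0]

    def test_three_slice_hand_case(self):
        # dice(U1,U2)=0.8, dice(U2,U3)=0.6 -> [0.8, 0.7, 0.6]
        u1 = np.zeros((1, 10), np.uint8); u1[0, :4] = 1
        u2 = np.zeros((1, 10), np.uint8); u2[0, :6] = 1
        u3 = np.zeros((1, 10), np.uint8); u3[0, 3:10] = 1  # |∩|=3, sizes 6,7 -> 6/13
        d12, d23 = dice(u1, u2), dice(u2, u3)
        scores = adjacent_dice_scores([u1, u2, u3])
        assert scores == pytest.approx([d12, (d12 + d23) / 2, d23])
        assert d12 == pytest.approx(0.8)

    def test_two_slices_share_their_single_pair(self):
        rng = np.random.default_rng(0)
        a, b = _random_stack(rng, 2)
        scores = adjacent_dice_scores([a, b])
        assert scores[0] == scores[1] == dice(a, b)

    def test_single_slice_scores_zero(self):
        assert adjacent_dice_scores([np.ones((3, 3), np.uint8)]) == [0.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_pairwise_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        stack = _random_stack(rng, n=7)
        n = len(stack)
        expected = []
        for i in range(n):
            if i == 0:
                expected.append(dice(stack[0], stack[1]))
            elif i == n - 1:
                expected.append(dice(stack[-2], stack[-1]))
            else:
                expected.append((dice(stack[i - 1], stack[i]) + dice(stack[i], stack[i + 1])) / 2)
        assert adjacent_dice_scores(stack) == pytest.approx(expected, abs=1e-12)


class TestSelectSlices:
    def test_threshold_zero_selects_nothing(self):
        assert select_slices([0.2, 0.9, 0.0], 0.0) == []

    def test_threshold_one_selects_all_below_one(self):
        assert select_slices([0.8, 1.0, 0.99], 1.0) == [0, 2]

    def test_hand_case(self):
        assert select_slices([0.8, 0.7, 0.6], 0.75) == [1, 2]

    def test_lower_threshold_never_selects_more(self):
        rng = np.random.default_rng(1)
        scores = list(rng.random(20))
        for hi in (0.9, 0.7, 0.5):
            assert len(select_slices(scores, hi - 0.2)) <= len(select_slices(scores, hi))


def _state_one_case(n=8, labeled=()):
    statuses = {"c": [SEG_LABELED if i in labeled else BBOX_ONLY for i in range(n)]}
    return AnnotationState(statuses=statuses, ss=len(labeled), sbb=n - len(labeled))


class TestOracleCorrect:
    def test_interval_zero_corrects_all(self):
        state = _state_one_case()
        gt = np.ones((8, 2, 2), np.uint8)
        masks = np.zeros_like(gt)
        kept = oracle_correct([1, 3, 5], gt, 0, state, "c", masks)
        assert kept == [1, 3, 5]
        assert state.ss == 3

    def test_interval_two_keeps_every_third(self):
        state = _state_one_case()
        gt = np.ones((8, 2, 2), np.uint8)
        masks = np.zeros_like(gt)
        kept = oracle_correct([0, 1, 2, 4, 6, 7], gt, 2, state, "c", masks)
        assert kept == [0, 4]  # positions 0 and 3 of the sorted selection

    def test_corrected_masks_equal_ground_truth_bitwise(self):
        state = _state_one_case()
        rng = np.random.default_rng(0)
        gt = (rng.random((8, 4, 4)) > 0.5).astype(np.uint8)
        masks = np.zeros_like(gt)
        kept = oracle_correct([2, 5], gt, 0, state, "c", masks)
        for i in kept:
            assert np.array_equal(masks[i], gt[i])
            assert state.statuses["c"][i] == CORRECTED

    def test_status_never_regresses(self):
        state = _state_one_case(labeled=(0,))
        with pytest.raises(ValueError):
            state.set_status("c", 0, BBOX_ONLY)


class TestWorkload:
    @pytest.mark.parametrize("ss, sbb, expected", [
        (320, 10800, 1040),
        (0, 11120, 741),
        (5, 0, 5),
    ])
    def test_equivalent_workload(self, ss, sbb, expected):
        assert equivalent_workload(ss, sbb) == expected

    def test_exact_variant_keeps_fraction(self):
        assert equivalent_workload_exact(0, 11120) == pytest.approx(11120 / 15)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            equivalent_workload(-1, 0)


class TestSchedule:
    def test_dice_ts_linear_to_one(self):
        s = IasalSchedule(dice_ts_start=0.6, n_rounds=5, correction_interval_start=3)
        vals = [s.dice_ts(r) for r in range(5)]
        assert vals[0] == pytest.approx(0.6)
        assert vals[-1] == 1.0
        assert np.allclose(np.diff(vals), np.diff(vals)[0])

    def test_interval_steps_down_to_zero(self):
        s = IasalSchedule(dice_ts_start=0.6, n_rounds=5, correction_interval_start=3)
        assert [s.interval(r) for r in range(5)] == [3, 2, 1, 0, 0]

    def test_nonterminating_schedule_rejected(self):
        with pytest.raises(ValueError, match="non-terminating"):
            IasalSchedule(dice_ts_start=0.6, n_rounds=2, correction_interval_start=5)


class TestRunIasal:
    """Integration behaviour of the annotation loop on a tiny phantom problem."""

    @staticmethod
    def _setup(small_volumes):
        from swsal.annotations import SparseConfig, select_sparse_slices
        from swsal.network import BackboneConfig, DualHeadNet
        from swsal.trainer import TrainConfig

        volumes = small_volumes[:2]
        sparse_indices = {
            v.case_id: select_sparse_slices(v.n_slices, SparseConfig(s_int=2)) for v in volumes
        }
        state = AnnotationState.from_sparse(volumes, sparse_indices)
        net = DualHeadNet(BackboneConfig(base_channels=3, depth=2), seed=0)
        cfg = TrainConfig(max_rounds=2, batch_size=4, seed=0)
        return volumes, state, net, cfg

    def test_single_round_schedule_annotates_everything(self, small_volumes):
        from swsal.iasal import run_iasal

        volumes, state, net, cfg = self._setup(small_volumes)
        sched = IasalSchedule(dice_ts_start=1.0, n_rounds=1, correction_interval_start=0)
        _, state, df = run_iasal(net, volumes, "bone", state, sched, cfg, retrain_rounds=1)
        assert len(df) == 1
        assert state.all_labeled

    def test_workload_counters_reconcile(self, small_volumes):
        from swsal.iasal import run_iasal

        volumes, state, net, cfg = self._setup(small_volumes)
        initial_ss = state.ss
        sched = IasalSchedule(dice_ts_start=0.5, n_rounds=3, correction_interval_start=2)
        _, state, df = run_iasal(net, volumes, "bone", state, sched, cfg, retrain_rounds=1)
        assert state.ss == initial_ss + df["n_corrected"].sum()
        assert df["n_corrected"].ge(0).all()
        assert df["ss"].is_monotonic_increasing

    def test_cold_start_retrains_from_scratch(self, small_volumes):
        from swsal.iasal import run_iasal
        from swsal.network import DualHeadNet

        volumes, state, net, cfg = self._setup(small_volumes)
        params_before = net.get_params()
        sched = IasalSchedule(dice_ts_start=1.0, n_rounds=1, correction_interval_start=0)
        net, _, _ = run_iasal(
            net, volumes, "bone", state, sched, cfg, retrain_rounds=1, warm_start=False
        )
        fresh = DualHeadNet(net.config, seed=cfg.seed)
        # the returned net descends from a fresh seed init, not the incoming params
        assert not any(np.array_equal(a, b) for a, b in zip(net.get_params()[:1], params_before[:1]))
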