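import numpy as np
import pytest

from iluq.chem import parse_ion_pair
from iluq.screening import (
    ScreeningStage,
    run_sequential_screen,
    run_stage,
)
from iluq.uncertainty import ThresholdSpec


def _pairs(n):
    return [
        parse_ion_pair(f"{'C' * (i + 1)}[NH3+].[Cl-]", f"c{i:03d}")
        for i in range(n)
    ]


def preset_predictor(table):
    """A stage predictor backed by a pair_id -> (prediction, ru) table."""

    def predict(pairs, conditions):
        pred = np.array([table[p.pair_id][0] for p in pairs])
        ru = np.array([table[p.pair_id][1] for p in pairs])
        return pred, ru

    return predict


RU_THR = ThresholdSpec("II", 0.5, {}, "RU")


class TestRunStage:
    def test_pass_through_when_all_reliable_and_percentile_100(self):
        pairs = _pairs(5)
        table = {p.pair_id: (float(i), 0.1) for i, p in enumerate(pairs)}
        stage = ScreeningStage("viscosity", preset_predictor(table), RU_THR,
                               direction="keep_low", cutoff_rule=("percentile", 100.0))
        survivors, record = run_stage(pairs, stage)
        assert len(survivors) == 5
        # ordered ascending by prediction for keep_low
        assert [p.pair_id for p in survivors] == [p.pair_id for p in pairs]
        assert record.n_unreliable == 0 and record.n_failed_cutoff == 0

    def test_hand_fixture_absolute_cutoff_tally(self):
        """5 candidates with preset (prediction, RU): survivors match a
        by-hand tally."""
        pairs = _pairs(5)
        table = {
            "c000": (1.0, 0.1),   # reliable, passes <= 2.0
            "c001": (3.0, 0.1),   # reliable, fails cutoff
            "c002": (1.5, 0.9),   # unreliable
            "c003": (2.0, 0.5),   # reliable (tie at threshold), passes (tie at cutoff)
            "c004": (0.5, 0.2),   # reliable, passes
        }
        stage = ScreeningStage("viscosity", preset_predictor(table), RU_THR,
                               direction="keep_low", cutoff_rule=("absolute", 2.0))
        survivors, record = run_stage(pairs, stage)
        assert {p.pair_id for p in survivors} == {"c000", "c003", "c004"}
        assert record.n_unreliable == 1
        assert record.n_failed_cutoff == 1
        # merit order: ascending prediction
        assert [p.pair_id for p in survivors] == ["c004", "c000", "c003"]

    def test_empty_input_empty_output(self):
        stage = ScreeningStage("viscosity", preset_predictor({}), RU_THR)
        survivors, record = run_stage([], stage)
        assert survivors == [] and record.n_in == 0

    def test_keep_high_direction(self):
        pairs = _pairs(4)
        table = {p.pair_id: (float(i), 0.0) for i, p in enumerate(pairs)}
        stage = ScreeningStage("co2_capacity", preset_predictor(table), RU_THR,
                               direction="keep_high", cutoff_rule=("absolute", 2.0))
        survivors, _ = run_stage(pairs, stage)
        assert [p.pair_id for p in survivors] == ["c003", "c002"]

    def test_conservation_invariant(self):
        rng = np.random.default_rng(17)
        pairs = _pairs(60)
        table = {p.pair_id: (rng.normal(), rng.gamma(1.0, 0.4)) for p in pairs}
        stage = ScreeningStage("viscosity", preset_predictor(table), RU_THR,
                               direction="keep_low", cutoff_rule=("percentile", 40.0))
        _, record = run_stage(pairs, stage)
        assert (record.n_unreliable + record.n_failed_cutoff
                + record.n_survivors) == record.n_in == 60

    def test_loosening_cutoff_never_shrinks_survivors(self):
        rng = np.random.default_rng(23)
        pairs = _pairs(40)
        table = {p.pair_id: (rng.normal(), rng.gamma(1.0, 0.4)) for p in pairs}
        sizes = []
        for cut in (-1.0, 0.0, 1.0, 5.0):
            stage = ScreeningStage("viscosity", preset_predictor(table), RU_THR,
                                   direction="keep_low",
                                   cutoff_rule=("absolute", cut))
            survivors, _ = run_stage(pairs, stage)
            sizes.append(len(survivors))
        assert sizes == sorted(sizes)

    def test_mu_threshold_rejected(self):
        with pytest.raises(ValueError, match="RU"):
            ScreeningStage("viscosity", preset_predictor({}),
                           ThresholdSpec("II", 0.5, {}, "MU", "C-MF"))


class TestSequentialScreen:
    def test_single_stage_reduces_to_run_stage(self):
        pairs = _pairs(6)
        table = {p.pair_id: (float(i), 0.1) for i, p in enumerate(pairs)}
        stage = ScreeningStage("viscosity", preset_predictor(table), RU_THR,
                               direction="keep_low", cutoff_rule=("absolute", 3.0))
        direct, _ = run_stage(pairs, stage)
        report = run_sequential_screen(pairs, [stage])
        assert [p.pair_id for p in report.survivors] == [p.pair_id for p in direct]

    def test_two_stage_funnel_5_3_1(self):
        pairs = _pairs(5)
        t1 = {"c000": (1.0, 0.1), "c001": (1.0, 0.1), "c002": (1.0, 0.1),
              "c003": (9.0, 0.1), "c004": (1.0, 0.9)}
        t2 = {"c000": (0.9, 0.1), "c001": (0.1, 0.1), "c002": (0.8, 0.8),
              "c003": (0.0, 0.1), "c004": (0.0, 0.1)}
        stages = [
            ScreeningStage("viscosity", preset_predictor(t1), RU_THR,
                           direction="keep_low", cutoff_rule=("absolute", 5.0)),
            ScreeningStage("log_ec50", preset_predictor(t2), RU_THR,
                           direction="keep_high", cutoff_rule=("absolute", 0.85)),
        ]
        report = run_sequential_screen(pairs, stages)
        assert report.funnel() == [5, 3, 1]
        assert [p.pair_id for p in report.survivors] == ["c000"]

    def test_duplicate_stage_properties_rejected(self):
        stage = ScreeningStage("viscosity", preset_predictor({}), RU_THR)
        with pytest.raises(ValueError, match="distinct"):
            run_sequential_screen([], [stage, stage])

    def test_absolute_cutoffs_are_order_independent(self):
        """A candidate passing every stage's gate survives under either
        stage order when cutoffs are absolute."""
        rng = np.random.default_rng(31)
        pairs = _pairs(100)
        t1 = {p.pair_id: (rng.normal(), rng.gamma(1.0, 0.3)) for p in pairs}
        t2 = {p.pair_id: (rng.normal(), rng.gamma(1.0, 0.3)) for p in pairs}

        def stages(order):
            s1 = ScreeningStage("viscosity", preset_predictor(t1), RU_THR,
                                direction="keep_low", cutoff_rule=("absolute", 0.5))
            s2 = ScreeningStage("log_ec50", preset_predictor(t2), RU_THR,
                                direction="keep_high", cutoff_rule=("absolute", -0.5))
            return [s1, s2] if order == "ab" else [s2, s1]

        surv_ab = {p.pair_id for p in run_sequential_screen(pairs, stages("ab")).survivors}
        surv_ba = {p.pair_id for p in run_sequential_screen(pairs, stages("ba")).survivors}
        assert surv_ab == surv_ba
        # brute force: candidates individually passing both gates
        expected = {
            p.pair_id for p in pairs
            if t1[p.pair_id][1] <= 0.5 and t1[p.pair_id][0] <= 0.5
            and t2[p.pair_id][1] <= 0.5 and t2[p.pair_id][0] >= -0.5
        }
        assert surv_ab == expected
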