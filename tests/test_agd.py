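"""AGD: grid generation, update rules, selection, stopping, correlations."""

import numpy as np
import pandas as pd
import pytest

from fbccnn.agd import (
    AGDSearch,
    CandidateGrid,
    RoundResult,
    enumerate_round,
    hyperparam_correlations,
    init_grids,
    marginal_trend,
    next_grid,
    select_seed_sets,
    should_stop,
)
from fbccnn.model import HyperparamSet


def _result(rows):
    return RoundResult(
        round_index=0,
        records=[(HyperparamSet(**hp), tr, te, lo) for hp, tr, te, lo in rows],
    )


class TestGrids:
    def test_round1_triples_at_8_channels(self):
        g = init_grids(8)
        assert g.axes["nk1"] == (8.0, 16.0, 64.0)
        assert g.axes["k2"] == (8.0, 16.0, 64.0)
        assert g.axes["s2"] == (1 / 8, 1 / 4, 1.0)
        assert g.nfb_candidates == (1, 3, 7)

    def test_full_product_is_243(self):
        combos, removed = enumerate_round(init_grids(8), nfft=110)
        assert len(combos) == 243
        assert removed == 0

    def test_stride_candidates_resolve_against_k2(self):
        combos, _ = enumerate_round(init_grids(8))
        for hp in combos:
            assert hp.s2 <= hp.k2
        # K2=64 instantiates the stride triple as (8, 16, 64)
        s2_at_64 = sorted({hp.s2 for hp in combos if hp.k2 == 64})
        assert s2_at_64 == [8, 16, 64]

    def test_single_free_axis_gives_three(self):
        g = CandidateGrid(
            axes={"nk1": (16.0, 16.0, 16.0), "nk2": (16.0, 16.0, 16.0),
                  "k2": (8.0, 16.0, 64.0), "s2": (1.0, 1.0, 1.0)},
            nfb_candidates=(3,),
        )
        combos, _ = enumerate_round(g)
        assert len(combos) == 3

    def test_all_invalid_strides_raise(self):
        g = CandidateGrid(
            axes={"nk1": (8.0, 8.0, 8.0), "nk2": (8.0, 8.0, 8.0),
                  "k2": (8.0, 16.0, 64.0), "s2": (2.0, 3.0, 4.0)},
            nfb_candidates=(1,),
        )
        with pytest.raises(ValueError, match="no valid combination"):
            enumerate_round(g)

    def test_k2_clamped_by_input_width(self):
        g = init_grids(64)  # k2 up to 512
        combos, _ = enumerate_round(g, nfft=110)
        for hp in combos:
            assert hp.k2 <= 2 * 110 * hp.nfb


class TestTrendAndUpdate:
    @pytest.mark.parametrize(
        "perfs,expected",
        [
            ((60, 70, 80), "increasing"),
            ((60, 80, 70), "peaked"),
            ((80, 70, 60), "decreasing"),
            ((70, 70, 70), "peaked"),      # ties refine
            ((80, 70, 80), "decreasing"),  # valley falls through
        ],
    )
    def test_marginal_trend(self, perfs, expected):
        assert marginal_trend(perfs) == expected

    @pytest.mark.parametrize(
        "trend,expected",
        [
            ("increasing", (64.0, 128.0, 512.0)),
            ("peaked", (12.0, 16.0, 40.0)),
            ("decreasing", (1.0, 4.0, 8.0)),
        ],
    )
    def test_update_rules_on_8_16_64(self, trend, expected):
        assert next_grid((8, 16, 64), trend) == expected

    def test_oscillation_triggers_refinement(self):
        out = next_grid((8, 16, 64), "increasing", prev_trend="decreasing")
        assert out == next_grid((8, 16, 64), "peaked")

    def test_stride_refinement_under_decreasing_rule(self):
        # decreasing on (K2/8, K2/4, K2) -> (K2/64, K2/16, K2/8)
        out = next_grid((1 / 8, 1 / 4, 1.0), "decreasing", integer=False,
                        upper=1.0)
        assert out == (1 / 64, 1 / 16, 1 / 8)
        # increasing collapses onto the K2 ceiling -> (K2, K2, K2)
        out = next_grid((1 / 8, 1 / 4, 1.0), "increasing", integer=False,
                        upper=1.0)
        assert out == (1.0, 1.0, 1.0)

    def test_upper_clamp_collapse_freezes(self):
        assert next_grid((8, 16, 64), "increasing", upper=64) == (64, 64, 64)


class TestSelection:
    def test_ranked_by_test_then_train_then_loss(self):
        base = dict(nfb=1, nk1=8, nk2=8, k2=8)
        res = _result([
            (dict(base, s2=1), 90, 70, 0.5),
            (dict(base, s2=2), 95, 80, 0.4),
            (dict(base, s2=3), 99, 80, 0.3),
            (dict(base, s2=4), 99, 60, 0.2),
        ])
        picks = select_seed_sets(res, top_m=2)
        assert [p.s2 for p in picks] == [3, 2]

    def test_all_equal_takes_enumeration_order(self):
        base = dict(nfb=1, nk1=8, nk2=8, k2=8)
        res = _result([(dict(base, s2=i), 50, 50, 1.0) for i in (1, 2, 3)])
        picks = select_seed_sets(res, top_m=2)
        assert [p.s2 for p in picks] == [1, 2]

    def test_top_m_exceeding_available_warns(self):
        base = dict(nfb=1, nk1=8, nk2=8, k2=8)
        res = _result([(dict(base, s2=1), 50, 50, 1.0)])
        with pytest.warns(UserWarning, match="only 1"):
            picks = select_seed_sets(res, top_m=3)
        assert len(picks) == 1

    def test_manual_chooser_override(self):
        base = dict(nfb=1, nk1=8, nk2=8, k2=8)
        res = _result([
            (dict(base, s2=1), 90, 70, 0.5),
            (dict(base, s2=2), 95, 80, 0.4),
        ])
        picks = select_seed_sets(res, chooser=lambda table: [1])
        assert picks[0].s2 == 1  # second-ranked row


class TestStopping:
    @pytest.mark.parametrize(
        "history,stop",
        [([78.6, 79.0], True), ([70.0, 78.0], False), ([70.0], False)],
    )
    def test_should_stop(self, history, stop):
        assert should_stop(history, tol_pct=1.0) is stop


class TestCorrelations:
    def _rows(self, rng, n=243):
        rows = []
        for _ in range(n):
            k2 = int(rng.integers(4, 40))
            nk1 = int(rng.integers(4, 40))
            acc = 2.0 * k2  # exact linear dependence on K2
            rows.append((dict(nfb=3, nk1=nk1, nk2=8, k2=k2, s2=2),
                         min(acc, 100), min(acc, 100) * 0.9, 1.0))
        return rows

    def test_perfect_linearity_gives_r_one(self):
        rng = np.random.default_rng(0)
        res = _result(self._rows(rng))
        corr, pairwise = hyperparam_correlations(res)
        assert corr.loc["k2", "test_acc"] == pytest.approx(1.0, abs=1e-9)
        assert pairwise["test_acc_norm"].min() == 0.0
        assert pairwise["test_acc_norm"].max() == 1.0

    def test_independent_hyperparameter_near_zero(self):
        rng = np.random.default_rng(1)
        res = _result(self._rows(rng))
        corr, _ = hyperparam_correlations(res)
        assert abs(corr.loc["nk1", "test_acc"]) < 0.2

    def test_constant_column_is_undefined_not_zero(self):
        rng = np.random.default_rng(2)
        corr, _ = hyperparam_correlations(_result(self._rows(rng)))
        assert np.isnan(corr.loc["nfb", "test_acc"])

    def test_too_few_combinations_rejected(self):
        res = _result([(dict(nfb=1, nk1=8, nk2=8, k2=8, s2=1), 50, 50, 1.0)])
        with pytest.raises(ValueError, match="at least 3"):
            hyperparam_correlations(res)


def unimodal_objective(hp):
    """Smooth log-quadratic bowl with its optimum (f=100) inside the
    round-0 span at (K2=96, S2=24, Nk1=32, Nk2=32)."""
    val = 100 * np.exp(
        -((np.log(hp.k2 / 96)) ** 2 + (np.log(hp.s2 / 24)) ** 2
          + 0.1 * (np.log(hp.nk1 / 32)) ** 2
          + 0.1 * (np.log(hp.nk2 / 32)) ** 2) / 2
    )
    return val, val, 100 - val


class TestSearchDriver:
    def test_two_rounds_recover_unimodal_optimum_within_5pct(self):
        s = AGDSearch(unimodal_objective, n_channels=8, nfft=110,
                      max_rounds=2, nfb_candidates=(3,)).fit()
        assert (100.0 - s.best_performance_) / 100.0 < 0.05
        assert len(s.state_.results) == 2

    def test_history_serializable(self):
        s = AGDSearch(unimodal_objective, n_channels=8, nfft=110,
                      max_rounds=2, nfb_candidates=(3,)).fit()
        blob = s.state_.to_dict()
        assert len(blob["rounds"]) == 2
        assert all(len(r["selected"]) == 2 for r in blob["rounds"])

    def test_flat_objective_stops_early(self):
        s = AGDSearch(lambda hp: (50.0, 50.0, 1.0), n_channels=8,
                      max_rounds=4, nfb_candidates=(1,)).fit()
        assert s.state_.stopped
        assert len(s.state_.results) == 2
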