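"""Greedy acquisition, ensembling rules, train-set regimes, and trace
invariants of the active-learning engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aldock.active_loop import (
    ActiveConfig,
    RunTrace,
    acquire_batch,
    build_train_set,
    ensemble_meanrank,
    ensemble_topfromevery,
    run_active_learning,
    stopping_diagnostic,
)
from aldock.models import ModelSpec
from aldock.oracle import SyntheticOracleSpec, make_synthetic_library


class TestAcquireBatch:
    def test_increasing_predictions_return_first_ids(self):
        pool = np.arange(10, 30)
        pred = np.linspace(0, 1, 20)
        ids, terminal = acquire_batch(pred, pool, 5)
        np.testing.assert_array_equal(ids, pool[:5])
        assert not terminal

    def test_all_equal_ties_break_by_ascending_id(self):
        pool = np.array([7, 3, 9, 1, 5])
        ids, _ = acquire_batch(np.zeros(5), pool, 3)
        np.testing.assert_array_equal(ids, [1, 3, 5])

    def test_short_pool_returned_whole_and_empty_pool_terminal(self):
        pool = np.array([4, 2])
        ids, terminal = acquire_batch(np.array([0.5, 0.1]), pool, 10)
        np.testing.assert_array_equal(ids, [2, 4])
        assert not terminal
        ids, terminal = acquire_batch(np.empty(0), np.empty(0, dtype=int), 5)
        assert len(ids) == 0 and terminal

    @given(seed=st.integers(0, 10_000), n=st.integers(1, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_full_sort_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        size = rng.integers(1, 10_000)
        pool = np.sort(rng.choice(20_000, size=size, replace=False))
        pred = np.round(rng.normal(size=size), 1)  # coarse values force ties
        got, _ = acquire_batch(pred, pool, n)
        order = sorted(range(size), key=lambda i: (pred[i], pool[i]))
        expected = pool[order][: min(n, size)]
        np.testing.assert_array_equal(got, expected)


class TestMeanRank:
    def test_single_model_identity(self):
        pred = np.array([0.3, -1.0, 0.7, 0.0])
        pool = np.arange(4)
        combined = ensemble_meanrank([pred], pool)
        np.testing.assert_array_equal(np.argsort(combined), np.argsort(pred))

    def test_hand_enumerated_two_model_example(self):
        """Model ranks (1,3),(2,1),(3,2) -> mean ranks (2.0, 1.5, 2.5);
        acquisition order ligand1, ligand0, ligand2."""
        pred_a = np.array([-3.0, -2.0, -1.0])  # ranks 1,2,3
        pred_b = np.array([-1.0, -3.0, -2.0])  # ranks 3,1,2
        combined = ensemble_meanrank([pred_a, pred_b], np.arange(3))
        np.testing.assert_allclose(combined, [2.0, 1.5, 2.5])
        ids, _ = acquire_batch(combined, np.arange(3), 3)
        np.testing.assert_array_equal(ids, [1, 0, 2])

    def test_model_order_invariance(self):
        rng = np.random.default_rng(3)
        preds = [rng.normal(size=50) for _ in range(4)]
        pool = np.arange(0, 50, 2)
        a = ensemble_meanrank(preds, pool)
        b = ensemble_meanrank(preds[::-1], pool)
        np.testing.assert_array_equal(a, b)

    def test_ties_get_midranks(self):
        combined = ensemble_meanrank([np.array([1.0, 1.0, 0.0])], np.arange(3))
        np.testing.assert_allclose(combined, [2.5, 2.5, 1.0])

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce_average_of_rank_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n_models = rng.integers(1, 6)
        pool = np.sort(rng.choice(2000, size=rng.integers(2, 1000), replace=False))
        preds = [np.round(rng.normal(size=2000), 1) for _ in range(n_models)]
        got = ensemble_meanrank(preds, pool)
        # independent construction: explicit per-model midrank vectors
        from scipy.stats import rankdata

        expected = np.mean([rankdata(p[pool]) for p in preds], axis=0)
        np.testing.assert_allclose(got, expected)


class TestTopFromEvery:
    def test_identical_models_degenerate_to_single_top(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=100)
        pool = np.arange(100)
        got = ensemble_topfromevery([pred] * 4, pool, 10)
        expected, _ = acquire_batch(pred, pool, 10)
        np.testing.assert_array_equal(np.sort(got), np.sort(expected))

    def test_disjoint_tops_contribute_equally(self):
        # model 1 prefers ids 0..3, model 2 prefers ids 10..13
        pred1 = np.where(np.arange(20) < 4, -1.0, 1.0) + np.arange(20) * 1e-3
        pred2 = np.where((np.arange(20) >= 10) & (np.arange(20) < 14), -1.0, 1.0) \
            + np.arange(20) * 1e-3
        got = ensemble_topfromevery([pred1, pred2], np.arange(20), 4)
        assert len(got) == 4
        assert set(got) == {0, 1, 10, 11}

    def test_overlapping_tops_refill_to_exact_size(self):
        rng = np.random.default_rng(5)
        pool = np.arange(100)
        preds = [rng.normal(size=100) for _ in range(3)]
        got = ensemble_topfromevery(preds, pool, 10)
        assert len(got) == 10
        assert len(set(got.tolist())) == 10

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce_set_construction(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 6))
        pool = np.sort(rng.choice(300, size=int(rng.integers(5, 100)), replace=False))
        n = int(rng.integers(1, 30))
        preds = [np.round(rng.normal(size=300), 1) for _ in range(k)]
        got = ensemble_topfromevery(preds, pool, n)

        # brute force with plain python loops
        import math

        share = math.ceil(n / k)
        per_model = [
            [int(i) for i in sorted(pool.tolist(), key=lambda i, p=p: (p[i], i))]
            for p in preds
        ]
        chosen, seen = [], set()
        for ranked in per_model:
            for lig in ranked[:share]:
                if lig not in seen:
                    seen.add(lig)
                    chosen.append(lig)
        for lig in per_model[-1]:
            if len(chosen) >= min(n, len(pool)):
                break
            if lig not in seen:
                seen.add(lig)
                chosen.append(lig)
        np.testing.assert_array_equal(got, chosen[: min(n, len(pool))])


class TestBuildTrainSet:
    def test_add_vs_noadd_counts(self):
        batches = [np.arange(i * 100, (i + 1) * 100) for i in range(3)]
        assert len(build_train_set(batches, "add")) == 300
        assert len(build_train_set(batches, "noadd")) == 100

    def test_first_iteration_regimes_identical(self):
        batches = [np.arange(50)]
        np.testing.assert_array_equal(
            build_train_set(batches, "add"), build_train_set(batches, "noadd")
        )

    def test_add_rows_are_union_of_batches(self):
        rng = np.random.default_rng(1)
        ids = rng.permutation(600)
        batches = [ids[:200], ids[200:400], ids[400:]]
        got = build_train_set(batches, "add")
        assert set(got.tolist()) == set(ids.tolist())

    def test_empty_trace_is_error(self):
        with pytest.raises(ValueError):
            build_train_set([], "add")


@pytest.fixture(scope="module")
def small_campaign_library():
    return make_synthetic_library(
        SyntheticOracleSpec(n_ligands=4000, n_bits=64, seed=21)
    )


class TestRunActiveLearning:
    def test_trace_invariants_and_reproducibility(self, small_campaign_library):
        lib, _ = small_campaign_library
        cfg = ActiveConfig(batch_size=250, n_iterations=4, ensembling="MeanRank",
                           train_regime="add", seed=5)
        t1 = run_active_learning(lib, cfg)
        t2 = run_active_learning(lib, cfg)
        t1.validate()
        docked = t1.docked_ids
        assert len(np.unique(docked)) == len(docked) == 1000
        H = t1.cumulative_hits()
        assert np.all(np.diff(H) >= 0) and H[-1] <= t1.k_hits
        for r1, r2 in zip(t1.records, t2.records):
            np.testing.assert_array_equal(r1.acquired, r2.acquired)

    def test_wellspecified_model_recovers_hits_quickly(self, small_campaign_library):
        """Noiseless linear oracle: one model iteration suffices to point at
        the true top of the library."""
        lib, _ = small_campaign_library
        cfg = ActiveConfig(batch_size=200, n_iterations=3, ensembling="LastModel",
                           seed=1)
        trace = run_active_learning(lib, cfg)
        assert trace.records[-1].cum_hits >= 0.99 * trace.k_hits

    @pytest.mark.parametrize("ensembling", ["LastModel", "MeanRank", "TopFromEveryModel"])
    def test_all_ensembling_regimes_run(self, small_campaign_library, ensembling):
        lib, _ = small_campaign_library
        cfg = ActiveConfig(batch_size=200, n_iterations=3, ensembling=ensembling,
                           window=2, seed=2)
        trace = run_active_learning(lib, cfg)
        assert len(trace.records) == 3
        assert trace.records[1].train_size == 200  # noadd default

    def test_add_regime_grows_train_size(self, small_campaign_library):
        lib, _ = small_campaign_library
        cfg = ActiveConfig(batch_size=200, n_iterations=4, train_regime="add", seed=2)
        trace = run_active_learning(lib, cfg)
        assert [r.train_size for r in trace.records] == [0, 200, 400, 600]

    def test_random_baseline_yield_tracks_chance(self, small_campaign_library):
        """Uniformly random acquisition retrieves ~docked*beta hits."""
        lib, _ = small_campaign_library
        finals = []
        for seed in range(8):
            cfg = ActiveConfig(batch_size=400, n_iterations=5, baseline="random",
                               seed=seed)
            finals.append(run_active_learning(lib, cfg).records[-1].cum_hits)
        n, d = lib.n, 2000
        k = round(0.01 * n)
        expect = d * k / n
        var = d * (k / n) * (1 - k / n) * (n - d) / (n - 1)
        se = np.sqrt(var / 8)
        assert abs(np.mean(finals) - expect) < 3 * se

    def test_second_docking_fixed_predictions(self):
        lib, paired = make_synthetic_library(
            SyntheticOracleSpec(n_ligands=4000, n_bits=64, noise_to_signal=0.5, seed=9)
        )
        cfg = ActiveConfig(batch_size=200, n_iterations=5, seed=0)
        trace = run_active_learning(lib, cfg, fixed_predictions=paired.realization_b)
        rand = run_active_learning(
            lib, ActiveConfig(batch_size=200, n_iterations=5, baseline="random", seed=0)
        )
        assert trace.records[-1].cum_hits > rand.records[-1].cum_hits

    def test_budget_truncation(self, small_campaign_library):
        lib, _ = small_campaign_library
        cfg = ActiveConfig(batch_size=1500, n_iterations=3, baseline="random", seed=0)
        trace = run_active_learning(lib, cfg)
        assert [len(r.acquired) for r in trace.records] == [1500, 1500, 1000]
        trace.validate()

    def test_score_stats_recorded(self, small_campaign_library):
        lib, _ = small_campaign_library
        cfg = ActiveConfig(batch_size=300, n_iterations=2, seed=3)
        trace = run_active_learning(lib, cfg)
        for rec in trace.records:
            s = lib.scores[rec.acquired]
            assert rec.score_min == s.min()
            assert rec.score_mean == pytest.approx(s.mean())
            assert rec.score_median == pytest.approx(np.median(s))

    def test_trace_jsonl_round_trip(self, small_campaign_library, tmp_path):
        lib, _ = small_campaign_library
        cfg = ActiveConfig(batch_size=200, n_iterations=3, seed=4,
                           base_model=ModelSpec("ridge"))
        trace = run_active_learning(lib, cfg)
        path = tmp_path / "trace.jsonl"
        trace.to_jsonl(path)
        loaded = RunTrace.from_jsonl(path)
        assert loaded.config == cfg
        assert loaded.k_hits == trace.k_hits
        for a, b in zip(trace.records, loaded.records):
            np.testing.assert_array_equal(a.acquired, b.acquired)
            assert a.cum_hits == b.cum_hits


class TestStoppingDiagnostic:
    def test_random_campaign_ratio_near_one(self, small_campaign_library):
        lib, _ = small_campaign_library
        ratios = []
        for seed in range(6):
            cfg = ActiveConfig(batch_size=400, n_iterations=5, baseline="random",
                               seed=seed)
            diag = stopping_diagnostic(run_active_learning(lib, cfg))
            ratios.extend(diag["ratio"].tolist())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.35)

    def test_perfect_predictor_ratio_far_above_one(self, small_campaign_library):
        lib, paired = small_campaign_library
        cfg = ActiveConfig(batch_size=200, n_iterations=3, seed=1)
        trace = run_active_learning(lib, cfg, fixed_predictions=paired.true_score)
        diag = stopping_diagnostic(trace)
        assert diag["ratio"].iloc[1] > 5.0

    def test_exhausted_hits_flagged_zero(self, small_campaign_library):
        lib, paired = small_campaign_library
        # perfect predictor exhausts all 40 hits almost immediately
        cfg = ActiveConfig(batch_size=1000, n_iterations=4, seed=1)
        trace = run_active_learning(lib, cfg, fixed_predictions=paired.true_score)
        diag = stopping_diagnostic(trace)
        assert trace.records[-1].cum_hits == trace.k_hits
        assert not diag["hits_exhausted"].iloc[0]
        # once every hit is found the expected random yield goes to zero
        last = diag.iloc[-1]
        assert last["ratio"] == 0.0 or last["expected_random"] > 0
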