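"""The two-step active-learning loop: seeding, selection, accounting, audit."""

import random

import numpy as np
import pytest

from pepal.active_learning import (
    RunConfig,
    default_prescreen_policy,
    discovery_curve,
    run,
    run_labelled_order,
    screening_baseline,
    weighted_random_selection,
)
from pepal.oracle import SyntheticOracle, SyntheticOracleConfig, true_ap
from pepal.peptides import RestrictionFilter, enumerate_space


@pytest.fixture(scope="module")
def dipeptide_run():
    # shared small run: full dipeptide space, noiseless oracle
    cfg = RunConfig(length=2, batch_size=10, max_iterations=8, rng_seed=0)
    oracle = SyntheticOracle(SyntheticOracleConfig(noise_slope=0.0))
    return run(cfg, oracle=oracle)


class TestPrescreenPolicy:
    @pytest.mark.parametrize("length,expected", [(1, 20), (2, 400), (3, 3000), (6, 6000)])
    def test_default_policy(self, length, expected):
        assert default_prescreen_policy(length) == expected

    def test_policy_below_batch_size_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(length=3, batch_size=20, prescreen_policy=lambda L: 10)

    def test_constant_policy_passthrough(self):
        cfg = RunConfig(length=2, batch_size=10, max_iterations=2,
                        prescreen_policy=lambda L: 10, rng_seed=1)
        rec = run(cfg, oracle=SyntheticOracle(SyntheticOracleConfig(noise_slope=0.0)))
        # with N == batch, step 2 is a pass-through rank of step 1's picks
        for it in rec.iterations[1:]:
            assert set(it.selected) == set(it.step1_pred)


class TestSeedingAndFirstIteration:
    def test_seed_peptide_is_polyalanine(self, dipeptide_run):
        assert dipeptide_run.training.sequences[0] == "AA"
        assert dipeptide_run.seed_labels == 1

    def test_first_iteration_is_random_fallback(self, dipeptide_run):
        first = dipeptide_run.iterations[0]
        assert first.random_fallback and len(first.selected) == 10
        assert not first.step1_pred and not first.step2_pred

    def test_later_iterations_are_model_driven(self, dipeptide_run):
        assert all(not it.random_fallback for it in dipeptide_run.iterations[1:])


class TestBudgetAccounting:
    def test_oracle_calls_match_batches(self, dipeptide_run):
        assert dipeptide_run.oracle_calls == 8 * 10
        assert dipeptide_run.iterations[-1].oracle_calls == 80

    def test_seed_label_outside_loop_budget(self, dipeptide_run):
        assert len(dipeptide_run.training) == 8 * 10 + 1

    def test_no_peptide_labelled_twice(self, dipeptide_run):
        seqs = dipeptide_run.training.sequences
        assert len(seqs) == len(set(seqs))


class TestDeterminismAndStopping:
    def test_same_seed_reproduces_run(self):
        cfg = RunConfig(length=2, batch_size=5, max_iterations=3, rng_seed=9)
        a = run(cfg, oracle=SyntheticOracle(SyntheticOracleConfig(seed=9)))
        b = run(cfg, oracle=SyntheticOracle(SyntheticOracleConfig(seed=9)))
        assert a.labelled_frame().equals(b.labelled_frame())

    def test_single_iteration_limit(self):
        cfg = RunConfig(length=2, batch_size=5, max_iterations=1, rng_seed=0)
        rec = run(cfg)
        assert len(rec.iterations) == 1 and rec.oracle_calls == 5

    def test_ap_threshold_stops_immediately(self):
        cfg = RunConfig(length=2, batch_size=5, max_iterations=50,
                        ap_stop_threshold=0.5, rng_seed=0)
        rec = run(cfg)
        assert len(rec.iterations) == 1 and rec.status == "ap-threshold-reached"

    def test_space_exhaustion_terminates(self):
        # 400 dipeptides, batch 50: the 9th iteration finds nothing left
        cfg = RunConfig(length=2, batch_size=50, max_iterations=20, rng_seed=0)
        rec = run(cfg, oracle=SyntheticOracle(SyntheticOracleConfig(noise_slope=0.0)))
        assert rec.status == "exhausted-space"
        assert len(rec.training) == 400


class TestRestrictedRuns:
    def test_every_label_satisfies_restriction(self, calc):
        filt = RestrictionFilter.parse("logP_WW<0")
        cfg = RunConfig(length=2, batch_size=5, max_iterations=4,
                        restriction=filt, rng_seed=2)
        rec = run(cfg)
        for seq in rec.training.sequences:
            assert calc.logp_ww(seq) < 0

    def test_restriction_excluding_seed_starts_empty(self, calc):
        # polyalanine fails Z >= 1, so the run starts with no seed label
        filt = RestrictionFilter.parse("Z>=1")
        cfg = RunConfig(length=2, batch_size=5, max_iterations=2,
                        restriction=filt, rng_seed=0)
        rec = run(cfg)
        assert rec.seed_labels == 0
        assert all(calc.net_charge(s) >= 1 for s in rec.training.sequences)


class TestStepTwoConservatism:
    def test_batch_is_subset_of_step1_shortlist(self, dipeptide_run):
        for it in dipeptide_run.iterations[1:]:
            assert set(it.selected) <= set(it.step1_pred)
            assert set(it.selected) <= set(it.step2_pred)


class TestConvergence:
    def test_noiseless_exhaustive_prescreen_finds_global_optimum(self):
        # brute-force ground truth over all 400 dipeptides is the oracle
        cfg_oracle = SyntheticOracleConfig(noise_slope=0.0)
        optimum = max(enumerate_space(2), key=lambda p: true_ap(p, cfg_oracle))
        cfg = RunConfig(length=2, batch_size=10, max_iterations=10, rng_seed=3)
        rec = run(cfg, oracle=SyntheticOracle(cfg_oracle))
        assert optimum in rec.training.sequences

    def test_mean_measured_ap_climbs_from_random_start(self):
        # self-improvement: over the climb phase (before the sparse top of
        # the space is drained) the per-iteration mean AP trends upward and
        # model-driven iterations beat the random first batch
        slope_wins = beat_random_wins = 0
        for seed in range(5):
            cfg = RunConfig(length=3, batch_size=10, max_iterations=8, rng_seed=seed)
            rec = run(cfg, oracle=SyntheticOracle(SyntheticOracleConfig(seed=seed)))
            means = rec.per_iteration_mean_ap()
            slope_wins += np.polyfit(np.arange(len(means)), means, 1)[0] > 0
            beat_random_wins += np.mean(means[1:]) > means[0]
        assert slope_wins >= 4
        assert beat_random_wins >= 4


class TestWeightedRandomSelection:
    def test_equal_weights_keep_top_pick(self):
        preds = {p: 2.0 for p in ["AA", "AC", "AD", "AE"]}
        batch = weighted_random_selection(preds, 2, random.Random(0))
        assert len(batch) == 2 and batch[0] == "AA"  # lexicographic tie-break

    def test_dominant_weight_nearly_always_sampled(self):
        preds = {"TOP": 10.0, "BIG": 5.0}
        preds.update({f"p{i}": 0.05 for i in range(20)})
        hits = 0
        for seed in range(200):
            batch = weighted_random_selection(preds, 3, random.Random(seed))
            assert batch[0] == "TOP"
            hits += "BIG" in batch
        assert hits / 200 > 0.9

    def test_batch_of_one_is_pure_greedy(self):
        preds = {"AA": 1.0, "WW": 3.0}
        assert weighted_random_selection(preds, 1, random.Random(0)) == ["WW"]

    def test_fewer_candidates_than_batch_takes_all(self):
        preds = {"AA": 1.0, "WW": 3.0}
        assert set(weighted_random_selection(preds, 10, random.Random(0))) == set(preds)

    def test_mode_runs_inside_loop(self):
        cfg = RunConfig(length=2, batch_size=5, max_iterations=3,
                        selection_mode="top1-weighted-random", rng_seed=1)
        rec = run(cfg)
        assert rec.oracle_calls == 15


class TestScreeningBaseline:
    def test_accounting_includes_training_labels(self):
        space = list(enumerate_space(2))
        oracle = SyntheticOracle(SyntheticOracleConfig(noise_slope=0.0))
        res = screening_baseline(50, 10, space, oracle, seed=0)
        assert res["oracle_calls"] == 60
        assert res["mean_ap_top_k"] >= res["mean_ap_all_labels"]

    def test_zero_topk_flagged(self):
        space = list(enumerate_space(2))
        res = screening_baseline(20, 0, space, SyntheticOracle(), seed=0)
        assert res["mean_ap_top_k"] is None and res["oracle_calls"] == 20

    def test_budget_overflow_rejected(self):
        with pytest.raises(ValueError):
            screening_baseline(395, 10, list(enumerate_space(2)), SyntheticOracle())


class TestDiscoveryCurve:
    def test_reference_fully_found(self):
        curve = discovery_curve(["AA", "AC", "AD"], ["AC", "AD"])
        assert curve[-1][1] == 1.0
        fractions = [f for _, f in curve]
        assert fractions == sorted(fractions)

    def test_disjoint_reference_flat_zero(self):
        curve = discovery_curve(["AA", "AC"], ["WW"])
        assert all(f == 0.0 for _, f in curve)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            discovery_curve(["AA"], [])

    def test_run_labelled_order_matches_frame(self, dipeptide_run):
        order = run_labelled_order(dipeptide_run)
        assert order == list(dipeptide_run.labelled_frame()["sequence"])


class TestRunRecordOutputs:
    def test_labelled_frame_schema(self, dipeptide_run):
        df = dipeptide_run.labelled_frame()
        assert list(df.columns) == [
            "iteration", "sequence", "step1_pred", "step2_pred", "measured_ap",
        ]
        assert len(df) == dipeptide_run.oracle_calls

    def test_config_snapshot_serialises(self, dipeptide_run):
        import json

        snap = json.loads(dipeptide_run.config.to_json())
        assert snap["length"] == 2 and snap["prescreen_n"] == 400
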