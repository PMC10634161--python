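import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifsgp import (
    ForestConfig,
    IfsgpError,
    SimulationConfig,
    StepSchedule,
    build_schedule,
    make_cv_plan,
    run_ifs,
    simulate,
)
from ifsgp.ifs_core import COARSE_BREAKPOINTS


class TestSchedule:
    def test_single_snp(self):
        assert build_schedule(1).snp_counts.tolist() == [1]

    def test_three_snps(self):
        assert build_schedule(3).snp_counts.tolist() == [1, 2, 3]

    def test_default_regimes_for_one_thousand(self):
        counts = build_schedule(1000).snp_counts
        expected = (
            list(range(1, 101)) + list(range(105, 501, 5)) + list(range(510, 1001, 10))
        )
        assert counts.tolist() == expected

    def test_p_appended_when_regimes_overshoot(self):
        counts = build_schedule(103).snp_counts
        assert counts.tolist() == list(range(1, 101)) + [103]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.integers(1, 300_000))
    def test_always_starts_at_one_increases_and_ends_at_p(self, p):
        counts = build_schedule(p).snp_counts
        assert counts[0] == 1
        assert counts[-1] == p
        assert np.all(np.diff(counts) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(IfsgpError):
            build_schedule(0)
        with pytest.raises(IfsgpError):
            build_schedule(10, [(5, 0)])
        with pytest.raises(IfsgpError):
            build_schedule(10, [(5, 1), (3, 1)])


class TestCvPlan:
    def test_each_repetition_partitions_all_individuals(self):
        plan = make_cv_plan(103, n_folds=5, n_repetitions=4, seed=1)
        for rep in range(4):
            seen = np.concatenate(
                [plan.fold_indices(rep, f)[1] for f in range(5)]
            )
            assert np.array_equal(np.sort(seen), np.arange(103))

    def test_fold_sizes_differ_by_at_most_one(self):
        plan = make_cv_plan(103, n_folds=5, n_repetitions=4, seed=1)
        for rep in range(4):
            sizes = [len(plan.fold_indices(rep, f)[1]) for f in range(5)]
            assert max(sizes) - min(sizes) <= 1

    def test_repetitions_are_reshuffled_but_seeded(self):
        a = make_cv_plan(50, 5, 3, seed=2)
        b = make_cv_plan(50, 5, 3, seed=2)
        assert np.array_equal(a.assignments, b.assignments)
        assert not np.array_equal(a.assignments[0], a.assignments[1])

    def test_more_folds_than_individuals_rejected(self):
        with pytest.raises(IfsgpError):
            make_cv_plan(3, n_folds=5)


@pytest.fixture(scope="module")
def small_signal():
    return simulate(
        SimulationConfig(n_individuals=120, n_snps=150, n_causal=8,
                         heritability=0.7, seed=13)
    )


class TestRunIfs:
    def test_test_fold_never_leaks_into_ranking_or_fit(self, small_signal):
        d = small_signal
        plan = make_cv_plan(120, 5, 2, seed=3)
        schedule = StepSchedule(np.array([1, 10, 150]), [])
        seen = []

        def audit(rep, fold, n_snps, train_idx, test_idx):
            seen.append((rep, fold, n_snps))
            assert len(np.intersect1d(train_idx, test_idx)) == 0
            assert np.array_equal(
                np.sort(np.concatenate([train_idx, test_idx])), np.arange(120)
            )

        run_ifs(d.genotypes, d.phenotype, schedule, plan,
                ForestConfig(n_trees=10, seed=3), on_fit=audit)
        # exact model accounting: one fit per (step, fold, repetition)
        assert len(seen) == 3 * 5 * 2

    def test_single_step_schedule_gives_full_model_curve(self, small_signal):
        d = small_signal
        plan = make_cv_plan(120, 5, 2, seed=4)
        schedule = StepSchedule(np.array([150]), [])
        curve = run_ifs(d.genotypes, d.phenotype, schedule, plan,
                        ForestConfig(n_trees=30, seed=4))
        assert curve.snp_counts.tolist() == [150]
        assert curve.per_repetition_r2.shape == (1, 2)

    def test_standard_error_definition(self, small_signal):
        d = small_signal
        plan = make_cv_plan(120, 5, 3, seed=5)
        schedule = StepSchedule(np.array([5, 150]), [])
        curve = run_ifs(d.genotypes, d.phenotype, schedule, plan,
                        ForestConfig(n_trees=20, seed=5))
        expected = curve.per_repetition_r2.std(axis=1, ddof=1) / np.sqrt(3)
        assert np.allclose(curve.se_r2, expected)
        assert np.allclose(curve.mean_r2, curve.per_repetition_r2.mean(axis=1))

    def test_null_data_yields_flat_low_curve(self, null_dataset):
        d = null_dataset
        plan = make_cv_plan(200, 5, 3, seed=6)
        schedule = build_schedule(300, COARSE_BREAKPOINTS)
        curve = run_ifs(d.genotypes, d.phenotype, schedule, plan,
                        ForestConfig(n_trees=50, seed=6))
        assert np.all(curve.mean_r2 < 0.1)

    def test_signal_curve_peaks_before_full_model(self, small_signal):
        d = small_signal
        plan = make_cv_plan(120, 5, 3, seed=7)
        schedule = build_schedule(150, COARSE_BREAKPOINTS)
        curve = run_ifs(d.genotypes, d.phenotype, schedule, plan,
                        ForestConfig(n_trees=50, seed=7))
        assert curve.snp_counts[np.argmax(curve.mean_r2)] < 150

    def test_per_fold_aggregation_mode_runs(self, small_signal):
        d = small_signal
        plan = make_cv_plan(120, 5, 2, seed=8)
        schedule = StepSchedule(np.array([10, 150]), [])
        curve = run_ifs(d.genotypes, d.phenotype, schedule, plan,
                        ForestConfig(n_trees=10, seed=8), pooled=False)
        assert curve.per_repetition_r2.shape == (2, 2)

    def test_curve_tsv_roundtrip(self, small_signal, tmp_path):
        d = small_signal
        plan = make_cv_plan(120, 5, 2, seed=9)
        schedule = StepSchedule(np.array([5, 150]), [])
        curve = run_ifs(d.genotypes, d.phenotype, schedule, plan,
                        ForestConfig(n_trees=10, seed=9))
        from ifsgp import IfsCurve

        curve.to_tsv(tmp_path / "c.tsv")
        back = IfsCurve.from_tsv(tmp_path / "c.tsv")
        assert np.allclose(back.mean_r2, curve.mean_r2)
        assert np.allclose(back.per_repetition_r2, curve.per_repetition_r2)
        assert np.array_equal(back.snp_counts, curve.snp_counts)
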