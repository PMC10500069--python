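import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mindeeg.evaluation import (Fold, LeakageError, Strategy, check_no_leakage,
                                kruskal_wallis, make_split, mann_whitney_u,
                                run_cell, summarize_results, transfer_finetune)
from mindeeg.nets import ShallowConvNet


def fake_labels(n_subjects=5, per_class=20):
    y = np.tile(np.r_[np.zeros(per_class, int), np.ones(per_class, int)], n_subjects)
    subjects = np.repeat([f"S{i}" for i in range(n_subjects)], 2 * per_class)
    return y, subjects


class TestMakeSplit:
    def test_mix_network_fractions_60_20_20(self):
        y, subjects = fake_labels(5, 100)  # 1000 trials
        plan = make_split(Strategy.MIX, y, subjects, "net", seed=0, n_reps=3)
        for fold in plan.folds:
            assert len(fold.train) == 600
            assert len(fold.val) == 200
            assert len(fold.test) == 200

    def test_mix_svm_fractions_80_20(self):
        y, subjects = fake_labels(5, 100)
        plan = make_split(Strategy.MIX, y, subjects, "svm", seed=0, n_reps=2)
        for fold in plan.folds:
            assert len(fold.train) == 800
            assert fold.val is None
            assert len(fold.test) == 200

    def test_splits_are_stratified(self):
        y, subjects = fake_labels(3, 30)
        plan = make_split(Strategy.MIX, y, subjects, "net", seed=1, n_reps=2)
        for fold in plan.folds:
            for part in (fold.train, fold.val, fold.test):
                assert abs(np.mean(y[part]) - 0.5) < 0.01

    def test_inter_has_one_fold_per_subject(self):
        y, subjects = fake_labels(11, 10)
        plan = make_split(Strategy.INTER, y, subjects, "svm", seed=0)
        assert len(plan.folds) == 11
        for fold in plan.folds:
            held = fold.held_out_subject
            assert set(subjects[fold.test]) == {held}
            assert held not in set(subjects[fold.train])

    def test_inter_network_fold_has_validation(self):
        y, subjects = fake_labels(4, 20)
        plan = make_split(Strategy.INTER, y, subjects, "net", seed=0)
        for fold in plan.folds:
            assert fold.val is not None and len(fold.val) > 0
            assert held_out_absent(fold, subjects)

    def test_deterministic_given_seed(self):
        y, subjects = fake_labels(4, 25)
        a = make_split(Strategy.MIX, y, subjects, "net", seed=5, n_reps=2)
        b = make_split(Strategy.MIX, y, subjects, "net", seed=5, n_reps=2)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa.train, fb.train)
            np.testing.assert_array_equal(fa.test, fb.test)

    def test_intra_requires_single_subject(self):
        y, subjects = fake_labels(2, 10)
        with pytest.raises(ValueError, match="single subject"):
            make_split(Strategy.INTRA, y, subjects, "svm", seed=0)

    def test_intra_single_class_rejected(self):
        y = np.zeros(20, int)
        subjects = np.array(["S0"] * 20, dtype=object)
        with pytest.raises(ValueError, match="2 classes"):
            make_split(Strategy.INTRA, y, subjects, "svm", seed=0)


def held_out_absent(fold, subjects):
    seen = set(subjects[fold.train]) | set(subjects[fold.val])
    return fold.held_out_subject not in seen


class TestLeakageGuards:
    def test_overlapping_test_and_train_rejected(self):
        fold = Fold(train=np.array([0, 1, 2]), test=np.array([2, 3]))
        with pytest.raises(LeakageError):
            check_no_leakage(fold)

    def test_held_out_subject_in_train_rejected(self):
        subjects = np.array(["A", "A", "B", "B"], dtype=object)
        fold = Fold(train=np.array([0, 1, 2]), test=np.array([3]),
                    held_out_subject="B")
        with pytest.raises(LeakageError, match="held-out"):
            check_no_leakage(fold, subjects)

    def test_clean_fold_passes(self):
        fold = Fold(train=np.array([0, 1]), test=np.array([3]), val=np.array([2]))
        check_no_leakage(fold)

    def test_transfer_pretraining_leak_rejected(self):
        net = ShallowConvNet(max_epochs=1)
        with pytest.raises(LeakageError, match="pretraining"):
            transfer_finetune(net, np.zeros((10, 2, 120)), np.zeros(10, int),
                              pretrain_subjects={"S1", "S2"}, target_subject="S1",
                              seed=0)


class TestRunCell:
    def test_eleven_rows_per_mix_cell(self, small_trialset):
        df = run_cell("csp", Strategy.MIX, "MBSR1_REST1", small_trialset,
                      n_reps=11, base_seed=0)
        assert len(df) == 11
        assert df.seed.tolist() == list(range(11))
        assert df.accuracy.between(0, 1).all()

    def test_inter_rows_match_subject_count(self, small_trialset):
        df = run_cell("csp", Strategy.INTER, "MBSR1_REST1", small_trialset,
                      base_seed=0)
        assert len(df) == 3  # three subjects in the fixture

    def test_transfer_with_svm_method_rejected(self, small_trialset):
        with pytest.raises(ValueError, match="network methods"):
            run_cell("csp", Strategy.TRANSFER, "MBSR1_REST1", small_trialset)

    def test_intra_restricted_to_state_tasks(self, small_trialset):
        with pytest.raises(ValueError, match="state tasks"):
            run_cell("csp", Strategy.INTRA, "REST1_REST2", small_trialset)

    def test_unknown_method_rejected(self, small_trialset):
        with pytest.raises(ValueError, match="unknown method"):
            run_cell("lda", Strategy.MIX, "MBSR1_REST1", small_trialset)

    def test_mix_reproducible(self, small_trialset):
        a = run_cell("csp", Strategy.MIX, "MBSR1_REST1", small_trialset,
                     n_reps=3, base_seed=4)
        b = run_cell("csp", Strategy.MIX, "MBSR1_REST1", small_trialset,
                     n_reps=3, base_seed=4)
        assert a.accuracy.tolist() == b.accuracy.tolist()

    def test_planted_effect_recovered_by_fbcsp(self, small_trialset):
        df = run_cell("fbcsp", Strategy.MIX, "MBSR1_REST1", small_trialset,
                      n_reps=2, base_seed=0)
        assert df.accuracy.mean() >= 0.9

    def test_intra_produces_mean_over_subjects(self, small_trialset):
        df = run_cell("csp", Strategy.INTRA, "MBSR1_REST1", small_trialset,
                      n_reps=2, base_seed=0)
        assert len(df) == 2
        assert df.accuracy.between(0, 1).all()


class TestTransferRunCell:
    def test_one_row_per_target_subject(self, hetero_trialset):
        df = run_cell("shallow", Strategy.TRANSFER, "MBSR1_REST1",
                      hetero_trialset, base_seed=0,
                      net_params=dict(max_epochs=2, patience=2),
                      finetune_epochs=2)
        assert len(df) == 4  # four subjects in the fixture
        assert df.accuracy.between(0, 1).all()


class TestTransferFinetune:
    def test_zero_epochs_equals_pretrained(self, hetero_trialset):
        from mindeeg.preprocess import assemble_task

        sub, y = assemble_task(hetero_trialset, "MBSR1_REST1")
        subjects = sub.subjects
        target = "S01"
        mask = subjects == target
        net = ShallowConvNet(max_epochs=2, patience=2, seed=0)
        net.fit(sub.trials[~mask], y[~mask])
        before = net.predict(sub.trials[mask])
        acc = transfer_finetune(net, sub.trials[mask], y[mask],
                                pretrain_subjects=set(subjects[~mask]),
                                target_subject=target, seed=1, max_epochs=0)
        np.testing.assert_array_equal(net.predict(sub.trials[mask]), before)
        assert 0.0 <= acc <= 1.0


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.z < 0

    def test_identical_samples_not_significant(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p > 0.9

    def test_antisymmetric_in_arguments(self):
        a, b = [1.0, 3.0, 5.0, 2.5], [2.0, 4.0, 6.0]
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(b, a)
        assert r1.z == pytest.approx(-r2.z, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_u_statistic_matches_exact_enumeration(self):
        """U equals the count of (a, b) pairs with a > b (+ half the ties),
        verified by brute-force enumeration on small samples."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 8, size=rng.integers(2, 6)).astype(float)
            b = rng.integers(0, 8, size=rng.integers(2, 6)).astype(float)
            res = mann_whitney_u(a, b)
            brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert res.u == pytest.approx(brute, abs=1e-9)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=12)
        b = rng.normal(0.8, size=10)
        res = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestKruskalWallis:
    def test_identical_groups_yield_zero_h(self):
        h, p = kruskal_wallis([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_constant_data_handled(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_direction_agrees_with_mann_whitney_on_two_groups(self):
        a, b = [1.0, 1.1, 1.2, 0.9], [5.0, 5.2, 4.9, 5.1]
        h, p_kw = kruskal_wallis([a, b])
        p_mw = mann_whitney_u(a, b).p
        assert (p_kw < 0.05) == (p_mw < 0.05)

    def test_separated_groups_significant_vs_permutation_oracle(self):
        """The chi-square p-value agrees in decision with an exact
        permutation distribution of H for three well-separated groups.
        (Three elements per group: with two, no permutation p-value can
        fall below 1/15, so significance at 0.05 is unattainable.)"""
        groups = [[1.0] * 3, [5.0] * 3, [9.0] * 3]
        h_obs, p = kruskal_wallis(groups)
        pooled = [x for g in groups for x in g]
        count = total = 0
        for perm in set(itertools.permutations(pooled)):
            gs = [list(perm[0:3]), list(perm[3:6]), list(perm[6:9])]
            h, _ = kruskal_wallis(gs)
            count += h >= h_obs - 1e-12
            total += 1
        exact_p = count / total
        assert exact_p < 0.05 and p < 0.05

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestSummarize:
    def test_summary_structure(self, small_trialset):
        import pandas as pd

        frames = [
            run_cell("csp", Strategy.MIX, task, small_trialset, n_reps=3, base_seed=0)
            for task in ("MBSR1_REST1", "REST1_REST2")
        ]
        out = summarize_results(pd.concat(frames, ignore_index=True))
        assert "mix|csp|MBSR1_REST1" in out["cells"]
        assert "across_tasks" in out["tests"]["mix"]
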