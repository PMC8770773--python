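import numpy as np
import pytest

from conftest import make_roi_dataset, noise_roi_dataset
from fearmvcc import inference
from fearmvcc.decoder import select_features, train_classifier, cross_classify
from fearmvcc._seeds import derive_rng
from fearmvcc.inference import (
    GroupNull,
    InferenceError,
    ParticipantNull,
    condition_difference_test,
    empirical_p,
    group_null,
    group_observed_accuracy,
    participant_null,
)


def _participant(rng, pid="sub-01", n_train=16, n_test=12, n_vox=10, K=4,
                 n_perm=40, seed=0, two_conditions=False):
    train = noise_roi_dataset(n_train, n_vox, rng, participant_id=pid)
    test = noise_roi_dataset(n_test, n_vox, rng, participant_id=pid)
    subsets = {"view": np.ones(n_test, bool)}
    if two_conditions:
        # split the balanced test set into two balanced halves
        half = n_test // 2
        quarter = half // 2
        mask_a = np.zeros(n_test, bool)
        mask_a[:quarter] = True
        mask_a[half:half + quarter] = True
        subsets = {"A": mask_a, "B": ~mask_a}
    return participant_null(train, test, subsets, K=K, n_perm=n_perm, seed=seed)


class TestParticipantNull:
    def test_deterministic_under_seed(self, rng):
        rng2 = np.random.default_rng(1234)
        a = _participant(rng, seed=3)
        b = _participant(rng2, seed=3)
        np.testing.assert_array_equal(a.nulls["view"], b.nulls["view"])

    def test_fast_loop_equals_public_operations(self, rng):
        """The inlined permutation loop reproduces exactly what the public
        feature-selection / training / classification route computes."""
        import warnings

        from fearmvcc.decoder import _binary_labels

        train = noise_roi_dataset(16, 10, rng, participant_id="sub-09")
        test = noise_roi_dataset(12, 10, rng, participant_id="sub-09")
        subsets = {"view": np.ones(12, bool)}
        pn = participant_null(train, test, subsets, K=4, n_perm=25, seed=7)
        y = _binary_labels(train)
        perm_rng = derive_rng(7, "perm", "sub-09", train.roi_name)
        want = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(25):
                y_perm = y[perm_rng.permutation(len(y))]
                sel = select_features(train, 4, labels=y_perm)
                clf = train_classifier(train, sel, labels=y_perm)
                (res,) = cross_classify(clf, test, subsets)
                want.append(res.accuracy)
        np.testing.assert_allclose(pn.nulls["view"], want)

    def test_null_mean_near_chance(self, rng):
        """Averaged over datasets, the permutation null centers on 50%.

        Conditioned on one small fixed test set the null mean legitimately
        deviates by a few points (the permuted models' votes need not
        balance over 12 trials), so the check averages several datasets.
        """
        means = [_participant(rng, n_perm=150, seed=s).nulls["view"].mean()
                 for s in range(8)]
        assert np.mean(means) == pytest.approx(50.0, abs=3.0)

    def test_signal_data_observed_high_null_at_chance(self, rng):
        """Label permutation destroys signal: observed 100%, null ~50%."""
        half = 8
        X = np.vstack([rng.standard_normal((half, 6)) + [6, 0, 0, 0, 0, 0],
                       rng.standard_normal((half, 6)) - [6, 0, 0, 0, 0, 0]])
        train = make_roi_dataset(X, ["CSplus"] * half + ["CSminus"] * half)
        Xt = np.vstack([rng.standard_normal((4, 6)) + [6, 0, 0, 0, 0, 0],
                        rng.standard_normal((4, 6)) - [6, 0, 0, 0, 0, 0]])
        test = make_roi_dataset(Xt, ["CSplus"] * 4 + ["CSminus"] * 4)
        pn = participant_null(train, test, {"view": np.ones(8, bool)},
                              K=6, n_perm=300, seed=0)
        assert pn.observed["view"] == 100.0
        assert pn.nulls["view"].mean() == pytest.approx(50.0, abs=6.0)

    def test_invalid_n_perm_rejected(self, rng):
        with pytest.raises(InferenceError):
            _participant(rng, n_perm=0)

    def test_seed_pairing_across_conditions(self, rng):
        """Identical data in two condition subsets yields identical nulls,
        because every condition is scored under the same permuted model."""
        train = noise_roi_dataset(16, 8, rng)
        half_X = rng.standard_normal((6, 8))
        X = np.vstack([half_X, half_X])
        viewed = ["CSplus"] * 3 + ["CSminus"] * 3
        test = make_roi_dataset(X, viewed * 2)
        mask_a = np.arange(12) < 6
        pn = participant_null(train, test, {"A": mask_a, "B": ~mask_a},
                              K=4, n_perm=50, seed=0)
        np.testing.assert_array_equal(pn.nulls["A"], pn.nulls["B"])


class TestGroupNull:
    def _constant_nulls(self, value=50.0, n_participants=5, n_perm=20):
        return [
            ParticipantNull(participant_id=f"sub-{i:02d}",
                            nulls={"view": np.full(n_perm, value)},
                            observed={"view": value}, n_perm=n_perm, seed=0)
            for i in range(n_participants)
        ]

    def test_constant_nulls_give_constant_group_null(self):
        gn = group_null(self._constant_nulls(), "view", n_boot=100, seed=0)
        np.testing.assert_allclose(gn.values, 50.0)

    def test_single_participant_resamples_own_null(self, rng):
        pn = ParticipantNull("sub-01", {"view": np.array([40.0, 60.0])},
                             {"view": 55.0}, n_perm=2, seed=0)
        gn = group_null([pn], "view", n_boot=200, seed=0)
        assert set(gn.values) <= {40.0, 60.0}

    def test_mean_matches_law_of_total_expectation(self, rng):
        nulls = [
            ParticipantNull(f"sub-{i}", {"view": rng.uniform(30, 70, 500)},
                            {"view": 50.0}, n_perm=500, seed=0)
            for i in range(6)
        ]
        gn = group_null(nulls, "view", n_boot=4000, seed=1)
        expect = np.mean([pn.nulls["view"].mean() for pn in nulls])
        # Monte-Carlo tolerance: sd(group mean)/sqrt(n_boot) is ~0.07 pp
        assert gn.values.mean() == pytest.approx(expect, abs=0.3)

    def test_empty_participant_list_rejected(self):
        with pytest.raises(InferenceError):
            group_null([], "view", n_boot=10, seed=0)

    def test_mismatched_n_perm_rejected(self):
        nulls = self._constant_nulls(n_perm=10) + self._constant_nulls(n_perm=20)
        with pytest.raises(InferenceError):
            group_null(nulls, "view", n_boot=10, seed=0)


class TestEmpiricalP:
    def _null(self, values):
        return GroupNull(values=np.asarray(values, float), condition="view",
                         n_boot=len(values), seed=0)

    def test_observed_above_entire_null(self):
        res = empirical_p(99.0, self._null(np.full(10_000, 50.0)))
        assert res.p_value == pytest.approx(1 / 10_001)

    def test_observed_below_entire_null_one_tailed(self):
        res = empirical_p(10.0, self._null(np.full(100, 50.0)), tail="greater")
        assert res.p_value == 1.0

    def test_two_tailed_doubles_smaller_tail(self):
        null = self._null(np.arange(100.0))
        hi = empirical_p(98.5, null, tail="two")
        lo = empirical_p(0.5, null, tail="two")
        assert hi.p_value == pytest.approx(2 * (1 + 1) / 101)
        assert lo.p_value == pytest.approx(2 * (1 + 1) / 101)

    def test_p_strictly_positive_and_capped(self):
        null = self._null(np.full(50, 50.0))
        assert 0 < empirical_p(100.0, null).p_value <= 1
        assert empirical_p(50.0, null, tail="two").p_value == 1.0

    def test_uniform_under_null(self, rng):
        """Type-I calibration at small scale: ~5% rejections at alpha=0.05."""
        rejections = 0
        n_rep = 250
        for rep in range(n_rep):
            null = rng.normal(50.0, 5.0, 400)
            observed = rng.normal(50.0, 5.0)
            p = (1 + (null >= observed).sum()) / (1 + len(null))
            rejections += p < 0.05
        from scipy.stats import binom

        lo, hi = binom.interval(0.999, n_rep, 0.05)
        assert lo <= rejections <= hi


class TestConditionDifferenceTest:
    def test_identical_conditions_give_zero_difference(self, rng):
        nulls = []
        for i in range(4):
            v = rng.uniform(30, 70, 50)
            nulls.append(ParticipantNull(f"sub-{i}", {"A": v, "B": v.copy()},
                                         {"A": 60.0, "B": 60.0},
                                         n_perm=50, seed=0))
        res = condition_difference_test(nulls, "A", "B", n_boot=500, seed=0)
        assert res.observed_difference == 0.0
        assert res.p_value == 1.0

    def test_swapping_conditions_negates_difference_keeps_p(self, rng):
        nulls = []
        for i in range(5):
            nulls.append(ParticipantNull(
                f"sub-{i}",
                {"A": rng.uniform(30, 70, 80), "B": rng.uniform(30, 70, 80)},
                {"A": float(rng.uniform(55, 70)), "B": float(rng.uniform(40, 55))},
                n_perm=80, seed=0))
        ab = condition_difference_test(nulls, "A", "B", n_boot=1000, seed=0)
        ba = condition_difference_test(nulls, "B", "A", n_boot=1000, seed=0)
        assert ab.observed_difference == pytest.approx(-ba.observed_difference)
        # two-tailed p is tail-symmetric up to bootstrap resampling noise
        assert ab.p_value == pytest.approx(ba.p_value, abs=0.05)

    def test_missing_condition_rejected(self, rng):
        nulls = [ParticipantNull("sub-0", {"A": np.zeros(10)}, {"A": 50.0},
                                 n_perm=10, seed=0)]
        with pytest.raises(InferenceError):
            condition_difference_test(nulls, "A", "B", n_boot=10, seed=0)

    def test_attenuation_difference_detected_at_high_snr(self, rng):
        """Seed-paired view-vs-imagine test flags a generated attenuation."""
        from fearmvcc.design import apply_exclusions, build_phase_schedule
        from fearmvcc.synthgen import make_pattern_truth, simulate_roi_dataset

        train_sched = apply_exclusions(
            build_phase_schedule("classifier_training", 3, 0))
        test_sched = apply_exclusions(build_phase_schedule("conditioning", 3, 1))
        truth = make_pattern_truth(40, seed=5, imagery_gain=0.3, noise_sd=2.0,
                                   participant_variability_sd=0.2)
        nulls = []
        for i in range(6):
            pid = f"sub-{i:02d}"
            train = simulate_roi_dataset(train_sched, truth, seed=i,
                                         participant_id=pid).analysis_view()
            test = simulate_roi_dataset(test_sched, truth, seed=i + 100,
                                        participant_id=pid).analysis_view()
            instr = test.meta["instruction"].to_numpy()
            nulls.append(participant_null(
                train, test, {"view": instr == "view", "imagine": instr == "imagine"},
                K=20, n_perm=150, seed=0))
        res = condition_difference_test(nulls, "view", "imagine",
                                        n_boot=1000, seed=0)
        assert res.observed_difference > 0
        assert res.p_value < 0.05

    def test_group_observed_accuracy_is_mean(self):
        nulls = [ParticipantNull(f"s{i}", {"A": np.zeros(5)}, {"A": 40.0 + i * 10},
                                 n_perm=5, seed=0) for i in range(3)]
        assert group_observed_accuracy(nulls, "A") == pytest.approx(50.0)
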