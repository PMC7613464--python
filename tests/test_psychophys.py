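"""WUR computation/QC, up-down threshold, Box-Cox and Lilliefors."""

import numpy as np
import pytest
from scipy import stats

from windupkit.errors import ParameterError, SequenceError
from windupkit.psychophys import (
    BoxCoxResult,
    UpDownSequence,
    WurRecord,
    boxcox_transform,
    boxcox_tune,
    compute_wur,
    lilliefors_statistic,
    qc_exclude,
    summarize_wur,
    updown_threshold,
)
from windupkit.synthgen import WurSimParams, gen_wur_cohort


def record(single, train, pid="p"):
    return WurRecord(pid, np.asarray(single, float), np.asarray(train, float))


class TestComputeWur:
    def test_identical_ratings_give_unit_wur(self):
        assert compute_wur(record([3, 4, 5], [3, 4, 5])) == pytest.approx(1.0)

    def test_cohort_magnitudes(self):
        r = record([2.85] * 5, [4.00] * 5)
        assert compute_wur(r) == pytest.approx(4.00 / 2.85)

    def test_zero_single_ratings_excluded(self):
        r = record([0, 0, 0], [5, 5, 5])
        assert compute_wur(r) is None
        assert r.excluded

    def test_scale_invariance(self):
        r1 = record([2, 3, 4], [5, 6, 7])
        r2 = record([4, 6, 8], [10, 12, 14])
        assert compute_wur(r1) == pytest.approx(compute_wur(r2))

    def test_mean_of_ratios_option(self):
        r = record([1, 2], [2, 6])
        assert compute_wur(r, method="mean_of_ratios") == pytest.approx((2 + 3) / 2)


class TestQcExclude:
    def test_boundary_kept_strictly_greater_excluded(self):
        keep = record([1] * 5, [6] * 5, "keep")  # WUR exactly 6
        drop = record([1] * 5, [6.01] * 5, "drop")
        kept, excluded = qc_exclude([keep, drop])
        assert [r.participant_id for r, _ in kept] == ["keep"]
        assert [r.participant_id for r, _ in excluded] == ["drop"]

    def test_partition_is_lossless(self):
        records, _ = gen_wur_cohort(WurSimParams(n_participants=200, outlier_fraction=0.1, seed=1))
        kept, excluded = qc_exclude(records)
        assert len(kept) + len(excluded) == 200

    def test_outlier_fraction_recovered(self):
        records, truth = gen_wur_cohort(
            WurSimParams(n_participants=1000, outlier_fraction=0.1, seed=3)
        )
        _, excluded = qc_exclude(records)
        frac = len(excluded) / 1000
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 1000)


class TestSummarizeWur:
    def test_median_of_three(self):
        kept = [(record([1] * 5, [w] * 5, f"p{w}"), float(w)) for w in (1, 2, 3)]
        s = summarize_wur(kept)
        assert s["wur_median"] == 2.0

    def test_constant_cohort_zero_iqr(self):
        kept = [(record([2] * 5, [3] * 5, f"p{i}"), 1.5) for i in range(10)]
        s = summarize_wur(kept)
        assert s["wur_iqr"] == 0.0

    def test_lognormal_median_recovered(self):
        params = WurSimParams(n_participants=2000, seed=9)
        records, _ = gen_wur_cohort(params)
        kept, _ = qc_exclude(records)
        s = summarize_wur(kept)
        true_median = float(np.exp(params.log_wur_mean))
        # MC error of a log-normal sample median at n=2000
        assert s["wur_median"] == pytest.approx(true_median, rel=0.05)


class TestUpDown:
    LADDER = (0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0)

    def test_never_withdrawing_returns_heaviest(self):
        trials = [(f, False) for f in self.LADDER]
        assert updown_threshold(UpDownSequence(trials, self.LADDER)) == 2.0

    def test_always_withdrawing_returns_lightest(self):
        trials = [(f, True) for f in reversed(self.LADDER)]
        assert updown_threshold(UpDownSequence(trials, self.LADDER)) == 0.04

    def test_malformed_transition_rejected(self):
        # force increases after a withdrawal
        with pytest.raises(SequenceError):
            UpDownSequence([(0.6, True), (1.0, False)], self.LADDER)

    def test_off_ladder_force_rejected(self):
        with pytest.raises(SequenceError):
            UpDownSequence([(0.5, False)], self.LADDER)

    def test_mixed_sequence_threshold_lies_between_reversal_forces(self):
        trials = [(0.6, False), (1.0, True), (0.6, False), (1.0, True),
                  (0.6, False), (1.0, True)]
        thr = updown_threshold(UpDownSequence(trials, self.LADDER))
        assert 0.4 < thr < 1.4

    def test_simulated_deterministic_threshold_recovered(self):
        # true threshold between 0.4 and 0.6 g: withdraw iff force >= 0.5
        ladder = self.LADDER
        true_thr = 0.5
        estimates = []
        for start in range(len(ladder)):
            pos = start
            trials = []
            changes = 0
            while len(trials) < 12:
                force = ladder[pos]
                resp = force >= true_thr
                trials.append((force, resp))
                if len(trials) >= 2 and trials[-1][1] != trials[-2][1]:
                    changes += 1
                if changes >= 1 and len(trials) >= 6:
                    break
                pos = max(0, pos - 1) if resp else min(len(ladder) - 1, pos + 1)
            try:
                estimates.append(updown_threshold(UpDownSequence(trials, ladder)))
            except SequenceError:
                pass
        med = float(np.median(estimates))
        # within one ladder step of the true threshold
        assert 0.16 <= med <= 1.0


class TestBoxCox:
    def test_lognormal_data_tunes_near_zero(self):
        rng = np.random.default_rng(12)
        x = np.exp(rng.normal(0.0, 0.8, size=2000))
        res = boxcox_tune(x)
        assert abs(res.lmbda - 0.0) <= 0.2

    def test_normal_data_tunes_near_one(self):
        # needs real relative spread: for tightly concentrated data every
        # power transform is near-affine and lambda is unidentifiable
        rng = np.random.default_rng(13)
        x = rng.normal(20.0, 6.0, size=2100)
        x = x[x > 0][:2000]
        res = boxcox_tune(x)
        assert abs(res.lmbda - 1.0) <= 0.3

    def test_lambda_one_is_affine_so_statistic_matches_raw(self):
        rng = np.random.default_rng(14)
        x = np.abs(rng.normal(10, 2, 500)) + 0.1
        d_raw = lilliefors_statistic(x)
        d_t = lilliefors_statistic(boxcox_transform(x, 1.0))
        assert d_t == pytest.approx(d_raw, abs=1e-12)

    def test_scale_invariance_of_tuned_lambda(self):
        rng = np.random.default_rng(15)
        x = np.exp(rng.normal(0.5, 0.6, size=800))
        assert boxcox_tune(x).lmbda == pytest.approx(boxcox_tune(7.3 * x).lmbda)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ParameterError):
            boxcox_tune(np.array([1.0, -2.0, 3.0]))


class TestLilliefors:
    def test_perfect_normal_quantiles_give_small_d(self):
        n = 100
        x = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        d = lilliefors_statistic(x)
        # brute-force bound: ECDF steps of 1/n around a near-perfect fit
        assert d <= 1.0 / n

    def test_duplication_leaves_d_nearly_unchanged(self):
        # ECDF and moments are duplication-invariant; only the ddof=1
        # variance correction (the R-convention estimator) shifts D by O(1/n)
        rng = np.random.default_rng(16)
        x = rng.normal(size=60)
        assert lilliefors_statistic(np.concatenate([x, x])) == pytest.approx(
            lilliefors_statistic(x), abs=2.0 / 60
        )

    def test_agrees_with_statsmodels_oracle(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        rng = np.random.default_rng(17)
        for _ in range(5):
            x = rng.gamma(2.0, 1.0, size=80)
            d_sm, _ = sm_lilliefors(x, dist="norm")
            assert lilliefors_statistic(x) == pytest.approx(d_sm, abs=1e-10)

    def test_uniform_data_rejected_by_mc_p(self):
        rng = np.random.default_rng(18)
        x = rng.uniform(size=200)
        d, p = lilliefors_statistic(x, mc_reps=500, seed=1)
        assert p < 0.01

    def test_too_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            lilliefors_statistic([1.0, 2.0, 3.0])
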