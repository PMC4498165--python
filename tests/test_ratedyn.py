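import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from arcpipe.config import DynamicsConfig
from arcpipe.ratedyn import (RateSeries, auroc, auroc_timecourse, bin_rates,
                             epoch_tests, group_compare, isi_statistics,
                             lick_mask, modulation_index, short_isi_rate)
from arcpipe.synth import simulate_spike_train
from arcpipe.types import SessionTimeline, SpikeTrain

TIMELINE = SessionTimeline(0.0, 600.0, 900.0, 3600.0)


def auroc_oracle(baseline, test):
    """Exhaustive pairwise comparison: P(test > baseline) + 0.5 P(tie)."""
    wins = sum(1.0 if t > b else 0.5 if t == b else 0.0
               for t in test for b in baseline)
    return wins / (len(test) * len(baseline))


def stationary_series(lam, rng, timeline=TIMELINE, bin_s=5.0):
    n = int((timeline.session_end - timeline.baseline_start) / bin_s)
    rates = rng.poisson(lam * bin_s, n) / bin_s
    return RateSeries(bin_s, timeline.baseline_start + np.arange(n) * bin_s,
                      rates)


def stepped_series(lam, mult, step_time, rng, timeline=TIMELINE, bin_s=5.0):
    series = stationary_series(lam, rng, timeline, bin_s)
    post = series.start_times >= step_time
    series.rates[post] = rng.poisson(lam * mult * bin_s, post.sum()) / bin_s
    return series


class TestBinRates:
    def test_uniform_spikes_give_expected_rate(self):
        train = SpikeTrain("u", np.linspace(0.1, 4.9, 10))
        series = bin_rates(train, 5.0, (0, 5))
        assert series.rates == pytest.approx([2.0])

    def test_empty_train_gives_zero_series(self):
        series = bin_rates(SpikeTrain("u", []), 5.0, (0, 100))
        assert np.all(series.rates == 0)

    def test_rate_mass_conserves_spike_count(self, rng):
        times = np.sort(rng.uniform(0, 100, 321))
        series = bin_rates(SpikeTrain("u", times), 5.0, (0, 100))
        assert series.rates.sum() * 5.0 == pytest.approx(321)

    def test_span_shorter_than_bin_rejected(self):
        with pytest.raises(ValueError):
            bin_rates(SpikeTrain("u", [1.0]), 5.0, (0, 3))


class TestAuroc:
    def test_fully_separated_samples(self):
        assert auroc([1, 2, 3], [4, 5, 6]) == 1.0

    def test_identical_samples(self):
        assert auroc([1, 2, 2, 5], [1, 2, 2, 5]) == 0.5

    def test_interleaved_example(self):
        # brute force over the 4 ordered pairs: (1>0), (1<2 no), (3>0), (3>2)
        assert auroc([0, 2], [1, 3]) == 0.75

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            auroc([], [1.0])

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=8),
           st.lists(st.integers(0, 5), min_size=1, max_size=8))
    def test_matches_exhaustive_pairwise_oracle(self, a, b):
        assert auroc(a, b) == pytest.approx(auroc_oracle(a, b))

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=8),
           st.lists(st.floats(0, 100), min_size=1, max_size=8))
    def test_complementarity(self, a, b):
        assert auroc(a, b) + auroc(b, a) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        a, b = rng.poisson(4, 30), rng.poisson(6, 40)
        f = lambda x: np.exp(0.3 * x) + 7
        assert auroc(a, b) == pytest.approx(auroc(f(a), f(b)))


class TestAurocTimecourse:
    def test_stationary_unit_hovers_at_half(self, rng):
        series = stationary_series(6.0, rng)
        tc = auroc_timecourse(series, TIMELINE)
        assert abs(np.nanmean(tc.auroc) - 0.5) < 0.05

    def test_baseline_against_itself_is_half(self, rng):
        series = stationary_series(6.0, rng)
        base = series.select(300.0, 600.0)
        assert auroc(base, base) == 0.5

    @pytest.mark.parametrize("mult,side", [(0.4, -1), (2.0, +1)])
    def test_step_multiplier_sets_sign(self, rng, mult, side):
        series = stepped_series(5.0, mult, TIMELINE.food_time, rng)
        tc = auroc_timecourse(series, TIMELINE)
        post = tc.auroc[tc.window_starts >= TIMELINE.food_time]
        assert np.sign(np.nanmean(post) - 0.5) == side

    def test_short_baseline_warns(self, rng):
        tl = SessionTimeline(500.0, 620.0, 900.0, 3600.0)
        series = stationary_series(6.0, rng, tl)
        with pytest.warns(UserWarning, match="baseline"):
            auroc_timecourse(series, tl)


class TestEpochTests:
    def test_stationary_unit_no_epochs_significant(self, rng):
        # single stationary draw; full calibration in the acceptance suite
        results = epoch_tests(stationary_series(8.0, rng), TIMELINE)
        assert [r.epoch for r in results] == ["CUE", "EARLY", "MID", "LATE"]
        assert not any(r.significant for r in results)

    def test_step_drop_at_food_hits_feeding_epochs(self, rng):
        series = stepped_series(8.0, 0.4, TIMELINE.food_time, rng)
        results = {r.epoch: r for r in epoch_tests(series, TIMELINE)}
        for epoch in ("EARLY", "MID", "LATE"):
            assert results[epoch].significant
            assert results[epoch].direction == -1
        assert not results["CUE"].significant

    def test_step_at_lickspout_only_hits_cue(self, rng):
        series = stepped_series(8.0, 0.3, TIMELINE.lickspout_time, rng)
        series.rates[series.start_times >= TIMELINE.food_time] = \
            stationary_series(8.0, rng).rates[
                series.start_times >= TIMELINE.food_time]
        results = {r.epoch: r for r in epoch_tests(series, TIMELINE)}
        assert results["CUE"].significant and results["CUE"].direction == -1

    def test_lick_mask_drops_bins_near_licks(self, rng):
        series = stationary_series(5.0, rng)
        licks = np.array([1000.0, 2000.0])
        mask = lick_mask(series, licks, window_s=8.0)
        near = np.abs(series.start_times[:, None] - licks[None, :]).min(axis=1)
        assert np.array_equal(mask, near > 8.0)
        # masked analysis still runs
        results = epoch_tests(series, TIMELINE, bin_mask=mask)
        assert len(results) == 4


class TestModulationIndex:
    @pytest.mark.parametrize("a,b,expected",
                             [(5.0, 5.0, 0.0), (5.0, 0.0, 1.0),
                              (5.0, 10.0, -1 / 3)])
    def test_values(self, a, b, expected):
        assert modulation_index(a, b) == pytest.approx(expected)

    def test_both_zero_flagged(self):
        assert np.isnan(modulation_index(0.0, 0.0))


class TestShortISIRate:
    def test_regular_slow_spiking_has_none(self):
        train = SpikeTrain("u", np.arange(0, 100, 0.1))
        assert short_isi_rate(train, (0, 100)) == 0.0

    def test_pair_counting_arithmetic(self):
        base = np.arange(20) * 5.0 + 1.0
        times = np.sort(np.concatenate([base, base + 0.040]))
        train = SpikeTrain("u", times)
        assert short_isi_rate(train, (0, 100)) == pytest.approx(0.2)

    def test_poisson_rate_matches_exponential_tail(self, rng):
        lam = 20.0
        train = simulate_spike_train(lambda t: np.full_like(t, lam), 1.0,
                                     (0, 2000), rng)
        observed = short_isi_rate(train, (0, 2000))
        expected = lam * (1 - np.exp(-lam * 0.05))
        assert observed == pytest.approx(expected, rel=0.05)


class TestISIStatistics:
    def test_identical_isis_flagged_degenerate(self):
        train = SpikeTrain("u", np.arange(100) * 0.1)
        stats_ = isi_statistics(train)
        assert stats_.degenerate
        assert stats_.cv_log10_isi == 0.0

    def test_unimodal_log_isis_rarely_rejected(self):
        config = DynamicsConfig(dip_n_boot=500)
        ok = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            isis = 10 ** rng.normal(-1.0, 0.4, 500)
            train = SpikeTrain("u", np.cumsum(isis))
            ok += isi_statistics(train, config).dip_p > 0.05
        assert ok >= 10

    def test_separated_bimodal_log_isis_rejected(self):
        rng = np.random.default_rng(0)
        logs = np.concatenate([rng.normal(-2.0, 0.3, 250),
                               rng.normal(-0.5, 0.3, 250)])
        train = SpikeTrain("u", np.cumsum(10 ** rng.permutation(logs)))
        stats_ = isi_statistics(train, DynamicsConfig(dip_n_boot=500))
        assert stats_.dip_p < 0.05

    def test_cv_uses_sd_over_mean(self, rng):
        isis = 10 ** rng.normal(-1.0, 0.3, 400)
        train = SpikeTrain("u", np.cumsum(isis))
        stats_ = isi_statistics(train, DynamicsConfig(dip_n_boot=50))
        logs = np.log10(np.diff(train.times))
        assert stats_.cv_log10_isi == pytest.approx(logs.std() / logs.mean())
        assert stats_.cv_inverse == pytest.approx(logs.mean() / logs.std())


class TestGroupCompare:
    def test_identical_groups_give_zero_t(self):
        res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_diurnal_difference_detected(self, rng):
        am = rng.normal(1.4, 0.3, 10)
        pm = rng.normal(7.6, 0.3, 9)
        res = group_compare(am, pm)
        assert res.p_value < 0.01
        assert res.mean_a == pytest.approx(am.mean())
        assert res.mean_b == pytest.approx(pm.mean())

    def test_single_value_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [2.0, 3.0])
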