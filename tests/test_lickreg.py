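import numpy as np
import pytest

from arcpipe.config import LickRegConfig
from arcpipe.lickreg import (KernelDesign, KernelModel, build_design,
                             detect_bouts, regression_epoch)
from arcpipe.types import EventKind, EventSeries, SpikeTrain


def licks(times):
    return EventSeries(EventKind.LICK, np.asarray(times, dtype=float))


def bouts(times):
    return EventSeries(EventKind.BOUT_ONSET, np.asarray(times, dtype=float))


class TestBoutDetector:
    def test_burst_after_silence_is_one_bout(self):
        t = 20.0 + np.arange(6) * 0.15
        found = detect_bouts(licks(t))
        assert found.n_events == 1
        assert found.times[0] == pytest.approx(20.0)

    def test_three_licks_are_not_a_bout(self):
        found = detect_bouts(licks(20.0 + np.arange(3) * 0.15))
        assert found.n_events == 0

    def test_four_licks_are_a_bout(self):
        found = detect_bouts(licks(20.0 + np.arange(4) * 0.15))
        assert found.n_events == 1

    def test_sub_gap_pause_does_not_split_a_bout(self):
        t = np.concatenate([20.0 + np.arange(4) * 0.15,
                            25.0 + np.arange(4) * 0.15])  # 5-s pause
        found = detect_bouts(licks(t))
        assert found.n_events == 1
        assert found.times[0] == pytest.approx(20.0)

    def test_super_gap_pause_splits_bouts(self):
        t = np.concatenate([20.0 + np.arange(4) * 0.15,
                            40.0 + np.arange(4) * 0.15])
        found = detect_bouts(licks(t))
        assert np.allclose(found.times, [20.0, 40.0])

    def test_first_lick_counts_as_gap_preceded(self):
        found = detect_bouts(licks(0.5 + np.arange(5) * 0.2))
        assert found.n_events == 1

    def test_empty_lick_series(self):
        assert detect_bouts(licks([])).n_events == 0


class TestDesign:
    def test_full_design_has_39_columns(self):
        rng = np.random.default_rng(0)
        design = build_design(licks(np.sort(rng.uniform(5, 895, 400))),
                              bouts(np.sort(rng.uniform(5, 895, 30))),
                              (0, 900))
        assert design.X.shape[1] == 1 + 19 + 19
        assert design.dropped == []

    def test_no_events_leaves_intercept_only(self):
        design = build_design(licks([]), bouts([]), (0, 100))
        assert design.columns == ["offset"]
        assert len(design.dropped) == 38

    def test_isolated_lick_populates_one_entry_per_lag(self):
        design = build_design(licks([100.0]), bouts([]), (0, 200))
        lick_cols = [j for j, c in enumerate(design.columns)
                     if c.startswith("lick@")]
        block = design.X[:, lick_cols]
        assert len(lick_cols) == 19
        assert np.count_nonzero(block) == 19
        assert np.all(block.sum(axis=0) == 1)

    def test_offset_equals_mean_rate_without_events(self, rng):
        design = build_design(licks([]), bouts([]), (0, 500))
        counts = rng.poisson(3.0 * 0.5, design.n_bins)
        res = KernelModel(counts / 0.5, design).fit()
        assert res.offset == pytest.approx(counts.mean() / 0.5)


class TestKernelFit:
    def _design(self, seed=0, span=900.0, n_licks=400, n_bouts=40):
        rng = np.random.default_rng(seed)
        return build_design(
            licks(np.sort(rng.uniform(5, span - 5, n_licks))),
            bouts(np.sort(rng.uniform(5, span - 5, n_bouts))),
            (0, span))

    def test_noise_free_coefficients_recovered_exactly(self):
        design = self._design()
        rng = np.random.default_rng(1)
        true = rng.normal(0, 1, design.X.shape[1])
        true[0] = 4.0
        res = KernelModel(design.X @ true, design).fit()
        est = np.concatenate([[res.offset],
                              res.lick_kernel["coef"].to_numpy(),
                              res.bout_kernel["coef"].to_numpy()])
        assert np.nanmax(np.abs(est - true) / np.abs(true).max()) < 1e-8

    def test_isolated_events_reproduce_event_triggered_average(self):
        # widely separated bouts, no licks, no noise: the fitted bout kernel
        # must equal the event-triggered rate change exactly
        onsets = np.arange(50.0, 1800.0, 60.0)
        design = build_design(licks([]), bouts(onsets), (0, 1800))
        kernel = np.exp(-0.5 * ((np.arange(19) - 10) / 3.0) ** 2) * 3.0
        bout_cols = [j for j, c in enumerate(design.columns)
                     if c.startswith("bout@")]
        y = np.full(design.n_bins, 5.0)
        for j, col in zip(bout_cols, kernel):
            y += design.X[:, j] * col
        res = KernelModel(y, design).fit()
        assert np.allclose(res.bout_kernel["coef"], kernel, atol=1e-10)
        assert res.offset == pytest.approx(5.0)

    def test_significance_thresholds_bonferroni(self):
        res = KernelModel(np.zeros(100) + 1.0,
                          build_design(licks([]), bouts([]), (0, 50))).fit()
        assert res.alpha_corrected == pytest.approx(0.05 / 19)

    def test_shuffled_events_lose_significance(self):
        rng = np.random.default_rng(2)
        design = self._design(seed=2, span=1800.0)
        kernel = np.zeros(19)
        kernel[9:11] = 4.0
        bout_cols = [j for j, c in enumerate(design.columns)
                     if c.startswith("bout@")]
        y = 8.0 + design.X[:, bout_cols] @ kernel + rng.normal(0, 2.0,
                                                               design.n_bins)
        n_sig_true = KernelModel(y, design).fit().n_significant()
        # refit with freshly drawn (shuffled) event times
        shuffled = self._design(seed=99, span=1800.0)
        n_sig_shuf = KernelModel(y, shuffled).fit().n_significant()
        assert n_sig_true >= 2
        assert n_sig_shuf <= 1

    def test_noisy_recovery_rmse_under_20_percent(self):
        # 1800 bins (15 min), 40 bouts, noise SD = half the offset
        offset, peak = 6.0, 3.0
        kernel = peak * np.exp(-0.5 * ((np.arange(19) - 9) / 2.0) ** 2)
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            onsets = np.sort(rng.uniform(5, 895, 40))
            design = build_design(licks([]), bouts(onsets), (0, 900))
            bout_cols = [j for j, c in enumerate(design.columns)
                         if c.startswith("bout@")]
            y = (offset + design.X[:, bout_cols] @ kernel
                 + rng.normal(0, 0.5 * offset, design.n_bins))
            res = KernelModel(y, design).fit()
            errs.append(np.sqrt(np.mean(
                (res.bout_kernel["coef"].to_numpy() - kernel) ** 2)))
        assert np.mean(errs) < 0.2 * peak

    def test_threefold_bout_response_relative_modulation(self):
        # bout response peaking at 3x the offset rate: relative modulation
        # of the peak coefficient is +200%
        offset = 5.0
        onsets = np.arange(50.0, 1800.0, 45.0)
        design = build_design(licks([]), bouts(onsets), (0, 1800))
        kernel = np.zeros(19)
        kernel[9] = 2.0 * offset
        bout_cols = [j for j, c in enumerate(design.columns)
                     if c.startswith("bout@")]
        rng = np.random.default_rng(3)
        y = (offset + design.X[:, bout_cols] @ kernel
             + rng.normal(0, 0.2, design.n_bins))
        res = KernelModel(y, design).fit()
        assert res.relative_modulation("bout") == pytest.approx(2.0,
                                                                abs=0.05)

    def test_rank_deficient_design_rejected(self):
        design = build_design(licks([100.0]), bouts([]), (0, 200))
        design.X = np.column_stack([design.X, design.X[:, 1]])
        design.columns = design.columns + ["dup"]
        with pytest.raises(ValueError, match="rank"):
            KernelModel(np.zeros(design.n_bins), design).fit()


class TestSessionRegression:
    def test_epoch_defaults_to_15_to_45_min_post_food(self):
        t0, t1 = regression_epoch(900.0)
        assert (t0, t1) == (900.0 + 15 * 60, 900.0 + 45 * 60)

    def test_session_inhibited_unit_shows_positive_lick_modulation(
            self, feeding_session, session_events):
        s = feeding_session
        span = regression_epoch(s.timeline.food_time)
        span = (span[0], min(span[1], s.timeline.session_end))
        idx = next(i for i, u in enumerate(s.truth.units)
                   if u.label.value == "ARC_INH")
        model = KernelModel.from_events(
            s.spike_trains[idx], session_events[EventKind.LICK], None, span)
        res = model.fit()
        sig = res.lick_kernel[res.lick_kernel["significant"]]
        assert len(sig) >= 1
        assert sig["coef"].max() > 0
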