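"""Phase categorization, firing statistics and correlograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pallidalnet.analysis import (
    LABELS,
    categorize,
    correlogram,
    firing_stats,
    group_summary,
    phase_histogram,
    phase_vector,
)
from pallidalnet.spiketrain import SpikeTrain
from pallidalnet.stn import SWAProtocol, swa_phase

PROTO = SWAProtocol.healthy()


def train_of(times, t0=0.0, t1=13000.0, unit=0):
    return SpikeTrain(unit, np.asarray(times, dtype=float), t0, t1)


class TestPhaseVector:
    def test_identical_phases_give_full_confidence(self):
        times = 200.0 + 1300.0 * np.arange(10)  # one spike per cycle, same phase
        vec = phase_vector(train_of(times), PROTO)
        assert vec.confidence == pytest.approx(1.0)
        assert vec.mean_phase == pytest.approx(swa_phase(200.0, PROTO))

    def test_antipodal_spikes_cancel(self):
        times = np.sort(np.concatenate([
            100.0 + 1300.0 * np.arange(10),
            750.0 + 1300.0 * np.arange(10),  # 650 ms = half a cycle later
        ]))
        vec = phase_vector(train_of(times), PROTO)
        assert vec.confidence == pytest.approx(0.0, abs=1e-12)

    def test_empty_train_flagged(self):
        vec = phase_vector(train_of([]), PROTO)
        assert vec.confidence == 0.0
        assert np.isnan(vec.mean_phase)

    @settings(derandomize=True, max_examples=40)
    @given(
        offset=st.floats(0.0, 1300.0),
        n=st.integers(5, 60),
        seed=st.integers(0, 1000),
    )
    def test_confidence_invariant_under_phase_rotation(self, offset, n, seed):
        """Shifting every spike by the same offset rotates the mean
        phase but leaves the confidence unchanged."""
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0.0, 10000.0, n))
        times = times[np.concatenate([[True], np.diff(times) > 1e-6])]
        a = phase_vector(train_of(times, t1=20000.0), PROTO)
        b = phase_vector(train_of(times + offset, t1=21400.0), PROTO)
        assert b.confidence == pytest.approx(a.confidence, abs=1e-9)
        expected = (a.mean_phase + swa_phase(offset, PROTO)) % (2 * np.pi)
        if a.confidence > 1e-6:
            assert b.mean_phase == pytest.approx(expected, abs=1e-6) or \
                abs(b.mean_phase - expected) == pytest.approx(2 * np.pi, abs=1e-6)


class TestCategorization:
    def test_quiet_rule_precedes_confidence(self):
        """Nine perfectly phase-locked spikes over ten cycles are QU:
        fewer than one spike per SWA cycle."""
        times = 200.0 + 1300.0 * np.arange(9)
        report = categorize(train_of(times, t1=13000.0), PROTO, window=(0.0, 13000.0))
        assert report.label == "QU"
        assert report.phase.confidence == pytest.approx(1.0)

    def test_uniform_spikes_are_nm(self):
        times = np.arange(50.0, 13000.0, 65.0)  # uniform over the cycle
        report = categorize(train_of(times), PROTO, window=(0.0, 13000.0))
        assert report.label == "NM"
        assert report.phase.confidence < 0.1

    def test_active_phase_firing_is_ta(self):
        times = np.sort(np.concatenate(
            [250.0 + 1300.0 * k + np.arange(0, 200, 50) for k in range(10)]
        ))
        report = categorize(train_of(times), PROTO, window=(0.0, 13000.0))
        assert report.label == "TA"

    def test_inactive_phase_firing_is_ti(self):
        times = np.sort(np.concatenate(
            [800.0 + 1300.0 * k + np.arange(0, 300, 60) for k in range(10)]
        ))
        report = categorize(train_of(times), PROTO, window=(0.0, 13000.0))
        assert report.label == "TI"

    def test_default_window_is_latter_half(self):
        early = 100.0 + 65.0 * np.arange(50)  # all spikes in the first half
        report = categorize(train_of(early), PROTO)
        assert report.label == "QU"

    def test_every_neuron_gets_exactly_one_label(self, healthy_battery):
        _, batteries = healthy_battery
        for reports in batteries:
            assert len(reports) == 100
            for r in reports:
                assert r.label in LABELS


class TestFiringStats:
    def test_periodic_train_has_zero_cv(self):
        rate, cv = firing_stats(train_of(np.arange(0.0, 13000.0, 100.0)))
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_rate_is_count_over_window(self):
        times = np.linspace(10.0, 12990.0, 130)
        rate, _ = firing_stats(train_of(times))
        assert rate == pytest.approx(10.0)

    def test_poisson_train_cv_near_one(self):
        rng = np.random.default_rng(4)
        times = np.cumsum(rng.exponential(50.0, 4000))
        train = SpikeTrain(0, times, 0.0, times[-1] + 1.0)
        _, cv = firing_stats(train)
        assert cv == pytest.approx(1.0, abs=0.07)

    def test_too_few_spikes_flagged_not_zero(self):
        _, cv = firing_stats(train_of([100.0, 200.0]))
        assert np.isnan(cv)


class TestCorrelogram:
    def brute_force(self, a, b, bin_width, n_bins, auto=False):
        half = 0.5 * n_bins * bin_width
        edges = np.linspace(-half, half, n_bins + 1)
        counts = np.zeros(n_bins)
        for i, ta in enumerate(a.times):
            for j, tb in enumerate(b.times):
                if auto and i == j:
                    continue
                lag = tb - ta
                if -half <= lag < half:
                    counts[int((lag + half) // bin_width)] += 1
        return counts

    def test_matches_exhaustive_enumeration(self):
        """For small trains the windowed histogram must equal the
        all-pairs enumeration exactly."""
        rng = np.random.default_rng(11)
        a = SpikeTrain(0, np.sort(rng.uniform(0, 5000, 40)), 0.0, 5000.0)
        b = SpikeTrain(1, np.sort(rng.uniform(0, 5000, 50)), 0.0, 5000.0)
        cg = correlogram(a, b, bin_width=20.0, n_bins=30)
        np.testing.assert_array_equal(cg.raw_counts, self.brute_force(a, b, 20.0, 30))

    def test_auto_excludes_zero_lag_pairs(self):
        rng = np.random.default_rng(12)
        a = SpikeTrain(0, np.sort(rng.uniform(0, 5000, 45)), 0.0, 5000.0)
        cg = correlogram(a, a, bin_width=10.0, n_bins=20)
        np.testing.assert_array_equal(
            cg.raw_counts, self.brute_force(a, a, 10.0, 20, auto=True)
        )

    def test_independent_poisson_trains_flat_at_one(self):
        """Brillinger normalization: independent stationary Poisson
        trains give bins near 1, mostly inside the 95% band."""
        rng = np.random.default_rng(13)
        t = 150_000.0
        ta = np.cumsum(rng.exponential(50.0, 3500))
        tb = np.cumsum(rng.exponential(50.0, 3500))
        a = SpikeTrain(0, ta[ta < t], 0.0, t)
        b = SpikeTrain(1, tb[tb < t], 0.0, t)
        cg = correlogram(a, b, bin_width=3.0, n_bins=30)
        assert cg.counts.mean() == pytest.approx(1.0, abs=0.1)
        inside = (cg.counts >= cg.ci_low) & (cg.counts <= cg.ci_high)
        assert inside.mean() >= 0.9

    def test_shifted_copy_peaks_at_shift(self):
        rng = np.random.default_rng(14)
        times = np.sort(rng.uniform(0, 20000, 300))
        a = SpikeTrain(0, times, 0.0, 21000.0)
        b = SpikeTrain(1, times + 42.0, 0.0, 21100.0)
        cg = correlogram(a, b, bin_width=10.0, n_bins=20)
        assert cg.lags[np.argmax(cg.counts)] == pytest.approx(45.0, abs=5.0)

    def test_time_rescaling_leaves_normalization_invariant(self):
        """Scaling both trains and the interval by a common factor
        rescales lags but not normalized counts."""
        rng = np.random.default_rng(15)
        times = np.sort(rng.uniform(0, 10000, 200))
        other = np.sort(rng.uniform(0, 10000, 250))
        a1 = SpikeTrain(0, times, 0.0, 10000.0)
        b1 = SpikeTrain(1, other, 0.0, 10000.0)
        a2 = SpikeTrain(0, 2 * times, 0.0, 20000.0)
        b2 = SpikeTrain(1, 2 * other, 0.0, 20000.0)
        c1 = correlogram(a1, b1, bin_width=10.0, n_bins=20)
        c2 = correlogram(a2, b2, bin_width=20.0, n_bins=20)
        np.testing.assert_allclose(c1.counts, c2.counts, rtol=1e-12)

    def test_empty_train_rejected(self):
        a = train_of([100.0])
        with pytest.raises(ValueError):
            correlogram(a, train_of([]), 10.0, 10)


class TestGroupOutputs:
    def test_phase_histogram_conserves_spikes(self):
        trains = [
            train_of(250.0 + 1300.0 * np.arange(10), unit=0),
            train_of(300.0 + 1300.0 * np.arange(10), unit=1),
        ]
        reports = [categorize(t, PROTO, window=(0.0, 13000.0)) for t in trains]
        edges, counts, mean_phase, conf = phase_histogram(
            reports, trains, PROTO, "TA"
        )
        assert counts.sum() == sum(len(t) for t in trains)
        assert 0.0 <= mean_phase < 2 * np.pi
        assert conf == pytest.approx(1.0)

    def test_phase_histogram_missing_label_rejected(self):
        trains = [train_of(250.0 + 1300.0 * np.arange(10))]
        reports = [categorize(trains[0], PROTO, window=(0.0, 13000.0))]
        with pytest.raises(ValueError):
            phase_histogram(reports, trains, PROTO, "QU")

    def test_single_trial_summary_flags_sd(self):
        trains = [train_of(250.0 + 1300.0 * np.arange(10))]
        reports = [categorize(trains[0], PROTO, window=(0.0, 13000.0))]
        summary = group_summary([reports])
        assert np.isnan(summary["TA"]["count_sd"])
        assert summary["TA"]["count_mean"] == 1.0
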