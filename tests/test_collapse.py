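"""SNR-collapse operators: baselines, flagging, resampling, windowing, averaging."""

import numpy as np
import pytest

from mvpakit.collapse import (
    CollapseConfig,
    average_trials,
    balance_epochs,
    baseline_correct,
    flag_bad_epochs,
    resample_epochs,
    sliding_window_average,
)
from mvpakit.containers import PAIR_ID_NONE

from conftest import make_epochs


@pytest.fixture()
def gaussian_epochs():
    rng = np.random.default_rng(11)
    return make_epochs(rng.standard_normal((24, 4, 80)))


class TestBaselineCorrect:
    def test_constant_epochs_become_zero(self):
        E = make_epochs(np.full((4, 2, 80), 3.7))
        out = baseline_correct(E, (-0.2, 0.0))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_interval_mean_is_zero_and_post_shifted(self, gaussian_epochs):
        out = baseline_correct(gaussian_epochs, (-0.2, 0.0))
        mask = out.time_mask(-0.2, 0.0)
        assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-12
        pre_mean = gaussian_epochs.data[:, :, mask].mean(axis=2, keepdims=True)
        assert np.allclose(out.data, gaussian_epochs.data - pre_mean)

    def test_idempotent(self, gaussian_epochs):
        once = baseline_correct(gaussian_epochs, (-0.2, 0.0))
        twice = baseline_correct(once, (-0.2, 0.0))
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_empty_interval_errors(self, gaussian_epochs):
        with pytest.raises(ValueError, match="no samples"):
            baseline_correct(gaussian_epochs, (0.551, 0.559))


class TestFlagBadEpochs:
    def test_spike_trial_rejected(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((30, 3, 50))
        data[17, 1, 25] = 50.0
        E = make_epochs(data)
        kept, rejected = flag_bad_epochs(E, threshold=10.0)
        assert list(rejected) == [17]
        assert kept.n_trials == 29
        # survivors keep their pairing metadata
        keep_mask = np.ones(30, bool)
        keep_mask[17] = False
        assert np.array_equal(kept.pair_ids, E.pair_ids[keep_mask])

    def test_infinite_threshold_keeps_all(self, gaussian_epochs):
        kept, rejected = flag_bad_epochs(gaussian_epochs, threshold=np.inf)
        assert rejected.size == 0 and kept.n_trials == gaussian_epochs.n_trials

    def test_threshold_just_below_max_rejects_exactly_one(self, gaussian_epochs):
        E = gaussian_epochs
        mean = E.data.mean(axis=(0, 2), keepdims=True)
        sd = E.data.std(axis=(0, 2), keepdims=True)
        stats = (np.abs((E.data - mean) / sd)).max(axis=(1, 2))
        order = np.sort(stats)
        threshold = (order[-1] + order[-2]) / 2
        kept, rejected = flag_bad_epochs(E, threshold)
        assert len(rejected) == 1 and rejected[0] == stats.argmax()

    def test_all_flagged_errors(self):
        E = make_epochs(np.random.default_rng(1).standard_normal((6, 2, 30)))
        with pytest.raises(ValueError, match="threshold"):
            flag_bad_epochs(E, threshold=1e-6)


class TestResample:
    def test_1000_to_200_hz_sample_count(self):
        E = make_epochs(
            np.random.default_rng(2).standard_normal((4, 2, 1200)), sfreq=1000.0
        )
        out = resample_epochs(E, 200.0)
        assert out.n_times == 240 and out.sfreq == 200.0
        assert np.allclose(np.diff(out.times), 1 / 200.0)

    def test_identity_when_target_equals_native(self, gaussian_epochs):
        out = resample_epochs(gaussian_epochs, gaussian_epochs.sfreq)
        assert np.array_equal(out.data, gaussian_epochs.data)

    def test_passband_preserved_stopband_attenuated(self):
        t = -0.2 + np.arange(1200) / 1000.0
        for freq, check in ((10.0, "pass"), (450.0, "stop")):
            sig = np.sin(2 * np.pi * freq * t)[None, None, :].repeat(2, axis=0)
            E = make_epochs(sig, sfreq=1000.0)
            out = resample_epochs(E, 100.0)
            core = out.data[0, 0, 20:-20]  # avoid edge transients
            amplitude = np.sqrt(2) * core.std()
            if check == "pass":
                assert amplitude == pytest.approx(1.0, abs=0.01)
            else:
                assert amplitude < 0.05

    def test_invalid_targets_error(self, gaussian_epochs):
        with pytest.raises(ValueError):
            resample_epochs(gaussian_epochs, -5.0)
        with pytest.raises(ValueError):
            resample_epochs(gaussian_epochs, 2 * gaussian_epochs.sfreq)


class TestSlidingWindow:
    def test_window_count_formula(self):
        E = make_epochs(
            np.random.default_rng(3).standard_normal((2, 2, 1200)), sfreq=1000.0
        )
        out = sliding_window_average(E, window_len_ms=10, step_fraction=0.6)
        assert out.n_times == 199  # floor((1200 - 10) / 6) + 1

    def test_constant_signal_unchanged(self):
        E = make_epochs(np.full((2, 2, 80), 2.5))
        out = sliding_window_average(E, window_len_ms=50, step_fraction=0.6)
        assert np.allclose(out.data, 2.5, atol=1e-12)

    def test_single_sample_window_is_identity(self, gaussian_epochs):
        out = sliding_window_average(gaussian_epochs, window_len_ms=10, step_fraction=1.0)
        assert np.array_equal(out.data, gaussian_epochs.data)
        assert np.allclose(out.times, gaussian_epochs.times)

    def test_tiling_windows_preserve_time_mean(self, gaussian_epochs):
        out = sliding_window_average(gaussian_epochs, window_len_ms=40, step_fraction=1.0)
        assert np.allclose(
            out.data.mean(axis=2), gaussian_epochs.data.mean(axis=2), atol=1e-12
        )

    def test_window_longer_than_epoch_errors(self, gaussian_epochs):
        with pytest.raises(ValueError, match="longer than the epoch"):
            sliding_window_average(gaussian_epochs, window_len_ms=2000)


class TestAverageTrials:
    def test_group_counts(self):
        E = make_epochs(np.random.default_rng(4).standard_normal((192, 2, 20)))
        out = average_trials(E, group_size=2, seed=0)
        assert out.class_counts() == (48, 48)
        assert (out.pair_ids == PAIR_ID_NONE).all()

    def test_leftovers_dropped(self):
        E = make_epochs(
            np.random.default_rng(5).standard_normal((196, 2, 20)),
            labels=np.repeat([0, 1], 98),
        )
        out = average_trials(E, group_size=6, seed=0)
        assert out.class_counts() == (16, 16)

    def test_pseudo_trial_variance_shrinks_by_group_size(self):
        rng = np.random.default_rng(6)
        E = make_epochs(rng.standard_normal((1600, 1, 10)))
        out = average_trials(E, group_size=4, seed=1)
        assert out.n_trials == 400
        assert out.data.var() == pytest.approx(0.25, rel=0.10)

    def test_group_size_one_is_identity(self, gaussian_epochs):
        out = average_trials(gaussian_epochs, group_size=1, seed=0)
        assert np.array_equal(out.data, gaussian_epochs.data)

    def test_too_few_trials_errors(self):
        E = make_epochs(np.random.default_rng(7).standard_normal((6, 2, 10)))
        with pytest.raises(ValueError, match="group_size"):
            average_trials(E, group_size=5, seed=0)


class TestBalance:
    def test_downsample_to_minority(self):
        labels = np.r_[np.zeros(100, int), np.ones(96, int)]
        E = make_epochs(
            np.random.default_rng(8).standard_normal((196, 2, 10)), labels=labels
        )
        out = balance_epochs(E, seed=0)
        assert out.class_counts() == (96, 96)

    def test_already_balanced_unchanged(self, gaussian_epochs):
        out = balance_epochs(gaussian_epochs, seed=0)
        assert np.array_equal(out.data, gaussian_epochs.data)

    def test_seeded_determinism(self):
        labels = np.r_[np.zeros(30, int), np.ones(20, int)]
        E = make_epochs(
            np.random.default_rng(9).standard_normal((50, 2, 10)), labels=labels
        )
        a = balance_epochs(E, seed=5)
        b = balance_epochs(E, seed=5)
        assert np.array_equal(a.data, b.data)


def test_operators_preserve_channels_and_label_alphabet(gaussian_epochs):
    E = gaussian_epochs
    for out in (
        baseline_correct(E, (-0.2, 0.0)),
        resample_epochs(E, 50.0),
        sliding_window_average(E, 30, 0.6),
        average_trials(E, 2, seed=0),
        balance_epochs(E, seed=0),
    ):
        assert out.n_channels == E.n_channels
        assert set(np.unique(out.labels)) <= {0, 1}


def test_collapse_config_validation():
    CollapseConfig().validate(1000.0)
    with pytest.raises(ValueError, match="window_step_fraction"):
        CollapseConfig(window_step_fraction=0.0).validate()
    with pytest.raises(ValueError, match="avg_group_size"):
        CollapseConfig(avg_group_size=0).validate()
    with pytest.raises(ValueError, match="resample_hz"):
        CollapseConfig(resample_hz=500.0).validate(sfreq=100.0)
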