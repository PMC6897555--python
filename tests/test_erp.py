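"""ERP operators: baseline, artifact rejection, averaging, window means."""

import numpy as np
import pytest

from cplearn.erp import (
    ComponentWindow,
    ERP,
    SubjectExcluded,
    baseline_correct,
    component_mean,
    difference_wave,
    reject_extreme,
    reject_probability,
    split_and_average,
)


class TestBaseline:
    def test_constant_offset_removed(self, epochs_factory):
        ep = epochs_factory(np.full((3, 100, 5), 5.0))
        out = baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_idempotent_on_zero_baseline(self, epochs_factory):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 100, 5))
        i0, i1 = 30, 50  # [-0.2, 0) s at 100 Hz with tmin=-0.5
        data[:, i0:i1, :] -= data[:, i0:i1, :].mean(axis=1, keepdims=True)
        ep = epochs_factory(data, tmin=-0.5)
        out = baseline_correct(ep)
        assert np.allclose(out.data, ep.data)

    def test_baseline_means_vanish(self, epochs_factory):
        rng = np.random.default_rng(1)
        ep = epochs_factory(rng.normal(3, 10, size=(4, 200, 12)))
        out = baseline_correct(ep)
        i0, i1 = out.sample_range(-0.2, 0.0)
        assert np.abs(out.data[:, i0:i1, :].mean(axis=1)).max() < 1e-9

    def test_window_outside_epoch_rejected(self, epochs_factory):
        ep = epochs_factory(np.zeros((1, 100, 2)))
        with pytest.raises(ValueError):
            baseline_correct(ep, window=(-2.0, 0.0))


class TestRejectExtreme:
    def test_constructed_spike_caught(self, epochs_factory):
        data = np.random.default_rng(2).normal(0, 5, size=(3, 50, 10))
        data[1, 20, 4] = 150.0
        ep = epochs_factory(data)
        kept, rejected = reject_extreme(ep)
        assert list(rejected) == [4]
        assert kept.n_trials == 9

    def test_clean_data_untouched(self, epochs_factory):
        ep = epochs_factory(np.random.default_rng(3).uniform(-50, 50, (3, 50, 10)))
        kept, rejected = reject_extreme(ep)
        assert rejected.size == 0 and kept.n_trials == 10

    def test_matches_exhaustive_scan(self, epochs_factory):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 30, size=(4, 80, 30))
        ep = epochs_factory(data)
        _, rejected = reject_extreme(ep, limit=100.0)
        brute = [
            tr for tr in range(30) if np.abs(data[:, :, tr]).max() > 100.0
        ]
        assert list(rejected) == brute
        assert len(brute) > 0  # the fixture must actually exercise rejection

    def test_all_rejected_signals_unusable(self, epochs_factory):
        ep = epochs_factory(np.full((2, 50, 5), 200.0))
        with pytest.raises(ValueError):
            reject_extreme(ep)


class TestRejectProbability:
    def test_infinite_limits_reject_nothing(self, epochs_factory):
        ep = epochs_factory(np.random.default_rng(5).normal(size=(3, 50, 20)))
        kept, rejected = reject_probability(ep, single_sd=np.inf, global_sd=np.inf)
        assert rejected.size == 0 and kept.n_trials == 20

    def test_high_variance_outlier_trial_rejected(self, epochs_factory):
        rng = np.random.default_rng(6)
        data = rng.normal(0, 1, size=(5, 100, 40))
        data[:, :, 13] = rng.normal(0, 10, size=(5, 100))
        _, rejected = reject_probability(epochs_factory(data))
        assert 13 in rejected

    def test_homogeneous_gaussian_rejection_stays_low(self, epochs_factory):
        # the filter's own null: clean trials should stay under the 10% regime
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ep = epochs_factory(rng.normal(0, 10, size=(10, 200, 200)))
            _, rejected = reject_probability(ep)
            rates.append(rejected.size / 200)
        assert np.mean(rates) < 0.10

    def test_too_few_trials_rejected(self, epochs_factory):
        ep = epochs_factory(np.random.default_rng(8).normal(size=(2, 50, 5)))
        with pytest.raises(ValueError):
            reject_probability(ep)

    def test_filter_composition_order(self, epochs_factory):
        # extreme first, then probability: composing on a fixture reproduces
        # the union of the documented rejected sets
        rng = np.random.default_rng(9)
        data = rng.normal(0, 5, size=(4, 100, 50))
        data[0, 10, 7] = 400.0          # extreme-value artifact
        # distributional outlier that stays under the ±100 µV extreme cut
        data[:, :, 21] = rng.normal(0, 20, size=(4, 100))
        ep = epochs_factory(data)
        ep1, rej_ext = reject_extreme(ep)
        ep2, rej_prob = reject_probability(ep1)
        assert 7 in rej_ext
        surviving = ep1.metadata["trial"].to_numpy()
        assert 22 in surviving[rej_prob]  # trial numbers are 1-based
        assert 22 not in ep2.metadata["trial"].to_numpy()


class TestSplitAndAverage:
    def test_identical_trials_average_to_themselves(self, epochs_factory):
        wave = np.random.default_rng(10).normal(size=(3, 60))
        data = np.repeat(wave[:, :, None], 8, axis=2)
        ep = epochs_factory(data)
        before, after = split_and_average(ep, [1, 2, 3, 4], [5, 6, 7, 8])
        assert np.allclose(before.data, wave)
        assert np.allclose(after.data, wave)

    def test_noise_shrinks_like_root_n(self, epochs_factory):
        rng = np.random.default_rng(11)
        template = np.sin(np.linspace(0, 4 * np.pi, 100))[None, :]
        errs = {}
        for n in (20, 180):
            data = template[:, :, None] + rng.normal(0, 1, size=(1, 100, 2 * n))
            ep = epochs_factory(data)
            b, a = split_and_average(ep, np.arange(1, n + 1), np.arange(n + 1, 2 * n + 1))
            errs[n] = np.sqrt(((b.data - template) ** 2).mean())
        assert errs[180] < errs[20] / 2  # expected 1/3 ratio, with slack

    def test_excess_rejection_flags_subject(self, epochs_factory):
        ep = epochs_factory(np.zeros((2, 50, 30)))
        # pretend 100 trials were scheduled per condition: >20% lost
        with pytest.raises(SubjectExcluded):
            split_and_average(
                ep, np.arange(1, 16), np.arange(16, 31), n_scheduled=(100, 100)
            )

    def test_overlapping_sets_rejected(self, epochs_factory):
        ep = epochs_factory(np.zeros((2, 50, 10)))
        with pytest.raises(ValueError):
            split_and_average(ep, [1, 2, 3], [3, 4, 5])


def make_erp(data, sfreq=100.0, tmin=-0.5, ch_names=None):
    n_ch = data.shape[0]
    if ch_names is None:
        ch_names = tuple(f"C{i}" for i in range(n_ch))
    return ERP(data=np.asarray(data, float), ch_names=ch_names, sfreq=sfreq, tmin=tmin)


class TestComponentMean:
    def test_flat_waveform(self):
        erp = make_erp(np.ones((4, 100)))
        cw = ComponentWindow("X", (100.0, 300.0), ("C0", "C2"))
        assert component_mean(erp, cw).mean_voltage == pytest.approx(1.0)

    def test_linearity(self):
        rng = np.random.default_rng(12)
        x = make_erp(rng.normal(size=(4, 100)))
        y = make_erp(rng.normal(size=(4, 100)))
        cw = ComponentWindow("X", (0.0, 400.0), ("C1", "C3"))
        a, b = 2.5, -1.25
        combo = make_erp(a * x.data + b * y.data)
        lhs = component_mean(combo, cw).mean_voltage
        rhs = a * component_mean(x, cw).mean_voltage + b * component_mean(y, cw).mean_voltage
        assert lhs == pytest.approx(rhs)

    def test_matches_manual_slice(self):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(3, 200))
        erp = make_erp(data)  # 100 Hz, tmin -0.5
        cw = ComponentWindow("X", (150.0, 220.0), ("C0", "C1"))
        got = component_mean(erp, cw).mean_voltage
        # [150, 220) ms at 100 Hz from tmin -500 ms -> samples 65..71
        assert got == pytest.approx(data[[0, 1], 65:72].mean())

    def test_unknown_channel_rejected(self):
        erp = make_erp(np.zeros((2, 50)))
        cw = ComponentWindow("X", (0.0, 100.0), ("Oz",))
        with pytest.raises(ValueError):
            component_mean(erp, cw)


def test_hdf5_roundtrip(epochs_factory, tmp_path):
    from cplearn.erp import EpochArray

    rng = np.random.default_rng(17)
    ep = epochs_factory(rng.normal(size=(3, 50, 6)), ch_names=("Oz", "Pz", "Fz"))
    path = tmp_path / "ep.h5"
    ep.to_hdf5(path)
    back = EpochArray.from_hdf5(path)
    assert np.array_equal(back.data, ep.data)
    assert back.ch_names == ep.ch_names
    assert back.sfreq == ep.sfreq and back.tmin == ep.tmin
    assert back.metadata["trial"].tolist() == ep.metadata["trial"].tolist()


class TestDifferenceWave:
    def test_self_difference_is_zero(self):
        erp = make_erp(np.random.default_rng(14).normal(size=(3, 50)))
        assert np.allclose(difference_wave(erp, erp).data, 0.0)

    def test_zero_baseline_returns_after(self):
        after = make_erp(np.random.default_rng(15).normal(size=(3, 50)))
        zero = make_erp(np.zeros((3, 50)))
        assert np.allclose(difference_wave(after, zero).data, after.data)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(16)
        a = make_erp(rng.normal(size=(3, 50)))
        b = make_erp(rng.normal(size=(3, 50)))
        assert np.allclose(difference_wave(a, b).data, a.data - b.data)

    def test_shape_mismatch_rejected(self):
        a = make_erp(np.zeros((3, 50)))
        b = make_erp(np.zeros((3, 60)))
        with pytest.raises(ValueError):
            difference_wave(a, b)
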