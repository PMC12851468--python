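"""High-gamma envelope, epoching, binning, and responsive-channel screening."""

import numpy as np
import pandas as pd
import pytest

from neurorsa.signal import (EpochSet, bin_timecourse, epoch, extract_hgp,
                             mean_response, normalize_hgp, select_responsive)

FS = 1000.0


def _epochs_from_array(env, fs=FS, t0=-0.5, stimuli=None):
    n_tr, n_ch, n_s = env.shape
    time = np.arange(n_s) / fs + t0
    if stimuli is None:
        stimuli = [f"s{i}" for i in range(n_tr)]
    return EpochSet(envelope=env, time=time, trial_stimulus=np.array(stimuli),
                    fs=fs, channel_id=[f"c{i}" for i in range(n_ch)])


class TestExtractHgp:
    def test_inband_tone_envelope(self):
        t = np.arange(0, 4, 1 / FS)
        sig = 2.0 * np.sin(2 * np.pi * 100 * t)
        env = extract_hgp(sig, fs=FS)[0]
        core = env[1000:-1000]
        assert np.all(np.abs(core - 2.0) < 0.1)

    def test_out_of_band_rejected(self):
        t = np.arange(0, 4, 1 / FS)
        sig = np.sin(2 * np.pi * 10 * t)
        env = extract_hgp(sig, fs=FS)[0]
        assert env[1000:-1000].max() < 0.05

    def test_am_envelope_recovery(self):
        t = np.arange(0, 6, 1 / FS)
        slow = 1.5 + np.sin(2 * np.pi * 1.3 * t)
        sig = slow * np.sin(2 * np.pi * 120 * t)
        env = extract_hgp(sig, fs=FS)[0]
        r = np.corrcoef(env[1000:-1000], slow[1000:-1000])[0, 1]
        assert r > 0.99

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            extract_hgp(np.zeros(1000), fs=300.0, band=(70, 170))


class TestEpoch:
    def _events(self, onsets):
        return pd.DataFrame({"onset": onsets, "duration": 1.0,
                             "stimulus_id": [f"s{i}" for i in
                                             range(len(onsets))]})

    def test_sample_count_convention(self):
        env = np.random.default_rng(0).random((1, 6000))
        ep = epoch(env, FS, self._events([2.0]), window=(-0.5, 1.5))
        assert ep.envelope.shape == (1, 1, 2000)
        assert ep.time[0] == pytest.approx(-0.5)
        assert np.any(ep.time == 0.0)  # onset sample included

    def test_constant_envelope(self):
        env = np.full((2, 5000), 3.25)
        ep = epoch(env, FS, self._events([1.0, 2.5]))
        assert np.all(ep.envelope == 3.25)

    def test_permutation_equivariance(self):
        env = np.random.default_rng(1).random((1, 9000))
        ev = self._events([1.0, 3.0, 5.0])
        a = epoch(env, FS, ev)
        shuffled = ev.iloc[[2, 0, 1]].reset_index(drop=True)
        shuffled = shuffled.sort_values("onset").reset_index(drop=True)
        b = epoch(env, FS, shuffled)
        # same onsets, same epochs regardless of construction order
        assert np.allclose(a.envelope, b.envelope)

    def test_out_of_range_event_lists_trial(self):
        env = np.zeros((1, 3000))
        with pytest.raises(ValueError, match=r"trials \[1\]"):
            epoch(env, FS, self._events([1.0, 2.9]))


class TestMeanResponse:
    def test_constant_window(self):
        env = np.full((3, 2, 2000), 5.0)
        ep = _epochs_from_array(env)
        rm = mean_response(ep, window=(0.1, 0.6))
        assert np.all(rm.values == 5.0)

    def test_repeat_averaging(self):
        env = np.zeros((2, 1, 2000))
        env[0] += 2.0
        env[1] += 4.0
        ep = _epochs_from_array(env, stimuli=["a", "a"])
        rm = mean_response(ep)
        assert rm.values[0, 0] == pytest.approx(3.0)

    def test_window_outside_epoch_raises(self):
        ep = _epochs_from_array(np.zeros((2, 1, 2000)))
        with pytest.raises(ValueError):
            mean_response(ep, window=(2.0, 3.0))

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(2)
        env = rng.random((6, 2, 2000))
        stims = ["a", "b", "c", "a", "b", "c"]
        ep1 = _epochs_from_array(env, stimuli=stims)
        order = [3, 1, 5, 0, 4, 2]
        ep2 = _epochs_from_array(env[order],
                                 stimuli=[stims[i] for i in order])
        assert np.allclose(mean_response(ep1).values,
                           mean_response(ep2).values)


class TestSelectResponsive:
    def test_strong_channel_flagged_null_channels_calibrated(self):
        rng = np.random.default_rng(3)
        n_tr, n_null = 60, 120
        env = rng.standard_normal((n_tr, n_null + 1, 2000)) + 10.0
        # channel 0: add response in (0.1, 0.6) s
        env[:, 0, 600:1100] += 2.0
        ep = _epochs_from_array(env)
        res = select_responsive(ep)
        assert bool(res.loc[0, "responsive"])
        fp = res["responsive"].iloc[1:].mean()
        assert 0.0 <= fp <= 0.12  # ~alpha with MC noise at 120 channels

    def test_degenerate_channel_not_flagged(self):
        env = np.ones((5, 1, 2000))
        res = select_responsive(_epochs_from_array(env))
        assert res.loc[0, "p"] == 1.0
        assert not res.loc[0, "responsive"]

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            select_responsive(_epochs_from_array(np.zeros((1, 1, 2000))))


class TestBinTimecourse:
    def test_bin_count_convention(self):
        ep = _epochs_from_array(np.zeros((1, 1, 2000)))
        binned = bin_timecourse(ep, 0.3, 0.02)
        assert binned.envelope.shape[2] == 86
        assert binned.time[0] == pytest.approx(-0.5 + 0.15)

    def test_constant_preserved(self):
        ep = _epochs_from_array(np.full((2, 1, 2000), 7.0))
        binned = bin_timecourse(ep, 0.3, 0.02)
        assert np.allclose(binned.envelope, 7.0)

    def test_linear_ramp_gives_center_values(self):
        ep = _epochs_from_array(np.tile(np.linspace(0, 1, 2000),
                                        (1, 1, 1)))
        binned = bin_timecourse(ep, 0.2, 0.1)
        ramp_at = np.interp(binned.time, ep.time, ep.envelope[0, 0])
        # mean of a linear ramp over a window = value at its midpoint
        assert np.allclose(binned.envelope[0, 0], ramp_at, atol=1e-3)

    def test_width_equals_step_matches_block_means(self):
        rng = np.random.default_rng(4)
        env = rng.random((2, 2, 2000))
        ep = _epochs_from_array(env)
        binned = bin_timecourse(ep, 0.1, 0.1)
        blocks = env.reshape(2, 2, 20, 100).mean(axis=3)
        assert np.allclose(binned.envelope, blocks)

    def test_width_larger_than_span_rejected(self):
        with pytest.raises(ValueError):
            bin_timecourse(_epochs_from_array(np.zeros((1, 1, 100))), 1.0, 0.1)


class TestNormalizeHgp:
    def test_baseline_statistics(self):
        rng = np.random.default_rng(5)
        env = 3.0 + 2.0 * rng.standard_normal((20, 2, 2000))
        z = normalize_hgp(_epochs_from_array(env))
        base = z.envelope[:, :, z.window_mask((-0.5, 0.0))]
        assert abs(base.mean()) < 1e-10
        assert abs(base.std() - 1.0) < 1e-10

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        env = rng.random((5, 1, 2000))
        a = normalize_hgp(_epochs_from_array(env))
        b = normalize_hgp(_epochs_from_array(4.0 * env + 2.0))
        assert np.allclose(a.envelope, b.envelope)

    def test_constant_channel_raises(self):
        env = np.ones((5, 1, 2000))
        with pytest.raises(ValueError, match="c0"):
            normalize_hgp(_epochs_from_array(env))
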