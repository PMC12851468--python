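"""Stimulus-locked high-gamma envelopes, epochs, and responsive channels.

The high-gamma power (HGP) proxy for local population firing is the
amplitude envelope of the 70-170 Hz band: the signal is band-pass filtered
with a zero-phase 4th-order Butterworth filter (forward-backward, reflective
padding) and the envelope is the magnitude of its Hilbert analytic signal.

Window convention: every time window ``(t0, t1)`` is half-open ``[t0, t1)``
on the sample grid, and the sample at t = 0 is the stimulus-onset sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.stats import ttest_rel

from .synthdata import Recording

DEFAULT_BAND = (70.0, 170.0)
DEFAULT_EPOCH_WINDOW = (-0.5, 1.5)
DEFAULT_RESPONSE_WINDOW = (0.1, 0.6)
DEFAULT_BASELINE_WINDOW = (-0.5, 0.0)


@dataclass
class EpochSet:
    """Trial x channel x time envelope array, time relative to onset."""

    envelope: np.ndarray
    time: np.ndarray
    trial_stimulus: np.ndarray
    fs: float
    channel_id: list[str]

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.trial_stimulus = np.asarray(self.trial_stimulus)
        if self.envelope.ndim != 3:
            raise ValueError("envelope must be trial x channel x time")
        if self.envelope.shape[2] != len(self.time):
            raise ValueError("time axis mismatch")
        if self.envelope.shape[0] != len(self.trial_stimulus):
            raise ValueError("trial mapping mismatch")
        if self.envelope.shape[1] != len(self.channel_id):
            raise ValueError("channel id mismatch")

    @property
    def n_trials(self) -> int:
        return self.envelope.shape[0]

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples with ``window[0] <= t < window[1]``."""
        eps = 1e-9
        return (self.time >= window[0] - eps) & (self.time < window[1] - eps)


@dataclass
class ResponseMatrix:
    """Mean response per stimulus per channel within a fixed window."""

    values: np.ndarray
    stimulus_id: list[str]
    channel_id: list[str]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.stimulus_id), len(self.channel_id)):
            raise ValueError("values shape must be (n_stimuli, n_channels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.stimulus_id,
                            columns=self.channel_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW
                   ) -> "ResponseMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), window)

    def subset(self, channels: list[str]) -> "ResponseMatrix":
        idx = [self.channel_id.index(c) for c in channels]
        return ResponseMatrix(self.values[:, idx], list(self.stimulus_id),
                              list(channels), self.window)


def extract_hgp(recording: Recording | np.ndarray, fs: float | None = None,
                band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Continuous high-gamma envelope per channel (zero-phase filtering)."""
    if isinstance(recording, Recording):
        signal, fs = recording.signal, recording.fs
    else:
        signal = np.atleast_2d(np.asarray(recording, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a raw array")
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, fs/2)")
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, signal, axis=-1)
    return np.abs(hilbert(filtered, axis=-1))


def epoch(envelope: np.ndarray, fs: float, events: pd.DataFrame,
          window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
          channel_id: list[str] | None = None) -> EpochSet:
    """Cut a continuous envelope into stimulus-locked epochs.

    The epoch covers ``[window[0], window[1])``; the sample nearest each
    event onset is the t = 0 sample.
    """
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    n_ch, n_samples = envelope.shape
    if channel_id is None:
        channel_id = [f"ch{i:03d}" for i in range(n_ch)]
    off0 = int(round(window[0] * fs))
    n_win = int(round((window[1] - window[0]) * fs))
    time = (np.arange(n_win) + off0) / fs
    onsets = events["onset"].to_numpy(dtype=float)
    starts = np.round(onsets * fs).astype(int) + off0
    bad = [int(i) for i, s in enumerate(starts)
           if s < 0 or s + n_win > n_samples]
    if bad:
        raise ValueError(f"epoch window out of recording range for trials {bad}")
    out = np.empty((len(starts), n_ch, n_win))
    for t, s in enumerate(starts):
        out[t] = envelope[:, s:s + n_win]
    return EpochSet(envelope=out, time=time,
                    trial_stimulus=events["stimulus_id"].to_numpy(),
                    fs=fs, channel_id=list(channel_id))


def mean_response(epochs: EpochSet,
                  window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW,
                  stimulus_order: list[str] | None = None) -> ResponseMatrix:
    """Mean envelope in ``window`` per stimulus (repeats averaged) per channel."""
    mask = epochs.window_mask(window)
    if not mask.any():
        raise ValueError(f"window {window} outside epoch span")
    trial_means = epochs.envelope[:, :, mask].mean(axis=2)
    stims = epochs.trial_stimulus.astype(str)
    if stimulus_order is None:
        stimulus_order = sorted(set(stims))
    values = np.empty((len(stimulus_order), trial_means.shape[1]))
    for i, s in enumerate(stimulus_order):
        sel = stims == s
        if not sel.any():
            raise ValueError(f"stimulus {s!r} has no trials")
        values[i] = trial_means[sel].mean(axis=0)
    return ResponseMatrix(values, list(stimulus_order), list(epochs.channel_id),
                          tuple(window))


def select_responsive(epochs: EpochSet,
                      response_window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW,
                      baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided paired t-test across trials of response vs baseline means.

    A channel is visually responsive when its per-trial mean envelope in the
    response window differs from the baseline-window mean at ``p < alpha``.
    Zero-variance trial differences yield p = 1 (never flagged).  No
    multiple-comparison correction is applied at this screening stage.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    resp = epochs.envelope[:, :, epochs.window_mask(response_window)].mean(axis=2)
    base = epochs.envelope[:, :, epochs.window_mask(baseline_window)].mean(axis=2)
    pvals = np.empty(resp.shape[1])
    for c in range(resp.shape[1]):
        diff = resp[:, c] - base[:, c]
        if np.allclose(diff, diff[0]):
            pvals[c] = 1.0
        else:
            pvals[c] = ttest_rel(resp[:, c], base[:, c]).pvalue
    return pd.DataFrame({"channel_id": epochs.channel_id, "p": pvals,
                         "responsive": pvals < alpha})


def bin_timecourse(epochs: EpochSet, width_s: float, step_s: float) -> EpochSet:
    """Sliding-window means: bin value = mean over ``[c - w/2, c + w/2)``.

    Centers start at the earliest center fully inside the epoch and advance
    by ``step_s``; the returned :class:`EpochSet` carries the bin centers as
    its time axis and ``1/step_s`` as its sampling rate.
    """
    if step_s <= 0:
        raise ValueError("step must be positive")
    span = epochs.envelope.shape[2] / epochs.fs
    if width_s > span + 1e-9:
        raise ValueError("bin width exceeds epoch span")
    n_bins = int(np.floor((span - width_s) / step_s + 1 + 1e-9))
    t0 = epochs.time[0]
    centers = t0 + width_s / 2 + step_s * np.arange(n_bins)
    binned = np.empty(epochs.envelope.shape[:2] + (n_bins,))
    for b, c in enumerate(centers):
        mask = epochs.window_mask((c - width_s / 2, c + width_s / 2))
        binned[:, :, b] = epochs.envelope[:, :, mask].mean(axis=2)
    return EpochSet(envelope=binned, time=centers,
                    trial_stimulus=epochs.trial_stimulus.copy(),
                    fs=1.0 / step_s, channel_id=list(epochs.channel_id))


def normalize_hgp(epochs: EpochSet,
                  baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
                  ) -> EpochSet:
    """Z-score each channel against its trial-pooled baseline statistics."""
    mask = epochs.window_mask(baseline_window)
    if not mask.any():
        raise ValueError("baseline window outside epoch span")
    base = epochs.envelope[:, :, mask]  # trials x ch x t
    mu = base.mean(axis=(0, 2))
    sd = base.std(axis=(0, 2))
    for c, s in enumerate(sd):
        if s == 0:
            raise ValueError(
                f"zero baseline variance in channel {epochs.channel_id[c]!r}")
    z = (epochs.envelope - mu[None, :, None]) / sd[None, :, None]
    return EpochSet(envelope=z, time=epochs.time.copy(),
                    trial_stimulus=epochs.trial_stimulus.copy(),
                    fs=epochs.fs, channel_id=list(epochs.channel_id))
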