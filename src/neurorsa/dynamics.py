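"""Population state-space dynamics for high- vs low-memorability stimuli.

Condition-averaged multichannel envelope time courses are projected onto
leading principal components ("state space"); the divergence between two
condition trajectories is summarised as the time-summed Euclidean distance
in the retained components, with a stimulus-label permutation null in which
the PCA is refit inside every permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import EpochSet
from .synthdata import StimulusSet


@dataclass
class Trajectory:
    """Per-condition PCA score time courses."""

    conditions: list[str]
    coords: np.ndarray  # condition x bin x component
    bin_centers: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(ev) > 1e-10):
            raise ValueError("components must be ordered by decreasing variance")


def split_by_memorability(stimuli: StimulusSet, k: int = 50
                          ) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k stimuli by memorability score.

    Ties are broken by stable stimulus order (earlier stimuli win the
    higher rank).
    """
    n = stimuli.n
    if 2 * k > n:
        raise ValueError("2k must not exceed the number of stimuli")
    if k < 1:
        raise ValueError("k must be positive")
    order = np.argsort(-stimuli.memorability_score, kind="stable")
    high = [stimuli.stimulus_id[i] for i in order[:k]]
    low = [stimuli.stimulus_id[i] for i in order[-k:]]
    return high, low


def _condition_channel_means(binned: EpochSet, ch_idx: list[int],
                             condition_sets: list[list[str]]) -> np.ndarray:
    """condition x bin x channel mean envelope over each condition's trials."""
    stims = binned.trial_stimulus.astype(str)
    n_bins = binned.envelope.shape[2]
    out = np.empty((len(condition_sets), n_bins, len(ch_idx)))
    for i, cond in enumerate(condition_sets):
        mask = np.isin(stims, list(cond))
        if not mask.any():
            raise ValueError(f"condition {i} matches no trials")
        out[i] = binned.envelope[np.ix_(mask.nonzero()[0], ch_idx)].mean(axis=0).T
    return out


def _pca_scores(data: np.ndarray, n_components: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Center over rows (channel means) and project onto leading PCs."""
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    var = s ** 2 / max(1, data.shape[0] - 1)
    return scores, var[:n_components]


def population_trajectories(binned: EpochSet, channels: list[str],
                            condition_sets: dict[str, list[str]],
                            n_components: int = 3) -> Trajectory:
    """One PCA on the concatenated condition x bin matrix; scores per condition.

    Per condition and bin, the envelope is averaged over that condition's
    trials per channel; the resulting (conditions * bins) x channels matrix
    is centred by channel means (no variance scaling — channels share units
    after normalisation) and a single PCA is fitted on it.
    """
    if n_components > len(channels):
        raise ValueError("n_components exceeds channel count")
    ch_idx = [binned.channel_id.index(c) for c in channels]
    names = list(condition_sets.keys())
    means = _condition_channel_means(binned, ch_idx,
                                     [condition_sets[c] for c in names])
    n_cond, n_bins, n_ch = means.shape
    flat = means.reshape(n_cond * n_bins, n_ch)
    scores, ev = _pca_scores(flat, n_components)
    coords = scores.reshape(n_cond, n_bins, n_components)
    return Trajectory(conditions=names, coords=coords,
                      bin_centers=binned.time.copy(), explained_variance=ev)


def _divergence(coords: np.ndarray) -> float:
    """Time-summed Euclidean distance between the two condition trajectories."""
    return float(np.linalg.norm(coords[0] - coords[1], axis=1).sum())


def trajectory_divergence(binned: EpochSet, channels: list[str],
                          high: list[str], low: list[str],
                          n_perm: int = 1000, n_components: int = 3,
                          seed: int | None = None) -> tuple[float, float]:
    """Divergence D between high/low trajectories and its permutation p.

    The null reassigns the pooled stimuli to two groups of the original
    sizes at random; trajectories and the PCA are recomputed inside every
    permutation.  p = (1 + #{D_null >= D}) / (n_perm + 1).
    """
    if n_components > len(channels):
        raise ValueError("n_components exceeds channel count")
    ch_idx = [binned.channel_id.index(c) for c in channels]

    def compute_d(h: list[str], l: list[str]) -> float:
        means = _condition_channel_means(binned, ch_idx, [h, l])
        n_cond, n_bins, n_ch = means.shape
        scores, _ = _pca_scores(means.reshape(-1, n_ch), n_components)
        return _divergence(scores.reshape(n_cond, n_bins, n_components))

    d_obs = compute_d(list(high), list(low))
    pooled = list(high) + list(low)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(pooled))
        h = [pooled[i] for i in perm[:len(high)]]
        l = [pooled[i] for i in perm[len(high):]]
        null[k] = compute_d(h, l)
    p = (1 + int(np.sum(null >= d_obs))) / (n_perm + 1)
    return d_obs, p


def condition_mean_hgp(epochs: EpochSet, channels: list[str],
                       condition_sets: dict[str, list[str]]
                       ) -> dict[str, dict[str, np.ndarray | None]]:
    """Condition-averaged normalised envelope: mean and SEM across channels.

    Per channel, trials of each condition are averaged; the group curve is
    the mean across channels and the error band the standard error across
    channels (absent with a single channel).
    """
    ch_idx = [epochs.channel_id.index(c) for c in channels]
    stims = epochs.trial_stimulus.astype(str)
    out: dict[str, dict[str, np.ndarray | None]] = {}
    for name, cond in condition_sets.items():
        mask = np.isin(stims, list(cond))
        if not mask.any():
            raise ValueError(f"condition {name!r} matches no trials")
        per_ch = epochs.envelope[np.ix_(mask.nonzero()[0], ch_idx)].mean(axis=0)
        mean = per_ch.mean(axis=0)
        sem = (per_ch.std(axis=0, ddof=1) / np.sqrt(len(ch_idx))
               if len(ch_idx) > 1 else None)
        out[name] = {"mean": mean, "sem": sem, "time": epochs.time.copy()}
    return out
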