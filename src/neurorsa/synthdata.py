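"""Ground-truth synthetic data: stimuli, correlated feature spaces, recordings.

This module emulates the kind of data produced by an intracranial one-back
viewing experiment: a stimulus set organised into object categories, three
mutually correlated feature embeddings (visual, semantic, memorability), and
multichannel recordings in which a configurable subset of channels is
linearly tuned to exactly one feature space.  Every generator is
deterministic given its seed, and the tuning of every channel is recorded in
a :class:`GroundTruth` entry so downstream selection procedures can be
validated against known truth.

Feature-space construction
--------------------------
The visual and semantic spaces are category-clustered Gaussians (category
means plus within-category item noise); the semantic space is a calibrated
mixture of a projection of the visual space and an independent clustered
component.  The memorability space is a mixture of projections of the other
two plus an independent non-clustered component.  Mixing weights are solved
numerically on the realised data so that the Spearman correlations between
the upper triangles of the three feature RDMs hit the requested
``cross_corr`` targets.  The scalar memorability score is the first
principal-component score of the memorability space rescaled to [0, 1], so
the memorability embedding "varies primarily along a single dimension"
reflecting the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

ATTRIBUTES = ("visual", "semantic", "memorability")

#: default within-category noise SD giving moderate category separability
#: (silhouette roughly 0.2-0.4 for Gaussian category means of unit SD)
DEFAULT_WITHIN_SD = 0.9

#: default feature-space dimensionalities (visual, semantic, memorability)
DEFAULT_DIMS = (64, 64, 16)

#: default pairwise RDM Spearman-correlation targets
#: (visual-semantic, visual-memorability, semantic-memorability)
DEFAULT_CROSS_CORR = (0.4, 0.3, 0.2)


class InfeasibleCrossCorrError(ValueError):
    """Requested feature-RDM correlation triple cannot be realised."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """Ordered stimuli with category labels and scalar memorability scores."""

    stimulus_id: list[str]
    category: np.ndarray
    memorability_score: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.stimulus_id)) != len(self.stimulus_id):
            raise ValueError("stimulus ids must be unique")
        self.category = np.asarray(self.category)
        self.memorability_score = np.asarray(self.memorability_score, dtype=float)
        if len(self.category) != len(self.stimulus_id):
            raise ValueError("one category per stimulus required")
        if len(self.memorability_score) != len(self.stimulus_id):
            raise ValueError("one memorability score per stimulus required")
        if not np.all(np.isfinite(self.memorability_score)):
            raise ValueError("memorability scores must be finite")

    @property
    def n(self) -> int:
        return len(self.stimulus_id)


@dataclass
class FeatureSpace:
    """Stimulus-by-dimension embedding for one attribute."""

    attribute: str
    matrix: np.ndarray
    stimulus_id: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("feature matrix must be 2-D with >=1 dimension")
        if self.matrix.shape[0] != len(self.stimulus_id):
            raise ValueError("row count must equal stimulus count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix must be finite")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class GroundTruth:
    """Generator record of one synthetic channel's tuning."""

    channel_id: str
    roi: str
    tuned_attribute: str  # visual / semantic / memorability / none
    effect_size: float
    onset_latency: float = 0.1
    response_duration: float = 0.5
    weight_vector: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tuned_attribute not in ATTRIBUTES + ("none",):
            raise ValueError(f"unknown tuned_attribute {self.tuned_attribute!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.tuned_attribute == "none" and self.effect_size != 0:
            raise ValueError("untuned channels must have effect_size 0")
        if self.onset_latency < 0 or self.response_duration <= 0:
            raise ValueError("invalid latency/duration")


@dataclass
class Recording:
    """Continuous multichannel signal with events and electrode metadata."""

    signal: np.ndarray  # channels x samples
    fs: float
    events: pd.DataFrame  # columns: onset, duration, stimulus_id
    channels: pd.DataFrame  # columns: name, roi, x, y, z

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.fs <= 2 * 170.0:
            raise ValueError("sampling rate must exceed twice the 170 Hz band edge")
        onsets = self.events["onset"].to_numpy(dtype=float)
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        span = self.signal.shape[1] / self.fs
        if onsets.size and (onsets[0] < 0 or onsets[-1] >= span):
            raise ValueError("event onsets must lie inside the signal span")
        names = self.channels["name"].tolist()
        if len(set(names)) != len(names):
            raise ValueError("channel ids must be unique")


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def make_stimulus_set(
    n_categories: int = 50,
    n_per_category: int = 10,
    seed: int = 0,
    score_dist: tuple[float, float] = (2.0, 2.0),
) -> StimulusSet:
    """Create ``n_categories * n_per_category`` stimuli with category labels.

    Memorability scores are drawn i.i.d. from a Beta distribution
    (``score_dist`` holds its two shape parameters), giving a unimodal
    distribution on [0, 1] with within-category spread.  The scores are
    provisional: :func:`make_feature_spaces` regenerates them from the
    memorability embedding so that score and embedding are consistent.
    """
    if n_categories < 2 or n_per_category < 2:
        raise ValueError("need at least 2 categories of at least 2 stimuli")
    rng = np.random.default_rng(seed)
    n = n_categories * n_per_category
    width = max(4, len(str(n - 1)))
    ids = [f"stim{i:0{width}d}" for i in range(n)]
    cats = np.repeat([f"cat{c:03d}" for c in range(n_categories)], n_per_category)
    scores = rng.beta(score_dist[0], score_dist[1], size=n)
    return StimulusSet(stimulus_id=ids, category=cats, memorability_score=scores)


# ---------------------------------------------------------------------------
# feature spaces
# ---------------------------------------------------------------------------

def _clustered_matrix(cat_index: np.ndarray, dim: int, rng: np.random.Generator,
                      within_sd: float) -> np.ndarray:
    """Category means ~ N(0,1) per dimension plus within-category noise."""
    n_cat = int(cat_index.max()) + 1
    means = rng.standard_normal((n_cat, dim))
    x = means[cat_index] + within_sd * rng.standard_normal((len(cat_index), dim))
    return _standardize(x)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    scale = np.sqrt((x ** 2).mean())
    return x / scale if scale > 0 else x


def _projection_map(d_from: int, d_to: int, rng: np.random.Generator) -> np.ndarray:
    """Random matrix with orthonormal columns (or rows if d_to > d_from)."""
    a = rng.standard_normal((d_from, max(d_from, d_to)))
    q, _ = np.linalg.qr(a)
    return q[:, :d_to]


def _rdm_utv(x: np.ndarray) -> np.ndarray:
    return pdist(x, metric="euclidean")


def _spearman(u: np.ndarray, v: np.ndarray) -> float:
    ru, rv = rankdata(u), rankdata(v)
    ru -= ru.mean()
    rv -= rv.mean()
    denom = np.sqrt((ru ** 2).sum() * (rv ** 2).sum())
    return float((ru * rv).sum() / denom)


def make_feature_spaces(
    stimuli: StimulusSet,
    dims: Sequence[int] = DEFAULT_DIMS,
    cross_corr: Sequence[float] = DEFAULT_CROSS_CORR,
    seed: int = 0,
    within_sd: float = DEFAULT_WITHIN_SD,
    max_residual: float | None = None,
) -> tuple[dict[str, FeatureSpace], StimulusSet]:
    """Build the three feature spaces with calibrated RDM cross-correlations.

    ``cross_corr`` = (visual-semantic, visual-memorability,
    semantic-memorability) Spearman targets for the RDM upper triangles.
    Mixing weights are solved on the realised matrices, so at moderate n the
    achieved correlations track the targets closely.

    Returns the spaces keyed by attribute and a new :class:`StimulusSet`
    whose memorability scores are the rescaled first principal-component
    scores of the memorability space.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise ValueError("dims must be three positive integers")
    r_vs, r_vm, r_sm = (float(r) for r in cross_corr)
    for r in (r_vs, r_vm, r_sm):
        if not 0 <= r < 1:
            raise InfeasibleCrossCorrError("cross_corr entries must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    _, cat_index = np.unique(stimuli.category, return_inverse=True)
    d_v, d_s, d_m = dims
    if max_residual is None:
        # feasibility slack limited by sampling noise of the realised RDM
        # correlation, whose effective sample size is the stimulus count
        # (upper-triangle entries share row effects), not the pair count
        max_residual = max(0.05, 2.0 / np.sqrt(stimuli.n))

    x_v = _clustered_matrix(cat_index, d_v, rng, within_sd)
    e_s_clustered = _clustered_matrix(cat_index, d_s, rng, within_sd)
    e_s_white = _standardize(rng.standard_normal((stimuli.n, d_s)))
    e_m = _standardize(rng.standard_normal((stimuli.n, d_m)))
    q_vs = _projection_map(d_v, d_s, rng)
    q_vm = _projection_map(d_v, d_m, rng)
    q_sm = _projection_map(d_s, d_m, rng)

    utv_v = _rdm_utv(x_v)

    proj_v_s = _standardize(x_v @ q_vs)

    # Two category-clustered spaces on the same partition are intrinsically
    # positively RDM-correlated, so the calibration parameter u spans
    # u < 0: independent space whose clustering fades to white noise
    # u >= 0: fully clustered independent space mixed with the visual
    #         projection with weight u
    def semantic_mix(u: float) -> np.ndarray:
        if u >= 0:
            e = e_s_clustered
            g = u
        else:
            w = 1.0 + u  # cluster weight in [0, 1)
            e = _standardize(np.sqrt(w) * e_s_clustered
                             + np.sqrt(1.0 - w) * e_s_white)
            g = 0.0
        return _standardize(g * proj_v_s + np.sqrt(max(0.0, 1 - g * g)) * e)

    def f(u: float) -> float:
        return _spearman(_rdm_utv(semantic_mix(u)), utv_v) - r_vs

    lo, hi = f(-0.999), f(0.999)
    if lo >= 0:
        if lo > max_residual:
            raise InfeasibleCrossCorrError(
                f"visual-semantic target {r_vs} below attainable range")
        u_hat = -0.999
    elif hi < 0:
        raise InfeasibleCrossCorrError(
            f"visual-semantic target {r_vs} above attainable range")
    else:
        u_hat = brentq(f, -0.999, 0.999, xtol=1e-3)
    x_s = semantic_mix(u_hat)
    utv_s = _rdm_utv(x_s)

    proj_v_m = _standardize(x_v @ q_vm)
    proj_s_m = _standardize(x_s @ q_sm)

    def memorability_mix(a: float, b: float) -> np.ndarray:
        c = np.sqrt(max(0.0, 1 - a * a - b * b))
        return _standardize(a * proj_v_m + b * proj_s_m + c * e_m)

    if r_vm == 0 and r_sm == 0:
        a_hat, b_hat = 0.0, 0.0
    else:
        def resid(ab: np.ndarray) -> np.ndarray:
            u = _rdm_utv(memorability_mix(ab[0], ab[1]))
            return np.array([_spearman(u, utv_v) - r_vm,
                             _spearman(u, utv_s) - r_sm])
        sol = least_squares(resid, x0=np.array([r_vm, r_sm]),
                            bounds=(0.0, 0.99), xtol=1e-3, ftol=1e-4,
                            diff_step=0.05)
        a_hat, b_hat = sol.x
        if np.max(np.abs(sol.fun)) > max_residual:
            raise InfeasibleCrossCorrError(
                f"cross_corr triple ({r_vs}, {r_vm}, {r_sm}) infeasible: "
                f"best residuals {sol.fun}")
    x_m = memorability_mix(a_hat, b_hat)

    # memorability score = first PC score of the memorability space in [0, 1]
    u, s, _ = np.linalg.svd(x_m - x_m.mean(axis=0), full_matrices=False)
    pc1 = u[:, 0] * s[0]
    lo, hi = pc1.min(), pc1.max()
    scores = (pc1 - lo) / (hi - lo) if hi > lo else np.full(stimuli.n, 0.5)

    spaces = {
        "visual": FeatureSpace("visual", x_v, list(stimuli.stimulus_id)),
        "semantic": FeatureSpace("semantic", x_s, list(stimuli.stimulus_id)),
        "memorability": FeatureSpace("memorability", x_m, list(stimuli.stimulus_id)),
    }
    new_stimuli = StimulusSet(list(stimuli.stimulus_id), stimuli.category.copy(),
                              scores)
    return spaces, new_stimuli


# ---------------------------------------------------------------------------
# channel rosters and tuned projections
# ---------------------------------------------------------------------------

def make_ground_truth(
    spaces: dict[str, FeatureSpace],
    roster: Sequence[tuple[str, str, float, int]],
    seed: int = 0,
    onset_latency: float = 0.1,
    response_duration: float = 0.5,
) -> list[GroundTruth]:
    """Expand a roster of ``(roi, tuned_attribute, effect_size, n_channels)``
    entries into per-channel :class:`GroundTruth` records with random unit
    weight vectors over the tuned space."""
    rng = np.random.default_rng(seed)
    out: list[GroundTruth] = []
    i = 0
    for roi, attr, effect, count in roster:
        for _ in range(int(count)):
            if attr == "none":
                w = None
            else:
                w = rng.standard_normal(spaces[attr].dim)
                w /= np.linalg.norm(w)
            out.append(GroundTruth(
                channel_id=f"ch{i:03d}", roi=roi, tuned_attribute=attr,
                effect_size=float(effect) if attr != "none" else 0.0,
                onset_latency=onset_latency, response_duration=response_duration,
                weight_vector=w, seed=seed + i))
            i += 1
    return out


def tuned_projection(gt: GroundTruth, spaces: dict[str, FeatureSpace]) -> np.ndarray:
    """Standardised projection of the stimuli onto the channel's tuning axis.

    Untuned channels get a zero vector.
    """
    if gt.tuned_attribute == "none":
        n = next(iter(spaces.values())).matrix.shape[0]
        return np.zeros(n)
    x = spaces[gt.tuned_attribute].matrix
    p = x @ gt.weight_vector
    sd = p.std()
    return (p - p.mean()) / sd if sd > 0 else np.zeros_like(p)


# ---------------------------------------------------------------------------
# continuous recordings
# ---------------------------------------------------------------------------

def _one_over_f_noise(n_samples: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with a 1/f power spectrum (spectrally shaped white noise)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])  # amplitude ~ f^-1/2 -> power ~ 1/f
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n_samples)
    return x / x.std()


def _band_noise(n_samples: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise confined to ``band`` (FFT brick-wall shaping)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    x = np.fft.irfft(spec * mask, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _inband_sd_of_one_over_f(fs: float, band: tuple[float, float]) -> float:
    """SD of the in-band component of unit-SD 1/f noise (analytic)."""
    # power(f) ~ 1/f between f_lo = 1/duration and Nyquist; use 0.5 Hz as the
    # effective low cutoff of the synthesised background
    f_lo, f_hi = 0.5, fs / 2
    frac = np.log(band[1] / band[0]) / np.log(f_hi / f_lo)
    return float(np.sqrt(frac))


def _trial_envelope_window(fs: float, duration: float, ramp: float = 0.05) -> np.ndarray:
    """Rectangular window of ``duration`` with raised-cosine ramps of ``ramp`` s."""
    n = max(1, int(round(duration * fs)))
    w = np.ones(n)
    nr = int(round(ramp * fs))
    if nr > 0 and 2 * nr <= n:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        w[:nr] = r
        w[-nr:] = r[::-1]
    return w


def make_recording(
    stimuli: StimulusSet,
    spaces: dict[str, FeatureSpace],
    ground_truth: Sequence[GroundTruth],
    fs: float = 1000.0,
    trial_isi: tuple[float, float] = (0.5, 0.75),
    seed: int = 0,
    stim_duration: float = 1.0,
    band: tuple[float, float] = (70.0, 170.0),
    baseline_gain: float = 1.0,
    pre_pad: float = 1.0,
    post_pad: float = 2.0,
) -> Recording:
    """Synthesise a continuous recording with gamma-band responses.

    Each channel is 1/f background noise plus, for every trial, a gamma-band
    carrier whose envelope is a latency-shifted raised-cosine window scaled by
    ``sigma_b * effect_size * (baseline_gain + z)`` where ``z`` is the
    standardised tuned-feature projection of the shown stimulus and
    ``sigma_b`` the in-band SD of the background — so ``effect_size`` is the
    evoked-envelope SD in units of the background's in-band floor.  Amplitudes
    are floored at zero.  Stimuli are presented once each in seeded random
    order with a 1 s display and a uniformly jittered inter-stimulus interval.
    """
    if len(ground_truth) < 1:
        raise ValueError("need at least one channel")
    if fs < 500:
        raise ValueError("fs must be >= 500 Hz")
    for gt in ground_truth:
        if gt.tuned_attribute != "none" and gt.tuned_attribute not in spaces:
            raise ValueError(f"no feature space for {gt.tuned_attribute}")
    known = set(next(iter(spaces.values())).stimulus_id)
    missing = [s for s in stimuli.stimulus_id if s not in known]
    if missing:
        raise ValueError(f"stimuli absent from feature spaces: {missing[:5]}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(stimuli.n)
    isis = rng.uniform(trial_isi[0], trial_isi[1], size=stimuli.n)
    onsets = pre_pad + np.concatenate([[0.0], np.cumsum(stim_duration + isis[:-1])])
    n_samples = int(round((onsets[-1] + stim_duration + post_pad) * fs))
    events = pd.DataFrame({
        "onset": onsets,
        "duration": stim_duration,
        "stimulus_id": [stimuli.stimulus_id[i] for i in order],
    })

    sigma_b = _inband_sd_of_one_over_f(fs, band)
    stim_pos = {s: i for i, s in enumerate(stimuli.stimulus_id)}
    signal = np.empty((len(ground_truth), n_samples))
    rows = []
    for ci, gt in enumerate(ground_truth):
        ch_rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + ci]))
        bg = _one_over_f_noise(n_samples, fs, ch_rng)
        x = bg
        if gt.effect_size > 0:
            z = tuned_projection(gt, spaces)
            carrier = _band_noise(n_samples, fs, band, ch_rng)
            env = np.zeros(n_samples)
            w = _trial_envelope_window(fs, gt.response_duration)
            for onset, stim in zip(onsets, events["stimulus_id"]):
                amp = sigma_b * gt.effect_size * (
                    baseline_gain + z[stim_pos[stim]])
                amp = max(0.0, amp)
                i0 = int(round((onset + gt.onset_latency) * fs))
                i1 = min(i0 + len(w), n_samples)
                env[i0:i1] += amp * w[: i1 - i0]
            x = bg + carrier * env
        signal[ci] = x
        rows.append({"name": gt.channel_id, "roi": gt.roi,
                     "x": float(ch_rng.uniform(-70, 70)),
                     "y": float(ch_rng.uniform(-100, 70)),
                     "z": float(ch_rng.uniform(-50, 80))})
    channels = pd.DataFrame(rows)
    return Recording(signal=signal, fs=fs, events=events, channels=channels)


# ---------------------------------------------------------------------------
# fast response-matrix path
# ---------------------------------------------------------------------------

def make_response_matrix(
    stimuli: StimulusSet,
    spaces: dict[str, FeatureSpace],
    ground_truth: Sequence[GroundTruth],
    seed: int = 0,
    baseline: float = 0.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Stimulus x channel response table bypassing the time-series path.

    response = baseline + effect_size * standardised tuned projection +
    unit-variance Gaussian noise; same tuning contract as
    :func:`make_recording`.
    """
    rng = np.random.default_rng(seed)
    n = stimuli.n
    values = np.empty((n, len(ground_truth)))
    for ci, gt in enumerate(ground_truth):
        z = tuned_projection(gt, spaces)
        values[:, ci] = baseline + gt.effect_size * z \
            + noise_sd * rng.standard_normal(n)
    return pd.DataFrame(values, index=list(stimuli.stimulus_id),
                        columns=[gt.channel_id for gt in ground_truth])


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

@dataclass
class NeuronTuning:
    """Tuning of one synthetic neuron: attribute (or 'none') and rate gain."""

    neuron_id: str
    tuned_attribute: str = "none"
    gain: float = 0.0  # Hz per SD of the tuned projection
    weight_vector: np.ndarray | None = None


def make_spike_trains(
    stimuli: StimulusSet,
    tuning: Sequence[NeuronTuning],
    spaces: dict[str, FeatureSpace] | None = None,
    baseline_rate: float = 5.0,
    trial_window: tuple[float, float] = (0.25, 1.25),
    seed: int = 0,
) -> pd.DataFrame:
    """Inhomogeneous Poisson spike trains, one trial per stimulus.

    Within a trial the rate is constant at
    ``max(0, baseline_rate + gain * z)`` where ``z`` is the neuron's
    standardised tuned projection of the shown stimulus; spike times are
    uniform within ``trial_window`` (seconds relative to onset).
    """
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be >= 0")
    t0, t1 = trial_window
    if t1 <= t0:
        raise ValueError("trial_window must have positive length")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, str, float]] = []
    for nt in tuning:
        if nt.tuned_attribute == "none" or nt.gain == 0:
            z = np.zeros(stimuli.n)
        else:
            if spaces is None:
                raise ValueError("spaces required for tuned neurons")
            w = nt.weight_vector
            if w is None:
                w_rng = np.random.default_rng(abs(hash(nt.neuron_id)) % 2**31)
                w = w_rng.standard_normal(spaces[nt.tuned_attribute].dim)
                w /= np.linalg.norm(w)
            gt = GroundTruth(channel_id=nt.neuron_id, roi="MTL",
                             tuned_attribute=nt.tuned_attribute, effect_size=1.0,
                             weight_vector=w)
            z = tuned_projection(gt, spaces)
        rates = np.maximum(0.0, baseline_rate + nt.gain * z)
        counts = rng.poisson(rates * (t1 - t0))
        for trial, c in enumerate(counts):
            if c == 0:
                continue
            times = np.sort(rng.uniform(t0, t1, size=c))
            rows.extend((nt.neuron_id, trial, stimuli.stimulus_id[trial], float(t))
                        for t in times)
    return pd.DataFrame(rows, columns=["neuron_id", "trial", "stimulus_id",
                                       "t_spike_s"])
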