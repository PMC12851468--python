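"""Representational dissimilarity matrices over stimuli.

Constructors for feature RDMs (Euclidean or cosine distance between
embedding rows), scalar-channel RDMs (absolute response differences — the
1-D Euclidean case), and population RDMs (Euclidean distance between
multichannel response vectors), plus the fixed row-major upper-triangle
vectorisation used by every correlation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .signal import ResponseMatrix
from .synthdata import FeatureSpace

METRICS = ("euclidean", "cosine", "absdiff")


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix with stimulus labels."""

    matrix: np.ndarray
    stimulus_id: list[str]
    metric: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.stimulus_id)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix must be square with one row per stimulus")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("RDM entries must be finite")
        if np.any(self.matrix < 0):
            raise ValueError("RDM entries must be nonnegative")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12):
            raise ValueError("RDM diagonal must be zero")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.stimulus_id)


def feature_rdm(space: FeatureSpace, metric: str = "euclidean") -> RDM:
    """RDM of a feature space: pairwise euclidean or cosine distances."""
    x = space.matrix
    if x.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    if metric == "euclidean":
        d = pdist(x, metric="euclidean")
    elif metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        zero = np.flatnonzero(norms == 0)
        if zero.size:
            raise ValueError(
                f"cosine distance undefined for zero-norm stimulus "
                f"{space.stimulus_id[zero[0]]!r}")
        d = pdist(x, metric="cosine")
        d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    else:
        raise ValueError(f"unsupported feature metric {metric!r}")
    return RDM(squareform(d), list(space.stimulus_id), metric)


def channel_rdm(responses: np.ndarray, stimulus_id: list[str]) -> RDM:
    """Scalar-response RDM: entry (i, j) = |r_i - r_j|."""
    r = np.asarray(responses, dtype=float).ravel()
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    if r.size != len(stimulus_id):
        raise ValueError("one response per stimulus required")
    d = pdist(r[:, None], metric="cityblock")
    return RDM(squareform(d), list(stimulus_id), "absdiff")


def population_rdm(responses: ResponseMatrix,
                   channels: list[str] | None = None) -> RDM:
    """Euclidean distance between stimulus response vectors over ``channels``."""
    if channels is None:
        channels = list(responses.channel_id)
    if len(channels) == 0:
        raise ValueError("channel subset must be nonempty")
    unknown = [c for c in channels if c not in responses.channel_id]
    if unknown:
        raise ValueError(f"unknown channel ids: {unknown}")
    sub = responses.subset(list(channels))
    d = pdist(sub.values, metric="euclidean")
    return RDM(squareform(d), list(responses.stimulus_id), "euclidean")


def utv(rdm: RDM | np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Upper-triangle vector (diagonal excluded) in row-major (i<j) order."""
    m = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]
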