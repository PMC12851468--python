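"""RDM correlation with permutation inference.

Full RSA (Spearman by default), the Mantel permutation test, partial RDM
correlation (residualising on control RDMs), per-channel attribute
selection, and time-resolved RSA with onset/peak latency extraction.

Permutation machinery
---------------------
A Mantel null is built by applying a random stimulus relabelling jointly to
the rows and columns of one RDM before correlating.  For rank (Spearman)
correlation the rank transform commutes with relabelling — the multiset of
upper-triangle values is unchanged — so ranks are computed once and each
permutation reduces to a gather plus a dot product.  Permutation p-values
use the (1 + k) / (1 + B) estimator and are therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, ttest_rel
from statsmodels.stats.multitest import multipletests

from .rdm import RDM, utv
from .signal import EpochSet, ResponseMatrix


class CollinearControlsError(ValueError):
    """Control RDMs are rank-deficient after vectorisation."""


@dataclass
class RsaResult:
    """Correlation between two RDMs with its permutation p-value."""

    rho: float
    p: float
    n_perm: int
    method: str
    controls: list[str] = field(default_factory=list)
    null: np.ndarray | None = None


@dataclass
class TimecourseRSA:
    """Time-resolved RSA of one channel set against one feature RDM."""

    bin_centers: np.ndarray
    rho: np.ndarray  # channels x bins
    rho_mean: np.ndarray  # group mean per bin
    significant: np.ndarray  # bool per bin, after FDR + run-length rule
    onset_latency: float | None
    peak_latency: float | None
    channel_id: list[str]
    min_run: int


def _check_alignment(a: RDM, b: RDM) -> None:
    if a.stimulus_id != b.stimulus_id:
        raise ValueError("RDMs must share the same stimulus order")


def _transform(v: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        return rankdata(v)
    if method == "pearson":
        return np.asarray(v, dtype=float)
    raise ValueError(f"unknown method {method!r}")


def _corr(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-variance vector in correlation")
    return float(u @ v / (nu * nv))


def rsa_corr(rdm_a: RDM, rdm_b: RDM, method: str = "spearman") -> float:
    """Correlation of the two RDM upper triangles (average ranks for ties)."""
    _check_alignment(rdm_a, rdm_b)
    return _corr(_transform(utv(rdm_a), method), _transform(utv(rdm_b), method))


def _permuted_utv(sym: np.ndarray, perm: np.ndarray, iu) -> np.ndarray:
    """Upper triangle of ``sym`` after joint row/column relabelling."""
    return sym[perm][:, perm][iu]


def mantel(rdm_a: RDM, rdm_b: RDM, n_perm: int = 1000,
           seed: int | None = None, method: str = "spearman",
           tail: str = "greater", keep_null: bool = False) -> RsaResult:
    """Mantel permutation test: relabel ``rdm_b``'s stimuli ``n_perm`` times."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    _check_alignment(rdm_a, rdm_b)
    va = _transform(utv(rdm_a), method)
    vb = _transform(utv(rdm_b), method)
    va = va - va.mean()
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb - vb.mean())
    if na == 0 or nb == 0:
        raise ValueError("zero-variance RDM vector")
    ua = va / na
    obs = float(ua @ (vb - vb.mean()) / nb)

    n = rdm_a.n
    sym = squareform(vb)  # symmetric matrix of transformed values
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        null[k] = ua @ _permuted_utv(sym, perm, iu) / nb
    if tail == "greater":
        exceed = int(np.sum(null >= obs))
    else:
        exceed = int(np.sum(np.abs(null) >= abs(obs)))
    p = (1 + exceed) / (n_perm + 1)
    return RsaResult(rho=obs, p=p, n_perm=n_perm, method=method,
                     null=null if keep_null else None)


def partial_rsa(neural_rdm: RDM, target_rdm: RDM, control_rdms: list[RDM],
                n_perm: int = 1000, seed: int | None = None,
                method: str = "spearman", tail: str = "greater",
                keep_null: bool = False) -> RsaResult:
    """Partial RDM correlation, permuting the neural RDM's stimulus labels.

    Target and neural upper-triangle vectors (rank-transformed for
    Spearman) are residualised on the control vectors (with intercept); the
    statistic is the Pearson correlation of the residuals.  With an empty
    control list this reduces to :func:`mantel` applied to the neural RDM.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_alignment(neural_rdm, target_rdm)
    for c in control_rdms:
        _check_alignment(neural_rdm, c)
    vn = _transform(utv(neural_rdm), method)
    vt = _transform(utv(target_rdm), method)
    vcs = [_transform(utv(c), method) for c in control_rdms]

    m = vn.size
    design = np.column_stack([np.ones(m)] + vcs)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearControlsError("control RDM vectors are collinear")
    q, _ = np.linalg.qr(design)

    def resid(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    rt = resid(vt)
    nt = np.linalg.norm(rt)
    if nt < 1e-10 * np.linalg.norm(vt):
        raise CollinearControlsError(
            "target RDM is collinear with the controls")
    rt_unit = rt / nt

    def stat(v: np.ndarray) -> float:
        rv = resid(v)
        nv = np.linalg.norm(rv)
        if nv < 1e-10 * np.linalg.norm(v):
            return 0.0  # neural RDM fully explained by the controls
        return float(rt_unit @ rv / nv)

    obs = stat(vn)
    sym = squareform(vn)
    iu = np.triu_indices(neural_rdm.n, k=1)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(neural_rdm.n)
        null[k] = stat(_permuted_utv(sym, perm, iu))
    if tail == "greater":
        exceed = int(np.sum(null >= obs))
    else:
        exceed = int(np.sum(np.abs(null) >= abs(obs)))
    p = (1 + exceed) / (n_perm + 1)
    return RsaResult(rho=obs, p=p, n_perm=n_perm, method=method,
                     controls=[c.metric for c in control_rdms],
                     null=null if keep_null else None)


def select_channels_rsa(responses: ResponseMatrix,
                        feature_rdms: dict[str, RDM],
                        n_perm: int = 1000, alpha: float = 0.05,
                        seed: int | None = None, method: str = "spearman",
                        roi: dict[str, str] | None = None,
                        chunk: int = 50) -> pd.DataFrame:
    """Per channel x attribute Mantel selection (scalar-channel RDMs).

    The Mantel null is symmetric in which RDM is relabelled, so one
    permutation set of the *feature* RDM is shared across channels; each
    channel's null correlations are then a single matrix product.  Channels
    with degenerate (constant) responses are reported unselected with
    ``reason='degenerate'``.
    """
    if len(responses.channel_id) < 2:
        raise ValueError("need at least 2 channels")
    stim_ids = list(responses.stimulus_id)
    n = len(stim_ids)
    iu = np.triu_indices(n, k=1)

    # transformed, centred, unit-norm channel utvs
    n_ch = len(responses.channel_id)
    u_rows = np.zeros((n_ch, n * (n - 1) // 2))
    degenerate = np.zeros(n_ch, dtype=bool)
    for c in range(n_ch):
        d = pdist(responses.values[:, c, None], metric="cityblock")
        v = _transform(d, method)
        v = v - v.mean()
        nv = np.linalg.norm(v)
        if nv == 0:
            degenerate[c] = True
        else:
            u_rows[c] = v / nv

    rows = []
    ss = np.random.SeedSequence(seed)
    for attr_seed, (attr, frdm) in zip(ss.spawn(len(feature_rdms)),
                                       sorted(feature_rdms.items())):
        if frdm.stimulus_id != stim_ids:
            raise ValueError(f"feature RDM {attr!r} stimulus order mismatch")
        va = _transform(utv(frdm), method)
        na = np.linalg.norm(va - va.mean())
        sym = squareform(va)
        obs = u_rows @ (va - va.mean()) / na
        exceed = np.zeros(n_ch, dtype=int)
        rng = np.random.default_rng(attr_seed)
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            block = np.empty((b, va.size))
            for k in range(b):
                perm = rng.permutation(n)
                block[k] = _permuted_utv(sym, perm, iu)
            block -= block.mean(axis=1, keepdims=True)
            null = (block @ u_rows.T) / na  # b x n_ch
            exceed += (null >= obs[None, :]).sum(axis=0)
            done += b
        pvals = (1 + exceed) / (n_perm + 1)
        for c, cid in enumerate(responses.channel_id):
            if degenerate[c]:
                rows.append({"channel_id": cid, "attribute": attr,
                             "rho": np.nan, "p": 1.0, "selected": False,
                             "reason": "degenerate"})
            else:
                rows.append({"channel_id": cid, "attribute": attr,
                             "rho": float(obs[c]), "p": float(pvals[c]),
                             "selected": bool(pvals[c] < alpha), "reason": ""})
    table = pd.DataFrame(rows)
    table["roi"] = table["channel_id"].map(roi) if roi else "all"
    return table[["channel_id", "roi", "attribute", "rho", "p", "selected",
                  "reason"]]


def enforce_min_run(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only runs of at least ``min_run`` consecutive True values."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j < mask.size and mask[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def _per_stimulus_bin_means(binned: EpochSet, stimulus_order: list[str]
                            ) -> np.ndarray:
    """Average repeated trials: stimulus x channel x bin array."""
    stims = binned.trial_stimulus.astype(str)
    out = np.empty((len(stimulus_order),) + binned.envelope.shape[1:])
    for i, s in enumerate(stimulus_order):
        sel = stims == s
        if not sel.any():
            raise ValueError(f"stimulus {s!r} has no trials")
        out[i] = binned.envelope[sel].mean(axis=0)
    return out


def time_resolved_rsa(binned: EpochSet, feature_rdm: RDM,
                      channels: list[str] | None = None,
                      baseline_window: tuple[float, float] = (-0.5, 0.0),
                      alpha: float = 0.05, min_run: int = 5,
                      method: str = "spearman") -> TimecourseRSA:
    """Per-bin RSA with a paired t-test against each channel's baseline.

    For every channel and time bin the bin's scalar-channel RDM is
    correlated with the feature RDM.  Per bin, a two-sided paired t-test
    across channels compares the bin correlations with each channel's mean
    baseline-bin correlation; Benjamini-Hochberg FDR is applied across bins
    at q = ``alpha`` and only runs of at least ``min_run`` consecutive
    significant bins are kept.  Onset is the first kept bin center; peak is
    the kept bin with maximal group-mean correlation.
    """
    if channels is None:
        channels = list(binned.channel_id)
    if len(channels) < 2:
        raise ValueError("need at least 2 channels for the paired test")
    ch_idx = [binned.channel_id.index(c) for c in channels]
    stim_ids = list(feature_rdm.stimulus_id)
    vals = _per_stimulus_bin_means(binned, stim_ids)[:, ch_idx, :]
    n_ch, n_bins = len(ch_idx), vals.shape[2]

    va = _transform(utv(feature_rdm), method)
    va = va - va.mean()
    na = np.linalg.norm(va)
    ua = va / na

    rho = np.empty((n_ch, n_bins))
    for c in range(n_ch):
        for b in range(n_bins):
            d = pdist(vals[:, c, b, None], metric="cityblock")
            v = _transform(d, method)
            v = v - v.mean()
            nv = np.linalg.norm(v)
            rho[c, b] = ua @ v / nv if nv > 0 else 0.0

    centers = binned.time
    eps = 1e-9
    base_mask = (centers >= baseline_window[0] - eps) & \
                (centers < baseline_window[1] - eps)
    if not base_mask.any():
        raise ValueError("no bins inside the baseline window")
    baseline_rho = rho[:, base_mask].mean(axis=1)

    pvals = np.empty(n_bins)
    for b in range(n_bins):
        diff = rho[:, b] - baseline_rho
        if np.allclose(diff, diff[0]):
            pvals[b] = 1.0
        else:
            pvals[b] = ttest_rel(rho[:, b], baseline_rho).pvalue
    rejected = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    significant = enforce_min_run(rejected, min_run)

    rho_mean = rho.mean(axis=0)
    onset = peak = None
    if significant.any():
        kept = np.flatnonzero(significant)
        onset = float(centers[kept[0]])
        peak = float(centers[kept[np.argmax(rho_mean[kept])]])
    return TimecourseRSA(bin_centers=centers.copy(), rho=rho,
                         rho_mean=rho_mean, significant=significant,
                         onset_latency=onset, peak_latency=peak,
                         channel_id=list(channels), min_run=min_run)
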