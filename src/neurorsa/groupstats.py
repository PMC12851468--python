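"""Group-level inference over channel selections.

Binomial exceedance tests of selection proportions against a chance rate,
2x2 chi-square comparisons of selection proportions between methods,
Benjamini-Hochberg FDR, per-ROI summaries, and a channel-subsampling
bootstrap used to check that a proportion is not driven by a few channels.

Binomial convention: the reported p-value is the *strict exceedance*
probability P(X > k) = 1 - CDF(k) for X ~ Binomial(N, p0).  The chi-square
statistic is Pearson's, one degree of freedom, without Yates continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, chi2

from statsmodels.stats.multitest import multipletests


def binom_exceedance(k: int, n: int, p0: float = 0.05) -> float:
    """P(X > k) for X ~ Binomial(n, p0) — strict exceedance."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= N")
    return float(binom.sf(k, n, p0))


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a nonnegative 2x2 count matrix")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    total = t.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(rows, cols) / total
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, alpha=q, method="fdr_bh")[0]


@dataclass
class RoiSummaryRow:
    roi: str
    attribute: str
    k: int
    n: int
    percent: float
    p: float


def roi_summary(selection: pd.DataFrame, p0: float = 0.05) -> pd.DataFrame:
    """Selection counts and binomial exceedance p per ROI x attribute.

    ``selection`` needs columns channel_id, roi, attribute, selected.  The
    denominator N is the number of (responsive) channels contributing rows
    for that ROI; ROIs with N = 0 are skipped.
    """
    rows = []
    for (roi, attr), grp in selection.groupby(["roi", "attribute"], sort=True):
        n = len(grp)
        if n == 0:
            continue
        k = int(grp["selected"].sum())
        rows.append(RoiSummaryRow(roi=str(roi), attribute=str(attr), k=k, n=n,
                                  percent=100.0 * k / n,
                                  p=binom_exceedance(k, n, p0)))
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class BootstrapResult:
    distribution: np.ndarray  # bootstrap percentages
    interval: tuple[float, float]  # central 95% interval
    observed: float
    inside: bool


def bootstrap_subsample_selection(selected: np.ndarray, frac: float = 0.75,
                                  n_boot: int = 1000,
                                  seed: int | None = None,
                                  groups: np.ndarray | None = None
                                  ) -> BootstrapResult:
    """Subsample channels without replacement; record selected-percentage.

    ``selected`` is the boolean selection flag per channel of one
    ROI/attribute cell.  Each iteration draws ``floor(frac * N)`` channels
    and records the percentage selected; the observed percentage is checked
    against the central 95% interval of the bootstrap distribution.  With
    ``groups`` (e.g. a participant label per channel) the draw is
    stratified: ``floor(frac * n_g)`` channels from each group.
    """
    selected = np.asarray(selected, dtype=bool)
    n = selected.size
    if n < 2:
        raise ValueError("need at least 2 channels")
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    if groups is not None:
        groups = np.asarray(groups)
        if groups.size != n:
            raise ValueError("one group label per channel required")
        strata = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    else:
        strata = [np.arange(n)]
    rng = np.random.default_rng(seed)
    dist = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate([
            rng.choice(s, size=max(1, int(np.floor(frac * s.size))),
                       replace=False) for s in strata])
        dist[i] = 100.0 * selected[idx].mean()
    observed = 100.0 * selected.mean()
    lo, hi = np.percentile(dist, [2.5, 97.5])
    inside = bool(lo <= observed <= hi)
    return BootstrapResult(distribution=dist, interval=(float(lo), float(hi)),
                           observed=float(observed), inside=inside)
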