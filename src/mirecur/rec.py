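"""Rank-based recurrence (REC) baseline score.

Within each cohort, for a fixed miRNA the N genes are ranked by their
regression t-statistic; the rank r is normalized to rr = r/N - 1/(2N),
uniform on a lattice in (0, 1) under the null.  Fisher's combination
s = -2 sum_d ln(rr_d) is referred to a chi-square with 2D degrees of
freedom, and the REC score is the log10 lower-tail probability
log10 P(chi2_{2D} <= s): genuinely repressive pairs rank near the negative
extreme in every cohort, driving rr toward 1, s toward 0 and REC strongly
negative.  Pairs with REC below a cutoff (default -1) are called positive.

Rank direction: genes are ranked by decreasing t (the most negative
t-statistic receives rank N), the only direction under which more-negative
REC indicates recurrent repression; ``ascending=True`` flips it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

RR_CLAMP_MARGIN = 0.25  # clamp rr to [1/(4N), 1 - 1/(4N)] in degenerate cases


def normalized_ranks(tvals, ascending: bool = False):
    """Normalized ranks rr = r/N - 1/(2N) of one miRNA's t-statistics across N genes.

    Ranks are assigned by decreasing t by default (rank N = most negative t);
    ties receive midranks.  Returns (rr, degenerate_flag).
    """
    t = np.asarray(tvals, float)
    N = t.size
    if N < 2:
        raise ValueError("need at least 2 genes to rank")
    if not np.isfinite(t).all():
        raise ValueError("t-statistics must be finite")
    degenerate = np.ptp(t) == 0
    r = stats.rankdata(t if ascending else -t, method="average")
    rr = r / N - 1.0 / (2 * N)
    lo, hi = RR_CLAMP_MARGIN / N, 1.0 - RR_CLAMP_MARGIN / N
    return np.clip(rr, lo, hi), degenerate


def rec_combine(rr):
    """Fisher-combine normalized ranks into (s, rec).

    s = -2 sum_d ln(rr_d) ~ chi2(2D) under independent uniform ranks; rec is
    the log10 lower tail P(chi2_{2D} <= s) computed on the log scale so small
    probabilities do not underflow.
    """
    rr = np.atleast_2d(np.asarray(rr, float))
    if (rr <= 0).any() or (rr >= 1).any():
        raise ValueError("rr values must lie strictly in (0, 1)")
    D = rr.shape[1]
    s = -2.0 * np.log(rr).sum(axis=1)
    # log lower-tail of chi2(2D) = log of the regularized lower incomplete gamma
    with np.errstate(divide="ignore"):
        logp = np.log(special.gammainc(D, s / 2.0))
    underflow = ~np.isfinite(logp)
    if underflow.any():
        # series log P = -s/2 + D log(s/2) - log(D!) + log(1 + O(s)) for s -> 0
        ssmall = s[underflow]
        logp[underflow] = (-ssmall / 2.0 + D * np.log(np.maximum(ssmall, 1e-300) / 2.0)
                           - special.gammaln(D + 1))
    rec = logp / np.log(10.0)
    if rr.shape[0] == 1 and np.ndim(s) == 1 and s.size == 1:
        return float(s[0]), float(rec[0])
    return s, rec


def chi2_lower_tail_even_df(s: float, D: int) -> float:
    """Closed-form P(chi2_{2D} <= s) = 1 - e^{-s/2} sum_{j<D} (s/2)^j / j!.

    Exact for even degrees of freedom; used as an independent cross-check of
    :func:`rec_combine`.
    """
    h = s / 2.0
    total, term = 0.0, 1.0
    for j in range(D):
        if j > 0:
            term *= h / j
        total += term
    return 1.0 - np.exp(-h) * total


def rec_scores(tstats: np.ndarray, ascending: bool = False) -> np.ndarray:
    """REC scores for a full (M, N, D) t-statistic (or z-score) tensor.

    Ranks are taken within each (miRNA, cohort) slice across genes, combined
    over cohorts per pair.  Returns an (M, N) array of REC scores.
    """
    M, N, D = tstats.shape
    rr = np.empty_like(tstats)
    for k in range(M):
        for d in range(D):
            rr[k, :, d], _ = normalized_ranks(tstats[k, :, d], ascending=ascending)
    _, rec = rec_combine(rr.reshape(M * N, D))
    return rec.reshape(M, N)


def call_positives(rec, cutoff: float = -1.0):
    """Positive call iff rec < cutoff (strict)."""
    return np.asarray(rec, float) < cutoff


def rec_table(rec: np.ndarray, s: np.ndarray | None, mirnas, genes,
              cutoff: float = -1.0) -> pd.DataFrame:
    """Long-format REC results sorted most-negative first."""
    M, N = rec.shape
    kk, ii = np.meshgrid(np.arange(M), np.arange(N), indexing="ij")
    df = pd.DataFrame({
        "mirna": np.asarray(mirnas)[kk.ravel()],
        "gene": np.asarray(genes)[ii.ravel()],
        "rec": rec.ravel(),
    })
    if s is not None:
        df["s"] = s.ravel()
    df["positive"] = call_positives(df["rec"].to_numpy(), cutoff)
    return df.sort_values(["rec", "gene", "mirna"], kind="mergesort").reset_index(drop=True)
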