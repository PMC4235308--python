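"""Validation and downstream procedures for ranked interaction lists.

Covers the evaluation toolbox applied to inferred recurrent interactions:
top-k overlap against reference pair sets (with a shuffled-score baseline),
one-sided rank tests for external score comparisons, hypergeometric and
resampling-based gene-set enrichment, and the mean-split Kaplan-Meier /
log-rank prognostic screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

DEFAULT_KS = tuple(range(2000, 20001, 2000))


def topk_overlap_curve(ranked_pairs, ref, ks=DEFAULT_KS) -> pd.DataFrame:
    """Count reference pairs among the top-k of a ranked interaction list.

    Parameters
    ----------
    ranked_pairs : ordered sequence of (miRNA, gene) tuples, best first.
    ref : set of (miRNA, gene) reference pairs.
    ks : increasing cutoffs; a k beyond the list length is truncated
        (flagged in the ``truncated`` column).
    """
    ks = list(ks)
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("ks must be strictly increasing")
    ranked = list(ranked_pairs)
    ref = set(ref)
    hits = np.cumsum([1 if p in ref else 0 for p in ranked]) if ranked else np.array([])
    rows = []
    for k in ks:
        kk = min(k, len(ranked))
        rows.append({"k": k, "count": int(hits[kk - 1]) if kk else 0,
                     "truncated": k > len(ranked)})
    return pd.DataFrame(rows)


def shuffle_baseline(ranked_pairs, seed: int):
    """Uniform random permutation of the ranking, reproducible from ``seed``."""
    ranked = list(ranked_pairs)
    if not ranked:
        raise ValueError("empty ranking")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ranked))
    return [ranked[j] for j in perm]


def location_shift_test(values_a, values_b, alternative: str = "less",
                        paired: bool = False) -> float:
    """One-sided Wilcoxon test that ``values_a`` is shifted relative to ``values_b``.

    Unpaired: rank-sum (Mann-Whitney), exact for small samples, normal
    approximation with tie correction otherwise.  Paired: signed-rank on the
    elementwise differences.  ``alternative`` is "less" or "greater" for the
    location of a relative to b.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal lengths")
        d = a - b
        if np.all(d == 0):
            return 1.0  # degenerate: no information
        return float(stats.wilcoxon(a, b, alternative=alternative).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative=alternative).pvalue)


def hypergeometric_enrichment(hits: int, draws: int, successes_in_pop: int,
                              pop: int) -> float:
    """Upper-tail hypergeometric P(X >= hits) for draws from a finite population."""
    if not (0 <= hits <= min(draws, successes_in_pop) <= pop) or draws > pop:
        raise ValueError(
            f"inconsistent counts: hits={hits}, draws={draws}, "
            f"successes={successes_in_pop}, pop={pop}"
        )
    return float(stats.hypergeom.sf(hits - 1, pop, successes_in_pop, draws))


@dataclass
class ResamplingResult:
    observed: int
    p_value: float
    null_mean: float
    null_sd: float
    reps: int
    null_counts: np.ndarray | None = None


def resampling_geneset_enrichment(pool, signature, geneset, reps: int = 10_000,
                                  seed: int = 0,
                                  keep_null: bool = False) -> ResamplingResult:
    """Empirical gene-set enrichment of a signature's target genes.

    The observed statistic is the number of *distinct* gene-set genes among
    the signature interactions' targets.  The null resamples ``len(signature)``
    interactions uniformly without replacement from the pool ``reps`` times;
    the p-value uses the add-one correction (1 + #{null >= obs}) / (reps + 1).
    """
    geneset = set(geneset)
    if not geneset:
        raise ValueError("empty gene set")
    pool = list(pool)
    signature = list(signature)
    if len(signature) > len(pool):
        raise ValueError("signature larger than pool")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    def count(pairs):
        return len({g for _, g in pairs} & geneset)

    observed = count(signature)
    pool_genes = np.array([g for _, g in pool], dtype=object)
    rng = np.random.default_rng(seed)
    n_sig = len(signature)
    null = np.empty(reps, dtype=int)
    for r in range(reps):
        idx = rng.choice(len(pool), size=n_sig, replace=False)
        null[r] = len(set(pool_genes[idx]) & geneset)
    p = (1 + int((null >= observed).sum())) / (reps + 1)
    return ResamplingResult(observed, p, float(null.mean()), float(null.std()),
                            reps, null if keep_null else None)


def mean_split(values):
    """Dichotomize at the sample mean: 'high' iff value > mean, ties to 'low'.

    Returns (labels, degenerate_flag); a constant vector is all-'low' and
    flagged degenerate.
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    labels = np.where(v > v.mean(), "high", "low")
    return labels, bool(np.ptp(v) == 0)


@dataclass
class KMEstimate:
    """Product-limit survival curve: right-continuous step function."""

    event_times: np.ndarray
    survival: np.ndarray   # S at each event time (after the drop)

    def __call__(self, t):
        t = np.asarray(t, float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if np.ndim(t) == 0 else out


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); censored
    records reduce the risk set only.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_["KM_estimate"]
    ev_times = np.unique(times[events == 1])
    surv = sf.reindex(ev_times, method="ffill").to_numpy(dtype=float)
    return KMEstimate(ev_times, surv)


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square test on one degree of freedom.

    Returns (statistic, p_value, degenerate); a comparison with no events or
    zero variance is degenerate with statistic 0 and p = 1.
    """
    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    ea = np.asarray(events_a, int)
    eb = np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0, True
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat, p = float(res.test_statistic), float(res.p_value)
    if not np.isfinite(stat) or not np.isfinite(p):
        return 0.0, 1.0, True
    return stat, p, False


def prognostic_screen(interactions, compendium, clinical: dict,
                      alpha: float = 0.1, min_events: int = 3,
                      comparison: list | None = None):
    """Mean-split log-rank screen over interactions and cohorts.

    For every interaction (miRNA, gene) and every cohort with usable
    clinical data, each member's expression is mean-split and tested by
    log-rank; the interaction is flagged in that cohort iff *both* members'
    p-values fall below ``alpha``.  Cohorts with fewer than ``min_events``
    observed events are skipped.

    Returns
    -------
    dict with keys ``flags`` (DataFrame of flagged interaction-cohort pairs
    with both p-values), ``counts`` (per-interaction number of flagging
    cohorts), ``skipped_cohorts``, and — when ``comparison`` is given — a
    2x2 ``contingency`` table (recurrent vs comparison x flagged-anywhere vs
    not) ready for an exact proportion test.
    """
    usable, skipped = [], []
    for ds in compendium.datasets:
        clin = clinical.get(ds.cancer_code)
        if clin is None:
            skipped.append(ds.cancer_code)
            continue
        clin = clin.set_index("sample").reindex(ds.gene_expr.sample_ids).dropna()
        if int(clin["event"].sum()) < min_events:
            skipped.append(ds.cancer_code)
            continue
        usable.append((ds, clin))
    if not usable:
        raise ValueError("no cohort with usable clinical data")

    def member_p(ds, clin, feature):
        if feature in ds.gene_expr.feature_ids:
            mat = ds.gene_expr
        elif feature in ds.mirna_expr.feature_ids:
            mat = ds.mirna_expr
        else:
            return None
        row = mat.values[mat.feature_ids.index(feature)]
        expr = pd.Series(row, index=mat.sample_ids).reindex(clin.index)
        labels, degen = mean_split(expr.to_numpy())
        if degen:
            return None
        hi = labels == "high"
        if hi.all() or (~hi).all():
            return None
        t = clin["time_days"].to_numpy()
        e = clin["event"].to_numpy().astype(int)
        _, p, degen = logrank_test(t[hi], e[hi], t[~hi], e[~hi])
        return None if degen else p

    def screen(pairs):
        rows = []
        for mir, gene in pairs:
            for ds, clin in usable:
                pg = member_p(ds, clin, gene)
                pm = member_p(ds, clin, mir)
                if pg is None or pm is None:
                    continue
                if pg < alpha and pm < alpha:
                    rows.append({"mirna": mir, "gene": gene,
                                 "cohort": ds.cancer_code,
                                 "p_gene": pg, "p_mirna": pm})
        return pd.DataFrame(rows, columns=["mirna", "gene", "cohort", "p_gene", "p_mirna"])

    flags = screen(interactions)
    counts = (flags.groupby(["mirna", "gene"]).size().rename("n_cohorts").reset_index()
              if len(flags) else
              pd.DataFrame(columns=["mirna", "gene", "n_cohorts"]))
    out = {"flags": flags, "counts": counts, "skipped_cohorts": skipped}

    if comparison is not None:
        comp_flags = screen(comparison)
        rec_hit = len(set(map(tuple, flags[["mirna", "gene"]].itertuples(index=False)))) \
            if len(flags) else 0
        cmp_hit = len(set(map(tuple, comp_flags[["mirna", "gene"]].itertuples(index=False)))) \
            if len(comp_flags) else 0
        out["contingency"] = np.array([
            [rec_hit, len(list(interactions)) - rec_hit],
            [cmp_hit, len(list(comparison)) - cmp_hit],
        ])
    return out
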