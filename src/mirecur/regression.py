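"""Per-cohort covariate-adjusted miRNA-target regression scoring.

For every (miRNA k, gene i) pair in cohort d the model

    y_i = b0 + b_cn * cn_i + b_dm * dm_i + b_mir * x_k + eps,   eps ~ N(0, s^2)

is fitted by ordinary least squares; the miRNA coefficient's t-statistic
(T - 4 residual df) is mapped through the t CDF and the standard-normal
quantile to a z-score that is N(0, 1) under the null of no interaction.
Copy number and promoter methylation act as per-gene nuisance covariates so
that dosage and epigenetic effects on target expression do not masquerade as
miRNA repression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .compendium import CancerDataset

Z_CAP_DEFAULT = 8.0


@dataclass
class RegressionFit:
    """OLS fit of one (gene, miRNA) pair in one cohort."""

    beta0: float
    beta_cn: float
    beta_dm: float
    beta_mir: float
    se_mir: float
    tstat: float
    df: int
    degenerate: bool = False
    dropped: tuple = field(default_factory=tuple)


def fit_interaction_regression(y, cn, dm, x) -> RegressionFit:
    """OLS fit of ``y ~ 1 + cn + dm + x`` returning the miRNA coefficient's t-statistic.

    Zero-variance covariates are dropped (recorded in ``dropped``) and the
    residual df adjusted accordingly.  A constant response, a zero-variance
    miRNA or a zero-residual fit yields ``tstat = 0`` with the degenerate
    flag set.
    """
    y = np.asarray(y, float)
    cn = np.asarray(cn, float)
    dm = np.asarray(dm, float)
    x = np.asarray(x, float)
    T = y.size
    if not (cn.size == dm.size == x.size == T):
        raise ValueError("all vectors must have the same length")
    if T < 5:
        raise ValueError(f"need T >= 5 samples, got {T}")

    # pairwise-complete: drop samples with any missing value
    ok = np.isfinite(y) & np.isfinite(cn) & np.isfinite(dm) & np.isfinite(x)
    y, cn, dm, x = y[ok], cn[ok], dm[ok], x[ok]
    T = y.size
    if T < 5:
        raise ValueError("fewer than 5 complete samples after missing-value drop")

    cols = [("const", np.ones(T)), ("cn", cn), ("dm", dm), ("mir", x)]
    dropped = tuple(n for n, v in cols[1:] if np.ptp(v) == 0)
    keep = [(n, v) for n, v in cols if n == "const" or np.ptp(v) > 0]
    names = [n for n, _ in keep]
    X = np.column_stack([v for _, v in keep])
    df = T - X.shape[1]

    betas = {"const": 0.0, "cn": 0.0, "dm": 0.0, "mir": 0.0}
    if "mir" not in names or np.ptp(y) == 0 or df < 1:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        for n, b in zip(names, coef):
            betas[n] = float(b)
        return RegressionFit(betas["const"], betas["cn"], betas["dm"], betas["mir"],
                             se_mir=np.nan, tstat=0.0, df=max(df, 1),
                             degenerate=True, dropped=dropped)

    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # collinear beyond zero-variance (e.g. cn == dm): drop later duplicates
        q, r = np.linalg.qr(X)
        indep = np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0])
        names = [n for n, k in zip(names, indep) if k]
        X = X[:, indep]
        dropped = dropped + tuple(n for n in ("cn", "dm") if n not in names)
        if "mir" not in names:
            return RegressionFit(0.0, 0.0, 0.0, 0.0, np.nan, 0.0,
                                 max(T - X.shape[1], 1), True, dropped)
        df = T - X.shape[1]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)

    resid = y - X @ coef
    rss = float(resid @ resid)
    for n, b in zip(names, coef):
        betas[n] = float(b)
    j = names.index("mir")
    XtX_inv = np.linalg.inv(X.T @ X)
    if df < 1 or rss <= max(1e-12 * float(y @ y), 0.0):
        return RegressionFit(betas["const"], betas["cn"], betas["dm"], betas["mir"],
                             np.nan, 0.0, max(df, 1), True, dropped)
    sigma2 = rss / df
    se = math.sqrt(sigma2 * XtX_inv[j, j])
    return RegressionFit(betas["const"], betas["cn"], betas["dm"], betas["mir"],
                         se, betas["mir"] / se, df, False, dropped)


def t_to_z(tstat: float, df: int, z_cap: float = Z_CAP_DEFAULT):
    """Map a t-statistic to a standard-normal z-score through the CDF.

    z = Phi^{-1}( F_t(t; df) ), computed on the log scale so that extreme
    tails do not underflow; |z| is capped at ``z_cap`` (flag returned).

    Returns
    -------
    (z, capped) : tuple of float and bool
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t = float(tstat)
    if t == 0.0:
        return 0.0, False
    # work in the lower tail of |t| for symmetric precision, restore sign after
    logp = stats.t.logcdf(-abs(t), df)
    z_neg = float(special.ndtri_exp(logp))  # Phi^-1(exp(logp)), stable in the far tail
    z = z_neg if t < 0 else -z_neg
    if abs(z) > z_cap:
        return math.copysign(z_cap, z), True
    return z, False


def score_cohort(ds: CancerDataset, z_cap: float = Z_CAP_DEFAULT,
                 pairs: list | None = None):
    """Compute the (M x N) z-score matrix for one cohort.

    Vectorized via Frisch-Waugh-Lovell: per gene, y and all miRNA profiles
    are residualized against [1, cn, dm]; the miRNA coefficient, its standard
    error and t-statistic then follow from the simple regression of the
    residuals, identical to the full OLS fit.

    Returns
    -------
    (z, mask) : z shape (M, N); mask True where a valid z was computed.
    """
    Y = ds.gene_expr.values        # N x T
    X = ds.mirna_expr.values       # M x T
    CN = ds.copy_number.values
    DM = ds.methylation.values
    N, T = Y.shape
    M = X.shape[0]
    z = np.zeros((M, N))
    mask = np.zeros((M, N), dtype=bool)
    capped = np.zeros((M, N), dtype=bool)

    pair_cols = None
    if pairs is not None:
        pair_cols = {}
        gpos = {g: i for i, g in enumerate(ds.genes)}
        mpos = {m: k for k, m in enumerate(ds.mirnas)}
        for mir, gene in pairs:
            if mir in mpos and gene in gpos:
                pair_cols.setdefault(gpos[gene], []).append(mpos[mir])

    Xc = X - X.mean(axis=1, keepdims=True)
    x_has_var = np.ptp(X, axis=1) > 0
    any_missing = not (np.isfinite(Y).all() and np.isfinite(X).all()
                       and np.isfinite(CN).all() and np.isfinite(DM).all())

    for i in range(N):
        if pair_cols is not None and i not in pair_cols:
            continue
        ks = pair_cols[i] if pair_cols is not None else None
        row_missing = any_missing and not (
            np.isfinite(Y[i]).all() and np.isfinite(CN[i]).all()
            and np.isfinite(DM[i]).all() and np.isfinite(X).all()
        )
        if row_missing:
            # fall back to the per-pair path with pairwise-complete samples
            for k in (ks if ks is not None else range(M)):
                try:
                    fit = fit_interaction_regression(Y[i], CN[i], DM[i], X[k])
                except ValueError:
                    continue
                if not fit.degenerate:
                    z[k, i], capped[k, i] = t_to_z(fit.tstat, fit.df, z_cap)
                    mask[k, i] = True
            continue

        covs = [np.ones(T)]
        for v in (CN[i], DM[i]):
            if np.ptp(v) > 0:
                covs.append(v)
        Zc = np.column_stack(covs)  # T x p
        Q, _ = np.linalg.qr(Zc)
        ry = Y[i] - Q @ (Q.T @ Y[i])
        rX = Xc - (Xc @ Q) @ Q.T    # miRNA residuals, M x T
        df = T - Zc.shape[1] - 1
        if df < 1:
            continue
        sxx = np.einsum("kt,kt->k", rX, rX)
        sxy = rX @ ry
        syy = float(ry @ ry)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            rss = syy - beta * sxy
            rss = np.maximum(rss, 0.0)
            se = np.sqrt(rss / df / sxx)
            tvals = beta / se
        valid = x_has_var & (sxx > 0) & (se > 0) & np.isfinite(tvals) \
            & (rss > 1e-12 * max(syy, 1e-300)) & (syy > 0)
        for k in (ks if ks is not None else range(M)):
            if valid[k]:
                z[k, i], capped[k, i] = t_to_z(tvals[k], df, z_cap)
                mask[k, i] = True
    return z, mask


@dataclass
class ZScoreTensor:
    """Per-cohort interaction z-scores, shape (M, N, D), plus validity mask."""

    z: np.ndarray
    computed_mask: np.ndarray
    mirnas: list
    genes: list
    cohorts: list

    @property
    def D(self) -> int:
        return self.z.shape[2]


def score_compendium(comp, z_cap: float = Z_CAP_DEFAULT,
                     pairs: list | None = None) -> ZScoreTensor:
    """Score every cohort of a compendium; stacks per-cohort z matrices."""
    zs, masks = [], []
    for ds in comp.datasets:
        z, m = score_cohort(ds, z_cap=z_cap, pairs=pairs)
        zs.append(z)
        masks.append(m)
    return ZScoreTensor(
        np.stack(zs, axis=2), np.stack(masks, axis=2),
        comp.common_mirnas, comp.common_genes,
        [ds.cancer_code for ds in comp.datasets],
    )


@dataclass
class CandidateSet:
    """Pairs with negative z in at least ``ceil(frac * D)`` cohorts."""

    pairs: list            # list of (k, i) index tuples
    neg_count: np.ndarray  # per-pair count of cohorts with z < 0
    frac: float
    required: int


def filter_candidates(zt: ZScoreTensor, frac: float = 0.75) -> CandidateSet:
    """Retain pairs whose z-score is strictly negative in >= ceil(frac*D) cohorts.

    Masked (uncomputed) cohort entries never count as negative; z == 0 counts
    as non-negative.
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    D = zt.D
    required = math.ceil(frac * D)
    neg = ((zt.z < 0) & zt.computed_mask).sum(axis=2)  # M x N
    ks, iis = np.nonzero(neg >= required)
    pairs = list(zip(ks.tolist(), iis.tolist()))
    return CandidateSet(pairs, neg[ks, iis], frac, required)
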