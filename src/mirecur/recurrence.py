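"""Empirical-Bayes EM over latent binary interaction configurations.

Each candidate pair carries a latent binary vector (t_1, ..., t_D) saying in
which cohorts the interaction is real.  Given per-cohort likelihoods
L0_d = p(z_d | t_d = 0) and L1_d = p(z_d | t_d = 1) and conditional
independence of the z's given the t's, the joint likelihood of a
configuration factorizes over cohorts.  A single prior over all 2^D
configurations is shared by every pair, initialized uniform (1/2^D each),
and refined by EM: the E-step computes each pair's configuration posterior
by Bayes rule, the M-step re-estimates the prior as the average posterior
over pairs.  Iteration stops when the total log-likelihood (sum of per-pair
log-evidence) increases by less than ``tol`` (default 1e-5).  The recurrence
posterior of a pair is the posterior mass of the all-ones configuration —
the probability the interaction is active in every cohort simultaneously.

Configurations are enumerated with cohort 1 as the least-significant bit, so
configuration index c activates cohort d iff bit (d - 1) of c is set; the
all-ones configuration is index 2^D - 1.  All products are accumulated in
log space and normalized with log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

CONFIG_ENUM_LIMIT = 20


class RecurrenceError(ValueError):
    pass


def config_bits(D: int) -> np.ndarray:
    """(2^D, D) binary matrix: row c holds the configuration bits, cohort 1 = LSB."""
    if D > CONFIG_ENUM_LIMIT:
        raise RecurrenceError(
            f"D = {D} exceeds the configuration enumeration limit "
            f"({CONFIG_ENUM_LIMIT}); full 2^D enumeration is infeasible"
        )
    c = np.arange(2**D)[:, None]
    return ((c >> np.arange(D)[None, :]) & 1).astype(float)


def config_log_likelihood(L0, L1) -> np.ndarray:
    """Log-likelihood of every configuration for one pair (or a batch of pairs).

    Entry c equals sum_d log(L1_d if bit d of c else L0_d).  Accepts 1-D
    vectors of length D or 2-D arrays (n_pairs, D); returns (2^D,) or
    (n_pairs, 2^D) accordingly.
    """
    L0 = np.asarray(L0, float)
    L1 = np.asarray(L1, float)
    if L0.shape != L1.shape:
        raise RecurrenceError(f"L0/L1 shape mismatch: {L0.shape} vs {L1.shape}")
    single = L0.ndim == 1
    if single:
        L0, L1 = L0[None, :], L1[None, :]
    D = L0.shape[1]
    bits = config_bits(D)                      # (C, D)
    ll = np.log(L0) @ (1.0 - bits.T) + np.log(L1) @ bits.T   # (n, C)
    return ll[0] if single else ll


@dataclass
class ConfigPrior:
    """Shared prior over the 2^D binary configurations (cohort 1 = LSB)."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, float)
        C = self.probs.size
        if C & (C - 1):
            raise RecurrenceError("prior length must be a power of two")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise RecurrenceError("prior must be a probability vector")

    @property
    def D(self) -> int:
        return int(np.log2(self.probs.size))

    @classmethod
    def uniform(cls, D: int) -> "ConfigPrior":
        if D > CONFIG_ENUM_LIMIT:
            raise RecurrenceError(
                f"D = {D} exceeds the configuration enumeration limit "
                f"({CONFIG_ENUM_LIMIT})"
            )
        C = 2**D
        return cls(np.full(C, 1.0 / C))


def e_step(prior: ConfigPrior, loglik: np.ndarray):
    """Posterior over configurations for each pair, plus per-pair log-evidence.

    posterior(c) proportional to prior(c) * exp(loglik(c)), normalized via
    log-sum-exp; log-evidence is the log of the normalizing constant.
    """
    loglik = np.atleast_2d(np.asarray(loglik, float))
    with np.errstate(divide="ignore"):
        logprior = np.log(prior.probs)
    joint = loglik + logprior[None, :]
    logev = logsumexp(joint, axis=1)
    post = np.exp(joint - logev[:, None])
    return post, logev


def m_step(posteriors: np.ndarray) -> ConfigPrior:
    """Re-estimate the shared prior as the mean posterior over pairs."""
    posteriors = np.atleast_2d(np.asarray(posteriors, float))
    if posteriors.shape[0] == 0:
        raise RecurrenceError("m_step needs at least one pair")
    probs = posteriors.mean(axis=0)
    return ConfigPrior(probs / probs.sum())


@dataclass
class RecurrenceResult:
    """EM output: per-pair recurrence posteriors and convergence diagnostics."""

    recurrence_posterior: np.ndarray   # mass of the all-ones configuration
    prior: ConfigPrior
    loglik_trace: list
    n_iter: int
    converged: bool
    posteriors: np.ndarray | None = None   # full (n_pairs, 2^D), optional


def run_em(L0: np.ndarray, L1: np.ndarray, tol: float = 1e-5,
           max_iter: int = 200, keep_posteriors: bool = False,
           relative: bool = False, chunk_size: int = 200_000) -> RecurrenceResult:
    """Fit the shared configuration prior by EM and return recurrence posteriors.

    Parameters
    ----------
    L0, L1 : arrays of shape (n_pairs, D)
        Per-cohort likelihoods of each pair's z-score under no-interaction
        and interaction (strictly positive; floored upstream).
    tol : float
        Stop when the total log-likelihood increases by less than this
        (absolute by default; set ``relative=True`` for relative change).
    chunk_size : int
        Pairs are streamed in chunks of this size so the (n_pairs, 2^D)
        posterior block is never fully materialized.

    The procedure is deterministic: no randomness is involved.
    """
    L0 = np.asarray(L0, float)
    L1 = np.asarray(L1, float)
    if L0.shape != L1.shape or L0.ndim != 2:
        raise RecurrenceError("L0 and L1 must be (n_pairs, D) arrays of equal shape")
    if (L0 <= 0).any() or (L1 <= 0).any():
        raise RecurrenceError("likelihoods must be strictly positive (apply the floor)")
    n_pairs, D = L0.shape
    if n_pairs == 0:
        raise RecurrenceError("no candidate pairs")
    C = 2**D if D <= CONFIG_ENUM_LIMIT else None
    if C is None:
        raise RecurrenceError(
            f"D = {D} exceeds the configuration enumeration limit "
            f"({CONFIG_ENUM_LIMIT}); reduce D or restrict cohorts"
        )

    bits = config_bits(D)
    logL0, logL1 = np.log(L0), np.log(L1)

    def chunk_loglik(sl):
        return logL0[sl] @ (1.0 - bits.T) + logL1[sl] @ bits.T

    prior = ConfigPrior.uniform(D)
    trace: list = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        total = 0.0
        acc = np.zeros(C)
        for start in range(0, n_pairs, chunk_size):
            sl = slice(start, min(start + chunk_size, n_pairs))
            post, logev = e_step(prior, chunk_loglik(sl))
            total += float(logev.sum())
            acc += post.sum(axis=0)
        trace.append(total)
        new_prior = ConfigPrior(acc / acc.sum())
        if len(trace) >= 2:
            delta = trace[-1] - trace[-2]
            if relative:
                delta = abs(delta) / max(abs(trace[-2]), 1e-300)
            if delta < tol:
                converged = True
                prior = new_prior
                break
        prior = new_prior

    # final posteriors under the converged prior
    rec = np.empty(n_pairs)
    full = np.empty((n_pairs, C)) if keep_posteriors else None
    for start in range(0, n_pairs, chunk_size):
        sl = slice(start, min(start + chunk_size, n_pairs))
        post, _ = e_step(prior, chunk_loglik(sl))
        rec[sl] = post[:, C - 1]
        if full is not None:
            full[sl] = post
    return RecurrenceResult(rec, prior, trace, it, converged, full)


def recurrence_table(result: RecurrenceResult, pairs, zt,
                     positive_cutoff: float = 0.0,
                     high_conf_cutoff: float = 0.2) -> pd.DataFrame:
    """Ranked table of candidate pairs with posteriors and per-cohort z-scores.

    Sorted by recurrence posterior descending, then gene id ascending and
    miRNA id ascending as deterministic tie-breaks.  ``positive`` flags
    posterior > ``positive_cutoff``; ``high_confidence`` flags posterior >=
    ``high_conf_cutoff``.
    """
    rows = []
    for (k, i), post in zip(pairs, result.recurrence_posterior):
        row = {
            "mirna": zt.mirnas[k],
            "gene": zt.genes[i],
            "recurrence_posterior": post,
        }
        for d, code in enumerate(zt.cohorts):
            row[f"z_{code}"] = zt.z[k, i, d] if zt.computed_mask[k, i, d] else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df["positive"] = df["recurrence_posterior"] > positive_cutoff
    df["high_confidence"] = df["recurrence_posterior"] >= high_conf_cutoff
    return df.sort_values(
        ["recurrence_posterior", "gene", "mirna"],
        ascending=[False, True, True], kind="mergesort",
    ).reset_index(drop=True)
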