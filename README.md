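# mirecur

Inference of **recurrent miRNA–target interactions** across multiple cancer
cohorts from paired expression, copy-number and DNA-methylation matrices.

MicroRNAs repress their target genes, but a negative expression correlation
observed in a single tumour cohort is hard to interpret: sample size,
tumour purity and platform effects make the same coefficient "significant"
in one cohort and not in another. `mirecur` asks a sharper question — for
which (miRNA, gene) pairs is the repressive association present in *all* D
cohorts simultaneously — and answers it with a posterior probability rather
than an arbitrary score cutoff.

## Model

For gene *i*, miRNA *k*, cohort *d*, target expression is regressed on the
gene's copy number (cn), promoter methylation (dm) and the miRNA (OLS):

    y_i = β0 + β_cn·cn_i + β_dm·dm_i + β_mir·x_k + ε

The miRNA coefficient's t-statistic (T − 4 df) becomes a z-score
z = Φ⁻¹(F_t(t)), N(0, 1) under the null. Pairs with z < 0 in ≥ 75% of
cohorts are candidates. Per cohort, the candidate z's are decomposed into
null and interaction components by an empirical-Bayes two-group model
(local false discovery rate: Lindsey density estimate + empirical null by
central matching), yielding likelihoods L0 = p(z|no interaction) and
L1 = p(z|interaction). Each pair's latent activity pattern across cohorts
is one of 2^D binary configurations; a shared prior over configurations is
fitted by EM (uniform start, E-step by Bayes rule, M-step averaging
posteriors, stop when the total log-likelihood gain < 1e-5). The
**recurrence posterior** is the posterior mass of the all-ones
configuration. The rank-based REC score (normalized ranks rr = r/N − 1/2N,
Fisher combination s = −2Σ ln rr vs χ²(2D), positive iff
REC = log10 P(χ²_2D ≤ s) < −1) is included as a baseline, along with
reference-overlap, enrichment and mean-split Kaplan–Meier/log-rank
prognostic screens.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Everything is runnable without external data through the bundled synthetic
compendium generator, which plants known recurrent and cohort-specific
interactions:

```python
import numpy as np
import mirecur as m
from mirecur.locfdr import fit_locfdr, derive_likelihoods
from mirecur.simulate import pair_labels

cfg = m.SimulationConfig(seed=11)        # D=4 cohorts, 300 genes x 30 miRNAs
comp, truth = m.simulate_compendium(cfg)
zt = m.score_compendium(comp)            # (30, 300, 4) z-score tensor
cand = m.filter_candidates(zt)           # z < 0 in >= 3 of 4 cohorts
ks = np.array([k for k, _ in cand.pairs]); iis = np.array([i for _, i in cand.pairs])
L0 = np.empty((len(cand.pairs), zt.D)); L1 = np.empty_like(L0)
for d in range(zt.D):
    z = zt.z[ks, iis, d]
    fit = fit_locfdr(z)
    print(f"cohort {d}: p0={fit.p0:.3f} null=({fit.null_mean:+.3f}, {fit.null_sd:.3f})")
    lik = derive_likelihoods(fit, z)
    L0[:, d], L1[:, d] = lik.L0, lik.L1
res = m.run_em(L0, L1)
lab = pair_labels(truth, comp.M, comp.N)[ks, iis]
post = res.recurrence_posterior
print(f"candidates={len(cand.pairs)}  EM iters={res.n_iter}")
print(f"mean posterior: recurrent={post[lab=='recurrent'].mean():.3f} "
      f"specific={post[lab=='cohort_specific'].mean():.3f} "
      f"null={post[lab=='null'].mean():.4f}")
```

Output:

```
cohort 0: p0=0.851 null=(-0.482, 0.700)
cohort 1: p0=0.820 null=(-0.543, 0.626)
cohort 2: p0=0.844 null=(-0.529, 0.666)
cohort 3: p0=0.831 null=(-0.551, 0.681)
candidates=3004  EM iters=59
mean posterior: recurrent=1.000 specific=0.020 null=0.0043
```

The candidate set is negatively skewed by construction, so the fitted
empirical null sits left of zero with sub-unit spread, and most candidate
z-scores are still attributed to the null (p0 ≈ 0.84). Planted recurrent pairs
receive posterior ≈ 1, cohort-specific pairs (same effect size, one cohort)
are correctly down-weighted ~100-fold, and null pairs sit near zero.

The same pipeline is available as a CLI over a YAML config
(`mirecur --config cfg.yaml run`, stage verbs `simulate preprocess score
locfdr infer rec evaluate survival`), writing TSV artifacts and a manifest
that makes re-runs idempotent.

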