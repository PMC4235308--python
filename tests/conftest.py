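import numpy as np
import pytest

import mirecur as m
from mirecur.locfdr import derive_likelihoods, fit_locfdr


@pytest.fixture(scope="session")
def small_compendium():
    """Small planted compendium: D=3, 60 genes, 8 miRNAs, 40 samples."""
    cfg = m.SimulationConfig(D=3, N=60, M=8, T=40, seed=7)
    return m.simulate_compendium(cfg)


@pytest.fixture(scope="session")
def default_run():
    """Full inference run on the default planted compendium (D=4, 300x30, T=60).

    Computed once per session; reused by recovery and invariant tests.
    """
    cfg = m.SimulationConfig(seed=11)
    comp, truth = m.simulate_compendium(cfg)
    zt = m.score_compendium(comp)
    cand = m.filter_candidates(zt)
    ks = np.array([k for k, _ in cand.pairs])
    iis = np.array([i for _, i in cand.pairs])
    D = zt.D
    L0 = np.empty((len(cand.pairs), D))
    L1 = np.empty_like(L0)
    fits = []
    for d in range(D):
        zv = zt.z[ks, iis, d]
        fit = fit_locfdr(zv)
        lik = derive_likelihoods(fit, zv)
        L0[:, d], L1[:, d] = lik.L0, lik.L1
        fits.append(fit)
    result = m.run_em(L0, L1)
    return {
        "comp": comp, "truth": truth, "zt": zt, "cand": cand,
        "ks": ks, "iis": iis, "L0": L0, "L1": L1, "fits": fits,
        "result": result,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
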