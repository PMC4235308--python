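"""Configuration-driven orchestration of the full inference pipeline.

Stages (dependency order): ``simulate`` (optional synthetic inputs),
``preprocess`` (read + align cohort matrices), ``score`` (per-cohort
z-tensor), ``locfdr`` (candidate filter + two-group fits + likelihoods),
``infer`` (recurrence EM), ``rec`` (rank-based baseline), ``evaluate``
(reference overlap), ``survival`` (prognostic screen).  Every artifact is a
TSV (plus an npz cache for the z-tensor and likelihoods); a manifest records
the config hash, seeds and stage outputs so re-runs skip up-to-date stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import compendium as comp_mod
from . import evaluate as eval_mod
from . import locfdr as locfdr_mod
from . import rec as rec_mod
from . import recurrence as rec_inf
from . import regression as reg_mod
from . import simulate as sim_mod

log = logging.getLogger("mirecur")

STAGE_ORDER = ["simulate", "preprocess", "score", "locfdr", "infer", "rec",
               "evaluate", "survival"]
STAGE_DEPS = {
    "preprocess": [],
    "score": ["preprocess"],
    "locfdr": ["score"],
    "infer": ["locfdr"],
    "rec": ["score"],
    "evaluate": ["infer"],
    "survival": ["infer"],
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "mirecur_out"
    seed: int = 0
    cohorts: dict = field(default_factory=dict)   # code -> {gene_expr, mirna_expr, ...}
    simulate: dict | None = None                  # SimulationConfig overrides
    prevalence_frac: float = 0.05
    raw_expression: bool = False                  # apply prevalence + log2 on read
    candidate_frac: float = 0.75
    z_cap: float = 8.0
    locfdr: dict = field(default_factory=dict)    # n_bins, poly_df, mode, min_n, ...
    tol: float = 1e-5
    max_iter: int = 200
    posterior_positive: float = 0.0
    posterior_high_conf: float = 0.2
    rec_cutoff: float = -1.0
    survival_alpha: float = 0.1
    reference_pairs: str | None = None
    chunk_size: int = 200_000

    def validate(self):
        if not (0 < self.prevalence_frac <= 1):
            raise ConfigError("prevalence_frac must be in (0, 1]")
        if not (0 < self.candidate_frac <= 1):
            raise ConfigError("candidate_frac must be in (0, 1]")
        if self.tol <= 0:
            raise ConfigError("tol must be positive")
        if not (0 < self.survival_alpha < 1):
            raise ConfigError("survival_alpha must be in (0, 1)")
        if self.simulate is None and not self.cohorts:
            raise ConfigError("config needs either a 'simulate' block or 'cohorts'")
        for code, paths in self.cohorts.items():
            for key in ("gene_expr", "mirna_expr", "copy_number", "methylation"):
                if key not in paths:
                    raise ConfigError(f"cohort {code}: missing path for {key}")
                if not os.path.exists(paths[key]):
                    raise ConfigError(f"cohort {code}: {paths[key]} does not exist")
        if self.reference_pairs and not os.path.exists(self.reference_pairs):
            raise ConfigError(f"reference_pairs file {self.reference_pairs} missing")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    blob = yaml.safe_dump(
        {k: getattr(cfg, k) for k in sorted(PipelineConfig.__dataclass_fields__)},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _resolve_stages(requested):
    if requested is None:
        return [s for s in STAGE_ORDER if s != "simulate"]
    return [s for s in STAGE_ORDER if s in set(requested)]


class PipelineState:
    """In-memory artifacts handed between stages within one run."""

    def __init__(self):
        self.compendium = None
        self.truth = None
        self.clinical = {}
        self.ztensor = None
        self.candidates = None
        self.likelihoods = None   # (L0, L1) arrays (n_pairs, D)
        self.result = None
        self.table = None


def run_pipeline(cfg: PipelineConfig, stages=None, force: bool = False) -> dict:
    """Execute the requested stages in dependency order.

    Returns the manifest dict; raises :class:`ConfigError` on validation
    problems and ``FileNotFoundError`` naming the stage to run when an
    upstream artifact is missing.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    chash = config_hash(cfg)
    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    manifest = {"config_hash": chash, "seed": cfg.seed, "stages": {}}
    if os.path.exists(manifest_path):
        try:
            with open(manifest_path) as fh:
                prev = json.load(fh)
            if prev.get("config_hash") == chash:
                manifest["stages"] = prev.get("stages", {})
        except (json.JSONDecodeError, OSError):
            pass

    state = PipelineState()
    wanted = _resolve_stages(stages)
    if stages is None:
        # drop optional downstream stages whose inputs are not configured
        has_clinical = (cfg.simulate or {}).get("survival") is not None or any(
            "clinical" in paths for paths in cfg.cohorts.values())
        if not has_clinical:
            wanted = [s for s in wanted if s != "survival"]
        if not cfg.reference_pairs:
            wanted = [s for s in wanted if s != "evaluate"]
    if cfg.simulate is not None and "preprocess" in wanted and "simulate" not in wanted:
        wanted = ["simulate"] + wanted

    def outputs_exist(stage):
        info = manifest["stages"].get(stage)
        return bool(info) and all(os.path.exists(p) for p in info.get("outputs", []))

    def transitive_deps(stage):
        seen, frontier = set(), list(STAGE_DEPS.get(stage, []))
        while frontier:
            d = frontier.pop()
            if d not in seen:
                seen.add(d)
                frontier.extend(STAGE_DEPS.get(d, []))
        return [s for s in STAGE_ORDER if s in seen]

    for stage in wanted:
        # hydrate upstream state from on-disk artifacts for deps not being run
        for dep in transitive_deps(stage):
            if dep not in wanted:
                _load_cached(dep, cfg, state)
        if not force and outputs_exist(stage) and _load_cached(stage, cfg, state):
            log.info("stage %s up-to-date, skipped", stage)
            manifest["stages"][stage]["skipped"] = True
            continue
        t0 = time.time()
        outputs = _STAGE_FUNCS[stage](cfg, state)
        manifest["stages"][stage] = {
            "outputs": outputs, "wall_s": round(time.time() - t0, 3),
            "skipped": False,
        }
        log.info("stage %s done in %.2fs (%d outputs)", stage,
                 time.time() - t0, len(outputs))
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------- stages

def _stage_simulate(cfg: PipelineConfig, state: PipelineState):
    sim_kwargs = dict(cfg.simulate or {})
    survival_kwargs = sim_kwargs.pop("survival", None)
    sim_cfg = sim_mod.SimulationConfig(seed=cfg.seed, **sim_kwargs)
    comp, truth = sim_mod.simulate_compendium(sim_cfg)
    state.compendium, state.truth = comp, truth
    outdir = os.path.join(cfg.outdir, "inputs")
    mani = sim_mod.write_compendium_tsvs(comp, outdir)
    outputs = [p for paths in mani.values() for p in paths.values()]
    tpath = os.path.join(outdir, "ground_truth.tsv")
    truth.labels.to_csv(tpath, sep="\t", index=False)
    outputs.append(tpath)
    if survival_kwargs is not None:
        scfg = sim_mod.SurvivalConfig(seed=cfg.seed + 1, **survival_kwargs)
        state.clinical = sim_mod.simulate_survival(comp, scfg)
        for code, df in state.clinical.items():
            p = os.path.join(outdir, f"{code}_clinical.tsv")
            df.to_csv(p, sep="\t", index=False)
            outputs.append(p)
    return outputs


def _stage_preprocess(cfg: PipelineConfig, state: PipelineState):
    if state.compendium is None:
        if not cfg.cohorts:
            raise FileNotFoundError(
                "no compendium in memory and no cohort paths configured; "
                "run stage 'simulate' or declare cohorts"
            )
        datasets = []
        for code, paths in cfg.cohorts.items():
            ge = comp_mod.read_matrix(paths["gene_expr"], "gene_expr_log2")
            me = comp_mod.read_matrix(paths["mirna_expr"], "mirna_expr_log2")
            if cfg.raw_expression:
                ge = comp_mod.log2_zero_replace(
                    comp_mod.filter_prevalence(ge, cfg.prevalence_frac))
                me = comp_mod.log2_zero_replace(
                    comp_mod.filter_prevalence(me, cfg.prevalence_frac))
            cn = comp_mod.read_matrix(paths["copy_number"], "copy_number")
            dm = comp_mod.read_matrix(paths["methylation"], "methylation_beta")
            genes = [g for g in ge.feature_ids
                     if g in set(cn.feature_ids) and g in set(dm.feature_ids)]
            ge = ge.reindex_features(genes)
            cn = cn.reindex_features(genes)
            dm = dm.reindex_features(genes)
            clin = None
            if "clinical" in paths:
                state.clinical[code] = comp_mod.read_clinical(paths["clinical"])
            datasets.append(comp_mod.CancerDataset(code, ge, me, cn, dm, clin))
        state.compendium = comp_mod.build_compendium(datasets)
    comp = state.compendium
    summary = pd.DataFrame({
        "cohort": [ds.cancer_code for ds in comp.datasets],
        "samples": [ds.T for ds in comp.datasets],
        "genes": comp.N, "mirnas": comp.M,
    })
    p = os.path.join(cfg.outdir, "compendium_summary.tsv")
    summary.to_csv(p, sep="\t", index=False)
    return [p]


def _stage_score(cfg: PipelineConfig, state: PipelineState):
    if state.compendium is None:
        raise FileNotFoundError("compendium missing; run stage 'preprocess' first")
    zt = reg_mod.score_compendium(state.compendium, z_cap=cfg.z_cap)
    state.ztensor = zt
    npz = os.path.join(cfg.outdir, "ztensor.npz")
    np.savez_compressed(npz, z=zt.z, mask=zt.computed_mask,
                        mirnas=np.array(zt.mirnas), genes=np.array(zt.genes),
                        cohorts=np.array(zt.cohorts))
    outputs = [npz]
    for d, code in enumerate(zt.cohorts):
        df = pd.DataFrame({
            "mirna": np.repeat(zt.mirnas, len(zt.genes)),
            "gene": np.tile(zt.genes, len(zt.mirnas)),
            "z": zt.z[:, :, d].ravel(),
            "computed": zt.computed_mask[:, :, d].ravel().astype(int),
        })
        p = os.path.join(cfg.outdir, f"zscores_{code}.tsv")
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        outputs.append(p)
    return outputs


def _stage_locfdr(cfg: PipelineConfig, state: PipelineState):
    zt = state.ztensor
    if zt is None:
        raise FileNotFoundError("z-tensor missing; run stage 'score' first")
    cand = reg_mod.filter_candidates(zt, cfg.candidate_frac)
    state.candidates = cand
    ks = np.array([k for k, _ in cand.pairs])
    iis = np.array([i for _, i in cand.pairs])
    D = zt.D
    n = len(cand.pairs)
    L0 = np.empty((n, D))
    L1 = np.empty((n, D))
    rows = []
    opts = dict(cfg.locfdr)
    for d in range(D):
        zvals = zt.z[ks, iis, d]
        fit = locfdr_mod.fit_locfdr(zvals, **opts)
        lik = locfdr_mod.derive_likelihoods(fit, zvals)
        L0[:, d], L1[:, d] = lik.L0, lik.L1
        rows.append({"cohort": zt.cohorts[d], "p0": fit.p0,
                     "null_mean": fit.null_mean, "null_sd": fit.null_sd,
                     "n": fit.n, "mode": fit.mode})
    state.likelihoods = (L0, L1)
    outputs = []
    p = os.path.join(cfg.outdir, "locfdr_summary.tsv")
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    p = os.path.join(cfg.outdir, "candidates.tsv")
    pd.DataFrame({
        "mirna": [zt.mirnas[k] for k in ks],
        "gene": [zt.genes[i] for i in iis],
        "neg_count": cand.neg_count,
    }).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    p = os.path.join(cfg.outdir, "likelihoods.npz")
    np.savez_compressed(p, L0=L0, L1=L1, ks=ks, iis=iis)
    outputs.append(p)
    return outputs


def _stage_infer(cfg: PipelineConfig, state: PipelineState):
    if state.likelihoods is None:
        raise FileNotFoundError("likelihoods missing; run stage 'locfdr' first")
    if state.ztensor is None:
        raise FileNotFoundError("z-tensor missing; run stage 'score' first")
    L0, L1 = state.likelihoods
    result = rec_inf.run_em(L0, L1, tol=cfg.tol, max_iter=cfg.max_iter,
                            chunk_size=cfg.chunk_size)
    state.result = result
    table = rec_inf.recurrence_table(result, state.candidates.pairs, state.ztensor,
                                     cfg.posterior_positive, cfg.posterior_high_conf)
    state.table = table
    outputs = []
    p = os.path.join(cfg.outdir, "recurrence_table.tsv")
    table.to_csv(p, sep="\t", index=False, float_format="%.6g")
    outputs.append(p)
    p = os.path.join(cfg.outdir, "config_prior.tsv")
    pd.DataFrame({"configuration": np.arange(result.prior.probs.size),
                  "prior": result.prior.probs}).to_csv(
        p, sep="\t", index=False, float_format="%.10g")
    outputs.append(p)
    p = os.path.join(cfg.outdir, "em_trace.tsv")
    pd.DataFrame({"iteration": np.arange(1, len(result.loglik_trace) + 1),
                  "loglik": result.loglik_trace}).to_csv(
        p, sep="\t", index=False, float_format="%.10g")
    outputs.append(p)
    log.info("EM converged=%s after %d iterations; %d positive, %d high-confidence",
             result.converged, result.n_iter,
             int(table["positive"].sum()), int(table["high_confidence"].sum()))
    return outputs


def _stage_rec(cfg: PipelineConfig, state: PipelineState):
    zt = state.ztensor
    if zt is None:
        raise FileNotFoundError("z-tensor missing; run stage 'score' first")
    rec = rec_mod.rec_scores(zt.z)
    df = rec_mod.rec_table(rec, None, zt.mirnas, zt.genes, cfg.rec_cutoff)
    p = os.path.join(cfg.outdir, "rec_scores.tsv")
    df.to_csv(p, sep="\t", index=False, float_format="%.6g")
    return [p]


def _stage_evaluate(cfg: PipelineConfig, state: PipelineState):
    if state.table is None:
        raise FileNotFoundError("recurrence table missing; run stage 'infer' first")
    outputs = []
    if cfg.reference_pairs:
        ref = comp_mod.read_pair_list(cfg.reference_pairs)
        ranked = list(zip(state.table["mirna"], state.table["gene"]))
        n = len(ranked)
        ks = [k for k in eval_mod.DEFAULT_KS if k <= n] or [n]
        curve = eval_mod.topk_overlap_curve(ranked, ref, ks)
        shuffled = eval_mod.shuffle_baseline(ranked, cfg.seed)
        curve["count_shuffled"] = eval_mod.topk_overlap_curve(shuffled, ref, ks)["count"]
        p = os.path.join(cfg.outdir, "topk_overlap.tsv")
        curve.to_csv(p, sep="\t", index=False)
        outputs.append(p)
    return outputs


def _stage_survival(cfg: PipelineConfig, state: PipelineState):
    if state.table is None:
        raise FileNotFoundError("recurrence table missing; run stage 'infer' first")
    if not state.clinical:
        raise FileNotFoundError("no clinical tables available for the survival screen")
    high = state.table[state.table["high_confidence"]]
    pairs = list(zip(high["mirna"], high["gene"]))
    if not pairs:
        pairs = list(zip(state.table["mirna"], state.table["gene"]))[:50]
    res = eval_mod.prognostic_screen(pairs, state.compendium, state.clinical,
                                     alpha=cfg.survival_alpha)
    p = os.path.join(cfg.outdir, "prognostic_flags.tsv")
    res["flags"].to_csv(p, sep="\t", index=False, float_format="%.6g")
    return [p]


def _load_cached(stage, cfg, state) -> bool:
    """Rehydrate in-memory state from a previous run's artifacts where possible."""
    try:
        if stage == "score":
            npz = np.load(os.path.join(cfg.outdir, "ztensor.npz"), allow_pickle=False)
            state.ztensor = reg_mod.ZScoreTensor(
                npz["z"], npz["mask"], list(npz["mirnas"]), list(npz["genes"]),
                list(npz["cohorts"]))
            return True
        if stage == "locfdr":
            npz = np.load(os.path.join(cfg.outdir, "likelihoods.npz"))
            state.likelihoods = (npz["L0"], npz["L1"])
            pairs = list(zip(npz["ks"].tolist(), npz["iis"].tolist()))
            neg = np.zeros(len(pairs), dtype=int)
            state.candidates = reg_mod.CandidateSet(pairs, neg, cfg.candidate_frac, 0)
            return True
        if stage == "infer":
            path = os.path.join(cfg.outdir, "recurrence_table.tsv")
            state.table = pd.read_csv(path, sep="\t")
            return True
        if stage == "simulate":
            indir = os.path.join(cfg.outdir, "inputs")
            sim_kwargs = dict(cfg.simulate or {})
            D = sim_kwargs.get("D", sim_mod.SimulationConfig.D)
            datasets = []
            for d in range(D):
                code = f"SYN{d}"
                datasets.append(comp_mod.CancerDataset(
                    code,
                    comp_mod.read_matrix(os.path.join(indir, f"{code}_gene_expr.tsv"),
                                         "gene_expr_log2"),
                    comp_mod.read_matrix(os.path.join(indir, f"{code}_mirna_expr.tsv"),
                                         "mirna_expr_log2"),
                    comp_mod.read_matrix(os.path.join(indir, f"{code}_copy_number.tsv"),
                                         "copy_number"),
                    comp_mod.read_matrix(os.path.join(indir, f"{code}_methylation.tsv"),
                                         "methylation_beta"),
                ))
                clin_path = os.path.join(indir, f"{code}_clinical.tsv")
                if os.path.exists(clin_path):
                    state.clinical[code] = comp_mod.read_clinical(clin_path)
            state.compendium = comp_mod.build_compendium(datasets)
            return True
        if stage == "preprocess":
            if state.compendium is not None:
                return True
            if cfg.simulate is not None:
                return _load_cached("simulate", cfg, state)
            return False
        return True
    except (OSError, KeyError):
        return False


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "score": _stage_score,
    "locfdr": _stage_locfdr,
    "infer": _stage_infer,
    "rec": _stage_rec,
    "evaluate": _stage_evaluate,
    "survival": _stage_survival,
}
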