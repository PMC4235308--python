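"""Aligned multi-omics pan-cancer data structures.

A cohort ("cancer dataset") couples four feature-by-sample matrices measured
on the same tumour samples: gene expression (log2), mature-miRNA expression
(log2 RPM), per-gene copy-number scores (Gistic2-style, continuous) and
per-gene promoter methylation (beta values in [0, 1]).  A compendium aligns
D >= 2 such cohorts to shared gene and miRNA universes so that downstream
per-pair statistics are comparable across cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VALID_KINDS = ("gene_expr_log2", "mirna_expr_log2", "copy_number", "methylation_beta")


class CompendiumError(ValueError):
    """Raised when a matrix or cohort violates a structural invariant."""


@dataclass
class OmicsMatrix:
    """One feature-by-sample numeric matrix with a declared kind.

    Parameters
    ----------
    feature_ids : list of str
        Row identifiers (genes or miRNAs); must be unique.
    sample_ids : list of str
        Column identifiers; must be unique.
    values : ndarray of shape (n_features, n_samples)
    kind : str
        One of ``gene_expr_log2``, ``mirna_expr_log2``, ``copy_number``,
        ``methylation_beta``.
    """

    feature_ids: list
    sample_ids: list
    values: np.ndarray
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.kind not in VALID_KINDS:
            raise CompendiumError(f"unknown matrix kind {self.kind!r}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise CompendiumError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = pd.Index(self.feature_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise CompendiumError(f"duplicate feature ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CompendiumError("duplicate sample ids")
        if self.kind == "methylation_beta":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise CompendiumError("methylation beta values outside [0, 1]")

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def reindex_features(self, ids: Sequence[str]) -> "OmicsMatrix":
        """Return a copy restricted/reordered to ``ids`` (all must be present)."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            rows = [pos[f] for f in ids]
        except KeyError as exc:
            raise CompendiumError(f"feature {exc.args[0]!r} absent from matrix") from exc
        return OmicsMatrix(list(ids), self.sample_ids, self.values[rows, :], self.kind)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_matrix(path, kind: str) -> OmicsMatrix:
    """Read a tab-separated feature-by-sample matrix.

    The first column holds feature ids, the header row sample ids, and the
    body must be numeric (empty cells become NaN and are resolved by the
    downstream pairwise-complete policy).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise CompendiumError(f"cannot parse {path}: {exc}") from exc
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise CompendiumError(f"duplicate feature ids in {path}: {dupes[:5]}")
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & df.notna()
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise CompendiumError(
            f"non-numeric cell in {path} at feature {r!r}, sample {c!r}: {df.loc[r, c]!r}"
        )
    return OmicsMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                       body.to_numpy(dtype=float), kind)


def filter_prevalence(m: OmicsMatrix, min_frac: float = 0.05) -> OmicsMatrix:
    """Drop features expressed (nonzero) in fewer than ``ceil(min_frac * T)`` samples.

    Operates on the raw (pre-log) scale where absent expression is exactly 0.
    """
    if not 0 < min_frac <= 1:
        raise CompendiumError(f"min_frac must be in (0, 1], got {min_frac}")
    T = len(m.sample_ids)
    need = math.ceil(min_frac * T)
    counts = np.sum(np.nan_to_num(m.values, nan=0.0) != 0, axis=1)
    keep = counts >= need
    if not keep.any():
        raise CompendiumError("empty matrix after prevalence filter")
    ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return OmicsMatrix(ids, m.sample_ids, m.values[keep, :], m.kind)


def log2_zero_replace(m: OmicsMatrix) -> OmicsMatrix:
    """log2-transform after replacing zeros with the matrix-wide minimum positive value.

    A single global floor keeps the transform monotone and reproducible; set
    ``per_feature=True`` on :func:`log2_zero_replace_per_feature` for a
    row-wise floor instead.
    """
    vals = m.values
    if np.nanmin(vals) < 0:
        raise CompendiumError("negative values cannot be log2-transformed")
    pos = vals[np.isfinite(vals) & (vals > 0)]
    if pos.size == 0:
        raise CompendiumError("matrix entirely zero: no replacement value exists")
    floor = pos.min()
    out = np.where(vals == 0, floor, vals)
    return OmicsMatrix(m.feature_ids, m.sample_ids, np.log2(out), m.kind)


def log2_zero_replace_per_feature(m: OmicsMatrix) -> OmicsMatrix:
    """Variant of :func:`log2_zero_replace` using each feature's own minimum positive value."""
    vals = m.values.copy()
    if np.nanmin(vals) < 0:
        raise CompendiumError("negative values cannot be log2-transformed")
    for i in range(vals.shape[0]):
        row = vals[i]
        pos = row[np.isfinite(row) & (row > 0)]
        if pos.size == 0:
            raise CompendiumError(f"feature {m.feature_ids[i]!r} entirely zero")
        row[row == 0] = pos.min()
    return OmicsMatrix(m.feature_ids, m.sample_ids, np.log2(vals), m.kind)


def select_promoter_probe(
    probe_betas: np.ndarray,
    gene_expr_row: np.ndarray,
    platforms: Sequence[str] | None = None,
    platform_priority: Sequence[str] = ("HM450", "HM27"),
):
    """Pick one promoter methylation probe per gene.

    Among candidate probes (rows of ``probe_betas``), probes from the
    highest-priority platform present are considered first; within that set
    the probe whose beta profile has the most negative Pearson correlation
    with the gene's expression is returned.

    Returns
    -------
    (index, betas) : tuple of int and ndarray
    """
    probe_betas = np.asarray(probe_betas, dtype=float)
    gene_expr_row = np.asarray(gene_expr_row, dtype=float)
    if probe_betas.ndim != 2 or probe_betas.shape[1] != gene_expr_row.size:
        raise CompendiumError("probe matrix and expression vector sample counts differ")
    n = probe_betas.shape[0]
    if n == 0:
        raise CompendiumError("no candidate probes")
    if platforms is not None and len(platforms) != n:
        raise CompendiumError("one platform tag per probe required")

    if platforms is None:
        cand = list(range(n))
    else:
        cand = []
        for plat in platform_priority:
            cand = [i for i, p in enumerate(platforms) if p == plat]
            if cand:
                break
        if not cand:  # platforms outside the priority list: consider all
            cand = list(range(n))

    best, best_r = None, np.inf
    ey = gene_expr_row - gene_expr_row.mean()
    sy = np.sqrt((ey**2).sum())
    for i in cand:
        row = probe_betas[i]
        ex = row - row.mean()
        sx = np.sqrt((ex**2).sum())
        if sx == 0 or sy == 0:
            continue  # zero-variance probe: correlation undefined, skip
        r = float((ex * ey).sum() / (sx * sy))
        if r < best_r:
            best, best_r = i, r
    if best is None:
        raise CompendiumError("all candidate probes have zero variance")
    return best, probe_betas[best]


@dataclass
class CancerDataset:
    """All four omics matrices of one cohort, aligned on samples and genes."""

    cancer_code: str
    gene_expr: OmicsMatrix
    mirna_expr: OmicsMatrix
    copy_number: OmicsMatrix
    methylation: OmicsMatrix
    clinical: pd.DataFrame | None = None

    def __post_init__(self):
        sids = self.gene_expr.sample_ids
        for m in (self.mirna_expr, self.copy_number, self.methylation):
            if m.sample_ids != sids:
                raise CompendiumError(
                    f"{self.cancer_code}: sample ids differ between matrices"
                )
        gids = self.gene_expr.feature_ids
        for m in (self.copy_number, self.methylation):
            if m.feature_ids != gids:
                raise CompendiumError(
                    f"{self.cancer_code}: gene universes differ between "
                    "expression, copy-number and methylation matrices"
                )
        if self.T < 5:
            raise CompendiumError(
                f"{self.cancer_code}: needs T >= 5 samples for the 4-parameter "
                f"regression (got {self.T})"
            )

    @property
    def T(self) -> int:
        return len(self.gene_expr.sample_ids)

    @property
    def genes(self) -> list:
        return self.gene_expr.feature_ids

    @property
    def mirnas(self) -> list:
        return self.mirna_expr.feature_ids

    def restrict(self, genes: Sequence[str], mirnas: Sequence[str]) -> "CancerDataset":
        return CancerDataset(
            self.cancer_code,
            self.gene_expr.reindex_features(genes),
            self.mirna_expr.reindex_features(mirnas),
            self.copy_number.reindex_features(genes),
            self.methylation.reindex_features(genes),
            clinical=self.clinical,
        )


@dataclass
class PanCancerCompendium:
    """D aligned cohorts restricted to shared gene and miRNA universes."""

    datasets: list
    common_genes: list = field(default_factory=list)
    common_mirnas: list = field(default_factory=list)
    dropped: dict = field(default_factory=dict)

    @property
    def D(self) -> int:
        return len(self.datasets)

    @property
    def N(self) -> int:
        return len(self.common_genes)

    @property
    def M(self) -> int:
        return len(self.common_mirnas)


def build_compendium(datasets: Sequence[CancerDataset]) -> PanCancerCompendium:
    """Intersect gene/miRNA universes across cohorts and re-index every matrix.

    Feature order after intersection is lexicographic, so the result is
    byte-reproducible regardless of input cohort order.
    """
    if len(datasets) < 2:
        raise CompendiumError(f"need at least 2 cohorts, got {len(datasets)}")
    genes = set(datasets[0].genes)
    mirnas = set(datasets[0].mirnas)
    for ds in datasets[1:]:
        genes &= set(ds.genes)
        mirnas &= set(ds.mirnas)
    if not genes or not mirnas:
        raise CompendiumError("empty gene or miRNA intersection across cohorts")
    common_genes = sorted(genes)
    common_mirnas = sorted(mirnas)
    dropped = {
        ds.cancer_code: {
            "genes": len(ds.genes) - len(common_genes),
            "mirnas": len(ds.mirnas) - len(common_mirnas),
        }
        for ds in datasets
    }
    restricted = [ds.restrict(common_genes, common_mirnas) for ds in datasets]
    return PanCancerCompendium(restricted, common_genes, common_mirnas, dropped)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV with columns ``sample``, ``time_days``, ``event``."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time_days", "event"}
    if not required.issubset(df.columns):
        raise CompendiumError(f"clinical table must have columns {sorted(required)}")
    if (df["time_days"] <= 0).any():
        raise CompendiumError("clinical times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise CompendiumError("event flag must be 0 or 1")
    return df


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name, description, then tab-separated members."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *members = parts
            members = [m for m in members if m]
            if members:
                sets[name] = members
    return sets


def read_pair_list(path) -> set:
    """Read a two-column TSV of (miRNA, gene) reference pairs."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["mirna", "gene"], usecols=[0, 1], dtype=str)
    return set(zip(df["mirna"], df["gene"]))
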