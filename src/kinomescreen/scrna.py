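"""Tumor-compartment stratification and rank-based gene-set scoring.

Workflow, mirroring the published single-cell analysis: annotate cells by
marker expression (SOX2 tumor, CD14/CD68 macrophage, CD3D T cell, CD79A
B cell, MBP oligodendrocyte, PECAM1 endothelial, PDGFRB pericyte); compute
the per-sample fraction of tumor cells with focal-gene (CHEK2) CPM > 0;
dichotomize samples at the cohort median of that frequency; score each cell
for a gene set with a rank-based recovery-curve AUC (AUCell-style); compare
score distributions between high and low groups with a two-tailed
Mann-Whitney test; and run per-gene Welch differential expression between
focal-positive and focal-negative tumor cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import MannWhitneyResult, bh_adjust, mannwhitney_u
from .simulate import DEFAULT_MARKER_SETS

TUMOR = "tumor"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class MarkerPanel:
    """Cell-type -> marker gene symbols (the glioma panel by default)."""

    sets: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_SETS)
    )

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("marker panel is empty")
        for t, genes in self.sets.items():
            if not genes:
                raise ValueError(f"marker set for {t!r} is empty")

    def restrict(self, universe: Sequence[str]) -> "MarkerPanel":
        """Drop symbols missing from the gene universe (with a warning)."""
        uni = set(universe)
        kept: dict[str, tuple[str, ...]] = {}
        for t, genes in self.sets.items():
            present = tuple(g for g in genes if g in uni)
            missing = set(genes) - set(present)
            if missing:
                warnings.warn(f"markers for {t!r} missing from universe: {sorted(missing)}")
            if present:
                kept[t] = present
            else:
                warnings.warn(f"cell type {t!r} dropped: no markers in universe")
        if not kept:
            raise ValueError("no marker genes present in the gene universe")
        return MarkerPanel(kept)


def annotate_cells(adata: ad.AnnData, panel: MarkerPanel | None = None) -> pd.Series:
    """Marker-argmax cell typing.

    Per cell, each type's score is the mean ``log1p(CPM)`` over its markers;
    the label is the argmax type if its score is positive, else
    ``"unassigned"``. Ties break deterministically by type-name order.
    """
    panel = (panel or MarkerPanel()).restrict(list(adata.var_names))
    types = sorted(panel.sets)
    X = np.asarray(adata.X)
    scores = np.empty((adata.n_obs, len(types)))
    for j, t in enumerate(types):
        idx = [adata.var_names.get_loc(g) for g in panel.sets[t]]
        scores[:, j] = np.log1p(X[:, idx]).mean(axis=1)
    best = np.argmax(scores, axis=1)  # first max -> alphabetical tie-break
    labels = np.where(scores[np.arange(adata.n_obs), best] > 0, np.array(types)[best], UNASSIGNED)
    return pd.Series(labels, index=adata.obs_names, name="cell_type")


def focal_positive_frequency(
    adata: ad.AnnData,
    focal_gene: str,
    cell_types: pd.Series,
    compartment: str = TUMOR,
) -> pd.Series:
    """Per-sample fraction of compartment cells with focal-gene CPM > 0.

    Samples with no compartment cells are dropped with a warning.
    """
    if focal_gene not in adata.var_names:
        raise ValueError(f"focal gene {focal_gene!r} absent from gene universe")
    mask = (cell_types.reindex(adata.obs_names) == compartment).to_numpy()
    if not mask.any():
        raise ValueError(f"no cells annotated as {compartment!r}")
    expr = np.asarray(adata.X)[:, adata.var_names.get_loc(focal_gene)]
    df = pd.DataFrame(
        {"sample": adata.obs["sample_id"].to_numpy()[mask], "pos": expr[mask] > 0}
    )
    freqs = df.groupby("sample", observed=True)["pos"].mean()
    all_samples = pd.unique(adata.obs["sample_id"])
    dropped = set(map(str, all_samples)) - set(map(str, freqs.index))
    if dropped:
        warnings.warn(f"samples without {compartment} cells dropped: {sorted(dropped)}")
    freqs.name = f"{focal_gene}_pos_freq"
    return freqs.astype(float)


@dataclass(frozen=True)
class StratificationResult:
    """Median dichotomization of per-sample focal-positive frequencies."""

    freqs: pd.Series
    median: float
    labels: pd.Series  # "high" / "low" per sample
    degenerate: bool = False

    @property
    def high_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "high"])

    @property
    def low_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "low"])


def dichotomize_samples(freqs: pd.Series) -> StratificationResult:
    """Split samples at the cohort median frequency.

    Standard midpoint median; a sample is ``high`` iff its frequency is
    strictly above the median (samples exactly at the median go to ``low``).
    All-identical frequencies degenerate to everything ``low``, with a
    warning.
    """
    if len(freqs) < 2:
        raise ValueError("need >=2 samples to dichotomize")
    med = float(np.median(freqs.to_numpy()))
    labels = pd.Series(np.where(freqs > med, "high", "low"), index=freqs.index, name="group")
    degenerate = freqs.nunique() == 1
    if degenerate:
        warnings.warn("all frequencies identical; stratification is degenerate (all low)")
    return StratificationResult(freqs=freqs, median=med, labels=labels, degenerate=degenerate)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT file (name, description, members...) into GeneSets."""
    from gseapy import read_gmt

    return {name: GeneSet(name, tuple(genes)) for name, genes in read_gmt(str(path)).items()}


def auc_score(
    adata: ad.AnnData,
    gene_set: GeneSet,
    max_rank_frac: float = 0.05,
    tie_seed: int = 0,
) -> np.ndarray:
    """Per-cell recovery-curve AUC of a gene set among the top-ranked genes.

    Genes are ranked per cell by descending expression with ties broken by a
    seeded random permutation of the gene axis. With ``c(k)`` the number of
    set genes at rank <= k and ``K = ceil(max_rank_frac * n_genes)``, the
    score is ``sum_{k<=K} c(k) / sum_{k<=K} min(k, m)`` where *m* is the set
    size after intersection with the universe — 1 iff the set genes fill the
    top *m* ranks, 0 iff none ranks within *K*. Depends on expression only
    through ranks, hence invariant to per-cell monotone transforms.
    """
    members = [g for g in gene_set.genes if g in adata.var_names]
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the universe")
    n_genes = adata.n_vars
    K = max(1, math.ceil(max_rank_frac * n_genes))
    m = len(members)
    X = np.asarray(adata.X)
    perm = np.random.default_rng(tie_seed).permutation(n_genes)
    # stable argsort over permuted columns = descending sort, random tie-break
    order = np.argsort(-X[:, perm], axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(X.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, n_genes + 1)
    inv = np.empty(n_genes, dtype=int)
    inv[perm] = np.arange(n_genes)
    member_idx = [adata.var_names.get_loc(g) for g in members]
    member_ranks = ranks[:, inv[member_idx]]
    # sum_{k<=K} c(k) == sum_i max(0, K - r_i + 1) by exchanging summation
    numer = np.clip(K - member_ranks + 1, 0, None).sum(axis=1)
    denom = sum(min(k, m) for k in range(1, K + 1))
    return numer / denom


def compare_groups_mw(scores_high, scores_low) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U between the two groups' per-cell scores."""
    return mannwhitney_u(scores_high, scores_low)


def welch_de(
    adata: ad.AnnData,
    focal_gene: str,
    cell_types: pd.Series,
    compartment: str = TUMOR,
) -> pd.DataFrame:
    """Per-gene Welch t between focal-positive and focal-negative tumor cells.

    Strata are compartment cells with focal CPM > 0 vs CPM = 0; each needs at
    least two cells. Returns t, Satterthwaite df, two-sided p and BH q per
    gene (the focal gene itself excluded).
    """
    if focal_gene not in adata.var_names:
        raise ValueError(f"focal gene {focal_gene!r} absent from gene universe")
    mask = (cell_types.reindex(adata.obs_names) == compartment).to_numpy()
    X = np.asarray(adata.X)[mask]
    fidx = adata.var_names.get_loc(focal_gene)
    pos = X[:, fidx] > 0
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError(
            f"need >=2 {compartment} cells in each focal stratum "
            f"(got {int(pos.sum())} positive, {int((~pos).sum())} negative)"
        )
    keep = np.arange(adata.n_vars) != fidx
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance genes
        res = stats.ttest_ind(X[pos][:, keep], X[~pos][:, keep], axis=0, equal_var=False)
    out = pd.DataFrame(
        {
            "t": res.statistic,
            "df": res.df,
            "p": res.pvalue,
            "mean_focal_pos": X[pos][:, keep].mean(axis=0),
            "mean_focal_neg": X[~pos][:, keep].mean(axis=0),
        },
        index=adata.var_names[keep],
    )
    out["q_bh"] = bh_adjust(out["p"])
    return out


@dataclass(frozen=True)
class StratifyScoreResult:
    """End-to-end stratification + signature-score comparison output."""

    cell_types: pd.Series
    stratification: StratificationResult
    scores: pd.Series  # per compartment cell
    mw: MannWhitneyResult
    n_high_cells: int
    n_low_cells: int


def stratify_and_score(
    adata: ad.AnnData,
    focal_gene: str,
    gene_set: GeneSet,
    panel: MarkerPanel | None = None,
    compartment: str = TUMOR,
    max_rank_frac: float = 0.05,
    tie_seed: int = 0,
) -> StratifyScoreResult:
    """Annotate, stratify by focal-positive frequency, score and compare.

    Compartment cells are pooled by their sample's high/low label and the two
    per-cell AUC score distributions compared with a two-tailed Mann-Whitney
    test.
    """
    cell_types = annotate_cells(adata, panel)
    freqs = focal_positive_frequency(adata, focal_gene, cell_types, compartment)
    strat = dichotomize_samples(freqs)
    scores = pd.Series(
        auc_score(adata, gene_set, max_rank_frac=max_rank_frac, tie_seed=tie_seed),
        index=adata.obs_names,
        name=f"auc_{gene_set.name}",
    )
    in_comp = cell_types == compartment
    sample_of = adata.obs["sample_id"].astype(str)
    group = sample_of.map(strat.labels)
    hi = scores[in_comp & (group == "high").to_numpy()]
    lo = scores[in_comp & (group == "low").to_numpy()]
    if hi.empty or lo.empty:
        raise ValueError("one stratum has no compartment cells; cannot compare")
    mw = compare_groups_mw(hi.to_numpy(), lo.to_numpy())
    return StratifyScoreResult(
        cell_types=cell_types,
        stratification=strat,
        scores=scores[in_comp],
        mw=mw,
        n_high_cells=len(hi),
        n_low_cells=len(lo),
    )
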