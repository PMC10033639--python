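"""Screen scoring: filtering, CPM+1 normalization, fold changes and NTC calls.

The scoring recipe follows the screen's published analysis exactly:

1. guides with raw read counts < 40 are excluded (per guide, per sample);
2. normalized reads per sgRNA = reads / total reads in the sample x 10^6 + 1;
3. per-guide arm means (WT and CD8KO hosts) over the samples passing the
   filter, then fold change fc = mean_WT / mean_CD8KO;
4. a guide whose fc exceeds the most enriched non-targeting control (NTC) is
   *enriched*; one below the most depleted NTC is *depleted*; guides whose
   normalized arm means are both < 5 are *unanalyzable*;
5. genes are ranked by mean log2 fold change (most negative = rank 1) and
   compared against the NTC guide population with Welch's t;
6. early-vs-late selection within a host genotype is tested per gene with an
   unpaired two-tailed (Welch) t-test on pooled per-guide normalized counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import WelchResult, bh_adjust, welch_ttest
from .library import GuideLibrary, SampleSheet

# guide classification labels
ENRICHED = "enriched"
DEPLETED = "depleted"
NEUTRAL = "neutral"
LOW_COUNT_EXCLUDED = "low_count_excluded"
UNANALYZABLE = "unanalyzable"

#: raw-count floor below which a (guide, sample) observation is discarded
DEFAULT_MIN_RAW = 40
#: normalized-count floor below which both arm means leave a guide unanalyzable
DEFAULT_MIN_NORM = 5.0


def apply_count_filter(raw: pd.DataFrame, min_raw: int = DEFAULT_MIN_RAW) -> pd.DataFrame:
    """Boolean pass-flag layer: ``True`` where ``raw >= min_raw``.

    Filtering never alters the stored counts. An all-zero sample (every guide
    excluded) triggers a warning.
    """
    passed = raw >= min_raw
    dead = ~passed.any(axis=0)
    for sample in raw.columns[dead]:
        warnings.warn(f"sample {sample!r}: every guide fails the raw>={min_raw} filter")
    return passed


def normalize_cpm(raw: pd.DataFrame) -> pd.DataFrame:
    """CPM + 1 normalization: ``raw / sample_total * 1e6 + 1``.

    Sample totals use the full library (the count filter does not change
    totals). Raises if any sample total is zero, naming the sample.
    """
    totals = raw.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total reads; cannot normalize")
    return raw / totals * 1e6 + 1.0


def aggregate_arm(
    norm: pd.DataFrame,
    pass_mask: pd.DataFrame,
    sheet: SampleSheet,
    group_by: str | Sequence[str] = "genotype",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-guide group means of normalized counts over filter-passing samples.

    Groups are the distinct values of ``group_by`` (``"genotype"`` or
    ``("genotype", "stage")``; composite groups are labelled
    ``"<genotype>:<stage>"``). A guide is *usable* in a group only if it
    passes the raw filter in at least ``max(2, ceil(n_group / 2))`` of the
    group's samples; otherwise its mean is reported but flagged unusable
    (low-count exclusion for comparisons involving that group).

    Returns
    -------
    (means, usable)
        Two guide x group DataFrames; ``means`` holds NaN where no sample
        passed.
    """
    cols = [group_by] if isinstance(group_by, str) else list(group_by)
    st = sheet.table
    means: dict[str, pd.Series] = {}
    usable: dict[str, pd.Series] = {}
    for key, sub in st.groupby(cols, sort=True):
        label = key if isinstance(key, str) else ":".join(map(str, key))
        samples = [s for s in sub["sample_id"] if s in norm.columns]
        if not samples:
            raise ValueError(f"group {label!r} has no samples in the count matrix")
        vals = norm[samples]
        ok = pass_mask[samples]
        n_pass = ok.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            means[label] = vals.where(ok).mean(axis=1)
        usable[label] = n_pass >= max(2, math.ceil(len(samples) / 2))
    return pd.DataFrame(means), pd.DataFrame(usable)


def guide_fold_changes(
    means: pd.DataFrame,
    usable: pd.DataFrame,
    library: GuideLibrary,
    numerator: str = "WT",
    denominator: str = "CD8KO",
    min_norm: float = DEFAULT_MIN_NORM,
) -> pd.DataFrame:
    """Per-guide fold-change table (``fc = mean_WT / mean_CD8KO``).

    Classes assigned here: ``low_count_excluded`` where the filter rule fired
    in either arm, ``unanalyzable`` where both arm means are < ``min_norm``.
    Remaining guides are provisionally ``neutral`` until
    :func:`classify_by_ntc_envelope` applies the NTC envelope.
    """
    for arm in (numerator, denominator):
        if arm not in means.columns:
            raise ValueError(f"arm {arm!r} absent from aggregated means")
    t = library.table.set_index("guide_id")[["gene", "is_ntc"]].copy()
    t["mean_num"] = means[numerator].reindex(t.index)
    t["mean_den"] = means[denominator].reindex(t.index)
    both_usable = (usable[numerator] & usable[denominator]).reindex(t.index).fillna(False)
    low = ~both_usable
    unan = both_usable & (t["mean_num"] < min_norm) & (t["mean_den"] < min_norm)
    t["fc"] = np.where(low | unan, np.nan, t["mean_num"] / t["mean_den"])
    t["log2fc"] = np.log2(t["fc"])
    t["class"] = NEUTRAL
    t.loc[unan, "class"] = UNANALYZABLE
    t.loc[low, "class"] = LOW_COUNT_EXCLUDED
    return t.rename(columns={"mean_num": f"mean_{numerator}", "mean_den": f"mean_{denominator}"})


@dataclass(frozen=True)
class NTCEnvelope:
    """Null fold-change envelope spanned by the usable non-targeting guides."""

    max_ntc_fc: float
    min_ntc_fc: float
    ntc_fc_mean: float
    ntc_fc_sd: float
    n_ntc_used: int

    def __post_init__(self) -> None:
        if not (self.min_ntc_fc <= self.ntc_fc_mean <= self.max_ntc_fc):
            raise ValueError("NTC envelope violates min <= mean <= max")


def ntc_envelope(guide_table: pd.DataFrame) -> NTCEnvelope:
    """Envelope over NTC guides not excluded by the count/norm filters."""
    ntc = guide_table[
        guide_table["is_ntc"] & ~guide_table["class"].isin([LOW_COUNT_EXCLUDED, UNANALYZABLE])
    ]
    if len(ntc) < 2:
        raise ValueError(f"need >=2 usable NTC guides to anchor the envelope, got {len(ntc)}")
    fc = ntc["fc"].to_numpy()
    return NTCEnvelope(
        max_ntc_fc=float(fc.max()),
        min_ntc_fc=float(fc.min()),
        ntc_fc_mean=float(fc.mean()),
        ntc_fc_sd=float(fc.std(ddof=1)),
        n_ntc_used=len(ntc),
    )


def classify_by_ntc_envelope(guide_table: pd.DataFrame, envelope: NTCEnvelope) -> pd.DataFrame:
    """Label targeting guides enriched/depleted/neutral against the envelope.

    Strict inequalities: a fold change equal to an envelope bound stays
    neutral, and NTC guides are never labelled enriched or depleted.
    """
    t = guide_table.copy()
    open_rows = ~t["class"].isin([LOW_COUNT_EXCLUDED, UNANALYZABLE])
    targeting = open_rows & ~t["is_ntc"].astype(bool)
    t.loc[open_rows, "class"] = NEUTRAL
    t.loc[targeting & (t["fc"] > envelope.max_ntc_fc), "class"] = ENRICHED
    t.loc[targeting & (t["fc"] < envelope.min_ntc_fc), "class"] = DEPLETED
    return t


def gene_summary(guide_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate classified guides to genes and rank by depletion.

    Per gene: counts of depleted/enriched guides, mean log2fc over usable
    guides, depletion rank (ascending mean log2fc; most negative = rank 1,
    over genes with >=1 usable guide), and a two-sided Welch t p-value of the
    gene's guide log2fcs against the NTC guide log2fcs (plus BH-adjusted q).
    Genes with no usable guide are emitted unranked with ``no_usable_guides``
    set.
    """
    usable_mask = ~guide_table["class"].isin([LOW_COUNT_EXCLUDED, UNANALYZABLE])
    ntc_log2fc = guide_table.loc[
        guide_table["is_ntc"].astype(bool) & usable_mask, "log2fc"
    ].to_numpy()
    rows = []
    targeting = guide_table[~guide_table["is_ntc"].astype(bool)]
    for gene, sub in targeting.groupby("gene", sort=True):
        used = sub[usable_mask.reindex(sub.index)]
        n_used = len(used)
        p = np.nan
        if n_used >= 2 and ntc_log2fc.size >= 2:
            p = welch_ttest(used["log2fc"].to_numpy(), ntc_log2fc).pvalue
        rows.append(
            {
                "gene": gene,
                "n_guides_used": n_used,
                "n_depleted": int((used["class"] == DEPLETED).sum()),
                "n_enriched": int((used["class"] == ENRICHED).sum()),
                "mean_log2fc": used["log2fc"].mean() if n_used else np.nan,
                "p_vs_ntc": p,
                "no_usable_guides": n_used == 0,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    ranked = out.index[~out["no_usable_guides"]]
    ranks = out.loc[ranked, "mean_log2fc"].rank(method="first", ascending=True)
    out["depletion_rank"] = ranks.reindex(out.index)
    out["q_vs_ntc_bh"] = bh_adjust(out["p_vs_ntc"])
    return out


@dataclass(frozen=True)
class TemporalResult:
    """Early-vs-late Welch t-test on a gene's pooled guide-level counts."""

    gene: str
    genotype: str
    mean_early: float
    mean_late: float
    t_statistic: float
    p_two_sided: float
    df: float
    n_early: int
    n_late: int
    #: sign of (mean_late - mean_early): -1 decline, +1 rise, 0 flat
    direction: int
    degenerate: bool = False


def temporal_selection_test(
    norm: pd.DataFrame,
    sheet: SampleSheet,
    library: GuideLibrary,
    gene: str,
    genotype: str,
    early_stage: str = "early",
    late_stage: str = "late",
) -> TemporalResult:
    """Test whether a gene's guides were selected over time within one host arm.

    Observations are the gene's per-guide normalized counts pooled over mice
    within (genotype, stage); the raw-count filter is deliberately not applied
    here, since depletion to (near) zero reads *is* the temporal signal.
    """
    guides = library.table.loc[library.table["gene"] == gene, "guide_id"]
    if guides.empty:
        raise ValueError(f"gene {gene!r} not in library")
    obs = {}
    for stage in (early_stage, late_stage):
        samples = [s for s in sheet.samples_in(genotype, stage) if s in norm.columns]
        vals = norm.loc[guides, samples].to_numpy().ravel()
        if vals.size < 2:
            raise ValueError(f"need >=2 observations in ({genotype}, {stage}), got {vals.size}")
        obs[stage] = vals
    res: WelchResult = welch_ttest(obs[early_stage], obs[late_stage])
    me, ml = float(obs[early_stage].mean()), float(obs[late_stage].mean())
    return TemporalResult(
        gene=gene,
        genotype=genotype,
        mean_early=me,
        mean_late=ml,
        t_statistic=res.statistic,
        p_two_sided=res.pvalue,
        df=res.df,
        n_early=obs[early_stage].size,
        n_late=obs[late_stage].size,
        direction=int(np.sign(ml - me)),
        degenerate=res.degenerate,
    )


def representation_coverage(cells_per_mouse: int, n_mice: int, n_guides: int) -> int:
    """Library fold representation: ``floor(cells_per_mouse * n_mice / n_guides)``.

    E.g. 200,000 cells/mouse across 11 mice over a ~3,000-guide library gives
    733X coverage.
    """
    for name, v in (("cells_per_mouse", cells_per_mouse), ("n_mice", n_mice), ("n_guides", n_guides)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    if n_guides == 0:
        raise ValueError("n_guides must be positive")
    return int(cells_per_mouse) * int(n_mice) // int(n_guides)


@dataclass(frozen=True)
class ScreenScores:
    """Full scoring output: normalized matrix, guide/gene tables, envelope."""

    norm: pd.DataFrame
    pass_mask: pd.DataFrame
    guide_table: pd.DataFrame
    gene_table: pd.DataFrame
    envelope: NTCEnvelope


def score_screen(
    raw: pd.DataFrame,
    library: GuideLibrary,
    sheet: SampleSheet,
    min_raw: int = DEFAULT_MIN_RAW,
    min_norm: float = DEFAULT_MIN_NORM,
) -> ScreenScores:
    """Run the full filter -> CPM+1 -> arm-mean -> fc -> NTC-call pipeline."""
    pass_mask = apply_count_filter(raw, min_raw=min_raw)
    norm = normalize_cpm(raw)
    means, usable = aggregate_arm(norm, pass_mask, sheet, group_by="genotype")
    guide_table = guide_fold_changes(means, usable, library, min_norm=min_norm)
    env = ntc_envelope(guide_table)
    guide_table = classify_by_ntc_envelope(guide_table, env)
    gene_table = gene_summary(guide_table)
    return ScreenScores(norm, pass_mask, guide_table, gene_table, env)
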