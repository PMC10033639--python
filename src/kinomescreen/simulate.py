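"""Synthetic data generators with known ground truth.

Three simulators mirror the statistical structure the downstream analyses
assume, so the whole pipeline is testable offline:

* :func:`simulate_screen` — a pooled knockout screen: lognormal plasmid
  abundances, a per-mouse implantation bottleneck (multinomial draw of
  ``cells_per_mouse`` cells), host-genotype-specific per-generation selection
  on clone weights, and a multinomial sequencing draw per (mouse, stage)
  sample. Truth tables (per-gene selection coefficients) are emitted
  alongside the data and never read by analysis code.
* :func:`simulate_scrna` — per-cell CPM matrices with marker-defined cell
  types, a focal gene (CHEK2 stand-in) whose detection probability varies
  across samples, and a planted coupling between focal-low samples and
  elevated expression of a designated gene signature in tumor cells.
* :func:`simulate_survival` — exponential event times with group-specific
  hazards and administrative censoring.

All simulators are fully determined by their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .library import GENOTYPES, NTC_GENE, GuideLibrary, SampleSheet

# --------------------------------------------------------------------------
# pooled screen
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study design for a synthetic two-arm, two-stage pooled screen.

    ``selection`` maps gene -> (s_WT, s_CD8KO): per-generation log-fitness of
    that gene's knockout clones in each host arm (0 for unlisted genes; NTCs
    are always neutral). Stages map labels to generation counts; each
    simulated mouse belongs to one (genotype, stage) cohort, matching the
    barcoded early/late sacrifice design.
    """

    seed: int
    n_genes: int
    guides_per_gene: int = 4
    n_ntc: int = 100
    cells_per_mouse: int = 200_000
    mice_per_arm: int = 4
    stages: tuple[tuple[str, float], ...] = (("early", 6.0), ("late", 12.0))
    depth_per_sample: float = 1e7
    plasmid_sigma: float = 0.5
    selection: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    #: optional Dirichlet pre-draw concentration for extra sequencing
    #: overdispersion; None = single multinomial per sample
    dirichlet_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.n_genes * self.guides_per_gene + self.n_ntc <= 0:
            raise ValueError("library must contain at least one guide")
        if self.n_genes < 0 or self.guides_per_gene < 0 or self.n_ntc < 0:
            raise ValueError("library sizes must be nonnegative")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be positive")
        if self.cells_per_mouse <= 0 or self.mice_per_arm <= 0:
            raise ValueError("cells_per_mouse and mice_per_arm must be positive")
        if self.plasmid_sigma <= 0:
            raise ValueError("plasmid_sigma must be positive")
        if not self.stages or any(t < 0 for _, t in self.stages):
            raise ValueError("stages must be nonempty with generations t >= 0")
        genes = set(self.gene_names())
        unknown = set(self.selection) - genes
        if unknown:
            raise ValueError(f"selection refers to unknown genes: {sorted(unknown)}")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """n distinct random DNA k-mers."""
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = ["".join(row) for row in alphabet[rng.integers(0, 4, size=(n, k))]]
        for s in block:
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


def simulate_screen(
    cfg: ScreenSimConfig,
) -> tuple[GuideLibrary, SampleSheet, pd.DataFrame, dict[str, tuple[float, float]]]:
    """Simulate one pooled screen; returns (library, sheet, counts, truth).

    Generative chain per mouse: lognormal plasmid weights -> multinomial
    implantation bottleneck of ``cells_per_mouse`` cells -> clone weights
    scaled by ``exp(s * t)`` for the mouse's stage -> Poisson sequencing depth
    around ``depth_per_sample`` -> multinomial read draw. The truth table maps
    every gene (NTC included) to its (s_WT, s_CD8KO).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names()
    records = []
    for g in genes:
        for k in range(1, cfg.guides_per_gene + 1):
            records.append((f"{g}_g{k}", g, False))
    for k in range(1, cfg.n_ntc + 1):
        records.append((f"NTC_g{k:03d}", NTC_GENE, True))
    lib_df = pd.DataFrame(records, columns=["guide_id", "gene", "is_ntc"])
    lib_df["protospacer"] = _random_kmers(rng, len(lib_df), 20)
    library = GuideLibrary(lib_df[["guide_id", "gene", "protospacer", "is_ntc"]])

    w = rng.lognormal(0.0, cfg.plasmid_sigma, size=len(lib_df))
    w /= w.sum()
    s_by_arm = {}
    for ai, arm in enumerate(GENOTYPES):
        s = np.array([cfg.selection.get(g, (0.0, 0.0))[ai] for g in lib_df["gene"]])
        s[lib_df["is_ntc"].to_numpy()] = 0.0
        s_by_arm[arm] = s

    n_samples = len(GENOTYPES) * len(cfg.stages) * cfg.mice_per_arm
    barcodes = _random_kmers(rng, n_samples, 8)
    sheet_rows, columns = [], {}
    bi = 0
    for arm in GENOTYPES:
        for stage, t in cfg.stages:
            for m in range(1, cfg.mice_per_arm + 1):
                sid = f"{arm}_{stage}_m{m}"
                cells = rng.multinomial(cfg.cells_per_mouse, w)
                clone_w = cells * np.exp(s_by_arm[arm] * t)
                tot = clone_w.sum()
                p = clone_w / tot if tot > 0 else np.full_like(w, 1.0 / len(w))
                if cfg.dirichlet_concentration is not None:
                    alpha = np.maximum(p * cfg.dirichlet_concentration, 1e-12)
                    p = rng.dirichlet(alpha)
                depth = rng.poisson(cfg.depth_per_sample)
                columns[sid] = rng.multinomial(int(depth), p)
                sheet_rows.append((sid, arm, stage, sid, barcodes[bi]))
                bi += 1
    sheet = SampleSheet(
        pd.DataFrame(sheet_rows, columns=["sample_id", "genotype", "stage", "mouse_id", "barcode"])
    )
    counts = pd.DataFrame(columns, index=library.guide_ids)
    counts.index.name = "guide_id"
    truth = {g: tuple(map(float, cfg.selection.get(g, (0.0, 0.0)))) for g in genes}
    truth[NTC_GENE] = (0.0, 0.0)
    return library, sheet, counts, truth


def write_screen_fastq(
    counts: pd.DataFrame,
    library: GuideLibrary,
    sheet: SampleSheet,
    path: str | Path,
    anchor: str = "TTGTGGAAAGGACGAAACACCG",
    filler: str = "GTTTTAGAGCTAGAAAT",
) -> int:
    """Emit one multiplexed synthetic amplicon FASTQ reproducing ``counts``.

    Each read is ``barcode + anchor + protospacer + filler``; running
    demultiplex + count_guides on the file returns ``counts`` exactly.
    Returns the number of reads written.
    """
    proto = library.table.set_index("guide_id")["protospacer"]
    bc = sheet.table.set_index("sample_id")["barcode"]
    n = 0
    with open(path, "w") as fh:
        for sample in counts.columns:
            for gid, c in counts[sample].items():
                seq = f"{bc[sample]}{anchor}{proto[gid]}{filler}"
                qual = "I" * len(seq)
                for _ in range(int(c)):
                    n += 1
                    fh.write(f"@read{n} {sample}\n{seq}\n+\n{qual}\n")
    return n


# --------------------------------------------------------------------------
# single-cell matrices
# --------------------------------------------------------------------------

#: the glioma marker panel used throughout: one short marker list per type
DEFAULT_MARKER_SETS: dict[str, tuple[str, ...]] = {
    "tumor": ("SOX2",),
    "macrophage": ("CD14", "CD68"),
    "tcell": ("CD3D",),
    "bcell": ("CD79A",),
    "oligodendrocyte": ("MBP",),
    "endothelial": ("PECAM1",),
    "pericyte": ("PDGFRB",),
}

_DEFAULT_SIGNATURE = tuple(f"ISG{i:03d}" for i in range(1, 21))


@dataclass(frozen=True)
class ScRNASimConfig:
    """Design for synthetic per-cell CPM matrices with a planted association.

    Samples differ in the focal gene's detection probability (spanning the
    cohort median); tumor cells from samples in the lower half additionally
    express the designated signature at ``exp(coupling)``-fold the baseline.
    ``coupling = 0`` plants no association (the null).
    """

    seed: int
    n_samples: int = 28
    cells_per_sample: int = 60
    n_background_genes: int = 200
    marker_sets: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_SETS)
    )
    focal_gene: str = "CHEK2"
    signature_name: str = "IFN_RESPONSE"
    signature_genes: tuple[str, ...] = _DEFAULT_SIGNATURE
    coupling: float = 1.0
    detect_range: tuple[float, float] = (0.05, 0.6)
    dropout: float = 0.1
    dispersion: float = 0.5
    type_props: Mapping[str, float] = field(
        default_factory=lambda: {"tumor": 0.55, "macrophage": 0.2, "oligodendrocyte": 0.15, "tcell": 0.10}
    )

    def __post_init__(self) -> None:
        if not self.signature_genes:
            raise ValueError("signature_genes (the coupled gene set) must be nonempty")
        if self.n_samples < 2 or self.cells_per_sample < 1:
            raise ValueError("need >=2 samples and >=1 cell per sample")
        if not self.marker_sets or any(not v for v in self.marker_sets.values()):
            raise ValueError("marker_sets must be nonempty sets")
        if set(self.type_props) - set(self.marker_sets):
            raise ValueError("type_props refers to types without markers")
        if not (0 <= self.dropout < 1) or self.dispersion <= 0:
            raise ValueError("invalid dropout/dispersion")


def _nb_counts(rng: np.random.Generator, rate: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws with mean ``rate`` and shape ``1/dispersion``."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, 1.0, size=rate.shape) / shape * rate
    return rng.poisson(lam)


def simulate_scrna(cfg: ScRNASimConfig) -> ad.AnnData:
    """Simulate a cells x genes CPM AnnData with ground truth in ``.obs``/``.uns``.

    ``obs`` carries ``sample_id``, ``true_type`` and the sample-level truth
    flag ``true_low_sample``; ``uns`` records the signature, the focal gene
    and the per-sample detection probabilities. Marker genes are expressed
    only in their own type, so the separable annotation case is exact.
    """
    rng = np.random.default_rng(cfg.seed)
    types = sorted(cfg.type_props)
    props = np.array([cfg.type_props[t] for t in types], dtype=float)
    props /= props.sum()

    marker_genes = [g for t in sorted(cfg.marker_sets) for g in cfg.marker_sets[t]]
    background = [f"GENE{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    genes = list(dict.fromkeys(marker_genes + [cfg.focal_gene] + list(cfg.signature_genes) + background))
    gi = {g: j for j, g in enumerate(genes)}
    n_genes = len(genes)

    bg_rate = rng.lognormal(1.0, 1.0, size=len(background))
    p_detect = np.linspace(*cfg.detect_range, cfg.n_samples)
    p_detect = rng.permutation(p_detect)
    low_sample = p_detect < np.median(p_detect)
    sample_ids = [f"S{i:02d}" for i in range(1, cfg.n_samples + 1)]

    n_cells = cfg.n_samples * cfg.cells_per_sample
    X = np.zeros((n_cells, n_genes))
    obs_sample, obs_type = [], []
    sig_idx = [gi[g] for g in cfg.signature_genes]
    bg_idx = [gi[g] for g in background]
    focal_idx = gi[cfg.focal_gene]

    row = 0
    for s, sid in enumerate(sample_ids):
        cell_types = rng.choice(len(types), size=cfg.cells_per_sample, p=props)
        for ct in cell_types:
            tname = types[ct]
            rate = np.zeros(n_genes)
            rate[bg_idx] = bg_rate
            for mg in cfg.marker_sets[tname]:
                rate[gi[mg]] = 50.0
            sig_rate = 5.0
            if tname == "tumor" and low_sample[s]:
                sig_rate *= np.exp(cfg.coupling)
            rate[sig_idx] = sig_rate
            if tname == "tumor":
                rate[focal_idx] = 20.0 * rng.binomial(1, p_detect[s])
            elif tname == "macrophage":
                rate[focal_idx] = 20.0 * rng.binomial(1, 0.5)
            counts = _nb_counts(rng, rate, cfg.dispersion).astype(float)
            if cfg.dropout > 0:
                counts *= rng.binomial(1, 1.0 - cfg.dropout, size=n_genes)
            X[row] = counts
            obs_sample.append(sid)
            obs_type.append(tname)
            row += 1

    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells with zero total counts left unnormalized")
        totals[zero] = 1.0
    X = X / totals[:, None] * 1e6

    obs = pd.DataFrame(
        {
            "sample_id": pd.Categorical(obs_sample, categories=sample_ids),
            "true_type": obs_type,
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    obs["true_low_sample"] = obs["sample_id"].map(dict(zip(sample_ids, low_sample))).astype(bool)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    adata.uns["focal_gene"] = cfg.focal_gene
    adata.uns["signature"] = {cfg.signature_name: list(cfg.signature_genes)}
    adata.uns["truth"] = {
        "coupling": cfg.coupling,
        "detect_prob": dict(zip(sample_ids, map(float, p_detect))),
        "low_samples": [sid for sid, lo in zip(sample_ids, low_sample) if lo],
    }
    return adata


def write_scrna_tsv(adata: ad.AnnData, out_dir: str | Path) -> None:
    """Write a genes x cells matrix TSV plus a cell-metadata TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = pd.DataFrame(adata.X.T, index=adata.var_names, columns=adata.obs_names)
    mat.to_csv(out / "matrix.tsv", sep="\t", index_label="gene")
    adata.obs.to_csv(out / "cells.tsv", sep="\t", index_label="cell_id")


def read_scrna_tsv(in_dir: str | Path) -> ad.AnnData:
    """Read the matrix/metadata TSV pair written by :func:`write_scrna_tsv`."""
    out = Path(in_dir)
    mat = pd.read_csv(out / "matrix.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(out / "cells.tsv", sep="\t", index_col=0)
    return ad.AnnData(X=mat.T.to_numpy(), obs=obs, var=pd.DataFrame(index=mat.index))


# --------------------------------------------------------------------------
# survival tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Exponential survival with group-specific hazards and a censoring horizon."""

    seed: int
    groups: Mapping[str, tuple[int, float]]  # group -> (n, hazard rate)
    censor_time: float = np.inf

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        for g, (n, lam) in self.groups.items():
            if n < 1:
                raise ValueError(f"group {g!r}: n must be >= 1")
            if lam <= 0:
                raise ValueError(f"group {g!r}: hazard must be positive")
        if self.censor_time < 0:
            raise ValueError("censor_time must be nonnegative")


def simulate_survival(cfg: SurvivalSimConfig) -> pd.DataFrame:
    """Survival table: subject_id, time, event (1=death, 0=censored), group."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group in sorted(cfg.groups):
        n, lam = cfg.groups[group]
        t = rng.exponential(1.0 / lam, size=n)
        event = t <= cfg.censor_time
        obs = np.minimum(t, cfg.censor_time)
        for i in range(n):
            rows.append((f"{group}_{i + 1:03d}", float(obs[i]), int(event[i]), group))
    return pd.DataFrame(rows, columns=["subject_id", "time", "event", "group"])
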