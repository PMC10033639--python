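# Methods

## Screen scoring model

The screen contrasts pooled knockout clones grown in two host arms: WT mice
(CD8 T cells intact) and CD8KO mice. A clone depleted in WT but not CD8KO
hosts marks a gene whose loss sensitizes tumor cells to CD8-mediated
killing; symmetric logic applies to enrichment.

Scoring follows the published recipe exactly and makes its implicit choices
explicit:

* **Count filter.** A (guide, sample) observation is discarded when raw
  reads < 40. The filter is applied per guide per sample; it never alters
  stored counts and does not affect normalization totals (the formula
  normalizes by "total reads for all sgRNAs in the sample").
* **Normalization.** `norm = raw / sample_total × 10⁶ + 1`. The +1
  pseudocount floors every value at 1 and makes fold changes well defined.
  Conservation Σ(norm − 1) = 10⁶ holds per sample to relative 10⁻⁹ in
  double precision.
* **Arm aggregation.** The published analysis reports one fold change per
  guide per arm but not the cross-mouse combination rule. We use the
  arithmetic mean of normalized counts over the arm's filter-passing
  samples, and require passes in at least max(2, ⌈half the arm's samples⌉)
  samples; otherwise the guide is `low_count_excluded` for comparisons
  involving that arm. Mean-of-normalized (rather than per-mouse fold
  changes) matches the single-fc-per-guide presentation of the source
  figures; the half-the-samples floor is a robustness compromise for a
  design where each mouse is an independent bottlenecked replicate.
* **Fold change and calls.** fc = mean_WT / mean_CD8KO. Guides with both
  arm means < 5 (normalized) are `unanalyzable` — the same rule the
  original analysis used when low counts "prevented further analysis".
  The NTC envelope is [min, max] of fold changes over usable non-targeting
  guides (≥ 2 required); calls use strict inequalities, so a tie at the
  bound stays neutral and NTCs are never called. With N usable NTCs, a
  null targeting guide escapes the envelope with probability ≈ 2/(N+1)
  (~2% at the default 100 NTCs), which the neutral-screen suite confirms
  empirically.
* **Gene level.** Mean log₂fc over usable guides; depletion rank 1 = most
  negative; a two-sided Welch t of the gene's guide log₂fcs against the NTC
  guide log₂fcs gives `p_vs_ntc` (the source reports significance for the
  top hit without naming a test; Welch on log fold changes is the natural
  choice), with Benjamini-Hochberg q as a secondary column. Genes with no
  usable guide are emitted unranked and flagged.
* **Temporal test.** Within one genotype, the gene's per-guide normalized
  counts pooled over mice are compared early vs late with an unpaired
  two-tailed Welch t (no multiplicity adjustment, mirroring the published
  legend). The raw ≥ 40 filter is deliberately *not* applied to these
  observations: a clone swept to zero reads at the late stage is the
  signal, and filtering it out would bias the test toward the null.
  Degenerate inputs (zero variance in both stages) return p = 1 for equal
  means and a positive-underflow-floor p with a flag otherwise.
* **Coverage.** ⌊cells_per_mouse × n_mice / n_guides⌋, floor rounding —
  200,000 × 11 / 3,000 = 733X, ×12 = 800X.

## Screen simulator

The generator reproduces the features the scoring is sensitive to, nothing
more:

* plasmid abundance ~ lognormal(0, σ), σ = 0.5 (typical library skew),
  normalized to a probability vector;
* per mouse, a multinomial implantation bottleneck of exactly
  `cells_per_mouse` = 200,000 cells (clonal sampling noise);
* selection acts multiplicatively: clone weight × exp(s·t), with s the
  per-generation log-fitness of that gene's knockouts in the mouse's arm
  (0 for unlisted genes and always 0 for NTCs) and t the stage's generation
  count (defaults: early = 6, late = 12);
* sequencing is a single multinomial of Poisson(depth) reads per sample
  (optional Dirichlet pre-draw adds overdispersion; off by default).

Each simulated mouse belongs to one (genotype, stage) cohort of
`mice_per_arm` = 4 animals, matching the barcoded early/late sacrifice
design and guaranteeing ≥ 2 samples per design cell for the temporal test.
Per-sample depth defaults to 10⁷ reads: at the 420-guide default library a
planted clone with s_WT = −1 still carries ~140 raw reads per early WT
sample (clearing the 40-read filter, so the gene receives a depletion
rank), while its late-stage counts collapse to ~0 — the regime the filter
and the temporal test are designed around. The published screen reports no
per-sample depths; this value was fixed from that desk calculation. What
the simulator does not model: PCR jackpotting, guide-efficiency
heterogeneity, inter-mouse tumor microenvironment variation. Passing tests
therefore demonstrate correctness of the scoring arithmetic and calibration
of its null behavior, not robustness to those real-data artifacts.

## FASTQ quantification

Reads are `barcode + anchor + protospacer + …`. Demultiplexing is exact
barcode matching (duplicates rejected at sheet load); counting matches the
20-mer after the first anchor occurrence (or at a fixed offset) exactly
against the library, forward strand only, qualities ignored. An optional
1-mismatch mode uses a precomputed Hamming-1 neighborhood with ambiguous
k-mers discarded; exact protospacer hits always win. Read fates are
conserved: assigned + unassigned + ambiguous + skipped = total, per sample.
The synthetic FASTQ emitter is the round-trip oracle: counts → reads →
counts is the identity.

## Single-cell stratification

* **Cell typing** is marker-argmax over mean log1p(CPM), a deliberate
  simplification (the original study reused upstream annotations that are
  not re-derivable); ties break by type-name order and an all-zero marker
  profile is `unassigned`. Ground-truth labels from the simulator are the
  test surface.
* **Stratification**: per-sample fraction of tumor cells with focal CPM > 0,
  split at the cohort median (midpoint median; ties at the median go to
  "low"). All-identical frequencies degrade to all-low with a warning.
* **AUC score**: genes ranked per cell by descending expression, ties broken
  by one seeded random permutation of the gene axis (recorded seed;
  reproducibility over an undocumented tie policy). The recovery-curve area
  uses K = ⌈0.05 · n_genes⌉ (the AUCell convention). The implementation
  uses the closed form Σᵢ max(0, K − rᵢ + 1) over set-gene ranks, equal to
  Σ_{k≤K} c(k) by exchanging the order of summation; tests verify against
  the exhaustive sum. The score depends on expression only through ranks,
  so it is invariant to per-cell monotone transforms.
* **Mann-Whitney**: exact null enumeration when both n ≤ 8 and the pooled
  sample is tie-free; otherwise the tie-corrected normal approximation
  *without* continuity correction, so identical groups give exactly p = 1.
* **Welch DE**: per-gene Welch t with Satterthwaite df between
  focal-positive and focal-negative tumor cells (≥ 2 cells per stratum),
  BH q alongside raw p.

The single-cell simulator plants, in the tumor cells of samples whose focal
detection probability lies below the cohort median, an exp(coupling)-fold
increase of a designated signature (default coupling = 1). Negative-binomial
counts (dispersion 0.5), 10% dropout, CPM normalization; 28 samples × 60
cells over ~230 genes. Under coupling = 0 the dichotomize-and-compare
pipeline rejects at ~5% (the acceptance suite measures the rate over 200
replicates): the per-cell Mann-Whitney is close to nominal here because
cells are independent given the sample under the null. Real cohorts have within-sample correlation that
this generator omits, so on real data the per-cell test is anti-conservative
— the same caveat applies to the published analysis it mirrors.

## Survival

Kaplan-Meier and log-rank are standard procedures and are delegated to
lifelines behind this package's validated surface; tests verify them
against independent hand tabulations of the product-limit and O−E/V
formulas. Conventions: events precede censorings tied at the same time;
median = smallest t with S(t) ≤ 0.5, reported as an explicit undefined
sentinel when the curve never reaches 0.5; two-sided p from chi-square with
df = 1.

## Problem sizes and numerical choices

Default study sizes — 100 genes × 4 guides + 20–100 NTCs, 16 samples at 10⁷
reads; 28 samples × 60 cells; 200 stratification replicates and 1000
log-rank null replicates — were chosen so the Monte-Carlo standard error of
every reported rate stays below ~1.5 percentage points. Tolerances: oracle
agreements asserted at 10⁻¹⁰; CPM conservation at 10⁻⁶ relative;
calibration bands at roughly ±3 Monte-Carlo standard errors around the
nominal rate.

## Known limitations

* No MAGeCK/BAGEL-style hierarchical ranking, copy-number correction or
  guide-efficiency modeling; the NTC envelope is an order statistic and its
  width scales like 1/N_NTC.
* Cell typing ignores doublets, ambient RNA and continuous states.
* The compositional side effect of a highly expressed focal gene on CPM
  values is present in both simulator and analysis (as it is in real CPM
  data); the rank-based AUC largely absorbs it.
* No Cox models, multi-group trend tests or interval censoring.
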