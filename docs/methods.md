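# Methods

`screenkit` implements the quantitative analysis stack of a CRISPR
drug-resistance screening study in EGFR-mutant lung cancer: pooled-screen
enrichment statistics, cross-screen integration, arrayed high-content
translocation scoring, gene-set/TF enrichment, and IHC H-scores. Every
stage can be exercised on synthetic data with planted ground truth; this
note records the models, the defaults and why, and what the synthetic
benchmarks do and do not establish.

## Pooled screen model

Guide counts are modelled as negative binomial with mean `mu` and
variance `mu + phi * mu^2` (dispersion on the quadratic term, shared
across guides — the common parameterisation for screen counts). The
analysis pipeline is:

1. **Size factors** — median-of-ratios against the per-guide geometric
   mean pseudo-reference, computed on guides with all-positive counts.
   This is the standard depth normalisation for count matrices and is
   exactly scale-equivariant.
2. **Guide test** — per guide, the fold change is
   `log2((mean normalised drug + 0.5) / (mean normalised vehicle + 0.5))`
   (pseudocount used for the fold change only, never for the test).
   Dispersion is estimated by pooled method of moments on the normalised
   vehicle replicates, `phi = sum(s2_g - m_g) / sum(m_g^2)`, floored at
   1e-8; with a single vehicle replicate the floor applies and the test
   degenerates towards Poisson. The enrichment p-value is the upper NB
   tail of the *summed* raw drug count given the vehicle-derived rate
   scaled by the total drug depth; the sum of `r` NB(mu, phi) draws is
   NB(r*mu, phi/r), so the sum uses dispersion `phi / n_drug`. The
   depletion p is the analogous lower tail. Normalised ranks `u` are
   mid-rank ties of ascending p within each direction, divided by the
   total number of guides.
3. **alpha-RRA** — per gene with sorted ranks `u_(1) <= ... <= u_(k)`,
   only guides with guide-level p below `alpha` (default 0.05) are
   selected; the score is
   `rho = min_j Beta(j, k - j + 1).cdf(u_(j))` over selected positions,
   or 1 when nothing is selected. The permutation p-value reassigns
   guides to genes preserving guides-per-gene (`p = (b + 1) / (B + 1)`,
   default B = 10 000; an exhaustive mode enumerates all assignments on
   small universes and is verified against brute-force enumeration).
   Null distributions are shared across genes with equal guide counts.
   Benjamini-Hochberg FDR is applied per direction.
4. **Hit calling** — a resistance hit is enriched, has linear fold change
   `2^median guide log2FC >= 2` and permutation p < 0.005. The
   fold-change boundary is inclusive (`>=`) and configurable; only the
   enriched direction feeds resistance calling, the depleted direction is
   exposed for sensitizer analyses.

Comparisons are drug vs vehicle; the plasmid library sample is generated
and carried for QC but does not enter the test.

## Cross-screen integration

Hit tables from independent screens (cell line x drug x knockout or
activation modality) are combined by counting, per gene, the screens in
which it is a hit; genes absent from a screen count as non-hits there.
Genes with recurrence >= 4 (configurable) form the core resistance set.
Knockout and activation screens are counted symmetrically. Gene matching
is exact and case-sensitive; alias resolution is out of scope.

## High-content arrayed screen

Per-cell records carry nuclear and cytoplasmic mean intensities per
channel, area, and a border flag. Scoring steps:

* **QC filter** — border cells are removed; per well, cells are ranked by
  area and `floor(n * 0.1)` cells are trimmed from each end (ties broken
  by stable input order, so equal-area cells are trimmed in input order).
* **Well summary** — the per-well statistic is the *median* over retained
  cells (robust to segmentation outliers; no specific statistic is
  mandated by the assay description, so the median is this package's
  choice). Marker intensity per cell is the mean of the nuclear and
  cytoplasmic compartment means; the translocation statistic is the
  per-cell nuclear/cytoplasmic ratio (cells with zero cytoplasmic signal
  are excluded rather than clamped).
* **Two-point normalisation** — for pathway markers,
  `normalised(x) = -100 * (ref_max - x) / (ref_max - ref_min)` with
  `ref_max` the mean of NTC-vehicle well statistics (maps to 0) and
  `ref_min` the mean of NTC-drug well statistics (maps to -100). The map
  is affine, so it is equivariant under any affine transformation of the
  raw intensities.
* **Translocation hits** — per perturbation, the Nuc:Cyt fold change is
  the mean of its well medians divided by the mean of treatment-matched
  NTC well medians; a hit needs a fold strictly greater than 1.2
  (">20% increase"). Hits are evaluated under drug by default; the
  evaluation arm is configurable because the assay description does not
  pin it down. Replicate wells are averaged at the well-median level.
* **Association** — a 2x2 Fisher exact test relates translocation-hit
  status to "pathway preservation", defined here as a normalised effect
  >= -50 (half-rescue) on pAKT or pERK; the preservation floor is a
  package choice and configurable. The Fisher p sums hypergeometric
  probabilities of all margin-fixed tables no more likely than the
  observed one. The rank-sum test is exact (full enumeration over group
  assignments, midranks for ties) when both samples have <= 8
  observations, and the tie-corrected normal approximation (no continuity
  correction) otherwise.

## Enrichment

Over-representation is the upper-tail hypergeometric test of the overlap
between a DE list and each gene set, intersected with an explicit
background; BH FDR across sets. The odds ratio comes from the overlap
2x2 table with a Haldane 0.5 correction when a cell is zero. The
combined score is `-ln(p) * odds_ratio`: the widely used combined metric
of significance and effect size is not reproducible without the original
tool's background-rank simulations, so this documented stand-in is used
and labelled as such in outputs. TF activity runs the same test on TF
target sets (significance p < 0.01); the display "activity" is the
combined score min-max scaled across the profile then `log2(1 + scaled)`
— a display transform chosen here, since none is mandated.

DE lists are filtered at p < 0.01 and linear |FC| >= 1.5 (inclusive
boundary on FC).

Pre-ranked enrichment follows the weighted KS running sum (weight
exponent 1 on |score|; 0 gives the unweighted closed form). P-values use
gene-label permutations, sign-matched, because inputs are pre-ranked
lists rather than sample-level phenotypes. A set spanning the entire
list yields ES = 0 with a warning.

Per-cell signature (module) scores expect library-size-normalised,
log1p-transformed expression (`normalize_counts`, scale 1e4). Genes are
ranked by average expression and cut into 24 equal-count bins; each
signature gene contributes 100 control genes sampled with replacement
from its bin, and the score is the per-cell signature mean minus the
pooled control mean. Bin and control counts follow the conventional
defaults of this score family and are configurable; a constant matrix
scores exactly 0.

## IHC H-score

`H = %1+ + 2 * %2+ + 3 * %3+`, in [0, 300], computed per compartment
(nucleus, cytoplasm) from the percentage of tumour cells per staining
intensity category. Percentages are the canonical input (a
count-to-percentage helper is provided) and carry full precision;
rounding happens only at report time. Group comparisons reuse the
rank-sum test for consistency with the rest of the pipeline — a package
choice, since the in-vivo comparison does not name its test.

## Synthetic-data generators

The generators define the benchmark conditions; their defaults are the
study conditions where stated, and fixed package choices otherwise.

* **Pooled screen** (`ScreenSimConfig`): 1000 genes x 5 guides, 20
  resistant genes at planted log2FC 2 under drug, expected depth 300
  reads/guide, dispersion 0.1, 2 replicates per arm, plus one plasmid
  sample. Per-guide means scatter lognormally around the mean depth
  (sigma 0.25) to emulate uneven library representation.
  `dropout_fraction = 0.1` marks guides of resistant genes as inefficient
  (no effect): a ~10% inefficient-guide rate is typical of modern
  genome-wide libraries and exercises alpha-RRA's partial-evidence
  behaviour.
* **Cell tables** (`CellSimConfig`): lognormal areas (median ~490 um^2)
  and intensities (median-1 multiplicative noise, CV 0.3 — the assay
  gives no noise model, and lognormal respects positive support and
  multiplicative optics); baseline Nuc:Cyt 0.8 (cytoplasmic retention in
  untreated cells); border cells at 10%; drug scales pathway markers to
  0.10-0.20 of baseline (strong pathway shutdown) and multiplies the
  Nuc:Cyt ratio by 1.5 (acute translocation under treatment). Planted
  perturbation folds multiply the Nuc:Cyt ratio; the NTC fold is 1 by
  construction.
* **DE lists**: each background gene enters the DE list with probability
  0.2, boosted by the enrichment factor inside active sets. The null
  calibration checks run on a genome-scale background (20 000 genes) with
  large sets (300-2000 genes) so that the discrete hypergeometric p has a
  dense support: the maximum pmf step (~0.02-0.03) then sits below the
  1000-sample KS critical value at alpha 0.01 (~0.052), making the
  uniformity test meaningful rather than an automatic rejection of
  discreteness.
* **IHC**: multinomial category draws converted to percentages.

What the synthetic benchmarks show: the estimators recover planted
effects at the study's cut-offs (sensitivity >= 0.90 / precision >= 0.95
for the pooled screen; >= 0.95 / false-call <= 2% for translocation) and
hold their nominal error rates under the null. What they do not show:
robustness to real-data pathologies absent from the generators —
copy-number effects and GC bias in counts, segmentation errors beyond
border/size artefacts, batch and plate-position effects, correlated
guides, or gene-set redundancy.

## Numerical choices and degenerate inputs

* p-values are clipped into `(tiny, 1]`; permutation p-values are bounded
  below by `1/(B+1)`.
* The pooled dispersion floor is 1e-8; two identical arms therefore give
  `log2FC = 0` with `p_enrich >= 0.5` rather than NaN.
* Fisher's summation uses a `1 + 1e-7` relative tolerance when comparing
  table probabilities (ties at float precision count as "as likely") and
  snaps totals within 1e-12 of 1 to exactly 1.
* A two-point scale with equal anchors (no assay window) is an error, as
  is a screen comparison without both arms, an empty rank-sum sample, or
  a gene set that is empty after background intersection (silently
  skipped per set, error when the whole query is outside the background).
* All stochastic operations take explicit seeds; the pipeline derives
  per-stage seeds from the config seed and never touches global state.

## Problem sizes

The shipped test suite runs the full benchmark grid (5-seed recovery and
10-seed null calibration at 1000 genes x 5 guides with B = 10 000;
20-seed translocation calling at 2000 cells/well; 1000-seed enrichment
calibration) in well under a minute of compute; the end-to-end pipeline
smoke runs use 40-200 genes and 40-300 cells/well, sizes chosen so the
whole suite stays fast while every statistical path is exercised at the
benchmark scale.
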