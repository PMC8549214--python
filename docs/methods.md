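# Methods

`zhengomics` re-implements, as a tested library, an integrated strategy
for differentiating two Traditional Chinese Medicine (TCM) syndromes of
coronary heart disease (CHD) — Cold Congealing and Qi Stagnation (CCQS)
and Qi Stagnation and Blood Stasis (QSBS) — by combining serum
proteomics, serum metabolomics and network pharmacology of the herbal
formulae prescribed for each syndrome. Patient-level data for this kind
of study are typically not deposited, so the package ships a synthetic
cohort generator with planted ground truth; every statistical claim the
test-suite makes is a claim about recovery of that planted structure.

## Differential proteins

Proteins are called differential between a syndrome group and healthy
controls (HC) by the volcano rule: raw-scale fold change FC > 1.1
together with an equal-variance Student t-test p < 0.05 on log2
intensities. FC is folded to ≥ 1 (`max(m_A/m_B, m_B/m_A)` on raw group
means); direction is the sign of the disease-vs-control difference. No
multiplicity correction enters the call (the rule is a fixed FC+p
screen); Benjamini–Hochberg q-values are attached for information.
Welch's t-test and log-scale FC are available behind flags. Missing
intensities are imputed per feature with half of the minimum observed
value, the standard left-censoring surrogate; features never observed
are dropped. QC consists of per-feature CV over the 11 standard-sample
replicates (sd/mean on the raw scale, ddof = 1) and pairwise Pearson
correlation of samples on log2 intensities.

Clinical baseline tables are tested with one-way ANOVA computed from
per-group (n, mean, sd) — algebraically identical to raw-data ANOVA —
and Pearson chi-square homogeneity tests without continuity correction
for comorbidity counts.

## Differential metabolites

The multivariate screen is O-PLS-DA in the Trygg–Wold formulation: each
orthogonal round computes the PLS weight w ∝ Xᵀy (unit norm), score
t = Xw, loading p = Xᵀt/(tᵀt), then the orthogonal weight
w_o = p − (wᵀp)w (normalised), score t_o = Xw_o and loading p_o, and
deflates X by t_o p_oᵀ; a single predictive component is fitted on the
deflated matrix. With zero orthogonal rounds the model is exactly PLS-DA
component 1, and orthogonal scores are uncorrelated with the centred
class vector by construction — both are asserted as invariants.

Columns are mean-centred and unit-variance scaled before fitting (the
metabolomics default, making VIP comparable across features; Pareto
scaling is a flag). VIP is computed over the predictive component only:
VIP_j = sqrt(J·Σ_a SSY_a (w_aj/‖w_a‖)²/Σ_a SSY_a), which forces
mean(VIP²) = 1 identically. Q² = 1 − PRESS/SS uses seeded, stratified
ten-fold cross-validation with full refit (including centring/scaling)
per fold; folds shrink with a warning when the smaller class is smaller
than the fold count.

The univariate screen is a two-sided Mann–Whitney U test per feature
(exact for small tie-free samples, tie-corrected normal approximation
otherwise) with BH adjustment. A metabolite is differential when
VIP > 1 **and** q < 0.05 (untargeted) or p < 0.05 (targeted); all
inequalities strict. One orthogonal component is the default; the
original component count is not knowable from a published study, and one
round is the common choice for binary contrasts.

## Network pharmacology

Compound activity rules are per source: TCMSP-style records are active
iff oral bioavailability OB ≥ 30 % and drug-likeness DL ≥ 0.18
(inclusive, mirroring the ≥ symbols); ETCM-style records iff their
drug-likeness grading is good or moderate; pharmacopeia quality markers
(Q-markers) unconditionally. A compound recorded under several sources
is active if any rule accepts it, and its target sets are unioned. A
formula's putative target set is the union over its herbs' active
compounds; the signature targets of a syndrome are the triple
intersection over its three formulae; F1/F2-specific signatures come
from the two-way Venn partition. Disease relatedness uses Jaccard
indices on shared genes (JIg) and shared variants (JIv), retained iff
JIg > 0.2 AND JIv > 0.05 (strict; the conjunction is the stricter
reading of two thresholds listed side by side, OR is a flag). Drugs are
binned by the longest matching ATC-code prefix among the configured
categories (C cardiovascular, A10 antidiabetic, A08 anti-obesity, B01
antithrombotic, case-insensitive; multi-code drugs may appear in several
bins), and signature partitions are intersected with each bin's
pharmacological target union.

## Graph analytics

Gene prioritisation uses Zhou-style label propagation,
F = αSF + (1−α)Y with S = D^(−1/2)WD^(−1/2), α = 0.5, iterated to
sup-norm tolerance 1e−9; the fixed point equals
(1−α)(I−αS)^(−1)Y, and the dense solve is kept as an independent oracle.
Seeded differential proteins are expanded by the k = 10 top-scoring
non-seeds (ties broken by score desc, id asc, so expansion is
reproducible). Integrated metabolite–gene subnetworks are induced on
matched seed metabolites/genes plus "bridge" nodes adjacent to at least
two matched seeds (≥ 1 behind a flag); isolated matched seeds are
dropped, and an `origin` attribute (DM / DP / signature / bridge, in
that precedence) partitions the nodes.

## Enrichment

Over-representation uses the hypergeometric upper tail
p = P(X ≥ k) with X ~ Hypergeom(N, K, n), equal to the one-sided Fisher
exact test on the corresponding 2×2 table (asserted against scipy's
Fisher implementation on random configurations). The default gene
universe is every id annotated to at least one loaded set — published
platforms use proprietary backgrounds that cannot be reproduced — and is
overridable. Joint gene+metabolite queries run the same single test on
the combined namespace (namespaces must be disjoint). Report percentages
are 100·k/|input list| rounded to two decimals.

Term redundancy is summarised DAVID-style: pairwise Cohen's kappa
between term membership profiles over the query items, then greedy
seed-and-merge clustering. The "high" stringency preset is κ ≥ 0.85,
seed-partner minimum 3, merge when shared membership reaches 0.5 of the
smaller group — a declared surrogate for DAVID's unpublished preset; all
three numbers are config keys. Cluster enrichment score is −log10 of the
geometric mean of member p-values (p floored at 1e−300).

## Biomarker panels

Panels are fixed marker lists (marker selection is input, not
inference), fitted by maximum-likelihood logistic regression via
Newton/IRLS on standardized markers (tolerance 1e−8, ≤ 100 iterations).
Complete or quasi-complete separation is detected as a diverging
coefficient norm and triggers a ridge refit (penalty 1e−6, intercept
unpenalised) with a flag; constant markers get coefficient 0. AUC is the
Mann–Whitney U statistic over n₊n₋ with ties counted ½; the explicit
threshold-sweep curve's trapezoid integral equals the U-based AUC to
1e−12 and both are computed. Cross-syndrome evaluation freezes the
training standardization and coefficients. AUCs are apparent (no
resampling), matching how such panels are usually reported.

## Synthetic data generator

The generator emulates the study conditions: 44 CCQS / 37 QSBS / 30 HC
serum samples plus 11 standard replicates; 470 identified and ~388
reliably quantified proteins; 1000 untargeted metabolomics features and
306 targeted metabolites; planted differential features of
(17, 16, 7) proteins and (90, 115, 110) untargeted metabolites
(CCQS-specific, QSBS-specific, shared; the targeted triple is
(28, 35, 34), the same proportions at 306 features).

* **Intensities.** Feature baselines are log-normal, spanning ~6 decades
  (log2 ∈ [12, 31]) for quantified proteins; cohort samples add
  biological noise of sd 0.2 on log2 (~15 % CV). This tightness is
  deliberate: a 1.1-fold-change threshold only discriminates when null
  dispersion is small, which is exactly the regime implied by a study
  that calls only ~24 of 388 proteins differential at these sample
  sizes. Standard samples carry multiplicative technical noise
  calibrated so their CV ≈ 0.05, giving ≥ 95 % of features CV < 0.10.
* **Effects.** Planted features shift by ±`effect_log2fc` (default 0.5)
  in their syndrome's samples; shared features shift identically in
  both syndromes. Planted proteins are drawn from the upper 70 % of the
  abundance range — differential calls in practice concentrate in
  well-quantified proteins.
* **Missingness.** Dropout is missing-not-at-random at the cell level: a
  single global soft detection floor, with each cell missing with
  logistic probability in its own log2 intensity (scale 1.5 log2
  units); the floor is calibrated by bisection so the quantified tier
  averages `missing_rate` = 1 % missing. Identified-only proteins carry
  heavy per-feature censoring (~80 %), so a presence filter (≥ 70 % of
  cohort samples) recovers the quantified tier. Metabolomics tables are
  complete, as they would be after upstream peak processing.
* **Knowledge base.** Six formulae with herb counts (7, 5, 5, 2, 11, 3)
  over 26 distinct herbs (shared herbs fill the last seven slots); each
  herb carries 12–24 compounds whose OB/DL/grading attributes straddle
  the activity thresholds. Per-syndrome signature cores (18 common + 12
  CCQS + 10 QSBS genes) are injected into every formula of the syndrome
  through a guaranteed-active Q-marker carrier, so the triple
  intersection provably contains the core; drug target sets couple each
  ATC category to one core (C→common, A10→CCQS, A08/B01→QSBS). Disease
  records are constructed so exactly 15 of 40 candidates clear both
  Jaccard thresholds. Two planted pathways collect syndrome-specific
  planted proteins and metabolites so enrichment signal survives into
  the integrated view; a scale-free PPI graph is enriched with
  high-weight neighbours of each syndrome's planted proteins; the
  metabolite–gene association graph links pathway co-members.
* **Determinism.** Each generator draws from its own seeded substream,
  and shared identities come from a dedicated layout stream, so any
  subset of generators can be called in any order with identical
  results; one seed reproduces byte-identical serialized outputs.

What the generator does **not** emulate: raw spectra, chromatographic
drift, batch effects beyond the standard-sample design, correlated
protein co-regulation, non-Gaussian biological tails, or identifier
ambiguity across knowledge bases. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
noise model, not robustness to everything real cohorts exhibit.

## Problem sizes and numerical choices

The default end-to-end run (full study-scale cohort) takes ~1 s; the
ten-seed recovery suite a few seconds. Q² fold assignment is seeded and
stratified with ties resolved by sample order; all significance
thresholds are strict inequalities; degenerate cases are defined
explicitly (zero-variance t-test features → p = 1, empty Jaccard
union → 0, degenerate kappa pairs → 0 with a warning, propagation with
α = 0 → the seed indicator). Report JSON is sorted and type-normalised
so identical configuration and seed give byte-identical files.
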