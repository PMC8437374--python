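# Methods

This note documents the models, numerical choices and known limitations of
`guildscope`. Notation: tables are taxa × samples; n is the number of
samples, p the number of taxa/variables; "GA" is the case group
(gestational anemia, Hb < 100 g/L at the third trimester), "control" the
reference.

## Synthetic cohort model (`synthio`)

The generator emulates a prospective two-trimester pregnancy cohort with
genus-level 16S data. For each subject i and timepoint t:

1. draw one latent factor z_{ib} ~ N(0,1) per guild block b;
2. taxon j in block b has log-abundance
   `a_ij = mu_j + sqrt(rho) z_{ib} + sqrt(1-rho) e_ij`,
   with e_ij ~ N(0,1), so any two same-block taxa have latent correlation
   exactly `rho = within_block_corr` (default 0.7; blocks are assigned
   round-robin so sizes are balanced);
3. taxon baselines mu_j ~ N(0, 1.5²) give a realistic rank-abundance
   spread; at T3 a fixed per-taxon shift delta_j ~ N(0, 0.3²) is added,
   emulating compositional drift over pregnancy;
4. planted differential taxa get `log(2) × log2fc` added for case subjects;
5. abundances are exponentiated and normalised (softmax), and counts drawn
   `Multinomial(depth_i, composition_i)` with depth_i log-normal around
   `depth_mean` (default 40,000 reads, σ = 0.25) — above the conventional
   rarefaction depth of ~31,291 so rarefaction has work to do, and with
   ~16% of samples falling below it, so the drop rule is exercised.

Outcome labels: if per-block log-odds are supplied, the label is Bernoulli
with `logit P(case) = alpha + Σ_b beta_b z-score(block-b relative
abundance at T2)`, where alpha is solved (Brent) so the expected case
fraction equals `n_case/(n_case+n_control)` (defaults 156/558, the study
prevalence). Otherwise exactly n_case random subjects are labelled cases.

Thirteen covariates mirror a pregnancy-cohort questionnaire (age, BMI,
parity, gravidity, income, education, passive smoking, antibiotic use,
supplement use, pre-/during-pregnancy alcohol and caffeine), drawn
independently of the outcome; clinical indices are Gaussian with group
shifts in SD units, and case Hb at the outcome timepoint (the last
timepoint generated) is drawn from a normal truncated below 100 g/L so the
diagnostic definition holds by construction.

One global seed expands into per-stage generators via
`SeedSequence(seed, spawn_key=(stage_index,))` with a frozen stage table,
so individual stages are reproducible in isolation.

What the generator does **not** emulate: taxonomic misassignment, raw-read
artefacts, zero-inflation beyond what multinomial sampling induces,
within-subject longitudinal autocorrelation (the two timepoints are
independent draws sharing only taxon-level baselines), and covariate–
outcome confounding. Passing tests therefore demonstrate correctness of
the machinery under a favourable, well-specified generative model, not
performance on real stool data.

## Cohort statistics

Exclusion criteria are applied in order; a multiply-flagged subject counts
once, under the first criterion (flags are generated mutually exclusive,
so flow-chart subtraction is exact). χ² is the uncorrected Pearson
statistic — the variant that reproduces the published baseline p-values
(0.98 fetal gender, 0.48 parity; gravidity computes to 0.7447 against a
printed 0.75, a rounding artefact of the source table). The continuous
test is Welch's unequal-variance t; published continuous p-values are not
reproducible from printed summaries and are not targeted. Percentages are
always recomputed from counts; printed rounding is presentation-only.

## Diversity and PERMANOVA

Shannon uses log base 2. Rarefaction subsamples without replacement
(multivariate hypergeometric) to exactly the requested depth and drops
shallower samples, mirroring standard practice. PERMANOVA uses Anderson's
among/within squared-distance decomposition with the +1 permutation
convention, so p ∈ [1/(B+1), 1]; a degenerate matrix (all distances equal)
gives F identical across permutations and p = 1. PCoA double-centres
−d²/2 and reports negative eigenvalues but excludes them from proportions
explained. UniFrac is delegated to scikit-bio (which requires a rooted,
two-child-root tree); unweighted UniFrac on a star tree equals Jaccard
distance, which is used as a property test. The Wilcoxon rank-sum test is
exact (full enumeration) when both groups have ≤ 20 tie-free observations,
otherwise the tie-corrected normal approximation.

## Differential abundance

The LEfSe-style pipeline is deterministic: no bootstrap subsampling, so
identical inputs give identical outputs; the threshold semantics
(q < 0.05, |LDA| > 2) are unchanged. FDR is applied across taxa at the
Kruskal–Wallis stage. The effect size rescales relative abundances to
counts-per-million; with one feature and two classes the discriminant axis
is the feature itself, so the score is `sign × log10(1 + |Δ mean CPM|)` —
0 for identical class means, and > 2 only when class means differ by more
than ~10⁻⁴ in relative abundance. The covariate-adjusted models fit OLS of
arcsine-√ proportions (log10 with half-minimum pseudocount available) on
group + covariates; categorical covariates are dummy-encoded against the
alphabetically first level; rank deficiency is an error naming the
collinear columns.

## Guild discovery and the partial-correlation network

Taxa are clustered hierarchically on `1 − Spearman ρ` between abundance
profiles (Ward linkage by default; clustering on rows of the Kendall
matrix is available behind a flag). For each candidate k the tree is cut
and every pair of clusters is tested by PERMANOVA on `D = 1 − τ` (Kendall
τ-b, tie-corrected — genus vectors are heavily tied; constant taxa get
τ = 0 with a warning). The chosen k is the largest candidate with all
pairwise p < 0.05; if none qualifies, the k with maximal mean
between-cluster R² is used and logged prominently, with full per-k
diagnostics always retained so users can override.

A caveat discovered while validating this rule: because candidate clusters
are cut from the same distance matrix the PERMANOVA then tests, the
procedure is anti-conservative under pure noise — Ward picks the split
that maximises separation, and the permutation test can call it
significant. With genuinely structured data the rule recovers the planted
guild count reliably (median adjusted Rand index 1.0 over ten seeds at
ρ = 0.8); on structureless data it tends to report the largest candidate k
rather than falling back. Users should read the diagnostics, not just k.

The network is the graphical lasso on the sample correlation matrix over a
100-point log-spaced λ path from λ_max (empty graph) down to 0.01·λ_max,
selecting λ by EBIC with γ = 0.5 (`EBIC = −2ℓ + E log n + 4γE log p`).
Edge weights are partial correlations `−ω_ij/√(ω_ii ω_jj)`. Because lasso
shrinkage of strong edges lets tiny spurious edges absorb residual
marginal correlation, edges with |partial correlation| below the detection
bound `sqrt(log(p(p−1)/2)/n)` (Jankova & van de Geer; the same remedy as
qgraph's `threshold` option) are pruned after selection — this is what
removes the transitive X–Z edge in the X→Y→Z chain check while leaving
genuine edges untouched. Non-positive-definite input correlations are
diagonally regularised and logged.

## Clinical associations

Partial Spearman correlations rank-transform *both* the variables and the
covariate design columns before residualising (residualising ranks on raw
covariates leaves monotone leakage; ranking the design removes it — binary
dummies are unaffected). p-values use the t approximation with
`df = n − 2 − #covariates`; BH is applied jointly across the whole taxa ×
indices grid, which is the conservative reading of a blanket "FDR < 0.05".
Missing clinical values are handled complete-case per index with counts
logged. Point-biserial correlation is Pearson on a 0/1 encoding and its
p-value coincides with the pooled two-sample t-test (property-tested).

## Prediction

Splits are class-stratified at a 0.6 discovery fraction by default, with
exact per-class discovery counts available (e.g. 91/244 vs 65/158). All
feature selection — differential genera, guild membership — happens on
discovery samples only, and validation features are standardised with
discovery means/SDs, so validation AUCs are leakage-free (stricter than
typical published pipelines, where selection on the full cohort is
common). The classifier is ridge-penalised logistic regression (C = 1);
nothing deeper is warranted for ≤ 10-feature biomarker panels, and the
ridge stabilises correlated guild abundances. AUC is the tie-aware
Mann–Whitney statistic computed from mid-ranks, identical to exhaustive
pair counting; DeLong variance uses placement values computed in
O(n log n) via mid-ranks, with normal-approximation CIs truncated to
[0, 1] (a degenerate variance at AUC 0 or 1 collapses the CI with a
warning).

## Problem sizes used in tests and the acceptance script

Calibration suites use 500 replicates at 199 permutations (PERMANOVA
type-I error), 500 binormal replicates at n = 100/100 (DeLong coverage),
and 100 study-sized (156/402) null communities of 80 genera (LEfSe
specificity). Structure recovery plants 4 blocks of 15 genera at ρ = 0.8,
n = 500; the prediction comparison uses the full study geometry (156/402,
two timepoints, depth 40,000) with the outcome driven by one guild at 1.0
log-odds per SD and clinical shifts set to zero, over 10 seeds. These
sizes make the whole suite run in a few minutes on one CPU while keeping
every rate estimate's Monte-Carlo error well inside its acceptance band.

## Known limitations

- Published AUCs and taxon lists from any real cohort are out of reach by
  design: the synthetic generator defines the test conditions, not the
  cohort that motivated them.
- The LDA effect size is a deterministic stand-in for LEfSe's
  bootstrap-averaged discriminant; scores agree in sign and threshold
  behaviour, not numerically.
- The k-selection rule's noise behaviour (above) means the reported guild
  count should be read together with its diagnostics table.
- Two-timepoint data are independent draws per subject; do not use the
  generator to study within-subject temporal dynamics.
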