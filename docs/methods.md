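# Methods

This note documents the statistical models implemented in `evcargo`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Study design and data model

The pipeline assumes a paired design: two tumor models (NSCLC, CML), each
contributing a drug-sensitive cell line and its MDR (P-gp-overexpressing)
counterpart, profiled as cells and as the EVs they release, in three
biological replicates — 24 libraries. Inputs are integer count matrices
(features × samples) with a separate sample-metadata table and a feature
annotation carrying transcript biotypes. All downstream operations take
explicit subsets; there is no hidden global filtering.

## Differential expression

**Filter.** Features are tested only if CPM ≥ `cpm_cutoff` (default 2) in at
least `min_samples_passing` samples (default 3, one full replicate group).
Untested features carry no p-value.

**Normalization.** TMM scaling factors: the reference sample is the one
whose upper-quartile relative abundance is closest to the mean upper
quartile; per sample, the factor is 2 to the precision-weighted mean of
M-values (log2 ratios vs the reference) after trimming 30% of M and 5% of A
on each side (rank-based, symmetric); factors are rescaled to geometric mean
1. Weights are the delta-method asymptotic variance of M. If trimming
removes every feature (tiny matrices), the untrimmed weighted mean is used.

**Dispersion.** A single common dispersion φ under variance = μ + φμ² is
estimated by maximizing the conditional log-likelihood of the
library-equalized counts given each group's per-feature sum, summed over all
groups with ≥ 2 replicates:

  ℓ(φ) = Σ_g Σ_f [ Σ_i lnΓ(y_fi + r) − n_g lnΓ(r) + lnΓ(n_g r) − lnΓ(z_f + n_g r) ],  r = 1/φ

maximized over log10 φ ∈ [−8, 2] by bounded scalar optimization; estimates
at the lower boundary are clamped to 0 (Poisson). Library equalization
scales each sample's counts to the geometric mean of the effective library
sizes; the scaled values enter the Γ terms directly (a quasi-likelihood use
of the conditional likelihood — adequate here and verified by parameter
recovery on simulated data).

**Exact test.** With equal per-sample means under the null, the group sums
are NB(n_A μ, φ/n_A) and NB(n_B μ, φ/n_B), and the law of y_A given the
total t is negative hypergeometric:

  P(y_A = a | t) ∝ C(a + n_A/φ − 1, a) · C(t − a + n_B/φ − 1, t − a)

independent of μ. The two-sided p-value is the minimum-likelihood sum — the
total probability of all splits whose null probability is ≤ that of the
observed split (with a 1e−7 relative slack for floating-point ties, the same
convention as the exact binomial test it reduces to at φ = 0). Group sums
are rounded to integers after library equalization. Per-feature log2 fold
change is log2((y_B + 0.5)/(y_A + 0.5)) adjusted for group size; the prior
count of 0.5 keeps zero counts finite while still allowing |logFC| in the
8+ range observed for strong effects at this sequencing depth. Sign
convention: positive logFC = higher in MDR. BH step-up adjustment caps at 1.

When the total for a feature is 0, p = 1 and logFC = 0 by convention.

**Raw vs adjusted significance.** The consensus stage defaults to raw
p < α = 0.05 (the convention for per-contrast calls in small paired designs)
with a switch to BH-adjusted p; both are always computed and reported.

## Selectivity regression and threshold grid search

Per condition (model × phenotype), counts are summed over the three
replicates of each compartment and converted to RPM against the summed total
of the analysis universe (counted reads, not aligned reads — the only
denominator available at count level), then log2-transformed. Species with
positive summed counts in both compartments form (x, y) pairs; species
detected in exactly one compartment are tallied as `n_unique_cell` /
`n_unique_ev` (the latter expected 0 when EV content derives from cellular
RNA). "Detected" is summed count > 0; "above zero" on the log2 RPM scale is
strict (RPM > 1).

OLS of y on x, R² = squared Pearson correlation. The grid search evaluates
thresholds lo, lo+step, …, hi (defaults 0, 0.1, 10 → 101 thresholds); a
point is retained iff x > T AND y > T (symmetric noise-floor reading;
x-only and y-only variants are available as a config switch). A fit needs
≥ 3 retained points, otherwise it is flagged undefined and excluded from the
argmax rather than raising. T_max is the smallest threshold attaining the
maximal defined R² — ties break toward discarding the least data. The
verdict compares the grid maximum against a configurable ceiling (default
0.8, strict less-than at the boundary): below → selective packaging, at or
above → proportional.

## Consensus, composition, target join

Venn regions are exclusive memberships over the union of significant sets;
the universe per contrast is its filter-passing features (a feature filtered
out in a contrast is not "non-significant" there, it is unobserved).
Features tested in one model but filtered in the other are excluded from the
consensus table and counted in `n_one_model_only`. Directional consensus
requires significance in both models and strictly equal, non-zero logFC
signs. Biotype composition is the per-sample fraction of reads per biotype
(unannotated features fall back to "other"). The miR→target join is a local
inner join against a user-supplied two-column table; no external database is
queried.

## Clustering and ordination QC

Feature clustering z-scores each row of log2 CPM, then applies 1 − Pearson
correlation distance (or Euclidean) with average linkage (configurable);
constant rows are rejected by name under correlation distance. Sample
ordination uses the leading-fold-change distance — the RMS of the `top_k`
(default 500, the conventional choice) largest absolute log2 CPM differences
between two samples — embedded by classical (Torgerson) scaling into two
dimensions. Determinism: eigenpairs ordered by descending eigenvalue; each
dimension's sign is fixed by making its largest-magnitude loading positive;
non-positive eigenvalues give zero coordinates.

## qPCR quantification

ΔCt = mean Ct(target) − mean Ct(reference) per condition (means over
replicate wells; wells are not paired), ΔΔCt = ΔCt(test) − ΔCt(calibrator),
fold = 2^−ΔΔCt. Per-replicate folds (each test-condition well against the
condition's mean reference Ct) are reported for spread. Amplification
efficiency is assumed ideal (the plain 2^−ΔΔCt model). The reference's
stability is asserted, not estimated: a between-condition shift ≥ 0.5
cycles logs a warning. Concordance with sequencing is sign agreement of
log2 fold with logFC, both non-zero.

## Synthetic data generator

What it emulates: per-feature log2 baselines Normal(5, 2) shared across
models plus an independent per-model offset (sd 1.0) so models differ at
baseline; NB counts with dispersion 0.1; library sizes uniform in 1–5 M
(unstated for this assay class; exposed in config); planted MDR cell effects
on a `de_fraction` (default 10%) of features with |logFC| ~ |Normal(2, 0.5)|
and random sign, a `shared_de_fraction` (default 30%) of which get the same
sign in both models with independently drawn magnitudes (cross-model effects
of identical direction but different size); a disjoint set of EV-only MDR
effects implemented as phenotype-dependent packaging; log-normal packaging
factors (natural-log sd 1.5) on 30% of species in selective mode; logistic
detection on log2 abundance (midpoint 2.0, slope 1.0) so low-abundance
species drop out of EVs; per-model, expected drug-sensitive cell abundance
is rescaled per biotype so read composition matches the planted mix
(pseudogene 0.15, miRNA 0.03, protein-coding 0.55, rRNA 0.05, tRNA 0.07,
snRNA 0.05, other 0.10).

Two deliberate modeling choices:

* **Cell MDR effects are not transmitted to EV abundance.** EV expected
  abundance is built from the drug-sensitive cell baseline. In the data this
  emulates, the species altered in cells and the species altered in EVs were
  essentially disjoint; a multiplicative pass-through of cell effects cannot
  produce that structure. EV-specific MDR effects enter as
  phenotype-dependent packaging instead. The truth table therefore records
  cell and EV log fold changes separately per model.
* **EV ⊆ cell detection is enforced at count level** (`enforce_ev_subset`):
  species with zero observed cell counts in a model/phenotype get their EV
  counts zeroed, emulating cargo derived strictly from cellular RNA. Without
  this, sampling noise at low abundance would create spurious unique-to-EV
  species that data of this kind does not show.

What it does not emulate: read-level artifacts (adapter, ligation bias),
sequence content, batch effects, correlated dispersion-abundance trends,
biotype-specific abundance distributions, and any real miR identities.
Passing tests therefore demonstrate correctness and calibration of the
statistics under the assumed generative model, not performance on any
particular real dataset.

qPCR simulation: Ct = intercept − log2(abundance) + Normal(0, sd) per
replicate, with the reference required to be expression-stable in truth.

## Problem sizes and numerical conventions

Simulation-based checks use 400–5000 features as appropriate to the property
being tested: 5000 for error-rate calibration and the selectivity ceiling
(where tail behavior matters), 3000 for bias/dispersion recovery, 400 for
the consensus-recovery study repeated over 10 seeds — sizes at which the
Monte Carlo error of each checked quantity is small relative to its
acceptance band. The consensus-recovery check calls significance on
BH-adjusted p-values: with ~400 tested features per contrast, raw p < 0.05
admits about one false concordant pair per run by chance alone, which would
make "exact recovery" unmeasurable; adjustment removes that floor while the
planted effects (|logFC| ≥ 2 at expected count ≥ 200) remain far below the
threshold.

All randomness flows through `numpy.random.default_rng` seeds carried in the
configs; identical seeds give byte-identical outputs. Ties in the exact test
use a 1e−7 relative probability slack; the TMM trim is rank-based and
symmetric; grid thresholds are generated as lo + k·step to avoid
floating-point drift.

## Known limitations

* The exact test's library equalization (scale to geometric mean, round
  group sums) is a simplification of the quantile-adjustment some
  implementations use; it preserves the conditional argument and calibrates
  correctly in simulation (type-I error 0.049 at nominal 0.05), but
  per-feature p-values can differ slightly from other tools'.
* The common dispersion is a single value; no tagwise shrinkage, no
  abundance trend, no GLM/quasi-likelihood path, no batch covariates.
* RPM uses counted reads as denominator; pipelines computing RPM against all
  aligned reads will shift both axes by a constant, which changes thresholds'
  absolute meaning but not the regression structure.
* The packaging model is multiplicative with logistic dropout — the minimal
  mechanism producing both unique-to-cell species and an imperfect EV-vs-cell
  regression; real sorting mechanisms (RISC loading, sequence motifs) are
  not modeled.
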