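# Methods

`protpanel` implements a multi-stage biomarker-discovery analysis for
case–control aptamer proteomics: matched serum / CSF / brain cohorts are
QC-filtered and normalized, a multi-protein disease signature is selected
by an annealing search and evaluated as nested random-forest panels across
tissue modalities, the winning signature is compressed to a one-number-
per-sample score for replication, and the mechanistic arm runs per-protein
regression scans, hypergeometric pathway enrichment, and weighted
co-expression module analysis. A synthetic-study generator reproduces the
statistical structure these stages assume, so the whole pipeline is
testable without clinical data access.

## Data model and preprocessing

Expression travels as a samples × assays matrix of relative fluorescence
units (RFU) with an explicit transform state (`raw → log2 → standardized →
residualized`). Assay ids are opaque strings; one protein may be measured
by several assays (isoform-level reagents), and two panel generations
share an overlapping assay subset (1047 by default) used for any
cross-modality analysis.

* **Sample QC.** Each sample carries a QC scale factor from experimental
  controls; samples outside the closed interval **[0.4, 2.5]** are
  removed. The bounds are conventionally inclusive.
* **Transforms.** `log2` then per-protein Z-score using the sample
  (n−1) standard deviation.
* **Residualization.** One ordinary least-squares fit per protein
  (Gaussian GLM) on a per-dataset covariate list (e.g. cohort, LEDD,
  assay date, preparation date); the protein is replaced by its
  residuals. Categorical covariates are dummy-coded against the
  alphabetically first level; dates become days since the dataset's
  earliest date. Samples with missing covariates are dropped and
  reported. Constant covariates are an error here (they indicate a
  misconfigured covariate list), but the differential-regulation scan
  drops them silently, since e.g. `cohort` is legitimately constant in a
  single-cohort scan.
* **Batch adjustment.** ComBat in its standard parametric empirical-Bayes
  form, written against the matrix directly: per-protein standardization
  on a design containing batch indicators and protected covariates,
  per-batch additive/multiplicative effect estimates, shrinkage via
  normal / inverse-gamma priors (the usual iterative posterior-mean
  solution), then removal and back-scaling. `shrink=False` gives the
  closed-form location/scale adjustment, convenient for exact tests.
  Single-sample batches and batch–covariate confounding are errors.
* **PC–confounder scan.** Top-k PCs (SVD of the centered matrix) are
  tested against each candidate confounder — one-way ANOVA F for
  categoricals, Pearson t-test for numerics — and pairs are flagged at a
  Benjamini–Hochberg-adjusted p < α (default 0.01). Adjusting within the
  k × confounders family keeps the false-flag rate at the stated level;
  with unadjusted flagging a routine 5 PC × 10 covariate screen would
  flag ~1 pair in 2 by chance.

## Discovery: annealing selection and nested panels

**Search.** Subset selection runs as a greedy annealing search: start
from a small random subset (the minimum admissible size, 5), and at each
iteration propose adding, removing, or swapping one protein (probabilities
0.25 / 0.25 / 0.5, subset size clamped to [5, 100]). A proposal is
accepted only if it strictly improves the subset's cross-validated
discrimination. An optional temperature accepts worse proposals with
probability `exp(Δ/T)` (off by default — pure greedy).

**Fitness.** Discrimination is measured by the pooled out-of-fold mean
binomial log-likelihood (negative deviance) of an unpenalized logistic
model under stratified 5-fold cross-validation. An AUC variant is
available (`metric="auc"`), but deviance is the default for a structural
reason: AUC is a rank statistic that saturates at 1.0 the moment a subset
separates the classes out-of-fold, after which *no* proposal is strictly
better and the search freezes — in particular, uninformative members of
the current subset can never be pruned, and selection frequencies end up
reflecting the random initial subset. Deviance is continuous in the
predicted probabilities, so pruning a noise protein still registers as an
improvement and chains keep converging. In planted-signal experiments
(30 informative of 300 proteins, log2 effect 0.6, n = 500) the deviance
fitness raised top-30 planted recovery from ~7/30 to ~25/30.

**Restarts and selection counts.** The iteration budget (default 1000,
the conventional choice for this search) is spread over `n_restarts`
independent chains (default 20), each with a fresh random start and fresh
CV folds, and each run to a removal local optimum at the end of its
budget (greedy backward elimination under the same strict-improvement
rule). A protein's `selection_count` is the number of chains whose
*final* subset contains it — the same notion of "how often a protein is
selected" that resampled feature-selection wrappers report. Counting
every accepted intermediate state instead (available as
`count_mode="accepted"`) lets transient early-chain members accumulate
counts indistinguishable from signal; final-subset counting across
restarts is what makes the frequencies interpretable. Fresh folds per
chain matter for the same reason: a protein that only looks good on one
particular fold split cannot recur across chains. Ranks are dense ranks
of the counts; ties are broken by the protein's marginal case–control
|t| on the training data (then lexicographically), so `top(N)` is
deterministic and the tail of the ranking is ordered by actual
discriminative strength rather than id.

**Panels.** For N in a configured range (the full analysis uses 1–200), a
random forest is fit on exactly the top-N proteins (500 trees,
√p features per split, class-balanced bootstrap — all configurable; the
forest hyperparameters are conventional defaults, not tuned). Training
accuracy is the out-of-bag estimate. Panels are evaluated on held-out
modalities as per-sample case probabilities; the best panel per modality
is the one with the highest held-out AUC. Panel proteins missing from a
test matrix (replication sets where only part of a signature passes QC)
are handled by policy: `drop_and_refit` (default; refit the forest on the
surviving members), `impute_mean`, or `error`.

**Inference.** AUC is computed by the Mann–Whitney identity (ties count
½). Significance uses label permutations with the add-one estimator
p = (r+1)/(B+1) — at the conventional B = 10 000 the smallest attainable
p is 1.0 × 10⁻⁴. Confidence intervals are class-stratified percentile
bootstrap (default 2000 resamples); the point estimate is clipped into
its own interval.

## Signature compression and replication

A panel becomes one score per sample either as the mean of the members'
Z-scores (`meanz`) or as the first left singular vector of the
standardized panel submatrix (`eigengene`), scaled to unit variance. The
SVD sign is arbitrary, so the eigengene is anchored to correlate
positively with the mean-Z score of the same panel and the orientation is
recorded. Associations with clinical outcomes use logistic regression for
case status and ordinary linear regression for continuous measures
(MoCA, MDS-UPDRS III), unadjusted by default with an optional covariate
list. A perfectly separated logistic fit raises rather than returning an
arbitrary huge coefficient.

## Differential regulation and enrichment

The scan fits one regression per protein: binomial link with status as
outcome and protein + covariates (default age, sex, cohort) as
predictors; Gaussian link for continuous outcomes. The Gaussian scan is
computed in closed form via Frisch–Waugh–Lovell residualization (exactly
equal to per-protein OLS, verified against statsmodels to 1e-10), which
keeps 1000-protein scans fast. Non-convergent or separated logistic fits
are flagged and excluded from the Benjamini–Hochberg denominator so the
FDR applies to actually-tested hypotheses. Samples missing an outcome are
dropped per outcome. The targeted mode fits univariate models with no
covariates and reports unadjusted p-values with a ±/·/blank significance
matrix — the convention for testing a pre-specified candidate list.

Enrichment is a hypergeometric upper-tail test of the overlap between a
query list and each gene set, both intersected with a stated universe —
by default the assays that passed QC on the relevant panel rather than
the whole proteome, which avoids inflating enrichment for
well-represented pathways. BH adjustment runs across tested sets; sets
below 3 members (configurable) are not tested.

## Co-expression modules

Unsigned soft-power adjacency `|cor|^β` with β = 2 (the configuration
default for protein panels, where correlations are weaker than in
transcript data), topological overlap similarity, average-linkage
clustering of the TOM dissimilarity with a static height cut (default
0.85), minimum module size 30, merging of modules whose eigengenes
correlate above 0.8, and a block-wise mode (k-means pre-clustering of TOM
rows) for matrices wider than `block_size`. A static cut was chosen over
dynamic tree cutting because it is fully specifiable and testable; the
dynamic hybrid cut is a possible extension. Module labels follow the
conventional color sequence by decreasing size. Each module gets an
eigengene (first PC of the standardized member submatrix, sign-anchored
to positive mean member correlation, unit variance), a kME table
(member–eigengene correlations), and a hub — the member with maximal
|kME|, ties lexicographic. Module–trait association reuses the signature
association machinery per eigengene.

## Severity

The composite severity score is the equal-weight mean of z(UPDRS-III) and
z(30 − MoCA) over cases with both measures, so both components increase
with severity and the score is invariant to affine rescaling of either
scale. The equal-weight composite is a stated substitute for a score whose
exact construction is not public; the weights are configurable. Strata are
bottom 15% (mild) / top 10% (severe) by default with an intermediate
remainder, or a median split (odd middle sample on the "below" side); ties
break by sample id. Stratified evaluation re-scores a panel sweep on
{stratum cases} ∪ {all controls} and reports the best panel per stratum
with its N, permutation p and bootstrap CI.

## Synthetic studies

The generator emulates the structure the pipeline assumes, at the shapes
of a three-cohort study (serum 572 samples at 69.9% cases, CSF 85 at
82.4%, brain 37 at 64.9%, and panels of 1129 / 4006 assays with a
1047-assay intersection; case/control counts are fixed, not sampled).
Signal is planted additively on the log2 scale and exponentiated to RFU,
so effects read as log2 fold-changes:

    log2 x = baseline + status·β·attenuation·max(0, 1 + c·severity)
             + severity·slope + block factors + batch + ε

* per-protein baselines ~ N(10, 1.5²) shared across modalities;
* `attenuation` scales case effects per modality (default 1 / 0.8 / 0.6
  for serum / CSF / brain), so cross-tissue transfer is imperfect;
* latent severity is N(0,1) per case (0 for controls); MoCA is a
  decreasing and UPDRS-III an increasing noisy transform of it, with
  marginals near the cohort table values; `c` couples effect size to
  severity (0 by default);
* co-expression blocks add a shared factor scaled so the within-block
  correlation equals the configured ρ;
* batch effects are per-batch location/scale on the log2 scale;
* noise is iid Gaussian with sd 0.5 by default — with the default
  30 planted proteins at log2 effect 0.6 this makes single proteins
  individually informative but noisy (per-protein AUC ≈ 0.8), the regime
  the pipeline is designed for.

All randomness flows through NumPy's PCG64 `default_rng`; a fixed seed
reproduces a study exactly on any platform. Metadata carries the latent
severity as ground truth for tests; real data would not.

What the generator does **not** model: aptamer cross-reactivity and
dilution-bin chemistry, non-Gaussian abundance distributions, missing
assay values, longitudinal structure, and realistic LEDD–severity
dependence. Passing tests therefore demonstrate that the pipeline
recovers the structure it assumes, not that it would perform identically
on clinical cohorts.

## Test and script problem sizes

The test suite and `scripts/acceptance.py` run the pipeline at reduced
but structurally faithful sizes, chosen so the full suite completes on a
single CPU in minutes: discovery uses 300 proteins with 30 planted
(log2 effect 0.6, 500 train / 200 test samples), panel sweeps cover
N = 5–60 with 200 trees, scans use 1000 proteins at n = 400, module
recovery uses two planted 40-protein blocks (ρ = 0.7) among noise at
n = 300, and stratified evaluation uses 30% quantile strata so each
stratum retains enough cases for a stable AUC. Permutation counts are
9999 or 999 depending on the resolution a check needs.

## Known limitations

* The annealing search is greedy by default; with highly correlated
  signal proteins the selected subsets are one of many near-equivalent
  panels, and selection frequencies should be read accordingly.
* ComBat's EB shrinkage assumes roughly comparable per-batch variances;
  heavily heteroscedastic batches are better handled per-dataset.
* The static TOM cut height is a tuning constant; very weak modules
  (within-ρ well below 0.5 at power 2) fall into grey.
* Logistic scans at extreme effect sizes can separate perfectly; such
  fits are flagged, not silently reported.
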