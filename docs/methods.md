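# Methods

## The analysis model

The package treats the field plot as the experimental unit throughout: seeds
of four plants per plot are pooled, so metabolite profiles, morphology and
germination traits are plot-level observations, and every test compares
groups of plots (five replicate plots per line × treatment in the emulated
design).

**Relative metabolite content.** Raw GC-MS peak heights confound biology
with three nuisance factors: the amount of seed extracted, the overall
sample load reaching the detector, and the analytic run block. The
normalization chain divides, in order, by (1) the sample's extracted seed
mass, (2) the sample's total peak sum over its non-missing metabolites, and
(3) the per-block median of each metabolite. Step 2's sum is taken over
non-missing metabolites only, which keeps samples with scattered missing
values usable at the cost of a small load-estimate bias when missingness is
heavy. After step 3 the median of every metabolite within every block is
exactly 1 (over non-missing entries), which is both the definition of RMC
and a cheap invariant to assert. The chain is invariant to rescaling any
sample by a positive constant and to a global change of seed-mass units.
Values are natural-log transformed before testing; the log base is
irrelevant to t-tests and correlations, so one convention is fixed.

**Missing-value completion.** Correlation, PCA and clustering need a
complete matrix. Missing cells are filled by iterative low-rank
reconstruction: initialize at column means, then alternate fitting
`n_components` (default 5) principal components and replacing missing cells
with the reconstruction until the largest change falls below `tol`
(default 1e-6) or `max_iter` (1000) iterations — the EM-for-PCA scheme
familiar from probabilistic-PCA completion routines. Observed cells are
never altered, repeated application is idempotent, and metabolites missing
in more than half the samples are excluded from the model and reported
rather than imputed. Hypothesis tests (QTL and treatment scans) run on the
non-imputed values: imputation is only for the stages that structurally
require completeness, so no test statistic is computed against invented
data.

**Germination vigor.** Per plate of 50 sown seeds: final percent; T50 as
the first integer day on which cumulative germination reaches half of the
seeds that eventually germinated (no interpolation — observed plate T50s
are small integers and plot values are their means); SD-plate as the sample
SD (n−1) of per-seed germination days reconstructed from the daily
increments. T50 and SD-plate are undefined for plates with 0 (respectively
< 2) germinated seeds; undefined values propagate as missing, never as 0,
and plot aggregation is the unweighted mean of the defined plate values
(plates share a common design size, so weighting would change nothing).
The salinity response of a line is the ratio of its plot-mean traits in SDS
over SDF, with a Welch t-test on the plot-level values.

**QTL calling.** All two-group comparisons use the Welch
(unequal-variance) t-test with Welch–Satterthwaite degrees of freedom —
robust at n = 5 and indistinguishable from the pooled test when variances
agree. The degenerate case of two zero-variance groups with equal means
returns p = 1. The fold-change QTL is the log-scale interaction contrast
(mean IL,SDS − mean IL,SDF) − (mean M82,SDS − mean M82,SDF), whose sign
equals the sign of log(FC_IL/FC_M82) from cell means; its standard error
pools the four cell variances. Multiplicity is applied per scan with n
equal to the comparisons actually performed in that scan: plain Bonferroni
(α/n) for the metabolite maps, the permissive Bonferroni **Bcp** (α/√n)
for trait scans and asterisk tiers (α ∈ {0.05, 0.01, 0.001}), and raw
α = 0.01 for the within-line treatment comparisons. Which rule each scan
uses is configurable.

**Signed network and the ms1/ms2 bipartition.** Spearman rank correlation
(average ranks for ties, t-approximation p-values, pairwise deletion of
missing observations so that traits undefined for some plots still
correlate over the rest) over all metabolite and germination-trait pairs;
BH-FDR over the upper triangle; edges kept at adjusted p < 0.05 and
|r| > 0.4 (a threshold scan over candidate cutoffs reports the standard
graph measures so the choice can be revisited per dataset). Communities
come from Walktrap (4 steps) with |r| as walk weights — random walks need
non-negative weights, so the sign lives on the edge attribute — cut at
maximal modularity. Each community is split into two subsets such that
positive edges prefer the same subset and negative edges opposite ones,
minimizing |r|-weighted frustration (an unweighted objective is a flag
away): exhaustive search up to 15 nodes (2¹⁴ colorings), above that a
steepest-descent single-flip local search from a sign-propagating BFS start
plus 49 seeded random restarts. The subsets are then assembled globally: a
meta-graph of community subsets with aggregated signed weights is 2-colored
by the same objective, and the side holding the majority of metabolites
negatively correlated with germination percent is labelled ms1. Germination
traits are overlaid on the network but excluded from community detection
and set assignment; their edges anchor the orientation and are scored for
consistency (negative-to-percent / positive-to-T50-or-SD-plate edges should
land in ms1, the mirror image in ms2). Note that flipping *every*
correlation's sign does not simply swap the sets — sign-flipping a balanced
graph breaks balance on odd cycles — whereas flipping the germination-edge
signs swaps the labels exactly, which is what the orientation rule
guarantees.

**Vigor integration.** PCA on the centered, unit-variance-scaled log RMC
(metabolite variances are heterogeneous; center-only is available);
component signs are fixed by making each loading vector's
largest-magnitude entry positive, so results are deterministic. k-means
with k = 3 (mirroring the three germination groups' cluster structure;
configurable), Euclidean distance, 50 restarts under a fixed seed. Group
enrichment is the Pearson chi-square of the k × 3 contingency table of
clusters against non- (0%), intermediate- (1–94%) and well- (≥95%)
germinating plots; the well/intermediate boundary is configurable. The
well-vs-non metabolite contrasts report fold differences as ratios of
back-transformed (linear-scale) group means, both directions, with the
intermediate group's mean carried along.

## The synthetic-data generator

The generator emulates the statistical skeleton of the field trial, not its
chromatograms: 72 ILs + M82 × {SDF, SDS} × 5 plots (730 samples), 65
metabolites. Latent log-abundances are multivariate normal with
within-set correlation 0.6 inside each of two latent sets (40 and 25
metabolites) and −0.4 across them, residual SD 0.3. Planted effects are
added on the latent scale:

* **Metabolite QTLs** — 15% of ILs carry shifts on 3 metabolites each;
  magnitudes are drawn uniformly in [0.5×, 2×] of the `qtl_effect` scale
  (default 1.2 log units, i.e. ~1.8- to ~11-fold) with random sign, so a
  scan faces both clear and marginal loci, and only the strong tail
  survives a Bonferroni map at n = 5 — the realistic regime.
* **Salinity shifts** — default zero on metabolites: the emulated study's
  SDS-vs-SDF comparisons sat at the null rate (~1% at p < 0.01), so no
  systematic shift is the study condition; the parameter exists to plant
  effects. Salinity does raise the seed-abortion probability
  (default +0.08 over a 0.10 base), reducing maturation percent under SDS;
  seed weight is unaffected by treatment by construction.
* **Deteriorated plots** — 10% of plots receive a strong (1.5 log-unit)
  shift up in set 1 and down in set 2, modelling the post-harvest-stressed,
  metabolically distinct, (near-)non-germinating seed lots observed in such
  trials (~10% of plots). Without this subpopulation there would be no
  non-germinating group for the cluster-enrichment analysis to find.

Peak heights are `exp(latent) × seed mass × block factor × load factor`
with per-(block, metabolite) and per-sample lognormal factors (SD 0.3 and
0.2), blocks assigned round-robin, and 5% of entries deleted completely at
random — MCAR is the weakest assumption and nothing in the emulated
protocol suggests otherwise. Germination is driven by the per-plot balance
score (mean latent set-2 minus set-1): each of 50 seeds per plate (3
plates) germinates with probability logistic(2.5 + 2.5·score), and
germination day is a shifted negative binomial on days 1–14 with mean
max(1.5, 3.0 − 0.5·score) and dispersion 6 — integer-day counts with plate
T50s in the observed 2–8 day range. All randomness flows from one seed
through named substreams per component, so regeneration is bit-identical
and component-local.

What the generator does **not** emulate: retention-time drift, peak
co-elution and annotation error; season-to-season agronomic differences
(season is a metadata level only); spatial field structure; dormancy
dynamics; correlated missingness. Passing recovery tests therefore show
the pipeline is correct and well-calibrated under the assumed structure —
they do not certify performance against instrument artifacts the generator
does not produce.

## Recovery scoring and problem sizes

`seedmet.recovery` regenerates a dataset, runs normalization → imputation →
per-condition networks → ms1/ms2 assembly, and scores: adjusted Rand index
of the recovered sets against the planted assignment (≥ 0.9 averaged over
10 seeds at defaults; in practice 1.0), germination-edge consistency
(≥ 0.9; in practice 1.0), and the chi-square enrichment of non-germinating
plots in one k-means cluster (p ≪ 10⁻⁴). QTL sensitivity is scored on a
dedicated scan at effect 0.5, plot noise SD 0.15, five replicates: 15 of 72
ILs carry the effect under both growth conditions (the generator plants
line QTLs irrespective of treatment), and a locus counts as recovered when
either per-condition map calls it at Bcp with the correct direction —
the same way putative QTLs are read off the two condition maps. Averaged
sensitivity is ~0.98; restricted to a single condition's map it is ~0.81,
dominated by the shared control-replicate variance draw.

Monte-Carlo calibration checks run at 10⁴ replicates with group size 15,
where the Welch reference distribution is essentially exact; at n = 5 the
Welch procedure itself is mildly conservative (true size ≈ 0.042 at
α = 0.05), a property of the test, not of the implementation, which matches
scipy to 10⁻¹⁰.

## Numerical choices and degenerate inputs

* Edge retention uses |r| > r_min with a 10⁻⁹ float guard, so a cutoff of
  exactly 1.0 still keeps perfect correlations.
* Correlation-matrix factorization for the generator uses the symmetric
  eigendecomposition with negative eigenvalues clipped at −10⁻⁸, so the
  singular perfect-correlation targets (ρ = ±1) generate correctly while
  indefinite targets are rejected as infeasible.
* Constant columns are excluded from correlation (undefined r) with a
  warning; pairs with fewer than 4 complete observations get missing r;
  missing p-values pass through BH-FDR untested.
* A metabolite entirely missing within a block stays missing there (warned);
  a zero sample sum is an error; non-positive values are an error at the
  log step with the offending cells listed.
* Ties in the bipartition objective are broken by search order
  (deterministic); exact search fixes the first node's color since the
  objective is color-flip symmetric.
* k-means and PCA are deterministic given the pipeline seed (fixed
  `random_state`, full SVD, loading-sign convention).

## Limitations

* The frustration heuristic above 15 nodes is a local search with restarts:
  equality with the exact optimum is verified on random graphs up to 12
  nodes, but very large communities could in principle settle in a local
  optimum.
* The pairwise-deletion Spearman p-values use the t approximation per pair;
  at very small pairwise n this is rough (pairs under 4 complete
  observations are dropped instead).
* Plot-level totals in the germination link are binomial given the balance
  score; overdispersion between plates of the same plot beyond the shared
  score is not modelled.
* The pipeline assumes one season per run; multi-season data are analysed
  by filtering to a season before the network stage (season is carried as
  metadata throughout).
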