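# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline runs.

## Metabolic models and environments

A model is a list of metabolites (with compartments) and reactions (signed
stoichiometries with bounds), serialized in the community JSON layout.
Reactions carry one of five kinds. When a file does not annotate them, the
kinds are inferred: the objective is *biomass*; a reaction touching exactly
one metabolite is an *exchange*; a reaction whose metabolites span two or
more compartments is a *transport*; everything else is *internal*.
*Maintenance* (growth-independent ATP hydrolysis) is never inferred — it
must be annotated, because stoichiometrically it looks like an exchange.
File annotations always override inference.

Environments are uptake bounds on exchange reactions. Substrates are
supplied in carbon-normalized units (cmol/gDW/h) so every carbon source
enters at equal carbon flux; the single-substrate default is −1. Freely
available exchanges (oxygen, nitrogen, trace elements in a genome-scale
setting) are opened to −1000, the conventional file encoding of
"unbounded", which the solver layer maps to −∞. All other exchanges are
closed below. The maintenance lower bound defaults to 0: flux
distributions are estimated for resources in excess, where
growth-independent maintenance is negligible.

For nutrient mixtures the default convention (`equal_split`) divides a
fixed total uptake equally among the k components, keeping total carbon
constant across environments. A second convention (`paper_printed`)
reproduces historically quoted per-source bounds of −1 for pairs and
−0.033 for triplets; the two conventions are mutually inconsistent with
constant total carbon, so both are available and neither is silently
substituted for the other. Pearson correlation is scale-invariant, so the
choice rescales flux vectors without changing single-substrate
similarities; it can matter for mixture-vs-single comparisons.

## FBA, pFBA and the similarity metric

FBA maximizes biomass flux subject to S·v = 0 and bounds, solved with
HiGHS via `scipy.optimize.linprog`. Infeasibility and unboundedness are
reported as explicit statuses, never as silent zeros. pFBA adds a second
stage: the biomass optimum is held (relative slack 1e−9) and total
absolute flux Σ|v| is minimized after splitting every reaction into
forward and reverse non-negative components. Variable ordering is fixed by
model order, so the solver's choice among residual degenerate optima is
reproducible. The test suite checks both stages against a brute-force
vertex-enumeration oracle on networks small enough to enumerate.

Metabolic similarity between environments is the Pearson correlation of
their internal-reaction flux vectors, computed over the *full* internal
vector including zero fluxes (no pruning rule is imposed). An environment
that cannot grow raises an error — the analysis assumes the model has been
curated to grow on every substrate considered — and an internal vector with
zero variance yields flagged NaN entries rather than a fabricated value.
Similarity entries inherit the solver tolerance (~1e−6). Robustness across
organism models is obtained by running the similarity matrix per model and
correlating the matrices over shared substrates with the Mantel machinery;
no dedicated operation is needed.

## Growth-rate estimation

The headline estimate is an average growth rate over the ascending part of
the curve: r = ln(N2/N1)/(t2 − t1), natural log, units 1/h. (t1, N1) is
the third recorded point — the first two readings are discarded as bubble
artifacts — and t2 is the time of maximum derivative of the smoothed
log-OD curve, clamped to at least 5 h to avoid low-density fitting noise.
ODs are floored at 0.001 (the detection limit) before logs. The smoother is
a cubic smoothing spline on log-OD with its penalty chosen by generalized
cross-validation — a close, fully specified stand-in for an adaptive GAM.
Replicates are averaged at the OD level before estimation, one rate per
strain × substrate.

This estimator deliberately folds lag time into the rate (its purpose is to
rank strains by realized growth, lag included) and ignores everything after
the derivative peak (minimizing confounding by diauxic growth on secreted
by-products). Two consequences are worth noting. First, on a lagged curve
the estimate is lower than the instantaneous exponential rate by the factor
(t2 − lag)/(t2 − t1); the synthetic generator therefore draws short lags
(0.25–1.25 h, emulating preconditioned cultures) when planted-rate recovery
is being tested. Second, on an exact exponential the estimate equals the
true rate regardless of the window, which is what the recovery checks
exploit. Four alternative metrics (fixed 16 h endpoint, maximum smoothed
derivative, least-squares logistic rate, trapezoidal AUC) are computed for
robustness analyses; a non-convergent logistic fit yields a missing value
for that metric only.

Trait matrices may be normalized per substrate (default — it compares the
taxonomic distribution of rates within an environment) or per strain; the
choice is exposed because either is defensible. Clade contrasts use
Welch's t-test between the fermenter clade (E+: Enterobacteriaceae,
Aeromonadaceae, Erwiniaceae, Yersiniaceae) and the respirator clade (P+:
Pseudomonadaceae, Moraxellaceae).

## Metabolomics

The pipeline starts at an integrated peak table; peak picking and
annotation are out of scope. The control filter is relative and
per-metabolite: a metabolite is removed if any no-carbon control sample
exceeds 5% of that metabolite's maximum height across all samples. (The
alternative global-maximum reading of "5% of maximum peak height" is not
offered; the per-metabolite reading matches the filter's purpose of
removing medium components rather than low-intensity noise.) The growth
gate removes a carbon source entirely if any replicate failed to reach
OD 0.04. Replicates are averaged per carbon source, then each metabolite
row is z-scored across carbon sources with the sample standard deviation
(n−1); a replicate-level variant z-scores across all samples instead.
Missing peaks are zeros (absence of integration), not missing-at-random,
and strains are always analyzed separately. Substrates cluster by
average-linkage hierarchical clustering on 1 − r with label-sorted,
deterministic tie-breaking.

## Community similarity and variance partitioning

Counts are rarefied without replacement (multivariate hypergeometric) to a
common depth — by default the minimum sample total, the "highest depth
possible" — with a single seeded generator and label-sorted sample order
for bit-reproducibility. Taxa aggregate by summing counts within Genus /
Family / Clade groups; unmapped taxa go to an explicit "unassigned" bucket
(Other at the Clade level) because dropping them would break the
normalization that Renkonen similarity requires. Renkonen similarity is
computed on relative abundances after rarefaction and demands normalized
inputs — it never renormalizes silently. Coarsening the taxonomy can only
increase the similarity (min-sum over merged bins), a property the tests
assert exhaustively.

Variance partitioning regresses the centered relative-abundance matrix on
dummy-coded factors by least squares (redundancy analysis) and reports
Ezekiel-adjusted R² for each factor alone and both together; pure, shared
and residual fractions follow by inclusion–exclusion. Fractions can be
slightly negative — a known property of adjusted R², not an error — and a
null factor carries a small-sample bias of about −p/(n − p − 1), which the
test designs size their sample counts around. No Hellinger transform is
applied by default because none is prescribed; the implementation is
cross-checked against R vegan's `varpart` in the test suite.

## Permutation statistics

The Mantel test correlates upper-triangle entries of two square symmetric
matrices; the null simultaneously permutes rows and columns of the second
matrix, with permutations sampled with replacement from the permutation
group (standard Monte-Carlo Mantel, default 9999 permutations). P-values
use the add-one convention p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1), so the
smallest attainable p is 1/(n_perm + 1). The one-tailed Mann-Whitney U test
uses exact enumeration when both groups have ≤ 8 tie-free observations and
the midrank normal approximation with tie-corrected variance otherwise.
Plain correlations are pairwise-complete and need at least 3 pairs.

## Nearest-template prediction

The predictor is a 1-nearest-neighbour classifier in flux space: the
target's composition is predicted to be the observed composition on the
most metabolically similar non-identical template substrate, with exact
ties broken to the lexicographically smallest label so leave-one-out runs
are deterministic. Performance is the Renkonen similarity between predicted
and observed composition at the requested taxonomic level. The null is
exhaustive — the Renkonen similarity of *every* non-identical
(target, template) pair — rather than Monte-Carlo, and predictions are
compared to it with the one-tailed Mann-Whitney test. For mixtures, the
mixture's pFBA flux vector is correlated against each single-substrate
vector, the mixture's own components are excluded as templates, and an
absent observed composition leaves performance unset rather than failing.

## Synthetic data

The generators produce the four input classes with the statistical
structure the analysis assumes, as pure functions of (config, seed):

- **Toy models.** The fixed fixture has three substrates: two entering the
  cytosol at the same node (internal flux similarity exactly 1) and one
  using its own entry pathway (similarity exactly −0.5 against the shared
  downstream reaction). Branched variants draw a linear backbone with
  random shortcut reactions and k substrate entry points; feasibility on
  every substrate is guaranteed by construction since every node drains to
  biomass.
- **Growth curves.** True rates follow base ± clade_effect × similarity-to-
  reference plus strain effects and noise, truncated at 0.01/h; curves are
  lagged logistics on a 30-minute grid over 48 h with multiplicative
  log-normal OD noise (default sd 0.05).
- **Peak tables.** 69 annotated metabolites of which 14 carry significant
  control background (so the default table retains 55 after filtering);
  substrates fall into secretion blocks with block-specific metabolite
  signatures and log-normal heights.
- **Communities.** Each taxon carries a linear functional over internal
  flux space, clade-aligned with either the reference environment's flux
  mode or the most dissimilar mode; expected abundance is a softmax of
  fitness/temperature modulated by per-inoculum dropout and log-normal
  jitter; counts are multinomial at 2733 reads. This softmax-on-fitness
  stand-in preserves the causal chain (flux-determined traits →
  composition) at negligible cost; a mechanistic consumer-resource
  simulation is deliberately out of scope.

Defaults mirror the study scale: 62 strains, 19 substrates, 3 inocula,
read depth 2733, 48 taxa, clade effect 0.3/h, inoculum jitter sd 0.3.
What the generators do *not* emulate: sequencing chimeras and
contamination, diauxic shifts and evaporation in growth curves,
retention-time drift in LC-MS, and true cross-feeding dynamics — so
passing tests demonstrate correctness of the *analysis* under its stated
assumptions, not robustness to every artifact of real data.

## Numerical conventions

LP feasibility tolerance follows HiGHS defaults; pFBA holds the optimum to
1e−9 relative; growth below 1e−8 counts as "no growth"; Renkonen inputs
must sum to 1 within 1e−9; matrix symmetry is required within 1e−9;
correlations are clipped to [−1, 1]. Degenerate inputs (constant flux
vectors, zero-variance metabolites or trait slices, empty samples) are
flagged or raised explicitly, never imputed.

## Problem sizes

The test and acceptance runs use 20-substrate branched networks, 100-curve
recovery batches, 400-trial Mantel calibrations at 999 permutations, and
20-seed community simulations — sizes chosen so each property is measured
with comfortable statistical margin while the whole suite stays fast.
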