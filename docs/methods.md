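# Methods

This note records the models implemented in `hostspec`, the conventions
fixed where the reference analysis left the choice open, and what the
synthetic-data experiments do and do not demonstrate.

## Data model and alignment

Inputs are a rooted host phylogeny (Newick, branch lengths required on
every non-root edge, polytomies allowed), a per-species trait table (CSV;
columns typed continuous / binary / categorical / fuzzy, where a fuzzy
group is a set of proportion columns summing to 1 per complete row) and a
long-format association table (host, parasite, present, optional sampling
counts). Species labels are matched exactly after trimming, collapsing
internal whitespace and treating underscores as spaces; analyses run on the
intersection of species present in all inputs, and drops are logged rather
than silently reconciled — no synonym guessing is attempted. Duplicate
association rows aggregate by logical OR of presence and summation of
counts, with presence forced wherever `n_infested > 0`.

## Derived traits

* **Diet diversity** is the Shannon index (nats) of the 10-category diet
  composition, −Σ p ln p with 0·ln 0 := 0, bounded by ln 10 ≈ 2.303.
* **Composite habitat indicators** are logical ORs of IUCN-style flags:
  anthropogenic = introduced vegetation ∪ artificial terrestrial; forest =
  forest ∪ shrubland; dry bush = desert ∪ savanna ∪ grassland. Missing raw
  flags count as absence (OR semantics over presence flags).
* **Centring/scaling** of continuous predictors divides by one *population*
  SD (divisor n). Only "one SD" is conventionally stated for such
  pipelines; the divisor had to be fixed, is recorded per column as
  (mean, sd), and supports exact back-transformation.
* **Imputation** replaces each missing cell with a uniform draw from the
  column's observed values — not a continuous uniform over the range — so
  imputed values stay in-support for binary and continuous columns alike.
  Fuzzy compositions are imputed as whole observed rows (the only way to
  preserve the unit-sum constraint), which means partially observed
  compositions are replaced wholesale; scalar observed cells are never
  touched. Deterministic given a seed.

## Distances

**Patristic distances** are path sums of branch lengths, divided by the
maximum so entries span [0, 1] (the same max-scaling is applied to every
dendrogram's cophenetic matrix, making phylogenetic and niche distances
commensurable).

**Abouheif proximity and C.** The proximity between tips i and j is the
product over interior nodes on the i–j path (MRCA included) of one over the
node's number of direct descendants; the diagonal absorbs the remainder so
rows sum to 1. C is the proximity-weighted cross-product of the centred
trait over its sum of squares; under random permutation its null mean is
−1/(n − 1). Niche variables are weighted by 1/max(C, 0.01): the inverse is
undefined for non-positive autocorrelation, so C is clipped at a
configurable floor (0.01), keeping weights positive and finite. A fuzzy
group receives one weight from the mean C of its member columns.

**Weighted Gower distance.** Per-variable contributions all lie in [0, 1]:
continuous variables contribute |x_i − x_j| after SD-scaling divided by the
maximum observed pairwise difference; binary variables contribute a 0/1
mismatch; a fuzzy group contributes half the L1 distance between
compositions (total variation). The combined distance is the
weight-normalised sum. Continuous columns with zero pairwise range are
dropped with a warning (their contribution is undefined); constant binary
or fuzzy variables simply contribute zero. This dialect is one concrete
member of the mixed-variable Gower family; it is documented here and
pinned by a brute-force oracle test rather than claimed to match any
particular legacy implementation.

**Dendrogram ensemble.** Each niche matrix (habitat: 9 binary
micro-habitat flags + cohabitation diversity + midrange longitude and
latitude; diet: the 10-category fuzzy composition + diet diversity) is
clustered with eight agglomerative schemes — single, complete, average,
weighted average, centroid, median, Ward, and Ward on squared
dissimilarities with heights mapped back by square root (the classic
ward.D / ward.D2 distinction). "Eight dendrogram topologies" fixes the
count but not the identity of the algorithms; these are the canonical
eight. Centroid and median linkage can produce inversions; ultrametricity
of cophenetic matrices is only guaranteed (and only asserted) for monotone
linkages.

## Host specificity

For blending weight a ∈ [0, 1] and exponent p (default 2),
FPDist = (a·PDist^p + (1 − a)·FDist^p)^(1/p); a = 1 and a = 0 return the
input matrices exactly rather than through `(x**p)**(1/p)`. STD\* is the
plain mean of the s(s−1)/2 pairwise distances among a parasite's s hosts
(no variance correction — the uncorrected mean is the documented choice).

Each null iteration draws a ~ U(0,1), picks one dendrogram uniformly from
the ensemble, computes observed STD\* on the parasite's hosts and expected
STD\* on an equal-size uniform draw (without replacement) from the sampled
pool, **under the same a and dendrogram**, so the differential isolates
host identity from weighting and topology noise. When a subsample size k is
configured and the parasite has more than k hosts, a fresh subsample of
observed hosts is drawn every iteration (the device that puts a
138-host parasite on equal footing with a 31-host one). Differentials are
summarised in 10 equal-width α bins by default (configurable) with median,
2.5%/97.5% quantiles, extremes and a significance flag (interval excludes
zero); empty bins are flagged, never interpolated.

Calibration is assessed at the per-α-bin level: for a parasite whose hosts
are themselves a uniform draw, each bin's 95% interval should exclude zero
at roughly the nominal rate. A pooled all-α interval is *not* a calibrated
5% test, because the observed host set's deviation is a single realisation
shared across α — the per-bin reading matches how the differential
boxplots are interpreted.

## Phylogenetic logistic regression

For species i with binary infestation y_i:

    y_i ~ Bernoulli(logit⁻¹(l_i)),
    l_i = x_i'β + u_phylo,i + u_threat[t(i)] + e_i,   e_i ~ N(0, 1)

with u_phylo ~ N(0, σ²_phylo·K) and an iid threat-class intercept. K is the
shared root-to-tip path length of each pair divided by the maximum tip
depth (a Brownian-motion correlation, PSD by construction; validated to
eigenvalue ≥ −1e-8). Residual variance is fixed at 1 because it is not
identifiable for binary data.

Fixed effects default to body mass, diet diversity, cohabitation
diversity, the three composite habitat indicators, 'parasite' and
'ectoparasite' citation counts (continuous terms centred/scaled) plus a
cohabitation × anthropogenic-use interaction built from the scaled
component.

**Priors.** β ~ N(0, 10²) (diffuse; the original fixed-effect prior is not
printed anywhere, so a conventional diffuse choice is documented). Both
variance components use the parameter-expanded construction u = α·v with
α ~ N(0, 1) and v standard (correlated through K for the phylogenetic
term): the implied prior on σ² = α² is a one-degree-of-freedom scaled
chi-square, and the redundant multiplicative parameter decorrelates the
scale from the effects, improving mixing. The expansion-scale variance (1)
is the package's fixed hyperparameter choice.

**Sampler.** The posterior is the contract; the scheme is MCMC with (a)
elementwise random-walk Metropolis on the latent liabilities l (their full
conditionals are independent given the linear predictor; proposal SD 2.0,
fixed — the conditionals have SD < 1 so acceptance sits near one half) and
(b) exact Gaussian Gibbs updates for β, the phylogenetic effects (in the
eigenbasis of K, where the conditional precision is diagonal and each
sweep costs two dense matrix–vector products), the threat-class effects
and both expansion scalars. Chains are seeded independently via
`SeedSequence.spawn`; runs are deterministic given the seed. Correctness is
checked two ways: against an independent random-walk Metropolis sampler on
the identical posterior (variance components off), and by
credible-interval coverage of known simulation truths.

**Summaries.** Posterior mode = argmax of a Gaussian KDE (Silverman
bandwidth) on a 512-point grid spanning the draws; intervals are shortest
95% highest-density windows; convergence uses the split-chain
Gelman–Rubin factor (floored at 1; undefined for constant chains and
flagged NaN) and lag-1 autocorrelation of the thinned draws.

**Variance decompositions.** The phylogenetic share per draw is
σ²_phylo / (σ²_phylo + σ²_threat + 1 + π²/3) — latent-scale intraclass
style, counting the fixed unit residual and the logistic link variance
π²/3 in the denominator. "Remaining explained variation" among fixed
effects is interpreted as the per-draw across-species variance of each
term's contribution x_k β_k, normalised over terms. Both decompositions are
documented interpretations: there is no single canonical "% of variation"
formula for a binary mixed model, so these shares characterise this
implementation and should be cited as such.

**Effect transformations.** Odds change for a δ shift is
100·(exp(βδ) − 1). Probability change for a raw-unit shift of a continuous
predictor converts through the recorded scaling SD and averages
logit⁻¹(η + βδ/sd) − logit⁻¹(η) over species and draws (η includes the
realised random effects), reported in percentage points. Fitted
probabilities use posterior modes of the coefficients and of each species'
phylogenetic intercept.

## Synthetic data generator

The generator emulates a compiled association database at desk scale. A
pure-birth (Yule) tree (default 300 species, birth rate 1, a final
exponential hold time keeps terminal branches positive and the tree
ultrametric) carries Brownian-motion traits from root value 0: log body
mass (exponentiated to kilograms), cohabitation diversity, citation counts
(exponentiated BM plus independent noise, giving the skew of real citation
data), midrange latitude/longitude. Nine binary habitat flags threshold
Brownian liabilities; inside the full-dataset generator the liabilities are
standardised across the pool first so each flag's prevalence is stable
across tree realisations (deep shared branches otherwise let entire pools
drift past the cut). The 10-category diet composition is a softmax of
Brownian liabilities offset by log-concentration. Threat classes are
uniform over four labels. Infestation outcomes are drawn from exactly the
regression model above; defaults are an anthropogenic-use effect of 1.5,
a body-mass effect of −0.5, intercept −1.5, all other coefficients 0,
σ²_phylo = 1, σ²_threat = 0.5 — a strong habitat effect and substantial
phylogenetic structure at roughly the prevalence scale of a real pool.
A truth file records every generative parameter.

What the generator does **not** emulate: real mammal trait marginals,
geographic or sampling-effort structure beyond the citation covariates'
existence, correlated missingness, or taxonomy/synonymy noise. Passing
tests therefore demonstrate internal correctness and statistical
calibration of the methods under their own assumptions, not conclusions
about real host-parasite systems.

## Problem sizes and numerical choices

Validation experiments run at 300 species (a desk-scale stand-in for a
~700-species pool): null calibration uses 200 uniform-random parasites ×
1,000 iterations; specialist detection 20 independent pools ×
1,000 iterations; parameter recovery 20 replicates at a reduced schedule
of 2 chains × 20,000 iterations, 10,000 burn-in, thinning 10. The full
reference schedule (2 × 2,000,000 / 1,000,000 / 1,000 → 2,000 retained
draws) is exercised as an arithmetic identity. Eigenvalues of K are floored
at 1e-10 before inversion; distance symmetry is enforced to 1e-10 and
fuzzy unit-sums to 1e-8; degenerate inputs (constant traits, single-host
parasites, single chains, empty α bins, zero-depth trees) raise or are
flagged rather than silently patched.

## Known limitations

* The latent-liability Metropolis step uses a fixed proposal scale; for
  responses far more imbalanced than the defaults, mixing of the intercept
  slows and longer schedules are warranted (diagnostics report it).
* Specificity nulls are uniform draws from the pool, not
  phylogenetically structured nulls, matching the modelled design.
* The Gower dialect and the identity of the eight linkage methods are
  package conventions (documented above); results depending on those
  choices should cite this note rather than assume universality.
* Prevalence-level (binomial count) modelling is out of scope; only
  species-level presence/absence is analysed.
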