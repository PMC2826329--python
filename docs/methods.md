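# Methods

`phylorecomb` implements a comparative analysis of how recombination rates
evolve across plant species, at two scales: genome-wide rates assembled
from genetic maps, and within-gene rates estimated from haplotype
alignments. This note documents the models, the numerical choices, and
what the synthetic-data generators do and do not emulate.

## Genome-wide rates

The genome-wide recombination rate of a species is its corrected total
genetic-map length (cM) divided by its physical genome size (Mb). Two
map-length corrections are provided:

- **add2s** (default): the mean inter-marker spacing
  `s = ΣL_c / Σ(m_c − 1)` is added twice per chromosome, once beyond each
  terminal marker: `corrected = ΣL_c + 2sC`. This always exceeds the raw
  total.
- **chakravarti**: each chromosome is inflated by `(m_c + 1)/(m_c − 1)`.

Genome sizes given as haploid C-values are converted at 1 pg = 978 Mb.
Records are excluded when the map covers less than 60% of the genome or
the heterozygosity estimate rests on fewer than five SSR loci; the
exclusion log names the violated rule per species. Rates are modelled on
the natural-log scale (`log_rate = ln(rate)`); fitted intercepts near
−1.5 for trees then correspond to rates near 0.2 cM/Mb, which is the
right order for large-genome taxa. A paired Wilcoxon signed-rank test on
log rates supports the decision to pool domesticated species with their
wild relatives (pool when p > 0.05); the choice of a paired nonparametric
test is ours — no published construction is being matched.

The coverage filter is applied before the correction, since the
correction formulas operate on the retained per-chromosome data.

## Trees, calibration, covariance

Trees are rooted, with branch lengths in Myr after calibration.
Calibration follows the BLADJ idea: constrained nodes keep their ages
exactly; every undated node is placed by linear interpolation along the
path from its nearest dated ancestor to its nearest dated descendant
(fewest intervening edges), which evenly spaces a chain of undated nodes
between two dated ones. When several dated descendants are equally near,
the one reached through the child subtree with the lexicographically
smallest leading tip label wins — a deterministic tie-break we chose;
the original Phylocom tool does not document its own.

The Brownian-motion covariance matrix has `V_ij` = depth of the MRCA of
tips i and j from the root. The correlation matrix `R = V / depth` is
only defined for ultrametric trees; ultrametricity is checked at a
relative tolerance of 1e-6 (calibrated trees are ultrametric by
construction; the tolerance absorbs rounding). Non-ultrametric input is
rejected rather than silently normalized.

Polytomies are accepted in parsing and resolved only where an algorithm
requires bifurcation: they become ladders of zero-length internal
branches, children ordered by smallest descendant tip label. This leaves
V (and hence all GLS quantities) exactly unchanged and makes the
contrast count a fixed n − 1.

## Phylogenetic signal

Standardized independent contrasts follow Felsenstein's post-order
algorithm: contrast `(x_i − x_j)/√(b_i + b_j)`, internal value the
branch-weighted mean, parent branch extended by `b_i b_j/(b_i + b_j)`.
The "variance of contrasts" is defined as the mean of squared
standardized contrasts without centring; this makes the algebraic
identity `Σ contrast² = (x − â1)ᵀV⁻¹(x − â1)` exact, where `â` is the
GLS mean (equivalently the Felsenstein root value).

Blomberg's K is computed from the GLS quadratic forms,

    K = [MSE0 / MSE] / [(tr V − n/(1ᵀV⁻¹1)) / (n − 1)],

with `MSE0` the ordinary and `MSE` the V-whitened mean squared deviation
from `â`. K = 1 under pure Brownian motion; on a star phylogeny with
equal branches K is identically 1 for any trait.

The significance test reshuffles trait values uniformly across tips.
Signal shows as a small observed contrast variance, so
`p = (1 + #{null ≤ observed}) / (1 + n_perm)` (the plus-one rule keeps p
strictly positive). Because the ranking by contrast variance and by K
need not produce identical tail counts, an upper-tail K-based p-value on
the same reshuffles is reported alongside, as is the boolean "observed
variance below the 5th percentile of the null" criterion and the null
mean. An exact mode enumerates all n! assignments for small trees.

## Regression models

Three models relate log rate to He and life-form: an uncorrected
Gaussian GLM (OLS), and two phylogeny-corrected fits where R enters a
generalized estimating equation. For a Gaussian identity-link GEE with a
*fixed* working correlation the estimating equations are exactly the GLS
normal equations, so the corrected fits are computed in a single GLS
step (no working-correlation iteration). Baseline life-form is
(angiosperm) tree; herb and shrub get dummies; the second corrected
model adds a conifer-tree dummy. Degrees of freedom default to n − p
with two-sided t p-values. Reference GEE implementations use their own
"phylogenetic df" heuristics, so p-values from such software can differ
from ours on identical data even when estimates agree; estimates and
SEs are the stable quantities to compare.

Fitted per-life-form means are `intercept + level coefficient` (at the
intercept's He scale by default), with delta-method SEs from the
coefficient covariance. Kruskal–Wallis comparisons use the tie-corrected
H with a chi-square approximation (k − 1 df).

## Within-gene recombination

Alignment columns are reduced to biallelic SNPs: indel/missing columns,
sites with more than two states, and (by default) singletons are
excluded, leaving parsimony-informative sites; each drop is logged with
its reason. The major allele is coded 0 (ties broken by first
occurrence — downstream statistics are invariant to this). Genes enter
the analysis when they span ≥ 800 bp, have ≥ 10 segregating sites and
are sampled for more than 20 chromosomes; eligibility counts all
biallelic segregating sites, while θπ, θW, Rm and ρ̂ are computed on the
parsimony-informative set.

θπ uses the unbiased pairwise-difference form `Σ 2p(1−p)·n/(n−1)/L`;
θW is `S/(a_n L)`.

**Rm** (Hudson–Kaplan): every four-gamete-incompatible site pair forces
a crossover strictly between the two sites; Rm is the minimum number of
points stabbing all such open intervals, computed by the right-endpoint
greedy sweep, which is provably optimal for interval stabbing (and is
verified against an exhaustive oracle in the tests). Intervals sharing
an endpoint count as disjoint.

**Composite-likelihood ρ**: the sampling probability of each folded
two-site haplotype configuration is tabulated by Monte-Carlo two-locus
coalescent simulation on a ρ grid (default 0–100, 10,000 replicates per
point). Conditioning on one mutation per locus in the θ → 0 limit is
implemented by weighting each replicate by the product of the two
marginal tree lengths and placing one mutation per tree uniformly by
branch length. The per-gene estimate maximizes
`Σ_pairs log P(config_ij | ρ · d_ij / d_total)` over a deterministic
search grid, with table log-probabilities interpolated linearly in
log(1 + ρ) and held flat beyond the last grid point; configurations
never observed at some grid ρ are floored at `1/(mc_reps + 1)` to avoid
−∞ composite likelihoods. Distances use physical positions when
available, else column indices. ρ/θ divides the per-gene ρ̂ by the
per-gene Watterson θ. Like all pairwise composite-likelihood estimators
this one is biased (typically downward at low ρ on informative-site
data) but strongly monotone in the true ρ, which is the property the
comparative analysis relies on and the one the test suite checks. A
posterior summary-statistics co-estimator of θ and ρ is deliberately not
implemented.

## Synthetic data

The generators produce every input with known ground truth:

- **Yule trees**: exponential waiting times at rate kλ, one extra
  interval after the n-th birth, so expected depth is Σ_{k=2}^{n} 1/(kλ).
- **Brownian traits**: preorder accumulation of Gaussian steps; a 2×2
  per-unit-branch covariance gives correlated trait pairs (the log-rate /
  He analogue).
- **Life-forms**: a continuous-time Markov switch along branches (default
  ≈ 2 expected switches per root-to-tip path, so states cluster in clades
  but all levels are usually present), or fixed clade painting, with
  additive effects on the log rate. Defaults: herb −0.9, shrub −0.7,
  conifer tree −1.1 around a tree intercept of −1.5 with He slope 0.8 —
  round numbers of the same magnitude as comparative estimates for these
  quantities.
- **Species tables**: He is a logistic squash of a Brownian trait into
  [0.3, 0.9] (a realistic SSR He range); the latent log rate adds the He
  term, the group effect, and a Brownian deviation (variance 0.25 per
  unit depth, so residuals are phylogenetically structured and the GLS
  model is correctly specified). Map lengths (equal chromosomes, 51
  markers each) and genome sizes (conifers drawn 8–30 Gb, angiosperms
  0.3–4 Gb) are back-solved so the rate pipeline returns the latent rate
  exactly, and every record passes the filters by construction.
- **Coalescent with recombination**: a backward-in-time ancestral
  recombination graph over the unit interval, tracking only ancestral
  segments (standard ms behaviour) and dropping segments that reach
  their marginal MRCA; infinite-sites mutations at rate θ/2 mapped to
  distinct integer bp (collisions resampled — negligible at test scales
  where L ≫ S). Validated against an independent coalescent simulator
  (msprime) on summary-statistic distributions in the tests.

What the generators do **not** emulate: measurement error in map lengths
and C-values, heterogeneous marker densities within a genome,
correlation between genome size and life-form beyond the conifer
painting, selection, demography, gene conversion, or the idiosyncrasies
of literature-curated data. Passing recovery tests therefore shows the
estimators are correct and calibrated under the stated models, not that
real comparative datasets satisfy those models.

## Problem sizes and determinism

Test and validation experiments use 50–100-tip trees, hundreds of
replicate datasets, two-locus tables with 10,000 Monte-Carlo replicates
per grid point, and 120–200 coalescent replicates per ρ level — sizes at
which every Monte-Carlo check resolves its target within the stated
tolerances. Every stochastic routine takes an explicit seed;
the pipeline derives per-stage seeds from one global seed, and re-running
with the same inputs and seed reproduces every number bit-for-bit.

## Known limitations

- BLADJ tie-breaking and per-node interpolation can, on adversarial
  constraint sets, propose a negative branch; this is detected and
  rejected rather than silently clamped.
- The composite ρ̂ is a point estimate with no confidence interval; its
  absolute scale depends on the grid and the informative-site thinning.
- GEE p-values are df-convention dependent (see above).
- The exact permutation mode is factorial in the tip count and guarded
  accordingly.
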