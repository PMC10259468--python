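# Methods

`metaboflow` implements a dual-metabolome analysis: it takes aligned
untargeted LC-MS feature tables of a set of diets (fruit purees) and of
consumers (fly pools) reared on them, and asks whether the consumers
process biochemically dissimilar diets through one generic metabolic
response ("metabolic generalism") or through diet-specific responses
("multi-host metabolic specialism"). This note records the models,
parameter choices and numerical conventions the package commits to.

## Data model

A `FeatureTable` is an ions x samples matrix of integrated peak areas
(arbitrary intensity units) plus sample metadata (kind in {fruit, fly,
control_fly, blank}; diet; generation; replicate). Ions are identified
as `MxxxTyyy` (m/z in a.m.u., retention time in seconds); since the two
ionization modes are aligned separately and merged afterwards,
identifiers are unique only within a mode and merged tables carry a
`_pos`/`_neg` suffix — the suffix convention is this package's choice,
as merged-id disambiguation has no single community standard. Absent
peaks are stored as 0, not NA: the upstream fill step integrates the
signal region for missing peaks, so 0 encodes "below detection".

## Preprocessing

1. **Blank suppression.** An ion is removed when its maximum area over
   the blank injections is >= its maximum area over all real samples.
   The comparator is max-vs-max, the conservative reading that only
   suppresses ions never clearly above instrument background; an ion
   with zero blank area is never removed.
2. **Mode merging** concatenates the positive- and negative-mode tables
   row-wise after suffixing ids; the sample sets must match.
3. **Control correction.** Fly areas are centred on the per-ion,
   per-generation median of the control flies (reared on the artificial
   medium alone), which removes signal contributed by the artificial
   component of the fruit media. Negative centred values are clamped to
   0 before thresholding, because a peak area cannot be negative; any
   corrected value below 1000 is then zeroed. The 1000-area cut
   approximates the practical quantification threshold of an Orbitrap
   instrument; it is the same threshold used for presence calls.
4. **Presence/absence.** An ion is present in a group (one fruit, or
   one fly-diet group) iff its area is strictly greater than 1000 in at
   least 3 of the group's replicates. Fly replicates are pooled across
   generations (6 samples per diet; 3 where only one generation
   exists), because presence is defined per diet category, not per
   batch. The strict `>` at the boundary is a convention; areas are
   continuous so the choice is measure-zero.
5. **Contamination screen.** Per diet, Kendall's tau-b between per-ion
   mean fruit area and mean fly area, over ions detected on either
   side. Direct carry-over of diet material into consumers would show
   up as a strong positive rank correlation; |tau| < 0.2 is read as
   absence of contamination. tau-b is used because ties at area 0 are
   common.

## Intersections and flow

Group membership across the 8 groups (4 fruits then 4 fly diets,
alphabetical within each block) is encoded as an 8-bit mask per ion.
Intersection sizes are the exact partition of ions by mask (the empty
mask is retained so conservation holds); top-k listings break ties by
ascending mask value. The intersection *degree* of an ion within a
domain is the popcount of that domain's 4 bits, and the 5x5 flow matrix
counts ions by (fruit degree, fly degree). Row/column sums equal the
marginal degree histograms and the grand total equals the ion count —
these conservation laws are asserted by property tests.

## Multivariate views

Quantitative analyses scale each ion to mean 0, variance 1 (sample sd,
n-1 denominator); constant ions are dropped with a logged count. PCA is
computed by SVD of the scaled samples x ions matrix; component signs
are fixed by making each component's largest-magnitude loading
positive, so score tables are reproducible. Hierarchical clustering
uses Ward linkage on Euclidean distances; samples are sorted by id
before linkage so the result is independent of input order. Ward is
chosen as the variance-minimising standard for scaled omics profiles;
the linkage is an argument for users who prefer another.

To compare chemical proximity with taxonomy, the sample dendrogram is
collapsed to one leaf per diet — defined only when each diet's samples
are monophyletic; otherwise the operation reports non-monophyly instead
of inventing a topology — and compared with a reference Newick tree by
a rooted Robinson-Foulds count (clades present in exactly one of the
two topologies; 0 iff identical).

## Diet signatures

For each diet d, a one-vs-rest binomial GLM with elastic-net penalty is
fitted to the control-corrected fly areas:

    min_{b0, b}  -(1/n) loglik(b0, b) + lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)

Features are standardized inside the fit (population sd, the glmnet
convention) and coefficients are reported on the standardized scale so
selected-set comparisons are meaningful. Two canonical parameter sets
are provided: `large` (alpha=0.5, lambda=0.01, blackcurrant lambda
0.001), aimed at optimal classification, and `compact` (alpha=0.9,
lambda=0.001, blackcurrant 0.0001), aimed at short curatable lists. The
per-diet override compensates for the smaller blackcurrant sample count
(one generation); class imbalance is otherwise not re-weighted.
Classification uses the 0.5 posterior-probability cut, and
`deviance_ratio = 1 - residual/null deviance`.

The solver is an in-package IRLS + cyclic coordinate-descent routine
(quadratic approximation with probabilities clamped to [1e-5, 1-1e-5];
soft-thresholding over an active set with full rescans). Off-the-shelf
stochastic solvers fail to converge on this problem class (separable
data, n in the tens, p in the thousands, small lambda); the
coordinate-descent fit is verified in the test suite against the glmnet
reference implementation, with identical selected sets and deviance
ratios to ~1e-5. The outer loop stops when coefficients are stationary
(max shift < 1e-6) or when the penalized objective is stationary
(relative change < 1e-9) — on separable data at tiny lambda the norm
creeps long after the objective and the selected set have stabilised.
A 10-fold cross-validated (alpha, lambda) sweep is exposed as an
optional exploration routine; the canonical parameter sets are fixed.

**Enrichment.** Medians are summarised by percentile bootstrap CIs
(default n_boot = 1000), the recommended summary for heavily skewed
data containing zeros. CI endpoints are taken as order statistics of
the bootstrap medians (outward-rounded), so they are always attainable
medians. A signature ion is flagged enriched when the focal group's CI
lies strictly above the pooled alternate groups' CI; CI separation is
this package's operationalisation of "significantly more present" — it
is conservative relative to a direct two-sample test. Fly and fruit
flags are reported separately.

**Log fits.** Mean fly areas are regressed on mean fruit areas (focal
diet, log10 scale) over a model's signature ions. Zeros are replaced by
half the minimum positive mean before the log, so the fit is unchanged
when no zeros occur.

## Resolving power

The qualitative-vs-quantitative experiment asks how many randomly
sampled ions identify a fly's diet. For each batch size, ion subsets
are drawn uniformly without replacement (the same subset for both data
modes, so the comparison is paired); samples are Ward-clustered on the
scaled quantitative areas or on the raw per-sample 0/1 detection
profile (area > 1000 per sample, without replicate pooling — each
sample keeps its own profile), the tree is cut at k = number of diets,
clusters are mapped to diets by the one-to-one assignment maximising
matches (Hungarian algorithm), and accuracy is the matched fraction.
An unsupervised clustering classifier is used because the accompanying
score is a clustering-comparison index; the classifier is pluggable via
`classify_by_clustering`. If a drawn batch has no varying feature, all
samples are placed in one degenerate cluster.

Adjusted Mutual Information uses natural logs, the exact hypergeometric
expected MI (EMI) under fixed margins, and the max-entropy normaliser:

    AMI = (MI - EMI) / (max(H_u, H_v) - EMI)

Degenerate cases: if the normaliser vanishes, AMI is 1 for identical
trivial partitions and 0 otherwise (a single-cluster partition against
anything non-identical scores 0). The EMI sum is checked in the tests
against full enumeration of all contingency tables for every margin
pair with N <= 8, and AMI against sklearn's max-normalised variant.

Default batch sizes are {10, 30, 100, 300, 1000, 3000, 10000} truncated
to the ion count. The repetition default is 10,000; the test suite and
the acceptance script use 200 repetitions, which bounds the Monte-Carlo
standard error of a mean accuracy by ~0.035 and keeps each curve within
seconds at desk scale.

## Synthetic data

The generator emulates the reference feeding design — 4 fruits x 3
puree replicates; fly pools for 4 diets x 2 generations x 3 replicates
(blackcurrant one generation); control flies per generation; 2 blank
injections — with every ion assigned to a planted class (see the table
in `metaboflow.synthetic`). Defaults, fixed once: 2000 ions; class
fractions core_shared 0.45, fruit_private 0.20, fly_de_novo_common
0.10, artificial_medium 0.06, blank_contaminant 0.06, fruit_only_shared
0.05, transferred_private 0.04, diet_signature 0.04 — calibrated so the
all-fruit/all-fly core is the largest intersection, ~10% of ions are
fly-only de novo metabolites, and each fruit keeps a private
complement, the qualitative regime reported for this study system.
Intensities are log-normal (peak areas are positive and right-skewed;
no noise model is published for these data): baseline area 5e4 with a
per-ion structural spread of 0.8 log units and per-sample noise
log_sd = 0.3; a multiplicative generation batch factor of 1.5 on fly
and control samples; a hard detection floor (dropout) at area 500;
planted-present cells floored at mean area 5000 (5x the presence
threshold) so planted patterns are identifiable. Signature ions are
elevated 4-fold in the focal diet's flies. Fruit-to-fruit quantitative
structure for ions shared by several fruits follows Brownian motion on
an ultrametric "chemical proximity" tree; the default tree places
blackcurrant as the chemical outgroup and does *not* pair cherry with
strawberry, so the chemical dendrogram deliberately violates the
Rosaceae phylogeny (set `chemical_tree = PHYLOGENY_NEWICK` to make them
agree).

Medium-derived (artificial_medium) ions are modelled at moderate
abundance (~4000 area) with a *shared* per-(ion, generation) medium
level and only small technical scatter (log_sd/6) between flies of the
same generation: all flies of a batch eat the same prepared medium.
This structure is what makes control-median centering effective; if
medium ions instead had fully independent per-sample noise at full
biological dispersion, subtracting the control median would leave
roughly half the samples above threshold no matter the implementation.

A second generator, `simulate_quantitative_contrast`, builds a fly-only
dataset whose diet signal is purely quantitative: every ion is present
in every sample (a 30% near-threshold fraction flickers at random,
carrying no diet information), and 5% of ions per diet are elevated
4-fold in the focal diet with no generation effect. Presence profiles
are then provably uninformative, isolating the qualitative-vs-
quantitative comparison.

What the generator does **not** emulate: chromatographic or spectral
structure (no adducts, isotopes, in-source fragments, so no
inter-feature correlation beyond the planted classes), retention-time
drift, missing-not-at-random dropout, heteroscedastic technical
variance between fruit extractions and fly pools (separate dispersion
knobs exist but default equal), or intermediate fruit-degree classes
(ions shared by exactly 2 or 3 fruits). Passing tests therefore
demonstrate correctness of the algorithms under a clean planted model,
not performance on real chromatographic data — in particular, real
feature tables' strong inter-ion correlation would make elastic-net
selected sets less stable than the synthetic results suggest.

## Problem sizes and determinism

All simulations run at 2000 ions and the reference sample layout (41
samples), the scale at which every planted structure of interest is
present with comfortable counts. Every stochastic routine takes an
explicit seed or Generator; identical inputs give bit-identical
outputs, and the resolving-power curves are reproducible bit-for-bit
under a fixed seed.

## Known limitations

- The elastic-net fit at the canonical `large` penalty, applied to a
  design with ~20 samples and thousands of ions, selects a tail of
  chance-correlated ions alongside the true markers: on synthetic
  recovery experiments the selected lists reach high recall (~0.9) of
  planted quantitative signatures but only ~0.6 precision, and sweeping
  lambda trades one against the other without reaching 0.9/0.9 jointly.
  This is a property of the estimator at this n/p (verified identically
  in glmnet), so selected lists should be read as enriched candidate
  sets, not as clean marker sets.
- Normalisation by internal standard or dry weight is out of scope (the
  upstream workflow applies none after alignment), as are peak picking,
  alignment, and metabolite identification.
- The presence threshold is applied to control-corrected fly areas for
  the qualitative dataset; applying it to raw areas instead changes the
  fly-side presence of medium-derived ions.
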