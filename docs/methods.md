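# Methods

`urheimat` implements a four-stage quantitative procedure for dating a small
language family and constraining the location of its homeland, together with
synthetic-data generators that reproduce the statistical structure each stage
assumes.  All empirical numbers quoted in the README are printed by the code
in `examples/` or by `scripts/acceptance.py`; this note documents the models,
the defaults, and the design decisions.

## 1. Tip-dated Bayesian phylogenetics of binary cognate data

**Data model.** A cognate matrix codes languages × cognate sets as present
(1), absent (0) or uncertain (?).  Cognate sets are grouped into meaning
concepts; at study scale: 5 languages (four extant, one extinct attested
until 900 BP), 251 concepts, 736 cognate sets.  `?` is treated as missing —
the likelihood sums over both states — since the coding does not distinguish
unattested items from uncertain cognacy.

**Substitution models.** Three binary gain/loss models are implemented:

- *CTMC*: reversible two-state chain with stationary presence frequency
  π₁; closed-form transition probabilities.
- *Binary covarion*: four states (0/1 × slow/fast).  Within-regime
  substitution runs at rate α (slow) or 1 (fast), both scaled by the visible
  equilibrium frequencies; switching between regimes at rate s preserves the
  visible state; hidden categories have equal weight.  At α = 1 the model
  collapses exactly to the CTMC (unit-tested).
- *Stochastic Dollo*: each cognate is born exactly once, uniformly per unit
  branch length over the tree plus a root stem (default stem duration =
  root age), and is lost independently at rate μ_D thereafter.  The birth
  intensity cancels between the column measure and the observability
  normalizer, so the likelihood depends only on μ_D.

All rate matrices are normalized to one expected visible substitution per
unit branch length; the clock carries the absolute per-year scale.  Optional
per-concept rate multipliers (mean one, lognormal(0, 0.5) hyperprior,
delta-exchange moves) and 4-category discrete-gamma rates across cognates
are available as independent switches.

**Ascertainment.** Only attested cognate sets enter a matrix, so each
concept's likelihood is conditioned on non-absence:
`logL_c = Σ_cols log P(col) − n_cols(c)·log(1 − P_c(all-absent))`, where
P_c(all-absent) is computed from a flagged all-zero column appended per
concept.  The correction strictly increases the log-likelihood.

**Tree prior.** Fossilized birth–death, evaluated for a labeled dated tree
conditioned on the root age and on both root lineages leaving sampled
descendants; extant tips are ρ-sampled (ρ = 1), the extinct language is a
ψ-sampled terminal tip.  With μ = ψ = 0, ρ = 1 the density reduces to the
Yule closed form; the normalization (including the labeling constant
2^{n−1}/n!) is validated by quadrature against the closed-form probability
that two root lineages leave exactly n tips.  A dated extinct tip has zero
probability when μ = 0 — a lineage that cannot die is eventually sampled at
the present — so configurations combining a fossil tip with zero death rate
are rejected.  The root age itself takes a proper Uniform(0, 50 000 yr)
prior; FBD hyperparameters are sampled in canonical form (diversification ~
lognormal(ln 2·10⁻⁴, 1.5) yr⁻¹ — centered on ln(n_tips)/root-age for a
handful of languages over ten millennia, since a faster scale measurably
biases node ages young — turnover ~ U(0,1), sampling proportion ~
Beta(1,1)), all configurable.

**Clocks and calibrations.** Strict clock (single rate, lognormal(ln 2·10⁻⁴,
1.5) prior — a basic-vocabulary replacement scale) or UCLN relaxed clock
(per-branch iid lognormal with real-space mean M and log-sd S; S ~
Exponential(1/3)).  Calibrations: the extinct tip fixed at 900 BP; a
Normal(1200, σ) prior on the Megrelian–Laz (Zan) node age with σ = 10 by
default and 50/100/200 available for sensitivity runs.  The calibration is a
soft density on the MRCA age of the calibrated tip set, not a monophyly
constraint.

**Sampler.** Metropolis–Hastings with: internal-node age slides, root-age
scaling, an independence draw of the root age over its admissible range
(added because the tree height is weakly identified and mixes slowly under
random-walk moves alone), whole-tree scaling, a rate/age "up-down" scaling,
narrow exchange on the topology, multiplicative scales for positive scalars,
reflected windows for unit-interval parameters, per-branch rate scales, and
concept-rate delta exchange.  A single root seed drives every draw; two runs
with the same configuration are bit-identical.  Retained sample count is
`floor(generations/thin) · (1 − burnin)`; the study configuration (200M
generations, thin 5000, 10% burn-in) retains 36 000 trees, verified by
proportionality on scaled chains.

**Summaries.** ESS by the initial-positive-pair truncation rule; HPD as the
shortest window of sorted samples containing ⌈0.95 n⌉ points (leftmost on
ties); MCC tree as the sampled topology maximizing the product of clade
posterior frequencies, with node heights set to clade-wise mean MRCA ages
(recorded as `height_rule: mean-age`).

## 2. Model selection

Marginal likelihoods by nested sampling: particles drawn from the joint
prior (equilibrated by prior-only MCMC), worst particle replaced by a
constrained clone run through `subchain_length` prior-MCMC steps rejected
below the likelihood floor; deterministic shrinkage ladder X_i = e^{−i/N};
sd from (H/N)^{1/2}; termination when the best live point's remaining mass
falls below 10⁻⁶ of the accumulated evidence, plus the live-point fill-in.
Log Bayes factors ≥ 5 are reported as very strong support.  The generic core
is validated against a conjugate normal–normal toy problem (within 3 sd) and
exact constant-likelihood evidence.

Nested sampling at small particle counts is noisy for these posteriors
(sd ≈ 1.5–2.5 nats per run at N = 12–20); the ranking criterion is therefore
assessed on a generator regime with a strong covarion signature (see §5).

## 3. Paleodistribution modelling

MaxEnt suitability: Gibbs distribution over background climate cells with
quadratic features (standardized linear + squared terms) and hinge features
(30 forward + 30 reverse knots per variable, evenly spaced over the
background range), fitted by penalized maximum likelihood (L-BFGS-B on a
positive/negative weight splitting).  L1 penalties: quadratic-class
multiplier interpolated from 1.0 (≤10 presences) to 0.25 (≥100) on a log
scale, hinge-class 0.5, each scaled by the feature's background sd over
√m — with the hinge sd floored at 0.5 so knots active on a handful of
background points cannot absorb sampling noise.  Output is the
complementary log-log transform `1 − exp(−e^H · raw)` (logistic available),
which maps a featureless model to ≈ 0.632 everywhere.

Ranges: occurrences thinned to one per pixel (deterministic first-in-sorted
retention); 10 000 background cells sampled without replacement at study
scale; binarization at the maximum-training-sensitivity-plus-specificity
threshold with background points standing in for absences, candidate
thresholds the distinct presence suitabilities, ties resolved to the lowest
threshold (ranges err inclusive, and a presence at the threshold is
predicted present); co-occurrence as the per-cell product of binary maps;
per-period combination of slices defaults to union (intersection and
frequency ≥ f rules available — the choice is configurable because either
reading of "combined" is defensible).

Rasters are ESRI ASCII grids (text); models serialize to JSON.

## 4. Biomes, societies, and genotype PCA

**Biomes.** Eight classes: four arboreal-pollen bins — [5,25), [25,50),
[50,75] and (75,100] % AP, lower-inclusive at 5/25/50 with 75 in the 50–75
class — plus Desert, Steppe, Tundra and Glacier below 5% AP, taken from the
site's land-cover label (no inference rule exists for them).  The
biome-climate model is an unpenalized multinomial logistic regression on
(MAT, AP) — fitted via scikit-learn behind `fit_multinomial`, predictors
standardized internally, coefficients reported on the raw scale re-based to
a zero reference class, |coef| capped at 30 with a warning under
separation.  Accuracy and Cohen's kappa ((p_o − p_e)/(1 − p_e)) from hard
argmax assignment.  Society maps: cell = 1 iff its biome belongs to the
culture × window association table (packaged as YAML; the final window is
4000–2000 BP with an optional extension to 1500 BP).  Mode aggregation
across slices breaks ties toward the earliest slice.  A crosstab routine
derives an association table from dated culture sites at a configurable
fraction cutoff (default 0.05).

**PCA.** smartpca conventions: allele frequency p̂ = (1 + Σcalls)/(2 + 2n)
over the modern reference panel, genotypes normalized as (g − 2p̂)/√(p̂(1−p̂)),
monomorphic SNPs dropped, missing reference calls mean-imputed, no
outlier-removal iterations.  Top-K eigenvectors by SVD (K = 10 computed, 2
reported), sign fixed by making the largest-magnitude loading positive.
Ancient/projected individuals are placed by least squares of their
normalized observed calls on the loadings restricted to their non-missing
SNPs; with no missingness this equals the plain scores (unit-tested to
1e−10).  EIGENSTRAT text triplets are read and written.

## 5. Synthetic-data generators: what they emulate

Every generator is fully determined by one seed (per-stage substreams), and
defaults are the study's stated sizes.

- **Dated trees**: forward birth–death; "the present" is the moment the
  lineage count first reaches n plus an exponential hold, giving a
  closed-form Yule mean root age (Σ_{k=2}^{n−1} 1/k + 1/n)/λ used as the
  simulation oracle.  One extinct tip is grafted at 900 BP onto a uniformly
  chosen coeval branch.  `kartvelian_reference_tree()` encodes the study's
  mean chronology (root 7641, Georgian–Zan 2617, Zan 1200, Old Georgian
  attachment 1100 BP) as the standard input for recovery experiments.
- **Cognates**: per-concept set counts are shifted-Poisson with mean
  736/251, repaired to exactly `n_concepts × mean` total columns (736 at
  study scale) so the bookkeeping of the coding file is reproduced; columns
  are simulated state-by-state down the tree and resimulated until at least
  one tip shows presence (the observability filter); `?` is inserted
  missing-at-random.  Defaults: covarion with α = 0.3 and s = 0.3 at a
  2·10⁻⁴ /yr clock — a moderate regime whose intermediate-rate columns keep
  divergence times identifiable (chronology recovery is the generator's
  primary job).  Optional per-branch and per-concept lognormal rate
  multipliers are available.

  Five-taxon identifiability forces a two-regime experimental design.  The
  covarion-vs-CTMC *ranking* experiments simulate an explicit
  strong-persistence regime (α = s = 0.02, branch-rate log-sd 0.5): words
  are conservative or labile and essentially never change regime, which is
  the regime where the covarion signature is detectable from five taxa
  (fitted log-likelihood margins of ~20–40 nats over the CTMC).  That same
  regime freezes half the columns and saturates the rest, which destroys
  date information — so dating experiments use the moderate default regime
  instead.  No single five-taxon regime exposes both signals at once.
  Relaxed-versus-strict clock preference is likewise not identifiable here:
  with free node ages and only two calibrations, a strict clock absorbs
  branch-rate variation by adjusting divergence times, and the evidence
  favors the smaller model — a real limitation of five-taxon data,
  documented rather than engineered away.
- **Climate**: Gaussian random fields (white noise smoothed at the
  configured correlation length, variance-corrected by the kernel's
  theoretical reduction so amplitude is scale-free), AR(1)-coupled across
  time slices, mapped affinely into the configured °C and mm ranges.  Real
  paleoclimate rasters have topography-driven anisotropy and temporal
  trends these fields do not emulate; passing tests demonstrate correctness
  of the range algebra, not realism of any particular reconstruction.
- **Taxa**: independent Gaussian climate responses per variable; presences
  sampled proportional to true suitability (pre-thinning).
- **Pollen sites**: biome labels drawn from the true softmax model on
  standardized climate; AP percentages drawn uniformly within the label's
  bin; low-AP classes carry their land-cover label.  Sites are dated near
  their climate slice.
- **Culture sites**: placed on cells whose projected biome matches a known
  society-biome table, dated within the table window near the slice —
  the truth for crosstab-recovery tests.
- **Genotypes**: ancestral frequencies U(0.05, 0.95); per-population
  frequencies Balding–Nichols at the configured FST; diploid binomial
  calls; ancients assigned to populations (optionally 50/50 admixed) with
  missing-completely-at-random calls at the configured rate (default 0.5).
  Real ancient-DNA pseudo-haploidy, damage and reference bias are not
  emulated.

## 6. Problem sizes and numerical choices

The study's own settings (200M generations; nested sampling on ten model
configurations) are hour-scale.  The shipped tests and the acceptance
script run the same code at reduced sizes chosen to keep full runs at
desk scale: split-date chains of 120k–260k generations (tree-height ESS
comfortably above 200), nested sampling with 12–20 particles and subchains
of 30–60 steps, 20-replicate coverage checks on 40-concept matrices.
Tolerances asserted in tests come from the quantities' own reported
uncertainties (e.g. the root-age HPD) or from closed-form oracles computed
in the test itself.

Degenerate inputs are defined errors: zero-variance traces flag and return
n; all-`?` columns contribute exactly zero log-likelihood; constant climate
layers reject MaxEnt fitting; a calibrated clade naming unknown languages
fails fast.

## 7. Known limitations

- Five taxa put hard limits on identifiability: relaxed-clock support
  depends on rate asymmetry within calibrated subtrees, and covarion
  support on strong slow/fast contrast; both are documented generator
  choices, not universal facts about the models.
- Nested sampling with constrained-MCMC replacement can terminate early on
  multimodal likelihoods; particle counts below ~10 visibly bias log-evidence
  downward for parameter-rich models.
- The FBD density conditions on the root age rather than an origin time;
  comparisons with origin-conditioned implementations require matching
  conventions.
- The MaxEnt regularization constants follow the reference defaults in
  spirit but not knot-for-knot; fitted weights are comparable, not
  identical, to other implementations.
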