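# Methods

This note documents the models and statistics implemented in `haplogeo`,
the conventions and numerical choices behind them, what the synthetic-data
generators emulate, and the problem sizes the test suite uses.

## Haplotype recoding

Input alignments are over `{A,C,G,T,N,-}`. Variation is recoded into
*mutation columns* before anything else is computed:

- **Substitutions**: one column per polymorphic alignment site outside
  indel/inversion regions. Sites where any sequence carries `N` are dropped
  (a single ambiguous base would otherwise manufacture spurious haplotypes).
- **Indels**: every distinct maximal gap span (same start and end across the
  sequences sharing it) becomes one binary presence/absence column; a 5-bp
  deletion therefore separates haplotypes by one step, the standard
  convention in cpDNA phylogeography where indels arise as single events.
- **Inversions** must be *declared* (as half-open column ranges): within a
  declared range each sequence is assigned the orientation whose match to
  the majority-orientation consensus is better, producing one binary
  column. Automatic inversion detection is deliberately out of scope — on
  spacer-sized fragments it is unreliable, and published studies identify
  inversions during alignment curation anyway. Overlapping declared ranges
  are an error.

Identical recoded vectors collapse into haplotypes, labelled in order of
first appearance. Distances between haplotypes count differing columns; a
gap character inside a substitution column acts as a wildcard (missing
state) and contributes no distance.

## Diversity and differentiation

Per-population haplotype diversity uses the unbiased estimator
h = n(1 − Σp²)/(n − 1); nucleotide diversity π is the mean number of
pairwise differences per site (recoded events) across individual pairs.

G_ST and N_ST follow the ordered/unordered decomposition with *unweighted*
population means: for a distance kernel d over haplotypes,

    v_i = n_i/(n_i−1) · Σ_k Σ_l x_ik x_il d_kl        (within pop i)
    v_S = mean_i v_i
    v_T = Σ_k Σ_l x̄_k x̄_l d_kl + v_S/(s·ñ)

with x̄ the unweighted mean frequency vector, s the number of populations
(n_i ≥ 2 only) and ñ their harmonic mean size; the differentiation
coefficient is (v_T − v_S)/v_T. The identity kernel (d_kl = 1 for k ≠ l)
gives h_S, h_T and G_ST; mutational distances give N_ST. These unbiased
estimators can legitimately go slightly negative in unstructured data.

The U-test permutes haplotype *labels* on the distance matrix, leaving
frequencies untouched, recomputes N_ST each time, and reports
U = (N_ST − mean_null)/sd_null with the one-tailed permutation p-value
(+1-corrected: p = (1 + #{null ≥ obs})/(B + 1)).

Diversity-versus-latitude uses ordinary least squares (statsmodels OLS) of
per-population h on latitude — the leading-edge-expansion check.

## AMOVA and SAMOVA

AMOVA partitions variance in *squared* mutational distances (the
Φ-statistics convention) into among-group (σ²_a), among-population-within-
group (σ²_b) and within-population (σ²_c) components, with the standard
unequal-sample-size coefficients (n′, n″, n‴). All sums of squares are
computed from the population-pair sum matrix W[p,q] = c_pᵀ d² c_q, which
makes a single AMOVA cheap enough to sit inside an annealing loop.
Negative component estimates are reported as-is and flagged, as the
classical method does.

SAMOVA searches for the K-group partition of populations maximising F_CT
subject to geographic contiguity. Contiguity is the Delaunay triangulation
of population coordinates (collinear layouts fall back to a chain along the
dominant axis; duplicate coordinates are jittered deterministically with a
warning). The search is simulated annealing: geometric cooling from T₀ = 1
by factor 0.95 down to 10⁻³ with 100 proposals per temperature; a proposal
moves one boundary population to an adjacent group and is rejected outright
if it would disconnect either group. The best of `n_starts` independent
runs (default 100) wins. For ≤ 12 populations an exhaustive enumeration of
contiguous partitions is available and is used as the oracle in tests. The
K-scan suggests the smallest K at which the forward F_CT gain drops below
0.01 and flags "no reliable grouping" when no K reaches F_CT = 0.5 — both
thresholds are judgement calls and are configurable.

## Median-joining networks

The base graph is the ε-relaxed minimum spanning network over haplotype
vectors (ε = 0 keeps exactly the union of all minimum spanning trees).
Median (Steiner) vectors are the per-column majority consensus of connected
triplets; a candidate median is accepted only if adding it *strictly*
decreases total network length, and the process iterates to a fixpoint.
Afterwards medians that lie on no shortest observed-to-observed path, or
have degree < 3, are pruned (iterated, since pruning can expose more).
Majority ties in a median column take the lexicographically smallest state,
making construction deterministic.

## Neutrality tests

Tajima's D uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂)
from S segregating columns and π mean pairwise differences. Fu's F_S is
ln(S′/(1−S′)) with S′ = P(K ≥ k_obs) under the Ewens distribution of the
number of alleles at θ = π, computed by the exact recursion
f_{m+1}(k) = (m f_m(k) + θ f_m(k−1))/(θ + m).

p-values come from neutral coalescent simulation (msprime; haploid samples,
mutation rate 0.5 per sequence per generation so that time is in
generations and population size equals θ). For Tajima's D the default is
the **lower-tail** convention P(D_sim ≤ D_obs) used by the standard
software family — so a positive D in a bottlenecked population prints
P near 1, exactly as published tables show; a `two_tailed` option doubles
the smaller tail. Fu's F_S reports the lower tail (expansion signal).

## Mismatch distribution and expansion dating

The expected distribution of pairwise differences after a sudden expansion
from θ₀ to θ₁ at τ mutational time units ago is

    F_j(τ) = F̂_j(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{i≤j} τ^i/i! [F̂_{j−i}(θ₀) − F̂_{j−i}(θ₁)]

with F̂_j(θ) = θ^j/(1+θ)^{j+1} the stationary curve. It is evaluated with
20 padded tail bins whose mass folds into the last reported bin, so the
vector always sums to 1.

Fitting minimises the SSD between observed and expected relative
frequencies by Nelder–Mead on square-root-transformed parameters (which
enforces τ, θ₀ ≥ 0 and θ₁ ≥ θ₀) from four starts spanning the practically
relevant corner (θ₀ small, θ₁ large), a moderate, an extreme and a
stationary configuration. The SSD surface has a flat ridge — large τ
extinguishes the expansion correction term, so a stationary histogram is
fitted equally well by any sufficiently large τ — and the fit therefore
applies a tie-break: among candidates within 10% relative SSD of the best,
the smallest τ wins. θ₁ is frequently driven to effectively unbounded
values when the data do not resolve the post-expansion level; this is the
familiar behaviour of the model, not a failure.

Goodness of fit is a parametric bootstrap: coalescent samples of size n
under the fitted expansion, each refitted; p = (1 + #{stat ≥ obs})/(B + 1)
for both SSD and Harpending's raggedness (computed with a leading zero
class), plus a percentile CI for τ. Modality of the histogram is classified
from a 3-bin moving average with boundary peaks counted.

Expansion dates use T = τ/(2 μ k g). The `paper` rounding mode floors to
the nearest hundred years, the convention that reproduces the published
worked examples (9,600 / 3,700 / 6,100 years BP for the three preset
(μ, k, g) combinations at τ = 0.625 / 0.438 / 0.082). Presets:
C_tibetana (μ = 0.71×10⁻⁹, k = 1826, g = 25), M_thunbergii (4×10⁻⁹, 1450,
10), S_superba (0.6×10⁻⁹, 1399, 8).

## Niche comparison

Rasters are plain-text ESRI ASCII grids; any externally produced
suitability surface on the same grid can enter the overlap machinery
directly. GeoTIFF input is out of scope.

Collinearity filtering drops, in layer order, any layer whose |Pearson r|
with an already-retained layer exceeds 0.70 (constant layers warn and are
retained). The seven-variable preset `PAPER_RETAINED_VARIABLES` records a
typical retained bioclim set.

Two transparent suitability models are provided: a Gaussian envelope
(product of per-variable Gaussians at the presence mean/SD, rescaled to
max 1) and a BIOCLIM-style percentile envelope (per-variable score
1 − 2|F(v) − 0.5| combined by minimum). Both need ≥ 10 deduplicated
presence cells. AUC is evaluated on an 80/20 presence split against random
background cells with half-weight ties. MaxEnt itself is not
reimplemented; the envelope models stand in as transparent, testable
suitability surfaces with the same interface.

Overlap is Schoener's D = 1 − ½Σ|p−q| and Hellinger-based
I = 1 − ½Σ(√p−√q)², both on surfaces normalised to probability
distributions; both are identically 1 on identical surfaces and 0 on
disjoint supports.

The identity test pools both species' presence cells, repartitions them
randomly into the original sample sizes, refits both models and recomputes
D and I, B times (default 100). p = (1 + #{null ≤ obs})/(B + 1), one-tailed
against niche difference. The pooled cells are canonically sorted and the
partition always drawn as (smaller n, rest), so swapping the input species
with the same seed reproduces the identical null distribution.

## Synthetic data

The coalescent generator emulates the sampling design of multi-population
cpDNA studies: a haploid, non-recombining locus, island-model migration,
demes on a west→east axis with emitted coordinates (so contiguity searches
and latitude regressions are exercisable), and an optional stepwise
expansion (ancestral size N_e/factor before time t). Truth records carry
θ_true = 2 N_e μ g k, τ_true = 2 μ g k t, and the true assignment. Mutation
is finite-sites JC69 by default, so recurrent hits are possible as in real
data; an infinite-sites switch gives clean theory checks. Simulation is
delegated to msprime; sequence construction and truth bookkeeping are
package code.

What it does *not* emulate: recombination, selection, rate heterogeneity
along the sequence, alignment error, or indels/inversions (the generator
emits substitution-only alignments; the recoding path is covered by
handcrafted alignments in the unit tests). Passing recovery tests therefore
shows the estimators are correct under the stated model, not that real
data meet the model.

The landscape generator produces standardised smoothed Gaussian random
fields as environmental layers, declared Gaussian niches per species, and
occurrences sampled proportional to true suitability without replacement.
Truth carries the true surfaces and the analytic true (D, I) per species
pair.

## Study conditions used by the validation suite

Chosen once as representative of the regime the methods target:

- **τ recovery**: 1000-fold single-deme expansions (θ₀ = 0.1 → θ₁ = 100)
  with μ = 4×10⁻⁹/site/year, g = 10 y, k = 1500 bp; n = 50; τ_true ∈
  {2, 5, 10}; 100 replicates each; pass if the median τ̂ is within ±20% of
  truth. Weak expansions sit on the flat SSD ridge where τ̂ is biased
  upward; the strong-growth regime is the one the model is used for.
- **Equilibrium π**: θ = 5, n = 50, 200 replicates, infinite-sites; mean
  pairwise differences within 5 ± 0.5.
- **U-test calibration**: 200 structureless datasets (common Dirichlet
  frequency vector, multinomial counts per population, random distances
  independent of frequencies — the exchangeability the permutation scheme
  assumes), 99 permutations, α = 0.05; observed type-I rate accepted in
  [0.01, 0.10].
- **SSD bootstrap calibration**: 100 datasets simulated under a true
  expansion (τ = 3, θ₀ = 0.5, θ₁ = 50, n = 25), each refitted and
  bootstrapped with B = 19 (rejection at α = 0.05 then means the observed
  SSD exceeded every replicate, with expected rate 1/20); observed rate
  accepted up to 0.12.
- **Identity test**: 40×40 rasters, 3 variables, 60 occurrences per
  species, 100 pseudoreplicates; same-niche pairs must give p > 0.05 and
  optima separated by ~7.5 niche widths must give p ≤ 0.01.

## Degenerate inputs and edge conventions

- Monomorphic species: differentiation and the U-test are undefined and
  say so; the 1×1 distance matrix warns.
- Populations with n = 1 are excluded from h_S/h_T/G_ST/N_ST and get
  h = π = NaN in per-population tables.
- σ² components can be negative (flagged); a non-positive total variance
  marks the AMOVA undefined.
- τ = 0 in the mismatch model is the stationary curve; dating accepts
  τ = 0 and returns 0 years.
- Permutation and bootstrap p-values always use the +1 correction and
  never return 0.

## Real-data targets

The published comparative statistics for the three species the presets
refer to (haplotype counts 19/13/9, h_T/h_S, N_ST/G_ST with U, SAMOVA
F_CT = 0.894, the neutrality values) require the original per-population
sampling table and the deposited haplotype sequences, which are not
redistributable here. They are encoded as dormant targets
(`haplogeo.published`): supplying the alignment and population table for a
species activates the corresponding comparisons; without inputs every
target reports `inactive`.
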