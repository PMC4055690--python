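# Methods

`ampdyn` analyses time series of 16S rRNA amplicon surveys and asks a
specific question of them: does the amplification bias of a primer pair
distort the *dynamics* a survey reports — turnover, similarity decay,
month-to-month change, ordination structure — or only its snapshot
composition?  The package couples a standard community-ecology analysis
stack to a synthetic data generator that encodes the causal structure
needed to pose that question as a falsifiable property.

## Diversity metrics

**Subsampling normalization.** Library sizes differ between samples, so
richness and Shannon entropy are computed on subsamples drawn without
replacement at a common depth (default 2125 reads).  A draw without
replacement is multivariate hypergeometric, which gives the closed form

    E[S_obs] = Σ_i [ 1 − C(N − N_i, d) / C(N, d) ]

for the expected number of taxa seen at depth `d` (evaluated with
log-gamma; exact to ~1e-9).  Monte-Carlo rarefaction curves (default 1000
iterations, empirical 2.5/97.5-percentile bands) are validated against this
expectation rather than against themselves.

**Shannon entropy** uses the natural log, `H = −Σ p_i ln p_i`, so
`0 ≤ H ≤ ln S_obs` with equality at uniformity.

**Bray-Curtis** is `1 − 2 Σ min(x_i, y_i) / (Σx + Σy)`.

**UniFrac** works on a per-branch decomposition of the rooted input tree.
For each branch (the edge above a node) we record its length and the set of
table taxa descending through it.  Unweighted UniFrac is the unique/observed
branch-length ratio on presence–absence; weighted UniFrac is
`Σ b |p_x − p_y|`, emitted in its normalized form (divided by
`Σ b (p_x + p_y)`) so all three metrics live on [0, 1] — a requirement of
the similarity conversion used by the decay regression.  Three choices are
deliberate and documented because the unweighted variant is sensitive to
them: the given root is the root (no midpoint re-rooting), polytomies are
kept as-is, and zero-length branches contribute nothing.  The implementation
is vectorized over a branch × taxon incidence matrix; its correctness is
checked in the test suite against a deliberately naive per-branch oracle and
against an independent library implementation.

## Ordination and permutation inference

**PCoA**: Gower double-centering of −D²/2, eigendecomposition, coordinates
scaled by √λ on the positive axes; negative eigenvalues (non-Euclidean
input) are reported and their axes dropped — no Lingoes/Cailliez correction.

**NMDS** minimizes Kruskal stress-1 by SMACOF majorization with isotonic
(pool-adjacent-violators) disparities, normalized each iteration so
`Σ d̂² = Σ d²`.  Defaults: k = 2, 20 starts (the first seeded from PCoA,
the rest random), 500 iterations, tolerance 1e-7.  Only the rank order of
the input enters, so the stress is invariant under strictly monotone
transforms of the distances; the per-run stress trace is monotone by
construction (an iteration that would increase stress terminates the run).
The final configuration is rotated to its principal axes.

**Procrustes/PROTEST**: both configurations centered and scaled to unit sum
of squares, optimal rotation from the SVD of X'Y, `m² = 1 − (Σσ)²`,
`correlation = √(1 − m²)`; the permutation test permutes rows of the second
configuration.

**Mantel**: Pearson correlation of the off-diagonal entries, one-sided
permutation test over sample relabelings, with an exact mode that
enumerates all n! relabelings for small n.

**CAP** (distance-based redundancy analysis): the distance matrix is
embedded by PCoA keeping positive-eigenvalue axes; the axes are regressed
on the centered, unit-variance constraints; constrained inertia is the sum
of squares of the fitted values, and significance comes from permuting
constraint rows under the ANOVA-like statistic
`pseudo-F = (constrained/q) / (residual/(n−q−1))` with q the constraint
rank.  Collinear or constant constraint columns are dropped with a warning.
Constraints may be fitted jointly (default) or one at a time.

All permutation p-values use `(count ≥ observed + 1)/(n_perm + 1)`, so the
smallest attainable p is `1/(n_perm+1)` and the observed statistic is a
member of its own null.  Calibration (uniform null p-values; type-I error
at the nominal level) is asserted by simulation in the acceptance suite.

## Temporal dynamics

**Core detection**: a taxon is present at a time point when its counts
summed over that time point's technical replicates are positive (a strict
all-replicates mode is exposed); the core is the set of taxa present at
every time point.  Raising the occupancy threshold can only shrink the
core.  Shared cores across primer regions are matched at the taxonomic rank
of order; taxa unclassified at order are grouped as
`unclassified_<deepest classified parent>`.

**Moving window**: for each consecutive month pair, the mean and SEM of the
distances over all replicate pairings (4 values with two replicates); a
single pairing reports SEM 0 with a flag.

**Similarity decay**: within each replicate track, all sample pairs at lag
≥ 1 month contribute `log10(1 − D)` regressed on lag by OLS.  Pairs with
similarity ≤ 0 are excluded (counted), not floored.  Region slopes are
compared with the pooled-variance two-sample t (df = n_A + n_B − 2); with
two replicates per region this is a df = 2 test, deliberately conservative
in power but — as the acceptance simulations show — slightly
anticonservative in level when the slope noise is non-normal (attained
level ≈ 6.5% rather than 5%).

**Taxa–time relationship**: whole-series singletons removed per replicate
track, cumulative distinct taxa S(t) accumulated over months (optionally
after aggregation to genus, with parent-labeled pseudo-genera for
unclassified reads), then OLS of log10 S on log10 t gives `S = c t^w`; `w`
is the replacement rate.  `w` is invariant to taxon relabeling and to
scaling all counts.

## The synthetic community generator

The generator emulates a year of monthly activated-sludge samples sequenced
with two primer pairs, two technical replicates each, at 2125 reads per
sample.  Its central design commitment: **both regions observe the same
latent community; they differ only by a strictly positive multiplicative
per-taxon bias followed by independent technical noise.**  Presence/absence
is therefore provably identical between regions before read sampling, and
any bias effect on dynamics summaries is measurable against the latent
truth.

Latent dynamics per taxon are an AR(1) walk on log abundance around a
lognormal base level — the simplest stationary autocorrelated positive
process, a stand-in with stated parameters rather than an inferred model.
Three community-wide structures are superimposed:

- a **seasonal temperature sinusoid** (mean 22 °C, amplitude 5 °C, warmest
  at month 9, so winter dips below 18 °C and summer exceeds 26 °C) that
  drives composition in two ways: per-taxon log-linear temperature
  responses (`temp_effect`, s.d. 1.2 log units per standardized degree),
  and seasonal modulation of the AR innovation s.d. (`season_effect` 1.3:
  warm months reshuffle the community more than cold ones).  Both are
  shared across taxa in profile, which is what lets month-to-month change
  patterns survive arbitrary per-taxon reweighting;
- **transient taxa** (default 80, against 20 core taxa) occupying random
  contiguous sub-windows of the year, exactly zero outside them; the
  transient block is rescaled once so the core holds 66% of abundance on
  average;
- a **bloom taxon**: a core taxon pinned at a 0.1% baseline with Gaussian
  log-bumps at months 2 and 11 whose amplitudes are solved so its true
  relative abundance peaks at 0.5%.  Its amplification bias is fixed at
  ×12 in one region and ×1 in the other, so the regions disagree about it
  roughly tenfold while agreeing about everything dynamic.

Bias vectors are i.i.d. lognormal (σ = 0.2) per taxon, drawn independently
per region, with the bloom factor assigned exactly.  This mirrors the
empirical picture of primer bias: most taxa moderately misrepresented,
a few drastically.  The magnitudes matter jointly: simulations during
design showed that a bloom reaching tens of percent of biased reads, or
heavy-tailed bias across all taxa, dominates one region's distance
structure and destroys the moving-window and decay agreement that real
paired-primer surveys report — so the defaults keep the biased bloom peak
near 5% of reads.

Technical replicates are independent multinomial draws from the same
biased column **after a per-replicate lognormal jitter** (σ = 0.4 log
units) emulating the compositional drift of separate PCR reactions.  Pure
multinomial replicates would be nearly identical at depth 2125, giving the
df = 2 slope test a within-group variance orders of magnitude below any
systematic effect; PCR jitter restores a realistic technical noise floor.
Jitter never creates or removes presence.

FISH fields of view are unions of random disks (DAPI) with probe masks
drawn as random pixel subsets at a target fraction perturbed per FOV;
probe ⊆ DAPI by construction.  The biovolume estimate is the per-FOV
probe/DAPI pixel-ratio mean, with pooled-pixel and probe∧DAPI intersection
modes exposed as options.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing error, chimeras, read-length and
copy-number variation, OTU-clustering artifacts, non-stationary community
shifts (upsets, bulking episodes beyond the single bloom), covariance
between operational covariates and community state other than temperature,
and any taxonomic realism (taxon labels are arbitrary).  The bias model is
multiplicative and time-invariant; template-specific PCR interactions that
vary with community context are out of scope.

## Numerical and procedural choices

- Distance matrices are computed after a single seed-controlled subsample
  per sample when a depth is given (subsample first, then distances).
- All stochastic operations take an explicit integer seed; one generator is
  threaded through multi-sample operations so per-sample draws are
  independent but reproducible.
- The two-region report matches samples across regions by
  (time point, replicate) before Mantel and Procrustes.
- Degenerate inputs are first-class: zero-variance paired tests report
  p = 1 (identical) or a flagged p = 0 (exact shift); single-pairing moving
  windows flag SEM 0; empty-DAPI FOVs are excluded and counted; constant
  constraint columns raise.
- The negative control for the bias-robustness property uses exchangeable
  months (no autocorrelation, seasonality, occupancy windows, or bloom).
  This is deliberate: two *independent* autocorrelated seasonal series
  still share lag structure — close months resemble each other in both —
  and a Mantel test legitimately detects that shared structure (r ≈ 0.6–0.9
  in simulations).  Only with exchangeable months does "independent
  communities" imply "uncorrelated distance matrices", which is the
  method-level artifact the control is meant to exclude.

## Problem sizes

The test and acceptance simulations run the full study design (12 months ×
2 regions × 2 replicates at depth 2125, 100 taxa) for 50-seed panels, with
FISH masks at 128 × 128 pixels and 30 FOVs per sample; permutation tests
use 199–999 permutations.  These sizes were chosen so the complete suite
exercises every pipeline stage end to end in well under an hour on one core
while keeping Monte-Carlo error far inside the asserted tolerances.

## Known limitations

- Weighted UniFrac is only emitted normalized by default; the raw variant
  is available per pair but not as a matrix metric label.
- CAP drops negative eigenvalues rather than applying a correction, so on
  strongly non-Euclidean matrices the constrained-inertia proportion refers
  to the positive-inertia subspace only.
- NMDS ties in the input distances are broken by stable sort order rather
  than primary/secondary tie treatment.
- The df = 2 slope comparison inherits the attained-level inflation noted
  above; with more replicates per region this vanishes.
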