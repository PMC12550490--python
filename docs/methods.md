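# Methods

`paleoterrapin` joins three strands of evidence about how Pleistocene
climate cycles shaped terrapin and tortoise populations: demographic
history inferred from single diploid genomes, habitat availability
reconstructed from occurrence records and paleoclimate grids, and
comparative statistics that relate the two to conservation status on a
species phylogeny. Every stage runs on synthetic inputs with known ground
truth, so the whole pipeline is testable offline; loaders accept
user-supplied files in the same formats.

## Coalescent HMM for effective population size

The two alleles of a diploid individual coalesce at a time (TMRCA) that
varies along the genome because of recombination. The genome is reduced to
100-bp bins coded heterozygous / homozygous / missing (the psmcfa-style
track, alphabet `K`/`T`/`N`), and the TMRCA is modelled as a hidden Markov
chain over discretized time intervals.

**Time discretization.** Time in units of 2·N₀ generations is cut into 64
atomic intervals with log-spaced edges t_k = 0.1·(exp((k/n)·ln(1+10·t_max)) − 1),
t_max = 15 by default; the last interval is unbounded. A pattern string
such as `2+2+25*2+4+6` ties atomic intervals into free intervals that share
one coalescence-rate parameter λ (token `m*a` means m free intervals of a
atomic each; that default pattern yields 29 free parameters over 64 atoms).

**Emission.** In state k with conditional-mean height t_k*, a bin is
heterozygous with probability 1 − exp(−θ·t_k*), θ = 4·N₀·μ·bin. Missing
bins are uninformative.

**Transition (SMC').** With probability exp(−ρ·t) no recombination occurs
within a bin and the state persists (ρ = 4·N₀·r·bin). Otherwise the
recombination point is uniform on (0, t); below the old TMRCA the floating
lineage re-coalesces at rate 2λ(v) (two target branches), returning to the
old height half the time (back-coalescence), and above it at rate λ(v).
The per-interval integrals are closed-form in the piecewise-constant rates;
the average over the recombination height uses 16-point Gauss–Legendre
quadrature. Rows are renormalized against residual quadrature error
(relative size ~1e-12 for smooth rate profiles).

**Fitting.** Exact E-step by scaled forward–backward (numba-compiled
kernels with a numpy fallback); generalized M-step that ascends the EM
Q-function in log-parameters with a bounded quasi-Newton step, split into a
(θ, ρ) block and a λ block, accepting only improvements — so the observed
log-likelihood is non-decreasing by construction. Because EM is very slow
in ρ (posterior paths under a sticky chain contain few recombination
jumps), the fit also performs a coarse direct line search of the observed
likelihood over ρ at initialization and every fifth iteration, again
accepting only improvements. Defaults: 25 EM iterations, relative-change
stop at 1e-6, initial θ from the heterozygous-bin fraction and ρ = θ/5.
A track with no heterozygous bins is flagged degenerate and returned
unchanged rather than fitted.

**Outputs and scaling.** The fitted λ_k give stepwise Ne_k = N₀/λ_k with
N₀ = θ/(4·μ·bin). Generation time is g = age at maturity + half the
reproductive longevity; the per-generation mutation rate comes from a
pairwise genomic distance d and divergence time T as μ = d·g/(2T). Times
scale to years by 2·N₀·g. Uncertainty comes from a block bootstrap
(5-Mb segments resampled to the original length and refitted, 30 replicates
by default); each replicate carries its own θ so scaling and resampling
commute. Trajectory summaries: min–max normalization to [0, 1] on a common
log-time grid inside a 10 kya – 10 Mya window, averaged per group
(all / habitat / climate zone); mean Ne for comparative work excludes the
four most recent steps, which carry few coalescent events.

**Problem sizes.** Parameter-recovery checks run on 10-Mb simulated
genomes: with ~100k bins and 29 free rates, the central intervals of the
coalescent mass (left edges in [0.4, 2.5] coalescent units, roughly the
25th–90th TMRCA percentiles) are where the data are informative; the outer
intervals see few segments and fluctuate freely, as with any
single-genome coalescent HMM.

## Synthetic data generators

*Genomes.* A sequential coalescent simulator draws the initial TMRCA from
the piecewise-exponential marginal, advances along the sequence with
recombination at rate 2·r·T per bp, and resamples TMRCA at each event with
the same SMC' kernel the HMM assumes (a flag switches to plain SMC, which
never back-coalesces). Heterozygous sites are Poisson-placed at 2·μ·T per
site. The hidden TMRCA segments are returned for oracle tests; a
cross-check against an independent coalescent simulator (msprime) confirms
the mean diversity.

*Climate and occurrences.* Layers are standardized smooth gradients plus
correlated noise on a planar grid (fixed nominal cell size in km, no
geodesic corrections, so area arithmetic is exact in tests). True
suitability is a logistic transform of a stated linear predictor on
baseline-standardized layers; per-period additive shifts move suitability
in a known direction. Occurrences are sampled proportional to suitability
with sub-cell jitter. Fewer than 15 occurrences requires an explicit
override, mirroring the species-exclusion rule.

*Comparative data.* A pure-birth tree with the root split at time zero and
waits rescaled to a fixed depth; traits are multivariate normal with the
Brownian covariance σ²·C (C from shared root-to-MRCA path lengths), plus an
optional additive effect of the at-risk status label.

*Chromosome reads.* Mapped positions are drawn per scaffold with weight
proportional to length, multiplied by a stated enrichment factor on the
true scaffold; an infinite factor removes the background entirely.

*Demo world.* `pipeline.run_demo` fixes the demo conditions once: six
species whose true Ne histories have two epochs with the change point at
14k generations — between the MIS19 (~787 kya) and LIG (~130 kya) ages at
the demo calibration — alternating decline/expansion toward the present,
and per-species climate shifts whose sign alternates with the same parity,
so both the Ne and area trend codes have known truth and a known (strong)
association. Genomes default to 1 Mb so the whole world runs in minutes.

What the generators do **not** emulate: sequencing error and genotyping
uncertainty, reference bias, non-equilibrium spatial structure in
occurrences (sampling bias, spatial clustering beyond the suitability
surface), trait evolution models beyond Brownian motion, and chimeric or
collapsed assembly regions. Passing tests therefore demonstrate the
correctness of the algorithms under their own model assumptions, not
robustness to those real-data artefacts.

## Niche models and suitable area

Occurrences are thinned to a minimum great-circle separation of 4.5 km by
randomized greedy selection (20 restarts, best retained set; exhaustive
search confirms optimality on small instances). Rasters are cropped to the
occurrence bounding box plus a 10° buffer. Collinear layers are reduced by
PCA on standardized cell values, keeping the leading components that
explain >90% of variance (capped at 6; constant layers are dropped).

The presence–background model is the Gibbs/maxnet formulation: a penalized
binomial likelihood of presences against background points on linear,
quadratic and pairwise-product expansions of the PC scores, standardized
over the background. The L1 penalty per feature is
multiplier · w_class · √n_presences (class weights default to 1; the
intercept is unpenalized), solved exactly via the positive/negative
coefficient split with bounded L-BFGS. An infinite multiplier shrinks all
coefficients to zero; at the default grid the candidate set is the 7
non-empty feature-class subsets × multipliers {1, 2, 5}. (The documented
protocol speaks of "nine combinations" of three feature classes, which
cannot be enumerated as exactly nine non-empty subsets; the grid is
configurable and its size is reported rather than guessed.)

Candidates are evaluated by random k-fold (k = 4) cross-validation —
refit on training presences, test-presence-vs-background AUC — and
selected by lowest AICc (K = nonzero coefficients, likelihood = product of
background-normalized raw suitabilities at presences) among models with
mean test AUC > 0.7; ties break to fewer coefficients, then the lower
multiplier. No passing model yields an explicit "no valid model" result.
Suitability output is cloglog by default (logistic by flag). Projection
applies the present-day PCA loadings to each period's stack; suitable area
is the count of cells at or above 0.36 times the cell area, ice-masked
cells excluded, normalized by the maximum across periods for display.
Residual spatial autocorrelation is checked by Moran's I in 21 distance
bands between 0 and 10 km with permutation p-values (999 permutations) on
presence-minus-predicted residuals at occurrence cells — the residual
definition is an assumption, flagged as such.

## Trend coding and association

For the period pairs MIS19→LIG and LIG→LGM, the change in a quantity is
coded from the sign of (earlier − later): negative → increasing, positive →
decreasing, zero → stable. Codes are cross-tabulated and tested by
Pearson's chi-squared; for 2×2 tables the Yates-corrected statistic is the
default report and the uncorrected one is always emitted beside it (the
identity χ²_uncorrected = n·Φ² is test-enforced). The Phi coefficient
(ad − bc)/√((a+b)(c+d)(a+c)(b+d)) requires binary codes, so species with a
stable code are excluded from Phi tables only. Global-temperature codes do
not vary between species within a period pair, so the temperature-vs-Ne
table pools the species-by-period-pair rows.

## Comparative regression

PGLS uses the Brownian covariance C (shared root-to-MRCA path lengths) as
the GLS weight matrix; estimation is exact GLS (statsmodels) with σ²
estimated from the GLS residual mean square — no Pagel's λ optimization.
Model 1 regresses H on status and current area, and mean Ne (four most
recent steps excluded) on status and mean past area; model 2 repeats
model 1 on at-risk species only; model 3 relates area (current and past
mean, separately) to the binary status — status enters as the predictor
because it is categorical, an interpretation flagged as such. Tukey HSD
contrasts compare GLS-adjusted group means with studentized-range adjusted
p-values; with identity covariance this reproduces the textbook procedure
(cross-checked against an independent implementation).

## Chromosome assignment (PRR)

For each micro-dissected chromosome sample, a scaffold's position
representation ratio is (positions on scaffold / positions in genome)
divided by (scaffold length / genome length); since PRR is lognormal the
threshold applies to its log. Enrichment calls require logPRR > 0, a
one-sided (greater) exact binomial p ≤ 0.01 — one-sided because only
enrichment is thresholded — and at least 2 supporting positions (a distance
filter on the mean pairwise spacing is available but off by default, since
the role of the spacing in the original decision rule is not specified).

## Numerical choices and degenerate inputs

- DOC filter boundaries are inclusive (depth exactly mean/3 or 2·mean is
  kept); a bin is missing when >90% of its sites are uncalled.
- Heterozygosity divides by total genome size by default (callable-site
  denominator by flag).
- Min–max normalization of a constant trajectory returns 0.5 with a
  warning; a zero-marginal 2×2 table yields Phi = NaN; a Moran band with
  fewer than one pair reports NaN.
- All generators and fits take explicit integer seeds; the pipeline fans a
  single global seed out to stages by stable SHA-256 hashing, so a fixed
  seed reproduces every report byte-for-byte.

## Known limitations

- The HMM's representative-time approximation makes the discrete kernel's
  stationary distribution deviate slightly (sub-percent at realistic ρ in
  central intervals) from the coalescent prior; at single-digit-Mb data
  sizes the dominant error is ridge-shaped sampling noise across adjacent
  intervals, visible as smooth wiggles around the truth.
- ρ is identifiable but weakly so at these sizes; its estimate is typically
  within ~30% of truth and the Ne trajectory is robust to that residual.
- Suitable-area arithmetic is planar; real-world use at continental scales
  would need geodesic cell areas.
- The Maxent regularization defaults are a simplification of the reference
  implementation's feature-class-specific schedules.
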