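# Methods

## Scope and model overview

`sealmove` quantifies the ecological and genetic separation of two sibling
seal species from satellite telemetry and multilocus genotypes. The pipeline
has five analytical stages (filtering, space use, movement, dive behavior,
assignment) plus a synthetic-data module that generates inputs with the
statistical structure each stage assumes, so the whole pipeline is testable
without field data.

## SDA filter

The speed–distance–angle filter removes implausible Argos fixes by three
rules: (1) class-Z fixes (no usable position) are removed first; (2) a fix
whose implied swim speed from the previous retained fix exceeds 2.5 m/s is
removed unless it lies within 5 km of that fix — fixes recorded in quick
succession legitimately imply high nominal speeds; (3) a fix is removed when
the turning angle at it exceeds 165° with an incoming leg > 2.5 km, or 155°
with a leg > 5 km — long, nearly perfect out-and-back spikes are positional
error, not swimming.

Design choices the rule statement leaves open:

* **Previous retained vs previous raw fix.** Speeds are computed against the
  previous *retained* fix and removal iterates to a fixpoint (equivalently:
  repeatedly remove the first violating fix of the current sequence).
  Single-pass filtering leaves secondary spikes uncovered by earlier
  removals. The implementation resumes scanning one position back after each
  removal, which is provably identical to a full rescan because a removal
  can only change the status of its immediate predecessor.
* **Simultaneous duplicates** keep the higher-quality class (3 > 2 > 1 > 0 >
  A > B); speed is undefined at Δt = 0.
* **Track ends.** The first fix is exempt from the speed rule and both ends
  from the angle rule (no angle is defined there).
* **Haul-out fixes** are filtered like any other fix; the flag is metadata.

A detail worth recording: with the dive-focus-style dominance rules below,
the angle thresholds of 165°/155° mean a genuine trip apex sampled by exactly
one fix can be discarded; this is a known cost of SDA filtering, visible in
the synthetic outlier-recovery study as a few percent of clean fixes removed.

## Brownian-bridge utilization distributions

All bridge math is planar, in a local azimuthal-equidistant projection
centered on the track centroid (exact radial great-circle distances; study
areas span only a few degrees, so angular distortion is negligible at the
1-km grid scale). The position at bridge fraction α between fixes z₁ (time
t₁) and z₂ (time t₂) is bivariate normal with mean (1−α)z₁ + αz₂ and
variance

    σ²(α) = T·α(1−α)·sig1² + (1−α)²·sig2₁² + α²·sig2₂²,  T = t₂ − t₁,

where `sig1` (km/√hr) scales motion variance and `sig2` is the per-fix
location-error SD (km) by Argos class: 3 = 0.5, 2 = 1, 1 = 1.2, 0 = 4.2,
A = 6.2, B = 10.3 (68th-percentile errors from GPS double-tagging
calibration). A step's UD contribution is the α-average of that density
(midpoint quadrature, 25 points by default; the quadrature-convergence test
shows halving the step changes the UD by < 10⁻³ total variation), weighted by
T, and the summed surface is normalized to unit mass. Cell masses are exact
per-cell bivariate-normal integrals (products of 1-D CDF differences), not
center-point approximations.

`sig1` is estimated by the leave-one-out maximum-likelihood scheme standard
for this estimator: every odd-indexed fix is scored under the bridge formed
by its two neighbors at its own time fraction, and the likelihood is
maximized by bounded golden-section search. Recovery on simulated Brownian
tracks (500 fixes, sig2 = 0.01 km) is within 20% of truth.

Further choices: grid cell 1 km with a margin of 3 × max(sig2); steps longer
than 24 hr are excluded (bridges over long gaps are flat and uninformative;
the gap threshold is configurable); monthly UDs partition steps by the
calendar month (UTC) of the step's start fix; species-level UDs pool all
individuals' filtered locations and sum duration-weighted step contributions
within animals. Isopleths take cells in decreasing probability order until
the target mass is reached, ties broken by (probability, row, column); land
is subtracted by exact cell-polygon intersection of shapely geometries
projected into the grid plane. The 90%/50% area ratio for a Gaussian UD
matches the χ²₂ quantile ratio ln(0.10)/ln(0.50) ≈ 3.32, a closed-form check
of the isopleth machinery.

## Distance from haul-out

At-sea bouts are maximal runs of non-hauled-out fixes anchored at the last
preceding haul-out fix (the haul-out flag comes from the tag's wet/dry
sensor equivalent; no positional inference is attempted). Distances are
great-circle, not planar — movements exceeding 1,500 km occur in this
system. A leading at-sea run with no prior haul-out has no anchor and is
dropped with a warning.

## Dive statistics

Tags report dives in 10 depth and 10 duration bins per 6-hr interval;
per-dive values are unobserved, so bin midpoints stand in for the
unobservable within-bin medians (the standard treatment of binned SDR data).
Mean depth/duration is the count-weighted midpoint mean; the maximum is the
upper edge of the last non-empty bin; the dive focus is

    focus = Σᵢ nᵢ(nᵢ−1) / [N(N−1)],

the probability that two dives drawn without replacement share a bin, with
the finite-sample correction making it usable at small N (undefined for
N < 2, and empty intervals propagate as missing, never zero). The focal
depth is the dominant bin's midpoint, defined only when focus > 0.50. Two
tied dominant bins give focus (m−1)/(2m−1) < 0.5, so a tie can never define
a focal depth; the shallower-bin tie-break in the code is purely defensive.
Time-at-depth proportion histograms are parsed but excluded from the focus
statistic, which is defined on dive counts.

## Mixed models and AICc model averaging

Each derived response is analyzed with a deterministic candidate set of
linear mixed models with a random intercept per animal, fitted by ML (not
REML — likelihoods must be comparable across fixed-effect structures):

* UD areas (log): null + singles {species, month, sex, mass} + all additive
  combinations + the species×month interaction wherever both mains are
  present — 20 models; independent residuals (one area per animal-month).
* Haul-out distances (log): null + singles + 2- and 3-term additive models —
  15 models; discrete AR(1) residual correlation within animal.
* Dive metrics (dive focus on the logit scale, with boundary clip
  p ∈ [1/(4N), 1−1/(4N)] because exact 0/1 focus values occur): the 20-model
  set; continuous-time AR(1) correlation ρ^|Δt| to handle unequal 6-hr
  interval spacing.

Month is categorical with September as the reference level; mass is centered.
The mixed-model likelihood is computed analytically: both AR(1) variants are
Gauss-Markov along the within-animal ordering, so R⁻¹ is tridiagonal in
closed form, and the random intercept enters by a rank-one Woodbury update —
every likelihood evaluation is O(n) per animal, and β plus the residual scale
are profiled out, leaving a 1–2 parameter Nelder-Mead search (three starts).
The no-correlation path reproduces statsmodels MixedLM ML fits to ~1e-4; the
analytic likelihood pieces are verified against dense linear algebra in the
tests.

Models are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed
effects plus variance/correlation parameters; Akaike weights
exp(−Δᵢ/2)/Σexp(−Δⱼ/2). Averaging uses the smallest weight-ordered prefix
holding ≥ 95% of the weight (renormalized), with natural (conditional)
averaging over the models containing each term and unconditional standard
errors SE̅ = Σ wᵢ√(SEᵢ² + (βᵢ−β̄)²); CIs are normal (±1.96·SE̅) and a CI
excluding zero marks a significant effect. Simulation checks: the averaged
species CI covers a true +0.5 logit effect in ≥ 90% of replicates
(20 animals × 100 intervals) and covers zero at roughly the nominal 95% rate
when no effect exists.

## Genetic assignment

A two-cluster (K = 2 — the biological question is a two-species assignment;
estimating K is out of scope) Gibbs sampler over diploid multilocus
genotypes. Cluster allele frequencies get a uniform Dirichlet prior
(λ = 1). The no-admixture model alternates frequency draws with hard
individual labels; the admixture model assigns each allele copy an origin
and draws individual ancestry q from Dirichlet(α + copy counts). The
ancestry concentration α is, by default, sampled by a Metropolis random walk
under a uniform prior on (0, 10) — with well-separated clusters α collapses
toward 0 and pure individuals reach posterior mean Q > 0.99, whereas a fixed
α = 1 bounds Q at (α+2L)/(2α+2L) (≈ 0.976 at 20 loci) purely by prior mass;
fixing α remains available. Missing genotypes are coded −9 and skipped in
all likelihood terms.

Chains: desk-scale defaults are 5,000 burn-in, 20,000 kept sweeps, 4
independent chains (study-scale settings of 50,000 / 10⁶ / 10 remain
configurable). Label switching is resolved by aligning each chain's
posterior allele frequencies to the first chain by correlation; a
between-run aligned-Q disagreement above 0.1 raises a convergence warning.
Species calls use the max-Q cluster when Q exceeds 0.81 (the reference-panel
threshold for confident assignment), else "ambiguous/admixed" — F1 hybrids
under the admixture model sit near Q ≈ 0.5. mtDNA assignment is
nearest-reference-haplotype by Hamming distance (reciprocal monophyly makes
the species' haplotype sets disjoint; ties are ambiguous), and a
nuclear-vs-mtDNA concordance table flags candidate hybrids or introgression.

## Synthetic data

* **Tracks.** Two-state movement: haul-out bouts (stationary at a site) and
  at-sea bouts alternate with exponential durations (trips/day sets the mean
  cycle; haul-out bouts average 8 hr). The at-sea path is an hourly
  correlated random walk — von Mises turning with persistence 0.8,
  gamma(4)-distributed step lengths (right-skewed but light-tailed, keeping
  hourly swim speeds in a phocid's realistic range) — pinned linearly to
  start and end at haul-out sites. Fix times are a Poisson process
  (8/day default; the filter handles the resulting irregular spacing).
  Positional error is isotropic bivariate normal in the local plane with the
  class-specific SDs above; the class mix defaults to the pre-filter
  composition reconstructed from the study dataset's reported class
  percentages (B ≈ .39, A ≈ .24, 1 ≈ .13, 0 ≈ .10, 2 ≈ .08, 3 ≈ .05, plus a
  nominal 1% Z). Outliers displace a fix by ≥ `outlier_km` in a random
  direction and are never adjacent (gross Argos errors are isolated in
  time). One integer seed drives everything through per-animal substreams.
* **Dive histograms.** Dives per interval are Poisson (25/interval default);
  bins are multinomial with the focal bin carrying weight (1+c)/(10+c) for
  concentration c — c = 0 is exactly uniform, c → ∞ puts all dives in one
  bin, and expected dive focus is monotone in c. Covariate effects shift the
  focal-bin index additively. Bin edges are configurable; no canonical edge
  set exists for these tags, so the defaults (0–250 m, 0–30 min) are merely
  plausible.
* **Genotypes.** Per locus and species, allele frequencies are symmetric
  Dirichlet draws with concentration `divergence` (smaller = spikier = more
  diverged; ∞ = identical uniform frequencies = no assignment information;
  `diagnostic=True` gives the species disjoint allele sets). Pure
  individuals are Hardy-Weinberg draws; F1s take one allele per locus from
  each species; missingness hits both copies of a locus together.

What the generators do **not** emulate: heavy-tailed/asymmetric real Argos
error, bathymetry or foraging structure in movement, behavioral dive-shape
classes, linkage or null alleles in genotypes. Passing tests therefore
demonstrate the *algorithms* are correct under the stated models, not that
the models capture every feature of field data.

## Numerical choices and problem sizes

Grid margin 3·max(sig2); isopleth ties broken deterministically; logit
boundary clip as above; Nelder-Mead with three starts for variance
parameters; golden-section for sig1. The simulation studies run at
desk-scale sizes chosen as the package's own defaults: 100 random tracks for
the filter-oracle study, 10 seeds × 500 fixes for sig1 recovery, 50 and 200
replicates for the CI-coverage studies (20×100 and 10×30 observations), and
full desk-scale MCMC for the headline assignment checks with shorter chains
(1,000/4,000) for the replicate-heavy comparisons.

## Known limitations

No dynamic (behavior-switching) Brownian bridge; no state-space
re-estimation of positions (the filter only removes fixes); no random
slopes, shrinkage averaging only as an option, and no multiple-testing
correction (none is part of this analysis); K > 2, linkage models, and
LOCPRIOR-style sample-group priors are out of scope; tree building and
haplotype networks are external to this package.
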