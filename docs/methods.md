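# Methods

## The promoter-cycle model

A single gene copy is described by an irreversible cycle of one
transcriptionally active state (`on`) and `N` sequential inactive states
(`off_1 … off_N`).  The gene leaves the active state at rate `1/τ_a`,
progresses through the inactive states at escape rates `k_1 … k_N` (the last
being the reactivation rate `k_a`), and transcribes at rate `k_m` only while
active.  mRNA is translated at rate `k_p` per transcript; both mRNA and
protein decay first-order (`γ_m`, `γ_p`).  All times are minutes, all rates
per minute.

The total silent period `T = Σ 1/k_i` is phase-type distributed: exponential
for `N = 1` (the telegraph model) and Gamma(`N`, `T/N`) for equal steps.
A peaked off-time distribution — a refractory period in reactivation — is
therefore the signature of several rate-limiting silent steps.  The on-state
is a single exponential stage; refractory *active* periods are outside the
model (none are expected on the sampling timescale).

Derived quantities: burst size `b = k_m τ_a`; normalized cycle duration
`f = (τ_a + T)/τ_m` with `τ_m = 1/γ_m`; mean mRNA `⟨m⟩ = b/f`.

## Exact trace likelihood

The observed data are uniformly sampled gray-level signals `s_0 … s_K`, one
trace per cell.  The emission model `P_e(s|p)` is Gaussian with mean
`gain·p + background` and variance `a + c·gain·p` (a camera floor plus a
shot-noise-like term); the original microscope calibration is not public, so
these four parameters are explicit inputs of the analysis and of the
synthetic-data generator.  Zero variance denotes a noiseless readout
(indicator emission), used by exactness tests.

The hidden state `(g, m, p)` lives on a finite lattice with copy-number
bounds chosen so the stationary mass beyond them is below a leak tolerance
`ε` (default `1e-4`): means and variances of `m` and `p` are computed from
the model (promoter noise included) and the bounds are `ε/2` upper quantiles
of moment-matched Poisson/negative-binomial laws.  Transitions leaving the
lattice are absorbing, so truncation only removes probability.  The
one-interval propagator is the matrix exponential of the lattice generator —
dense up to 2 000 states, uniformization (truncated Poisson series of sparse
products, nonnegative by construction) above.  The likelihood is the forward
algorithm over this lattice with the quasi-stationary lattice law (obtained
by long propagation of a product-form guess) as the `t = 0` prior and
per-step renormalization accumulated in log space; 576-step traces underflow
otherwise.  Protein is kept on the lattice rather than marginalized
analytically; analyses therefore use regimes with small protein copy
numbers.

## Reversible-jump MCMC

Sampled parameters are `k_m`, `τ_a` and the step durations `τ_1 … τ_N`;
`k_p`, `γ_m`, `γ_p` are measured quantities and stay fixed.  Priors are
log-uniform on every rate over `[1/600, 60] min⁻¹` and uniform on
`N ∈ {1 … N_max}` (default 12).  Moves:

* within-model — multiplicative log-normal update of one randomly chosen
  rate (default log-sd 0.1); combined with the scale-free prior the
  acceptance reduces to the likelihood ratio;
* birth — draw `u ~ U(0, 0.2·T]`, shrink existing steps by `(T−u)/T` and
  insert `u` at a uniform position, leaving `T` unchanged;
* death — remove the shortest step (ties: lowest index) and redistribute its
  duration proportionally.

The Jacobian of the birth rescaling is `((T−u)/T)^{N−1}` (the scale factor
itself depends on the durations through `T`; at `N = 1` the map
`(τ, u) → (u, τ−u)` is volume-preserving).  Exact detailed balance requires
two support restrictions: a birth whose inserted step would not be the
shortest is rejected (the deterministic remove-the-shortest death could not
reverse it), as is a death whose shortest step exceeds `0.2·T`.  With a flat
likelihood the chain reproduces the uniform prior over `N`, and on a
two-model problem with quadrature-computed marginal likelihoods the chain
occupancy matches the exact posterior — both are tests in the suite.

Default move mix 80/10/10 (within/birth/death), burn-in 20% of iterations.
Initialization is a cheap method-of-moments guess (N = 1, `k_m` from the
mean signal level).  Proposals whose truncated lattice would exceed a
configurable cap are treated as numerically infeasible (−∞), a hard bound on
the sampled region that the data never favor in practice.

## Trajectory deconvolution

Hidden paths conditioned on a trace are drawn exactly by forward filtering /
backward sampling with the *same* propagator object as the likelihood, so
filter and smoother cannot disagree (asserted in tests).  Paths live on the
observation grid: durations are multiples of `Δt`, and an active period
shorter than `Δt` that falls between samples is invisible, merging its two
flanking silent intervals.  The merge probability for exponential on-times
is `1 − (1 − e^{−Δt/τ_a})·τ_a/Δt` (≈ 26% at `τ_a = 8 min`, `Δt = 5 min`),
inflating mean silent durations accordingly — interval statistics therefore
carry an explicit resolution caveat, and calibration tests use regimes with
`τ_a ≫ Δt`.  Intervals touching trace boundaries are censored and excluded,
standard renewal practice.

## Noise decomposition

Population mRNA noise splits by the law of total variance over cells:
intrinsic variance = mean within-cell variance, extrinsic variance =
variance of per-cell means, both normalized by the squared pooled mean.
Confidence bands are percentile bootstrap over cells (1 000 replicates);
"parametric bootstrap" in the sense of resampling cells, the labeled choice
where the alternative (resampling parameters) was also defensible.

Model-based intrinsic noise is `η² = η_p² + η_c²` with the Poisson floor
`η_p² = 1/⟨m⟩` and the promoter term `η_c² = f·C`.  The coefficient `C` is
evaluated exactly from the stationary autocovariance of the on-indicator
filtered by mRNA turnover; integrating the filtered autocovariance gives the
resolvent form

    η_c² = ( γ_m [(γ_m I − Q)⁻¹]_{on,on} − π_on ) / π_on ,

with `Q` the promoter generator and `π_on = τ_a/(τ_a+T)`.  This form is
exact for arbitrary, including repeated, step rates; it is cross-validated
three ways: against long stochastic simulations (3-SE agreement), against
the equal-step bursting law `C(N) = (1 + 1/N)/2` (the `(1+η_T²)/2` link to
Gamma cycle-duration noise `η_T² = 1/N`), and against the constitutive limit
`C → 0` for `τ_a ≫ T`.  In the bursting regime `η_c²` is confined to
`[f/2, f]`, so promoter noise exceeds Poisson noise whenever `b > 2`;
partitioning the silent period into more equal steps reduces the promoter
term by at most a factor of two, and asymmetric partitions are suboptimal.

## UMI noise analysis

Counting `n ~ Binomial(m, q)` with a cell-specific recovery rate `q`
(mean `⟨q⟩`, CV² `ε_q²`) independent of the biological copy number `m` gives,
by exact moment algebra,

    η_n² = (1 − ⟨q⟩(1+ε_q²))/⟨n⟩ + ε_q² + (1+ε_q²)·η_m² ,

where `η_m²` is the total biological noise; because the biological Poisson
part is `⟨q⟩/⟨n⟩`, it merges with the sampling term into a pure `1/⟨n⟩`
decay, producing the characteristic two-regime curve (Poisson-like decay at
low counts, plateau at high counts).  Split controls obey
`η_n² = 1/⟨n⟩ + ε_q²` (re-splitting a large pool: same algebra with the
split fraction in place of `q` and negligible pool noise).  Inverting the
cells relation per gene yields the sampling-corrected biological noise;
negative corrections are clipped at zero and flagged, never dropped.  Genes
are analyzed in 8 log-spaced expression bins over mean counts 0.1–1000
(genes below 0.1 excluded); gene-level bands resample cells (500
replicates), class differences resample genes within bins.

For a gene with two independent alleles the promoter term halves while
extrinsic noise does not, so the corrected-noise difference between a
single-step class (TATA-like, `C ≈ 1`) and a many-step class (`C ≈ 1/2`) at
matched `f` and `b` is `f·(C₁ − C_N)/2 ≈ f/4`.  The synthetic generator
reproduces this quantitatively (driver `analysis/05_umi_noise.py`: predicted
0.027, measured 0.027 at `f = 0.163`).

Recovery parameters are inputs (from external calibration or the generator),
not estimated; spike-in estimation is out of scope.

## Synthetic-data generator

The trace generator emulates the time-lapse experiments: cohorts of 56 cells
(the middle of the 48–64 range used experimentally) recorded for 48 h at
5-min sampling, simulated exactly (Gillespie), started from the stationary
promoter law with a burn-in of `5·max(τ_m, 1/γ_p)`, and read out through the
Gaussian emission model.  Static cell-to-cell heterogeneity is log-normal
per parameter (mean-preserving), the mechanism generating extrinsic noise.
One cohort seed deterministically spawns per-cell simulation and emission
streams.  Not emulated: cell division and lineage (recordings are in
non-dividing confluent cells), imaging artifacts (drift, segmentation), and
temporal parameter drift within a cell — so passing tests validate the
inference and noise machinery under static heterogeneity, not robustness to
those real-data effects.  The UMI generator thins exact two-allele
stationary counts (or parametric surrogates) with log-normal cell-specific
recovery (⟨q⟩ = 0.1, ε_q² = 0.04) and builds split controls by pooling and
binomial re-splitting.

## Problem sizes and numerical choices

Analyses and tests run at deliberately small scale so every result is
recomputable on a laptop: inference demonstrations use cohorts of 12–16
cells × 24 h in low-copy-number regimes (a few hundred to ~2 000 lattice
states, `ε = 2×10⁻³`) with ~10³ RJ-MCMC iterations, and a fast protein
readout (`k_p = γ_p = 1`) so the signal closely tracks the mRNA layer.  At
this scale the posterior over `N` brackets the truth and burst size and `T`
are recovered well, but posterior means of strongly anti-correlated pairs
(`k_m`, `τ_a`) can sit several percent from the truth simply because the
posterior is wide; the bias bounds reported for full-scale cohorts (dozens
of cells × 48 h, ~10⁵ iterations) should not be expected from these short
runs.  Tie-breaks: the shortest-step rule removes the lowest index on exact
ties.  Degenerate inputs: `k_m = 0` collapses the lattice to zero copies and
makes intrinsic noise undefined (an error, not NaN); chains with no accepted
moves are flagged, not silently summarized.

## Known limitations

* Interval statistics are grid-quantized; sub-`Δt` active periods are
  unobservable (see deconvolution section).
* The emission model is a configurable stand-in for a microscope
  calibration; only self-consistency is validated.
* Hierarchical (per-cell) kinetic parameters, non-uniform sampling,
  reversible or branched promoter schemes, and protein-level noise
  propagation are out of scope.
* The likelihood's truncation leak (~`ε` per step, stationary-weighted) is a
  shared, slightly conservative bias across compared models, not an exact
  marginalization.
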