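# Methods

## Model

Haploid chromosome number is modelled as a continuous-time Markov chain on
the integer states `[n_min, n_max]` with `n_min = 1` (a haploid count cannot
be zero). Four state-independent rates parameterise the generator: gain
(n → n+1), loss (n → n−1), polyploidy (n → 2n) and demiploidy (n → 1.5n).
Demiploidy from an odd count has no integer target, so the rate is split
half/half between ⌊1.5n⌋ and ⌈1.5n⌉ — the rounding convention of the
ChromEvol model family. Rates are constants (no linear-in-n terms, no
binary-state co-evolution, no base-number parameter); those extensions are
deliberately out of scope.

**State space.** `n_max = ceil(padding_factor × max observed count)` with a
default padding factor of 2, so one round of whole-genome duplication from
the largest observed count stays inside the space. Saltational targets beyond
`n_max` are truncated onto `n_max` rather than dropped: dropping mass would
make generator rows sum below zero and bias every likelihood. A target that
coincides with its source (possible only at the boundary) is a null event.
The padding factor is exposed; doubling it changes log-likelihoods only
through rarely-visited boundary states, and users fitting clades whose counts
approach the boundary should verify insensitivity.

**Trees and units.** All inference runs on unit-depth trees. Input
chronograms are validated for ultrametricity against the *median* root-to-tip
distance (relative tolerance 1e-3 at read time, since published chronograms
carry rounding error; 1e-6 in synthetic tests), rescaled to depth 1, and the
original age is kept as `depth_myr`. Fitted rates are "events per unit tree
depth" internally and convert to events/Myr by dividing by `depth_myr` at
reporting time only. This keeps optimisation and MCMC well conditioned
regardless of clade age. How a published tree was calibrated is the user's
responsibility; `depth_myr` can be overridden as explicit metadata.
Polytomies are handled natively by the pruning recursion (product over all
children) rather than resolved with zero-length branches.

## Likelihood

Felsenstein pruning with per-node rescaling to max 1 and accumulated log
scalers (underflow control without arbitrary precision). Transition
probabilities for all branches of one tree are computed per *distinct* branch
length — exactly equivalent to per-branch computation — by uniformization:
with Λ = max leaving rate, `A = I + Q/Λ` is stochastic and
`P(t) = Σ_k Pois(k; Λt) A^k`. Every term is non-negative, so there is no
cancellation for skewed generators (where eigendecomposition loses accuracy),
and the series is truncated where the Poisson tail falls below ~1e-13 at the
longest branch. `scipy`'s scaling-and-squaring `expm` is the reference in
tests and the fallback for extreme Λt.

Root treatment is configurable: FitzJohn weighting (default; root prior
proportional to each state's conditional likelihood), uniform, or a fixed
state. The likelihood is the plain CTMC tip likelihood — it does not condition
on survival and is not an SSE-class model; rate estimates therefore ignore
any interaction between chromosome state and diversification.

## Bayesian inference

Metropolis–Hastings with multiplicative log-normal proposals, one parameter
per sweep, log-scale Jacobian in the acceptance ratio. Priors: exponential
with mean 1.0 per free rate by default — weakly informative at the scale
where one unit of branch length spans the clade's age — and uniform(0, 100)
for sensitivity analysis. `n_steps` counts retained draws (default 1,000,
matching a 1,000-step protocol); an additional burn-in of
`burn_in_frac/(1−burn_in_frac)` (default 25% of the total) is discarded.
Proposal scales adapt toward 30–45% acceptance during burn-in only and are
frozen afterward, keeping the retained chain Markovian. A single chain is the
default; effective sample sizes use the initial-positive-sequence estimator
`ESS = N/(1 + 2Σρ_k)`, and any parameter with ESS below 200 flags the run.
Chains rejecting every proposal for 200 consecutive sweeps abort with
diagnostics rather than returning a frozen posterior.

**Dysploidy rate.** Reported per draw as `(gain + loss)/depth_myr`. Summing
the two incremental rates is a definitional choice (the natural "events per
Myr" total for n±1 changes); the mean of the two is available behind
`combine="mean"`.

## Model comparison

Maximum likelihood by L-BFGS-B on log-rates (central-difference gradients;
forward differences stall short of the optimum and can violate the nestedness
inequality at the 1e-6 level), 5 random starts drawn from the prior scale,
fixed seed. The headline contrast is FULL (4 free rates) versus
DYSPLOIDY_ONLY (both saltational rates fixed at 0), classifying support for
polyploidy at ΔAIC > 5. Removing polyploidy and demiploidy together treats
them as one "saltational" block; the finer NO_POLY / NO_DEMI ladder exists
for sensitivity. AIC (not AICc) is the default, with AICc behind a flag for
small clades. Likelihood-ratio χ² tests are deliberately absent: rates fixed
at the boundary of the parameter space break the χ² asymptotics.

## Adequacy

Posterior predictive checks on two tip statistics: sample variance (N−1
denominator) of haploid counts and Shannon entropy (natural log) over the
empirical frequencies of raw, unbinned counts. For each of `n_replicates`
posterior draws (subsampled without replacement), a root state is drawn from
the root policy's distribution *under that draw* — propagating root
uncertainty — and a replicate dataset is simulated by the exact Gillespie
sampler along the tree. The p-value uses the add-one estimator
`(#{rep ≥ obs} + 1)/(n + 1)` (never exactly 0 or above 1); a doubled
two-sided version is reported alongside.

## Cross-clade layer

Variance decomposition operates on log₁₀ rates (rates are multiplicative;
cross-clade summaries are geometric means). One-way ANOVA F with its exact
F-distribution p-value; a one-way random-intercept REML model fitted by 1-D
profile restricted likelihood over the variance ratio θ = σ²_b/σ²_w with the
boundary θ = 0 admitted explicitly, so a zero between-group component is an
honest estimate rather than an optimiser failure (statsmodels' MixedLM serves
as an independent cross-check in the test suite). Significance comes from
permuting group labels freely at the tested level (default 9,999
permutations, add-one p-value); nesting is handled by testing each label
level separately. The decomposition consumes per-clade posterior *medians*;
posterior uncertainty is not propagated into the ANOVA/REML layer (a known
simplification, shared with point-estimate comparative practice).

PGLS assumes plain Brownian covariance, `V_ij` = root-to-MRCA shared path
length (no Pagel's λ); slope tested two-sided on n−2 df. On a star phylogeny
this reduces exactly to OLS. Genome size is log₁₀-transformed by default
before regression, like the rates.

## Synthetic data

The generators define the study conditions with known ground truth:

- **Trees**: pure-birth (Yule) trees grown to `n_tips` then rescaled to unit
  depth; the birth rate cancels under rescaling. Ultrametric by construction.
- **Counts**: exact Gillespie simulation branch by branch using the *same*
  generator matrix as the likelihood (identical boundary truncation), so
  simulator and propagator are coherent by construction; a full event log is
  returned, and replaying it reproduces the tip states. One RNG stream per
  branch is derived from the seed and a stable branch key (smallest tip label
  below the branch plus subtree size — unique per branch within a tree), so
  pruning one tip does not shift the randomness of unrelated branches.
- **Clade rate tables**: two-level group structure with log₁₀-normal group
  means (spread `sd_between`) and within-group spread `sd_within`; the true
  ICC `sd_b²/(sd_b²+sd_w²)` is returned with the table. The default grand
  mean (−1.64, i.e. ≈0.023 events/Myr) and within-group spread 0.5–0.7 reflect
  realistic cross-clade rate magnitudes and give fold ranges spanning two to
  three orders of magnitude over ~55 clades.
- **Covariates**: Brownian motion along the tree, root value 0.

What the generators do *not* emulate: sampling biases of real karyotype
databases, measurement error and intraspecific polymorphism in counts,
chronogram calibration error, diversification–trait interactions, and
heterogeneity of rates across a tree. Passing tests therefore establish
internal statistical correctness (calibration, coverage, recovery under the
model), not robustness to violations of the model on empirical data.

## Test and experiment sizes

Statistical acceptance checks run at these sizes, chosen to make the checks
sharp at desk scale: likelihood oracle on 50 random instances (≤5 tips, ≤6
states); simulator/propagator coherence on 10,000 single-branch replicates ×
5 rate sets (total-variation tolerance 0.03); posterior coverage on 50
datasets of 150-tip trees with gain = loss = 0.4 and 1,000 retained draws
(≥38/50 nominal-90% coverage, median-of-medians within 20%); prior
concordance on one 300-tip clade (25%); ΔAIC calibration on 30 + 30 datasets
of 150-tip trees (specificity ≤20%, sensitivity ≥60%); PPC calibration on 25
runs of 80-tip clades with 400 retained draws and 200 replicates (≥80% of
p-values inside (0.05, 0.95)); permutation type-I error on 500 null tables
(3 groups × 18, 999 permutations, rejection rate in [0.03, 0.07]); REML ICC
recovery at true ICC ∈ {0, 0.3, 0.7} (20 groups × 8, 100 tables, within
0.07); PGLS slope recovery of 0.871 over 100 simulations on a 60-tip tree
(within 0.1). Unit conversion (0.5 per unit tree over 50 Myr → 0.01
events/Myr) is exact.

## Numerical choices and edge cases

- Tie in the AIC contrast → the reduced (fewer-parameter) model is reported
  best.
- Non-integer haploid counts are rejected, never rounded (a strict-parsing
  flag downgrades to drop-with-warning); silent rounding would fabricate
  states.
- Impossible data (zero likelihood under a parameter draw) returns −∞ rather
  than raising inside optimisers/samplers; the PPC falls back to a uniform
  root draw for such draws.
- Constant MCMC traces report ESS = 1 with a degenerate-trace warning; zero
  within-group variance reports F = +∞ with a warning.
- ML fits start from e^x with x bounded in [−21, 5]; e^−21 is numerically
  zero relative to total tree length, so reduced-model optima are reachable
  by the full model within 1e-6 log-likelihood.

## Known limitations

No ancestral-state reconstruction, no state-dependent diversification, no
rate variation across branches, no tree inference or calibration. MCMC is a
single chain (multi-chain R-hat is not built in). The cross-clade layer
treats per-clade rates as known; a meta-analytic weighting of posterior
uncertainty would be the natural extension.
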