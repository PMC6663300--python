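# Methods

## The inference problem

Given simultaneous recordings of N processes (T samples, optionally R
replications), the goal is a minimal directed network in which a link
X → Y means that the past of X carries information about the present of Y
beyond what Y's own past and the other selected sources already provide.
The quantity that formalizes "beyond" is multivariate (conditional)
transfer entropy: the conditional mutual information
I(X_past; Y_t | Y_past, other selected source pasts). Conditioning on the
target's own past separates information *storage* from information
*transfer*; conditioning on other sources suppresses common-driver and
pathway effects and can expose synergies.

## Embedding and the greedy search

Candidate variables are (process, lag) pairs with lags 1..l_target for
the target's own past and 1..l_sources for every other process (defaults
l_target = l_sources = 5). Searching over all subsets is infeasible, so a
greedy search adds one variable at a time, always the one with the
largest estimated CMI contribution, and stops when that contribution is
no longer statistically significant. Per target:

1. **Target past.** Greedy selection over the target's own lags
   (maximizing active information storage / self-prediction).
2. **Source past.** Greedy selection over all source lags, conditioning
   on the step-1 set and on sources selected so far. The first accepted
   source contribution is exactly a bivariate transfer entropy.
3. **Pruning.** Variables accepted early may become redundant once later
   variables joined; each is re-tested in the context of the final set
   and the weakest is dropped while non-significant.
4. **Omnibus.** The collective transfer entropy
   T* = I(all selected sources; Y_t | target past) is tested once; the
   source set is accepted only if this final test passes.

All embedded variables share the same realization rows: the first
max(l_target, l_sources) samples of each replication are dropped once, so
every CMI in every iteration is estimated on the same
M = (T − max_lag) · R rows and values are comparable across iterations.
Ties in the argmax/argmin break deterministically toward the lowest
process index, then the smallest lag. Raw (possibly negative) CMI
estimates are used for ranking; the statistical tests alone decide
inclusion.

A directed link X → Y is reported whenever any selected source variable
of target Y belongs to process X; all selected lags are kept, and the lag
of the variable with the largest final conditional contribution serves as
the representative lag where one lag per link is needed.

## Estimators

**Gaussian.** The covariance-based plug-in estimator
I = ½[ln det Σ_xz + ln det Σ_yz − ln det Σ_xyz − ln det Σ_z] (nats).
Covariances use mean removal and 1/M normalization (the normalization
cancels in the differences). For VAR-class data this is exact and
equivalent to Granger causality. All CMIs for a recording are
log-determinants of submatrices of one precomputed embedded-covariance
matrix, which makes the analytic-null pipeline fast. Under conditional
independence, 2·M·I is asymptotically χ² with dim(x)·dim(y) degrees of
freedom (standard likelihood-ratio asymptotics; the omnibus statistic for
k selected source variables uses df = k). No finite-sample correction is
applied.

**Nearest-neighbor (KSG).** Kraskov algorithm 1 with k = 4 neighbors by
default, max-norm in every subspace, strict inequality on the radius, and
the Frenzel–Pompe digamma combination for the conditional form.
Deterministic, seeded jitter at amplitude 1e-8 × column-sd breaks
distance ties (values collide after, e.g., modulo maps); constant columns
are rejected rather than silently jittered. The estimator is model-free
and approximately invariant under monotone transforms, at the price of a
much larger run time, so it is paired with permutation surrogates rather
than an analytic null.

## Statistical testing

Every greedy iteration compares n candidates, so the selection test must
control the family-wise error rate over those comparisons. The **maximum
statistic** test builds the null distribution of the *maximum* surrogate
CMI across all n candidates: for each candidate, S surrogates are created
by permuting its embedded realization (whole replications when several
are available and their permutation count exceeds S; embedded samples
within replications otherwise), target and conditioning variables
untouched; the p-value is the fraction of surrogate maxima strictly
larger than the observed maximum. Treating the candidates' null estimates
as i.i.d., the implied per-variable false-positive rate is the
Dunn–Šidák relation vFPR = 1 − (1 − α)^(1/n), and the per-target rate
over the step-down iterations is α(1 − α^n)/(1 − α) ≈ α. With the
Gaussian estimator the surrogate loop is replaced by the analytic form
p = 1 − F(I*)^n.

The **minimum statistic** test mirrors this with minima for pruning: the
observed weakest contribution is compared against the null distribution
of the surrogate minimum; small p means even the weakest variable beats
chance. Analytically p = (1 − F(I_min))^n. A consequence of the extreme-
value null worth knowing: when one genuinely contributing variable is
present, a purely redundant companion survives pruning with probability
about α^(1/n) (≈ √α for n = 2), i.e. the test is deliberately
conservative about removal.

The **omnibus** test permutes the rows of all selected source
realizations jointly and compares T* against that null (analytically,
1 − F_k(T*)). Per-target omnibus p-values are then combined across
targets by Benjamini–Hochberg FDR at level q (default 0.05); a target
rejected at this level loses all its links. p-values use strict
inequality ("larger than"), so p = 0 is attainable; the configuration
rule S > 1/α guards the resolution of empirical nulls. Targets are
analyzed independently with per-target random streams spawned
deterministically from the master seed, so serial, parallel and sharded
runs agree bit-for-bit.

## Synthetic validation systems

Ground-truth networks are directed Erdős–Rényi graphs over off-diagonal
ordered pairs (default p = 3/N, expected in-degree 3(N−1)/N ≈ 3). Each
link carries one lag drawn uniformly from {1..5} and cross-coupling
weights into each target are uniform and normalized to sum to 0.4;
self-coupling is β = 0.5 at lag 1 and is not a link. Two dynamics:

* **VAR**: Y_t = β Y_{t−1} + Σ_X α_X X_{t−l_X} + η_t with i.i.d.
  Gaussian noise (mean 0, sd 0.1, uncorrelated across nodes). With these
  parameters the companion-matrix spectral radius lands in roughly
  0.90–0.95 at N = 100 (stable, stationary Gaussian); the simulator
  refuses radii ≥ 0.999 instead of resampling silently.
* **Coupled logistic maps**: the same weighted input is passed through
  the fully chaotic logistic map (r = 4), noise added, then wrapped
  modulo 1 into [0, 1). The marginal is strongly non-Gaussian, which is
  the regime that motivates the nearest-neighbor estimator.

Initial conditions are zeros (VAR) or uniform(0,1) (CLM); a burn-in of
1000 samples (a package choice; transients decay well within it at these
radii) is discarded before the T returned samples. These generators
emulate the stationary, fully observed, faithful setting in which the
information network provably reflects the structural network for large
samples. They do not emulate hidden nodes, nonstationarity, correlated or
state-dependent noise, or measurement filtering — passing the validation
suite says nothing about robustness to those.

## Evaluation

Link recovery is scored as binary classification over the N(N−1) ordered
off-diagonal pairs: precision TP/(TP+FP), recall TP/(TP+FN), specificity
TN/(TN+FP). Ratios with zero denominators are reported missing and
excluded from averages rather than coerced to 0 or 1. Lag recovery is the
mean |true − inferred| over recalled links (representative lag), divided
by the chance level for the lag range (1.6 for {1..5}); 0 is exact, 1 is
chance. The empty-network protocol estimates the per-target
false-positive rate under the complete null and compares it with the
exact 5th–95th percentile band of ⟨Binomial(N, α)/N⟩ (the sum over
repeats is itself binomial, so the band needs no simulation); the
network-level FDR stage is disabled there because the protocol validates
the per-target test level itself.

## Problem sizes and known limitations

The validation suite and the acceptance script run desk-scale versions of
the experiments: N = 10 (N = 100 for generator stability, N = 40 in the
null-calibration protocol), T up to 10 000, 10–20 seeds per condition,
Gaussian estimator with analytic nulls for all score sweeps, and the KSG
surrogate path exercised on small two-node systems. At this scale the
headline results reproduce: ≥ 98% precision/recall/specificity on VAR at
T = 10 000; FPR inside the binomial band on empty networks; the Gaussian
estimator on chaotic maps still recovering well over half the links at
T = 10 000; and at T = 1000 the recall gained by relaxing α from 0.001 to
0.05 exceeding five times the precision lost. One direction does not
survive the scale-down: at T = 100 and N = 10 the precision-loss /
recall-gain ratio is about 1–2, not ≥ 5; the same code at N = 40 gives a
ratio ≈ 7, so the reversal is a property of larger/pooled network sizes
and the corresponding desk-scale check is expected to fail at N = 10.

Other limitations: the analytic null is asymptotic (no finite-sample
correction); the i.i.d. treatment of candidate nulls is an approximation
that becomes anti-conservative for strongly correlated candidates; only
the two stated permutation schemes are provided (no block or circular
surrogates preserving autocorrelation); candidate lag sets are contiguous
1..l; and the KSG path with surrogates is computationally heavy —
budget roughly (candidates × iterations × S) tree searches.
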