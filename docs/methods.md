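# Methods

## Estimators

**Pearson correlation** is the sample product-moment coefficient
(delegated to `scipy.stats.pearsonr`).  Constant profiles raise an error
rather than returning 0: an undefined coefficient and an absent linear
trend are different findings.

**Mutual information** is the plug-in (maximum-likelihood) estimator on a
discretisation of each profile's value range: relative frequencies
k<sub>i</sub>/N stand in for probabilities and
I = H(X) + H(Y) − H(X,Y) in base-2 logs.  The implementation uses the
algebraically identical closed form
I = log₂N + (1/N)Σ k<sub>ij</sub> log₂(k<sub>ij</sub>/(k<sub>i</sub>k<sub>j</sub>)),
with 0·log₂0 ≡ 0 and a clamp to exactly 0 for rounding residue within
10⁻¹². No bias correction (Miller–Madow, shrinkage, k-NN) is applied; the
estimator is deliberately the plug-in on adaptive bins, and its
finite-sample overestimation on independent data is documented below.

**Discretisation.**  Two modes:

* *fixed*: M equal-width intervals over a declared (or observed) range,
  half-open with the last interval right-closed.  A value on an interior
  boundary belongs to the upper interval.
* *adaptive* (default, M = 11): equal-frequency intervals with boundaries
  at the empirical quantile positions ⌈iN/M⌉.  If a boundary would split a
  run of tied values, the lower interval absorbs the whole run, so
  intervals remain genuine sub-intervals of the value range (at the cost
  of counts deviating from N/M by the run length).  Interior boundary
  values are midpoints between the neighbouring order statistics.
  Profiles with fewer than M distinct values — or ties heavy enough to
  collapse two boundaries — are rejected (`DegenerateInputError`) instead
  of silently merging bins, because a silent change of M would change the
  value range of every downstream rank statistic; callers may lower M
  explicitly.

With exactly uniform marginals, H(X) = H(Y) = log₂M and
I = 2log₂M + Σ (k<sub>ij</sub>/N)log₂(k<sub>ij</sub>/N).  Adaptive bins are
only *approximately* uniform (⌈iN/M⌉ cuts, tie absorption), so the
implementation always uses the exact marginal entropies of the realised
counts rather than assuming 2log₂M; the two agree whenever N is a multiple
of M with no ties.

## The compressed rank index

All-pairs percentile ranks are computed without retaining the pair values:

* **U**: MI histogram, 35,000 bins of width 10⁻⁴ over [0, 3.5].  The range
  is the attainable MI under M = 11 (log₂11 ≈ 3.459 < 3.5); values at or
  above the cap — possible only with M > 11 — clamp into the last bin with
  a logged warning.
* **|r| histogram**: the same construction at the same 10⁻⁴ resolution
  needs 10,000 bins over [0, 1].  Ranks for r are computed on |r|, not
  signed r: a near-zero coefficient must rank near the bottom, and strong
  negative correlation is as much linear coexpression as strong positive.
* **V**: percentile thresholds v₀..v₁₀₀, v_i being the upper edge of the
  first bin whose cumulative count reaches ⌈i·total/100⌉ (v₀ = lower edge
  of the first occupied bin).  Thresholds are exact to one bin width.
  Ties at a percentile boundary resolve downward, deterministically.
* **T**: the lookup table (k/N)log₂(k/N) for k = 0..N.  Every entropy term
  of a pair's MI is then a table lookup over the precomputed per-probe
  interval labels; the table path and the direct evaluation agree to
  10⁻¹² (verified in the suite).

A percent rank is the largest i with v_i ≤ value, clamped to [1, 99] — at
percent resolution the extremes are never reported as 0 or 100.  Fewer
than 100 pairs make "1% of pairs" meaningless, so the standalone
percentile builder requires ≥ 100 values; index construction over smaller
matrices relaxes this (the thresholds degenerate gracefully) so that tiny
fixtures remain indexable.

Index building makes two streaming passes over the unordered pairs
(histograms first, then rank differences with V in hand); memory is
O(bins + P·N).  The index stores a content fingerprint of its source
matrix and refuses queries against any other.

## Hybrid score and top-k queries

MIr = β·r/max r + (1−β)·MI/max MI with maxima over the query probe's
candidate set (the query itself excluded; a probe paired with itself is an
error).  β defaults to 0.5.  The equation is applied with signed r, read
literally; `use_abs_r=True` switches numerator and maximum to magnitudes
for consistency with the |r|-based Ror.  Note the signed default can
amplify noise when every candidate's r is near zero (max r is then itself
noise); the magnitude option is the conservative choice in that regime.
Nonpositive maxima raise an error rather than producing an unnormalisable
score.  Top-k lists are sorted strongest-first with lexicographic probe-ID
tie-breaks, so results are deterministic.

"Total coexpression rate" is exposed as PP + AA alongside its parts;
samples with a marginal (M) call in either probe count toward none of the
four rates.

## Synthetic data

The generators stand in for real microarray compendia and define the package's test
conditions:

* profile pairs over n ≥ 5 samples, values nonnegative on a unit dynamic
  range, additive Gaussian noise with default SD 0.05 (≈5% of range,
  typical replicate scatter after normalisation).  Noisy profiles stay
  nonnegative by reflection (|y|), not clipping — clipping would pile tied
  zeros that equal-frequency binning rejects.
* `linear`: y = 0.9x + ε.  `monotone_nonlinear`: y = x³ + ε.
  `independent`: two independent uniforms.
* `permuted_dependency`: a deterministic bijection of x's rank that
  destroys the linear trend.  A per-rank random permutation would also
  destroy the *discretised* MI at M = 11 for large n (the dependency falls
  below the bin resolution), so the permutation acts on min(n, 11)
  equal-frequency rank blocks, which align with the adaptive bins:
  MI ≈ log₂11 while r ≈ 0 (the block permutation is chosen by a short
  seeded search minimising its correlation with the identity).  For n = 5
  this reduces to a five-point permutation with vanishing r and
  MI = log₂5 under five fixed bins.
* whole matrices: an `independent` background (i.i.d. log-normal
  intensities), a `latent_factor` background in which every probe loads on
  one shared per-sample factor (most pairs genuinely dependent, as in a
  real compendium), and planted pairs appended with predictable IDs.

What these fixtures do *not* emulate: probe-specific saturation,
batch/series structure, heteroscedastic array noise, and the long-tailed
MI distribution of a 41,477-probe platform.  Passing tests therefore
demonstrate correctness of the estimators and rank machinery, not
biological discovery performance.

The rank-pattern checks (linear pair → both ranks high; rank-permuted →
RoMI high, Ror low; independent → both low) run on a latent-factor cohort
of 48 background probes + 3 planted pairs over 400 samples.  Two choices
matter.  First, on a *purely null* background every pair is exchangeable,
so an independent pair's percentile is uniform on [1, 99] and "both ranks
low" would hold only by luck; a broadly correlated background (which real
compendia are) pins a truly independent pair genuinely below the crowd.
With ≈79% of pairs factor-driven, the construction itself implies the
test bands (high ≥ 90, low ≤ 40).  Second, n = 400 keeps the plug-in MI
bias of an independent pair, ≈ (M−1)²/(2N ln2) ≈ 0.18 bits, well below
the factor pairs' MI, so the rank separation is structural rather than
seed luck (the suite's fixed seed was not selected for outcome; the
pattern holds across seeds by this argument).

## Problem sizes and numerical choices

The test suite and the acceptance script use scaled-down but structurally
complete problems — cohorts of tens of probes and hundreds of samples,
sweeps of 1,000 simulated pairs at n = 1,000 — chosen so the full suite
runs in seconds while every code path (streaming, two-pass indexing,
clamping, degeneracy handling) is exercised.  The platform-scale pair
total 860,150,026 (P = 41,477) is checked analytically as P(P−1)/2, not by
enumeration.

Floating point: MI clamped at 0 within −10⁻¹²; histogram bin assignment is
plain floor division, so a value sitting exactly on a 10⁻⁴ bin edge may
land one bin off after rounding — within the ±1-percentile guarantee of
the rank machinery.  Matrix round-trips are bit-exact (shortest-repr
printing plus round-trip float parsing).

## Known limitations

* The plug-in MI of independent profiles is biased upward at small N
  (≈ 0.6 bits at N = 120, M = 11); rank statistics are unaffected (the
  bias is shared across pairs), but raw MI values at small N should not be
  read as dependency strength.
* Adaptive binning rejects heavily tied profiles rather than degrading; a
  matrix with many discrete-valued probes needs a smaller M.
* The rank index is percent-resolution by design; exact global ranks are
  out of scope.
* MIr with signed r is undefined (error) when all candidate correlations
  are nonpositive; use the |r| option there.
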