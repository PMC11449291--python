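# Methods

This note records the modelling assumptions, parameter defaults, numerical
choices and known limitations behind the package. It is written for users
who want to know exactly what the simulator and estimators compute, and
what passing tests do and do not establish.

## Generative model

Sequences are binary spin strings σ ∈ {−1, +1}^L. The additive trait is
τ(σ) = Σᵢ Dᵢσᵢ and selection acts through H(σ) = (κ/2)(τ − τ*)². The
fitness of a sequence is −H, so sequences whose trait sits at the favoured
value τ* are optimal; the curvature κ sets how sharply deviations are
punished. Because the trait is additive and the selection nonlinear
(quadratic), the large-|D| sites become collectively correlated — a
functional sector — even though no pairwise epistasis is built in.

**Effect vectors.** `make_effect_vector` plants the sector in the first
`L_S` positions. Defaults: L = 200, L_S = 20, sector effects drawn from
N(5, 0.25), background from N(0.5, 0.25) (arguments take standard
deviations, 0.5 in both cases). An optional `flip_fraction` negates the
leading share of sector components to produce mixed-sign sectors. The
selection strength defaults to the normalisation κ = 10 / ΣᵢDᵢ², and the
favoured trait to τ* = 90; these are the reference conditions used by the
test-suite fixtures and the acceptance script.

**Equilibrium sampling.** Each sequence starts uniform-random and evolves
by single-spin-flip Metropolis: a uniformly chosen site is proposed for
flipping and accepted with probability min(1, e^(−ΔH)). ΔH is computed
incrementally from the running trait value, so a proposal costs O(1). The
chain stops after a fixed number of *accepted* flips (default 3000, which
converges the sequence energy at the reference conditions). Stopping at an
acceptance means the sampled law is, exactly, the stationary law of the
jump chain — Boltzmann weight times the state's total acceptance
probability. The test suite verifies this against exact enumeration at
L = 10; at the reference conditions the per-state acceptance probability
is nearly constant, so the deviation from plain Boltzmann sampling is well
under the sampling noise of any quantity studied here.

**Phylogeny.** One equilibrium sequence becomes the ancestor of a perfect
binary tree with n generations (default 11, giving M = 2^11 = 2048
leaves). Exactly μ accepted mutations occur on each branch, under the same
Metropolis criterion, so selection continues to act during descent; with
`neutral=True` every proposal is accepted instead. Repeated and reverting
flips are allowed and each acceptance counts toward μ, so two siblings
differ by at most 2μ sites. Arbitrary rooted trees are supported through
newick input; there the number of accepted mutations per branch is
Poisson(rate × branch length) and the record reports the mean root-to-leaf
accepted-mutation count. Trees must carry branch lengths; duplicate leaf
labels are tolerated.

Every simulation retains all internal-node sequences, a per-branch log of
accepted flips (sufficient to replay each leaf exactly), and the per-site
score G: the earliest generation (tree level, 1 = the root's children) at
which the site differs from the root anywhere in the tree. Sites that
never deviate receive the sentinel G = n + 1 so they can be grouped or
filtered explicitly.

**Random numbers.** Every public operation takes a single seed.
Per-sequence and per-branch streams are spawned from it with numpy's
`SeedSequence`, so row m of an equilibrium alignment does not depend on M,
and a branch's stream does not depend on traversal order. The Metropolis
inner loop runs in a numba kernel seeded from the per-branch stream. A
chain that rejects 10^6 consecutive proposals aborts with a `StallError`
rather than looping forever (this requires extreme κ).

## Estimators

All methods start from single- and two-site frequencies with pseudocount
a: f̃ᵢ = a/q + (1−a)fᵢ and f̃ᵢⱼ = a/q² + (1−a)fᵢⱼ for i ≠ j, with the
same-site table f̃ᵢᵢ(s, s′) = δ(s, s′)f̃ᵢ(s).

* **Conservation**: 1 − Σ_s fᵢ(s) log_q fᵢ(s) ∈ [0, 1], computed without
  pseudocount by default (0·log 0 := 0).
* **Covariance (two-state)**: Cᵢⱼ = ⟨σᵢσⱼ⟩ − ⟨σᵢ⟩⟨σⱼ⟩; with pseudocount,
  Cᵢⱼ = (1−a)⟨σᵢσⱼ⟩ − (1−a)²⟨σᵢ⟩⟨σⱼ⟩ off the diagonal and
  Cᵢᵢ = (1−a)²(1−⟨σᵢ⟩²) + a(2−a).
* **ICOD**: invert that covariance (pseudocount a = 10⁻⁵ by default — the
  inversion is the only step that needs regularisation) and zero the
  diagonal, which strips conservation signal. The matrix is symmetrised
  after inversion; a condition number above 10¹² raises instead of
  returning noise. For categorical alignments the reference-sequence gauge
  drops the reference amino acid at each site (19 states/site, a = 0.05),
  the (19L)² covariance is inverted, each 19×19 site-pair block is
  compressed by Frobenius norm, the diagonal is zeroed, and the average
  product correction (APC) can be applied.
* **SCA**: the blocked q-state covariance weighted elementwise by
  φᵢ(s) = |ln[f̃ᵢ(s)(1−q̄ₛ) / ((1−f̃ᵢ(s))q̄ₛ)]| — the gradient of relative
  entropy against a background q̄ (uniform by default, (0.5, 0.5) for
  spins) — then per-pair Frobenius norm. Frequencies are clipped to
  [10⁻⁶, 1−10⁻⁶] before the logarithm. No sequence reweighting is applied
  by default. The default pseudocount is 10⁻⁶, for numerical safety only;
  the sweep in the acceptance script shows recovery changes by < 0.01%
  between a = 0 and a = 10⁻⁵.
* **Mutual information**: Σ f̃ᵢⱼ ln(f̃ᵢⱼ/(f̃ᵢf̃ⱼ)) with a = 10⁻³. Natural
  logarithm; the base only rescales rankings. The diagonal
  (self-information) is zeroed before eigen-analysis by default, in
  parallel with ICOD, since only off-diagonal structure is informative
  about coupling; `zero_diagonal=False` exposes the alternative.
* **APC**: M′ᵢⱼ = Mᵢⱼ − (row mean · column mean)/overall mean with all
  means over off-diagonal entries. Note that excluding the diagonal makes
  the correction inexact on a rank-one matrix — an O(1/L) residual
  remains, and APC is not idempotent in general (re-application divides by
  a near-zero mean). It is applied once or not at all.

Eigendecompositions sort eigenvalues descending (rank 0 = largest) and fix
each eigenvector's sign so its largest-magnitude component is positive;
all downstream scores use absolute components, so the convention is
cosmetic. The sector signal sits in the *largest* eigenvalue for ICOD,
SCA and MI, and the *smallest* for covariance — selection makes D a
direction of small variance.

## Evaluation

Recovery(v, D) = Σᵢ|vᵢDᵢ| / (‖v‖‖D‖); invariant to rescaling and to any
per-component sign pattern. Its chance expectation for a Gaussian random
vector is √(2/(πL))·Σᵢ|Dᵢ|/‖D‖ (verified by Monte Carlo in the tests).
Symmetrized AUC = 2|AUC − 0.5| ranks sites by |score| against the known
sector membership; the symmetrization absorbs the eigenvector sign
ambiguity. ROC curves use all distinct |score| values as thresholds with
trapezoidal tie handling (scikit-learn's convention).

Spectral outliers are operationalised by a spacing statistic: eigenvalues
are sorted descending and the outlier/bulk boundary is placed at the
largest gap among the leading gaps, accepted only if that gap exceeds 3×
the median bulk spacing. Both knobs are configurable; on equilibrium data
this detector reports one ICOD outlier and exactly L_S SCA outliers. The
block-diagonal approximation zeroes all sector/non-sector cross entries;
its spectrum is exactly the union of the two blocks' spectra. Discarding
the cross-blocks lowers the top ICOD eigenvalue by roughly the background
share of κΣD² (≈ 15% at the reference conditions — predicted by the
analytic outer-product matrix, and matched by simulation).

The phylogeny sweep regenerates data for each (μ, realization) pair and
scores every method on the same alignments. The reference protocol uses
100 realizations; the tests and the acceptance script use 10 (a fast mode
kept for runtime), and report dispersions so the reduced-replicate spread
is visible.

## Categorical-MSA pipeline

Filtering order is fixed: keep only columns where the reference is
non-gap, drop columns with > 30% gaps, then drop sequences with > 20%
gaps (the reference row is always retained); re-running the filter is the
identity. Jukes–Cantor distances d = −((q−1)/q)ln(1 − qp/(q−1)) exclude
sites where either sequence is gapped and cap saturated pairs (argument
≤ 0) at d = 10. Cutoff subsampling keeps sequences within a given
distance of the reference; the bundled cutoff grid spans 0.4–2.0. Gap
imputation copies the state of the nearest (Jukes–Cantor) sequence that
is non-gap at that site, ties broken by smallest row index. Per-cutoff
top eigenvectors are sign-aligned to the first (positive Pearson
correlation) and summed component by component.

DMS tables are reduced to per-site scores by the minimum (most
deleterious) log-enrichment per site. Binarisation fits one- and
two-component Gaussian mixtures and picks by BIC (a `modality` flag
overrides); the cutoff is the fitted mean (unimodal) or the fitted
density's minimum between the two component means (bimodal). If a
kernel-density estimate (Scott's-rule bandwidth, peaks by prominence)
shows more than two modes, the bimodal fit is restricted to the scores
below the third-most-negative peak. A mixture component with weight < 1%
triggers a unimodal fallback with a warning. Sites below the cutoff are
the sector; the effective depth M_eff = Σₘ 1/nₘ lumps sequences within
normalized Hamming distance 0.2.

## What the synthetic data does and does not emulate

The generator reproduces the features that matter for the question —
controlled selection on an additive trait, tunable tree-shaped
correlations, known ground truth — using a two-state alphabet, a single
selected trait, a quadratic nonlinearity and (by default) a perfectly
balanced tree with equal branch lengths. Real protein families have 20
states with biased usage, multiple selective pressures, epistasis beyond
the additive trait, highly unbalanced phylogenies and non-uniform
sampling. Passing the benchmarks therefore shows that the estimators
behave as designed *under the model's assumptions*; it does not by itself
establish rankings on natural alignments. The categorical pipeline is
exercised on synthetic families (a two-state model embedded in amino-acid
coding), where reference-gauge ICOD agrees with the two-state version on
sector membership but is noticeably noisier — 18 of its 19 gauge states
are unobserved — so single-alignment outputs fluctuate more than the
aggregated multi-cutoff score.

## Problem sizes and runtime

Default test and acceptance runs use the reference conditions (L = 200,
M = 2048, n = 11) with 10 realizations per μ for sweeps, one alignment of
M = 14000 for the inverse-covariance oracle, and L = 100 families for the
categorical end-to-end check. With the numba kernel a full acceptance run
is a few minutes on one CPU; the realization count, not the Monte Carlo
chain, dominates.
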