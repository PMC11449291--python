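# phylosector

Synthetic benchmarks of functional-sector inference under phylogeny.

Groups of collectively correlated amino-acid sites in protein alignments —
*sectors* — carry functional signal, but the statistical methods that look
for them (SCA, covariance analysis, inverse-covariance methods) all read
correlations out of a multiple sequence alignment, and correlations also
arise from the mere shared ancestry of homologous sequences.  This package
implements a controlled, fully synthetic study of how phylogeny corrupts
sector identification and mutational-effect inference, together with the
estimators being compared and the machinery needed to confront them with
experimental per-site mutational effects.

It is aimed at researchers in protein coevolution and statistical sequence
analysis who want a reproducible sandbox in which the amounts of selection
and of phylogeny are dials, and the ground truth is known exactly.

## Model

Sequences are binary spin strings σ ∈ {−1, +1}^L with an additive scalar
trait τ(σ) = Σᵢ Dᵢσᵢ, where D is the vector of per-site mutational
effects.  Nonlinear selection favours a trait value τ* through the
quadratic Hamiltonian

    H(σ) = (κ/2) (τ(σ) − τ*)²,

with selection strength κ.  The L_S sites with large |Dᵢ| form the sector.
Equilibrium sequences are sampled by single-spin-flip Metropolis Monte
Carlo from P(σ) ∝ exp(−H(σ)); phylogeny is added by evolving one
equilibrium ancestor along a perfect binary tree with n generations and a
fixed number μ of accepted mutations per branch (or along an arbitrary
newick tree with Poisson-distributed mutation counts).  Small μ means
strongly correlated leaves — strong phylogeny.

Four site-scoring methods are compared against the known D:

* **ICOD** — invert the pseudocounted covariance matrix of sites, zero its
  diagonal, take the top eigenvector.  On equilibrium data the
  off-diagonal entries approximate κDᵢDⱼ, so the top eigenvector is ≈ D.
* **covariance** — the eigenvector of the *smallest* eigenvalue of the
  covariance matrix (selection squeezes variance along D).
* **SCA** — covariance weighted elementwise by conservation factors φ,
  compressed per site pair by Frobenius norm; top eigenvector.
* **conservation** — per-site Kullback–Leibler divergence from the uniform
  distribution (plus **mutual information** as a pairwise alternative).

Performance is measured by the recovery Σᵢ|vᵢDᵢ| / (‖v‖‖D‖) — equal to 1
iff |v| ∝ |D|, with chance expectation √(2/πL)·Σ|Dᵢ|/‖D‖ — and by the
symmetrized AUC 2|AUC − 0.5| for sector-site identification.

A separate pipeline handles categorical (protein) alignments: gap/column
filtering, Jukes–Cantor phylogenetic-cutoff subsampling, nearest-neighbour
gap imputation, aggregation of per-cutoff eigenvectors, and binarisation
of deep-mutational-scanning score tables by Gaussian-mixture fits.

## Worked example

```python
from phylosector import (make_effect_vector, SelectionParams, kappa_for_target,
                         evolve_on_binary_tree, mean_pairwise_hamming,
                         null_recovery, recovery)
from phylosector.evaluation import score_msa

effects = make_effect_vector(seed=0)          # 20-site sector, L = 200
params = SelectionParams(kappa=kappa_for_target(effects.D), tau_star=90.0)
record = evolve_on_binary_tree(None, mu=15, n=11, effects=effects,
                               params=params, seed=1)
msa = record.leaf_msa
print(f"M = {msa.M} leaves, mean pairwise Hamming = {mean_pairwise_hamming(msa):.3f}")
for method in ("icod", "covariance", "sca", "conservation"):
    vec = score_msa(msa, method)
    print(f"{method:>12}: recovery = {recovery(vec, effects):.3f}")
print(f"        null: recovery = {null_recovery(effects):.3f}")
```

prints

```
M = 2048 leaves, mean pairwise Hamming = 0.449
        icod: recovery = 0.987
  covariance: recovery = 0.978
         sca: recovery = 0.910
conservation: recovery = 0.902
        null: recovery = 0.483
```

At this intermediate phylogeny level (μ = 15) every method identifies the
sector far above chance, with ICOD ahead; decreasing μ to 5 separates the
methods sharply (ICOD stays ≈ 0.93 while covariance and SCA drop towards
0.55).  The `PhylogenyRecord` also tracks every internal sequence and the
earliest generation G at which each site first mutated, which is what links
eigenvector components to phylogenetic depth.

A command-line interface mirrors the library:

```bash
phylosector simulate --mu 15 -n 11 --seed 1 -o out/
phylosector score out/msa.csv --method icod -o out/icod.csv
phylosector evaluate out/icod.csv out/effects.csv
phylosector sweep --mu-grid 5,15,50 --realizations 10 -o out/sweep
phylosector reproduce fig4 --fast --seed 0 -o out/fig4
```

`reproduce` re-runs the bundled reference experiments (ICOD spectrum with
its block-diagonal and analytic approximations; spectra under increasing
phylogeny; the recovery-vs-μ sweep; eigenvector components versus G;
opposite-spectrum-end scoring; a newick-tree sweep).

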