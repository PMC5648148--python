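# smcdeconv

Blind deconvolution of heterogeneous gene-expression matrices by a
likelihood-tempered sequential Monte Carlo (SMC) sampler.

## The problem

Bulk expression measurements from complex tissues mix the transcriptomes of
several cell types: the measured intensity of gene *i* in sample *j* is

```
y_ij = Σ_k x_ik m_kj + e_ij ,          Y = X M + E
```

where `X` (genes × cell types) holds the cell-type-specific expression
signatures, `M` (cell types × samples) the per-sample mixing proportions
(each column on the probability simplex), and `E` is additive zero-mean
Gaussian noise with precision λ. Given only `Y` (non-log RMA-scale
intensities) and the number of cell types `K`, the package estimates `X`,
`M` and λ, and uses the recovered signatures to call differentially
expressed genes between cell types. It is aimed at transcriptomics analysts
who have mixed-tissue microarray or bulk RNA profiles plus, ideally, a few
technical replicates of the pure cell types.

## The sampler

Everything is conjugate: Gaussian priors on `x_ik` and `m_kj`, a Gamma prior
on λ. Instead of sampling the posterior directly, the sampler follows the
likelihood-tempered sequence

```
π_t(θ) ∝ p(θ) · p(Y | θ)^ε_t ,   0 = ε_1 < ε_2 < … < ε_T = 1
```

with N weighted particles. At each temperature the log-weights are updated
by `(ε_t − ε_{t−1}) · log p(Y | θ_{t−1})`, normalized, resampled
(multinomial) whenever the effective sample size `ESS = 1/Σ w²` drops below
N/10, and only then propagated by a Gibbs scan of the closed-form tempered
conditionals — Gaussian for every `x_ik` and `m_kj`, Gamma for λ. Point
estimates are the weighted particle means; estimated proportion columns are
clamped at zero and rescaled to sum to one, and the cell-type label
permutation is resolved with marker genes derived from pure-sample
replicates. A plain Gibbs sampler over the same conditionals at ε = 1 is
included as an MCMC comparator, and a non-conjugate variant with a
Dirichlet prior on proportion columns (Metropolis–Hastings kernel in
additive-log-ratio space) is available.

See `docs/methods.md` for model details, default parameters and the design
of the synthetic benchmark generator.

## Worked example

Simulate a 200-gene, 3-type, 8-sample mixture benchmark, deconvolve it, and
score the estimates:

```
$ smcdeconv simulate --out data --genes 200 --celltypes 3 --samples 8 --seed 7
wrote dataset (I=200, K=3, J=8, noise_sd=37.7) to data

$ smcdeconv run --matrix data/Y.tsv --celltypes 3 --particles 512 --steps 60 \
      --seed 7 --out fit --pure-matrix data/Y_pure.tsv
deconvolved 200x8 matrix into K=3 types; results in fit

$ smcdeconv evaluate --mhat fit/M_hat.tsv --mtrue data/M_true.tsv \
      --xhat fit/X_hat.tsv --xtrue data/X_true.tsv --out scores
mad     0.00180884
pearson_r       0.999969
auroc_0gt1      0.996143
auroc_0gt2      1
auroc_1gt0      1
auroc_1gt2      0.99982
auroc_2gt0      1
auroc_2gt1      0.99562
```

The estimated proportions differ from the simulated truth by 0.0018 on
average (`mad`), correlate with it at r = 0.99997 (`pearson_r`), and the
recovered signatures identify differentially expressed genes between every
ordered pair of cell types nearly perfectly (`auroc_*`, area under the ROC
over a fold-change threshold sweep from 1 to 5). `fit/` also contains the
estimated signatures (`X_hat.tsv`), posterior spreads, the noise precision
(`lambda.txt`) and a `metadata.yaml` with the seed, temperature schedule,
ESS trace and resampling events — a seeded run is exactly reproducible.

The same pipeline is available from Python:

```python
from smcdeconv import simulate_dataset, deconvolve_dataset, SMCConfig

sim = simulate_dataset(I=200, K=3, J=8, seed=7)
study = deconvolve_dataset(sim, SMCConfig(n_particles=512, n_steps=60, seed=7))
print(study.pearson_r, study.mad)
```

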