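# cadee — recursive copula-splitting entropy estimation

`cadee` estimates the Shannon differential entropy H = −∫ p(x) ln p(x) dx of a
continuous D-dimensional distribution from N independent samples, together
with mutual information between groups of variables. It is aimed at problems
where entropy and dependence must be quantified from samples alone — feature
selection, independent-component analysis, network inference, and order
parameters of driven physical systems — and where the support of the
distribution is high-dimensional, unknown, or unbounded.

## Method

By Sklar's theorem a continuous joint density factors into its 1D marginals
and a copula density c on [0, 1]^D with uniform marginals, so

    H = Σ_k H_k + H_c,

where H_k are the marginal entropies and H_c ≤ 0 is the copula entropy
(H_c = −I, minus the total mutual information). The marginals are estimated
with standard 1D methods: a digamma-corrected m-spacing estimator
(m = N^(1/3)) when the support is unknown or unbounded, and a plug-in
histogram (B = N^0.4 bins) on [0, 1]. The copula entropy is estimated
recursively:

1. rank-transform each column: u_i = (rank_i − 1/2)/N, the empirical copula;
2. test all pairs of dimensions for dependence (Spearman correlation t-test
   at level α = 0.05, with a mutual-information fallback that compares the
   pair's 2D plug-in entropy against the null cutoff H_2c = −0.75 N^(−0.62));
3. if the dependence graph splits into connected blocks, estimate each block
   separately and add the results;
4. otherwise split the copula sample at its median (exactly 1/2 in every
   dimension) along the most-correlated dimension; then
   H_c = (H_left + H_right)/2 exactly, and each half is again a Sklar
   decomposition one level down;
5. stop when a block is 1D or fewer than `min_samples` (default 100) samples
   remain.

Every copula term that the recursion eventually drops is ≤ 0, so truncations
approach H from above; the cost is O(D² N log N).

## Worked example

```python
import numpy as np
from cadee import (DistributionSpec, Family, estimate_entropy,
                   exact_entropy, sample_distribution)

spec = DistributionSpec(Family.C2, dimension=10)   # 5 independent pairs,
x = sample_distribution(spec, 1_000_000, seed=11)  # each with p(x,y) = x + y
est = estimate_entropy(x)
print(f"exact    {exact_entropy(spec):+.5f} nats")
print(f"estimate {est.total:+.5f} = marginals {est.marginal_sum:+.5f}"
      f" + copula {est.copula:+.5f}")
print(f"depth {est.max_depth}, block splits {est.n_block_splits}, "
      f"leaves {est.n_leaves}")
```

prints

```
exact    -0.45431 nats
estimate -0.45945 = marginals -0.42732 + copula -0.03213
depth 8, block splits 125, leaves 244
```

The marginal sum collects the ten 1D entropies (each ≈ −0.0428 nats for the
x + 1/2 marginal); the copula part carries the dependence within the five
pairs (≈ −0.0053 nats per pair); their sum reproduces the exact value to
about 0.005 nats even though N = 10,000·D² badly under-samples a
10-dimensional cube.

The same machinery is exposed as a CLI:

```
cadee simulate --family C2 -d 10 --n 1000000 --seed 11 --out samples.csv
cadee estimate samples.csv
cadee benchmark --families C1,C2,C3 --dimensions 2,5,10
cadee converge --families C2,C3,UB1,UB2 --n-grid 1000,10000,100000
```

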