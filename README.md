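# fitscape

Simulation and analysis tools for **fitness-landscape learning**: how a
population whose quantitative traits are controlled by a sparse
gene-regulatory map can infer the signs of unknown selection coefficients
from the mere persistence of genotype variants, and how a simple
threshold-feedback rule turns that information into canalized, rapidly
adapting phenotypes.

## The model

A genotype is a Boolean string `s ∈ {0,1}^N_g`.  Trait `j` of `N_b`
quantitative traits is expressed as a sigmoid of a weighted gene sum,

    f_j(s) = σ( Σ_i w_ji s_i − h_j ),     σ(z) = 1 / (1 + e^(−bz)),

where the nonzero entries of row `j` of `W` form the trait's regulation set
`K_j` and `h_j` is an expression threshold.  Fitness couples traits to an
environment vector `b` through an exponential potential,

    F(s) = K_F · exp( Σ_j b_j f_j(s) ).

On top of this map the package provides:

- **`gpmap`** — trait models, environments, random model generators (sparse
  Bernoulli-β and fixed in-degree K), pleiotropy statistics, JSON/plain-text
  serialization.
- **`popdyn`** — finite-population Wright–Fisher dynamics: Poisson(F)
  offspring, per-gene mutation of offspring, and a genotype-blind "massacre"
  that caps the population at `N_popmax`.
- **`replicator`** — the infinite-population limit `X′ = X·F/F̄` (with mean
  fitness checked to be non-decreasing, per Fisher's theorem), the
  frequency-ratio growth law, the learning-time bound
  `T_c > −log(p0·p1)/(|b_j|·δ_j)`, and `infer_sign`, which reads the sign of
  `b_j` off the co-persistence of two genotype variants differing inside a
  single regulation set.
- **`regulation`** — strong-selection weak-mutation (SSWM) adaptive walks
  with threshold feedback: every ΔT steps the most strongly driven
  unregulated trait has its threshold locked to ∓D_h, canalizing the trait
  at its current expression; a modular schedule spreads the locks over
  rounds of a few traits each.
- **`ksat`** — with ternary weights and thresholds `h_j = −C_j + 0.5`,
  maximizing fitness is exactly K-SAT; includes a brute-force oracle,
  solution-cluster graph statistics, the critical clause densities
  `α_g ≈ 2^K ln(K)/K` and `α_c ≈ 2^K ln 2`, and DIMACS CNF import/export.
- **`bounds`** — the Chernoff/Hoeffding machinery quantifying how accurately
  the capped finite population follows the replicator limit, the
  false-persistence probability `ρ(p)` and the sign-test success bound
  `(1 − ρ(p0) − ρ(p1))^T_c`, each validated against Monte-Carlo tail
  frequencies.

## Worked example

Ten genes controlling two hundred traits is an extreme pleiotropy regime —
each gene influences about a hundred traits, and an unregulated adaptive
walk can hold almost no trait at a well-expressed level.  Threshold
regulation changes that:

```python
import numpy as np
from fitscape.regulation import preset_experiment

baseline = preset_experiment("pleiotropy", rounds=1, regulate=False,
                             rng=np.random.default_rng(0))
modular = preset_experiment("pleiotropy", rounds=190, regulate=True,
                            rng=np.random.default_rng(0))
print("baseline adapted traits:", baseline.final_adapted)
print("190-round regulation:   ", modular.final_adapted)
```

prints

```
baseline adapted traits: 2
190-round regulation:    110
```

— without regulation only a handful of the 200 traits end within 0.05 of
their optimal expression, while the modular walk, locking one or two traits
per round at the sign the walk has learned, holds over a hundred there (and
keeps them robust to further mutations).  The same machinery is available
from the command line:

```bash
fitscape learn --preset pleiotropy --rounds 190 --seed 0 --out trace.tsv
fitscape bounds-check --seed 1 --out bounds.tsv
```

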