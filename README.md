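# minepi — minimum-epistasis interpolation of sequence–function landscapes

High-throughput mutagenesis assays measure a phenotype (binding, activity,
fitness) for many combinations of mutations, but almost never for *all* of
them. `minepi` completes such a genotype–phenotype map over the full
combinatorial space of `l` sites × `α` alleles by inferring the **least
epistatic reconstruction compatible with the data**: mutational effects are
made to change as little as possible between adjacent genetic backgrounds.
It is aimed at analysts of deep mutational scanning and protein-binding
microarray–style data sets of moderate size (up to ~10⁶ genotypes).

## The method

Every pair of mutations at two sites, on a shared background, spans a
*face* of the Hamming graph — wild type `ab`, single mutants `Ab`, `aB`,
double mutant `AB` — with the local epistatic coefficient

```
ε = (f_AB − f_aB) − (f_Ab − f_ab).
```

Averaging ε² over all `s = C(l,2) C(α,2)² α^(l−2)` faces gives the
mean-squared epistasis `ε̄²(f) = fᵀC f`, a positive semi-definite quadratic
form whose coefficients depend only on Hamming distance and whose null
space is exactly the additive landscapes. Given observations `y` on a
genotype subset `B`, the reconstruction solves

```
minimize  fᵀC f   subject to  f_B = y,
```

a single sparse linear system `C_II f_I = −C_IB y` over the unobserved
genotypes `I`. The cost operator is tied to the graph Laplacian by
`2sC = L² − αL`, making the problem a discrete biharmonic boundary-value
problem — the sequence-space analog of thin-plate-spline interpolation.
At every unobserved genotype the solution equals the mean of the local
additive predictions through it (`f̂(i) = (M f̂)(i) = 2d₁(i) − d₂(i)`),
and because `f̂_I` is linear in `y`, observation noise propagates with the
closed-form covariance `σ² C_II⁻¹ C_IB C_BI C_II⁻¹`.

The package also provides the smoother `M` (in-sample noise filtering that
leaves out-of-sample predictions fixed), landscape simulators (the crater
model of transcription-factor binding, other distance-profile models, and
a sparse all-order interaction model), additive/L2/L1 regression baselines
with cross-validation, an evaluation suite (out-of-sample R², held-out-face
ε̄², local maxima, percentile FDR), and a weak-mutation Markov-chain
embedding for landscape visualization.

## Worked example

```python
import numpy as np
from minepi import ObservationSet, interpolate, make_space, prediction_covariance

space = make_space(l=2, alpha=2)                    # genotypes aa, ab, ba, bb
obs = ObservationSet(space, indices=np.array([0, 1, 2]),
                     y=np.array([0.0, 2.0, 1.0]))   # aa=0, ab=2, ba=1
result = interpolate(obs)
print(result.f_hat)                  # [0. 2. 1. 3.]
print(prediction_covariance(obs, sigma2=1.0))       # [3.]
```

The missing double mutant `bb` receives the additive prediction
`0 + (1−0) + (2−0) = 3.0` — the wild-type value plus both single-mutant
effects — and its noise-induced variance is `3σ²` because the prediction
is a ±1 combination of the three measurements.

The same operations are available from the shell:

```
minepi simulate --family crater --l 12 --alpha 2 --seed 7 --out crater.tsv
minepi interpolate --input obs.tsv --alphabet ab --length 12 --out pred.tsv
minepi smooth --input pred.tsv --alphabet ab --length 12 --out smooth.tsv
minepi embed --input smooth.tsv --alphabet ab --length 12 \
             --wild-type abbbaaaaaaaa --out coords.tsv
minepi benchmark --config run.yaml
```

Every command writes a JSON manifest (inputs, seeds, version, wall clock)
next to its output; identical manifests reproduce byte-identical tables.

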