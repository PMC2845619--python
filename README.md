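# swiss

**SWISS** (Standardized WithIn class Sum of Squares) is a cluster-validity
score for comparing *data-processing methods* — normalizations, experimental
designs, platforms, gene filters — by how well the processed data cluster
into classes that are known *a priori* (tumor/normal, receptor status,
reference samples, ...). It is aimed at people running high-dimensional
assays such as expression microarrays or RNA-Seq, who must choose between
processing pipelines before drawing any biological conclusion.

## The score

Let `x_ij` be the d-vector of features for the j-th sample of class `i`
(`i = 1..k`, `N` samples in total), `x̄` the overall mean and `x̄_i` the
mean of class `i`. Following classical ANOVA,

```
SST   = Σ_ij ‖x_ij − x̄‖²          total sum of squares
WISS  = Σ_ij ‖x_ij − x̄_i‖²        total within-class sum of squares
SWISS = WISS / SST                 ∈ [0, 1]
```

SWISS is the proportion of total variation *unexplained* by the class
structure: lower means tighter classes and/or larger between-class
separation. Because the within-class sum is standardized by SST, scores are
comparable across datasets on different scales and of different
dimensionality — which is exactly what makes it possible to compare, say, a
22K two-color array against one lane of RNA-Seq on the same samples.

The package provides:

- `swiss score` — SST, WISS and SWISS for a labeled matrix;
- `swiss compare` — a permutation test for whether one method's SWISS is
  *significantly* lower than another's, built on per-sample standardized
  contributions so the two methods may have different feature sets. Two
  empirical p-values are reported; a method is declared better only when its
  score is smaller **and** both p-values are below α (default 0.05);
- `swiss perfect` — the perfect-feature enhanced SWISS score: one ideal,
  perfectly class-separating feature per class is appended and the score
  recomputed, calibrating how large a *biologically meaningful* difference is;
- `swiss sweep` — SWISS as a function of the number of retained top-variance
  genes, with optional per-level permutation confidence bands;
- `swiss simulate` — seeded K-class Gaussian synthetic data with informative
  and pure-noise features.

All functionality is importable from the `swiss` Python package
(`swiss_score`, `permutation_test`, `enhanced_swiss`, `swiss_sweep`,
`simulate`, ...).

## Worked example

A two-feature toy with four samples at the corners of a 4×2 rectangle, the
left corners in class `a`, the right corners in class `b`:

```sh
$ cat toy.tsv
feature_id  s1  s2  s3  s4
g1          0   0   4   4
g2          0   2   0   2
$ cat labels.tsv
sample_id  class
s1  a
s2  a
s3  b
s4  b

$ swiss score --matrix toy.tsv --labels labels.tsv
SST   = 20.0000
WISS  = 4.0000
SWISS = 0.2000
```

Every sample is at squared distance 5 from the overall mean (2, 1), so
SST = 20; each is at squared distance 1 from its class mean ((0, 1) or
(4, 1)), so WISS = 4 and SWISS = 4/20 = 0.2 — only 20% of the variation is
left unexplained by the two classes. Appending one ideal class-separating
feature per class lowers the score further:

```sh
$ swiss perfect --matrix toy.tsv --labels labels.tsv
original SWISS = 0.2000
enhanced SWISS = 0.1333
  class a: perfect feature = 1.0000 inside, 0.0000 outside
  class b: perfect feature = 4.0000 inside, 1.0000 outside
```

A rival processing method whose SWISS lands below 0.1333 would beat this one
by more than a whole ideal feature's worth — a biologically meaningful gap,
not merely a statistically significant one.

Comparing two simulated "methods" on the same 40 samples — one with real
class separation, one pure noise:

```sh
$ swiss simulate --delta 2.0 --seed 17 --out-matrix A.tsv --out-labels L.tsv
$ swiss simulate --delta 0.0 --seed 18 --out-matrix B.tsv --out-labels Lb.tsv
$ swiss compare --matrix-a A.tsv --matrix-b B.tsv --labels L.tsv --permutations 1000 --seed 17
SWISS A  = 0.8772
SWISS B  = 0.9727
p_better = 0.0070
p_worse  = 0.0040
null 90% CI = [0.8902, 0.9556]
verdict  = A_better
```

Method A's score sits in the extreme left tail of the permuted null
population and B's in the right tail, so both p-values are below 0.05 and A
is significantly better.

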