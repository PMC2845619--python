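# Methods

## The score

For a features × samples matrix with every sample assigned to one of `k`
a-priori classes, SWISS is `WISS / SST`: the total within-class sum of
squared Euclidean distances to class means, divided by the total sum of
squared distances to the overall mean. It is the proportion of variation the
class structure leaves unexplained, the complement of the ANOVA
between/total variance ratio. Three invariances follow directly from the
definition and are what make cross-method comparison legitimate: SWISS is
unchanged by global rescaling, by adding a constant vector to every sample,
and by orthogonal rotation of feature space. It is *not* invariant to
per-feature standardization — deliberately so, since standardization is
itself a processing choice under evaluation.

Assumptions and conventions:

- Distances are Euclidean between sample columns; no other metric is
  offered.
- Matrices must be complete. Missing values are a preprocessing concern
  (imputation changes the data being scored), so the readers and
  constructors reject them with the offending feature/sample named.
- Samples are joined to labels by sample id, never by position, and the
  join must be exact in both directions: an unlabeled sample and a label
  for an absent sample are both errors.
- Singleton classes are allowed with a warning (labelings derived from
  clustering can produce them) but note that a singleton contributes 0 to
  WISS and thus deflates the score.
- Computation is two-pass (means first, then squared deviations) in double
  precision; the one-pass `Σx² − N·m²` form is avoided because it cancels
  catastrophically. Rounding in the two mean reductions can leave
  `WISS/SST` one ulp above 1 in degenerate cases (e.g. `k = 1`), so the
  ratio is clamped into [0, 1]; SST, WISS and the per-sample contributions
  are reported unclamped.

## The permutation test

To decide whether method A's SWISS is significantly lower than method B's on
the same samples, a null population of `B` scores (default 1000) is built
from hybrid datasets. The unit that is resampled is each sample's
*standardized contribution* `‖x_j − x̄_class(j)‖² / SST`, which is
dimension-free and sums to the SWISS score — the property that lets the test
compare methods living in different feature spaces. For each hybrid, every
sample independently contributes either its method-A or its method-B value
(fair coin); class means stay fixed at each method's observed means. Among
the possible schemes (recomputing class means per hybrid, permuting in blocks)
this is the one that respects the per-sample decomposition exactly and needs
no common feature space, which is why it was chosen.

Decision rule: `p_better` is the proportion of null scores ≤ the smaller
observed score, `p_worse` the proportion ≥ the larger; inequalities are
non-strict (ties count as extreme) and no add-one smoothing is applied, so
identical inputs give `p = 1.0` exactly. A method is declared better only
when its observed score is strictly smaller *and both* p-values fall below α
(default 0.05). The null's 5th and 95th nearest-rank percentiles form the
reported 90% confidence interval. The both-p rule is conservative: in the
simulations below its measured false-call rate at α = 0.05 is far under the
nominal level, and its power is low for small separations, rising steeply
once the separation is large (see `scripts/acceptance.py`).

Implementation notes:

- Coin flips are drawn as one `B × N` uniform block (iterations over rows,
  samples in sorted-id order over columns, C layout) from a single
  `numpy.random.default_rng(seed)`; a given seed reproduces the report
  bit-for-bit across runs and releases.
- Observed scores used for the tail counts are the contribution *sums*,
  the same floating-point reduction used for each null score, so the
  degenerate identical-methods case is exact rather than
  tolerance-dependent.
- `exhaustive_test` enumerates all `2^N` hybrids (N ≤ 20) and serves as
  the exact small-N oracle against which the sampler is validated.
- Comparisons of more than two methods are run as all pairwise tests with
  no multiplicity correction by default (a Bonferroni flag exists).

## Perfect-feature calibration

One ideal feature per class: average every gene over the class's samples,
then assign the maximum of those averages to the class's samples and the
minimum to all others (the extremes are taken within each class's own
averages). Such a feature has zero within-class variance, so appending all
`k` of them leaves WISS unchanged while adding nonnegative between-class
variation to SST: the enhanced score can only be ≤ the original, with
equality only when every class's averages are all equal (the feature is then
constant; it is kept, with a warning, so the count is always `k`). New
features are named `PERFECT::<class>`; a collision with an existing id is an
error rather than a silent rename. The enhanced score is reported alongside
the original rather than converted into a verdict: whether a rival method
clears it is interpretive guidance, and the calibration is sensitive to how
the gene set was filtered beforehand. Augmenting an already-augmented matrix
lowers the score again — the construction is not idempotent.

## Variance-filtering sweeps

Features are ranked by decreasing across-sample variance (unbiased, `N−1`
divisor; ties broken by feature id so the ranking is deterministic) and
SWISS is recomputed keeping the top `m` for a grid of counts — by default
powers of two from 16 up to, and always including, the full feature count.
Restriction keeps the matrix's original row order (the ranking only selects
the retained *set*), so the `m = d` level reproduces the unfiltered score
bit-exactly. With two methods the ranking can come from either method and be
applied to both (requiring a shared gene universe) or be derived
independently per method; with `--ci`, a full permutation test runs at every
level, each with its own seed substream derived from the master seed and the
count value, so adding grid points never perturbs existing levels. Per-count
confidence bars were preferred over a single full-set test because the null
distribution changes with the retained gene set. The sweep is descriptive:
it is not a gene-set selector, and choosing the count that minimizes SWISS
would overfit.

## Synthetic data

The generator draws K-class Gaussian data: `d_informative` features whose
class means sit at `0, δ, 2δ, ...` (class `i` offset `i·δ` on every
informative axis — the simplest layout that generalizes a two-cluster toy
geometry), plus `d_noise` features that are mean-zero for every class,
modelling genes with little variation across samples as opposed to
differentially expressed genes. All features share within-class standard
deviation `σ`; the final matrix is multiplied by a global `scale`, which by
the invariances above must not change SWISS and is used to exercise exactly
that. Defaults — `k = 2`, 20 samples per class, 10 informative + 90 noise
features, `δ = 2`, `σ = 1`, `scale = 1` — describe a moderately separated
two-class experiment: strong enough that the permutation test should detect
it against noise, weak enough that the test is genuinely exercised.

What the generator does *not* emulate: microarray noise structure (dye bias,
background, probe effects), count distributions of sequencing data,
correlated genes, batch effects, or missingness. Passing simulations
therefore demonstrate the statistical machinery — calibration of the test,
the closed-form null mean `E[SWISS] = (N−k)/(N−1)` for labels carrying no
information, power growth with separation — not robustness to real-platform
artifacts.

## Simulation sizes

The error-rate and power studies use 200 null pairs and 100 replicates per
separation level, at `N = 40`, `B = 1000` permutations; the null-expectation
check uses 2000 replicates at `N = 60`, `k = 3`. These sizes give binomial
standard errors a few percent wide, adequate for the one-decimal claims made
of them, and keep the whole suite comfortably fast.

## File formats and reports

Matrices are rectangular TSV/CSV tables (first column feature id, header row
sample ids, decimal points only); labels are two-column tables whose
optional header is recognized by conventional column names
(`sample`/`sample_id`/`id` and `class`/`label`/`group`/...) — the content of
the columns cannot distinguish a header, since class labels are routinely
non-numeric. JSON reports carry full-precision doubles plus the resolved
configuration, tool version, seed and input checksums (human-readable output
is rounded to 4 decimals); their shape is documented in
`docs/report.schema.json`. Vendor formats (GCT, SOFT, CEL) are out of scope.

## Known limitations

- Euclidean distance only; heavy-tailed or count data should be transformed
  upstream if that is inappropriate.
- The permutation scheme holds class means fixed; it does not model
  uncertainty in the means themselves, which matters most at very small N
  (where `exhaustive_test` at least removes sampling error in the null).
- The both-p decision rule trades power for conservatism; small true
  differences will often return "no significant difference".
- The perfect-feature calibration depends on the filtering state of the
  input and should be recomputed after any change to the gene set.
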