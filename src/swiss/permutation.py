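"""Permutation test comparing two processing methods by SWISS.

Two processing methods applied to the same samples (the matrices may
have entirely different feature sets and dimensionalities) each yield a
SWISS score.  To decide whether the lower score is significantly lower,
a null population of SWISS scores is built from hybrid datasets: each
sample's *standardized* within-class contribution (its squared distance
to its class mean divided by that method's SST, see
:class:`swiss.core.SwissResult`) is attributed to method A or method B
by a fair coin, independently per sample, and the contributions are
summed.  Standardized contributions are dimension-free, which is what
makes the null construction work across methods of different
dimensionality; class means are held fixed at each method's observed
means.

Two empirical p-values are reported: the proportion of null scores at or
below the smaller observed score (``p_better``) and the proportion at or
above the larger observed score (``p_worse``).  A method is declared
significantly better only when it has the strictly smaller SWISS score
and *both* p-values fall below ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import ClassAssignment, ExpressionMatrix, swiss_score

__all__ = [
    "MethodPair",
    "PermutationReport",
    "per_sample_contributions",
    "permutation_test",
    "exhaustive_test",
    "all_pairwise_tests",
]

_EXHAUSTIVE_LIMIT = 20


def per_sample_contributions(X: ExpressionMatrix, C: ClassAssignment) -> dict[str, float]:
    """Each sample's standardized within-class contribution.

    ``contribution_j = ||x_j - class_mean(j)||^2 / SST``; the values sum
    to the SWISS score of ``(X, C)``.
    """
    return swiss_score(X, C).contributions_by_sample()


@dataclass(frozen=True)
class MethodPair:
    """Two expression matrices over the same samples, with shared labels."""

    matrix_a: ExpressionMatrix
    matrix_b: ExpressionMatrix
    labels: ClassAssignment
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        sa, sb = set(self.matrix_a.sample_ids), set(self.matrix_b.sample_ids)
        if sa != sb:
            diff = sorted(sa ^ sb)
            raise ValueError(
                "the two matrices must cover the same samples; differing ids: " + ", ".join(diff)
            )

    @property
    def n_samples(self) -> int:
        return self.matrix_a.n_samples


@dataclass(frozen=True)
class PermutationReport:
    """Outcome of a two-method SWISS comparison.

    ``verdict`` is ``"A_better"`` / ``"B_better"`` (referring to
    ``method_a`` / ``method_b``) when that method has the strictly
    smaller observed SWISS and both p-values are below ``alpha``, else
    ``"no_significant_difference"``.  ``ci90`` is the nearest-rank 5th
    and 95th percentile of the null population.  ``seed`` is ``None``
    for the exhaustive (exact) test, which has no randomness.
    """

    method_a: str
    method_b: str
    swiss_a: float
    swiss_b: float
    null_scores: np.ndarray
    p_better: float
    p_worse: float
    ci90: tuple[float, float]
    alpha: float
    verdict: str
    B: int
    seed: Optional[int]
    exact: bool = False

    def to_dict(self, include_null: bool = True) -> dict:
        out = {
            "method_a": self.method_a,
            "method_b": self.method_b,
            "swiss_a": self.swiss_a,
            "swiss_b": self.swiss_b,
            "p_better": self.p_better,
            "p_worse": self.p_worse,
            "ci90": [self.ci90[0], self.ci90[1]],
            "alpha": self.alpha,
            "verdict": self.verdict,
            "B": self.B,
            "seed": self.seed,
            "exact": self.exact,
        }
        if include_null:
            out["null_scores"] = [float(x) for x in self.null_scores]
        return out


def _nearest_rank(sorted_scores: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic."""
    n = len(sorted_scores)
    rank = max(math.ceil(q * n), 1)
    return float(sorted_scores[rank - 1])


def _aligned_contributions(pair: MethodPair) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Contributions of both methods in canonical (sorted-id) sample order."""
    order = sorted(pair.matrix_a.sample_ids)
    ca = per_sample_contributions(pair.matrix_a, pair.labels)
    cb = per_sample_contributions(pair.matrix_b, pair.labels)
    return order, np.array([ca[s] for s in order]), np.array([cb[s] for s in order])


def _build_report(
    pair: MethodPair,
    null_scores: np.ndarray,
    obs_a: float,
    obs_b: float,
    alpha: float,
    seed: Optional[int],
    exact: bool,
) -> PermutationReport:
    lo, hi = min(obs_a, obs_b), max(obs_a, obs_b)
    p_better = float(np.mean(null_scores <= lo))
    p_worse = float(np.mean(null_scores >= hi))
    srt = np.sort(null_scores)
    ci90 = (_nearest_rank(srt, 0.05), _nearest_rank(srt, 0.95))
    significant = p_better < alpha and p_worse < alpha
    if significant and obs_a < obs_b:
        verdict = "A_better"
    elif significant and obs_b < obs_a:
        verdict = "B_better"
    else:
        verdict = "no_significant_difference"
    return PermutationReport(
        method_a=pair.name_a,
        method_b=pair.name_b,
        swiss_a=obs_a,
        swiss_b=obs_b,
        null_scores=null_scores,
        p_better=p_better,
        p_worse=p_worse,
        ci90=ci90,
        alpha=alpha,
        verdict=verdict,
        B=len(null_scores),
        seed=seed,
        exact=exact,
    )


def permutation_test(
    pair: MethodPair,
    B: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> PermutationReport:
    """Monte-Carlo SWISS permutation test.

    Each of the ``B`` null scores sums, over samples in sorted-id order,
    a fair-coin choice between the sample's method-A and method-B
    standardized contribution.  Coin flips are drawn as a single
    ``B x N`` uniform block (iterations over rows, samples over columns,
    C order), so results are bit-reproducible for a given ``seed``.  If
    ``seed`` is None a fresh one is drawn and recorded in the report.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    _, ca, cb = _aligned_contributions(pair)
    rng = np.random.default_rng(seed)
    flips = rng.random((B, len(ca))) < 0.5
    null_scores = np.where(flips, ca, cb).sum(axis=1)
    # Observed scores as contribution sums, the same reduction used for
    # the null, so the identical-methods case gives p = 1.0 exactly.
    return _build_report(pair, null_scores, float(ca.sum()), float(cb.sum()), alpha, seed, exact=False)


def exhaustive_test(pair: MethodPair, alpha: float = 0.05) -> PermutationReport:
    """Exact version of :func:`permutation_test` enumerating all 2^N hybrids.

    Only feasible for small sample sets (N <= 20); p-values are exact
    proportions over the full hybrid population.
    """
    n = pair.n_samples
    if n > _EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"exhaustive enumeration of 2^{n} hybrids is infeasible (N > "
            f"{_EXHAUSTIVE_LIMIT}); use permutation_test instead"
        )
    _, ca, cb = _aligned_contributions(pair)
    null_scores = np.zeros(1)
    obs_a = obs_b = 0.0
    for j in range(n):
        null_scores = np.concatenate([null_scores + cb[j], null_scores + ca[j]])
        # accumulate observed scores in the same left-to-right order as the
        # enumerated hybrids, so the all-A / all-B hybrids match them bit-exactly
        obs_a += ca[j]
        obs_b += cb[j]
    return _build_report(pair, null_scores, float(obs_a), float(obs_b), alpha, seed=None, exact=True)


def all_pairwise_tests(
    methods: Mapping[str, ExpressionMatrix],
    labels: ClassAssignment,
    B: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    bonferroni: bool = False,
) -> list[PermutationReport]:
    """Permutation tests for every unordered pair of named methods.

    No multiplicity correction by default; ``bonferroni=True`` divides
    ``alpha`` by the number of pairs before each verdict.
    """
    names = list(methods)
    n_pairs = len(names) * (len(names) - 1) // 2
    if n_pairs == 0:
        raise ValueError("need at least two methods to compare")
    eff_alpha = alpha / n_pairs if bonferroni else alpha
    ss = np.random.SeedSequence(seed)
    reports = []
    for idx, (i, j) in enumerate((i, j) for i in range(len(names)) for j in range(i + 1, len(names))):
        pair = MethodPair(methods[names[i]], methods[names[j]], labels, names[i], names[j])
        child = int(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(idx,)).generate_state(1)[0] % (2**31))
        reports.append(permutation_test(pair, B=B, alpha=eff_alpha, seed=child))
    return reports
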